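# Methods

## Problem setting

High-throughput behavioral screening records larval zebrafish in 96-well
plates under a programmed battery of stimuli (light transitions, acoustic
pulses, plate taps).  Each well's video is condensed to a motion index
(MI): per frame, the number of pixels whose grayscale intensity changed by
at least 10 units since the previous frame,

    m'(I^t) = #{ (i,j) : |I_ij^t − I_ij^(t−1)| ≥ 10 },   t = 2 … T.

The scientific object of this package is a *phenotypic distance* between
MI traces: given two wells, how similar are the behaviors they evoke?  The
conventional answer — Pearson correlation distance on the raw traces —
weights every frame equally and assumes frame-level alignment between
replicates, both of which fail for probabilistic, latency-jittered startle
responses.  The package's core is a learned alternative.

## Twin-network metric learning

Two parameter-sharing encoder branches map each member of a trace pair to
a 10-dimensional embedding; training minimizes the contrastive loss

    L = ½ d²                    for same-compound pairs,
    L = ½ max(0, m − d)²        for different-compound pairs,

with d the Euclidean embedding distance and margin m = 0.5.  Positive
pairs are two replicates of the same compound; negatives pair different
compounds.  The learned phenotypic distance is the embedding distance of a
trained encoder.

Two encoders are implemented:

* **Twin-NN** — a feed-forward network.  At canonical scale the input is
  the stride-5 subsample of a 101,250-frame trace (20,250 samples) and the
  layer widths are 4000, 500, 250, 100, 10, with batch normalization and
  ReLU after every linear layer except the last (six layers counting the
  input layer).
* **Twin-DN** — a 1-D DenseNet-style encoder: an initial convolution, three
  dense blocks (growth 12, four BN-ReLU-conv layers each) with transition
  pooling, global average pooling and a linear head to the embedding.  The
  dense-block dimensions are configurable; the defaults are the package's
  own choice since only the design family is prescribed.

Training follows the published recipe: Adam at learning rate 5e-4 with
weight decay 1e-6, batch size 32 (Twin-NN) or 8 (Twin-DN), pair order
randomly swapped per epoch, traces subsampled at stride 5 and min-max
normalized against frozen dataset bounds (0–6750 MI units).  The entire
stack — layers, backpropagation, Adam — is implemented on numpy arrays
with hand-derived gradients (verified against central finite differences
in the test suite), and is fully seeded: identical configuration gives
bit-identical training.

**Convergence rule.** The epoch cap and stopping rule are not prescribed,
so the package holds back a seeded 15% of *training* pairs and stops when
their pair AUROC has not improved for `patience` epochs (default 10;
desk-scale configs use 40), restoring the best snapshot.  The contrastive
validation loss itself is recorded but not used for stopping: it can drift
upward while ranking quality still improves, because nothing anchors the
absolute scale of positive-pair distances.  The drug-held-out test split
is never consulted during training.

**Desk-scale configuration.** `reduced_twin_config()` targets 5,000-frame
traces (stride-5 input of 1,000 samples) with hidden widths 600, 300, 150,
75.  The widths are deliberately wider, relative to the input, than the
canonical architecture: with only hundreds of training pairs (vs. ~10⁵ at
full scale) the narrower proportional network underfits unseen drugs,
which we measured as a 0.02–0.05 held-out AUROC deficit.

## Pair construction

Drugs — never wells — are split 80/20 into train/test, so no replicate of
any drug crosses the partition.  All same-drug pairs whose two members are
labeled active form the drug–drug positives; cross-drug negatives are
subsampled to match the positive count exactly.  A quarter of the final
positives come from control–control and tox–tox pairs (split evenly) and a
quarter of the negatives from control–drug, control–tox and tox–drug
(split evenly, ±1 pair): the quota shares are stated against the *total*,
so the total is solved as drug-drug-positives / 0.75.  When a bucket lacks
candidates (e.g., too few lethal wells for the tox–tox quota) the
shortfall is reallocated proportionally to the remaining buckets with a
logged warning.  Control wells are shared between the splits by design;
consequences for null-control evaluation are handled below.

## Activity filtering

Wells are labeled active / inactive (vehicle-like) / lethal by a random
forest on raw MI vectors (500 trees by default, seeded), with classes
balanced by seeded undersampling to the minority class and an 80/20 split
reporting held-out accuracy.  Vehicle wells seed the inactive class and
eugenol wells the lethal class.  Two deliberate choices:

* **Role precedence** — a vehicle well is never used as an "active" pair
  member regardless of the forest's opinion; lethal controls always feed
  the tox buckets.
* **Out-of-bag relabeling** — wells that were part of the forest's
  training set are scored with their out-of-bag votes rather than
  in-sample predictions.  Without this, an unconstrained forest memorizes
  its training wells and can never call a training drug inactive, which
  defeats the filter's purpose.

A drug's "phenotype strength" is the forest's P(active) averaged over its
replicates (the probability is the natural score; no formula is
prescribed).

## The synthetic screen generator

The simulator produces the statistical structure the method assumes, with
known ground truth.  Per 96-well plate: 8 DMSO + 2 H2O vehicle controls
(treated identically throughout) and 2 eugenol lethal controls at
canonical edge-column positions; the remaining 84 wells carry drugs.  Each
drug belongs to one phenotype class and is replicated on 7–10 plates
(seeded per drug).  In `fixed` layout mode every replicate of a drug sits
at the same well across plates (the naive screen design); in `randomized`
mode drugs are permuted over the treatment positions per plate.  Treatment
positions a drug does not occupy on a given plate are filled with extra
vehicle wells so every plate is complete.

A trace is built from a class response template keyed to the stimulus
schedule — sustained responses during light epochs, sharp exponentially
decaying startle bursts at acoustic/tap epochs, plus a tonic baseline —
with these replicate-level variability sources:

* startle responses fire with probability 0.75 per presentation, with
  per-presentation log-normal gain (σ = 0.3) and Gaussian latency jitter
  (σ = 35 frames ≈ 1.4 s) — fish startle probabilistically and with
  variable vigor and timing;
* light responses and baseline are replicate-stable apart from gain
  jitter — tonic/photic behavior is the reliable component;
* a global log-normal well amplitude (σ = 0.25) models fish number/size;
* additive truncated-Gaussian noise (σ = 25 MI units) plus
  first-difference-filtered "sensor" noise (σ = 12) whose power
  concentrates near the frame-rate Nyquist;
* camera-level spikes at light-epoch transitions in *every* well
  (amplitude 400 MI): a global illumination change flips pixels across the
  whole frame, so even a well with motionless fish shows MI spikes at
  light onsets.  Lethal wells are this common component plus a ~3 MI
  baseline and 10% residual noise, which keeps their mean below 2% of an
  active well's.

Class identity lives in the response gains, latencies, decay constants and
baseline level (`class_separation` scales all of them and is the
separability dial); drugs within a class perturb their class template by
±45%, and inactive drugs (default 25%) are behaviorally vehicle-identical.
These settings reproduce the qualitative regime reported for real screens:
correlation distance achieves roughly 0.70–0.85 pair AUROC (hurt by
latency jitter and unreliable bursts, which dominate the trace variance it
weights), Euclidean distance slightly less (additionally hurt by amplitude
jitter), and the trained twin network exceeds both by exploiting the
replicate-stable tonic and photic levels that mean-centered correlation
cannot see.

**What the simulator does not model:** per-fish motion, dose–response,
habituation across repeated stimuli, plate-edge evaporation effects,
temporal drift across a screening day, or the true spectral shape of the
real rig's positional irregularities.  Passing tests on this generator
therefore demonstrate that the pipeline recovers planted structure of the
kinds described — not that the learned metric's advantage transfers to any
particular real screen.

## The planted positional artifact

The shortcut-learning experiments plant a deterministic well-position-keyed
component: a cosine at 0.45 cycles/frame (just below Nyquist) whose
amplitude and phase vary smoothly with (row, column).  Two wells at the
same position on different plates receive the identical signal.  The
frequency is chosen so the component *aliases into* stride-5 subsampled
model inputs (0.45 → 0.25 cycles/sample) but is attenuated ≥ 90% by the
Hanning window-11 smoother — mirroring a high-frequency positional
irregularity that smoothing removes.  The real artifact's spectral shape
is uncharacterized; this single-tone model is a stand-in and is labeled as
such.  At desk scale the planted amplitude (400 MI units in the shortcut
fixtures) is larger than anything "imperceptible": with only ~600 training
pairs the model needs a stronger cue to latch onto than it would with the
~10⁵ pairs of a full screen.  The shortcut *mechanism* — fixed layouts make
position a perfect proxy for compound identity; randomized layouts destroy
the proxy — is scale-independent.

In the fixed-layout fixture the trained model scores pair AUROC ≥ 0.9 and
loses ≥ 0.10 of it when inputs are Hanning-smoothed before subsampling; in
the randomized-layout fixture the smoothing delta is within ±0.05.  The
shortcut fixtures use `class_separation = 0.4` (subtle phenotypes), since
a model with access to strong behavioral signal has little incentive to
exploit the artifact.

## Stress-test design notes

* **Label shuffling / input randomization** retrain from scratch (permuted
  labels with counts preserved / uniform random traces on the observed MI
  range) and must collapse to held-out AUROC ≈ 0.5.  "Held-out" is
  evaluated on drug–drug test pairs only: control wells appear in quota
  pairs of *both* splits, so a model can legitimately memorize their
  traces, and including them inflates a null that should be flat.
* **Well-distance prediction** relabels pairs by within-plate coordinate
  distance (well-pitch units; plate identity ignored, since the 2 and 5.2
  cutoffs are within-plate scales) and trains the twin model on these
  labels.  Two confounds are excluded by construction: only treatment
  wells are sampled (control wells sit at canonical positions, so role
  alone predicts position), and wells — not pairs — are split 80/20, so a
  per-well positional fingerprint memorized from training pairs cannot be
  replayed on test pairs.  On artifact-free randomized screens the
  held-out AUROC sits at chance; with a planted artifact it rises far
  above it, which is the positive control for the diagnostic.

## Downstream analyses

* **Replicate identification:** for every drug well, count same-drug
  replicates among its top-50 nearest wells (self excluded); per drug take
  the maximum over its wells (a per-well mean is available behind a flag);
  report the cumulative number of drugs with ≥ k replicates found.
* **kNN on QC drugs:** k = 15 neighbors over a replicate-level distance
  matrix, 8 train / 2 validation replicates per drug; ties break by summed
  distance then lexicographic drug id.  k exceeding the per-drug training
  replicate count is intentional (neighbors pool across drugs).
* **Behaviorome maps:** per-compound mean traces → distance matrix → a 2-D
  embedding of the precomputed distances (UMAP, n_neighbors = 10,
  min_dist = 0.1, seeded; the embedder is pluggable).
* **Phenosearch:** rectangular query × library distance matrix; per query
  the library is ranked ascending (ties by id) and truncated to the top
  500.  A library compound is a *hit* when its binary target profile
  shares ≥ 1 target with the query's (the threshold is configurable; no
  precise matching rule is prescribed).  The random baseline at sample
  fraction f is f × (total hits among ranked compounds) — the
  hypergeometric mean under uniform ordering — validated against a
  permutation oracle in the tests.  Target profiles come from a pluggable
  provider: synthetic ground truth, or a file of precomputed predictions
  (e.g., similarity-ensemble output); no target-prediction method is
  reimplemented.
* **Scaffold hopping:** all unordered compound pairs annotated with
  structural Tanimoto distance (ECFP4-equivalent Morgan radius-2/2048-bit
  fingerprints via rdkit when SMILES are available, otherwise supplied or
  synthetic fingerprints), phenotypic distance, and target-profile
  Tanimoto similarity.  Candidates pass target similarity > 0.2, structure
  distance > 0.5 and phenotypic distance < 0.3; quadrant labels use cuts
  at phenotypic 0.3 / structural 0.4.

An important consequence of the contrastive objective: same-class
*different-drug* pairs are negatives, so the model actively separates
drugs it trained on even when their phenotypes are similar.  Library
ranking and quadrant analyses therefore operate on compounds the model
has never seen (a separately simulated library sharing class templates via
`template_seed`), where class neighborhoods are preserved — which matches
the intended use of querying one screened library against another.

## Numerical choices and degenerate inputs

* Correlation distance of a zero-variance trace is defined as 1 with a
  warning (no correlation information).
* Tanimoto similarity of two empty fingerprints is defined as 0 with a
  warning.
* Hanning smoothing uses a unit-sum window with reflection padding; the
  window must be odd, ≥ 3 and no longer than the trace.
* The banded DTW uses the classic coarsen–project–refine scheme with
  radius 1 by default; an unbounded radius reproduces the exact dynamic
  program, which serves as its oracle.  Radius and step pattern are
  dialect parameters (absolute-difference local cost, standard three-way
  step).
* Traces shorter/longer than a model's expected input are right-truncated
  or zero-padded after subsampling.
* The twin stack computes in float32 (float64 available layer-wise for
  gradient testing); batch normalization uses ε = 1e-5 and momentum 0.1
  with unbiased running variance.

## Benchmark problem sizes

The bundled benchmarks run on reduced screens chosen to exercise every
pipeline stage at desk scale: 24 pseudo-drugs × 8 replicates across 8
plates (metric learning, shortcut contrast, replicate identification,
phenosearch with a 40-drug library), 84 drugs × 9 replicates for the
null-control battery (so held-out drug–drug pair counts exceed 1,000), and
5,000-frame traces throughout.  Canonical 101,250-frame traces and the
full-width architecture are supported by configuration.  Benchmark
quantities vary by a few hundredths of AUROC across generator seeds; the
documented margins hold at the canonical seeds used in the test suite.

## Known limitations

* The reduced-scale twin models are trained on hundreds of pairs; their
  absolute AUROCs are not comparable to full-scale screens.
* The distance scale of a trained embedding is arbitrary (bounded loosely
  by the margin); the 0.3 phenotypic-distance threshold in the quadrant
  analysis is meaningful for the trained models shipped in the benchmarks
  but should be recalibrated for new training runs.
* The Twin-DN encoder is implemented and gradient-verified, but the
  shipped benchmarks train Twin-NN only; at desk scale the convolutional
  model's extra cost buys no measurable benefit on 1,000-sample inputs.
* `fastdtw`-style banded DTW is O(n) per level but implemented in Python;
  at the canonical 101,250-frame length it is usable but slow — baseline
  comparisons at that scale should prefer correlation/Euclidean or
  subsampled DTW.
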