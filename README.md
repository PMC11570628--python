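# phenotwin

Twin-network metric learning for high-throughput behavioral screening.

Larval-zebrafish screens record each well of a 96-well plate under a
battery of stimuli and condense the video to a **motion index** (MI): per
frame, the number of pixels whose grayscale intensity changed by ≥ 10
units,

```
m'(I^t) = Σ_ij 1[ |I_ij^t − I_ij^(t−1)| ≥ 10 ]
```

Screening questions — *do these two wells show the same phenotype? which
library compounds mimic this drug?* — reduce to a distance between MI
traces.  The traditional choice, Pearson correlation distance, weights all
frames equally and assumes frame-level alignment, which fails for
probabilistic, latency-jittered startle responses.  `phenotwin` learns a
distance instead: a **twin (Siamese) network** embeds each trace and is
trained with a contrastive loss — ½d² for replicate pairs of the same
compound, ½·max(0, m − d)² (margin m = 0.5) for mismatched pairs — so
phenotypic similarity becomes Euclidean distance in the embedding.

The package is aimed at screening groups and methods developers who want
to (a) build and evaluate learned phenotypic distances from high-replicate
screens, (b) audit them for **shortcut learning** — models silently
reading plate-position artifacts from high-frequency trace components
instead of behavior — and (c) use the distance for replicate
identification, phenotypic library search ("phenosearch") and
scaffold-hopping analysis.  A seeded synthetic screen simulator with known
ground truth (phenotype classes, activity, target profiles, an optional
planted positional artifact) makes the whole pipeline testable at desk
scale.

## What's inside

| module | contents |
|---|---|
| `synthetic_data` | seeded screen simulator: 96-well plates, 7–10 replicates/drug, DMSO/H2O + eugenol controls, fixed vs. randomized layouts, planted near-Nyquist positional artifact |
| `motion_index` | MI from grayscale frame stacks; min-max normalization, stride subsampling, Hanning smoothing |
| `activity_filter` | random-forest active/inactive/lethal well labeling with balanced undersampling |
| `pair_builder` | drug-wise 80/20 splits, positive/negative pairs, exact balance, 25% control/tox quotas |
| `metric_models` | Twin-NN (feed-forward) and Twin-DN (1-D DenseNet) contrastive encoders, numpy training stack, checkpoints |
| `distances` | correlation, Euclidean, banded (FastDTW-style) and exact DTW, distance matrices |
| `evaluation` | pair ROC/PRC, kNN drug identification, top-50 replicate-ID curves, UMAP behaviorome maps |
| `stress_tests` | smoothing ablation, label shuffling, input randomization, well-distance prediction |
| `phenosearch` | library ranking, target-profile enrichment curves, control contamination, ECFP4/Tanimoto scaffold-hop quadrants |
| `io` / `cli` | trace-table formats, run configuration, `phenotwin` subcommand CLI |

## Worked example

Train a twin model on a simulated randomized screen and compare it with
the conventional distances:

```python
import numpy as np
from phenotwin import (SimConfig, generate_screen, build_pair_dataset,
                       build_twin_model, train, correlation_distance)
from phenotwin.activity_filter import train_activity_classifier, label_wells
from phenotwin.metric_models import reduced_twin_config, evaluate_pairs
from phenotwin.evaluation import mann_whitney_auroc

cfg = SimConfig(n_plates=8, n_drugs=24, replicates_per_drug=(8, 8),
                n_phenotype_classes=8, inactive_fraction=0.0,
                trace_length=5000, layout_mode="randomized", seed=0)
screen, truth = generate_screen(cfg)

rf = train_activity_classifier(screen, mode="binary", seed=0, n_trees=100)
labels = label_wells(rf, screen)
pairs = build_pair_dataset(screen, labels, seed=0)

model = train(build_twin_model(reduced_twin_config(seed=0)),
              pairs, screen.traces)

scores = evaluate_pairs(model, pairs, screen.traces, "test")
ia, ib, y = pairs.subset("test").arrays()
corr = [correlation_distance(screen.traces[a], screen.traces[b])
        for a, b in zip(ia, ib)]
print(f"learned AUROC     {mann_whitney_auroc(scores.distances, scores.labels):.3f}")
print(f"correlation AUROC {mann_whitney_auroc(np.array(corr), y):.3f}")
```

```
learned AUROC     0.875
correlation AUROC 0.768
```

The test split holds drugs the model never saw; the learned distance
separates same-drug from different-drug pairs about 0.11 AUROC better than
correlation distance, because it keys on replicate-stable tonic and photic
activity levels rather than on frame-aligned startle bursts.

The same pipeline runs from the shell:

```bash
phenotwin --seed 0 simulate screen/          # + ground_truth.json sidecar
phenotwin --seed 0 filter screen/ labels.csv
phenotwin --seed 0 pairs screen/ labels.csv pairs.csv
phenotwin --seed 0 train screen/ pairs.csv model.npz
phenotwin --seed 0 evaluate screen/ pairs.csv report.json --model model.npz
phenotwin --seed 0 stress screen/ pairs.csv model.npz stress.json
```

### Auditing for shortcut learning

On a *fixed-layout* screen with a planted well-position artifact, every
replicate of a drug sits at the same well, so position is a perfect proxy
for compound identity and the model exploits the artifact's near-Nyquist
component — pair AUROC looks excellent but collapses when inputs are
Hanning-smoothed first.  On the *randomized* counterpart the proxy is
destroyed and smoothing changes nothing:

```python
from phenotwin.stress_tests import smoothing_ablation
report = smoothing_ablation(model, pairs, screen.traces, window=11)
print(report.baseline_auroc, report.perturbed_auroc)
```

At the benchmark settings the fixed-layout model scores 0.941 raw and
drops by 0.161 under smoothing; the randomized-layout model moves by less
than 0.03.  `label_shuffle_test`, `random_input_test` and
`well_distance_test` complete the audit battery (all ≈ 0.5 held-out AUROC
on clean data).

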