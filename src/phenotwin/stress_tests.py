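"""Shortcut-learning diagnostic battery.

A twin model that scores well may be exploiting artifactual cues rather
than behavior.  Four diagnostics probe this:

* smoothing ablation — re-score pairs on Hanning-smoothed traces; a large
  AUROC drop means the model leaned on high-frequency components;
* label shuffling — retrain with permuted pair labels; held-out AUROC
  should collapse to 0.5;
* input randomization — retrain on random traces of the original length
  with labels fixed; held-out AUROC should collapse to 0.5;
* well-distance prediction — relabel pairs by plate-coordinate proximity
  (cutoffs in well-pitch units); on artifact-free data the model should
  not be able to predict plate position from the traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import mann_whitney_auroc
from .io import ScreenDataset
from .metric_models import (TwinModel, TwinModelConfig, build_twin_model,
                            evaluate_pairs, train, _pair_distances)
from .motion_index import smooth_hanning
from .pair_builder import PairDataset

__all__ = [
    "StressReport",
    "smoothing_ablation",
    "label_shuffle_test",
    "random_input_test",
    "well_distance_test",
]


@dataclass
class StressReport:
    test: str
    baseline_auroc: float
    perturbed_auroc: float
    config: dict = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self):
        for a in (self.baseline_auroc, self.perturbed_auroc):
            if np.isfinite(a) and not (0.0 <= a <= 1.0):
                raise ValueError(f"AUROC {a} outside [0, 1]")

    @property
    def delta(self) -> float:
        return self.perturbed_auroc - self.baseline_auroc


class _ArrayPairs:
    """Duck-typed pair container for relabeled/shuffled pair sets.

    Provides the ``subset``/``arrays`` interface that training consumes
    without enforcing pair-class/label consistency (which perturbed labels
    intentionally violate).
    """

    def __init__(self, ia, ib, y, splits, classes=None):
        self.ia = np.asarray(ia)
        self.ib = np.asarray(ib)
        self.y = np.asarray(y)
        self.splits = np.asarray(splits)
        self.classes = np.asarray(classes) if classes is not None else None

    def _mask(self, m):
        return _ArrayPairs(self.ia[m], self.ib[m], self.y[m], self.splits[m],
                           None if self.classes is None else self.classes[m])

    def subset(self, split):
        return self._mask(self.splits == split)

    def drug_drug_only(self):
        """Pairs whose wells are strictly split-private.

        Control and tox wells feed quota pairs in *both* splits, so a model
        can memorize their traces during training; drug wells never cross
        the drug partition.  Null-control AUROCs are therefore evaluated on
        drug-drug pairs.
        """
        if self.classes is None:
            return self
        return self._mask(np.char.startswith(self.classes.astype(str), "drug-drug"))

    def arrays(self):
        return self.ia, self.ib, self.y

    def __len__(self):
        return len(self.ia)


def _pairs_as_arrays(pair_dataset: PairDataset) -> _ArrayPairs:
    ia, ib, y = pair_dataset.arrays()
    splits = np.array([p.split for p in pair_dataset.pairs])
    classes = np.array([p.pair_class for p in pair_dataset.pairs])
    return _ArrayPairs(ia, ib, y, splits, classes)


def smoothing_ablation(model: TwinModel, pair_dataset: PairDataset,
                       traces: np.ndarray, window: int = 11,
                       split: str = "test",
                       retrain_on_smoothed: bool = False) -> StressReport:
    """Pair AUROC on raw vs. Hanning-smoothed inputs (smoothing applied to
    the full-rate traces, before subsampling/normalization).

    With ``retrain_on_smoothed`` a fresh model is trained on the smoothed
    traces instead of re-scoring the given one — the revised-screen check
    that smoothing no longer matters when there is no shortcut to lose.
    """
    if not model.trained:
        raise RuntimeError("smoothing ablation needs a trained model")
    scores_raw = evaluate_pairs(model, pair_dataset, traces, split)
    base = mann_whitney_auroc(scores_raw.distances, scores_raw.labels)
    smoothed = smooth_hanning(traces, window)
    if retrain_on_smoothed:
        fresh = build_twin_model(replace(model.config))
        train(fresh, pair_dataset, smoothed)
        scores_sm = evaluate_pairs(fresh, pair_dataset, smoothed, split)
    else:
        scores_sm = evaluate_pairs(model, pair_dataset, smoothed, split)
    pert = mann_whitney_auroc(scores_sm.distances, scores_sm.labels)
    return StressReport(test="smoothing_ablation", baseline_auroc=base,
                        perturbed_auroc=pert,
                        config={"window": window, "split": split,
                                "retrain_on_smoothed": retrain_on_smoothed})


def _train_and_score(config: TwinModelConfig, pairs: _ArrayPairs,
                     traces: np.ndarray, heldout_only: bool = False) -> float:
    model = build_twin_model(config)
    train(model, pairs, traces)
    X = model.preprocess(traces)
    test = pairs.subset("test")
    if heldout_only:
        test = test.drug_drug_only()
    ia, ib, y = test.arrays()
    d = _pair_distances(model, X, ia, ib)
    return mann_whitney_auroc(d, y)


def label_shuffle_test(pair_dataset: PairDataset, config: TwinModelConfig,
                       traces: np.ndarray, seed: int = 0,
                       baseline_auroc: float = float("nan")) -> StressReport:
    """Retrain from scratch on permuted labels (inputs fixed); label counts
    are preserved exactly and the permutation is seeded."""
    pairs = _pairs_as_arrays(pair_dataset)
    rng = np.random.default_rng(seed)
    y_shuf = pairs.y.copy()
    for split in ("train", "test"):       # permute within split: counts preserved
        m = pairs.splits == split
        y_shuf[m] = y_shuf[m][rng.permutation(m.sum())]
    shuffled = _ArrayPairs(pairs.ia, pairs.ib, y_shuf, pairs.splits, pairs.classes)
    auroc = _train_and_score(replace(config, seed=config.seed + 1), shuffled, traces,
                             heldout_only=True)
    return StressReport(test="label_shuffle", baseline_auroc=baseline_auroc,
                        perturbed_auroc=auroc, config={"seed": seed},
                        notes="expect held-out AUROC ~ 0.5")


def random_input_test(pair_dataset: PairDataset, config: TwinModelConfig,
                      traces: np.ndarray, seed: int = 0,
                      baseline_auroc: float = float("nan")) -> StressReport:
    """Retrain with every trace replaced by a random vector of the original
    length, drawn uniformly on the observed MI range; labels fixed."""
    rng = np.random.default_rng(seed)
    lo, hi = float(np.min(traces)), float(np.max(traces))
    random_traces = rng.uniform(lo, hi, size=np.asarray(traces).shape)
    pairs = _pairs_as_arrays(pair_dataset)
    auroc = _train_and_score(replace(config, seed=config.seed + 2), pairs, random_traces,
                             heldout_only=True)
    return StressReport(test="random_input", baseline_auroc=baseline_auroc,
                        perturbed_auroc=auroc,
                        config={"seed": seed, "range": (lo, hi)},
                        notes="expect held-out AUROC ~ 0.5")


def well_distance_test(dataset: ScreenDataset, config: TwinModelConfig,
                       cutoffs: tuple[float, ...] = (2.0, 5.2), seed: int = 0,
                       n_pairs: int = 4000) -> list[StressReport]:
    """Train the twin model to predict plate-coordinate proximity.

    Pairs of wells are labeled "same" when their within-plate Euclidean
    coordinate distance (well-pitch units; plate identity ignored) is below
    the cutoff.  Labels are balanced by subsampling, split 80/20, and a
    fresh model trained per cutoff.  On artifact-free data the held-out
    AUROC should sit at chance.
    """
    if any(c <= 0 for c in cutoffs):
        raise ValueError("cutoffs must be > 0")
    # Sample treatment wells only: control wells sit at canonical positions
    # in every layout, so including them would let the model read position
    # from well *role* rather than from positional signal in the traces.
    # Wells (not pairs) are split 80/20 into train/test so the model cannot
    # memorize a per-well positional fingerprint and replay it at test time.
    well_pool = dataset.indices_for_role("drug")
    if len(well_pool) < 20:
        raise ValueError("too few treatment wells for the well-distance test")
    rows = dataset.wells["row"].to_numpy()
    cols = dataset.wells["col"].to_numpy()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(well_pool)
    n_train_wells = int(0.8 * len(perm))
    groups = {"train": perm[:n_train_wells], "test": perm[n_train_wells:]}
    budgets = {"train": int(0.8 * n_pairs) // 2, "test": (n_pairs - int(0.8 * n_pairs)) // 2}

    reports = []
    for cutoff in cutoffs:
        ia_all, ib_all, y_all, split_all = [], [], [], []
        for split_name, wells_g in groups.items():
            # oversample candidates: close pairs are rare under uniform draws
            a = rng.choice(wells_g, size=40 * budgets[split_name])
            b = rng.choice(wells_g, size=40 * budgets[split_name])
            keep = a != b
            a, b = a[keep], b[keep]
            dist = np.hypot(rows[a] - rows[b], cols[a] - cols[b])
            y = (dist < cutoff).astype(int)
            pos = np.flatnonzero(y == 1)
            neg = np.flatnonzero(y == 0)
            k = min(len(pos), len(neg), budgets[split_name])
            if k == 0:
                raise ValueError(f"no pairs on one side of cutoff {cutoff}")
            sel = np.concatenate([pos[:k], neg[:k]])
            ia_all.append(a[sel])
            ib_all.append(b[sel])
            y_all.append(y[sel])
            split_all.append(np.full(2 * k, split_name))
        pairs = _ArrayPairs(np.concatenate(ia_all), np.concatenate(ib_all),
                            np.concatenate(y_all), np.concatenate(split_all))
        n_test = int((pairs.splits == "test").sum())
        auroc = _train_and_score(replace(config, seed=config.seed + 3), pairs,
                                 dataset.traces)
        reports.append(StressReport(
            test="well_distance", baseline_auroc=float("nan"),
            perturbed_auroc=auroc,
            config={"cutoff": cutoff, "seed": seed, "n_test_pairs": n_test},
            notes="expect ~0.5 on artifact-free data; >0.5 flags positional signal"))
    return reports
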