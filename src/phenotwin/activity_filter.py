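"""Random-forest activity filter for screen wells.

Many library compounds induce no observable behavioral phenotype at the
screening dose, and a few are lethal.  Treating replicates of such drugs
as "positive" pairs would mislabel vehicle-like traces, so wells are first
classified from their raw MI vectors with a random forest:

* binary mode — effective (drug-like) vs. ineffective (DMSO-like);
* ternary mode — effective / ineffective / toxic, with vehicle wells
  seeding the ineffective class and eugenol wells the toxic class.

Training classes are exactly balanced by seeded undersampling to the
minority class, and an 80/20 train/test split reports held-out accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import ROLE_DRUG, ROLE_LETHAL, ROLE_VEHICLE, ScreenDataset

__all__ = [
    "ACTIVE",
    "INACTIVE",
    "LETHAL",
    "ActivityModel",
    "balance_by_undersampling",
    "train_activity_classifier",
    "label_wells",
    "phenotype_strength",
]

ACTIVE, INACTIVE, LETHAL = "active", "inactive", "lethal"


@dataclass
class ActivityModel:
    forest: RandomForestClassifier
    mode: str                       # "binary" | "ternary"
    class_balance: dict[str, int]
    heldout_accuracy: float
    seed: int
    n_features: int
    train_indices: np.ndarray = field(repr=False, default=None)
    test_indices: np.ndarray = field(repr=False, default=None)
    #: well_id -> row in the forest's fit matrix; these wells are scored
    #: with out-of-bag votes so relabeling is never in-sample
    fit_well_rows: dict[str, int] = field(repr=False, default_factory=dict)


def balance_by_undersampling(groups: dict[str, np.ndarray], seed: int = 0) -> dict[str, np.ndarray]:
    """Downsample every class (seeded, without replacement) to the minority size."""
    if not groups or any(len(v) == 0 for v in groups.values()):
        empty = [k for k, v in groups.items() if len(v) == 0]
        raise ValueError(f"empty class(es) in balancing: {empty or 'none provided'}")
    rng = np.random.default_rng(seed)
    n_min = min(len(v) for v in groups.values())
    out = {}
    for name in sorted(groups):
        idxs = np.asarray(groups[name])
        if len(idxs) > n_min:
            idxs = np.sort(rng.choice(idxs, size=n_min, replace=False))
        out[name] = idxs
    return out


def _seed_labels(dataset: ScreenDataset, mode: str) -> dict[str, np.ndarray]:
    roles = dataset.wells["role"].to_numpy()
    groups = {
        ACTIVE: np.flatnonzero(roles == ROLE_DRUG),
        INACTIVE: np.flatnonzero(roles == ROLE_VEHICLE),
    }
    if len(groups[INACTIVE]) == 0:
        raise ValueError("dataset has no vehicle wells")
    if mode == "ternary":
        groups[LETHAL] = np.flatnonzero(roles == ROLE_LETHAL)
        if len(groups[LETHAL]) == 0:
            raise ValueError("ternary mode requires lethal control wells")
    elif mode != "binary":
        raise ValueError(f"mode must be binary|ternary, got {mode!r}")
    return groups


def train_activity_classifier(dataset: ScreenDataset, mode: str = "ternary",
                              split_fraction: float = 0.8, seed: int = 0,
                              n_trees: int = 500,
                              shuffle_labels: bool = False) -> ActivityModel:
    """Fit the forest on raw MI vectors with role-derived seed labels.

    ``shuffle_labels`` permutes training labels (a null control; held-out
    accuracy should collapse to chance).
    """
    groups = balance_by_undersampling(_seed_labels(dataset, mode), seed)
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for name, idxs in groups.items():
        X_parts.append(dataset.traces[idxs])
        y_parts.extend([name] * len(idxs))
    X = np.concatenate(X_parts, axis=0)
    y = np.array(y_parts)
    dataset_rows = np.concatenate([groups[name] for name in groups])
    order = rng.permutation(len(y))
    n_train = int(round(split_fraction * len(y)))
    tr, te = order[:n_train], order[n_train:]
    y_fit = y.copy()
    if shuffle_labels:
        y_fit[tr] = y_fit[tr][rng.permutation(len(tr))]
    # held-out accuracy from the 80/20 split; the deployed (labeling) forest
    # is then refit on all balanced examples, with OOB votes covering them
    split_forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                          n_jobs=1)
    split_forest.fit(X[tr], y_fit[tr])
    acc = float((split_forest.predict(X[te]) == y[te]).mean()) if len(te) else float("nan")
    y_all = y.copy()
    if shuffle_labels:
        y_all = y_fit
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1, oob_score=True, bootstrap=True)
    forest.fit(X, y_all)
    well_ids = dataset.wells["well_id"].to_numpy()
    fit_well_rows = {well_ids[r]: row for row, r in enumerate(dataset_rows)}
    return ActivityModel(forest=forest, mode=mode,
                         class_balance={k: len(v) for k, v in groups.items()},
                         heldout_accuracy=acc, seed=seed, n_features=X.shape[1],
                         train_indices=tr, test_indices=te,
                         fit_well_rows=fit_well_rows)


def _predict_labels(model: ActivityModel, dataset: ScreenDataset) -> np.ndarray:
    """Forest predictions with out-of-bag votes for wells seen during fit
    (so relabeling a training well is never an in-sample lookup)."""
    pred = model.forest.predict(dataset.traces).astype(object)
    oob = getattr(model.forest, "oob_decision_function_", None)
    if oob is not None and model.fit_well_rows:
        classes = model.forest.classes_
        for i, wid in enumerate(dataset.wells["well_id"]):
            row = model.fit_well_rows.get(wid)
            if row is not None and not np.any(np.isnan(oob[row])):
                pred[i] = classes[int(np.argmax(oob[row]))]
    return pred


def label_wells(model: ActivityModel, dataset: ScreenDataset) -> dict[str, str]:
    """Label every well; control-well roles override forest predictions
    (a vehicle well is never usable as an 'active' pair member)."""
    if dataset.traces.shape[1] != model.n_features:
        raise ValueError(
            f"trace length {dataset.traces.shape[1]} != training length {model.n_features}")
    pred = _predict_labels(model, dataset)
    labels = {}
    roles = dataset.wells["role"].to_numpy()
    for i, wid in enumerate(dataset.wells["well_id"]):
        if roles[i] == ROLE_VEHICLE:
            labels[wid] = INACTIVE
        elif roles[i] == ROLE_LETHAL:
            labels[wid] = LETHAL
        else:
            labels[wid] = str(pred[i])
    return labels


def _predict_proba(model: ActivityModel, dataset: ScreenDataset) -> np.ndarray:
    proba = model.forest.predict_proba(dataset.traces)
    oob = getattr(model.forest, "oob_decision_function_", None)
    if oob is not None and model.fit_well_rows:
        for i, wid in enumerate(dataset.wells["well_id"]):
            row = model.fit_well_rows.get(wid)
            if row is not None and not np.any(np.isnan(oob[row])):
                proba[i] = oob[row]
    return proba


def label_probabilities(model: ActivityModel, dataset: ScreenDataset) -> pd.DataFrame:
    """Per-well class probabilities alongside the final labels."""
    proba = _predict_proba(model, dataset)
    cols = {f"p_{c}": proba[:, i] for i, c in enumerate(model.forest.classes_)}
    labels = label_wells(model, dataset)
    return pd.DataFrame({"well_id": dataset.wells["well_id"],
                         "label": [labels[w] for w in dataset.wells["well_id"]],
                         **cols})


def phenotype_strength(model: ActivityModel, dataset: ScreenDataset) -> dict[str, float]:
    """Per-drug phenotype strength: forest P(active) averaged over replicates."""
    proba = _predict_proba(model, dataset)
    active_col = list(model.forest.classes_).index(ACTIVE)
    wells = dataset.wells
    out = {}
    for drug in dataset.drug_ids():
        mask = ((wells["treatment_id"] == drug) & (wells["role"] == ROLE_DRUG)).to_numpy()
        out[drug] = float(proba[mask, active_col].mean())
    return out
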