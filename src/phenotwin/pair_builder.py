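"""Labeled pair construction for twin-network metric learning.

Positive pairs are two replicates of the same compound (both labeled
active by the activity filter); negatives pair replicates of different
compounds.  Drugs — never individual wells — are split 80/20 into train
and test sets, so no replicate of any drug crosses the partition.
Negatives are subsampled to exactly match the positive count, and fixed
shares of the final sets come from control/tox pair classes: 25% of
positives from control-control and tox-tox (split evenly), 25% of
negatives from control-drug, control-tox and tox-drug (split evenly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io import ROLE_DRUG, ROLE_LETHAL, ROLE_VEHICLE, ScreenDataset

logger = logging.getLogger(__name__)

__all__ = [
    "WellRecord",
    "PairExample",
    "PairDataset",
    "split_by_drug",
    "build_pairs",
    "build_pair_dataset",
]

POSITIVE_CLASSES = ("drug-drug+", "control-control", "tox-tox")
NEGATIVE_CLASSES = ("drug-drug-", "control-drug", "control-tox", "tox-drug")


@dataclass(frozen=True)
class WellRecord:
    """One well's identity and metadata (0-based plate coordinates)."""

    well_id: str
    plate_id: str
    row: int
    col: int
    treatment_id: str
    role: str
    replicate_index: int


@dataclass(frozen=True)
class PairExample:
    index_a: int
    index_b: int
    label: str          # "same" | "different"
    pair_class: str
    split: str          # "train" | "test"

    def __post_init__(self):
        if self.index_a == self.index_b:
            raise ValueError("self-pair")
        expected = "same" if self.pair_class in POSITIVE_CLASSES else "different"
        if self.label != expected:
            raise ValueError(f"label {self.label!r} inconsistent with class {self.pair_class!r}")


@dataclass
class PairDataset:
    pairs: list[PairExample]
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.pairs)

    def subset(self, split: str) -> "PairDataset":
        return PairDataset([p for p in self.pairs if p.split == split],
                           provenance=dict(self.provenance, split=split))

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(index_a, index_b, y) with y = 1 for same, 0 for different."""
        ia = np.array([p.index_a for p in self.pairs], dtype=np.int64)
        ib = np.array([p.index_b for p in self.pairs], dtype=np.int64)
        y = np.array([1 if p.label == "same" else 0 for p in self.pairs], dtype=np.int64)
        return ia, ib, y

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.pairs:
            key = f"{p.split}/{p.pair_class}"
            out[key] = out.get(key, 0) + 1
        return out


def split_by_drug(drug_ids, fraction: float = 0.8, seed: int = 0):
    """Seeded disjoint, exhaustive drug-level train/test partition."""
    drug_ids = sorted(drug_ids)
    if len(drug_ids) < 2:
        raise ValueError("need at least 2 drugs to split")
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(drug_ids))
    n_train = int(round(fraction * len(drug_ids)))
    n_train = min(max(n_train, 1), len(drug_ids) - 1)
    train = sorted(drug_ids[i] for i in order[:n_train])
    test = sorted(drug_ids[i] for i in order[n_train:])
    return train, test


def _sample(pool: list, k: int, rng: np.random.Generator) -> list:
    if k >= len(pool):
        return list(pool)
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def _cross_drug_pairs(well_idx: np.ndarray, drug_of_well: np.ndarray,
                      k: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Sample k cross-drug unordered well pairs, seeded."""
    n = len(well_idx)
    if n <= 2500:
        ii, jj = np.triu_indices(n, k=1)
        keep = drug_of_well[ii] != drug_of_well[jj]
        pool = list(zip(well_idx[ii[keep]].tolist(), well_idx[jj[keep]].tolist()))
        return _sample(pool, k, rng)
    # rejection sampling for large screens
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < k:
        a, b = rng.integers(n, size=2)
        if a == b or drug_of_well[a] == drug_of_well[b]:
            continue
        i, j = int(well_idx[min(a, b)]), int(well_idx[max(a, b)])
        chosen.add((i, j))
    return sorted(chosen)


def _even_allocation(total: int, n_buckets: int) -> list[int]:
    base, rem = divmod(total, n_buckets)
    return [base + (1 if i < rem else 0) for i in range(n_buckets)]


def _fill_buckets(requests: list[int], pools: list[list], rng: np.random.Generator,
                  names: list[str]) -> list[list]:
    """Fill each bucket; reallocate shortfalls proportionally with a warning."""
    taken = [_sample(pool, k, rng) for pool, k in zip(pools, requests)]
    shortfall = sum(k - len(t) for k, t in zip(requests, taken))
    guard = 0
    while shortfall > 0 and guard < 10:
        guard += 1
        spare = [i for i in range(len(pools)) if len(taken[i]) < len(pools[i])]
        if not spare:
            break
        add = _even_allocation(shortfall, len(spare))
        shortfall = 0
        for i, extra in zip(spare, add):
            remaining = [p for p in pools[i] if p not in set(taken[i])]
            got = _sample(remaining, extra, rng)
            taken[i].extend(got)
            shortfall += extra - len(got)
        logger.warning("pair quota shortfall reallocated across buckets %s",
                       [names[i] for i in spare])
    return taken


def build_pairs(dataset: ScreenDataset, labels: dict[str, str], split_drugs,
                split_name: str = "train", quota_pos_ctrl: float = 0.25,
                quota_neg_ctrl: float = 0.25, seed: int = 0) -> PairDataset:
    """Construct balanced, quota-filled pairs for one drug split.

    ``labels`` maps well_id -> activity label; wells of a drug labeled
    inactive/lethal are excluded from drug-drug pairs.  Vehicle wells feed
    the control buckets regardless of classifier output, lethal-control
    wells the tox buckets.
    """
    rng = np.random.default_rng(seed)
    wells = dataset.wells
    split_set = set(split_drugs)
    roles = wells["role"].to_numpy()
    treatments = wells["treatment_id"].to_numpy()
    well_ids = wells["well_id"].to_numpy()

    active_mask = np.array([
        roles[i] == ROLE_DRUG and treatments[i] in split_set
        and labels.get(well_ids[i], "active") == "active"
        for i in range(len(wells))])
    drug_wells = np.flatnonzero(active_mask)
    drug_of = treatments[drug_wells]
    vehicle_wells = np.flatnonzero(roles == ROLE_VEHICLE)
    tox_wells = np.flatnonzero(roles == ROLE_LETHAL)

    # --- positives ---
    dd_pos: list[tuple[int, int]] = []
    for drug in sorted(split_set):
        idxs = drug_wells[drug_of == drug]
        dd_pos.extend((int(a), int(b)) for a, b in combinations(idxs, 2))
    if not dd_pos:
        raise ValueError(f"no positive drug-drug pairs available for split {split_name!r}")
    total_pos = int(round(len(dd_pos) / (1.0 - quota_pos_ctrl)))
    n_ctrl_pos = total_pos - len(dd_pos)
    cc_req, tt_req = _even_allocation(n_ctrl_pos, 2)
    cc_pool = [(int(a), int(b)) for a, b in combinations(vehicle_wells, 2)]
    tt_pool = [(int(a), int(b)) for a, b in combinations(tox_wells, 2)]
    cc, tt = _fill_buckets([cc_req, tt_req], [cc_pool, tt_pool], rng,
                           ["control-control", "tox-tox"])
    positives = ([(p, "drug-drug+") for p in dd_pos]
                 + [(p, "control-control") for p in cc]
                 + [(p, "tox-tox") for p in tt])

    # --- negatives: exactly as many as positives ---
    total_neg = len(positives)
    n_mixed = int(round(quota_neg_ctrl * total_neg))
    n_dd_neg = total_neg - n_mixed
    cd_req, ct_req, td_req = _even_allocation(n_mixed, 3)
    cd_pool = [(int(v), int(d)) for v in vehicle_wells for d in drug_wells]
    ct_pool = [(int(v), int(t)) for v in vehicle_wells for t in tox_wells]
    td_pool = [(int(t), int(d)) for t in tox_wells for d in drug_wells]
    cd, ct, td = _fill_buckets([cd_req, ct_req, td_req], [cd_pool, ct_pool, td_pool],
                               rng, ["control-drug", "control-tox", "tox-drug"])
    n_dd_neg = total_neg - len(cd) - len(ct) - len(td)
    dd_neg = _cross_drug_pairs(drug_wells, drug_of, n_dd_neg, rng)
    if len(dd_neg) < n_dd_neg:
        raise ValueError(
            f"quota shortfall in bucket drug-drug-: need {n_dd_neg}, "
            f"have {len(dd_neg)} candidates")
    negatives = ([(p, "drug-drug-") for p in dd_neg]
                 + [(p, "control-drug") for p in cd]
                 + [(p, "control-tox") for p in ct]
                 + [(p, "tox-drug") for p in td])
    if len(negatives) != len(positives):   # trim if reallocation overshot
        negatives = negatives[:len(positives)]

    pairs = [PairExample(a, b, "same", cls, split_name) for (a, b), cls in positives]
    pairs += [PairExample(a, b, "different", cls, split_name) for (a, b), cls in negatives]
    return PairDataset(pairs, provenance={
        "split": split_name, "seed": seed, "n_positive": len(positives),
        "n_negative": len(negatives), "quota_pos_ctrl": quota_pos_ctrl,
        "quota_neg_ctrl": quota_neg_ctrl})


def build_pair_dataset(dataset: ScreenDataset, labels: dict[str, str],
                       fraction: float = 0.8, quota_pos_ctrl: float = 0.25,
                       quota_neg_ctrl: float = 0.25, seed: int = 0) -> PairDataset:
    """Drug-wise split + per-split pair construction in one call."""
    train_drugs, test_drugs = split_by_drug(dataset.drug_ids(), fraction, seed)
    train = build_pairs(dataset, labels, train_drugs, "train",
                        quota_pos_ctrl, quota_neg_ctrl, seed)
    test = build_pairs(dataset, labels, test_drugs, "test",
                       quota_pos_ctrl, quota_neg_ctrl, seed + 1)
    return PairDataset(train.pairs + test.pairs, provenance={
        "seed": seed, "fraction": fraction,
        "train_drugs": train_drugs, "test_drugs": test_drugs,
        "train": train.provenance, "test": test.provenance})
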