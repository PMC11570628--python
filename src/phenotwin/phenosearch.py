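"""Phenosearch library ranking, MOA enrichment and scaffold-hopping analysis.

"Phenosearch" ranks a compound library by phenotypic distance to a query
drug's behavioral trace.  Enrichment is assessed against target profiles —
binary vectors over a shared target vocabulary supplied by a pluggable
provider (synthetic ground truth, or a file of precomputed predictions such
as SEA output): a library compound is a hit when its profile shares at
least one target with the query's.  Scaffold hopping looks for compound
pairs with similar bioactivity and phenotype but dissimilar chemistry:
high fingerprint (ECFP4/Tanimoto) distance, low phenotypic distance, and
non-trivial target-profile similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, cross_distance_matrix

__all__ = [
    "CompoundRecord",
    "PhenosearchResult",
    "phenosearch_rank",
    "moa_enrichment",
    "control_contamination",
    "tanimoto",
    "tanimoto_distance",
    "ecfp4_fingerprint",
    "synthetic_family_fingerprints",
    "quadrant_analysis",
]

FINGERPRINT_BITS = 2048


@dataclass
class CompoundRecord:
    compound_id: str
    smiles: str | None = None
    fingerprint: np.ndarray | None = None     # fixed-length 0/1 vector
    target_profile: np.ndarray | None = None  # binary over shared vocabulary
    dataset: str = "library"                  # "query" | "library"


@dataclass
class PhenosearchResult:
    """Per-query ranked library hits (ascending distance, ties by id)."""

    query_id: str
    ranked_ids: list[str]
    distances: np.ndarray
    top_k: int

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=float)
        if np.any(np.diff(d) < -1e-12):
            raise ValueError("ranking must be ascending in distance")
        self.distances = d


def phenosearch_rank(query_traces: np.ndarray, library_traces: np.ndarray,
                     metric, query_ids: list[str], library_ids: list[str],
                     top_k: int = 500,
                     metric_name: str = "") -> list[PhenosearchResult]:
    """Rank each library compound against each query by ascending distance.

    ``metric`` is any callable on a pair of rows (trace metric, or embedding
    metric on precomputed embeddings).  Ties break by library id.
    """
    if len(library_ids) == 0:
        raise ValueError("empty library")
    dmat = cross_distance_matrix(query_traces, library_traces, metric,
                                 query_ids, library_ids, metric_name)
    results = []
    lib = np.asarray(library_ids)
    for qi, qid in enumerate(query_ids):
        row = dmat.values[qi]
        order = np.lexsort((lib, row))[:top_k]
        results.append(PhenosearchResult(
            query_id=qid, ranked_ids=lib[order].tolist(),
            distances=row[order], top_k=top_k))
    return results


def _is_hit(profile: np.ndarray, query_profile: np.ndarray, min_shared: int = 1) -> bool:
    return int(np.minimum(profile, query_profile).sum()) >= min_shared


def moa_enrichment(result: PhenosearchResult,
                   target_profiles: dict[str, np.ndarray],
                   query_profile: np.ndarray,
                   fractions: np.ndarray | None = None,
                   min_shared: int = 1) -> pd.DataFrame:
    """Cumulative hit curve over the ranked list.

    A hit shares >= ``min_shared`` targets with the query profile.  The
    analytic random baseline at fraction f is f x (total hits among ranked
    compounds) — the hypergeometric mean under uniform ordering.  Compounds
    without a profile are excluded with a warning.
    """
    if fractions is None:
        fractions = np.linspace(0.05, 1.0, 20)
    kept = [cid for cid in result.ranked_ids if cid in target_profiles]
    if len(kept) < len(result.ranked_ids):
        warnings.warn(f"{len(result.ranked_ids) - len(kept)} ranked compounds "
                      "lack target profiles; excluded")
    hits = np.array([_is_hit(target_profiles[cid], query_profile, min_shared)
                     for cid in kept], dtype=int)
    n = len(hits)
    total_hits = int(hits.sum())
    cum = np.cumsum(hits)
    rows = []
    for f in fractions:
        k = max(int(round(f * n)), 1) if n else 0
        rows.append({"fraction": float(f),
                     "hits": int(cum[k - 1]) if n else 0,
                     "random_baseline": total_hits * k / n if n else 0.0})
    return pd.DataFrame(rows)


def control_contamination(result: PhenosearchResult,
                          well_roles: dict[str, str]) -> int:
    """Number of negative-control (vehicle) wells in the ranked list."""
    return sum(1 for cid in result.ranked_ids if well_roles.get(cid) == "vehicle")


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Jaccard similarity of two equal-length bit vectors; both-empty -> 0."""
    a = np.asarray(fp_a).astype(bool)
    b = np.asarray(fp_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("both fingerprints empty; Tanimoto defined as 0")
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_distance(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    return 1.0 - tanimoto(fp_a, fp_b)


def ecfp4_fingerprint(smiles: str, n_bits: int = FINGERPRINT_BITS) -> np.ndarray:
    """ECFP4-equivalent circular fingerprint (Morgan radius 2) via rdkit.

    rdkit is an optional dependency; fingerprints may instead be supplied
    directly on :class:`CompoundRecord`.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return np.array(fp, dtype=np.int8)


def synthetic_family_fingerprints(family_of: dict[str, int], seed: int = 0,
                                  n_bits: int = FINGERPRINT_BITS,
                                  bits_on: int = 120,
                                  flip_fraction: float = 0.1) -> dict[str, np.ndarray]:
    """Family-structured random fingerprints (synthetic stand-in for real
    chemistry): members of a family share a prototype bit pattern with a
    fraction of bits resampled per compound, so within-family Tanimoto is
    high and cross-family Tanimoto near zero."""
    rng = np.random.default_rng(seed)
    protos = {}
    for fam in sorted(set(family_of.values())):
        on = rng.choice(n_bits, size=bits_on, replace=False)
        protos[fam] = on
    fps = {}
    for cid in sorted(family_of):
        on = set(protos[family_of[cid]].tolist())
        n_flip = int(round(flip_fraction * bits_on))
        drop = rng.choice(sorted(on), size=n_flip, replace=False)
        add = rng.choice(n_bits, size=n_flip, replace=False)
        on = (on - set(drop.tolist())) | set(add.tolist())
        fp = np.zeros(n_bits, dtype=np.int8)
        fp[sorted(on)] = 1
        fps[cid] = fp
    return fps


def split_class_families(class_of: dict[str, int], shared_class: int = 0) -> dict[str, int]:
    """Structural family assignment where one phenotype class is shared by
    two disjoint chemical families (the scaffold-hopping scenario); every
    other class maps to a single family."""
    shared = sorted(d for d, c in class_of.items() if c == shared_class)
    fam = {}
    for d, c in class_of.items():
        if c == shared_class:
            fam[d] = 1000 + (shared.index(d) % 2)
        else:
            fam[d] = c
    return fam


def aggregate_enrichment(curves: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean hits/baseline over queries, fraction-aligned."""
    if not curves:
        raise ValueError("no curves to aggregate")
    out = curves[0][["fraction"]].copy()
    out["hits"] = np.mean([c["hits"].to_numpy() for c in curves], axis=0)
    out["random_baseline"] = np.mean([c["random_baseline"].to_numpy() for c in curves], axis=0)
    return out


def quadrant_analysis(pheno: DistanceMatrix,
                      fingerprints: dict[str, np.ndarray],
                      target_profiles: dict[str, np.ndarray],
                      target_sim_min: float = 0.2,
                      struct_dist_min: float = 0.5,
                      pheno_dist_max: float = 0.3,
                      axes_cuts: tuple[float, float] = (0.3, 0.4)) -> pd.DataFrame:
    """Annotate all unordered compound pairs for scaffold hopping.

    Columns: structure Tanimoto distance, phenotypic distance, target-profile
    Tanimoto similarity, a quadrant label at ``axes_cuts`` = (phenotypic cut,
    structural cut), and a ``scaffold_hop`` flag for pairs passing all three
    thresholds (bioactivity-alike, structure-unlike, phenotype-alike).
    Candidates sort first, by descending target similarity.  Pairs missing a
    fingerprint or profile are excluded with a warning.
    """
    if not pheno.is_square:
        raise ValueError("quadrant analysis needs a square phenotypic matrix")
    ids = pheno.ids
    missing = [i for i in ids if i not in fingerprints or i not in target_profiles]
    if missing:
        warnings.warn(f"{len(missing)} compounds lack fingerprints/profiles; excluded")
    kept = [i for i in ids if i not in set(missing)]
    idx = {cid: k for k, cid in enumerate(ids)}
    pheno_cut, struct_cut = axes_cuts
    rows = []
    for a_pos in range(len(kept)):
        for b_pos in range(a_pos + 1, len(kept)):
            a, b = kept[a_pos], kept[b_pos]
            sd = tanimoto_distance(fingerprints[a], fingerprints[b])
            pd_ = float(pheno.values[idx[a], idx[b]])
            ts = tanimoto(target_profiles[a], target_profiles[b])
            quadrant = ("low-pheno" if pd_ < pheno_cut else "high-pheno") + \
                       ("/high-struct" if sd > struct_cut else "/low-struct")
            rows.append({
                "compound_a": a, "compound_b": b,
                "struct_dist": sd, "pheno_dist": pd_, "target_sim": ts,
                "quadrant": quadrant,
                "scaffold_hop": (ts > target_sim_min and sd > struct_dist_min
                                 and pd_ < pheno_dist_max)})
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["scaffold_hop", "target_sim"],
                            ascending=[False, False]).reset_index(drop=True)
    return df
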