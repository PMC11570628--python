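"""Phenosearch ranking, MOA enrichment, Tanimoto and quadrant analysis."""

import numpy as np
import pandas as pd
import pytest

from phenotwin.distances import DistanceMatrix, euclidean_distance
from phenotwin.phenosearch import (aggregate_enrichment, control_contamination,
                                   ecfp4_fingerprint, moa_enrichment,
                                   phenosearch_rank, quadrant_analysis,
                                   split_class_families,
                                   synthetic_family_fingerprints, tanimoto,
                                   tanimoto_distance)


def _fp(bits, n=16):
    v = np.zeros(n, dtype=np.int8)
    v[list(bits)] = 1
    return v


class TestTanimoto:
    def test_identical_nonempty_is_one(self):
        assert tanimoto(_fp({1, 5}), _fp({1, 5})) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(_fp({0, 1}), _fp({4, 5})) == 0.0

    def test_counting_example(self):
        assert tanimoto(_fp({1, 2, 3}), _fp({2, 3, 4})) == 0.5
        assert tanimoto_distance(_fp({1, 2, 3}), _fp({2, 3, 4})) == 0.5

    def test_both_empty_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert tanimoto(_fp(set()), _fp(set())) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(_fp({0}, 8), _fp({0}, 16))


class TestECFP4:
    def test_fingerprint_shape_and_self_similarity(self):
        fp = ecfp4_fingerprint("CC(=O)Oc1ccccc1C(=O)O")  # aspirin
        assert fp.shape == (2048,) and fp.sum() > 0
        assert tanimoto(fp, fp) == 1.0

    def test_related_structures_intermediate_similarity(self):
        a = ecfp4_fingerprint("CC(=O)Oc1ccccc1C(=O)O")            # aspirin
        b = ecfp4_fingerprint("CC(C)Cc1ccc(cc1)C(C)C(=O)O")       # ibuprofen
        assert 0.0 < tanimoto(a, b) < 1.0

    def test_invalid_smiles_rejected(self):
        with pytest.raises(ValueError, match="SMILES"):
            ecfp4_fingerprint("not-a-molecule(((")


class TestSyntheticFamilies:
    def test_within_family_similar_cross_family_dissimilar(self):
        fam = {f"c{i}": i % 2 for i in range(8)}
        fps = synthetic_family_fingerprints(fam, seed=0)
        within = tanimoto(fps["c0"], fps["c2"])
        cross = tanimoto(fps["c0"], fps["c1"])
        assert within > 0.5 > cross

    def test_split_class_families_splits_only_shared_class(self):
        classes = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1}
        fam = split_class_families(classes, shared_class=0)
        assert len({fam["a"], fam["b"], fam["c"]}) == 2
        assert fam["d"] == fam["e"] == 1


class TestRanking:
    def test_exact_copy_ranks_first_with_zero_distance(self):
        rng = np.random.default_rng(0)
        q = rng.random((1, 20))
        lib = np.vstack([rng.random((4, 20)), q])
        res = phenosearch_rank(q, lib, euclidean_distance, ["q"],
                               [f"l{i}" for i in range(5)])
        assert res[0].ranked_ids[0] == "l4"
        assert res[0].distances[0] == 0.0

    def test_top_k_larger_than_library_returns_all(self):
        rng = np.random.default_rng(1)
        res = phenosearch_rank(rng.random((1, 5)), rng.random((3, 5)),
                               euclidean_distance, ["q"], list("abc"), top_k=500)
        assert len(res[0].ranked_ids) == 3

    def test_ranking_ascending_with_id_tiebreak(self):
        q = np.zeros((1, 2))
        lib = np.zeros((3, 2))   # all ties -> lexicographic ids
        res = phenosearch_rank(q, lib, euclidean_distance, ["q"], ["c", "a", "b"])
        assert res[0].ranked_ids == ["a", "b", "c"]

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            phenosearch_rank(np.zeros((1, 3)), np.zeros((0, 3)),
                             euclidean_distance, ["q"], [])


class TestEnrichment:
    def _result(self, ids, dists):
        from phenotwin.phenosearch import PhenosearchResult
        return PhenosearchResult("q", ids, np.asarray(dists, float), len(ids))

    def test_front_loaded_hits_linear_then_flat(self):
        ids = [f"c{i}" for i in range(20)]
        profiles = {c: _fp({0}) if i < 5 else _fp({9}) for i, c in enumerate(ids)}
        res = self._result(ids, np.arange(20.0))
        curve = moa_enrichment(res, profiles, _fp({0, 1}),
                               fractions=np.array([0.25, 0.5, 1.0]))
        assert curve["hits"].tolist() == [5, 5, 5]
        assert np.all(np.diff(curve["hits"]) >= 0)

    def test_random_ordering_within_permutation_band(self):
        rng = np.random.default_rng(2)
        ids = [f"c{i}" for i in range(100)]
        hits = rng.random(100) < 0.3
        profiles = {c: _fp({0}) if h else _fp({9}) for c, h in zip(ids, hits)}
        res = self._result(ids, np.arange(100.0))
        curve = moa_enrichment(res, profiles, _fp({0}))
        # permutation oracle: analytic baseline must sit inside the band
        perm_curves = []
        hit_vec = np.array([1 if hits[i] else 0 for i in range(100)])
        for _ in range(1000):
            shuffled = rng.permutation(hit_vec)
            cum = np.cumsum(shuffled)
            perm_curves.append([cum[max(int(round(f * 100)), 1) - 1]
                                for f in curve["fraction"]])
        perm = np.array(perm_curves)
        lo = np.percentile(perm, 2.5, axis=0)
        hi = np.percentile(perm, 97.5, axis=0)
        assert np.all(curve["random_baseline"] >= lo - 1e-9)
        assert np.all(curve["random_baseline"] <= hi + 1e-9)

    def test_missing_profiles_excluded_with_warning(self):
        res = self._result(["a", "b"], [0.0, 1.0])
        with pytest.warns(UserWarning, match="lack target profiles"):
            curve = moa_enrichment(res, {"a": _fp({0})}, _fp({0}))
        assert curve["hits"].iloc[-1] == 1

    def test_aggregate_means_curves(self):
        c1 = pd.DataFrame({"fraction": [0.5, 1.0], "hits": [2, 4],
                           "random_baseline": [1.0, 2.0]})
        c2 = pd.DataFrame({"fraction": [0.5, 1.0], "hits": [4, 6],
                           "random_baseline": [3.0, 4.0]})
        agg = aggregate_enrichment([c1, c2])
        assert agg["hits"].tolist() == [3.0, 5.0]


class TestContamination:
    def test_counts_vehicle_wells(self):
        from phenotwin.phenosearch import PhenosearchResult
        res = PhenosearchResult("q", ["w1", "w2", "w3"], np.arange(3.0), 3)
        roles = {"w1": "vehicle", "w2": "drug", "w3": "vehicle"}
        assert control_contamination(res, roles) == 2

    def test_zero_when_no_vehicles(self):
        from phenotwin.phenosearch import PhenosearchResult
        res = PhenosearchResult("q", ["w1"], np.zeros(1), 1)
        assert control_contamination(res, {"w1": "drug"}) == 0


class TestQuadrants:
    def _pheno(self, ids, values):
        return DistanceMatrix(np.asarray(values, float), ids=ids)

    def test_threshold_example_is_candidate(self):
        ids = ["a", "b"]
        pheno = self._pheno(ids, [[0, 0.2], [0.2, 0]])
        fps = {"a": _fp({0, 1, 2, 3, 4}), "b": _fp({5, 6, 7, 8, 9})}  # dist 1.0
        profs = {"a": _fp({0, 1, 2}), "b": _fp({1, 2, 3})}            # sim 0.5
        qa = quadrant_analysis(pheno, fps, profs)
        assert bool(qa["scaffold_hop"].iloc[0])

    def test_identical_compounds_not_candidates(self):
        ids = ["a", "b"]
        pheno = self._pheno(ids, [[0, 0.0], [0.0, 0]])
        fps = {"a": _fp({0, 1}), "b": _fp({0, 1})}
        profs = {"a": _fp({0}), "b": _fp({0})}
        qa = quadrant_analysis(pheno, fps, profs)
        assert not bool(qa["scaffold_hop"].iloc[0])  # struct distance 0 fails

    def test_quadrant_labels_partition_pairs(self):
        rng = np.random.default_rng(3)
        ids = [f"c{i}" for i in range(6)]
        vals = rng.random((6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        fps = {c: _fp(set(rng.choice(16, 5, replace=False))) for c in ids}
        profs = {c: _fp(set(rng.choice(16, 3, replace=False))) for c in ids}
        qa = quadrant_analysis(self._pheno(ids, vals), fps, profs)
        assert len(qa) == 15
        assert qa["quadrant"].value_counts().sum() == 15

    def test_duplicate_compound_entries_produce_duplicate_rows(self):
        ids = ["drugX", "drugX-2", "other"]
        vals = np.array([[0, 0.0, 0.5], [0.0, 0, 0.5], [0.5, 0.5, 0]])
        fp = _fp({0, 1, 2})
        fps = {"drugX": fp, "drugX-2": fp, "other": _fp({8, 9})}
        profs = {"drugX": _fp({0}), "drugX-2": _fp({0}), "other": _fp({5})}
        qa = quadrant_analysis(self._pheno(ids, vals), fps, profs)
        rows = qa[qa["compound_b"] == "other"]
        assert len(rows) == 2  # one per occurrence of the duplicated drug
        assert rows["struct_dist"].nunique() == 1

    def test_missing_annotation_excluded_with_warning(self):
        ids = ["a", "b", "c"]
        vals = np.zeros((3, 3))
        fps = {"a": _fp({0}), "b": _fp({1})}
        profs = {"a": _fp({0}), "b": _fp({0})}
        with pytest.warns(UserWarning, match="lack"):
            qa = quadrant_analysis(self._pheno(ids, vals), fps, profs)
        assert set(qa["compound_a"]) | set(qa["compound_b"]) == {"a", "b"}
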