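"""Synthetic screen generator: layouts, templates, noise and the artifact."""

import numpy as np
import pytest
from scipy import stats

from phenotwin.distances import correlation_distance
from phenotwin.io import ROLE_DRUG, ROLE_LETHAL, ROLE_VEHICLE
from phenotwin.motion_index import smooth_hanning
from phenotwin.synthetic_data import (ARTIFACT_FREQ, SimConfig, StimulusSchedule,
                                      default_stimulus_schedule, generate_layout,
                                      generate_screen, plant_positional_artifact,
                                      read_ground_truth, write_ground_truth)

SMALL = dict(n_plates=4, n_drugs=12, replicates_per_drug=(4, 4),
             n_phenotype_classes=4, trace_length=1000, seed=3)


class TestStimulusSchedule:
    def test_default_schedule_tiles_trace(self):
        sched = default_stimulus_schedule(5000)
        assert sched.epochs[0][0] == 0 and sched.length == 5000
        for (s0, e0, _), (s1, e1, _) in zip(sched.epochs, sched.epochs[1:]):
            assert e0 == s1 and e0 > s0

    def test_rejects_gaps_and_unknown_kinds(self):
        with pytest.raises(ValueError):
            StimulusSchedule([(0, 10, "dark"), (12, 20, "tap")])
        with pytest.raises(ValueError):
            StimulusSchedule([(0, 10, "strobe")])


class TestLayout:
    def test_fixed_mode_pins_drug_position_across_plates(self):
        recs = generate_layout(SimConfig(**SMALL, layout_mode="fixed"))
        by_drug = {}
        for r in recs:
            if r.role == ROLE_DRUG:
                by_drug.setdefault(r.treatment_id, set()).add((r.row, r.col))
        assert all(len(pos) == 1 for pos in by_drug.values())

    def test_randomized_mode_seeded_determinism(self):
        a = generate_layout(SimConfig(**SMALL, layout_mode="randomized"))
        b = generate_layout(SimConfig(**SMALL, layout_mode="randomized"))
        c = generate_layout(SimConfig(**{**SMALL, "seed": 4}, layout_mode="randomized"))
        assert a == b
        assert [r.treatment_id for r in a] != [r.treatment_id for r in c]

    def test_capacity_errors_name_the_deficit(self):
        with pytest.raises(ValueError, match="capacity"):
            SimConfig(**{**SMALL, "n_drugs": 96})
        with pytest.raises(ValueError, match="capacity"):
            SimConfig(**{**SMALL, "replicates_per_drug": (5, 5)})  # > n_plates

    def test_every_plate_is_complete(self):
        recs = generate_layout(SimConfig(**SMALL))
        assert len(recs) == 4 * 96
        per_plate = {}
        for r in recs:
            per_plate.setdefault(r.plate_id, set()).add((r.row, r.col))
        assert all(len(v) == 96 for v in per_plate.values())

    def test_each_plate_carries_configured_controls(self):
        recs = generate_layout(SimConfig(**SMALL))
        for plate in {r.plate_id for r in recs}:
            wells = [r for r in recs if r.plate_id == plate]
            assert sum(r.role == ROLE_LETHAL for r in wells) == 2
            assert sum(r.role == ROLE_VEHICLE for r in wells) >= 10

    def test_randomized_positions_uniform_over_treatment_wells(self):
        cfg = SimConfig(n_plates=10, n_drugs=60, replicates_per_drug=(10, 10),
                        n_phenotype_classes=4, trace_length=100,
                        layout_mode="randomized", seed=5)
        recs = generate_layout(cfg)
        control_cols = {0, 11}
        counts = {}
        for r in recs:
            if r.role == ROLE_DRUG:
                counts[(r.row, r.col)] = counts.get((r.row, r.col), 0) + 1
                assert r.col not in control_cols or (r.row, r.col) not in control_cols
        treatment_positions = [(i, j) for i in range(8) for j in range(12)
                               if j not in control_cols]
        observed = np.array([counts.get(p, 0) for p in treatment_positions])
        # only 80 of 84 positions can be treatment wells here (600 placements)
        _, p = stats.chisquare(observed)
        assert p > 0.01


class TestScreen:
    def test_bit_identical_for_identical_config(self):
        d1, g1 = generate_screen(SimConfig(**SMALL))
        d2, g2 = generate_screen(SimConfig(**SMALL))
        assert np.array_equal(d1.traces, d2.traces)
        assert g1.class_of_drug == g2.class_of_drug

    def test_traces_bounded_and_nonnegative(self):
        d, _ = generate_screen(SimConfig(**SMALL))
        assert d.traces.min() >= 0.0 and d.traces.max() <= 6750.0

    def test_lethal_wells_nearly_motionless(self):
        d, _ = generate_screen(SimConfig(**SMALL))
        lethal = d.traces[d.indices_for_role(ROLE_LETHAL)].mean()
        active = d.traces[d.indices_for_role(ROLE_DRUG)].mean()
        assert lethal < 0.02 * active

    def test_ground_truth_classes_and_activity(self):
        d, gt = generate_screen(SimConfig(**{**SMALL, "inactive_fraction": 0.25}))
        assert set(gt.class_of_drug) == set(d.drug_ids())
        assert sum(not a for a in gt.active.values()) == 3  # 25% of 12
        for drug, prof in gt.target_profile.items():
            assert prof.sum() >= 1

    def test_within_drug_distance_smaller_than_cross_class(self):
        """Monte-Carlo over replicate pairs: same-drug correlation distance is
        smaller in expectation than cross-class pairs."""
        d, gt = generate_screen(SimConfig(**{**SMALL, "n_plates": 6,
                                             "replicates_per_drug": (6, 6)}))
        wells = d.wells
        rng = np.random.default_rng(0)
        same, cross = [], []
        drug_idx = {t: np.flatnonzero((wells.treatment_id == t).to_numpy())
                    for t in d.drug_ids()}
        drugs = d.drug_ids()
        while len(same) < 200:
            t = drugs[rng.integers(len(drugs))]
            a, b = rng.choice(drug_idx[t], 2, replace=False)
            same.append(correlation_distance(d.traces[a], d.traces[b]))
            t2 = drugs[rng.integers(len(drugs))]
            if gt.class_of_drug[t2] == gt.class_of_drug[t]:
                continue
            c = rng.choice(drug_idx[t2])
            cross.append(correlation_distance(d.traces[a], d.traces[c]))
        assert np.mean(same) < np.mean(cross)

    def test_separability_dial_is_monotone(self):
        """Correlation-distance AUROC on same/different pairs rises with the
        between-class template separation."""
        from phenotwin.evaluation import mann_whitney_auroc
        aurocs = []
        for sep in (0.3, 1.0, 3.0):
            d, gt = generate_screen(SimConfig(**{**SMALL, "class_separation": sep}))
            wells = d.wells
            rng = np.random.default_rng(1)
            dists, labels = [], []
            drug_idx = {t: np.flatnonzero((wells.treatment_id == t).to_numpy())
                        for t in d.drug_ids()}
            drugs = d.drug_ids()
            for _ in range(300):
                t = drugs[rng.integers(len(drugs))]
                a, b = rng.choice(drug_idx[t], 2, replace=False)
                dists.append(correlation_distance(d.traces[a], d.traces[b]))
                labels.append(1)
                t2 = drugs[rng.integers(len(drugs))]
                c = rng.choice(drug_idx[t2])
                if t2 != t:
                    dists.append(correlation_distance(d.traces[a], d.traces[c]))
                    labels.append(0)
            aurocs.append(mann_whitney_auroc(np.array(dists), np.array(labels)))
        assert aurocs[0] < aurocs[1] < aurocs[2]

    def test_ground_truth_roundtrip(self, tmp_path):
        _, gt = generate_screen(SimConfig(**SMALL))
        path = write_ground_truth(gt, tmp_path / "gt.json")
        back = read_ground_truth(path)
        assert back.class_of_drug == gt.class_of_drug
        assert back.active == gt.active
        assert all(np.array_equal(back.target_profile[d], gt.target_profile[d])
                   for d in gt.target_profile)


class TestPositionalArtifact:
    def test_zero_amplitude_is_bitwise_identity(self):
        d, gt = generate_screen(SimConfig(**SMALL))
        out = plant_positional_artifact(d, gt, 0.0)
        assert out is d

    def test_same_position_gets_identical_component(self):
        d, gt = generate_screen(SimConfig(**SMALL))
        out = plant_positional_artifact(d, gt, 80.0)
        delta = out.traces - d.traces
        wells = d.wells
        pos_groups = wells.groupby(["row", "col"]).indices
        (i, j) = next(iter(v for v in pos_groups.values() if len(v) > 1))[:2]
        # identical except where clipping at zero interfered
        mask = (d.traces[i] + delta[i] > 0) & (d.traces[j] + delta[j] > 0)
        assert np.allclose(delta[i][mask], delta[j][mask])

    def test_hanning_removes_planted_power(self):
        """FFT-band oracle: >= 90% of the planted near-Nyquist power is gone
        after Hanning(11) smoothing."""
        d, gt = generate_screen(SimConfig(**SMALL))
        out = plant_positional_artifact(d, gt, 120.0)
        trace = out.traces[0]
        freqs = np.fft.rfftfreq(trace.size)
        band = np.abs(freqs - ARTIFACT_FREQ) < 0.02
        power_raw = (np.abs(np.fft.rfft(trace - trace.mean())) ** 2)[band].sum()
        sm = smooth_hanning(trace, 11)
        power_sm = (np.abs(np.fft.rfft(sm - sm.mean())) ** 2)[band].sum()
        assert power_sm <= 0.1 * power_raw

    def test_artifact_free_power_independent_of_position(self):
        """Permutation test (1,000 shuffles): with amplitude 0 the residual
        high-frequency power is unrelated to well position."""
        d, _ = generate_screen(SimConfig(**SMALL))
        traces = d.traces
        hf = traces[:, 1:] - traces[:, :-1]
        power = (hf ** 2).mean(axis=1)
        coord = (d.wells["row"] / 7 + d.wells["col"] / 11).to_numpy()
        obs = abs(np.corrcoef(power, coord)[0, 1])
        rng = np.random.default_rng(0)
        null = [abs(np.corrcoef(power, rng.permutation(coord))[0, 1])
                for _ in range(1000)]
        p = (1 + sum(n >= obs for n in null)) / 1001
        assert p > 0.01

    def test_negative_amplitude_rejected(self):
        d, gt = generate_screen(SimConfig(**SMALL))
        with pytest.raises(ValueError):
            plant_positional_artifact(d, gt, -1.0)
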