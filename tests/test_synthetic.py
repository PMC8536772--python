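import numpy as np
import pytest

from mmsgait.causality import gc_significance, lag_sweep
from mmsgait.mms import extract_mms
from mmsgait.signatures import gamma_signature, mode_decompose
from mmsgait.synthetic import (Coupling, GroundTruth, GroupSpec,
                               ModeMixtureSpec, simulate_cohort,
                               simulate_coupled_pair, simulate_subject)


class TestSimulateSubject:
    def test_peak_count_tracks_cadence(self, sim_recording):
        rec, truth = sim_recording
        for node in rec.node_names:
            series = extract_mms(rec.channels[node], rec.sampling_rate_hz)
            assert len(series) == pytest.approx(180, abs=10)

    def test_same_seed_bit_identical(self):
        truth = GroundTruth(seed=3)
        r1, _ = simulate_subject(truth, 30.0, 100.0)
        r2, _ = simulate_subject(truth, 30.0, 100.0)
        for node in r1.node_names:
            np.testing.assert_array_equal(r1.channels[node],
                                          r2.channels[node])

    def test_planted_amplitudes_recovered_by_mms(self):
        truth = GroundTruth(node_names=["pelvis"], seed=9)
        rec, realized = simulate_subject(truth, 120.0, 100.0)
        series = extract_mms(rec.channels["pelvis"], 100.0)
        planted = realized.planted_values["pelvis"]
        assert len(series) == len(planted)
        np.testing.assert_allclose(series.values, planted, atol=2e-3)

    def test_planted_gamma_scale_recovered(self):
        # ~150 spikes per walk; mean fitted NSR over a few seeded walks
        # within 10% of the planted scale (a single fit has ~12% SD)
        scales = []
        for seed in (21, 22, 23, 24, 25):
            truth = GroundTruth(node_names=["pelvis"],
                                amplitude_gamma={"pelvis": (81.0, 0.0089)},
                                seed=seed)
            rec, _ = simulate_subject(truth, 150.0, 100.0)
            series = extract_mms(rec.channels["pelvis"], 100.0)
            scales.append(gamma_signature(series.values)[1])
        assert np.mean(scales) == pytest.approx(0.0089, rel=0.10)

    def test_zero_gain_pairs_have_low_gc(self):
        truth = GroundTruth(seed=4)   # no couplings
        rec, _ = simulate_subject(truth, 180.0, 100.0)
        mms = {n: extract_mms(rec.channels[n], 100.0).values
               for n in rec.node_names}
        for a in rec.node_names:
            for b in rec.node_names:
                if a == b:
                    continue
                sweep = lag_sweep(mms[a], mms[b], range(1, 8), mode="ols")
                if sweep.max_gc is not None:
                    assert sweep.max_gc < 0.15

    def test_excessive_lag_rejected(self):
        truth = GroundTruth(couplings=[Coupling("pelvis", "foot_l",
                                                gain=0.4, lag=500)])
        with pytest.raises(ValueError, match="exceeds expected spike count"):
            simulate_subject(truth, 30.0, 100.0)

    def test_planted_lag_recovered_through_full_pipeline(self):
        hits = 0
        for seed in range(10):
            truth = GroundTruth(
                node_names=["a", "b"],
                couplings=[Coupling("a", "b", gain=0.4, lag=3)],
                seed=seed)
            rec, _ = simulate_subject(truth, 180.0, 100.0)
            x = extract_mms(rec.channels["b"], 100.0).values
            y = extract_mms(rec.channels["a"], 100.0).values
            sweep = lag_sweep(x, y, range(1, 9), mode="ols")
            hits += sweep.optimal_lag == 3
        assert hits >= 9

    def test_mode_mixture_shapes_amplitudes(self):
        spec = ModeMixtureSpec(mode1_weight=0.3)
        truth = GroundTruth(node_names=["pelvis"],
                            mode_mixture={"pelvis": spec}, seed=6)
        rec, _ = simulate_subject(truth, 600.0, 100.0)
        series = extract_mms(rec.channels["pelvis"], 100.0)
        res = mode_decompose(series.values, seed=0)
        assert res.mode1_fraction == pytest.approx(0.3, abs=0.1)


class TestFeedbackRecovery:
    @staticmethod
    def _detect(x, y, seed):
        s_ab = lag_sweep(x, y, range(1, 7), mode="ols")
        s_ba = lag_sweep(y, x, range(1, 7), mode="ols")
        g_ab = gc_significance(x, y, s_ab, alpha=0.01, n_surrogates=199,
                               seed=seed)
        g_ba = gc_significance(y, x, s_ba, alpha=0.01, n_surrogates=199,
                               seed=seed + 1)
        from mmsgait.causality import detect_feedback
        return detect_feedback(s_ab, s_ba, g_ab, g_ba)

    def test_sensitivity_and_specificity(self):
        n_pairs = 40
        tp = fp = 0
        for seed in range(n_pairs):
            x, y = simulate_coupled_pair(400, a2=0.2, b=0.5, lag=2,
                                         b_back=0.5, seed=seed)
            tp += self._detect(x, y, 1000 + seed)
            x, y = simulate_coupled_pair(400, a2=0.2, b=0.5, lag=2,
                                         b_back=0.0, seed=seed)
            fp += self._detect(x, y, 2000 + seed)
        assert tp / n_pairs >= 0.9
        assert 1 - fp / n_pairs >= 0.95


class TestSimulateCohort:
    def test_mode_weight_ordering_recovered(self):
        ok = 0
        runs = 10
        for seed in range(runs):
            specs = [
                GroupSpec(label="low", n_subjects=2, node_names=["pelvis"],
                          mode_mixture=ModeMixtureSpec(mode1_weight=0.2)),
                GroupSpec(label="high", n_subjects=2, node_names=["pelvis"],
                          mode_mixture=ModeMixtureSpec(mode1_weight=0.6)),
            ]
            cohort = simulate_cohort(specs, duration_s=240.0, rate_hz=100.0,
                                     seed=seed)
            fracs = {"low": [], "high": []}
            for rec, _ in cohort:
                series = extract_mms(rec.channels["pelvis"], 100.0)
                res = mode_decompose(series.values, seed=0)
                fracs[rec.group_label].append(res.mode1_fraction)
            ok += np.mean(fracs["high"]) > np.mean(fracs["low"])
        assert ok >= 0.95 * runs

    def test_single_subject_groups_valid(self):
        specs = [GroupSpec(label="solo", n_subjects=1)]
        cohort = simulate_cohort(specs, duration_s=30.0, seed=0)
        assert len(cohort) == 1
        assert cohort[0][0].subject_id == "solo_00"

    def test_disjoint_seeds_distinct(self):
        spec = [GroupSpec(label="g", n_subjects=1)]
        c1 = simulate_cohort(spec, duration_s=30.0, seed=1)
        c2 = simulate_cohort(spec, duration_s=30.0, seed=2)
        assert not np.array_equal(c1[0][0].channels["pelvis"],
                                  c2[0][0].channels["pelvis"])
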