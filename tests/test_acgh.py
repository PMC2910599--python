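"""Per-sample aCGH processing: QC, segmentation, state calling, amplification."""

import numpy as np
import pytest

from lineamp.acgh import (AmplificationConfig, EmptyProfileError, QCConfig,
                          SegmentationConfig, amplification_score, call_states,
                          detect_amplifications, qc_filter, segment_profile,
                          segment_values)

from _oracles import amplification_runs_oracle, segmentation_oracle
from conftest import make_profile


class TestQC:
    def _profile(self, sds, snrs):
        n = len(sds)
        reps = np.tile(np.array([[0.1, 0.2, 0.3]]), (n, 1))
        return make_profile(np.full(n, 0.2), replicate_sd=sds, snr=snrs,
                            replicates=reps)

    def test_high_replicate_sd_removed(self):
        prof = self._profile([0.08, 0.05], [10.0, 10.0])
        clean, rep = qc_filter(prof, QCConfig())
        assert clean.missing.tolist() == [True, False]
        assert rep.n_removed_sd == 1 and rep.n_removed_snr == 0

    def test_low_snr_removed(self):
        prof = self._profile([0.05, 0.05], [2.9, 5.0])
        clean, rep = qc_filter(prof, QCConfig())
        assert clean.missing.tolist() == [True, False]
        assert rep.n_removed_snr == 1

    def test_retained_clone_combined_is_replicate_mean(self):
        prof = self._profile([0.05, 0.05], [5.0, 5.0])
        clean, rep = qc_filter(prof, QCConfig())
        assert np.allclose(clean.log2, 0.2)
        assert rep.n_retained == 2
        assert rep.n_retained + rep.n_removed == rep.n_input

    def test_all_removed_raises(self):
        prof = self._profile([0.2, 0.2], [1.0, 1.0])
        with pytest.raises(EmptyProfileError):
            qc_filter(prof, QCConfig())

    def test_qc_never_modifies_retained_values(self, rng):
        n = 30
        reps = rng.normal(0, 0.02, size=(n, 3))
        prof = make_profile(reps.mean(axis=1),
                            replicate_sd=rng.uniform(0, 0.15, n),
                            snr=rng.uniform(1, 30, n), replicates=reps)
        clean, _ = qc_filter(prof, QCConfig())
        keep = ~clean.missing
        assert np.allclose(clean.log2[keep], prof.log2[keep])


class TestSegmentation:
    CFG = SegmentationConfig(penalty_lambda=0.5, penalty_scale=1.0)

    def test_two_level_noise_free_signal(self):
        prof = make_profile([0, 0, 0, 1, 1, 1])
        seg = segment_profile(prof, self.CFG)
        assert [(s.start_idx, s.end_idx, s.mean_log2, s.state) for s in seg.segments] \
            == [(0, 3, 0.0, 0), (3, 6, 1.0, 1)]

    def test_constant_input_single_neutral_segment(self):
        prof = make_profile([0.05] * 8)
        seg = segment_profile(prof, self.CFG)
        assert len(seg.segments) == 1
        assert seg.segments[0].state == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_dp_matches_power_set_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        values = rng.normal(0, 0.3, n) + np.repeat(
            rng.choice([0.0, 0.8], size=3), [n // 3, n // 3, n - 2 * (n // 3)])
        lam = float(rng.uniform(0.2, 1.5))
        cfg = SegmentationConfig(penalty_lambda=lam, penalty_scale=1.0)
        got = segment_values(values, cfg)
        want, _ = segmentation_oracle(values, lam)
        assert got == want

    def test_objective_non_increasing_with_more_breakpoints_allowed(self, rng):
        values = rng.normal(0, 0.2, 30) + np.repeat([0, 0.9, 0], 10)
        from lineamp.acgh import _capped_dp
        objs = [_capped_dp(values, 0.1, k)[1] for k in range(5)]
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_breakpoint_cap_enforced(self, rng):
        values = rng.normal(0, 1.0, 25)
        cfg = SegmentationConfig(penalty_lambda=1e-6, penalty_scale=1.0,
                                 max_breakpoints_per_chrom=3)
        assert len(segment_values(values, cfg)) <= 3

    def test_missing_clones_belong_to_covering_segment(self):
        missing = np.array([False, False, True, False, False, False])
        prof = make_profile([0, 0, np.nan, 1, 1, 1], missing=missing)
        seg = segment_profile(prof, self.CFG)
        spans = [(s.start_idx, s.end_idx) for s in seg.segments]
        assert spans[0][0] == 0 and spans[-1][1] == 6
        assert sum(hi - lo for lo, hi in spans) == 6


class TestStateCalling:
    def test_states_follow_segment_means(self):
        prof = make_profile([0.5] * 3 + [0.0] * 3 + [-0.5] * 3)
        seg = segment_profile(prof, SegmentationConfig(penalty_lambda=0.1,
                                                       penalty_scale=1.0))
        states = call_states(seg, prof)
        assert states.tolist() == [1] * 3 + [0] * 3 + [-1] * 3

    def test_vector_length_and_missing_flagged(self):
        missing = np.zeros(6, dtype=bool)
        missing[4] = True
        prof = make_profile([0.5] * 6, missing=missing)
        seg = segment_profile(prof, SegmentationConfig(penalty_scale=1.0))
        states = call_states(seg, prof)
        assert len(states) == 6
        assert np.isnan(states[4]) and states[0] == 1


class TestAmplification:
    def test_singleton_above_threshold_rejected(self):
        prof = make_profile([0.1, 0.7, 0.65, 0.2, 0.9])
        amps = detect_amplifications(prof, AmplificationConfig(0.6, 2))
        assert [(a.start_idx, a.end_idx) for a in amps] == [(1, 3)]

    def test_all_below_threshold_empty(self):
        prof = make_profile([0.1, 0.5, 0.6, 0.2])
        assert detect_amplifications(prof, AmplificationConfig(0.6, 2)) == []

    def test_run_cannot_bridge_missing_clone(self):
        missing = np.array([False, True, False, False])
        prof = make_profile([0.9, np.nan, 0.9, 0.9], missing=missing)
        amps = detect_amplifications(prof, AmplificationConfig(0.6, 2))
        assert [(a.start_idx, a.end_idx) for a in amps] == [(2, 4)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_run_scanner(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 21))
        values = rng.uniform(-0.2, 1.2, n)
        missing = rng.random(n) < 0.15
        prof = make_profile(np.where(missing, np.nan, values), missing=missing)
        got = [(a.start_idx, a.end_idx)
               for a in detect_amplifications(prof, AmplificationConfig(0.6, 2))]
        assert got == amplification_runs_oracle(values, missing, 0.6, 2)

    def test_stricter_threshold_yields_clonewise_subset(self, rng):
        values = rng.uniform(0, 1.2, 60)
        prof = make_profile(values)
        cover = {}
        for thr in (0.6, 0.8):
            mask = np.zeros(60, dtype=bool)
            for a in detect_amplifications(prof, AmplificationConfig(thr, 2)):
                mask[a.start_idx:a.end_idx] = True
            cover[thr] = mask
        assert np.all(cover[0.8] <= cover[0.6])

    def test_group_score_counts_covering_samples(self):
        profs = []
        for i in range(20):
            vals = np.zeros(10)
            if i < 7:
                vals[4:6] = 0.9
            profs.append(make_profile(vals, sample_id=f"S{i}"))
        counts, frac = amplification_score(profs, AmplificationConfig(0.6, 2))
        assert counts[4] == 7 and frac[4] == pytest.approx(0.35)
        assert counts[0] == 0

    def test_mismatched_grids_rejected(self):
        a = make_profile([0.0] * 5)
        b = make_profile([0.0] * 6)
        with pytest.raises(ValueError):
            amplification_score([a, b])
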