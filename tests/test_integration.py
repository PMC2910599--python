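"""Expression statistics and copy-number integration."""

import numpy as np
import pandas as pd
import pytest

from lineamp.acgh import SegmentationConfig, segment_profile
from lineamp.integration import (ExpressionMatrix, IntegrationConfig,
                                 collapse_probes, diff_expression,
                                 dosage_correlation, dosage_group_test,
                                 gene_status, gene_zscore, tumor_vs_normal,
                                 windowed_values, windowed_zscore)

from conftest import make_profile


def make_expr(values: dict, cohorts: dict, probe_map=None, scale="log10"):
    df = pd.DataFrame(values, index=list(cohorts)).T
    if probe_map is None:
        probe_map = pd.DataFrame([
            {"probe_id": p, "gene": p.split("_")[0], "chrom": "chr1",
             "start": 0, "end": 1000} for p in df.index])
    return ExpressionMatrix(values=df, probe_map=probe_map,
                            cohorts=pd.Series(cohorts), scale=scale)


class TestDiffExpression:
    def test_exact_one_tailed_p_for_separated_groups(self):
        expr = make_expr({"G1_p": [1, 2, 3, 4, 5, 6]},
                         {f"s{i}": c for i, c in enumerate("AAABBB")})
        res = diff_expression(expr, "A", "B", "B>A")
        assert res.loc["G1_p", "p"] == pytest.approx(0.05)

    def test_constant_probe_flagged_with_p_one(self):
        expr = make_expr({"G1_p": [2, 2, 2, 2]},
                         {"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        res = diff_expression(expr, "A", "B")
        assert res.loc["G1_p", "constant"] and res.loc["G1_p", "p"] == 1.0

    def test_direction_flips_with_alternative(self):
        expr = make_expr({"G1_p": [4, 5, 6, 1, 2, 3]},
                         {f"s{i}": c for i, c in enumerate("AAABBB")})
        pa = diff_expression(expr, "A", "B", "B>A").loc["G1_p", "p"]
        pb = diff_expression(expr, "A", "B", "A>B").loc["G1_p", "p"]
        assert pb < 0.1 < pa


class TestCollapseProbes:
    PM = pd.DataFrame([
        {"probe_id": "p1", "gene": "G1", "chrom": "chr1", "start": 0, "end": 1},
        {"probe_id": "p2", "gene": "G1", "chrom": "chr1", "start": 0, "end": 1},
        {"probe_id": "p3", "gene": "G2", "chrom": "chr1", "start": 5, "end": 6},
    ])

    def test_min_p_rule_keeps_lowest_p_probe(self):
        res = pd.DataFrame({"p": [0.03, 0.001, 0.2]}, index=["p1", "p2", "p3"])
        out = collapse_probes(res, self.PM, "min_p")
        assert out.loc["G1", "probe_id"] == "p2"
        assert out.loc["G2", "probe_id"] == "p3"  # single-probe gene: identity

    def test_max_intensity_rule(self):
        res = pd.DataFrame({"p": [0.5, 0.5]}, index=["p1", "p2"])
        intensity = pd.Series({"p1": 5.1, "p2": 7.9})
        out = collapse_probes(res, self.PM, "max_intensity", intensity)
        assert out.loc["G1", "probe_id"] == "p2"

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            collapse_probes(pd.DataFrame({"p": [0.1]}, index=["p1"]),
                            self.PM, "best_guess")


class TestWindowedZscore:
    def test_standardization_definition(self, rng):
        prof = make_profile(rng.normal(0, 0.3, 50))
        _, z = windowed_zscore(prof, 10_000)
        ok = ~np.isnan(z)
        assert abs(z[ok].mean()) < 1e-10
        assert abs(z[ok].std() - 1) < 1e-10

    def test_window_inside_segment_equals_segment_value(self):
        prof = make_profile([0.0] * 5 + [0.8] * 5)
        starts, means = windowed_values(prof, 10_000)
        inside = (starts >= 5 * 80_000) & (starts + 10_000 <= 10 * 80_000)
        assert np.allclose(means[inside], 0.8)

    def test_constant_profile_z_undefined(self):
        prof = make_profile([0.2] * 10)
        with pytest.raises(ValueError):
            windowed_zscore(prof, 10_000)

    def test_gene_average_over_covering_windows(self):
        prof = make_profile([0.0] * 5 + [1.0] * 5)
        starts, z = windowed_zscore(prof, 10_000)
        val = gene_zscore(starts, z, 10_000, 6 * 80_000, 7 * 80_000)
        assert val == pytest.approx(z[np.isfinite(z)].max())


class TestDosageCorrelation:
    def test_perfectly_monotone_pairs(self):
        rho, p = dosage_correlation([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho1, _ = dosage_correlation(x, y)
        rho2, _ = dosage_correlation(np.exp(x), y ** 3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_refuses_fewer_than_four_pairs(self):
        with pytest.raises(ValueError):
            dosage_correlation([1, 2, 3], [1, 2, 3])

    def test_null_rejection_rate_bounded(self, rng):
        # dosage decoupled from expression: one-tailed test at 5% should not
        # reject materially more often than nominal
        hits = 0
        n_genes = 400
        for _ in range(n_genes):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            _, p = dosage_correlation(x, y)
            hits += p <= 0.05
        assert hits / n_genes < 0.08

    def test_mean_rho_increases_with_coupling_strength(self, rng):
        means = []
        for slope in (0.0, 0.5, 2.0):
            rhos = []
            for _ in range(60):
                x = rng.normal(size=15)
                y = slope * x + rng.normal(size=15)
                rhos.append(dosage_correlation(x, y)[0])
            means.append(np.mean(rhos))
        assert means[0] < means[1] < means[2]


class TestDosageGroupTest:
    def test_separated_groups_significant_with_guards(self):
        res = dosage_group_test(np.array([10, 11, 12, 1, 2, 3]),
                                np.array([1, 1, 1, 0, 0, 0]))
        assert res.p == pytest.approx(0.05)
        assert res.median_higher and res.mean_higher

    def test_guard_fails_when_gain_group_lower(self):
        res = dosage_group_test(np.array([1, 2, 3, 10, 11, 12]),
                                np.array([1, 1, 1, 0, 0, 0]))
        assert not res.median_higher and not res.mean_higher

    def test_loss_samples_excluded_and_counted(self):
        res = dosage_group_test(np.array([5.0, 6.0, 1.0, 2.0, -4.0]),
                                np.array([1, 1, 0, 0, -1]))
        assert res.n_loss_excluded == 1
        assert res.n_gain == 2 and res.n_neutral == 2

    def test_empty_group_not_testable(self):
        res = dosage_group_test(np.array([1.0, 2.0]), np.array([0, 0]))
        assert not res.testable and np.isnan(res.p)


class TestTumorVsNormal:
    def _expr(self):
        return make_expr({"G_p": [0.0] * 4}, {f"s{i}": "T" for i in range(4)})

    def test_fold_is_ratio_of_linear_medians(self):
        expr = self._expr()
        fold, _ = tumor_vs_normal(expr, np.log10([8, 8, 8.0]), np.log10([2, 2, 2.0]))
        assert fold == pytest.approx(4.0)

    def test_identical_distributions(self):
        expr = self._expr()
        fold, p = tumor_vs_normal(expr, np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert fold == pytest.approx(1.0)
        assert p >= 0.5

    def test_modest_fold_fails_elevation_criterion(self):
        expr = self._expr()
        fold, _ = tumor_vs_normal(expr, np.full(5, np.log10(1.3)), np.zeros(5))
        cfg = IntegrationConfig()
        assert fold == pytest.approx(1.3)
        assert fold < cfg.fold_min


class TestGeneStatus:
    def test_majority_state_of_overlapping_clones(self):
        prof = make_profile([0.0] * 4 + [0.6] * 4)
        seg = segment_profile(prof, SegmentationConfig(penalty_lambda=0.1,
                                                       penalty_scale=1.0))
        assert gene_status(seg, prof, 5 * 80_000, 7 * 80_000) == 1
        assert gene_status(seg, prof, 0, 2 * 80_000) == 0
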