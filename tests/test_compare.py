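"""Two-cohort disparity machinery: imputation, aggregation, Fisher, pipeline."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lineamp.compare import (ComparisonConfig, StateMatrix, aggregate_regions,
                             alteration_frequency, compare_cohorts, fisher_3x2,
                             impute_missing_states)

from _oracles import fisher_3x2_oracle


def make_matrix(states, cohorts, spacing=1_000_000):
    states = np.asarray(states, dtype=float)
    n, m = states.shape
    start = np.arange(n) * spacing
    return StateMatrix(
        states=states,
        clone_ids=np.array([f"C{i}" for i in range(n)]),
        chrom=np.full(n, "chr1"), start=start, end=start + 80_000,
        sample_ids=np.array([f"S{i}" for i in range(m)]),
        cohorts=np.asarray(cohorts),
    )


class TestImputation:
    def test_unanimous_flanking_neighbours(self):
        m = make_matrix([[1], [np.nan], [1]], ["A"])
        out = impute_missing_states(m)
        assert out.states[1, 0] == 1

    def test_neighbours_beyond_window_leave_missing(self):
        m = make_matrix([[1], [np.nan], [1]], ["A"], spacing=12_000_000)
        out = impute_missing_states(m)
        assert np.isnan(out.states[1, 0])

    def test_nearest_neighbour_wins_over_farther(self):
        # +1 at 2 Mb beats -1 at 5 Mb
        m = make_matrix([[1], [1], [np.nan], [np.nan], [np.nan], [-1]], ["A"],
                        spacing=1_000_000)
        out = impute_missing_states(m)
        assert out.states[2, 0] == 1   # 1 Mb vs 3 Mb
        assert out.states[4, 0] == -1  # 1 Mb vs 3 Mb
        assert out.states[3, 0] == 0   # exact tie, disagreeing states

    def test_idempotent_and_observed_preserved(self, rng):
        states = rng.choice([-1.0, 0.0, 1.0, np.nan], size=(40, 6),
                            p=[0.2, 0.4, 0.2, 0.2])
        m = make_matrix(states, ["A"] * 6)
        once = impute_missing_states(m)
        twice = impute_missing_states(once)
        obs = ~np.isnan(states)
        assert np.array_equal(once.states[obs], states[obs])
        assert np.array_equal(once.states, twice.states, equal_nan=True)


class TestAggregation:
    def test_identical_samples_single_region(self):
        m = make_matrix(np.ones((8, 4)), ["A"] * 4)
        assert aggregate_regions(m, "A") == [(0, 8)]

    def test_eighty_percent_agreement_splits(self):
        # adjacent pair agrees in 8/10 samples: 0.8 < 0.9 forces a boundary
        col = np.zeros((2, 10))
        col[1, :2] = 1
        m = make_matrix(col, ["A"] * 10)
        assert aggregate_regions(m, "A") == [(0, 1), (1, 2)]

    def test_partition_covers_every_clone_once(self, rng):
        states = rng.choice([-1.0, 0.0, 1.0], size=(25, 10))
        m = make_matrix(states, ["A"] * 10)
        runs = aggregate_regions(m, "A")
        flat = [i for lo, hi in runs for i in range(lo, hi)]
        assert flat == list(range(25))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_left_to_right_pairwise_scan(self, seed):
        rng = np.random.default_rng(seed)
        states = rng.choice([-1.0, 0.0, 1.0, np.nan], size=(15, 8),
                            p=[0.1, 0.5, 0.3, 0.1])
        m = make_matrix(states, ["A"] * 8)
        runs = aggregate_regions(m, "A")
        # oracle: insert boundary whenever pairwise agreement < 0.9
        cuts = []
        for i in range(14):
            ok = ~(np.isnan(states[i]) | np.isnan(states[i + 1]))
            if ok.sum() and (states[i][ok] == states[i + 1][ok]).mean() < 0.9:
                cuts.append(i + 1)
        edges = [0] + cuts + [15]
        assert runs == list(zip(edges[:-1], edges[1:]))


class TestFisher:
    def test_three_table_example(self):
        p = fisher_3x2([[2, 0], [0, 0], [0, 2]])
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_columns_p_one(self):
        assert fisher_3x2([[3, 3], [4, 4], [2, 2]]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle_small_totals(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            t = rng.integers(0, 5, size=(3, 2))
            if 0 < t.sum() <= 12:
                break
        assert fisher_3x2(t) == pytest.approx(fisher_3x2_oracle(t), abs=1e-12)

    @given(st.lists(st.integers(0, 6), min_size=6, max_size=6))
    def test_column_exchange_symmetry(self, cells):
        t = np.asarray(cells).reshape(3, 2)
        if t.sum() == 0:
            return
        assert fisher_3x2(t) == pytest.approx(fisher_3x2(t[:, ::-1]), abs=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fisher_3x2(np.zeros((3, 2), dtype=int))

    def test_agrees_with_r_fisher_test(self, tmp_path):
        """Cross-check the exact r x c p-value against R's fisher.test."""
        tables = [[[8, 1], [10, 12], [2, 7]],
                  [[5, 0], [3, 3], [0, 4]],
                  [[1, 2], [3, 4], [5, 6]]]
        script = tmp_path / "fisher.R"
        lines = ["options(digits=15)"]
        for t in tables:
            flat = ",".join(str(v) for row in t for v in row)
            lines.append(
                f"cat(fisher.test(matrix(c({flat}), nrow=3, byrow=TRUE))$p.value, '\\n')")
        script.write_text("\n".join(lines))
        out = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True, check=True)
        r_ps = [float(v) for v in out.stdout.split()]
        for t, rp in zip(tables, r_ps):
            assert fisher_3x2(t) == pytest.approx(rp, rel=1e-8)


class TestCompareCohorts:
    def _planted_matrix(self, rng, freq_b=0.4, freq_a=0.0, n=50):
        states = np.zeros((30, 2 * n))
        for col in range(n):          # cohort A columns 0..n-1
            if rng.random() < freq_a:
                states[10:20, col] = 1
        for col in range(n, 2 * n):   # cohort B
            if rng.random() < freq_b:
                states[10:20, col] = 1
        return make_matrix(states, ["A"] * n + ["B"] * n, spacing=100_000)

    def test_planted_gain_reported_with_direction_and_frequencies(self):
        states = np.zeros((30, 100))
        states[10:20, 50:70] = 1      # 40% of B, 0% of A
        m = make_matrix(states, ["A"] * 50 + ["B"] * 50, spacing=100_000)
        regions = compare_cohorts(m, "A", "B")
        assert len(regions) == 1
        r = regions[0]
        assert r.direction_state == 1 and r.direction_cohort == "B"
        assert r.freq_a == 0.0 and r.freq_b == pytest.approx(0.40)
        assert set(r.clone_indices) == set(range(10, 20))

    def test_low_frequency_region_excluded_by_twenty_percent_rule(self):
        states = np.zeros((30, 200))
        states[10:20, 100:115] = 1    # 15% of B, 0% of A: p tiny but filtered
        m = make_matrix(states, ["A"] * 100 + ["B"] * 100, spacing=100_000)
        assert compare_cohorts(m, "A", "B") == []

    def test_small_frequency_difference_excluded(self):
        states = np.zeros((30, 100))
        states[10:20, :20] = 1        # 40% of A
        states[10:20, 50:72] = 1      # 44% of B: difference below 10%
        m = make_matrix(states, ["A"] * 50 + ["B"] * 50, spacing=100_000)
        assert compare_cohorts(m, "A", "B") == []

    def test_all_neutral_degenerate_returns_empty(self):
        m = make_matrix(np.zeros((10, 8)), ["A"] * 4 + ["B"] * 4)
        assert compare_cohorts(m, "A", "B") == []

    def test_adjacent_concordant_regions_merge_within_gap(self):
        states = np.zeros((9, 40))
        states[0:3, 20:35] = 1
        states[6:9, 20:35] = 1        # same carriers, 0.5 Mb gap at clones 3-5
        m = make_matrix(states, ["A"] * 20 + ["B"] * 20, spacing=250_000)
        regions = compare_cohorts(m, "A", "B")
        assert len(regions) == 1
        assert regions[0].start_bp == 0 and regions[0].end_bp > 8 * 250_000


class TestAlterationFrequency:
    def test_counting_and_denominator_rules(self):
        states = np.array([[1, 1, 1, 1, 0, 0, 0, 0, 0, -1],
                           [np.nan] * 10]).astype(float)
        m = make_matrix(states, ["A"] * 10)
        freq = alteration_frequency(m, "A")
        assert freq["gain"][0] == pytest.approx(0.4)
        assert freq["loss"][0] == pytest.approx(0.1)
        assert np.isnan(freq["gain"][1])  # all missing: undefined, not zero

    def test_conservation_of_counts(self, rng):
        states = rng.choice([-1.0, 0.0, 1.0, np.nan], size=(12, 20))
        m = make_matrix(states, ["A"] * 20)
        f = alteration_frequency(m, "A")
        n_gain = np.nansum(states == 1, axis=1)
        n_loss = np.nansum(states == -1, axis=1)
        n_neut = np.nansum(states == 0, axis=1)
        assert np.all(n_gain + n_loss + n_neut == f["n_observed"])
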