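"""Association-statistics layer: chi-square, Spearman, group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lupustrat.panels import ScoreTable
from lupustrat.stats import (
    ContingencyTable,
    dunn_posthoc,
    kruskal_wallis,
    one_way_anova,
    pearson_chi_square,
    score_vs_domain_activity,
    spearman,
    tukey_hsd,
    two_sample_t,
)


def table(counts):
    counts = np.asarray(counts)
    return ContingencyTable(
        counts,
        tuple(f"r{i}" for i in range(counts.shape[0])),
        tuple(f"c{j}" for j in range(counts.shape[1])),
    )


def chi_square_double_loop(counts):
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            expected = counts[i].sum() * counts[:, j].sum() / total
            stat += (counts[i, j] - expected) ** 2 / expected
    return stat


class TestChiSquare:
    def test_published_nea_cluster_table(self):
        result = pearson_chi_square(table([[1, 7], [7, 10], [17, 3]]))
        assert round(result.statistic, 1) == 14.5
        assert result.df == 2 and result.p_value < 0.001

    def test_published_ea_cluster_table(self):
        result = pearson_chi_square(table([[19, 12], [13, 5], [13, 3]]))
        assert round(result.statistic, 1) == 2.1

    def test_no_continuity_correction_on_2x2(self):
        result = pearson_chi_square(table([[45, 20], [25, 20]]))
        # the corrected statistic would be ~1.65; uncorrected matches print
        assert result.statistic == pytest.approx(2.149, abs=0.005)
        assert result.p_value == pytest.approx(0.142, abs=0.002)

    def test_identical_row_proportions_give_zero(self):
        result = pearson_chi_square(table([[10, 20], [5, 10]]))
        assert result.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            shape = (int(rng.integers(2, 5)), int(rng.integers(2, 4)))
            counts = rng.integers(1, 40, size=shape)
            mine = pearson_chi_square(table(counts)).statistic
            assert mine == pytest.approx(chi_square_double_loop(counts), abs=1e-12)

    def test_invariant_under_row_and_column_permutation(self):
        counts = np.array([[3, 9, 2], [8, 1, 6], [4, 4, 4]])
        base = pearson_chi_square(table(counts)).statistic
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = counts[rng.permutation(3)][:, rng.permutation(3)]
            assert pearson_chi_square(table(perm)).statistic == pytest.approx(base)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            table([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            table([[1, 2]])


class TestSpearman:
    def test_perfect_monotone_and_antitone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, x**3).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 6, 20).astype(float)  # many ties
        y = rng.integers(0, 6, 20).astype(float)
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).rho == pytest.approx(oracle, abs=1e-12)

    @given(
        scale=st.floats(0.1, 10, allow_nan=False),
        shift=st.floats(-5, 5, allow_nan=False),
    )
    def test_invariant_under_strictly_monotone_transforms(self, scale, shift):
        x = np.array([0.3, 1.7, 2.2, 4.0, 9.1, 0.1])
        y = np.array([2.0, 0.5, 3.3, 1.1, 8.8, 4.4])
        base = spearman(x, y).rho
        assert spearman(np.exp(scale * x) + shift, y).rho == pytest.approx(base)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            result = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(result.rho)


class TestGroupTests:
    def test_identical_groups_give_zero_statistics(self):
        g = [1.0, 2.0, 3.0, 4.0]
        assert two_sample_t(g, g).statistic == pytest.approx(0.0)
        assert one_way_anova([g, g]).statistic == pytest.approx(0.0)

    def test_welch_and_pooled_differ_under_unequal_variance(self):
        a = [0.0, 0.1, -0.1, 0.05, 0.2, -0.2]
        b = [1.0, 5.0, -3.0, 8.0, -6.0, 2.0]
        welch = two_sample_t(a, b, variant="welch")
        pooled = two_sample_t(a, b, variant="pooled")
        assert welch.df != pooled.df

    def test_kruskal_wallis_type_one_error_calibrated(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = [rng.normal(size=15) for _ in range(3)]
            if kruskal_wallis(groups).p_value <= 0.05:
                rejections += 1
        assert abs(rejections / n_sim - 0.05) <= 0.02

    def test_tukey_flags_only_shifted_group(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 0.1, 10), rng.normal(0, 0.1, 10),
                  rng.normal(5, 0.1, 10)]
        results = tukey_hsd(groups, labels=["a", "b", "c"])
        for r in results:
            involves_c = "c" in (r.group_a, r.group_b)
            assert (r.p_value <= 0.05) is involves_c

    def test_dunn_flags_only_shifted_group(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 25), rng.normal(0, 1, 25), rng.normal(4, 1, 25)]
        results = dunn_posthoc(groups, labels=["a", "b", "c"])
        for r in results:
            involves_c = "c" in (r.group_a, r.group_b)
            assert (r.p_value <= 0.05) is involves_c

    def test_dunn_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(size=12) for _ in range(3)]
        raw = {(r.group_a, r.group_b): r.p_value for r in dunn_posthoc(groups)}
        adj = {(r.group_a, r.group_b): r.p_value
               for r in dunn_posthoc(groups, adjust="bonferroni")}
        for key in raw:
            assert adj[key] >= raw[key] - 1e-12

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestScoreVsDomain:
    @staticmethod
    def _inputs(effect, n=60, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"p{i}" for i in range(n)]
        active = rng.random(n) < 0.5
        scores = ScoreTable(
            pd.DataFrame(
                {"neutrophil": rng.normal(0, 1, n) + effect * active},
                index=pd.Index(samples, name="sample"),
            )
        )
        clinical = pd.DataFrame(
            {
                "patient_id": samples,
                "renal_baseline": np.where(active, "A", "D"),
            }
        )
        return scores, clinical

    def test_planted_shift_detected(self):
        scores, clinical = self._inputs(effect=2.0)
        result = score_vs_domain_activity(scores, clinical, "renal")["neutrophil"]
        assert result.p_value < 0.001 and result.statistic > 0

    def test_null_type_one_error(self):
        rejections = 0
        n_sim = 200
        for seed in range(n_sim):
            scores, clinical = self._inputs(effect=0.0, n=40, seed=seed)
            result = score_vs_domain_activity(scores, clinical, "renal")["neutrophil"]
            rejections += result.p_value <= 0.05
        assert rejections / n_sim <= 0.07  # p > 0.05 in >= 93% of null runs

    def test_empty_group_skipped_with_warning(self):
        scores, clinical = self._inputs(effect=0.0, n=10)
        clinical["renal_baseline"] = "D"  # nobody active
        with pytest.warns(UserWarning, match="skipped"):
            out = score_vs_domain_activity(scores, clinical, "renal")
        assert out == {}

    def test_unknown_domain_rejected(self):
        scores, clinical = self._inputs(effect=0.0, n=10)
        with pytest.raises(ValueError, match="domain"):
            score_vs_domain_activity(scores, clinical, "kidney")
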