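"""Standardisation, complete-linkage agglomeration and archetype labels."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from conftest import brute_force_complete_linkage
from lupustrat.cluster import (
    StandardizedMatrix,
    complete_linkage_cluster,
    label_archetypes,
    standardize,
)
from lupustrat.panels import ScoreTable
from lupustrat.qpcr import ExpressionMatrix


def std_from(values):
    values = np.asarray(values, dtype=float)
    return StandardizedMatrix(
        tuple(f"g{i}" for i in range(values.shape[0])),
        tuple(f"s{j}" for j in range(values.shape[1])),
        values,
    )


class TestStandardize:
    def test_unit_spacing_row(self):
        expr = ExpressionMatrix(("g0",), ("a", "b", "c"), [[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(standardize(expr).values, [[-1.0, 0.0, 1.0]])

    def test_constant_row_zeroed_with_warning(self):
        expr = ExpressionMatrix(("g0", "g1"), ("a", "b"), [[5.0, 5.0], [0.0, 1.0]])
        with pytest.warns(UserWarning, match="constant"):
            std = standardize(expr)
        np.testing.assert_array_equal(std.values[0], 0.0)

    def test_single_sample_is_error(self):
        expr = ExpressionMatrix(("g0",), ("a",), [[1.0]])
        with pytest.raises(ValueError):
            standardize(expr)

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        expr = ExpressionMatrix(
            tuple(f"g{i}" for i in range(94)),
            tuple(f"s{j}" for j in range(80)),
            rng.normal(size=(94, 80)),
        )
        std = standardize(expr).values
        np.testing.assert_allclose(std.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(std.std(axis=1, ddof=1), 1.0, atol=1e-9)


class TestCompleteLinkage:
    def test_identical_points_single_cluster_zero_heights(self):
        std = std_from([[1.0, 1.0, 1.0]])
        a = complete_linkage_cluster(std, k=1)
        assert a.k == 1
        assert [m[2] for m in a.merges] == [0.0, 0.0]

    def test_one_dimensional_example(self):
        # points {0, 1, 10}: first merge at 1, final at max(9, 10) = 10
        std = std_from([[0.0, 1.0, 10.0]])
        a = complete_linkage_cluster(std, k=2)
        assert set(a.members(a.labels[0])) == {"s0", "s1"}
        assert a.members(a.labels[2]) == ("s2",)
        heights = [m[2] for m in a.merges]
        assert heights == [1.0, 10.0]

    def test_invalid_k_rejected(self):
        std = std_from([[0.0, 1.0]])
        for k in (0, 3):
            with pytest.raises(ValueError):
                complete_linkage_cluster(std, k=k)

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_brute_force_rescan_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(3, 9))
        values = rng.normal(size=(int(rng.integers(1, 6)), n))
        std = std_from(values)
        dist = squareform(pdist(values.T))
        for k in range(1, n + 1):
            mine = complete_linkage_cluster(std, k=k)
            oracle = brute_force_complete_linkage(dist, k)
            oracle_sets = frozenset(
                frozenset(std.samples[i] for i in c) for c in oracle
            )
            assert mine.partition() == oracle_sets

    def test_matches_library_linkage_on_larger_instances(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(20, 60))
        std = std_from(values)
        mine = complete_linkage_cluster(std, k=3)
        ref = fcluster(linkage(values.T, method="complete"), t=3, criterion="maxclust")
        assert adjusted_rand_score(mine.labels, ref) == pytest.approx(1.0)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(4)
        std = std_from(rng.normal(size=(10, 40)))
        a = complete_linkage_cluster(std, k=3)
        heights = [m[2] for m in a.merges]
        assert all(h1 <= h2 + 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_partition_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(8, 12))
        std = std_from(values)
        base = complete_linkage_cluster(std, k=3).partition()
        perm = rng.permutation(12)
        permuted = StandardizedMatrix(
            std.transcripts, tuple(std.samples[i] for i in perm), values[:, perm]
        )
        assert complete_linkage_cluster(permuted, k=3).partition() == base

    def test_tie_break_is_lexicographic(self):
        # four equidistant pairs: (0,1) must merge first, then (2,3)
        std = std_from([[0.0, 1.0, 10.0, 11.0]])
        a = complete_linkage_cluster(std, k=2)
        assert a.merges[0][:2] == (0, 1)
        assert a.merges[1][:2] == (2, 3)

    def test_newick_export_parses(self):
        std = std_from([[0.0, 1.0, 10.0]])
        text = complete_linkage_cluster(std, k=1).to_newick()
        assert text.endswith(";") and "s2" in text
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(text), "newick")
        assert tree.count_terminals() == 3


class TestArchetypes:
    @staticmethod
    def _label(planted_cohort, stratum):
        from lupustrat.cluster import standardize
        from lupustrat.panels import compute_scores, default_registry
        from lupustrat.qpcr import impute_nondetects, to_expression

        config, ct, clinical, truth = planted_cohort
        expr = to_expression(impute_nondetects(ct))
        samples = [s for s in expr.samples if s.startswith("NEA") == (stratum == "NEA")]
        std = standardize(expr.subset_samples(samples))
        assignment = complete_linkage_cluster(std, k=3, stratum=stratum)
        scores = compute_scores(expr, default_registry())
        scores = ScoreTable(scores.scores.loc[samples])
        return label_archetypes(assignment, scores), truth, samples

    def test_nea_planted_cohort_yields_nea_archetypes(self, small_cohort):
        labelled, truth, samples = self._label(small_cohort, "NEA")
        assert sorted(labelled.archetypes.values()) == sorted(
            ["IFN-low/neutrophil-high", "IFN-high/neutrophil-low", "all-high"]
        )

    def test_ea_planted_cohort_yields_ea_archetypes(self, small_cohort):
        labelled, truth, samples = self._label(small_cohort, "EA")
        assert sorted(labelled.archetypes.values()) == sorted(
            ["all-high", "IFN-high/neutrophil-low", "all-low"]
        )

    def test_archetypes_match_planted_clusters(self, small_cohort):
        labelled, truth, samples = self._label(small_cohort, "NEA")
        planted = truth.frame.set_index("patient_id")
        # majority archetype within each found cluster equals the planted one
        for cid in range(1, 4):
            members = labelled.members(cid)
            majority = planted.loc[list(members), "archetype"].mode()[0]
            assert labelled.archetypes[cid] == majority

    def test_single_cluster_labelled_against_stratum_median(self):
        std = std_from(np.zeros((2, 4)) + np.arange(4))
        assignment = complete_linkage_cluster(std, k=1)
        scores = ScoreTable(
            pd.DataFrame(
                {"IFN-Score-A": [1.0, 2.0, 3.0, 4.0],
                 "neutrophil": [4.0, 3.0, 2.0, 1.0]},
                index=list(std.samples),
            )
        )
        labelled = label_archetypes(assignment, scores)
        # cluster medians equal the stratum medians: ties resolve to high/high
        assert labelled.archetypes[1] == "all-high"

    def test_missing_scores_rejected(self):
        std = std_from([[0.0, 1.0, 5.0]])
        assignment = complete_linkage_cluster(std, k=2)
        scores = ScoreTable(
            pd.DataFrame({"IFN-Score-A": [0.0], "neutrophil": [0.0]}, index=["s0"])
        )
        with pytest.raises(ValueError, match="without scores"):
            label_archetypes(assignment, scores)
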