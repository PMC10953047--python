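"""Association statistics for cluster / response / score comparisons.

Thin, validated wrappers over scipy and statsmodels for the tests used in the
registry analysis — Pearson chi-square on contingency tables (never with a
continuity correction), Spearman correlation, Kruskal-Wallis with Dunn's post
hoc, two-sample t (Welch by default), one-way ANOVA with Tukey's HSD — plus
the score-versus-domain-activity comparison, which dichotomises patients at
BILAG grade A/B versus grade C or lower for an organ domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .bilag import DOMAINS
from .panels import ScoreTable

__all__ = [
    "ContingencyTable",
    "TestResult",
    "CorrelationResult",
    "PairwiseResult",
    "pearson_chi_square",
    "spearman",
    "kruskal_wallis",
    "two_sample_t",
    "one_way_anova",
    "tukey_hsd",
    "dunn_posthoc",
    "score_vs_domain_activity",
]

#: Significance convention used throughout the analysis.
ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyTable:
    """Labelled non-negative integer counts (e.g. clusters × response)."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("need at least 2 rows and 2 columns")
        if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        if (counts.sum(axis=1) == 0).any():
            raise ValueError("all-zero row in contingency table")
        if (counts.sum(axis=0) == 0).any():
            raise ValueError("all-zero column in contingency table")
        if len(self.row_labels) != counts.shape[0] or len(self.col_labels) != counts.shape[1]:
            raise ValueError("label lengths do not match counts shape")
        object.__setattr__(self, "counts", counts.astype(int))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ContingencyTable":
        return cls(
            frame.to_numpy(),
            tuple(str(r) for r in frame.index),
            tuple(str(c) for c in frame.columns),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    test: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")

    @property
    def significant(self) -> bool:
        return bool(self.p_value <= ALPHA)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_value: float


def pearson_chi_square(table: ContingencyTable) -> TestResult:
    """Pearson chi-square of independence, without continuity correction.

    statistic = Σ (O−E)²/E with expected counts from the row/column margins;
    df = (r−1)(c−1); p from the upper tail of the chi-square distribution.
    A zero expected count is an error (the statistic is undefined there).
    """
    counts = table.counts.astype(float)
    expected = sps.contingency.expected_freq(counts)
    zero = np.argwhere(expected == 0.0)
    if zero.size:
        r, c = zero[0]
        raise ValueError(
            f"zero expected count at row {table.row_labels[r]!r}, "
            f"column {table.col_labels[c]!r}"
        )
    stat, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return TestResult(float(stat), float(df), float(p), test="pearson-chi-square")


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties; p from the
    t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return CorrelationResult(float("nan"), float("nan"), int(x.size))
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), int(x.size))


def _check_groups(groups: Sequence[Sequence[float]], min_size: int) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    small = [i for i, g in enumerate(arrays) if g.size < min_size]
    if small:
        raise ValueError(f"groups below minimum size {min_size}: indices {small}")
    return arrays


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across ≥2 groups."""
    arrays = _check_groups(groups, min_size=1)
    if sum(g.size for g in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    stat, p = sps.kruskal(*arrays)
    return TestResult(float(stat), float(len(arrays) - 1), float(p), test="kruskal-wallis")


def two_sample_t(
    a: Sequence[float], b: Sequence[float], variant: str = "welch"
) -> TestResult:
    """Two-sample t test; ``variant`` is ``"welch"`` (default) or ``"pooled"``."""
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a, b = _check_groups([a, b], min_size=2)
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TestResult(
        float(res.statistic), float(res.df), float(res.pvalue), test=f"t-{variant}"
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA F test."""
    arrays = _check_groups(groups, min_size=2)
    stat, p = sps.f_oneway(*arrays)
    return TestResult(float(stat), float(len(arrays) - 1), float(p), test="anova-F")


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> list[PairwiseResult]:
    """Tukey's honestly-significant-difference post hoc over all group pairs."""
    arrays = _check_groups(groups, min_size=2)
    labels = list(labels) if labels is not None else [str(i + 1) for i in range(len(arrays))]
    res = sps.tukey_hsd(*arrays)
    out = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            out.append(
                PairwiseResult(
                    labels[i], labels[j],
                    float(res.statistic[i, j]), float(res.pvalue[i, j]),
                )
            )
    return out


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: str | None = None,
) -> list[PairwiseResult]:
    """Dunn's rank-based post hoc test over all group pairs.

    Pooled mid-ranks with tie correction; z statistic per pair
    z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T) (1/n_i + 1/n_j)) where
    T = Σ(t³−t) / (12(N−1)); two-sided normal p values, unadjusted by default
    (``adjust`` may be ``"bonferroni"`` or ``"holm"``).
    """
    arrays = _check_groups(groups, min_size=1)
    labels = list(labels) if labels is not None else [str(i + 1) for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start:start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairs, zs, ps = [], [], []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            pairs.append((labels[i], labels[j]))
            zs.append(float(z))
            ps.append(float(2.0 * sps.norm.sf(abs(z))))
    if adjust is not None:
        ps = list(multipletests(ps, method=adjust)[1])
    return [
        PairwiseResult(a, b, z, p) for (a, b), z, p in zip(pairs, zs, ps)
    ]


def score_vs_domain_activity(
    scores: ScoreTable,
    clinical: pd.DataFrame,
    domain: str,
    panel: str | None = None,
    variant: str = "welch",
    grade_column_suffix: str = "_baseline",
) -> dict[str, TestResult]:
    """Compare signature scores between active and inactive patients for one
    BILAG domain.

    Patients are dichotomised at grade A/B (active) versus grade C or lower
    for ``domain`` at baseline; each panel score (or just ``panel``) is
    compared between the two groups by a two-sample t test.  An empty group
    skips the comparison with a warning.
    """
    if domain not in DOMAINS:
        raise ValueError(f"unknown BILAG domain {domain!r}")
    col = f"{domain}{grade_column_suffix}"
    if col not in clinical.columns:
        raise ValueError(f"clinical table lacks column {col!r}")
    table = clinical
    if not set(scores.samples) <= set(table.index):
        id_cols = [c for c in table.columns if c.lower() in ("patient_id", "sample", "id")]
        if not id_cols:
            raise ValueError("clinical table is not indexed by patient id")
        table = table.set_index(id_cols[0])
    grades = table[col].reindex(scores.samples)
    active = grades.astype(str).str.upper().isin(["A", "B"]).to_numpy()
    panels = [panel] if panel is not None else list(scores.panels)
    out: dict[str, TestResult] = {}
    for name in panels:
        values = scores[name].to_numpy()
        a, b = values[active], values[~active]
        if a.size < 2 or b.size < 2:
            warnings.warn(
                f"domain {domain!r}, panel {name!r}: a group has <2 patients; "
                "comparison skipped",
                stacklevel=2,
            )
            continue
        out[name] = two_sample_t(a, b, variant=variant)
    return out
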