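"""End-to-end cohort model: data in, fitted stratification results out.

`CohortStratificationModel` wraps the whole registry analysis in a
model/results pair: construct it from a Ct matrix plus a clinical table,
call :meth:`~CohortStratificationModel.fit`, and read estimates off the
returned :class:`CohortStratificationResults` — signature scores, per-stratum
cluster assignments and archetypes, BILAG response labels, cluster × response
contingency tables with their chi-square statistics, and a text
``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import bilag
from .bilag import ResponseLabel, assessments_from_row, check_eligibility
from .cluster import (
    ClusterAssignment,
    complete_linkage_cluster,
    label_archetypes,
    standardize,
)
from .panels import (
    PanelRegistry,
    ScoreTable,
    compute_scores,
    default_registry,
    load_panel_registry,
)
from .qpcr import (
    CtMatrix,
    DEFAULT_CENSOR_CT,
    ExpressionMatrix,
    impute_nondetects,
    read_ct_table,
    to_expression,
)
from .stats import ContingencyTable, TestResult, pearson_chi_square

__all__ = ["CohortStratificationModel", "CohortStratificationResults"]


class CohortStratificationModel:
    """Ancestry-stratified transcriptional stratification of a treated cohort.

    Parameters
    ----------
    ct : CtMatrix
        Raw qPCR Ct values with non-detect flags, including the reference
        gene row.
    clinical : pandas.DataFrame
        One row per patient with a ``patient_id`` column matching the Ct
        sample ids, a stratum column (default ``stratum``), BILAG grade
        columns ``<domain>_baseline`` / ``<domain>_m6``, and optionally a
        ``rituximab_cycle`` column used to restrict to first-cycle patients.
    registry : PanelRegistry, optional
        Gene-panel registry; the packaged synthetic default when omitted.
    censor_ct : float
        Detection limit in cycles for non-detect imputation.
    k : int
        Number of clusters cut per stratum.
    persisting_b_rule, t_variant : str
        Readings of the response rule's persisting-B clause and the t-test
        variant passed through to downstream comparisons.
    """

    def __init__(
        self,
        ct: CtMatrix,
        clinical: pd.DataFrame,
        registry: PanelRegistry | None = None,
        censor_ct: float = DEFAULT_CENSOR_CT,
        k: int = 3,
        stratum_column: str = "stratum",
        persisting_b_rule: str = "total",
        t_variant: str = "welch",
        first_cycle_only: bool = True,
    ) -> None:
        if "patient_id" not in clinical.columns:
            raise ValueError("clinical table needs a patient_id column")
        if stratum_column not in clinical.columns:
            raise ValueError(f"clinical table needs a {stratum_column!r} column")
        missing = set(ct.samples) - set(clinical["patient_id"].astype(str))
        if missing:
            raise ValueError(
                f"{len(missing)} Ct samples have no clinical row, e.g. "
                f"{sorted(missing)[:3]}"
            )
        self.ct = ct
        self.clinical = clinical.copy()
        self.registry = registry if registry is not None else default_registry()
        self.censor_ct = float(censor_ct)
        self.k = int(k)
        self.stratum_column = stratum_column
        self.persisting_b_rule = persisting_b_rule
        self.t_variant = t_variant
        self.first_cycle_only = first_cycle_only

    @classmethod
    def from_files(
        cls,
        ct_path: str | Path,
        clinical_path: str | Path,
        registry_path: str | Path | None = None,
        reference_gene: str = "PPIA",
        nd_token: str = "ND",
        **kwargs,
    ) -> "CohortStratificationModel":
        ct = read_ct_table(ct_path, reference_transcript=reference_gene,
                           nondetect_token=nd_token)
        clinical = pd.read_csv(clinical_path, dtype={"patient_id": str})
        registry = (
            load_panel_registry(registry_path) if registry_path is not None else None
        )
        return cls(ct, clinical, registry=registry, **kwargs)

    # -- fitting ---------------------------------------------------------

    def _response_labels(self, indexed: pd.DataFrame) -> pd.Series:
        labels: dict[str, str] = {}
        for pid, row in indexed.iterrows():
            baseline, month6 = assessments_from_row(row)
            if not check_eligibility(baseline):
                labels[pid] = "ineligible"
                continue
            labels[pid] = bilag.classify_response(
                baseline, month6, persisting_b_rule=self.persisting_b_rule
            ).value
        return pd.Series(labels, name="response")

    def fit(self) -> "CohortStratificationResults":
        """Run imputation → scores → stratified clustering → response →
        association statistics and return the results object."""
        imputed = impute_nondetects(self.ct, censor_ct=self.censor_ct)
        expression = to_expression(imputed)
        scores = compute_scores(expression, self.registry)

        indexed = self.clinical.set_index(self.clinical["patient_id"].astype(str))
        strata = indexed[self.stratum_column].astype(str)
        scores = scores.with_stratum(strata.reindex(scores.samples))
        response = self._response_labels(indexed)

        analysed = [s for s in expression.samples if response.get(s) != "ineligible"]
        if self.first_cycle_only and "rituximab_cycle" in indexed.columns:
            analysed = [
                s for s in analysed if int(indexed.loc[s, "rituximab_cycle"]) == 1
            ]

        assignments: dict[str, ClusterAssignment] = {}
        for stratum in sorted(strata.unique()):
            members = [s for s in analysed if strata[s] == stratum]
            if len(members) < self.k:
                raise ValueError(
                    f"stratum {stratum!r} has {len(members)} analysable patients; "
                    f"cannot cut {self.k} clusters"
                )
            sub = standardize(expression.subset_samples(members))
            assignment = complete_linkage_cluster(sub, k=self.k, stratum=stratum)
            stratum_scores = ScoreTable(scores.scores.loc[members])
            assignments[stratum] = label_archetypes(assignment, stratum_scores)

        tables, tests = self._associations(assignments, strata, response)
        return CohortStratificationResults(
            model=self,
            expression=expression,
            scores=scores,
            assignments=assignments,
            response=response,
            contingency=tables,
            tests=tests,
        )

    def _associations(
        self,
        assignments: Mapping[str, ClusterAssignment],
        strata: pd.Series,
        response: pd.Series,
    ) -> tuple[dict[str, ContingencyTable], dict[str, TestResult]]:
        determined = response.isin(
            [ResponseLabel.RESPONDER.value, ResponseLabel.NONRESPONDER.value]
        )
        tables: dict[str, ContingencyTable] = {}
        tests: dict[str, TestResult] = {}
        for stratum, assignment in assignments.items():
            counts = []
            labels = []
            for cid in range(1, assignment.k + 1):
                members = [
                    s for s in assignment.members(cid) if determined.get(s, False)
                ]
                resp = sum(response[s] == "responder" for s in members)
                counts.append([resp, len(members) - resp])
                labels.append(f"{stratum}-{cid}")
            counts = np.asarray(counts)
            try:
                table = ContingencyTable(
                    counts, tuple(labels), ("responder", "nonresponder")
                )
                tables[stratum] = table
                tests[f"cluster_response_{stratum}"] = pearson_chi_square(table)
            except ValueError:
                pass  # degenerate table (e.g. no determined responses)
        # ancestry stratum × response, over all determined patients
        rows = []
        names = sorted(set(strata.loc[response.index[determined]].dropna()))
        for stratum in names:
            members = [
                s for s in response.index[determined] if strata.get(s) == stratum
            ]
            resp = sum(response[s] == "responder" for s in members)
            rows.append([resp, len(members) - resp])
        if len(rows) >= 2:
            try:
                table = ContingencyTable(
                    np.asarray(rows), tuple(names), ("responder", "nonresponder")
                )
                tables["ancestry"] = table
                tests["ancestry_response"] = pearson_chi_square(table)
            except ValueError:
                pass
        return tables, tests


@dataclass
class CohortStratificationResults:
    """Fitted stratification of one cohort.

    Attributes
    ----------
    scores : ScoreTable
        Per-patient signature scores with stratum labels.
    assignments : dict
        Stratum → :class:`ClusterAssignment` with archetype labels.
    response : pandas.Series
        Patient → response label (``responder`` / ``nonresponder`` /
        ``undetermined`` / ``ineligible``).
    contingency, tests : dict
        Cluster × response and ancestry × response tables and their
        chi-square results.
    """

    model: CohortStratificationModel
    expression: ExpressionMatrix
    scores: ScoreTable
    assignments: dict[str, ClusterAssignment]
    response: pd.Series
    contingency: dict[str, ContingencyTable] = field(default_factory=dict)
    tests: dict[str, TestResult] = field(default_factory=dict)

    def assignment_frame(self) -> pd.DataFrame:
        frames = [a.to_frame() for a in self.assignments.values()]
        out = pd.concat(frames, ignore_index=True)
        out["response"] = out["sample"].map(self.response)
        return out

    def responder_fraction(self, stratum: str) -> pd.Series:
        """Responder fraction per cluster among determined responses."""
        table = self.contingency[stratum]
        counts = table.counts
        return pd.Series(
            counts[:, 0] / counts.sum(axis=1), index=list(table.row_labels)
        )

    def cluster_characteristics(self, stratum: str) -> pd.DataFrame:
        """Cluster-characteristics report for one stratum: one row per
        variable with per-cluster summaries and a test statistic/p value
        (medians + Kruskal-Wallis for numeric variables, counts + chi-square
        for binary ones, responder counts for the response row)."""
        from .stats import kruskal_wallis, pearson_chi_square

        assignment = self.assignments[stratum]
        clinical = self.model.clinical.set_index(
            self.model.clinical["patient_id"].astype(str)
        )
        cluster_members = {
            cid: list(assignment.members(cid)) for cid in range(1, assignment.k + 1)
        }
        columns = [f"{stratum}-{cid}" for cid in cluster_members]
        rows = []

        def add_numeric(name: str, values: pd.Series) -> None:
            groups = [values.loc[m].dropna().to_numpy() for m in cluster_members.values()]
            cells = [f"{np.median(g):.1f}" if g.size else "" for g in groups]
            try:
                test = kruskal_wallis([g for g in groups if g.size])
                stat, p = test.statistic, test.p_value
            except ValueError:
                stat, p = np.nan, np.nan
            rows.append([name, *cells, round(stat, 2), round(p, 4)])

        def add_binary(name: str, values: pd.Series) -> None:
            groups = [values.loc[m].dropna().astype(int) for m in cluster_members.values()]
            cells = [f"{int(g.sum())} ({100 * g.mean():.0f})" if len(g) else ""
                     for g in groups]
            counts = np.array([[int(g.sum()), int(len(g) - g.sum())] for g in groups])
            try:
                test = pearson_chi_square(
                    ContingencyTable(counts, tuple(columns), ("yes", "no"))
                )
                stat, p = test.statistic, test.p_value
            except ValueError:
                stat, p = np.nan, np.nan
            rows.append([name, *cells, round(stat, 2), round(p, 4)])

        for panel in self.scores.panels:
            add_numeric(f"score:{panel}", self.scores[panel])
        for col in ("age", "sledai2k", "imd_rank", "prednisolone_mg"):
            if col in clinical.columns:
                add_numeric(col, pd.to_numeric(clinical[col], errors="coerce"))
        for col in ("rnp_sm_pos", "dsdna_pos", "antimalarial", "immunosuppressant"):
            if col in clinical.columns:
                add_binary(col, pd.to_numeric(clinical[col], errors="coerce"))
        if stratum in self.contingency:
            table = self.contingency[stratum]
            cells = [f"{r} ({100 * r / max(r + n, 1):.1f})"
                     for r, n in table.counts]
            test = self.tests.get(f"cluster_response_{stratum}")
            rows.append([
                "bilag_responder", *cells,
                round(test.statistic, 2) if test else np.nan,
                round(test.p_value, 4) if test else np.nan,
            ])
        return pd.DataFrame(
            rows, columns=["variable", *columns, "statistic", "p_value"]
        )

    def summary(self) -> str:
        lines = ["Cohort stratification", "=" * 60]
        for stratum, assignment in sorted(self.assignments.items()):
            lines.append(f"\nStratum {stratum}  (n={len(assignment.samples)})")
            for cid in range(1, assignment.k + 1):
                members = assignment.members(cid)
                arch = assignment.archetypes.get(cid, "?")
                extra = ""
                if stratum in self.contingency:
                    frac = self.responder_fraction(stratum)
                    key = f"{stratum}-{cid}"
                    if key in frac.index:
                        extra = f"  responders {100 * frac[key]:5.1f}%"
                lines.append(
                    f"  cluster {cid}: n={len(members):3d}  {arch:<24s}{extra}"
                )
            key = f"cluster_response_{stratum}"
            if key in self.tests:
                t = self.tests[key]
                lines.append(
                    f"  cluster x response: chi-square = {t.statistic:.1f}, "
                    f"df = {t.df:.0f}, P = {t.p_value:.3g}"
                )
        if "ancestry_response" in self.tests:
            t = self.tests["ancestry_response"]
            lines.append(
                f"\nAncestry x response: chi-square = {t.statistic:.1f}, "
                f"df = {t.df:.0f}, P = {t.p_value:.3g}"
            )
        counts = self.response.value_counts()
        lines.append(
            "\nResponse labels: "
            + ", ".join(f"{k}={v}" for k, v in counts.sort_index().items())
        )
        return "\n".join(lines)

    def to_summary_dict(self) -> dict:
        """Machine-readable summary (contingency tables and test results)."""
        payload: dict = {"strata": {}, "tests": {}}
        for stratum, assignment in self.assignments.items():
            payload["strata"][stratum] = {
                "n": len(assignment.samples),
                "clusters": {
                    str(cid): {
                        "n": len(assignment.members(cid)),
                        "archetype": assignment.archetypes.get(cid, ""),
                    }
                    for cid in range(1, assignment.k + 1)
                },
            }
        for name, table in self.contingency.items():
            payload["strata"].setdefault(name, {})
            payload["strata"][name]["contingency"] = {
                "rows": list(table.row_labels),
                "cols": list(table.col_labels),
                "counts": table.counts.tolist(),
            }
        for name, t in self.tests.items():
            payload["tests"][name] = {
                "statistic": t.statistic, "df": t.df, "p_value": t.p_value,
                "test": t.test,
            }
        return payload

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "scores": out_dir / "scores.csv",
            "assignments": out_dir / "assignments.csv",
            "response": out_dir / "response.csv",
            "summary": out_dir / "summary.json",
        }
        self.scores.save(paths["scores"])
        self.assignment_frame().to_csv(paths["assignments"], index=False)
        self.response.rename_axis("patient_id").to_csv(paths["response"])
        paths["summary"].write_text(json.dumps(self.to_summary_dict(), indent=2))
        for stratum, assignment in self.assignments.items():
            merge_path = out_dir / f"merges_{stratum}.tsv"
            assignment.merges_frame().to_csv(merge_path, sep="\t", index=False)
            (out_dir / f"dendrogram_{stratum}.nwk").write_text(
                assignment.to_newick() + "\n"
            )
            report_path = out_dir / f"cluster_characteristics_{stratum}.csv"
            self.cluster_characteristics(stratum).to_csv(report_path, index=False)
            paths[f"report_{stratum}"] = report_path
        return paths
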