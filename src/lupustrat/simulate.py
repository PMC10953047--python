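"""Seeded synthetic registry cohorts with known latent structure.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be exercised — and validated against ground
truth — without registry data:

* two ancestry strata (EA / NEA), each a mixture of three latent patient
  clusters with archetype-specific factor means (e.g. the NEA stratum holds
  an IFN-low/neutrophil-high, an IFN-high/neutrophil-low and an all-high
  cluster);
* six latent factors (IFN, plasmablast, neutrophil, myeloid, inflammation,
  erythropoiesis); within a cluster the non-IFN factor residuals are coupled
  to the IFN residual with stratum-specific target correlations, so the EA
  stratum shows IFN-coupled signatures while NEA plasmablast/neutrophil
  signatures are decoupled;
* a bimodal IFN factor in the EA stratum only (two-component Gaussian
  mixture, IFN-high clusters drawing from the high component);
* transcripts loading 1:1 on their panel's factor plus independent Gaussian
  noise, converted to Ct against a Normal(20, 0.5) reference gene and
  censored above the detection limit;
* BILAG 2004 baseline/month-6 grade trajectories constructed to satisfy the
  eligibility rule at baseline and to be consistent, under the response rule,
  with a responder flag drawn per cluster archetype.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import bilag
from .bilag import DOMAINS, DomainAssessment, ResponseLabel, classify_response
from .cluster import ARCHETYPES
from .panels import (
    EXTRA_ISG,
    IFN_SCORE_A,
    IFN_SCORE_B,
    PanelRegistry,
    default_registry,
)
from .qpcr import CtMatrix, censor_nondetects

__all__ = [
    "FACTORS",
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "censor_nondetects",
]

#: Latent factor order used throughout.
FACTORS: tuple[str, ...] = (
    "IFN",
    "plasmablast",
    "neutrophil",
    "myeloid",
    "inflammation",
    "erythropoiesis",
)

_NON_IFN = FACTORS[1:]

#: Panel → latent factor (all three ISG panels share the IFN factor).
PANEL_FACTOR: Mapping[str, str] = {
    IFN_SCORE_A: "IFN",
    IFN_SCORE_B: "IFN",
    EXTRA_ISG: "IFN",
    "plasmablast": "plasmablast",
    "neutrophil": "neutrophil",
    "myeloid": "myeloid",
    "inflammation": "inflammation",
    "erythropoiesis": "erythropoiesis",
}

#: Panel-level baseline expression offsets (reflected ΔCt units), chosen so
#: score medians fall in the range whole-blood TaqMan panels report.
PANEL_BASELINE: Mapping[str, float] = {
    IFN_SCORE_A: -2.5,
    IFN_SCORE_B: -3.4,
    EXTRA_ISG: -2.8,
    "plasmablast": -5.6,
    "neutrophil": -5.4,
    "myeloid": -4.5,
    "inflammation": -4.5,
    "erythropoiesis": -4.0,
}

#: Low-abundance transcripts pushed near the detection limit so that the
#: censoring/imputation path is exercised on realistic cohorts.
LOW_ABUNDANCE: Mapping[str, float] = {"ZBP1": -16.5, "SOCS1": -16.0}

# Archetype factor-mean shifts, in units of `cluster_shift`, for the non-IFN
# factors (plasmablast, neutrophil, myeloid, inflammation, erythropoiesis) and
# the IFN polarity (+1 high / −1 low).  Clusters 1..3 per stratum.
_ARCHETYPE_DEF: Mapping[str, tuple[dict, ...]] = {
    "EA": (
        {"name": "all-high", "ifn": +1,
         "shift": {"plasmablast": 0.5, "neutrophil": 1, "myeloid": 1,
                   "inflammation": 1, "erythropoiesis": 1}},
        {"name": "IFN-high/neutrophil-low", "ifn": +1,
         "shift": {"plasmablast": 0.0, "neutrophil": -1, "myeloid": -1,
                   "inflammation": -1, "erythropoiesis": -1}},
        {"name": "all-low", "ifn": -1,
         "shift": {"plasmablast": -0.5, "neutrophil": -1, "myeloid": -1,
                   "inflammation": -1, "erythropoiesis": -1}},
    ),
    "NEA": (
        {"name": "IFN-low/neutrophil-high", "ifn": -1,
         "shift": {"plasmablast": 0.0, "neutrophil": 1, "myeloid": 1,
                   "inflammation": 1, "erythropoiesis": 0}},
        {"name": "IFN-high/neutrophil-low", "ifn": +1,
         "shift": {"plasmablast": 0.0, "neutrophil": -1, "myeloid": -1,
                   "inflammation": -1, "erythropoiesis": 0}},
        {"name": "all-high", "ifn": +1,
         "shift": {"plasmablast": 0.0, "neutrophil": 1, "myeloid": 1,
                   "inflammation": 1, "erythropoiesis": 0}},
    ),
}

_ANCESTRY_POOLS: Mapping[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "EA": (("British", "Irish"), (0.92, 0.08)),
    "NEA": (("African", "South Asian", "Other Asian", "Other/mixed"),
            (0.32, 0.32, 0.13, 0.23)),
}


class ConfigError(ValueError):
    """Raised for invalid cohort configurations."""


@dataclass
class CohortConfig:
    """Study-condition constants for the synthetic cohort generator.

    Defaults encode the first-cycle clustering subsets: 82 EA and 55 NEA
    patients, cluster mixes matching the reported cluster sizes, coupling
    targets read from the printed stratum correlograms, and cluster-archetype
    responder probabilities matching the reported response rows.
    """

    n_ea: int = 82
    n_nea: int = 55
    cluster_mix_ea: tuple[float, float, float] = (33 / 82, 24 / 82, 25 / 82)
    cluster_mix_nea: tuple[float, float, float] = (9 / 55, 21 / 55, 25 / 55)
    #: Target association between the IFN latent factor and each non-IFN
    #: factor, as printed (plasmablast, neutrophil, myeloid, inflammation,
    #: erythropoiesis order).
    coupling_ea: tuple[float, ...] = (0.265, 0.530, 0.714, 0.598, 0.437)
    coupling_nea: tuple[float, ...] = (0.001, 0.109, 0.716, 0.445, 0.296)
    #: How the printed association values are read: "r_squared" treats them
    #: as squared correlations (target rho = sqrt(value)); "rho" uses them
    #: directly as correlation coefficients.
    coupling_scale: str = "r_squared"
    #: EA IFN factor two-component mixture: (mean_low, mean_high), (sd_low,
    #: sd_high), weight of the low component.  Cluster IFN polarity selects
    #: the component, so the marginal weight follows the cluster mix; the
    #: configured weight is the intended marginal and is validated against it.
    ifn_bimodal_ea: tuple[tuple[float, float], tuple[float, float], float] = (
        (-3.0, 1.0), (0.6, 0.6), 25 / 82,
    )
    #: NEA IFN factor: unimodal residual sd around the cluster shift.
    ifn_sd_nea: float = 0.6
    #: Factor-mean separation between archetype levels (reflected ΔCt units).
    cluster_shift: float = 2.0
    #: Within-cluster residual sd of each non-IFN factor.
    factor_sd: float = 0.6
    #: Stratum-level factor mean offsets (plasmablast runs higher in NEA).
    stratum_offset: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "EA": {"plasmablast": -0.5},
            "NEA": {"plasmablast": +0.5},
        }
    )
    #: Responder probability per stratum and cluster archetype (reported
    #: response rows: NEA 1/8, 7/17, 17/20; EA 19/31, 13/18, 13/16).
    response_prob: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "NEA": {
                "IFN-low/neutrophil-high": 1 / 8,
                "IFN-high/neutrophil-low": 7 / 17,
                "all-high": 17 / 20,
            },
            "EA": {
                "all-high": 19 / 31,
                "IFN-high/neutrophil-low": 13 / 18,
                "all-low": 13 / 16,
            },
        }
    )
    #: Fraction of patients with no month-6 assessment (→ undetermined).
    prob_missing_m6: float = 0.2
    censor_ct: float = 38.0
    noise_sd: float = 0.5
    reference_ct_mean: float = 20.0
    reference_ct_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name, mix in (("cluster_mix_ea", self.cluster_mix_ea),
                          ("cluster_mix_nea", self.cluster_mix_nea)):
            mix = np.asarray(mix, dtype=float)
            if mix.shape != (3,):
                raise ConfigError(f"{name} must have 3 entries")
            if (mix < 0).any() or (mix > 1).any():
                raise ConfigError(f"{name} probabilities must lie in [0, 1]")
            if abs(mix.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
        for name, coupling in (("coupling_ea", self.coupling_ea),
                               ("coupling_nea", self.coupling_nea)):
            arr = np.asarray(coupling, dtype=float)
            if arr.shape != (len(_NON_IFN),):
                raise ConfigError(f"{name} must have {len(_NON_IFN)} entries")
            if (np.abs(arr) > 1).any():
                raise ConfigError(f"{name} targets must lie in [−1, 1]")
        if self.coupling_scale not in ("r_squared", "rho"):
            raise ConfigError(f"unknown coupling_scale {self.coupling_scale!r}")
        for stratum, probs in self.response_prob.items():
            for archetype, p in probs.items():
                if archetype not in ARCHETYPES:
                    raise ConfigError(f"unknown archetype {archetype!r}")
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"response_prob[{stratum}][{archetype}]={p}")
        if not 0.0 <= self.prob_missing_m6 <= 1.0:
            raise ConfigError("prob_missing_m6 must lie in [0, 1]")
        if not np.isfinite(self.censor_ct) or self.censor_ct <= self.reference_ct_mean:
            raise ConfigError("censor_ct must be finite and above the reference mean Ct")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")

    def rho(self, stratum: str) -> np.ndarray:
        """Coupling targets as correlation coefficients, per factor."""
        values = np.asarray(
            self.coupling_ea if stratum == "EA" else self.coupling_nea, dtype=float
        )
        if self.coupling_scale == "r_squared":
            return np.sign(values) * np.sqrt(np.abs(values))
        return values

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["stratum_offset"] = {
            k: dict(v) for k, v in self.stratum_offset.items()
        }
        payload["response_prob"] = {
            k: dict(v) for k, v in self.response_prob.items()
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        payload = yaml.safe_load(Path(path).read_text())
        cfg = cls(**payload)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort (one row per patient)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.frame["true_cluster"].unique()) <= {1, 2, 3}:
            raise ValueError("cluster ids must be in {1, 2, 3}")

    def labels_for(self, samples) -> np.ndarray:
        return (
            self.frame.set_index("patient_id")
            .loc[list(samples), "true_cluster"]
            .to_numpy()
        )

    def stratum(self, stratum: str) -> pd.DataFrame:
        return self.frame[self.frame["stratum"] == stratum]

    def save(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def _draw_factors(
    rng: np.random.Generator,
    config: CohortConfig,
    stratum: str,
    clusters: np.ndarray,
) -> np.ndarray:
    """Per-patient latent factor matrix (n × 6) for one stratum."""
    n = clusters.size
    rho = config.rho(stratum)
    h = config.cluster_shift
    defs = _ARCHETYPE_DEF[stratum]
    offsets = config.stratum_offset.get(stratum, {})
    (mu_low, mu_high), (sd_low, sd_high), _ = config.ifn_bimodal_ea

    z_ifn = rng.standard_normal(n)
    z_rest = rng.standard_normal((n, len(_NON_IFN)))
    factors = np.empty((n, len(FACTORS)))
    for i in range(n):
        entry = defs[clusters[i] - 1]
        if stratum == "EA":
            mu, sd = (mu_high, sd_high) if entry["ifn"] > 0 else (mu_low, sd_low)
            ifn = mu + sd * z_ifn[i]
        else:
            ifn = entry["ifn"] * h + config.ifn_sd_nea * z_ifn[i]
        factors[i, 0] = ifn
        for j, name in enumerate(_NON_IFN):
            resid = rho[j] * z_ifn[i] + np.sqrt(max(0.0, 1 - rho[j] ** 2)) * z_rest[i, j]
            factors[i, j + 1] = (
                entry["shift"][name] * h
                + offsets.get(name, 0.0)
                + config.factor_sd * resid
            )
    return factors


_BASELINE_DOMAIN_WEIGHTS = {
    "renal": 0.28, "mucocutaneous": 0.24, "musculoskeletal": 0.20,
    "neuropsychiatric": 0.05, "cardiorespiratory": 0.07, "constitutional": 0.05,
    "hematology": 0.05, "gastroenterology": 0.03, "ophthalmic": 0.03,
}


def _draw_baseline(rng: np.random.Generator) -> DomainAssessment:
    """Baseline BILAG grades guaranteed to satisfy the eligibility rule."""
    domains = list(DOMAINS)
    weights = np.array([_BASELINE_DOMAIN_WEIGHTS[d] for d in domains])
    weights = weights / weights.sum()
    grades = {}
    for d in domains:
        grades[d] = rng.choice(["C", "D", "E"], p=[0.2, 0.6, 0.2])
    if rng.random() < 0.85:
        n_a = 1 if rng.random() < 0.7 else 2
        a_domains = rng.choice(domains, size=n_a, replace=False, p=weights)
        for d in a_domains:
            grades[d] = "A"
        n_b = rng.choice([0, 1, 2], p=[0.5, 0.3, 0.2])
    else:
        n_b = 2  # eligibility via two grade B manifestations
    free = [d for d in domains if grades[d] not in ("A",)]
    b_domains = rng.choice(free, size=min(n_b, len(free)), replace=False)
    for d in b_domains:
        grades[d] = "B"
    return DomainAssessment(grades)


def _draw_month6(
    rng: np.random.Generator,
    baseline: DomainAssessment,
    responder: bool,
) -> DomainAssessment:
    """Month-6 grades consistent with the drawn responder flag."""
    a_domains = [d for d in DOMAINS if baseline[d] == "A"]
    b_domains = [d for d in DOMAINS if baseline[d] == "B"]
    quiet = [d for d in DOMAINS if baseline[d] in ("C", "D", "E")]
    grades = {}
    for d in quiet:
        g = baseline[d]
        grades[d] = "D" if (g == "C" and rng.random() < 0.2) else g
    for d in a_domains + b_domains:
        grades[d] = "C"
    if responder:
        improved = a_domains + b_domains
        if improved and rng.random() < 0.5:
            grades[rng.choice(improved)] = "B"  # the one allowed persisting B
        return DomainAssessment(grades)
    # nonresponder: violate one clause, chosen uniformly among applicable
    options = ["many_B", "new_flare"]
    if a_domains:
        options.append("persist_A")
    violation = rng.choice(options)
    if violation == "persist_A":
        grades[rng.choice(a_domains)] = "A"
    elif violation == "many_B":
        candidates = a_domains + b_domains
        if len(candidates) >= 2:
            for d in rng.choice(candidates, size=2, replace=False):
                grades[d] = "B"
        else:
            grades[candidates[0]] = "B"
            grades[rng.choice(quiet)] = "B"  # second B is a new flare
    else:
        grades[rng.choice(quiet)] = rng.choice(["A", "B"])
    return DomainAssessment(grades)


def _clinical_row(
    rng: np.random.Generator,
    patient_id: str,
    stratum: str,
    archetype: str,
    baseline: DomainAssessment,
    month6: DomainAssessment | None,
) -> dict:
    pool, pool_p = _ANCESTRY_POOLS[stratum]
    ifn_high = archetype in ("IFN-high/neutrophil-low", "all-high")
    row = {
        "patient_id": patient_id,
        "stratum": stratum,
        "ancestry": rng.choice(pool, p=pool_p),
        "age": int(np.clip(rng.normal(40 if stratum == "EA" else 36, 11), 18, 80)),
        "sledai2k": int(np.clip(
            rng.normal(8 + 2 * (archetype == "all-high")
                       - 2 * (archetype == "all-low"), 4), 0, 30)),
        "imd_rank": int(rng.integers(1, 32845)),
        "rnp_sm_pos": int(rng.random() < (0.45 if ifn_high else 0.08)),
        "dsdna_pos": int(rng.random() < (0.65 if ifn_high else 0.45)),
        "antimalarial": int(rng.random() < 0.55),
        "immunosuppressant": int(rng.random() < 0.35),
        "prednisolone_mg": float(np.round(np.clip(rng.normal(11, 6), 0, 60), 1)),
        "rituximab_cycle": 1,
    }
    for d in DOMAINS:
        row[f"{d}_baseline"] = baseline[d]
    for d in DOMAINS:
        row[f"{d}_m6"] = month6[d] if month6 is not None else ""
    return row


def generate_cohort(
    config: CohortConfig,
    registry: PanelRegistry | None = None,
) -> tuple[CtMatrix, pd.DataFrame, GroundTruth]:
    """Generate one synthetic cohort: Ct matrix, clinical table, ground truth.

    Deterministic given ``config.seed``.  Transcript Ct values are
    ``reference Ct − (factor + panel baseline + noise)``; entries above
    ``config.censor_ct`` are flagged as non-detects.  Month-6 BILAG grades are
    generated to be consistent with the drawn responder flag under the
    response rule (checked defensively for every patient).
    """
    config.validate()
    registry = registry if registry is not None else default_registry()
    for panel in registry:
        if panel.name not in PANEL_FACTOR:
            raise ConfigError(f"panel {panel.name!r} maps to no latent factor")
    rng = np.random.default_rng(config.seed)

    samples: list[str] = []
    truth_rows: list[dict] = []
    clinical_rows: list[dict] = []
    all_factors: list[np.ndarray] = []
    for stratum, n, mix in (
        ("EA", config.n_ea, config.cluster_mix_ea),
        ("NEA", config.n_nea, config.cluster_mix_nea),
    ):
        clusters = rng.choice([1, 2, 3], size=n, p=np.asarray(mix) / np.sum(mix))
        factors = _draw_factors(rng, config, stratum, clusters)
        all_factors.append(factors)
        defs = _ARCHETYPE_DEF[stratum]
        for i in range(n):
            pid = f"{stratum}{i + 1:03d}"
            samples.append(pid)
            archetype = defs[clusters[i] - 1]["name"]
            p_resp = config.response_prob[stratum][archetype]
            responder = bool(rng.random() < p_resp)
            baseline = _draw_baseline(rng)
            missing = rng.random() < config.prob_missing_m6
            month6 = None if missing else _draw_month6(rng, baseline, responder)
            label = classify_response(baseline, month6)
            if month6 is not None:
                expected = (
                    ResponseLabel.RESPONDER if responder else ResponseLabel.NONRESPONDER
                )
                if label is not expected:  # pragma: no cover - generator contract
                    raise AssertionError(
                        f"generated trajectory inconsistent with responder flag "
                        f"for {pid}: {label} != {expected}"
                    )
            truth_rows.append(
                {
                    "patient_id": pid,
                    "stratum": stratum,
                    "true_cluster": int(clusters[i]),
                    "archetype": archetype,
                    "responder": int(responder),
                    **{f"factor_{f}": factors[i, j] for j, f in enumerate(FACTORS)},
                }
            )
            clinical_rows.append(
                _clinical_row(rng, pid, stratum, archetype, baseline, month6)
            )

    factors = np.vstack(all_factors)  # n_total × 6, rows aligned with samples
    n_total = factors.shape[0]
    reference_ct = rng.normal(config.reference_ct_mean, config.reference_ct_sd, n_total)

    transcript_names: list[str] = []
    values = []
    factor_index = {f: j for j, f in enumerate(FACTORS)}
    for panel in registry:
        f_col = factors[:, factor_index[PANEL_FACTOR[panel.name]]]
        for transcript in panel.transcripts:
            baseline_level = LOW_ABUNDANCE.get(
                transcript, PANEL_BASELINE[panel.name]
            )
            noise = rng.normal(0.0, config.noise_sd, n_total)
            expression = baseline_level + f_col + noise
            transcript_names.append(transcript)
            values.append(reference_ct - expression)
    ct_values = np.vstack([np.asarray(values), reference_ct[np.newaxis, :]])
    transcript_names.append("PPIA")
    ct = CtMatrix(
        transcripts=tuple(transcript_names),
        samples=tuple(samples),
        ct=ct_values,
        nondetect=np.zeros(ct_values.shape, dtype=bool),
        reference_transcript="PPIA",
    )
    ct = censor_nondetects(ct, config.censor_ct)
    clinical = pd.DataFrame(clinical_rows)
    truth = GroundTruth(pd.DataFrame(truth_rows))
    return ct, clinical, truth
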