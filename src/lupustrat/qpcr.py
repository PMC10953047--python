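"""qPCR Ct handling: parsing, non-detect censoring/imputation, reflected ΔCt.

A TaqMan array reports one cycle-threshold (Ct) value per transcript per
sample; reactions that never cross the detection threshold are *non-detects*
and are treated as right-censored in Ct (low abundance = high Ct).  Non-detects
are singly imputed per transcript with a censored-normal EM, Ct values are
normalised to the reference gene (PPIA by default) and the ΔCt is reflected so
that higher values mean greater expression:

    expression[g, s] = Ct[reference, s] − Ct[g, s]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtMatrix",
    "ExpressionMatrix",
    "CensoredNormalFit",
    "read_ct_table",
    "write_ct_table",
    "censor_nondetects",
    "impute_nondetects",
    "to_expression",
    "fit_censored_normal",
    "censored_normal_loglik",
    "DEFAULT_REFERENCE_GENE",
    "DEFAULT_CENSOR_CT",
    "DEFAULT_ND_TOKEN",
]

DEFAULT_REFERENCE_GENE = "PPIA"
DEFAULT_CENSOR_CT = 38.0
DEFAULT_ND_TOKEN = "ND"


class CtParseError(ValueError):
    """Structured parse/validation error for Ct tables."""


@dataclass
class CtMatrix:
    """Raw Ct values (transcripts × samples) with non-detect flags.

    ``ct`` is finite wherever ``nondetect`` is False; values under non-detect
    flags are withheld (NaN).  The reference transcript must be present and
    fully observed.
    """

    transcripts: tuple[str, ...]
    samples: tuple[str, ...]
    ct: np.ndarray
    nondetect: np.ndarray
    reference_transcript: str = DEFAULT_REFERENCE_GENE

    def __post_init__(self) -> None:
        self.transcripts = tuple(str(t) for t in self.transcripts)
        self.samples = tuple(str(s) for s in self.samples)
        self.ct = np.asarray(self.ct, dtype=float)
        self.nondetect = np.asarray(self.nondetect, dtype=bool)
        n_t, n_s = len(self.transcripts), len(self.samples)
        if self.ct.shape != (n_t, n_s) or self.nondetect.shape != (n_t, n_s):
            raise CtParseError("ct/nondetect shape does not match axis labels")
        if len(set(self.transcripts)) != n_t:
            raise CtParseError("duplicate transcript identifiers")
        if len(set(self.samples)) != n_s:
            raise CtParseError("duplicate sample identifiers")
        if self.reference_transcript not in self.transcripts:
            raise CtParseError(
                f"reference transcript {self.reference_transcript!r} not in table"
            )
        if not np.all(np.isfinite(self.ct[~self.nondetect])):
            raise CtParseError("non-finite Ct value outside the non-detect mask")
        ref = self.transcripts.index(self.reference_transcript)
        if self.nondetect[ref].any():
            raise CtParseError("reference transcript has non-detect entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ct.shape

    @property
    def n_nondetect(self) -> int:
        return int(self.nondetect.sum())

    def row(self, transcript: str) -> np.ndarray:
        return self.ct[self.transcripts.index(transcript)]

    def to_frame(self, nd_token: str = DEFAULT_ND_TOKEN) -> pd.DataFrame:
        """Ct table as a DataFrame with non-detects as ``nd_token``."""
        frame = pd.DataFrame(
            self.ct, index=list(self.transcripts), columns=list(self.samples)
        ).astype(object)
        rows, cols = np.nonzero(self.nondetect)
        for r, c in zip(rows, cols):
            frame.iat[r, c] = nd_token
        frame.index.name = "transcript"
        return frame

    def copy(self) -> "CtMatrix":
        return CtMatrix(
            self.transcripts,
            self.samples,
            self.ct.copy(),
            self.nondetect.copy(),
            self.reference_transcript,
        )


@dataclass
class ExpressionMatrix:
    """Reflected ΔCt values (transcripts × samples, reference row removed)."""

    transcripts: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.transcripts = tuple(str(t) for t in self.transcripts)
        self.samples = tuple(str(s) for s in self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.transcripts), len(self.samples)):
            raise ValueError("values shape does not match axis labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, transcript: str) -> np.ndarray:
        return self.values[self.transcripts.index(transcript)]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.values, index=list(self.transcripts), columns=list(self.samples)
        )
        frame.index.name = "transcript"
        return frame

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.samples.index(s) for s in samples]
        return ExpressionMatrix(self.transcripts, tuple(samples), self.values[:, idx])


def read_ct_table(
    path: str | Path,
    reference_transcript: str = DEFAULT_REFERENCE_GENE,
    nondetect_token: str = DEFAULT_ND_TOKEN,
    sep: str = "\t",
) -> CtMatrix:
    """Read a transcripts × samples Ct table (first column = transcript id).

    Non-detect cells hold ``nondetect_token``; all other cells must parse as
    decimal-point floats.  Errors name the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise CtParseError(f"duplicate transcript rows: {dupes}")
    if raw.columns.has_duplicates:
        raise CtParseError("duplicate sample columns")
    if reference_transcript not in raw.index:
        raise CtParseError(f"reference row {reference_transcript!r} missing from {path}")
    ct = np.empty(raw.shape, dtype=float)
    nondetect = np.zeros(raw.shape, dtype=bool)
    for i, transcript in enumerate(raw.index):
        for j, sample in enumerate(raw.columns):
            cell = raw.iat[i, j]
            text = "" if cell is None else str(cell).strip()
            if text == nondetect_token:
                ct[i, j] = np.nan
                nondetect[i, j] = True
                continue
            try:
                ct[i, j] = float(text)
            except ValueError as exc:
                raise CtParseError(
                    f"non-numeric cell at row {transcript!r}, column {sample!r}: "
                    f"{text!r}"
                ) from exc
    return CtMatrix(
        tuple(raw.index), tuple(raw.columns), ct, nondetect, reference_transcript
    )


def write_ct_table(
    ct: CtMatrix,
    path: str | Path,
    nd_token: str = DEFAULT_ND_TOKEN,
    sep: str = "\t",
) -> None:
    """Write a Ct table as TSV with non-detects as ``nd_token``."""
    frame = ct.to_frame(nd_token=nd_token)
    frame.to_csv(path, sep=sep)


def censor_nondetects(ct: CtMatrix, censor_ct: float = DEFAULT_CENSOR_CT) -> CtMatrix:
    """Flag entries with Ct above the detection limit as non-detects.

    Entries with Ct > ``censor_ct`` are marked non-detect and their numeric
    value withheld; everything else is unchanged.  Already-flagged entries
    stay flagged.
    """
    if not np.isfinite(censor_ct):
        raise ValueError("censor_ct must be finite")
    out = ct.copy()
    with np.errstate(invalid="ignore"):
        newly = ~out.nondetect & (out.ct > censor_ct)
    out.nondetect |= newly
    out.ct[out.nondetect] = np.nan
    return out


def censored_normal_loglik(
    mu: float | np.ndarray,
    sigma: float | np.ndarray,
    observed: np.ndarray,
    n_censored: int,
    censor_at: float,
) -> float | np.ndarray:
    """Log-likelihood of Normal(mu, sigma) with right-censoring at ``censor_at``.

    Vectorised over ``mu``/``sigma`` grids using the sufficient statistics of
    the observed values; used both by the EM ascent check and by the
    brute-force grid oracle.
    """
    observed = np.asarray(observed, dtype=float)
    n = observed.size
    s1 = observed.sum()
    s2 = float(observed @ observed)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    var = sigma**2
    ll = (
        -0.5 * n * np.log(2.0 * np.pi * var)
        - (s2 - 2.0 * mu * s1 + n * mu**2) / (2.0 * var)
    )
    if n_censored:
        ll = ll + n_censored * stats.norm.logsf(censor_at, loc=mu, scale=sigma)
    return ll


@dataclass
class CensoredNormalFit:
    """EM fit of a right-censored normal for one transcript."""

    mu: float
    sigma: float
    imputed_value: float
    n_iter: int
    converged: bool
    loglik_path: np.ndarray = field(repr=False)


def fit_censored_normal(
    observed: np.ndarray,
    n_censored: int,
    censor_at: float,
    max_iter: int = 500,
    tol: float = 1e-6,
    sigma_floor: float = 1e-3,
) -> CensoredNormalFit:
    """Fit Normal(mu, sigma) by EM with ``n_censored`` values censored above
    ``censor_at``.

    E-step replaces each censored value by E[X | X > c] and E[X² | X > c]
    under the current parameters (upper-truncated-normal moments via the
    inverse Mills ratio); M-step updates (mu, sigma) from the completed
    moments.  The censored log-likelihood is recorded each iteration and is
    non-decreasing up to round-off.
    """
    observed = np.asarray(observed, dtype=float)
    n_obs = observed.size
    if n_obs < 2:
        raise ValueError("need at least 2 observed values to fit a censored normal")
    n = n_obs + n_censored
    mu = float(observed.mean())
    sigma = float(max(observed.std(ddof=0), sigma_floor))
    s1 = observed.sum()
    s2 = float(observed @ observed)
    lls = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lls.append(
            float(censored_normal_loglik(mu, sigma, observed, n_censored, censor_at))
        )
        alpha = (censor_at - mu) / sigma
        # inverse Mills ratio for the upper tail, computed on the log scale
        lam = np.exp(stats.norm.logpdf(alpha) - stats.norm.logsf(alpha))
        m1 = mu + sigma * lam  # E[X | X > c]
        trunc_var = sigma**2 * (1.0 + alpha * lam - lam**2)
        m2 = trunc_var + m1**2  # E[X² | X > c]
        mu_new = (s1 + n_censored * m1) / n
        var_new = (s2 + n_censored * m2) / n - mu_new**2
        sigma_new = float(max(np.sqrt(max(var_new, 0.0)), sigma_floor))
        delta = max(abs(mu_new - mu), abs(sigma_new - sigma))
        mu, sigma = float(mu_new), sigma_new
        if delta < tol:
            converged = True
            break
    if not converged and n_censored > 0:
        warnings.warn(
            f"censored-normal EM did not converge in {max_iter} iterations "
            f"(last change above {tol}); returning last iterate",
            stacklevel=2,
        )
    alpha = (censor_at - mu) / sigma
    lam = np.exp(stats.norm.logpdf(alpha) - stats.norm.logsf(alpha))
    imputed = float(mu + sigma * lam)
    lls.append(float(censored_normal_loglik(mu, sigma, observed, n_censored, censor_at)))
    return CensoredNormalFit(
        mu=mu,
        sigma=sigma,
        imputed_value=max(imputed, censor_at),
        n_iter=it,
        converged=converged or n_censored == 0,
        loglik_path=np.asarray(lls),
    )


def impute_nondetects(
    ct: CtMatrix,
    censor_ct: float = DEFAULT_CENSOR_CT,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> CtMatrix:
    """Impute non-detects per transcript via the censored-normal EM.

    Each transcript with at least one non-detect is fitted across samples,
    treating flagged entries as right-censored at ``censor_ct``; every flagged
    entry of that transcript is replaced by the conditional mean
    E[X | X > censor_ct] at convergence (single imputation, always
    ≥ ``censor_ct``).  Observed entries are never altered.
    """
    out = ct.copy()
    fully_censored = [
        t for i, t in enumerate(ct.transcripts) if ct.nondetect[i].all()
    ]
    if fully_censored:
        raise ValueError(
            f"transcripts entirely non-detect, cannot impute: {fully_censored}"
        )
    for i, transcript in enumerate(ct.transcripts):
        mask = ct.nondetect[i]
        n_cens = int(mask.sum())
        if n_cens == 0:
            continue
        observed = ct.ct[i, ~mask]
        if observed.size < 2:
            raise ValueError(
                f"transcript {transcript!r} has {observed.size} observed value(s); "
                "need at least 2 to impute"
            )
        fit = fit_censored_normal(
            observed, n_cens, censor_ct, max_iter=max_iter, tol=tol
        )
        out.ct[i, mask] = fit.imputed_value
        out.nondetect[i, mask] = False
    return out


def to_expression(ct: CtMatrix) -> ExpressionMatrix:
    """Convert a fully observed Ct matrix to reflected ΔCt.

    ``value[g, s] = Ct[reference, s] − Ct[g, s]``; the reference row is
    removed.  Residual non-detects are an error — impute first.
    """
    if ct.nondetect.any():
        count = ct.n_nondetect
        raise ValueError(f"{count} non-detect entries remain; run imputation first")
    ref_idx = ct.transcripts.index(ct.reference_transcript)
    ref = ct.ct[ref_idx]
    keep = [i for i in range(len(ct.transcripts)) if i != ref_idx]
    values = ref[np.newaxis, :] - ct.ct[keep, :]
    transcripts = tuple(ct.transcripts[i] for i in keep)
    return ExpressionMatrix(transcripts, ct.samples, values)
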