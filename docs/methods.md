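# Methods

This note documents the models, rules and numerical choices behind
`lupustrat`, and what its synthetic cohorts do and do not emulate.

## qPCR processing

**Reflected ΔCt.** Each transcript's Ct is normalised to the reference gene
PPIA and reflected, `x[g, s] = Ct[PPIA, s] − Ct[g, s]`, so larger values mean
higher expression. The reference row must be fully observed; it is removed
from the expression matrix. Single-reference normalisation is deliberate —
multi-reference geometric means, efficiency correction and inter-plate
calibration are out of scope.

**Non-detects.** A reaction that never crosses the detection threshold is a
failure of *low* signal, i.e. a *high* Ct, so non-detects are right-censored
in Ct. The detection limit defaults to 38 cycles (common qPCR practice; the
threshold is configurable and recorded in logs). Imputation is per transcript
across samples with a censored-normal EM: the E-step replaces each censored
value with E[X | X > c] and E[X² | X > c] under the current Normal(μ, σ)
(upper-truncated-normal moments via the inverse Mills ratio, computed on the
log scale for stability), the M-step updates (μ, σ) from the completed
moments. Convergence: max |Δμ|, |Δσ| < 1e-6, at most 500 iterations, σ floored
at 1e-3; non-convergence warns and returns the last iterate. The censored
log-likelihood is recorded each iteration and asserted non-decreasing in
tests. Imputation is single (the conditional mean, identical for all censored
entries of a transcript, always ≥ the detection limit) and never alters an
observed value. No sample-level covariates enter the censoring model; this is
a declared simplification of published non-detect imputation approaches that
model sample effects.

## Signature scores

A panel score is the median reflected ΔCt over the panel's transcripts
(mid-median for even counts). The packaged registry carries the published
panel sizes — plasmablast 4 (M4.11, M7.7), neutrophil 15 (M5.15), myeloid 17
(M3.2, M5.7), inflammation 13 (M4.2), erythropoiesis 11 (M2.3, M3.1) — plus
13 transcripts for IFN-Score-A, 14 for IFN-Score-B and 7 further
interferon-stimulated genes carried in the matrix but belonging to no score,
for 94 transcripts in total. Because the real assay manifest is not public,
the packaged transcript membership is a synthetic stand-in; panel sizes are
validated on load and mismatches warn. The two IFN scores are computed as
panel medians like every other score, although they were originally derived
by factor analysis; with unit factor loadings in the generator the median is
a consistent estimator of the latent factor, which is why this
simplification is adequate for the synthetic validation (it is *not* a claim
about the original factor weights).

## Within-stratum clustering

Patients are clustered separately within each ancestry stratum on all 94
transcripts: per-transcript z-scores (n−1 denominator; constant transcripts
map to zero with a warning), Euclidean distances, complete-linkage
agglomeration, cut at exactly k = 3 (the cut is by cluster count, not
height, since no dendrogram height is part of the contract). The
agglomerator maintains inter-cluster distances with the Lance-Williams max
update and breaks distance ties by merging the lexicographically smallest
pair of current cluster indices, making the tree deterministic under input
order; tests verify exact partition agreement with a brute-force
agglomerator that rescans all point pairs each merge, and with an
independent library implementation on larger instances. Complete linkage is
reducible, so merge heights are non-decreasing; this is asserted. Archetype
labels dichotomise each cluster's median IFN-Score-A and neutrophil score at
the stratum-wide medians, ties resolving to "high", mapping to the four
labels `IFN-low/neutrophil-high`, `IFN-high/neutrophil-low`, `all-high`,
`all-low`. Cluster-number selection (silhouette, gap statistic) is a
non-goal; k is fixed at 3 per stratum.

## BILAG 2004 engine

Domains are the nine BILAG 2004 organ systems; grades A–E are taken as
given (item-level scoring is out of scope). Eligibility: ≥1 grade A or ≥2
grade B at baseline. Numerical score: A=12, B=8, C=1, D=0, E=0 summed over
domains (the standard BILAG 2004 numerical coding). The first-cycle
responder rule at month 6 requires (i) every baseline A improved to B or
lower, (ii) at most one persisting grade B, and (iii) no new A/B flare.
Two readings of clause (ii) are implemented: the default counts every
month-6 B, including a baseline A that improved only to B (the stricter,
auditable reading); `persisting_b_rule="from_b"` counts only baseline-B
domains still graded B. For clause (iii) a *new severe flare* is any domain
graded A at month 6 that was not A at baseline — including a baseline B
worsening to A — and a *new B flare* is a baseline C/D/E domain graded B at
month 6. The narrower reading (flares only from baseline C/D/E) would make
the rule non-monotone: worsening a baseline-B domain to A at month 6 would
escape all three clauses and could turn a nonresponder into a responder.
The adopted reading matches BILAG flare convention and makes the rule
monotone (worsening any month-6 grade toward A never creates a responder),
which the test suite verifies by exhaustive enumeration of all two-domain
grade transitions. A missing month-6 assessment yields `undetermined`;
response is undefined (an error) for ineligible baselines.

## Statistical layer

Contingency tables use the Pearson chi-square without continuity correction
— including 2×2 tables, because the uncorrected statistic is what reproduces
the published ancestry-by-response value (the corrected statistic would be
≈1.65 where 2.1 is printed, and the printed P = 0.142 pins the uncorrected
2.15). A zero expected count is an error naming the cell. Spearman uses
mid-ranks with the t approximation; Kruskal-Wallis is tie-corrected; the
two-sample t defaults to Welch (pooled by config); Tukey's HSD covers
parametric post hocs and a hand-computed Dunn z-test (pooled mid-ranks, tie
correction) covers the nonparametric ones, unadjusted by default with
Bonferroni/Holm available. Significance convention is p ≤ 0.05. No
multiple-testing control is applied across report tables, matching the
analysis this package operationalises. Printed statistics that require
patient-level data (e.g. the IgG t-test) are computed only for synthetic
cohorts and are not reproduction targets.

## Synthetic cohort generator

The generator defines the study conditions for every validation. Defaults:
82 EA and 55 NEA patients (the first-cycle clustering subsets), cluster
mixes 33/24/25 (EA) and 9/21/25 (NEA).

**Latent structure.** Six factors per patient (IFN, plasmablast, neutrophil,
myeloid, inflammation, erythropoiesis). Cluster archetypes shift factor
means by ±2.0 reflected-ΔCt units (`cluster_shift`): NEA-1 is IFN-low with
high neutrophil/myeloid/inflammation, NEA-2 the mirror image, NEA-3 high on
those axes with IFN high; plasmablast and erythropoiesis are flat across NEA
clusters. EA clusters are all-high / IFN-high-others-low / all-low, with
erythropoiesis following the neutrophil axis and a mild ±1.0 plasmablast
gradient. The EA IFN factor is a two-component Gaussian mixture (means −3.0
and +1.0, sds 0.6) selected by the cluster's IFN polarity, so the marginal
EA distribution is bimodal while the NEA IFN factor is unimodal around its
cluster shift (sd 0.6) — reproducing the published marginal pattern. The
separation and residual scales were fixed once to match the published
figures' visibly blocked heatmaps and tight per-cluster boxplot IQRs
(~1 ΔCt) relative to cluster median separations (~3–4 ΔCt); complete linkage
cannot recover archetypes from long, factor-elongated clusters, and the
published analysis evidently operated in the well-separated regime.

**Coupling.** Within a cluster, each non-IFN factor residual is
`ρ·z_IFN + √(1−ρ²)·z` against the shared standardised IFN residual. The
printed stratum association values (EA 0.265/0.530/0.714/0.598/0.437 and
NEA 0.001/0.109/0.716/0.445/0.296 for plasmablast/neutrophil/myeloid/
inflammation/erythropoiesis) are printed as "R²"; whether they are ρ or ρ²
is ambiguous, so both readings are supported (`coupling_scale`). The default
reads them as squared correlations (target ρ = √value): it takes the
notation literally and is the only reading under which the EA
plasmablast–IFN coupling (√0.265 ≈ 0.51) is strong enough to survive noise
attenuation and reproduce a clearly IFN-coupled EA plasmablast signature
alongside a decoupled NEA one.

**Transcripts.** Each transcript loads with coefficient 1 on its panel's
factor plus independent Normal(0, 0.5) noise and a panel-level baseline
offset chosen so score medians land in the published range (e.g. plasmablast
near −5.6). The reference gene is Normal(20, 0.5) per sample. Two
interferon-stimulated transcripts are given deep baselines (≈ −16) so that
IFN-low patients naturally produce non-detects and the censoring/imputation
path is exercised on every cohort; all other transcripts sit safely below
the detection limit.

**Clinical trajectories.** Every baseline satisfies the eligibility rule by
construction (one or two grade A domains, or the two-grade-B route, with
organ weights favouring renal/mucocutaneous/musculoskeletal involvement).
A responder flag is drawn per patient from the cluster archetype's response
probability (NEA 1/8, 7/17, 17/20; EA 19/31, 13/18, 13/16 — the published
response rows) and the month-6 grades are constructed to be consistent with
that flag under the rule engine: responders improve all A/B domains with at
most one persisting B; nonresponders violate one clause chosen uniformly
among those applicable (a persisting A, two month-6 Bs, or a new flare). The
generator re-classifies every generated trajectory and asserts agreement.
20% of patients lack the month-6 assessment (→ undetermined), matching the
published attrition (55 clustered vs 45 evaluable NEA patients). Ancestry
categories, serology flags, SLEDAI-2K, deprivation ranks and medications are
drawn from plausible marginals (e.g. RNP/Sm seropositivity enriched in
IFN-high archetypes) and carried as covariates only.

**What the generator does not emulate.** Amplification curves, probe
chemistry, batch and plate effects, within-panel loading heterogeneity,
sample-level censoring covariates, correlations between clinical covariates
and expression beyond the archetype means, and ancestry subgroup structure
within the NEA stratum. Passing recovery tests therefore demonstrates that
the pipeline is correct and well-calibrated under the declared latent
model — not that real registry data are this well separated.

## Problem sizes and determinism

All validation runs are seeded (`numpy.random.default_rng`; derived seeds
stay below 2³¹) and deterministic given config + seed, including byte-
identical pipeline reruns. Validation sizes were chosen to keep the full
suite and the acceptance script in the minutes range on a single core:
planted-recovery uses 100 simulated cohorts at the default stratum sizes,
coupling fidelity uses strata of n = 200, the censored-EM oracle uses
n = 500 with ~12% censoring against a 1601×1401 likelihood grid, the
brute-force linkage oracle covers 200 instances with n ≤ 8 at every k, the
rule audit enumerates all 625 two-domain transitions, and null calibration
uses 1000 simulations.
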