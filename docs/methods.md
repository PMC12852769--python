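# Methods

## Scope and data model

`metalrisk` assesses the chronic dietary risk to an adult consumer from ten
elements (Cd, Pb, Ni, Co, Se, Cu, Fe, Mg, Mn, Zn) measured in the muscle and
liver of sheep and goats.  The packaged study table holds group summaries
(mean ± SD, n = 20) for the eight species × sex × tissue groups; per-sample
tables with the same schema are accepted anywhere group summaries are.  A
measurement below the limit of detection is a first-class *censored* record
carrying its LOD (instrument ppb values divided by 1000 to mg/kg), never a
silent zero.

## Exposure and risk equations

For tissue concentration C (mg/kg), ingestion rate IR (kg/day) and body
weight BW (kg):

- EDI = IR · C / BW
- HQ = (EF · ED · IR · C) / (RfD · BW · AT)
- HI = Σ HQ (per tissue)
- ILCR = EDI · CSF

Defaults: IR(liver) = 0.002 kg/day; IR(meat) = 3.14 kg/year stored at full
precision as 3.14/365 kg/day (all equations consume daily intake); BW = 70
kg; EF = 365 d/y; ED = 70 y; AT = 25550 d.  Because EF·ED = AT exactly
(365 × 70 = 25550), HQ is evaluated via EDI/RfD whenever that identity holds
so the equality is bit-exact rather than approximate; the general formula is
used otherwise.

RfD (mg/kg-bw/day): Cd 0.001, Ni 0.02, Co 0.03, Se 0.005, Pb 0.004, Cu 0.04,
Fe 0.7, Mn 0.14, Zn 0.3.  Mg has no established RfD, CSF or MRL: it flows
through concentration handling and chemometrics but is excluded from
HQ/HI/ILCR.  CSF (per mg/kg-bw/day): Pb 0.0085, Cd 0.380, Ni 0.84 — the
standard USEPA oral slope factors.

ILCR bands: below 1 × 10⁻⁶ *negligible*, above 1 × 10⁻⁴ *unacceptable*, and
the closed interval between them *acceptable* — the middle band is the only
one conventionally described inclusively, so both boundaries are assigned to
it.  MRL screening uses strict inequality (limits are maxima, equality
complies).  The MRL table keeps muscle and liver limits separately with
their issuing authority (EC for Cd, Codex for Pb and Cu, WHO for Ni,
FAO/WHO for Mn and Zn); Co, Se, Fe and Mg have no packaged limit and screen
as `no_limit`.

## Pooling and non-detects

Published per-tissue risk figures require one concentration per (tissue,
element); the source tables give four group means.  The engine pools with an
equal-weight mean by default (`by_n` weighting is identical under the
balanced n = 20 design) and substitutes non-detects as zero by default,
with `half_lod` and `lod` policies available for sensitivity analysis.
ND→0 is the default because a non-detected carcinogen then contributes
exactly zero ILCR, the conventional treatment.  Some published per-element
HQ/ILCR values are not exactly recoverable from printed group means under
any single documented pooling rule (the published Cd-liver ILCR of
7.33 × 10⁻⁵, for instance, would require an effective liver intake near
0.11 kg/day against the stated 2 g/day); the engine therefore always reports
its own deterministic values and exposes the pooling rule and ND policy as
configuration rather than matching irreproducible cells.

## Monte Carlo propagation

Candidate families — lognormal, Weibull, scaled beta, normal — are fitted by
maximum likelihood (`scipy.stats`).  Fits are ranked by the Anderson–Darling
statistic, computed directly from the fitted CDF via
A² = −n − (1/n) Σ (2i−1)[ln F(x₍ᵢ₎) + ln(1 − F(x₍ₙ₊₁₋ᵢ₎))], with a
Kolmogorov–Smirnov p-value reported for reference; ties break by fewer free
parameters, then family name.  AD is used because it is the default
criterion in the commercial risk tools this stage replaces.  The scaled-beta
support defaults to [0.95·min, 1.05·max] of the sample (a margin on the
sample range when the data touch zero) to avoid boundary likelihood
singularities.  Fitting refuses samples smaller than 8 or constant samples;
a degenerate `point_mass` distribution covers fixed values, and constant
draw vectors are summarized with exact moments (sd identically 0).

Propagation draws one concentration per element per iteration, 10,000
iterations by default, clipping negative draws (possible under the normal
family) at zero.  Elements are independent by default — no inter-element
dependence is assumed in the uncertainty analysis — with per-element random
streams derived from one root seed and the element symbol, so adding or
removing an element never perturbs the others' draws and results are
bit-reproducible from the seed.  HI is formed per iteration as the sum of
HQ draws.  "95% confidence" reporting is operationalized as the 95th
percentile of the simulated distribution alongside the mean, which is what
the summary narrative quotes; 5th and 50th percentiles are included.

## Chemometrics

Pearson correlations use signed r with the conventional bands: strong
r > 0.7, moderate 0.5 ≤ r ≤ 0.7, weak otherwise (exhaustive and mutually
exclusive on [−1, 1]).  PCA standardizes columns (correlation PCA — the
variables span five orders of magnitude in concentration), orders components
by descending eigenvalue, reports loadings as eigenvector × √eigenvalue and
explained variance summing to 100%, and fixes the arbitrary eigenvector sign
by making each component's largest-magnitude loading positive.  HCA clusters
*elements* with 1 − r dissimilarity and average linkage by default —
correlation is the natural similarity for source apportionment — with
standardized-Euclidean/ward/complete available; columns are processed in
alphabetical order so equal-height merges resolve deterministically.
Per-sample data pooled across both tissues is the default analysis set, as
it is the only n large enough for stable correlation estimates.

## Synthetic cohorts

The generator emulates the packaged design: per group and element, n draws
from a marginal moment-matched to the printed (mean, SD) — lognormal by
default (μ = ln(m²/√(m²+s²)), σ² = ln(1+s²/m²)), since concentrations are
positive and right-skewed; Weibull and zero-truncated normal are
alternatives (the truncated normal moment-matches the untruncated
parameters; truncation bias is negligible at the packaged means ≫ SD).
Cells that are ND in the study are always emitted censored, and any draw
below the element's LOD is censored as it would be at the instrument.
Inter-element dependence is induced by a Gaussian copula specified on the
latent scale; realized Pearson correlations are attenuated by the marginal
transform, so tests validate realized correlations empirically rather than
asserting the latent value.

`planted_source_cohort` provides ground truth for the chemometric stage:
factor 1 loads 0.88 on {Cu, Cd, Fe, Co, Mn} ("terrestrial"), factor 2 on
{Pb, Ni, Zn} ("anthropogenic"), giving within-block correlations near 0.77;
Se and Mg are independent noise.  The two factors are mildly anti-correlated
(−0.3, cross-block r ≈ −0.23, magnitude below the moderate band) so the
cross-block dissimilarity exceeds the block-to-noise dissimilarity and a
2-cluster dendrogram cut separates the planted blocks reliably.  Latents map
to concentration scales affinely (20% CV around nominal element means),
which preserves Pearson correlations exactly.

What the synthetic data does *not* emulate: analytical measurement error,
spike recovery, instrument drift, age/season/feed covariates, or any
tissue-to-tissue dependence within an animal.  Tests passing on synthetic
cohorts therefore demonstrate correctness of the statistical machinery under
the stated model, not the field validity of the study design.

## Numerical and design choices

- Weibull moment matching solves the coefficient-of-variation equation for
  the shape on [0.05, 200] by Brent's method; the scale follows from the
  mean.
- HQ rank strings break ties alphabetically by element symbol for
  determinism.
- Report CSVs emit floats via `repr` and are read back with the round-trip
  float parser, so written and re-read values are bit-identical; report
  metadata records that concentrations are treated as mg/kg as given
  (wet/dry basis unspecified upstream).
- Pipeline outputs are written atomically (temp file + rename); the manifest
  records the package version, a SHA-256 config hash, the seed and the input
  checksum.
- Monte Carlo on group-summary input falls back to moment-matched lognormal
  concentration models per pooled cell; per-sample input gets full
  goodness-of-fit selection.

## Problem sizes used in the test suite

Distribution-recovery tests use 10,000 draws (MLE standard errors ≈ σ/√n
justify the ±0.02 tolerance on lognormal μ, σ); closed-form quantile checks
use 100,000 iterations with a 1% relative tolerance; cohort moment matching
is checked at n = 10,000 against 3-standard-error CLT bounds; chemometric
block recovery uses n = 2,000 samples where the null correlation sd is
≈ 0.022.

## Known limitations

- Left-censored cells are substituted (0, LOD/2, LOD), not modelled by
  censored-likelihood fitting.
- The Monte Carlo treats elements as independent; a joint run requires
  supplying a copula-generated cohort.
- Single adult scenario only: no child or subpopulation exposure, no dermal
  or inhalation routes.
- MRL screening compares means (or single values) against limits; it does
  not propagate sampling uncertainty into compliance probabilities.
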