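# Methods

This note documents the statistical machinery in `rmcq`, the defaults it
ships with, and the places where the design was genuinely open.

## Data model and cleaning

Items carry their scored labels in worst→best order, a set of non-scorable
labels, a reverse-coding flag (applied to numeric raw codes at matrix level),
and optionally an explicit recode rule (total over the item's labels, able to
merge categories, send labels to `NON_SCORED`, or send them to
`MEDIAN_IMPUTE`).  Scored codes are 0-based integers; after cleaning, a
higher code always means better treatment.  All downstream arithmetic assumes
this orientation.

Screening removes respondents with **more than** `max_missing = 5` missing
items; a respondent with exactly five is imputed and kept (the inclusive
boundary is a deliberate reading of an otherwise ambiguous rule and is
configurable).  Non-scorable answers are answers, not missingness: they do
not count against the threshold.  Imputation uses the **lower median** —
the lower-middle order statistic — so the imputed value is always a valid
category code, and median imputation leaves each column's median unchanged.

Two cleaned matrices leave the pipeline:

* the **factor-analysis matrix** is complete — missing, non-scorable and
  impute-flagged cells are all median-imputed, because the correlation
  estimators need every cell;
* the **scoring matrix** keeps missing and non-scorable cells absent —
  scores must be computable for one woman at a time without knowing
  population medians — while impute-flagged cells (explicit recode decisions)
  are filled on both paths.

The half-split shuffles respondents within each country with a seeded
generator and deals them alternately, guaranteeing per-country balance to ±1
and exact reproducibility.

## Polychoric correlations

Every association in the validation path is a polychoric correlation: the
ordinal pair is modelled as a discretized bivariate normal.  Estimation is
the standard two-step scheme — thresholds from the marginal cumulative
proportions through Φ⁻¹, then the pairwise correlation by maximizing the
contingency-table multinomial likelihood with thresholds fixed.  The
maximizer is found by Fisher scoring with analytic derivatives
(∂Φ₂(h,k;r)/∂r = φ₂(h,k;r)), run vectorized across all pairs at once; the
bivariate normal CDF is Genz's hybrid quadrature (TVPACK's BVND) with a fixed
20-point Gauss–Legendre rule, accurate to ~1e-14 and fully vectorized.  A
full 36-item matrix at n ≈ 1200 costs ~0.2 s, which is what makes parallel
analysis with per-replicate polychoric matrices affordable.

Numerical policies: thresholds are clamped to ±7.5 (Φ(7.5) = 1 to double
precision) instead of ±∞; empty cells of a pair's table receive a 0.5
continuity correction before likelihood evaluation; estimates are clipped to
±0.999 and flagged when a table is (near-)degenerate; a non-PSD matrix is
eigenvalue-smoothed (floor 1e-6, rescaled to unit diagonal) and flagged.
The per-observation asymptotic variance of each estimate — the inverse
Fisher information at the optimum, thresholds treated as fixed — is kept for
the DWLS weights; a delete-a-block jackknife alternative exists for small
samples where the information-based variances may be optimistic.

Bartlett's sphericity statistic, −(n−1−(2p+5)/6)·ln det R with p(p−1)/2
degrees of freedom, and the KMO measure (anti-image partial correlations
from R⁻¹) are computed on the polychoric matrix by default; whether the
original analyses used Pearson or polychoric input for these gates is not
documented anywhere, so the choice is explicit and either matrix can be
passed.

## Exploratory factor analysis

**Retention.**  Horn's parallel analysis compares the eigenvalues of the
observed correlation matrix with those of replicate datasets obtained by
independently permuting each observed column — this preserves every item's
marginal category counts, which matters for ordinal data.  The suggested
count is the leading run of observed eigenvalues above the reference summary.
Two summaries are available: the replicate **mean** (the classic rule, the
default) and the **95th percentile** (`summary="p95"`).  They serve different
purposes: under the null the observed eigenvalues are a draw from the same
ensemble as the reference, so the mean rule flags a spurious first factor
about half the time — only the percentile rule has ~5% false-retention
calibration.  The pipeline nevertheless starts the search from the mean
rule's suggestion because the search *descends*: an over-generous start is
harmless, an under-count is unrecoverable.

**Extraction.**  Principal-axis factoring iterates the eigendecomposition of
the reduced correlation matrix with communalities on the diagonal, started
at the squared multiple correlations.  Convergence is declared when the
largest communality change falls below 1e-5, with a 3000-iteration cap.
Both numbers are deliberate: solutions containing two-item factors contract
at roughly 0.998 per iteration near the fixed point, so the conventional
very tight tolerance either demands tens of thousands of iterations or
spuriously fails; 1e-5 is already an order of magnitude tighter than the
1e-3 used by the common R and SPSS implementations.  Communalities above 1
(Heywood cases) are clipped and flagged, never fatal.

**Rotation.**  Promax with κ = 4 (the conventional power; not documented in
the source analyses): Kaiser-normalized varimax, then an oblique
least-squares fit to the |loading|^κ target, columns rescaled so the implied
factor correlation matrix Φ = (UᵀU)⁻¹ has unit diagonal.

**Reliability.**  McDonald's ω per factor from the congeneric closed form
ω = (Σ|λ|)² / ((Σ|λ|)² + Σ(1−λ²)) on standardized items.  Absolute loadings
are used so a negatively keyed item contributes its magnitude — the
alternative (signed sum) would let one reversed item erase a scale's
reliability even when it measures the construct well.  Loadings at or above
1 in magnitude make the closed form undefined; inside the search such
Heywood loadings are clipped to 0.999 and flagged.

**Acceptance and search.**  The mechanical criteria: (1) no item with two or
more pattern loadings ≥ |0.4|; (2) at least three significant items per
factor, with two-item factors downgraded to warnings (they are legitimate
when both loadings are high and no smaller solution absorbs them); (3)
ω ≥ 0.7 per factor.  The fourth criterion — theoretical sense — cannot be
automated and is represented as a caller-supplied note plus targeted
overrides (`"omega:<factor>"`, `"cross:<item>"`, `"factor:<factor>"`) that
waive specific failures; nothing auto-passes it.  The search descends from
the suggested factor count; if no count is acceptable, the item that
cross-loaded in the most attempted solutions (ties to the lowest item index)
is eliminated and the search restarts on the reduced set.  Everything is
deterministic given its inputs, and the full trace (every k tried, every
criteria report, every elimination) is part of the output.

Items are mapped to their highest-|loading| factor when that loading reaches
0.4; exact ties go to the lower factor index and are flagged; everything else
is reported unassigned.

## Confirmatory factor analysis

The confirmatory model has one loading per assigned item, unit-variance
factors, all factor pairs free to correlate, and a unit-diagonal implied
correlation matrix.  Estimation is two-stage DWLS: thresholds and polychoric
correlations estimated first and fixed, then
F(θ) = Σ_{i<j} w_ij (r_ij − σ_ij(θ))² minimized by L-BFGS-B with analytic
gradients, with w_ij the inverse per-observation asymptotic variances of the
polychoric estimates (the diagonal weight matrix).  The test statistic is
the plain χ² = (n−1)·F_min — no robust mean/variance correction is applied,
a documented difference from software defaults that report scaled statistics.
The independence model (all correlations zero, same thresholds) supplies the
CFI/TLI baseline:

* CFI = 1 − max(χ²−df, 0) / max(χ²_b−df_b, χ²−df, 0)
* TLI = ((χ²_b/df_b) − (χ²/df)) / ((χ²_b/df_b) − 1), capped to [0, 1]
* RMSEA = √(max(χ²−df, 0) / (df·(n−1)))
* SRMR = root mean squared residual of the correlation matrix (lower
  triangle plus diagonal; the diagonal residual is zero in the correlation
  metric).

Conventional bands: CFI/TLI > 0.9 acceptable, > 0.95 good; RMSEA < 0.08
acceptable, < 0.05 good; SRMR < 0.08 good — with the caveat, honoured by the
pipeline's reporting rather than hard-coded rejection, that SRMR behaves
poorly with categorical data and a solution need not clear every band.

For the shipped 29-item, six-factor calibration: 406 correlations, 44 free
parameters, df = 362; the baseline has df = 406.

## Synthetic cohorts

The generator draws factor vectors from N(0, Φ) with Φ = 0.3 off-diagonal by
default (the calibration's factor correlations were never published; oblique
rotation implies they are nonzero, and 0.3 is a typical inter-construct
correlation for such instruments — it is configurable and echoed in every
output).  Item latents are the loading-weighted factor combination plus
unique noise scaled to unit total variance, discretized at equal-probability
thresholds by default; a `skewed` preset concentrates mass in the top
categories to mimic the strong ceiling effects of real experience surveys
and to stress the polychoric boundary handling.  Negatively keyed items are
emitted in their administered (reversed) coding so cleaning is exercised end
to end.

Two published pattern coefficients exceed 1 (legitimate for oblique pattern
loadings).  A latent-variable generator cannot use them as-is — they would
imply negative uniqueness — so generating loadings are capped at
|λ| ≤ 0.95 (configurable); scoring always uses the uncapped published
values.  Missingness is completely at random, at the sparse scale the
emulated study reported (~15 affected rows per ~2400, nearly all with ≤5
missing items and a rare heavily missing row); there is no informative
missingness mechanism.  Seven items sit outside the six-factor calibration;
the generator gives five of them weak single-factor loadings (0.31–0.37)
and two of them deliberate 0.3–0.35 cross-loadings, reproducing the
"weakly loading" and "persistently cross-loading" item classes a real
validation has to handle.

What the generator does **not** emulate: hospital-level clustering,
intervention time trends, real item marginals (the true prevalences were
never published item-by-item), differential item functioning across
countries, or any non-Gaussian latent structure.  Passing tests therefore
demonstrate that the pipeline recovers what this model family generates —
not that any particular real population satisfies the model.

## Fixtures as contract

The shipped 36-item schema is a documented **reconstruction**: the exact
prompts, response options, recode table and the precise set of reverse-coded
items of the original instrument are not public.  The schema file format is
the contract; corrected administration metadata can replace the fixture
without touching code.  The six-factor loading file uses the same format the
exploratory stage writes, so scoring runs identically off the published
calibration or a freshly estimated solution.

## Problem sizes in tests

The test suite and the acceptance script run the full search at n = 1217
(ten seeds), confirmatory fits at n = 1216, convergence checks at n = 5000,
and null calibrations at n = 1000 with 100 parallel-analysis replicates —
the subsample sizes of the emulated study where one exists, and sizes at
which the Monte-Carlo properties being asserted are stable where not.

## Known limitations

* Polychoric estimation is pairwise (limited information); no standard
  errors are produced for the correlations themselves beyond the diagonal
  asymptotic variances used as DWLS weights.
* Plain DWLS χ² is not robust; its fit indices are best compared within this
  package rather than against software reporting scaled statistics.
* The two-item factors are only just identified: their loadings converge
  slowly in extraction and their recovered patterns show more rotational
  bleed than the well-populated factors.
* The "theoretical sense" criterion is irreducibly human; the search encodes
  only the mechanical criteria plus explicit overrides.
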