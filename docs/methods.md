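# Methods

## Scope and data model

`foodrisk` operates on a `ConcentrationTable`: a sample × metal matrix
of trace-element concentrations in mg/kg dry weight, each sample
labelled with a sampling site, optionally accompanied by per-metal
detection limits (LOD). The packaged reference dataset is the published
2025 survey of *Brassica pekinensis* Lour. leaves from the Cecomaf
(n = 11) and Lutendele (n = 8) gardening stations in Kinshasa: 19
metals (Ti, V, Cr, Mn, Fe, Co, Ni, Cu, Zn, As, Se, Mo, Ag, Cd, Sn, Sb,
Ba, Pb, Hg), transcribed verbatim from the published table. Cells
reported as below the detection limit are stored as 0.0, exactly as
published; an LOD/2 substitution (`qc.substitute_below_lod`) exists for
sensitivity analyses but is off by default, because the published
downstream tables are reproduced only with the zeros. The published
LOD row covers 13 of the 19 metals (Ti–Mo plus Hg); the remaining six
carry no detection limit and are never LOD-flagged.

Units are fixed: concentrations mg/kg dry weight, ingestion rate g/day,
body weight kg, EDI µg/kg bw/day. The single µg→mg conversion (10⁻³)
is pinned inside the THQ formula and applied nowhere else, which keeps
unit discipline testable.

## Deterministic indices

For metal *i* with concentration `C_i`:

    EDI_i = C_i · DIR / BW
    THQ_i = EDI_i · EF · ED / (RfD_i · AT) · 10⁻³
    HI    = Σ_i THQ_i

Default scenario: DIR = 60 g/day, BW = 58 kg, EF = 365 days/year,
ED = 70 years, AT = 25,550 days. Since EF·ED = AT under these defaults,
THQ reduces to EDI·10⁻³/RfD; the identity `THQ · RfD · 10³ = EDI` holds
exactly for any scenario with EF·ED = AT and is property-tested. The
scenario contract deliberately does not require EF·ED ≤ AT: the formula
is applied as written for any positive parameters.

The hazard index is computed over the seven metals with an oral
reference dose — Mn (0.14), Fe (0.7), Cu (0.04), Zn (0.3),
As (3·10⁻⁴), Cd (10⁻³), Pb (4·10⁻³) mg/kg bw/day — and this set is
overridable but not extended by default: inventing reference doses for
Cr, Ni or Hg would not be defensible. All arithmetic is full double
precision; rounding (2 decimals for indices, 1 for fold ratios) happens
only at report emission. The published index table was assembled from
rounded intermediates, so reproduction tests compare each printed cell
at the larger of 0.02 absolute, 1 % relative, or half an ulp of the
precision the cell was printed at.

Food-limit screening uses FAO/WHO (2003) maximum permissible
concentrations — Cr 1.3, Cu 40, Cd 0.1, Pb 0.3, Hg 0.001 mg/kg. The
printed limit row in the source table is typographically garbled; these
values are fixed by back-calculation from the published fold-exceedance
statements (e.g. Cd: 2.95/29.5 → 0.1) and documented in the registry
source. The screening reports the maximum over the selected samples;
the computed Pb fold is 103.1 (30.94/0.3), whereas the publication
prints 103.3 — the report emits the computed value and the discrepancy
is documented rather than patched.

## Rank correlation

Spearman's coefficient is computed as the product-moment correlation of
mid-rank vectors: tied observations receive the mean of the rank
positions they span. Ties are common here because below-detection
cells are zeros and participate in ranking as zeros (no exclusion);
the no-tie shortcut `1 − 6Σd²/(n(n²−1))` does not reproduce the
published coefficients on tied columns, while the mid-rank form
reproduces all six quoted values (0.855, 0.929, 0.564 at Cecomaf;
0.910, 0.881, 0.524 at Lutendele) to ±0.001. The implementation is
cross-checked pair-by-pair against `scipy.stats.spearmanr`.

Two-sided p-values use the t transform `t = ρ√((n−2)/(1−ρ²))` with
n − 2 degrees of freedom by default (adequate at n ≥ 8); a permutation
method is available as an audit option — exhaustive enumeration of the
n! rank permutations for n ≤ 7, seeded Monte Carlo with the add-one
correction otherwise. The permutation null uses tie-free ranks 1..n,
which is exact for untied data and a close approximation under the mild
ties seen here. Significance is flagged at α = 0.05 two-sided with no
multiple-testing correction across the 171 pairs, matching the source
analysis. Note that by any standard two-sided test the Cd–Hg pairs
(ρ = 0.564 at n = 11, p ≈ 0.07; ρ = 0.524 at n = 8, p ≈ 0.18) are *not*
significant at 0.05, although the source bolds them; the package
reports the honest test. The source also labels its coefficients "R²";
they are rank correlations ρ, and are named so here.

## Monte Carlo exposure simulation

Each iteration draws an age/sex stratum by its population proportion, a
body weight and an ingestion rate from that stratum's distributions,
and one concentration per metal; the EDI follows from the same intake
formula as the deterministic chain. The per-metal exceedance
probability is the fraction of iterations with EDI above the metal's
tolerable-intake limit (WHO limits, µg/kg bw/day: Mn 700, Fe 1000,
Cu 40, Zn 1000, As 2.14, Cd 1, Pb 3.6), with binomial standard error
√(p(1−p)/n_iter). Default n_iter = 10,000.

Supported marginals: point, normal, lognormal (log-scale parameters),
triangular, and empirical resampling, each optionally truncated by
rejection sampling. Concentration defaults come from
`fit_concentration_dists`: a lognormal per metal whose log-mean/log-sd
are the moments of the log observations (zeros replaced by LOD/2 where
a detection limit is known; metals with fewer than three positive
values are skipped with a warning; an all-equal column degenerates to a
point mass). Lognormality is the smallest-assumption model for
nonnegative right-skewed concentration data and is fully overridable in
the config.

The default population model is *illustrative*, not survey data: adult
male (35 %, BW ~ N(65, 10) kg), adult female (40 %, BW ~ N(58, 10) kg),
child (25 %, BW ~ N(25, 8) kg), ingestion N(60, 15) g/day for adults
and N(40, 12) for children, truncated positive (BW > 20 kg adults,
> 5 kg children). No consumption survey of the study population exists,
so published exceedance percentages (which depend entirely on such
choices) are not reproduction targets; the module's correctness surface
is instead (a) exact 0/1 exceedance for point-mass configurations,
(b) agreement with the closed-form lognormal tail
`1 − Φ((ln L − µ)/σ)` within three binomial standard errors,
(c) bitwise reproducibility under a fixed seed, and (d) monotonicity of
the exceedance probability in the limit and in concentration scale —
all tested.

Determinism: one `numpy.random.Generator` keyed by a single seed, with
a fixed draw order (stratum indices; then per-stratum body-weight and
ingestion blocks; then one concentration block per metal in config
order), so identical configurations give identical results across
platforms with the same generator.

## Synthetic data

The generator produces tables with known ground truth: lognormal
marginals per metal coupled through a latent Gaussian copula. A target
Spearman correlation ρ_s for a pair maps to a latent Pearson
correlation r = 2·sin(πρ_s/6) (exact for bivariate Gaussian ranks);
the joint latent correlation matrix is validated positive definite via
Cholesky and rejected otherwise. Because lognormal transforms are
strictly monotone, the sample rank correlation converges to the target;
the test oracle is nevertheless a 10⁶-draw brute-force simulation of
the same latent model, not the closed form. Values drawn below a
configured detection limit are recorded as 0.0, mirroring the reference
dataset's convention and deliberately exercising the correlation
module's tie handling.

Recovery tests run at n = 500 with generator log-sd ≤ 0.8, so the
±0.05 recovery band on the log-mean is at least two standard errors
wide (se = σ/√n); rank-structure recovery is checked at ±0.08. What
passing shows: the pipeline's estimators are consistent for the model
the generator implements. What it does not show: robustness to features
of real surveys the generator omits — replicate measurement error,
spatial autocorrelation between plots, censoring patterns that differ
by site, or non-lognormal tails.

## Numerical and interface conventions

- Reader: CSV with a header row; the sample-id column is required, the
  site column optional (sites otherwise inferred from configurable
  sample-id prefixes, default CS→Cecomaf, LS→Lutendele, chosen so the
  published table can be stored verbatim). Comma-decimal dialects are
  supported. Malformed cells raise errors naming the row and column;
  duplicate ids and negative values are distinct, named errors.
- A row labelled `LOD` carries per-metal detection limits; blank cells
  mean "no limit reported". Write∘read is the identity on valid tables
  (floats emitted via `repr`, so round trips are exact).
- LOD flagging uses strict `<` (a value equal to its detection limit
  counts as detected, as printed values at the limit do).
- CRM recovery is 100·measured/certified, reported at one decimal by
  default and integer rounding on request; the packaged BCR-482
  mercury pair (0.46/0.48 mg/kg) gives 95.8 %, i.e. 96 % at integer
  rounding. The pass threshold defaults to 90 %.
- The full pipeline computes all results before writing any file, so a
  failing stage leaves no partial outputs; rerunning with the same
  inputs and seeds produces byte-identical CSV/text outputs.

## Known limitations

- The ingestion rate is applied to dry-weight concentrations as in the
  source analysis; if 60 g/day refers to fresh weight, intakes are
  overestimated by roughly the fresh/dry mass ratio.
- The reference dataset stores one value per sample row; replicate
  variance (reported only as "SD < 3 %") is not modelled.
- Carcinogenic risk indices (CRI/TCRI) are out of scope: no slope
  factors are available in the source record.
- The registry tags its food limits "FAO/WHO (2003)" as in the source
  table without resolving the citation-year inconsistencies in the
  surrounding text.
- Acceptance checks at desk scale: the deterministic pipeline and
  correlation analysis run on the full 19-sample dataset (instant); the
  Monte Carlo properties are verified at 10,000 iterations and the
  synthetic recovery at n = 500, the sizes at which the stated
  tolerance bands are statistically meaningful.
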