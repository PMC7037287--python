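# Methods

## Data model

A survey is a tidy table of `ConcentrationRecord` rows: one element
measurement (a replicate mean with its sample SD and replicate count,
default n = 3) for an area / cultivar / compartment cell. Soil rows carry
one of four depth intervals (0–20, 20–40, 40–60, 60–80 cm); plant and
soil concentrations are in mg/kg dry weight, must and wine in mg/L.
Columns reported in µg/L are divided by 1000 on load. Values below the
limit of quantification are kept as rows with `value = 0` and a
`censored` flag rather than dropped: grouped averages then treat them as
zero (matching how the source tables' printed averages behave) while the
censored count stays visible in every summary.

Reported tables round half-up to two decimals (`round_half_up`); all
computation is at full precision. Sample SD uses the n−1 denominator,
confirmed by recomputing the published RSD% rows.

### Known fixture inconsistencies

The bundled transcriptions keep the printed member values verbatim. Three
internal inconsistencies of the source tables are therefore *not*
"corrected" silently:

- the Simleul Silvaniei Zn area average is printed as 59.99 but its four
  printed depth members average to 58.99;
- the Baia Mare Co area average is printed as 22.57 but its members
  average to 22.92;
- the Simleul Silvaniei 40–60 cm Hg cell is printed as 0.57 ± 0.006,
  almost certainly a misprint for 0.057 (the printed area average 0.050
  is only consistent with 0.057).

Recomputation follows the members; the tests assert the first two gaps
explicitly as documented mismatches.

## Regulatory grading

Soil values are graded against tiered limits (normal value, alert
threshold, intervention threshold; alert and intervention split into
susceptible / less-susceptible land use). A tier is assigned only when
its bound is **strictly** exceeded, so a value sitting exactly on a
threshold stays in the tier below; grading the threshold values
themselves is a test invariant. `ratio_to_limit` is value / normal value.
Must and wine are graded against M.P.L.s; must has its own laxer Cu/Zn
limit (10 mg/L) and Pb limit (0.5 mg/L). Where only a wine limit is
stated (Cd, As) the must column reuses it; elements without any limit
(Ni, Co, Cr, Hg) grade as `no_limit`. Both limit sets are editable CSV
data files so other jurisdictions can be swapped in. The As limit is
stated in mg/L while As concentrations arrive in µg/L; the canonical-unit
conversion on load resolves the mismatch.

## Transfer chains

Translocation factors divide adjacent compartments
(root/soil, cane/root, leaf/cane, grape/cane, must/grape, wine/must);
mobility ratios divide any compartment by topsoil. Two choices are
exposed because the field literature is ambiguous:

- `soil_reference`: `depth_average` (default for TF chains, where the
  soil term is unqualified) or `topsoil_0_20` (default for MR, which is
  conventionally defined against the top soil layer).
- `site_policy`: `per_site_mean` (default — ratio per site, then averaged
  across sites within a cultivar) or `pooled` (ratio of across-site mean
  concentrations). The published per-cultivar ratios cannot be re-derived
  from the published aggregates under either policy (they evidently used
  unpublished replicate-level data), so correctness is established
  against synthetic ground truth and against the internally consistent
  summary rows (mean/SD/RSD of printed per-cultivar ratios) instead.

A censored concentration enters a numerator as 0 and invalidates a
denominator (the ratio propagates as missing with a warning — never
infinity). The default chain uses grapes/canes and must/grapes (the
published table layout); any pair list can be passed, including the
must/canes variant that appears in the defining equations.

The indicator band for classification defaults to [0.75, 1.25] as a
concrete reading of "a ratio at around 1"; it is a parameter. RSD% is
100·SD/mean and is undefined (NaN) for a zero mean; the characteristic
value 100·√3 ≈ 173.2 appears whenever exactly one of three ratios is
nonzero, however small — a property the tests pin down analytically.

## Duncan letters

One-way ANOVA (scipy) is followed by Duncan's multiple range test:
group means sorted descending, the range of each span of p means compared
against `q(1 − α_p, p, df) · sqrt(MSE / n_h)` with stage-wise levels
`α_p = 1 − (1 − α)^(p−1)`, studentized-range quantiles computed
numerically (so any alpha works, including the strict 0.005 used for
within-profile comparisons), and `n_h` the harmonic mean of group sizes.
The classic shortcut applies: a span declared homogeneous is never
subdivided, which makes letter groups contiguous in mean order and the
partition independent of input order. Letters are assigned from "a" at
the largest mean.

A deliberate consequence of the stage-wise levels is that under a
complete null with k groups the probability of *any* separation is
`1 − (1 − α)^(k−1)`, not α — the well-known laxness of this procedure.
The null-calibration test therefore checks exactness at k = 2 (where the
test reduces to a single pooled-variance comparison at level α) and
separately asserts the stage-wise rate at k = 3.

## Correlations

Pearson cells carry r, the two-tailed p from the t transform, and stars
(\* at 0.05, \*\* at 0.01). A zero-variance vector yields a degenerate
cell with r reported as 0 — mirroring how all-censored element columns
are tabulated — and fewer than 3 paired observations yields an
`insufficient` cell. The matrix builder resolves one value per
(area, cultivar) observation, broadcasting the per-area soil reference
across cultivars, and accepts `distance` as a pseudo-variable. No
multiple-testing correction is applied across the matrix.

## Chemometrics

LDA standardises features (z-score), uses priors proportional to class
counts and the eigen solver, and reports between-class explained-variance
percentages per discriminant axis; a singular within-class scatter is
rejected with advice to drop collinear elements rather than silently
regularised. Cross-validation refits the scaler and model per fold
(leave-one-out or stratified k-fold). The default element set for origin
discrimination is Cr, Hg, As, Cu, Zn, Pb, Ni, Cd — Co is excluded for
beverages because it is below LOQ in every must and wine sample, and an
all-zero column breaks the scatter matrices. For multivariate stages the
`impute_censored` helper replaces censored zeros by LOQ/2.

Because discrimination needs more observations than features, the
multivariate stages consume replicate-level profiles
(`synthetic.replicate_observations`, 3 sites × 3 cultivars × 3 replicates
= 27 observations); the record table itself stores only cell means. The
published cross-validation percentages for must and wine are not
reproducible targets for the same reason — the replicate-level survey
data behind them were never published.

Clustering defaults to Ward linkage on Euclidean distances of z-scored
profiles ("interval measure" in common statistical-package parlance);
metric, linkage and standardisation are parameters. Ties break by input
order (the scipy convention). The dendrogram exports to Newick through
scikit-bio with branch lengths equal to merge-height differences, so
root-to-tip distance equals the final merge height (ultrametric).

## Synthetic gradients

The generator encodes the structure the analyses assume, with known
ground truth:

- soil mean at distance d: `S_e · exp(−k_e · d)`, scaled per depth layer
  by `depth_slope^layer` (default 1.0 — no trend);
- each downstream compartment mean = upstream mean × configured partition
  ratio (the TF chain is exact by construction);
- each replicate = cell mean × lognormal factor with mean exactly 1 and
  relative spread `cv_noise` (σ² = ln(1 + cv²), μ = −σ²/2), so
  concentrations stay positive and ratios are recovered without bias;
- record value/SD are the replicate mean and sample SD; values below the
  per-element LOQ are emitted censored;
- every draw derives from (seed, site, element, cultivar, compartment)
  via a CRC-keyed seed sequence, so subsetting the configuration never
  shifts the surviving streams and equal seeds give byte-identical CSVs.

The bundled default (`gradient_default.yaml`) places three sites at 0, 5
and 60 km (the source distances of the motivating survey are unpublished;
these are plausible near/mid/background placements and fully
user-configurable), uses polluted-topsoil source strengths, decay rates
that put the far site at rural background levels, field-observed chain
partitions, `cv_noise = 0.1` and n = 3 replicates. Cultivar labels are
part of the configuration because transfer summaries and discrimination
are defined per cultivar.

What the generator does *not* emulate: soil chemistry covariates (pH,
organic matter), geochemical speciation, atmospheric deposition as a
second pathway, temporal dynamics, or inter-element correlation beyond
the shared distance gradient. Passing recovery tests therefore show the
estimators are correct under the stated noise model, not that real
surveys meet that model.

### Problem sizes used in checks

Ground-truth recovery runs 200 seeds at `cv_noise = 0.1` (3 sites,
3 cultivars, 3 replicates) and requires the median absolute relative
error of every recovered chain ratio to stay below 5% (observed ≈ 1.8%).
These runs disable censoring (`loq = 0`) to isolate estimator error: a
compartment that is below LOQ by construction (e.g. wine Hg under the
default truth) reports 0, which is the correct censored answer but not a
ratio estimate. Null calibration of the letter display uses 1000
two-group datasets; LDA chance level uses 60 label shuffles of the
27-observation wine matrix.

## Calibration QC

`fit_calibration` fits an ordinary least-squares line to (level,
response) points — the default level series is 2.5, 5, 10, 25, 50 —
and derives LoD = 3·SD/s and LoQ = 10·SD/s, with SD the residual
standard deviation on n−2 degrees of freedom (the usual reading of "SD
of the regression line"; the source is silent on the denominator) and s
the slope. LoQ/LoD = 10/3 identically, and both limits are invariant to
rescaling the response. No weighting is applied. Published per-element
LOQ footnote values cannot be re-derived without the underlying
calibration data and are treated as fixture constants only.
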