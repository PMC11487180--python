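# Methods

## Scope and model overview

The package implements four statistical/numerical procedures that together
take a protein-microarray binding screen to cell-biological readouts, plus
a synthetic-data layer that generates every input with known ground truth.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic benchmarks do and do not demonstrate.

## Array hit calling

Signals are standardized per array: `z = (x − mean)/sd` (sample SD), or
`z = (x − median)/(1.4826·MAD)` as a robust alternative. The robust
variant matters when true binders are frequent or strong, because they
inflate the mean/SD and can mask planted signals; the plain variant is the
default because it is the common convention for array screens. Hit calling
is a strict filter `z > θ` with θ = 2.5 by default; the boundary value is
not a hit. Duplicate probes for one gene collapse to their maximum Z —
a single strong spot is evidence of binding, and max-collapse commutes
with thresholding, which the tests assert. Readers accept delimited text
or spreadsheet workbooks and use a precomputed Z column when one is
present, since deposited array tables often ship Z rather than raw
intensities.

## Monte-Carlo gene-set enrichment

Given universe U, annotation set G ⊆ U and query Q, the statistic is
k = |Q′ ∩ G| with Q′ = Q ∩ U. The query is restricted to the universe
first: the null draws lists from U, so the observed statistic must live in
the same space. The null resamples lists of size |Q′| uniformly *without*
replacement (gene lists have no repeated genes), which makes the null
exactly hypergeometric; the analytic tail is computed with
`scipy.stats.hypergeom.sf` and attached to every result, giving each run a
built-in oracle check. The empirical p counts ties against significance
(`#{null ≥ k}/n_perm`), which makes "p < 0.05" identical to the rule that
the observed overlap strictly exceeds 95% of the reference overlaps. A
`(#+1)/(n+1)` pseudocount variant is available for reporting, and a
Benjamini–Hochberg helper covers the multi-set case; the significance call
itself always uses the default estimator so the decision rule is
unambiguous.

Sampling is vectorized with the random-key trick (the n smallest of |U|
iid uniform keys are a uniform n-subset) in fixed 512-row blocks, so
results depend only on the seed, and 10,000 permutations at the default
geometry (|U| = 24,609, |G| = 640, |Q| = 147) take a few seconds.

Calibration is inherently sub-nominal for this test: the null overlap is
discrete, so the achievable type-I rate at α = 0.05 is the largest
achievable tail probability below 0.05 plus Monte-Carlo smoothing. For
geometries with a reasonably fine-grained tail (null mean overlap of tens)
the realized rate is ≈ 0.040–0.045; the calibration test uses
|U| = 500, |G| = 200, |Q| = 150 with 500 permutations and 2000 replicates,
whose analytic rate is 0.041.

## Binding affinity (MST)

Fnorm is the hot-window/cold-window fluorescence ratio (optionally ‰).
The dose-response model is the quadratic 1:1 isotherm with ligand
depletion; with target T = 100 nM and titrations reaching the low
nanomolar, the hyperbolic approximation is measurably wrong at the bottom
of the ladder, so the quadratic is the default and the hyperbola a flag.
The bound fraction is evaluated in the cancellation-free form
`FB = 2L / (s + sqrt(s² − 4LT))`, `s = L + T + K_D`.

Fitting minimizes squared residuals over log₁₀ K_D (positivity by
construction) with baseline and amplitude profiled linearly at each
candidate K_D via the 2×2 normal equations; a 60-point log-spaced grid
spanning two decades beyond the titration range provides multistart
coverage, refined by bounded scalar minimization. Replicates are pooled
rather than averaged, and per-concentration SDs are available for
reporting. Amplitude sign is unconstrained. A fit whose K_D lands more
than 10× above the highest titrated concentration is refused
(`converged = False`, no K_D) — beyond that point the data contain
essentially no curvature and any reported number would be noise.

Uncertainty is a case-resampling bootstrap with percentile intervals
(68.3% and 95%). Resampling is joint over all points by default: the
natural-looking alternative of resampling within each concentration
stratum shrinks the resampling variability when strata hold only three
replicates (measured 95% CI coverage 85% vs 94% for the joint resample at
the default design), so stratification is opt-in.

Precision limits: Fisher-information analysis of the default design
(16-point two-fold ladder from 110 µM, T = 100 nM, 3 replicates, noise 5%
of amplitude) gives a best-case SD of ln K_D of about 0.11 at
K_D = 10 µM, 0.21 at 52 µM, 0.40 at 112 µM and 2.6 at 446 µM — weak
binders whose K_D approaches or exceeds the titration top are
fundamentally imprecise at this design, and the simulation tests show the
fitter operating at that bound. Median recovery across seeds is biased by
less than 2% for constructs within the titration span.

## Morphometry

Distances between duplicated centrosomes are Euclidean in 2D, matching
measurement on maximum-intensity projections (a 3D option exists but is
off by default); "split" means strictly greater than δ = 2.5 µm, so the
boundary value scores not-split. Mitotic cells are excluded before any
denominator is formed. Ciliation is summarized as percentage of cells per
imaging field, then mean ± SEM across fields — the aggregation unit of
per-field violin plots — with a pooled binomial-SEM mode for flat tables;
cilium lengths are summarized over ciliated cells only. The two-group
comparison is a two-sided label-permutation test with the
`(1 + #{|T*| ≥ |T|})/(1 + n_perm)` convention (ties toward the null),
which is finite-sample valid and calibrates within [0.035, 0.065] at
nominal 0.05 in the test suite.

## Synthetic data: what it emulates and what it does not

Arrays are simulated directly on the Z scale (standard-Gaussian null,
mean-shifted binders) because the screen filters on Z; this says nothing
about raw HuProt intensity distributions, scanner channels or inter-array
normalization, and recovery results on synthetic arrays therefore
demonstrate the filter logic, not robustness to real array artifacts.
Gene collections use synthetic symbols with an exactly planted overlap;
real annotation lists differ by curation version, which is why printed
enrichment p-values from any particular study are reproduced only in
distribution (oracle equivalence), not digit-for-digit. MST curves come
from the same isotherm family the fitter assumes, so fitting benchmarks
measure estimator precision, not model misspecification. Cell populations
use Bernoulli ciliation, positive truncated-Gaussian lengths and two
uniform distance regimes for cohesive vs split centrosomes; defaults
(ciliation 13.7%, length 1.9 ± 0.24 µm, split fraction 0.2) mirror the
reported ranges for PAK6-overexpressing neuroblastoma cells.

Default problem sizes (200 seeds per fitting benchmark, 2000 calibration
replicates, 10⁴-cell populations, 10⁴ permutations) were chosen so each
stage's sampling error is well below the tolerance it is tested at.

## Reproducibility

Every stochastic routine takes an explicit seed; generators derive
independent `numpy` streams from `(stream_id, seed)` so outputs are
bit-stable regardless of call order, and the pipeline manifest records
versions, seeds, parameters and input checksums. Rerunning a pipeline
config reproduces every output byte-for-byte.

## Known limitations

* The Z-score formula used for any given deposited array table is not
  always documented by its authors; when a table ships precomputed Z, the
  reader trusts it.
* The enrichment test is single-set by design; multi-set screening beyond
  the BH helper (GO-DAG traversal, term-size filtering, semantic grouping)
  is out of scope.
* Bootstrap intervals undercover mildly for weakly constrained K_D fits
  near the refusal boundary.
* Per-field SEM conventions depend on how an imaging "field" is defined;
  the generator's fixed field size is a simplification.
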