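# Methods

## CNVR construction

Calls are 1-based inclusive intervals (`length = end − start + 1`),
taken from a DELLY-style structural-variant VCF: `SVTYPE ∈ {DEL, DUP}`
and `END` in INFO, `GT` in FORMAT. A sample carries a record when its
genotype contains allele 1; `./.` and `0/0` do not. Copy-number FORMAT
fields (CN/RDCN) are ignored — the three-state coding below needs only
carrier status and call type. The PASS filter is a case-insensitive
substring match on "pass". Records with other SVTYPEs (INV, BND, …) are
skipped and counted.

Merging treats calls on one chromosome as nodes of an interval-overlap
graph; a CNVR is a connected component and spans the min start to max
end of its members. *Overlap means sharing at least one base*:
book-ended intervals (end = next start − 1) are not merged. Because
components of an interval graph are contiguous after sorting by start, a
single sweep suffices and the result is independent of input order.
Region ids are `DEL`/`DUP`/`MIX` + an 8-digit index assigned in
(chromosome, start) sort order. The size window [50 bp, 5 Mb] is applied
to calls before merging and to regions after merging; both bounds are
inclusive and configurable.

Coding: per sample and region, all-DEL → −1, all-DUP → +1, no call → 0.
A sample with both call types in one region (possible only in mixed
regions) is coded by the type with the larger total overlapped length;
an exact tie codes −1, because losses dominate these landscapes roughly
20:1 and the tie is vanishingly rare. Every such conflict is logged.
Carrier frequency is the fraction of samples with a nonzero code; the
filter keeps columns with frequency strictly above the floor (default
0.005, "above 0.5%").

## Relationship matrix

G = C Cᵀ / s, where C is the code matrix with each column mean-centered
and s = Σⱼ varⱼ (population variance, denominator n). This is the
VanRaden construction transplanted to three-state codes; with no stated
allele-frequency model for CNV codes, column-mean centering is the
defensible default. Consequences used as invariants: row sums of G are
exactly zero, the mean diagonal is exactly 1, G is PSD, and duplicating
every column leaves G unchanged. Zero-variance columns are dropped (they
carry no relationship information); if none remain, construction fails
rather than returning a zero matrix. A small configurable ridge
(default 1e−6) is added to the diagonal before the mixed-model solves,
since CNV GRMs built from few columns can be rank-deficient.

## Mixed model

One record per individual, so Z = I. For a trait y (missing phenotypes
dropped listwise; GRM and genotype rows subset *before* decomposition):

y = μ + W g + u + e,  u ~ N(0, G σ²ₐ),  e ~ N(0, I σ²ₑ).

With G = U D Uᵀ computed once, rotating by Uᵀ diagonalizes the
covariance: Var(Uᵀy) = σ²ₚ Λ(h²), λᵢ = h² dᵢ + (1 − h²), where
σ²ₚ = σ²ₐ + σ²ₑ and h² = σ²ₐ/σ²ₚ. The restricted likelihood is profiled
down to h² (σ²ₚ has a closed-form optimum with REML degrees of freedom
n − p) and maximized over [1e−6, 1 − 1e−6] by a 64-point grid followed
by bounded scalar minimization to 1e−8 — the grid guards against the
mild multimodality REML in h² can show, and a 1000-point grid oracle in
the tests checks the optimum. Fits require ≥30 samples and nonzero
phenotypic variance.

Per-marker testing is EMMAX-style: the variance *ratio* h² is fixed at
the null estimate and each CNVR column enters the fixed effects of a
weighted least-squares solve in the rotated basis. The residual scale is
re-profiled per marker with df = n − p, which makes the σ²ₐ = 0 limit
collapse *exactly* to ordinary least squares (a test asserts agreement
with an independent OLS fit to 1e−6). The statistic is Wald
χ²₁ = (β̂/se)²; a constant marker returns p = 1 with a `degenerate` flag
instead of failing. An `exact=True` option re-estimates h² per marker
with the marker in the model; fast and exact paths agree within
|Δlog₁₀p| ≤ 0.3 on well-conditioned simulations.

Multiple testing defaults to Bonferroni α/N over the tested regions
(N = 11,035 at α = 0.05 gives 4.531e−6); Benjamini–Hochberg q-values
are available behind `method="fdr_bh"` (via statsmodels). Calibration
diagnostics: QQ expected quantiles −log₁₀((i − 0.5)/m) and
λ_GC = median(χ²)/0.4549.

Fixed effects are intercept-only by default — the emulated design is a
single hatch reared in one house, leaving no structural covariates — but
an optional covariate matrix is threaded through the null fit and every
test.

## Annotation

A gene is proximal to a CNVR when the closed intervals
[gene.start, gene.end] and [max(1, start − flank), end + flank]
share ≥1 bp, flank = 50 kb. "Contained in the window" is deliberately
read as *any overlap* — requiring full containment would silently drop
long genes straddling the window edge. Genes are classified `inside`
(within the CNVR), `overlaps_cnvr`, or `flank_only`, and strand is
ignored (the window is symmetric). Queries use sorted per-chromosome
arrays with binary search; the tests keep a quadratic double loop as the
oracle. flank = 0 reduces to plain intersection, and the gene set is
monotone in the flank.

## Synthetic data

The generator states the world the analysis assumes rather than exposing
tuning dials:

- **Type proportions** default to 0.947/0.044/0.009 loss/gain/mixed —
  the split reported for an 834-bird laying-hen survey (10,446/491/98 of
  11,035 regions).
- **Sizes** are drawn by bin mass 87.4/9.6/1.3/1.5/0.2% over bins
  50–1000 / 1–5 k / 5–10 k / 10–50 k / ≥50 kb, log-uniform within a bin
  (CNV sizes are right-skewed at every scale), capped at 650 kb to match
  the largest region such surveys report. The published bin labels
  overlap ("0.05–5 kb" followed by "1–5 kb"); the first bin is
  implemented as 0.05–1 kb, the only reading under which the five
  percentages partition.
- **Placement** is rejection-sampled onto chromosomes chosen
  proportionally to length (default: the 38 chicken autosome lengths
  shipped as package data), keeping ≥1 bp gaps so distinct regions never
  merge back together.
- **Carrier frequencies** are Beta(1, 15) scaled to (0.001, 0.5) — mean
  ≈ 3%, mass piled near zero, mimicking the low carrier frequencies of
  real CNV landscapes. Mixed regions get ≥2 carriers split between
  genuinely overlapping DEL and DUP calls, so the classifier is
  exercised by construction, never short-circuited.
- **Phenotypes**: y = μ + Σ wⱼgⱼ + u + e with u ~ N(0, G σ²ₐ) drawn via
  the eigendecomposition of the realized G. Causal effects are
  back-computed from each region's empirical code variance so it
  explains its configured variance fraction; σ²ₑ absorbs the remainder
  so total modeled variance is 1. Default polygenic h² is 0.3, a typical
  value for poultry weight and egg-quality traits.

Everything is a pure function of (config, seed). What simulated data do
*not* carry: linkage disequilibrium between regions, genotyping error,
boundary uncertainty beyond the optional span jitter, or selection
structure — so a green recovery test establishes correctness of the
machinery under the stated model, not robustness to real-data artifacts.

## Numerical choices

- Rounding for presentation tables is half-up to 1 decimal (matches how
  such survey tables are printed; banker's rounding would flip several
  entries).
- GRM eigenvalues are clipped at 0 (warning below −1e−6); symmetry is
  enforced to 1e−10.
- p-values are floored at the smallest positive double so −log₁₀p stays
  finite.
- Bit-identical reruns: the pipeline is deterministic given (inputs,
  config); the manifest records a config hash, seed and per-stage row
  counts.

## Known limitations

- The GRM formula for CNV codes is a design choice; sources describing
  this analysis name the software family but not the construction, so a
  different centering (e.g. frequency-based) would shift variance
  components, though the Wald test is fairly insensitive to it.
- The EMMAX approximation understates per-marker uncertainty when a
  marker explains a large variance share; the `exact` option exists for
  spot-checks.
- Sex chromosomes are out of scope; the shipped chromosome table is
  autosomal.
- One record per individual: repeated measures would need an explicit Z
  and are not modeled.
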