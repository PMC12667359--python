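# Methods

This note documents the models implemented in `cladescan`, the parameter
choices that matter, the numerical decisions, and what the synthetic-data
experiments do and do not establish. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Haplotype copying model and local distances

Each recipient haplotype `j` is modelled as a mosaic of the other `N - 1`
haplotypes (the Li & Stephens scalar-copying model): a hidden donor process
that is retained across a variant interval with probability `1 - rho_v` and
redrawn uniformly from the `N - 1` donors with probability `rho_v`, and an
emission that copies the donor's allele with probability `1 - mu_v` and
miscopies with probability `mu_v`. The donor prior is uniform; a haplotype
never copies from itself. Forward and backward recursions are run per
recipient column with per-column rescaling to unit sum (logged scale
factors), not in log space — the distance below is a per-column ratio, so
the rescaling cancels exactly.

The local distance from recipient `j` to donor `i` at locus `ℓ` is

    d_ij = -log( max( f_ij b_ij / Σ_k f_kj b_kj , υ ) ),    υ = 4.94e-324,

the negative log posterior copying probability, clamped at the smallest
positive subnormal double so the maximum distance is `D = -log(υ) ≈ 744.44`.
The self-distance is defined to be 0 (the sorted column always starts at the
recipient itself), overriding the `f_jj = b_jj = 0` convention that would
otherwise put it at `D`.

An ancestral-allele-aware emission mode is available behind a flag: a
mismatch is penalised (`mu`) only when the *recipient* carries the derived
allele against an ancestral-carrying donor; a donor's private derived allele
can be copied over at no cost. This is this package's construction of an
asymmetric, orientation-aware emission and is not claimed to be identical to
any particular published variant; the default is the symmetric model.

*Parameters.* `rho` and `mu` are per-variant inputs on the variant map. The
synthetic cohorts default to `rho = 1e-2` per interval and `mu = 1e-4`
(dimensionless probabilities). `mu` sets the distance scale — one
mismatching variant costs roughly `log((1-mu)/mu) ≈ 9.2` — and, through the
regularization threshold below, how much of that scale counts as structure.

## Optimal checkpointing

Testing loci right-to-left needs forward states in the order `L, L-1, …, 1`
while the forward recursion only runs left-to-right. With a budget of `C`
stored forward states (besides the working state; the initial state at the
origin is always available for free), the minimal total forward distance
`M(l, c)` for `l` targets above a free base satisfies

    M(l, c) = min_{1<=m<=l}  m + M(l-m, c-1) + M(m-1, c),   M(l, 0) = l(l+1)/2 :

advance `m` intervals, drop a checkpoint, serve the upper segment with one
slot fewer, then reuse every slot below. Targets are taken evenly spaced
(the nested binomial structure this induces is what makes the row recursion
solvable with a monotone-argmin two-pointer sweep in roughly linear time;
`L = 1e6` solves in seconds). Unevenly spaced targets are mapped to their
rank order — optimal for even spacing, an approximation otherwise, with the
realized per-variant step count reported separately by the iterator. Cost
counts forward variant intervals only: the single backward sweep is shared
by any schedule and backward steps are the more expensive ones, which is why
the schedule prefers repeated forward restarts. The DP is verified against
a quadratic reference DP and, for `L <= 12, C <= 3`, against exhaustive
search over all feasible schedules; the schedule replayer checks budget
feasibility, descending emission order and cost bookkeeping action by
action. The streaming iterator produces decodings bit-identical to
from-scratch decoding and never retains anything `N x N` across targets.

## Sprigs and the generalized relatedness matrix

*Neighbourhoods.* `η_j` is the tied-nearest-neighbour set of column `j`
(always containing `j`). Two routes exist: the exact tied-argmin scan, and
the innermost level set of the gap clustering below (the by-product route
the pipeline uses — it absorbs the small decoding noise that breaks exact
ties).

*Sprigs.* Haplotypes that agree on being in each other's neighbourhood form
the mutual-agreement graph; greedy maximal cliques (seeds in ascending
index, growth by ascending neighbour index — a deterministic, documented
tie-break) of size >= 2 become disjoint sprigs. Cliques larger than 10
haplotypes are flagged but kept: the 2–10 range is descriptive of typical
data, not a rule. Collapsing haplotype pairs to samples gives the clade
genotype matrix `X` with entries 0/1/2.

*Relatedness.* Each distance column is clustered into level sets separated
by gaps of at least `c = -0.2 log(mu)` (natural log; `mu = 1e-8` gives
`c ≈ 3.68`, the package's mosaic default `1e-4` gives `c ≈ 1.84`). Writing
`K_t` for the donor count within boundary `t` and `g(x) = 0` for `x < c`,
`min(x, 1)` otherwise (the API accepts any per-level `g` with `g(0) = 0`),

    Psi_ij = Σ over level boundaries at or beyond i's level of g(gap_t)/K_t,
    Omega  = sym(B' Psi B),   B = I_n ⊗ 1_2.

Interior gaps are below `c` by construction, so this reproduces the
per-rank definition (`ψ_j(k) = g(d_(k+1) - d_(k))/k`, outermost level
contributing nothing) while needing only per-cluster summaries. The
clustering is a single-pass bucket algorithm (bucket width `c`; no split can
occur inside a bucket, only adjacent nonempty buckets can merge), `O(N)` per
column with at most `ceil(D/c) + 1` preallocated buckets, verified
identical to sort-then-split on random columns. Construction streams
column-by-column into the `n x n` accumulator; the dense `Psi` is only
materialised on request.

*Sprig removal.* To avoid testing a called sprig both through `X` and
through `Omega`, the innermost boundary contribution of every sprig-member
column (the level that defined its neighbourhood) is subtracted before
symmetrisation. The mechanics of this removal are this package's minimal
interpretation of "remove the sprig structure"; it is validated by the
property that a panel whose only structure is one planted sprig drops to
background relatedness after removal, and by the end-to-end null
calibration.

One consequence of taking the per-rank definition literally: a column whose
nearest donor sits further than `c` contributes `g(d_(2))/1` to the
recipient's own diagonal entry. A completely structureless panel therefore
yields `Omega = 0` only when `log(N-1) < c`; otherwise a pure diagonal
(self) term remains, which is harmless to calibration and mildly dilutive
to power.

## Rank matching

All tests assume the phenotype's null residuals are unit-variance Gaussian,
which removes the variance scale parameter. `rank_match` enforces this for
arbitrary traits: residuals of `Y` on `(1, A)` are replaced by a fresh draw
from the *null residual law* — a standard normal vector projected off
`(1, A)` — rearranged to carry the data's ranks, with the fitted part added
back. Every downstream stage must adjust for the same `(1, A)` span (the
pipeline inserts the intercept explicitly).

Two simpler schemes fail measurably and are worth recording. Deterministic
quantile (Blom) scores fix the residual vector's norm across replicates,
visibly distorting the quadratic-form null. Matching to *unprojected* iid
draws assumes the residual ranks are a uniform permutation; with covariates
they are not (leverage makes coordinates non-exchangeable), which again
shows up in quadratic-form calibration at `n` in the hundreds. Matching to
the projected law removes both effects. A second-order approximation
remains — the sorted values and the rank pattern of a projected residual
are weakly coupled, and the procedure splices the ranks of one draw with
the sorted values of another — which shrinks as `n/q` grows and is not
detectable in this package's calibration experiments at `n = 500` with
10^4 nulls.

## The three sub-tests

*Single-marker (SMT).* Two-sided Gaussian p-value of the standardized
genotype coefficient after projecting out the background — known variance 1
by rank matching, hence a z test rather than a t test. Monomorphic or
covariate-collinear genotypes yield `p = 1`, flagged.

*Stable distillation (SD).* Clade columns are processed in ascending
allele-count-then-index order (immaterial under the null, tested). Each
column is residualized against the background `(A, G)` and all previously
distilled directions; the unit direction `u_j` gives `z_j = u_j'Y ~ N(0,1)`
under H0 and a two-sided p-value; the direction is then removed from the
working response (`Y ← Y - u_j u_j'Y`). Orthogonal projections of a
spherical Gaussian are independent, so the per-clade p-values are i.i.d.
uniform under H0 and the output response carries no information about them
— this "carries no trace" reading of the distillation update is exact
removal, so refitting a distilled column on the output gives `p = 1`.
Downstream, the quadratic form extends its projector by the distilled
directions so its null spectrum matches the restricted response.

The per-clade p-values are combined by a Rényi-type outlier statistic on
the smallest `m = min(c_max, p)` order statistics, with censoring at the
quantile-filter threshold `t = InverseBetaCDF(c_max, p - c_max + 1, 0.01)`
(the 1% point of the `c_max`-th order statistic of `p` uniforms; filtered
coefficients are still distilled but enter the combination only through the
censored count). With `K` uncensored values and anchor `a = p_(m+1)` (or
`t` when `K <= m`),

    T = Σ_{k<=min(K,m)} log(a / p_(k))   ~   Gamma(min(K, m), 1)  given K,

by the exponential-spacings representation of uniform order statistics, so
`p_SD` is exactly calibrated conditional on `K` (with a conservative atom
at 1 of mass `(1-t)^p` when nothing passes). `c_max = 16` by default — the
assumed upper bound on simultaneously causal clades at one locus. With
fewer than `c_max` clades the Beta parameterization is undefined and the
combination falls back to the unfiltered test with a warning.

*Quadratic form (QForm).* The score statistic for the variance component is
`y'P Ω P y`, computed matrix-free as `(Py)'Ω(Py)`. Its null law is the
weighted chi-square with the eigenvalues of `PΩP` — generally indefinite.
`tr(PΩP)` and `||PΩP||_HS^2` come from the expansion through `ΩQ` and
`Q'ΩQ` (well under the `7(q+1)n² + 3n(q+1)²` arithmetic bound). Given the
leading `k` eigenvalues by magnitude, the remainder (mean `η1`, variance
`η2`) is approximated by the shifted difference of chi-squares
`|λ_k|(W'_a - W''_b + μ)` with `a + b = η2/(2λ_k²)`,
`a - b + μ = η1/|λ_k|`, `|μ|` minimal subject to `a, b >= 0` — exact first
two moments, both tails exponential at rate `1/(2|λ_k|)`, at least as heavy
as the true remainder's asymptotic rates. Satterthwaite's single scaled
chi-square is kept for comparison and as the `k = 0` provisional when the
remainder looks PSD. Note the heavier-tail guarantee is a *rate* statement:
at a fixed finite quantile the moment-matched DCS sits at or above the
exact tail when the remainder is a few moderate eigenvalues over dust below
a separated retained block, but can be mildly below it for smoothly
decaying spectra (`λ_{k+1} ≈ λ_k`) — the adaptive stopping rule below is
what controls accuracy there.

Survival probabilities are evaluated by characteristic-function (Imhof)
inversion. The integrand oscillates at frequency `|x - shift|/2` while its
envelope decays like `u^-(1 + Σh/2)`, so the integral is split: adaptive
quadrature over a bounded number of periods, then — where every arctan in
the phase has saturated — two QUADPACK Fourier integrals over `[u0, ∞)`.
A doubled-precision self-check re-inverts at a finer rule when two
evaluations disagree. Validated against chi-square closed forms (df 1–200,
p down to 1e-6, relative error <= 1e-10) and large Monte-Carlo.

Eigenvalues are extracted adaptively: `k = 0` unless the provisional
p-value beats a threshold (default 1e-3), then blocks of 16
largest-magnitude eigenvalues via matrix-free Lanczos until the p-value's
log10 moves less than 0.05 between blocks, with a dense solve as the
small-`n` fallback; block size, tolerance and the threshold are this
package's choices, validated against the dense oracle. Three inflation
parameters `(ν, δ*², δ†²)` generalize genomic control to the remainder: `ν`
rescales its degrees of freedom and the `δ²` terms add variance to each
chi-square arm. They are orthogonal to `(a, b, μ)` — never recomputed when
the inflation changes — and default to the identity. Their exact form is
this package's construction.

*Combination.* The three p-values are independent under H0 by the
distillation guarantees, so the combined statistic is the minimum over the
SMT-anchored subset Fisher p-values `{SMT}, {SMT,SD}, {SMT,Q},
{SMT,SD,Q}` (Gamma survivals `G_1, G_2, G_2, G_3`) — only alternatives in
which the core marker participates are interesting, and this reading makes
the four terms commensurate. The statistic's null distribution is simulated
(default 10^7 draws, seeded): a monotone PCHIP spline of `log SF(-log S)`
over quantile knots for the body, a maximum-likelihood exponential for
exceedances over the 0.999 quantile, spliced continuously. Missing
sub-tests (e.g. no sprigs at a locus) restrict the subset family, with
per-family tables.

## Synthetic data

The cohort generator is deliberately simple: founder haplotypes drawn from
per-variant allele frequencies (optionally stratified into founder pools as
a stand-in for multi-population structure), descendants as recombination
mosaics (switch probability 0.05 per interval), Poisson(0.3) private
mutations per haplotype, 500 bp variant spacing. It reproduces the features
the method consumes — local haplotype sharing, rare clades, mutual-nearest-
neighbour structure — but not calibrated population-genetic quantities (no
coalescent times, no realistic site-frequency spectrum, no LD decay
profile). Passing tests on these cohorts therefore establish the
*statistical* properties (calibration, independence, power direction,
recovery of planted structure), not population-genetic realism; planted
clades use full-span identical segments because partial-span clades are
genuinely ambiguous to a copying model that integrates flanking
information.

Phenotypes: covariates `a1` (standard Gaussian) and `a2` (Rademacher) with
unit fixed effects; null draws are `Y ~ N(a1 + a2, I)`. For signal `s`, the
causal genotype columns are residualized against `A`, length-normalized and
QR-factored; `Rβ` is set to `sqrt(q_chi2/|A|)·1` with `q_chi2` the
`1 - 10^-s` chi-square quantile on `|A|` df (the squared norm, not the
norm, matches the quantile — the only reading under which the oracle
statistic's value is the quantile), and the noise is projected off the
causal span. The oracle ANOVA `-log10 p` then equals `s` exactly in every
replicate (verified to 1e-6), and the observed signal splits evenly across
causal variants. Causal sets respect an allele-count class ("any",
doubletons, or a count interval); an infeasible class raises so the caller
rejects the panel and resimulates, rather than silently relaxing the class.

## Problem sizes

The shipped experiments run at reduced scale, chosen so the full suite and
the acceptance script complete comfortably on one CPU: null calibration at
n = 500 samples with 10^4 phenotypes at one locus of a 300-variant panel;
Monte-Carlo validation of the quadratic form at n = 50 with 10^7 draws;
scheduler claims at L = 10^5. Genome-scale behaviour (30,000-sample
cohorts, genome-wide FWER thresholds, full power curves) is out of scope;
the power checks here are direction-only (distillation beats the quadratic
form on sprig-borne signals; the combined p-value beats the single-marker
p-value when several clades are causal).

## Known limitations

- Rank matching is exactly null-preserving only up to the sorted-values /
  rank-pattern coupling noted above; with very few samples or many
  covariates the quadratic-form null can drift.
- Rank matching also caps the contribution of any single sample at the
  Gaussian order-statistic ceiling, so a signal carried by a 2-haplotype
  clade has a hard detectability limit regardless of effect size.
- The DCS tail is not uniformly conservative at finite quantiles (rate
  guarantee only); accuracy in the smooth-spectrum regime rests on the
  adaptive-k stopping rule.
- The scheduler is exactly optimal for evenly spaced targets only.
- Sprig calling enforces disjoint cliques; overlapping clade support is
  collapsed greedily and deterministically.
- Quantitative traits only; no binary-trait likelihoods. No tree topology
  inference beyond sprigs (larger clades live in `Omega`).
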