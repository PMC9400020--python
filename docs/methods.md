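# Methods

## The multi-site neutral model

The MSN model treats the communities at k sites of one host as local
communities coupled to a single neutral metacommunity. The metacommunity
relative abundances follow a Dirichlet process with concentration θ (the
fundamental biodiversity number: the rate at which new species enter the
pool), and the counts at site *i*, of total *J_i*, follow a
Dirichlet-multinomial with concentration vector *I_i·p*, where *p* are the
pool proportions and *I_i* the site's immigration concentration. The
migration probability is *m_i = I_i/(I_i + J_i − 1)*: the chance that a
death at site *i* is replaced by an immigrant rather than by local birth.
Reported *M*-values are the per-fit mean over sites of the posterior-median
*I_i* (concentrations, not probabilities — they exceed 1 for realistically
coupled sites), while *m_i* stays in (0, 1).

The joint likelihood used everywhere is

    L(θ, I, p) = Ewens(pooled abundance configuration | θ)
               + Σ_i DirMult(counts_i | I_i · p),

in log form. This Ewens × Dirichlet-multinomial factorization is the
standard finite-sample marginal of the hierarchical-Dirichlet-process
approximation to the multi-site neutral theory; the exact multi-site
sampling formula is intractable beyond a couple of sites and is a declared
non-goal.

### Gibbs sampler

Inference uses the Chinese-restaurant-franchise representation. Per
iteration:

1. For every site *i* and taxon *s* with count *n_is* > 0, the ancestor
   (table) count *t_is* is drawn from its exact conditional
   P(t | n, a) ∝ |s(n,t)| aᵗ with *a = I_i·p_s*. The draw uses the
   sequential table-opening construction — a sum of independent
   Bernoulli(a/(a+j)), j = 0..n−1 — which samples the Stirling-number
   distribution exactly in O(n) and vectorizes over a site's taxa. The
   log-space Stirling recursion is retained as `ancestor_count_log_pmf`
   and serves as the analytic reference in tests.
2. Pool proportions are drawn from Dirichlet(T_1,…,T_S, θ) with
   T_s = Σ_i t_is and the last mass an aggregate unseen component.
3. θ is resampled by the Escobar–West auxiliary-variable scheme given S
   species among ΣT tables; each *I_i* likewise given (Σ_s t_is, J_i).

Priors are vague gammas, shape 1 and rate 0.01, on θ and each *I_i*
(positive support, prior mean 100, effectively flat over the plausible
range). The full-scale schedule is 50,000 iterations with the first 25,000
discarded and every tenth retained draw, i.e. N = 2,500 posterior draws;
`MsnConfig.scaled()` (5,000 iterations, N = 500) is the desk-scale preset
used by the tests and the acceptance script. Chains are reproducible from
the single config seed (one generator per fit; all sub-draws come from it
in a fixed order).

L₀ is evaluated once per fit at the posterior medians of (θ, I) and the
posterior-mean pool proportions. Evaluating per retained draw instead
would be equally defensible; the point-estimate convention is fixed because
it makes L₀ and the simulated likelihoods directly comparable and the whole
test deterministic given the seed.

### Two-level neutrality test

N simulated datasets are drawn at the fitted point estimates at each of two
levels: metacommunity-level simulations redraw the pool (a Chinese-
restaurant realization of size ΣJ) and the local samples; local-level
simulations hold the fitted pool proportions fixed and redraw only the
Dirichlet-multinomial sampling step. Each simulation's likelihood is
evaluated at the same point estimates (for metacommunity simulations,
conditioning the local terms on the realized simulated pool). The
pseudo-*p* at a level is the fraction of simulations with L ≤ L₀; values
above 0.05 mean the data are indistinguishable from the neutral model at
that level, and small values reject neutrality. With data simulated from
the fitted model itself the metacommunity pseudo-*p* is calibrated (false
rejection ≤ 15% across seeds in the acceptance suite), and strongly
niche-structured data drive it down.

## The niche-neutral hybrid model

Each niche is internally neutral with its own (θ, x, γ). The expected
species count at abundance n,

    φ_n = θ xⁿ Γ(n+γ) / (Γ(n+1) Γ(1+γ)),

is the dispersal-limited, density-dependent neutral form: γ → 0 recovers
Fisher's log series θxⁿ/n (total richness −θ·ln(1−x)), x < 1 guarantees a
convergent series, and φ₁ = θx exactly. The literature the model family
descends from does not pin a unique closed form; this one is adopted for
its correct limits and parameter semantics, and is documented as the
package's choice.

Observed abundances are binned into Preston octaves ([2ʲ, 2ʲ⁺¹)). A niche
is fitted only if it occupies at least four octaves (fewer leave no degrees
of freedom after estimating three parameters); excluded niches are reported
with `included=False`, which also explains why a ten-site metacommunity
typically contributes fewer than ten fitted niches. Estimation maximizes a
Poisson likelihood of octave counts — more stable than minimizing χ²
directly when bins are nearly empty — with θ profiled out analytically
(it enters linearly) and a 3×3 multi-start Nelder–Mead over (x, γ); the fit
is deterministic. χ² is computed post hoc over occupied octaves with
df = occupied − 3, R² = 1 − SS_res/SS_tot on octave counts, and the niche
migration coefficient is reported as m = γ/(γ + J − 1) — of order 10⁻⁴ for
γ ≈ 1 against J in the thousands, hence printed as 0.000 at three decimals.
The metacommunity-level test adds χ² and df across included niches
(independent niches by assumption); per-niche p-values are reported raw,
with no multiple-testing correction, and 0.05 thresholds throughout.
Because the hybrid family nests the single-niche neutral case, purely
neutral data also pass.

## Niche detection

Fitting the two-site MSN model to every unordered site pair (45 pairs for
10 sites, plus same-site diagonal pairs drawn from two distinct
individuals) yields a symmetric matrix of mean M-values. Migration
homogenizes communities, so M is a similarity; sites are clustered on the
distance d(a,b) = 1 − M_ab/max(M) by average-linkage agglomeration with K
chosen by maximum silhouette (K = 1 returned for a constant matrix). The
heatmap-inspection step of the original analyses is thus replaced by an
explicit, testable procedure. Per-pair randomness is derived from the root
seed and the pair's site labels, making the matrix exactly equivariant
under permutations of site order. Per-site θ is the mean over all pairwise
fits involving the site; `n_draws_per_pair` defaults to 30 at full scale
(3 in the desk-scale tests). `dispersal_contrast` summarizes a focal
site's mean M against the others' and the corresponding θ contrast, with a
Wilcoxon rank-sum p on the two M sets.

## Parameter-heterogeneity tails

Pooled parameter values are compared against a continuous power law
p(x) ∝ x^(−α), x ≥ x_min, fitted by the closed-form MLE
α = 1 + n/Σln(x_i/x_min) with x_min minimizing the Kolmogorov–Smirnov
distance (x_min candidates capped at 100 quantile-spaced values, tails of
at least 10 points), goodness of fit by a 200-replicate semi-parametric
bootstrap, and normality by the D'Agostino omnibus test. The verdict
applies the 0.05 rule to both p-values.

## Synthetic data

The generator emulates the shape of multi-site digestive-tract 16S
surveys: ~10 sites × ~200 individuals, per-sample totals log-normally
jittered (σ = 0.3) around J_target = 5,000, per-niche richness of a few
dozen taxa. Three regimes span the continuum: `neutral` (one
Chinese-restaurant pool shared by all sites, Dirichlet-multinomial
sampling with I from the migration probability), `nnh` (per-niche pools
with niche-specific θ_k and m_k; niches share a fraction `overlap` of
sampling mass, default 0.1, kept low so the niche signal is detectable at
desk scale), and `niche` (disjoint fixed site compositions, multinomial
noise only). Default m = 0.005 puts the implied immigration concentrations
(~25 at J = 5,000) in the range the multi-site fits report on real data.

`table3_like_bank` plants the five-group digestive-tract structure: two
two-site groups and one four-site group of mutually coupled oral-type
sites sharing 20% of their sampling mass through a common oral pool, a
weakly coupled standalone site (KG analogue, m = 0.035), and a fully
disjoint stool analogue with a several-fold richer pool (θ = 300 versus
16–20), weak coupling (m = 0.02) and twice-deeper samples. The shared oral
component is what keeps the oral sites' pairwise-fit θ moderate (shared
taxa mean shared ancestry in the fit), so the stool/oral θ contrast
exceeds 2 while stool's pairwise M stays the matrix minimum — the same
qualitative pattern the real surveys show.

What the generator does not emulate: read-level 16S artifacts (chimeras,
copy-number variation), taxon-specific interactions, longitudinal
structure, and host covariates. Passing tests on these banks therefore
demonstrates that the estimators and tests recover planted neutral/hybrid/
niche structure at realistic sizes — not that any particular real dataset
is neutral or niche-structured.

## Numerical choices and scaling

All likelihoods and the Stirling pmf are computed in log space; octave
expectations aggregate φ_n with a max-shift before summation. Taxa absent
from every site are dropped before fitting; a site with J = 0 is dropped
with a warning. Dirichlet draws with very small shapes are guarded against
underflow. Test and acceptance runs use scaled problem sizes chosen as the
package's desk-scale defaults — 5,000-iteration Gibbs schedules, N = 500
(or fewer) neutrality simulations, 20–50 resampling replicates, J around
2,000 — while the library defaults preserve the full-scale schedule
(50,000 iterations, N = 2,500, 1,000 replicates). Resampling draws one
individual per site uniformly, independently across replicates (with
replacement), since per-individual identity linkage across sites is
generally unavailable in public multi-site banks.

## Known limitations

Pseudo-*p* values are posterior-predictive checks, not frequentist
p-values; their calibration is verified empirically, not guaranteed. The
NNH SAD family is one member of a class of admissible forms; parameter
values (especially x, which approaches J/(J+θ) on neutral-sampled data)
are family-specific and should be compared only within the family. The
niche count from silhouette clustering is a model-selection heuristic;
borderline silhouette differences between adjacent K are not evidence of a
real niche boundary. Formal power analysis of the neutrality tests is out
of scope.
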