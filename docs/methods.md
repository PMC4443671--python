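# Methods

## Beta-binomial frequency posteriors

Each observation (one SNP, one sample) is `y` reads of the rising allele
out of depth `n`. With the conjugate uniform prior Beta(1, 1) the posterior
is Beta(1 + y, 1 + n − y), whose mean and variance are computed in plain
arithmetic (well conditioned up to depths of ~10⁶). Two consequences
shape the test:

* the posterior variance shrinks roughly as 1/n, so sequencing depth
  directly controls how much each observation is trusted downstream;
* the symmetric prior makes the moments mirror-symmetric under swapping
  the two alleles (m → 1 − m, s² unchanged), so the whole pipeline is
  invariant to which allele is called "rising".

Zero-depth observations are kept by default and fall back to the prior
moments (m = 0.5, s² = 1/12); their huge variance makes them nearly
uninformative in the GP, and keeping them keeps the design rectangular.
A `drop_zero_depth` flag removes them instead.

## GP models and the Bayes factor

The centered posterior means of one SNP — all replicates stacked, since
observations at the same generation in different replicates are treated as
repeated observations of a single shared latent trajectory — are fitted
with a squared-exponential GP plus white noise plus the fixed beta-binomial
(FBB) diagonal, and with the nested noise-only model. The log marginal
likelihood is evaluated through a Cholesky factorization (never an explicit
inverse or determinant expansion). Mean subtraction in place of an inferred
constant mean is an approximation that can degrade if depths vary wildly
across observations; no correction is applied.

Hyperparameters are optimized in log space with analytic gradients
(L-BFGS-B), initialized at the best point of a scale-free grid:

* length scale ℓ ∈ {span/8, span/4, span/2, span, 2·span} with
  span = max(t) − min(t), bounded to [shortest spacing between distinct
  generations, 10·span]. The lower bound prevents overfitting wiggles
  between samples; replicates at identical generations do not define a
  zero spacing. Units: generations.
* signal variance σ_f² ∈ {0.1, 1, 10} × var(centered means) and noise
  variance σ_n² ∈ {0.01, 0.1, 1} × the same, floored at 10⁻¹² so
  log-space optimization stays finite.

The time-independent model has one free parameter and is refined the same
way in 1-D, with the closed-form stationary point mean(y² − fbb) as an
extra start. Its optimum, embedded at σ_f² = floor, is also added to the
time-dependent candidate set: since the models are nested, this guarantees
ln BF ≥ 0 up to the dense-vs-diagonal rounding difference (observed
~10⁻⁹), rather than relying on the optimizer to find the boundary. Any
non-PD covariance gets diagonal jitter of 10⁻⁸ × mean(diag), escalated
tenfold to at most 10⁻², after which the SNP is flagged `failed` and
excluded from ranking (never a crash, never a sentinel score).

Ranking is by descending ln BF with deterministic (chrom, pos) tie-breaks.
The estimator classes (`BetaBinomialGPTest`, `CMHTest`) follow
scikit-learn conventions so they compose with its tooling; the underlying
per-operation functions remain importable.

## CMH comparator

Per replicate, a 2×2 table of the two alleles' counts at the base and end
generations; the statistic sums (a_r − E[a_r]) over strata and normalizes
by the summed conditional variances, giving χ²(1) under the null of a
common unit odds ratio. Intermediate generations are ignored — the test's
defining limitation relative to BBGP. The 0.5 continuity correction is off
by default so the statistic is a smooth ranking score (the convention
of the upstream tooling this mirrors is not documented); a flag enables
it. Replicates missing a time point or with zero depth there are dropped
with a warning; p-values below float underflow are clamped to the smallest
positive double.

## Wright–Fisher simulator

The generator emulates a replicated Drosophila-style E&R design. Defaults
are the basic study conditions: census size N = 1000 diploids, H = 200
founder haplotypes, R = 5 replicates, G = 60 generations sampled at
{0, 14, 28, 44, 60}, selected loci with s = 0.1 and semi-dominance
h = 0.5 starting uniformly in [0.12, 0.8], 500 neutral + 25 selected loci,
and Poisson mean depth λ = 45. Neutral starting frequencies are uniform on
[0.05, 0.95] — a configurable stand-in for a real founder-haplotype
frequency spectrum. Each replicate is founded by drawing 2N haplotypes
with replacement from a pool of H founders carrying round(H·p0) focal
copies; each generation applies the deterministic selection update for
fitnesses (1+s, 1+hs, 1) followed by Binomial(2N, p′) drift, absorbing at
0 and 2N. Selected loci are only constrained through the starting-frequency
range, never by conditioning trajectories (that would bias the null).
Sequencing draws depth n ~ Poisson(λ) and reads y ~ Binomial(n, freq);
an optional flag inserts a finite DNA-pool stage (hypergeometric sample of
a fixed number of individuals, e.g. 500, then binomial reads), off by
default.

What the simulator deliberately does **not** model: linkage and
recombination maps (loci are independent), hence no hitchhiking or
interference between selected sites; X-chromosome inheritance; mutation.
Passing benchmarks here therefore demonstrate behaviour on independent
trajectories with realistic drift and depth noise, not robustness to the
linked-haplotype structure of real genomes. Notably, with 525 unlinked
loci and s = 0.1 both BBGP and CMH separate selected from neutral loci
perfectly (average precision 1.0 for both) — the advantage of BBGP
reported at genome scale rests largely on confounds (linkage, uneven
coverage) that the desk-scale generator removes.

## Evaluation

Precision, recall and average precision (AP = mean precision at the ranks
of the true positives) operate on strict orderings; rankers must resolve
ties first, which both do deterministically. The no-discrimination
reference is the positive fraction n_pos/N. That value is the asymptotic
expectation of AP under random ranking; for very sparse positives the
exact expectation is noticeably higher (about 1.7× at 10 positives in
1000 items, by direct Monte-Carlo) because early-rank precision terms
dominate, so the baseline should be read as an approximation tight only
for dense positives or very large N.

## Problem sizes and numerical choices

The shipped benchmark uses 525 loci and finishes both tests in a few
seconds (≈8 ms per SNP for the double GP fit at J = 25 observations);
the calibration checks use 10⁴ null CMH tables, 200 GP recovery fits at
J = 45, and 2000 drift trajectories. Monte-Carlo assertions use 3–4
standard-error tolerances with fixed seeds. All randomness flows through
`numpy.random.Generator` seeded explicitly; identical seeds reproduce
results bit-for-bit.
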