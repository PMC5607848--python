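# Methods

## Model

The observable is a tensor of base counts n_{v,s,a} at V candidate
positions across S samples (a indexes A,C,G,T; this alphabetical order is
fixed everywhere). The population is modelled as G strains. Strain g has a
one-hot base assignment τ_{v,g,·} at each position and relative frequency
π_{g,s} in sample s with Σ_g π_{g,s} = 1. Reads are observed through a
position-independent, row-stochastic base transition ("error") matrix
ε_{b,a} = P(observe a | true b). Assuming independence across positions
(read linkage is ignored) and samples, counts at (v, s) are multinomial
with base probabilities Σ_g Σ_b τ_{v,g,b} π_{g,s} ε_{b,a}.

Priors are conjugate and deliberately weak: symmetric Dirichlet(α) on each
π column, Dirichlet(δ) on each ε row, uniform over the four bases for each
τ_{v,g}. α and δ are not pinned down by the underlying study; we default to
α = 1.0 (uniform on the simplex) and δ = 0.1 (weakly favouring small error
rates, since ε rows should be near-delta) and expose both.

### Variant detection

Haplotype inference is only attempted at positions that are confidently
polymorphic. Working with sample-aggregated counts t_a (aggregation costs
little power at realistic depths and keeps the scan cheap), the null of a
single true base — whose maximum-likelihood value is the consensus
m0 = argmax t_a, ties to the lower base index — is tested against a
two-base alternative with secondary base m1 and consensus frequency p:

    log H1(p) = Σ_a t_a log(p ε_{m0,a} + (1 − p) ε_{m1,a}).

p is maximised over [0.5, 1 − p_min]. The lower end follows from m0 being
the consensus; an optimum pinned at a boundary yields a statistic clamped
to 0. The objective is concave in p, so the bounded maximisation is done
with a vectorised golden-section search to |interval| < 1e-6. The
statistic −2 log(H0/H1) is referred to the χ²(1) upper tail (the
multinomial coefficient cancels in the ratio and is omitted from both).
p_min defaults to 0.01; 0.03 is the conservative choice for noisy real
data. A "fast" mode replaces the optimisation with p̂ = t_{m0}/T (clipped
to the interval) for screening large gene sets.

ε is unknown a priori. Starting from a rough seed (diagonal 0.99,
off-diagonal 0.01/3), positions are classified with a Benjamini–Hochberg
cut (default FDR 1e-3; rejection is q < cutoff, strict), ε is re-estimated
as the row-normalised base-transition counts over non-variant positions
(consensus = true base) with a pseudocount of 1 per cell to keep all
entries positive, and the loop repeats until the variant set and ε are
unchanged (cap 20 iterations, warning on non-convergence). In simulations
with ε diagonal 0.995 and aggregate depth ~500 this converges in 3–4
iterations and recovers off-diagonal rates to within a few percent.

### Core-gene coverage filter

Single-copy core genes must share one coverage profile; genes recruiting
reads from unassembled relatives are flagged per sample when their
absolute deviation from the per-sample median coverage exceeds t (default
2.5) times the median of those deviations, and a gene is kept only if
unflagged in at least a fraction f (default 0.8) of samples. Removal is
global: a failing gene is dropped for all samples. When the median
deviation is zero, any nonzero deviation is flagged — identical-coverage
cores should agree exactly; an absolute floor could be added if this
over-flags on real data. Medians of even-length vectors are the mean of
the central pair. Samples whose mean core coverage is ≤ 5 (strict >)
can be dropped before inference.

### Gibbs sampler

One iteration is:

1. τ sweep — positions are conditionally independent given (π, ε), so for
   each strain in fixed ascending order, the 4-state conditionals of all
   positions are sampled as a block (log-space, normalised explicitly).
2. ν | τ, π, ε — each observed count n_{v,s,a} is allocated to true bases
   b by a multinomial with weights ∝ Σ_g τ_{v,g,b} π_{g,s} ε_{b,a}; then
   ε rows are sampled from Dir(ν_{·,·,a,b} + δ).
3. ξ | ν — allocations are further split over strains with weights
   ∝ τ_{v,g,b} π_{g,s} (ε cancels within fixed b); then π columns are
   sampled from Dir(ξ_{·,s,·,·,g} + α).

Conservation (Σ_b ν = n, Σ_g ξ = ν) and normalisation (π columns, ε rows,
one-hot τ) hold exactly at every sweep and are asserted in tests. Default
protocol is 100 burn-in + 100 stored samples; replicates (default 5) use
seed + replicate index. Summaries: posterior means, the maximum-posterior
sample, and discretised τ (argmax of the posterior mean one-hot, ties to
the lower base index).

### NTF initialisation

The sampler starts from a rank-G non-negative factorisation of the
per-position base proportions p_{v,s,a} = n_{v,s,a}/n_{v,s,·}, stacked as
a 4V×S matrix and fitted with the multiplicative updates that minimise the
generalised Kullback–Leibler divergence, interleaved with renormalisation
of τ′ over bases per (position, strain) and of π per sample. Iteration
stops when the divergence reduction falls below 1e-5. The updates run on
the stacked *proportion* matrix: that is the matrix whose divergence the
objective measures. The divergence trace is non-increasing in practice and
asserted so (tolerance 1e-8) in tests. Discretised τ′ (per-position
argmax) and π seed the sampler.

### Scaling to many positions and the fixed-π τ fit

π and ε are estimated accurately from a random subset of variants (default
1,000, seeded). Bases at all positions are then assigned by τ-only Gibbs
updates iterating through the stored (π_t, ε_t). The τ state for this pass
is initialised by running only the τ′ multiplicative update with π fixed
at the chain's posterior mean — this keeps strain labels aligned with the
chain and, importantly, avoids starting every strain at the aggregate
consensus: with realistic error rates the τ conditionals are
near-deterministic, and a consensus start can lock minority-base strains
into a wrong mode that single-site moves cannot leave.

### Choosing the strain number

For G = 1..G_max (replicates each), the posterior mean deviance
D = mean_t −2 log L(N | π_t, τ_t, ε_t) (multinomial coefficients included)
is averaged over replicates. The upper limit G_U is G − 1 at the first G
whose relative drop (E[D_{G−1}] − E[D_G])/E[D_{G−1}] falls below d
(default 5%), else G_max. Haplotype reproducibility is measured as mean
SNV uncertainty: the Hamming fraction to the closest match in each
replicate (non-exclusive nearest neighbour, as the quantity is defined),
averaged over replicates. Among G ≤ G_U, the selected G maximises the
count of haplotypes with uncertainty < 10% and mean relative abundance
> 5% (smallest G on ties). Deconvolution is only attempted with ≥ 5
variants.

### Gene presence/absence

With π̂ and ε̂ fixed at their core-run posterior means, per-sample strain
coverages are γ_{g,s} = π_{g,s} Y_s, where Y_s is total core-gene bases
over total core length. Gene coverage is modelled as
x_{f,s} ~ Pois(λ_{f,s} = Σ_g η_{f,g} γ_{g,s}) — each carrying strain
contributes an independent Poisson, and the superposition is Poisson —
with Γ(x+1) for the continuous coverage values. Variant counts at up to 20
randomly retained positions per gene follow the multinomial model with π̂
renormalised to the carrier set. η is binary (multi-copy genes are out of
scope; a geometric prior reduces to a presence/absence odds parameter,
default 1.0 = flat, exposed). The likelihood is treated as separable in
coverage and variants; no correction is made for variant positions also
contributing to mean coverage.

Sampling sweeps genes × strains: for each (f, g), η = 0 and η = 1 are
scored with the strain's bases marginalised analytically per position
(positions are conditionally independent; uniform prior contributes
−log 4 per position as the Occam penalty), η is drawn from the two-state
conditional, and τ is then sampled per position for present strains. An
all-absent proposal for a gene with nonzero coverage is admissible but
scored with λ floored at machine epsilon, and reads without any carrier
are penalised at 1e-16 per read. Initialisation is the single-sided
multiplicative NMF update of the coverage model (γ fixed), rounded to
{0,1}; before η sampling begins, 10 τ-only warm-up sweeps (η frozen) let
the base assignments equilibrate — without this the consensus-initialised
τ misleads the first high-depth η conditionals and the sampler can lock
into a confidently wrong joint mode. Default protocol: 20 burn-in + 20
stored sweeps; the final call rounds the posterior mean at 0.5; τ is
reported only for carrying strains.

### Genome divergence

Strains are summarised as gene-cluster frequency vectors υ_{g,c} (counts,
which reduce to presence for single-copy genes) and compared with
d = 1 − Σ min/Σ max. The bundled clustering helper is a greedy,
input-order-dependent, equal-length identity clusterer intended for
synthetic genes; real analyses should supply externally computed
gene → cluster tables.

## Simulator

The generator emulates, at the base-count level, the statistical structure
the inference assumes: species log-abundances y_{t,s} ~ N(μ_t, σ_t) with
μ_t ~ N(1, 0.25) and σ_t ~ Gamma(1, 1), softmax-normalised per sample;
strain proportions ρ ~ Dir(1) within species; strain coverage
z = R κ N_s / L with read length R = 150 (one mate of a 2×150 bp pair;
pairs count as two reads), reads per sample N_s = 6.25 × 10⁶ and genome
length L; variant counts multinomial under (τ, π, ε) with Poisson depths;
gene coverages Poisson superpositions; gene variants from the
carrier-renormalised multinomial. It does not emulate read-level effects:
mapping error, chimeric contigs, indels, position-dependent error
profiles, or strand bias. Passing tests therefore demonstrate correctness
of the inference given its model, and an upper bound on real-data
performance, not robustness to upstream artefacts.

## Experiment sizes and numerical choices

The bundled accuracy experiments use: variant detection at 50,000
invariant + 6,000 variant positions (minor fraction ≥ 0.05), 5 strains,
64 samples, ε diagonal 0.995, aggregate depth ≈ 512; deconvolution at
V = 200, S = 32, G = 5 with per-site depth 50; frequency recovery on the
same design with depth 400 — the scaled-down tensor needs the higher depth
for the π̂ posterior to be tight enough for a meaningful regression — and
gene assignment at 1,000 genes × 5 strains × 64 samples with presence
probability 0.7. Accuracy metrics are computed after optimal haplotype
label matching (Hungarian assignment on Hamming fractions).

Numerics: all likelihoods in log space with log-sum-exp; mixture
probabilities floored at 1e-300 before logs; LR statistics clamped at 0
with p-value 1; argmax ties always to the lowest base index; medians of
even vectors as the central-pair mean; golden-section tolerance 1e-6;
NTF/NMF convergence tolerances 1e-5 on the KL objective.

## Known limitations

* No read linkage: haplotypes are resolved only through frequency
  covariation across samples; a single sample carries no linkage signal
  and ≥ ~15–30 samples are realistically needed.
* Label switching within a chain is not corrected (only across runs, by
  matching); very similar strains can merge or swap.
* High-depth τ conditionals are near-deterministic, so mixing across
  symmetric modes is slow; point estimates are good but posterior spread
  for τ at high depth is understated.
* Gene copy numbers are restricted to {0, 1}.
* The identity clusterer never merges unequal-length sequences; it exists
  to exercise the divergence measure on synthetic data.
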