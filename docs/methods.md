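# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, the numerical machinery, and what the
synthetic-data tests do and do not establish.

## State space

A lineage state is a pair (biome category, region set): biome ∈ {alpine,
non-alpine, both}, regions a nonempty subset of {Americas, Asia, Caucasus,
Europe, Arctic}. The Arctic is ecologically merged with the alpine zone,
so any state combining Arctic occupancy with the non-alpine biome is
excluded from enumeration and rejected at validation, with the offending
species named. The full 5-region space has 3·31 − 16 = 77 states;
`enumerate_states` orders states deterministically (biome, range size,
lexicographic region indices) so indices are stable across runs. The
default maximum range size is 2 — multi-region species exist in the data,
but wide ranges inflate the state space quadratically and contribute
little likelihood mass; a flag raises it to 5.

The "both" category is a genuine generalist state with its own rates, not
an ambiguity code; tip states are taken as known (expert assignments),
with no tip-state uncertainty model.

## ClaSSE model

Anagenetic moves are single events: one biome step along
non-alpine ↔ both ↔ alpine preserving regions (rates q_NB, q_BN, q_BA,
q_AB), one region gained at rate d per reachable region (Arctic is
unreachable for non-alpine lineages), or one region lost at rate e
(ranges stay nonempty). Direct alpine ↔ non-alpine jumps are disallowed:
an upslope shift is by construction a generalist-to-alpine transition,
which is the quantity being measured; allowing direct jumps would route
flow around it.

Cladogenesis at biome-specific rate λ: for single-region parents all mass
is sympatric (both daughters inherit the parent state); for wider ranges
the mode weights (w_sym, w_sub, w_vic) split λ, with the subset-sympatric
mass divided uniformly over the |R| single-region daughters and the
vicariant mass uniformly over the 2^{|R|−1} − 1 unordered range
partitions (a maximum-entropy default; nothing in the data motivates a
non-uniform split). Extinction is biome-specific (μ).

The likelihood is the standard SSE pruning: along each branch

    dE_i/dt = μ_i − (λ_i+μ_i) E_i + (Q E)_i + Σ_w w E_j E_k
    dD_i/dt = −(λ_i+μ_i) D_i + (Q D)_i + Σ_w w (D_j E_k + D_k E_j)

with tip conditions D = ρ·1[observed], E = 1 − ρ; at nodes
D_i = Σ_w (w/2)(D^L_j D^R_k + D^L_k D^R_j); at the root the likelihood is
π·D divided by Σ_i π_i λ_i (1 − E_i)² (conditioning on survival of both
root lineages, standard SSE practice). The root prior π defaults to
uniform over the observed tip states; flat-over-all-states is available.
The default sampling fraction is ρ = 0.62 applied uniformly at the tips —
the study's global sampling fraction, reused here for the SSE likelihood
and overridable everywhere.

Numerics: the reference integrator is LSODA per branch at rtol 1e-8 /
atol 1e-10 with per-branch renormalisation of D (log factors
accumulated); E is asserted to stay in [0,1]. A second path integrates
all branches of a postorder "wave" simultaneously with fixed-grid RK4
(default 10 steps/branch, vectorised across branches), which agrees with
the adaptive path to ~1e-3 log-units on 100-tip trees and is what the
MCMC uses; proposals that overflow the integrator are rejected with
log-posterior −∞.

## MCMC

Single-component Metropolis–Hastings: log-scale Gaussian random walks on
each free rate, and a symmetric logit-space walk for the cladogenetic
weight simplex (flat simplex prior; the softmax Jacobian enters the
acceptance ratio). Priors are exponential(rate 10) on every rate — weakly
informative on the events/lineage/Myr scale, concentrating prior mass
below 0.5/Myr. Proposal scales adapt toward ~30% acceptance during
burn-in only (30% of the chain), so the post-burn-in kernel is fixed and
valid. Chains are reproducible from a seed; a prior-only mode (likelihood
switched off) is used to verify the sampler reproduces prior moments.

## Stochastic mapping

Node states are sampled root-ward: the root from π·D, each daughter pair
from the cladogenetic tensor weighted by the daughters' branch-top D
vectors, and each branch-bottom state from exp(Q t)[top,·] weighted by the
subtree D vector. Within a branch, histories are endpoint-conditioned
pure-CTMC paths: rejection sampling from the top state (50 attempts),
falling back to exact uniformization (Poissonised jump count, backward
R-power weighting, uniform order-statistic times, virtual jumps dropped).

Approximation: drawing node and branch-bottom states through exp(Q t)
ignores the state-dependent survival/speciation weighting that acts along
branch interiors. When diversification is biome-independent the scheme is
exact; with strongly state-dependent λ it slightly biases deep-time state
occupancy (visible as a mild tilt in occupancy-normalised rate series).
Tip states are reproduced exactly by construction, and event-count
calibration on single branches is exact.

## Shift rates through time

Events are classified from maps: upslope = anagenetic both → alpine;
mountain hop = anagenetic dispersal on a lineage whose state at the event
time is alpine; everything else "other". Cladogenetic range inheritance
is never counted as a hop ("immigration" is read as anagenetic movement).
Default windows >15 / 15–10 / 10–5 / 5–0 Ma; an event exactly on a
boundary belongs to the younger window. The default normalisation divides
window counts by window duration (events/Myr; whole-tree rates divide by
the root age). Because lineage number grows toward the present, this
normalisation rises toward the present even under constant per-lineage
rates; two alternatives are provided — per lineage-Myr, and per
source-biome lineage-Myr (counts divided by the occupancy time of the
event's source category), the latter being flat in expectation under a
time-homogeneous process and therefore the right scale for testing
whether a recency signal is real.

## Penalized-likelihood dating

Substitution lengths become counts x_i = round(len_i · L) with L the
effective alignment length (default 100,000, the order of a concatenated
target-capture alignment); the objective is the Poisson log-likelihood
plus κ times a roughness penalty (squared differences between each branch
rate and its parent's, plus the variance of the root's child rates).
Because the penalty is on absolute rate differences, the κ value at which
rates effectively collapse to a clock depends on the count scale (roughly
κ ≫ x/r²); the κ → ∞ checks in the test suite use instances scaled
accordingly.

Optimisation parameterises each internal node age as a proportion of its
feasible interval — between its propagated minimum bound (node minima are
pushed root-ward, maxima tip-ward, infeasibility detected up front) and
its parent's current age — so every iterate satisfies the calibrations
and the age ordering. A joint L-BFGS-B pass over (root age, proportions,
log rates) is followed by alternating refinement: the rate block given
ages (analytic gradient) and the age block given rates, iterated to a
1e-9 relative tolerance. Identifiability requires a root maximum
constraint or a fixed root age.

Cross-validation is leave-one-terminal-out and deterministic: for each κ
each terminal is pruned, the model refit, and the terminal's count
predicted as r̂·t̂·L from the pruned-tree branch spanning the attachment
point. The attachment age is not estimable from the pruned tree, so t̂ is
taken as the midpoint age of that branch — deterministic and unbiased to
first order; the induced per-terminal bias is common to all κ and cancels
in the comparison. Score is Σ (x_pred − x_obs)²/x_pred; ties prefer the
smallest κ (least smoothing assumed). Terminals attached directly to the
root are skipped (no spanning branch exists after pruning).

## Congruence branch lengths and gene shopping

Both trees are restricted to their shared taxa (pruning-induced degree-2
nodes suppressed, lengths summed; at least 4 shared taxa or the locus is
skipped with a warning). A species-tree branch matches a gene-tree branch
iff both the descendant and the parent restricted clade tip-sets are
identical; branches incident to the root compare descendant clades only,
both parent clades being the full shared set. Matched lengths are pooled
over loci and averaged unweighted (a mean of all stored lengths, not of
per-locus means). Zero-match branches get a missing value, are listed in
the coverage report, and are imputed — mean of adjacent matched branches,
swept until closure and logged — only when a downstream stage needs a
complete tree.

The congruence score of a locus is the fraction of species-tree internal
(non-root) nodes whose restricted clade appears in the restricted gene
tree — for identical taxon sets this is 1 minus the normalized rooted RF
distance; the metric is a plug-in point. Gene shopping takes the shortest
prefix of the ranking (ties broken by locus id) covering every taxon at
least k times and errors, naming the taxa, when coverage is impossible.

## Locus filters

Length means ungapped base count ('-' and 'N' excluded), the only
definition valid both before and after alignment; both characters count
as missing for the site filter (the conservative reading). Boundaries are
strict: "fewer than 300" drops 299 and keeps 300; "more than 95%" keeps a
column at exactly 95%. The relative filter's threshold is 40% of the
median of the *input* set (even n: mean of the central pair), applied in
a single pass; because removal can raise the median, a second application
is not guaranteed to be a no-op in pathological length distributions.

## Synthetic data

The forward simulator is an exact Gillespie realisation of the model
above: exponential waiting times with the summed per-lineage rate,
cladogenetic daughters drawn from the event tensor, extinct and unsampled
lineages pruned from the returned tree (the full event history is kept),
tips subsampled at ρ. Stopping is by extant count or by forward time; the
time-inhomogeneous mode multiplies chosen rates inside age-defined epochs
(e.g. q_BA × 5 for ages < 5 Ma) and therefore requires the time stop
rule. Under the count rule the final time is advanced by one further
exponential waiting time so terminal branches have nonzero length.

MSC gene trees use a built-in coalescent: one sample per species,
pairwise coalescence at rate 1/θ within each species-tree branch, forced
coalescence above the root; θ → 0 reproduces the species tree exactly,
large θ produces deep coalescence with symmetric minor topologies.
Branch lengths are converted to substitutions/site by a global rate times
per-locus lognormal multipliers. What this emulates: topological
discordance from incomplete lineage sorting and rate variation among
loci. What it does not: gene-tree estimation error, missing data,
alignment error, gene flow, or paralogy — so passing recovery tests show
correctness of the estimators under the model, not robustness to those
real-data pathologies.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to finish on one CPU:
likelihood-oracle agreement on 20 random 4-tip trees; speciation-rate
ordering recovery (generalist rate 4× the alpine rate) on 120-tip trees
with 1,800-iteration chains over 5 seeds, requiring the correct ordering
in ≥ 4/5; the recency signal (q_BA × 5 inside 5–0 Ma) on a ~300-tip
simulated clade with 200 stochastic maps; map calibration with 10,000
single-branch histories; dating recovery on 12-tip clock-like data with
L = 2×10⁶ sites. Full-scale analyses (hundreds of tips, 10⁵+ MCMC
iterations, the 77-state space) use the same code paths and simply take
longer.

## Known limitations

- The stochastic-mapping node-state approximation described above.
- The MCMC is a plain single-component sampler; for the 77-state space
  with many free rates it mixes slowly and long chains are needed.
- Penalized-likelihood dating reports point estimates only (no
  confidence intervals); the optimizer is local, with one deterministic
  initialisation from depth-proportional ages.
- The cross-validation attachment-age convention (midpoint) is one of
  several defensible choices; alternatives shift all κ scores equally on
  clock-like data but could matter under extreme rate variation.
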