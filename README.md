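# saxshift

Tools for quantifying how alpine plant diversity assembles across mountain
regions, built around the macroevolution of *Saxifraga*-like clades: do
alpine specialists arise by **upslope biome shifts** (generalists adapting
into the alpine zone), by **mountain hopping** (alpine specialists
dispersing between regions), or by in-situ alpine speciation — and how have
those rates changed through time?

The package is a library first (importable API plus the narrative scripts
in `examples/`), with a thin `saxshift` command-line wrapper for running
the stages as a pipeline.

## What it implements

1. **Locus cleaning filters** (`saxshift.filters`) — the per-locus rules
   used before and after alignment of target-capture exons: drop sequences
   of fewer than 300 ungapped bases, drop sequences shorter than 40% of the
   locus median, and strip alignment columns in which more than 95% of
   taxa carry no information.

2. **Congruence-aware branch lengths and gene shopping**
   (`saxshift.congruence`) — gene-tree/species-tree discordance corrupts
   molecular branch lengths estimated on a fixed species-tree topology.
   `branchwise_lengths` matches every gene-tree branch whose descendant
   *and* parent clades (after restriction to shared taxa) coincide with a
   species-tree branch, and averages the matched lengths.
   `congruence_rank`/`gene_shop` instead rank loci by the fraction of
   shared species-tree nodes and select loci down the ranking until every
   taxon is covered k times (default k = 2).

3. **Penalized-likelihood dating** (`saxshift.dating`) — node ages and
   per-branch substitution rates r_i maximise a Poisson likelihood on
   branch substitution counts x_i ≈ round(len_i · L) plus a roughness
   penalty,

   log L = Σ_i [ x_i log(r_i t_i L) − r_i t_i L − log x_i! ]
           − κ [ Σ_i (r_i − r_parent(i))² + Var(root-child rates) ],

   subject to min/max fossil calibrations; the smoothing κ is chosen by
   leave-one-terminal-out cross-validation.

4. **Joint biome×region ClaSSE model** (`saxshift.states`,
   `saxshift.classe`) — lineages occupy a nonempty subset of five regions
   (Americas, Asia, Caucasus, Europe, Arctic) and one of three biome
   categories (alpine, non-alpine, generalist "both"); "Arctic non-alpine"
   states are excluded (the Arctic is treated as alpine-equivalent). The
   full 5-region space has 77 states. Anagenetic events are biome shifts
   along non-alpine ↔ both ↔ alpine, dispersal (rate d per gainable
   region) and extirpation (rate e); speciation is sympatric,
   subset-sympatric or vicariant with simplex weights, at biome-specific
   rates λ. The likelihood is the standard SSE pruning (per-state E/D
   ODEs along branches, cladogenetic combination at nodes, survival
   conditioning at the root), rates are estimated by Metropolis–Hastings
   MCMC with exponential(10) priors, and full histories are drawn by
   stochastic character mapping.

5. **Shift rates through time** (`saxshift.rates`) — stochastic-map events
   are classified as upslope shifts (both → alpine), mountain hops
   (dispersal while alpine) or other, counted in time windows
   (default >15, 15–10, 10–5, 5–0 Ma) and divided by window duration to
   give posterior rate distributions.

6. **Synthetic data with known truth** (`saxshift.simulate`) — exact
   Gillespie forward simulation of the ClaSSE process (optionally
   time-inhomogeneous, e.g. a five-fold upslope rate in the last 5 Myr),
   multispecies-coalescent gene trees around a dated species tree, and
   valid assignment tables.

## Worked example

```bash
python examples/shift_rates_through_time.py
```

prints (simulating a clade whose upslope shift rate was boosted five-fold
inside the last 5 Myr, then inferring histories by stochastic mapping):

```
simulated clade: 325 tips, root age 18.5 Ma
posterior mean rates (events/Myr):
  window   upslope   hopping
     >15      0.23      0.01
   15-10      0.84      0.18
    10-5      2.55      0.84
     5-0     12.28      3.04
fraction of maps with 5-0 Ma upslope rate above the >15 Ma rate: 1.00
whole-tree upslope / hopping rate ratio: 3.9
```

The rate table is the package's core output: events per Myr for each
process in each time slice, averaged over 200 sampled histories. Here the
inferred upslope-shift rate rises steeply toward the present — the
generating signal — and upslope shifts outnumber inter-regional hops
overall. The other scripts in `examples/` demonstrate locus filtering,
congruence branch lengths and gene shopping, calibrated dating, and the
ClaSSE MCMC fit.

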