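"""Synthetic-data generators with known truth for every analysis stage.

* :func:`simulate_classe_tree` — exact event-driven (Gillespie) forward
  simulation of the joint biome-by-region ClaSSE process, optionally
  time-inhomogeneous (per-epoch rate multipliers, e.g. a five-fold upslope
  shift rate in the last 5 Myr), returning the reconstructed tree, tip
  states, and the full event history.
* :func:`simulate_gene_trees` — multispecies-coalescent gene trees around
  a dated species tree (one sample per species); deeper coalescence with a
  larger population scale produces topological discordance, and per-locus
  lognormal rate multipliers convert time to substitutions/site.
* :func:`make_assignment_table` / :func:`random_assignment_table` —
  assignment tables that round-trip losslessly through the loader and obey
  the Arctic constraint.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classe import ClasseGenerator, ClasseParams, build_generator
from .states import Biome, BiomeRegionState, REGIONS, AssignmentTable, StateSpace
from .trees import Node, PhyloTree

__all__ = [
    "SimConfig",
    "Epoch",
    "SimResult",
    "simulate_classe_tree",
    "simulate_gene_trees",
    "make_assignment_table",
    "random_assignment_table",
]


@dataclass(frozen=True)
class Epoch:
    """Rate multipliers active for event ages in (age_older, age_younger]."""

    age_older: float
    age_younger: float
    multipliers: dict

    def __post_init__(self) -> None:
        if self.age_older <= self.age_younger:
            raise ValueError("epoch must have age_older > age_younger")


@dataclass
class SimConfig:
    """Forward-simulation settings.

    Exactly one stop rule applies: ``n_tips`` (extant lineage count) or
    ``max_time`` (Myr of forward time; required when epochs are used, since
    epoch boundaries are expressed as ages).  ``rho`` subsamples extant
    tips.  MSC settings: ``pop_scale`` (coalescent time scale within
    species branches, Myr), ``n_loci``, and the lognormal sd of per-locus
    substitution-rate multipliers around ``subs_rate``.
    """

    params: ClasseParams = field(default_factory=ClasseParams)
    root_state: BiomeRegionState | None = None
    n_tips: int | None = None
    max_time: float | None = None
    seed: int = 0
    rho: float = 1.0
    epochs: tuple[Epoch, ...] = ()
    max_retries: int = 100
    pop_scale: float = 0.5
    n_loci: int = 10
    subs_rate: float = 0.01
    rate_sd: float = 0.3

    def __post_init__(self) -> None:
        if (self.n_tips is None) == (self.max_time is None):
            raise ValueError("exactly one of n_tips/max_time must be set")
        if self.n_tips is not None and self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.max_time is not None and self.max_time <= 0:
            raise ValueError("max_time must be positive")
        if self.epochs and self.max_time is None:
            raise ValueError("epochs (age-based) require a max_time stop rule")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")


@dataclass
class SimEvent:
    age: float
    lineage: int
    kind: str          # biome_shift | dispersal | extirpation |
    #                    speciation | extinction
    detail: tuple
    state_before: int
    state_after: int


@dataclass
class SimResult:
    """Forward-simulation output: reconstructed tree (extinct and
    unsampled lineages removed), tip states, and the complete history."""

    tree: PhyloTree | None
    tip_states: dict[str, int]
    space: StateSpace
    events: list[SimEvent]
    n_total_tips: int
    n_extinct: int
    origin_age: float


class _Lineage:
    __slots__ = ("node", "state", "id")

    def __init__(self, node: Node, state: int, lid: int) -> None:
        self.node = node
        self.state = state
        self.id = lid


def _epoch_generators(space: StateSpace, cfg: SimConfig
                      ) -> list[tuple[float, float, ClasseGenerator]]:
    """(forward start, forward end, generator) pieces covering [0, T]."""
    T = cfg.max_time
    if not cfg.epochs:
        return [(0.0, math.inf, build_generator(space, cfg.params))]
    cuts = sorted({0.0, T} | {T - e.age_older for e in cfg.epochs}
                  | {T - e.age_younger for e in cfg.epochs})
    cuts = [c for c in cuts if 0.0 <= c <= T]
    pieces = []
    for lo, hi in zip(cuts, cuts[1:]):
        mid_age = T - 0.5 * (lo + hi)
        p = cfg.params
        for ep in cfg.epochs:
            if ep.age_younger < mid_age <= ep.age_older:
                p = p.scaled(ep.multipliers)
        pieces.append((lo, hi, build_generator(space, p)))
    pieces[-1] = (pieces[-1][0], math.inf, pieces[-1][2])
    return pieces


def simulate_classe_tree(space: StateSpace, cfg: SimConfig) -> SimResult:
    """Forward Gillespie realisation of the ClaSSE process.

    Waiting times are exponential with total rate summed over lineages
    (speciation + extinction + anagenetic out-rate, capped at epoch
    boundaries under time-inhomogeneity); cladogenesis draws an unordered
    daughter-state pair from the event tensor.  The reconstructed tree
    drops extinct and unsampled lineages (with unifurcations suppressed);
    tips are subsampled with probability ``rho``.  Retries on total
    extinction up to ``cfg.max_retries``.
    """
    rng = np.random.default_rng(cfg.seed)
    for attempt in range(cfg.max_retries):
        result = _simulate_once(space, cfg, rng)
        if result is not None:
            return result
    raise RuntimeError(
        f"total extinction in {cfg.max_retries} consecutive attempts")


def _simulate_once(space, cfg, rng):
    if cfg.root_state is None:
        root_state = BiomeRegionState(Biome.BOTH,
                                      frozenset([space.regions[0]]))
    else:
        root_state = cfg.root_state
    root_idx = space.index_of(root_state)

    pieces = _epoch_generators(space, cfg)
    piece_i = 0
    gen = pieces[0][2]

    root_node = Node()
    lineages: list[_Lineage] = [_Lineage(root_node, root_idx, 0)]
    next_id = 1
    start_times: dict[int, float] = {id(root_node): 0.0}
    events_fwd: list[tuple] = []   # (t, lineage id, kind, detail, s0, s1)
    t = 0.0
    n_extinct = 0

    def total_rate():
        return sum(gen.lam[ln.state] + gen.mu[ln.state]
                   - gen.Q[ln.state, ln.state] for ln in lineages)

    while lineages:
        if cfg.n_tips is not None and len(lineages) >= cfg.n_tips:
            # advance to just before the next event so terminal branches
            # have nonzero length
            rate = total_rate()
            if rate > 0:
                t += rng.exponential(1.0 / rate)
            break
        rate = total_rate()
        if rate <= 0:
            t = cfg.max_time if cfg.max_time is not None else t
            break
        dt = rng.exponential(1.0 / rate)
        t_next = t + dt
        piece_end = pieces[piece_i][1]
        if t_next >= piece_end:
            t = piece_end
            piece_i += 1
            gen = pieces[piece_i][2]
            continue
        if cfg.max_time is not None and t_next >= cfg.max_time:
            t = cfg.max_time
            break
        t = t_next
        # pick lineage proportional to its total rate
        weights = np.array([gen.lam[ln.state] + gen.mu[ln.state]
                            - gen.Q[ln.state, ln.state] for ln in lineages])
        ln = lineages[int(rng.choice(len(lineages), p=weights / weights.sum()))]
        s = ln.state
        lam, mu = gen.lam[s], gen.mu[s]
        q_out = -gen.Q[s, s]
        u = rng.random() * (lam + mu + q_out)
        if u < lam:                                   # speciation
            opts = gen.clado_by_state[s]
            w = np.array([o[2] for o in opts])
            j, k, _, mode = opts[int(rng.choice(len(opts), p=w / w.sum()))]
            if rng.random() < 0.5:
                j, k = k, j
            ln.node.length = t - start_times[id(ln.node)]
            cj, ck = Node(), Node()
            ln.node.add_child(cj)
            ln.node.add_child(ck)
            start_times[id(cj)] = t
            start_times[id(ck)] = t
            events_fwd.append((t, ln.id, "speciation", (mode,), s, (j, k)))
            lineages.remove(ln)
            lineages.append(_Lineage(cj, j, next_id))
            lineages.append(_Lineage(ck, k, next_id + 1))
            next_id += 2
        elif u < lam + mu:                            # extinction
            ln.node.length = t - start_times[id(ln.node)]
            ln.node.label = f"extinct_{ln.id}"
            events_fwd.append((t, ln.id, "extinction", (), s, s))
            lineages.remove(ln)
            n_extinct += 1
        else:                                         # anagenetic move
            probs = gen.Q[s].copy()
            probs[s] = 0.0
            nxt = int(rng.choice(len(probs), p=probs / probs.sum()))
            kind_info = gen.move_kind[(s, nxt)]
            events_fwd.append((t, ln.id, kind_info[0],
                               tuple(kind_info[1:]), s, nxt))
            ln.state = nxt

    if not lineages:
        return None
    T = t
    # close surviving branches at T and label tips
    tip_states: dict[str, int] = {}
    for ln in lineages:
        ln.node.length = T - start_times[id(ln.node)]
        ln.node.label = f"t{ln.id}"
        tip_states[ln.node.label] = ln.state

    # subsample extant tips
    keep = [lb for lb in tip_states if rng.random() < cfg.rho]
    events = [SimEvent(age=T - et, lineage=lid, kind=kind, detail=detail,
                       state_before=s0, state_after=s1)
              for (et, lid, kind, detail, s0, s1) in events_fwd]
    can_speciate = any(p[2].lam.max() > 0 for p in pieces)
    if len(keep) < 2:
        if not can_speciate and keep:
            # a non-speciating process yields a single-lineage history
            return SimResult(tree=None,
                             tip_states={k: tip_states[k] for k in keep},
                             space=space, events=events,
                             n_total_tips=len(tip_states) + n_extinct,
                             n_extinct=n_extinct, origin_age=T)
        return None

    full = PhyloTree(root_node, units="myr")
    recon = full.pruned_to(keep)
    if recon.n_tips() < 2:
        return None
    recon.set_ages_from_lengths()
    return SimResult(tree=recon,
                     tip_states={k: tip_states[k] for k in recon.taxa},
                     space=space, events=events,
                     n_total_tips=len(tip_states) + n_extinct,
                     n_extinct=n_extinct, origin_age=T)


# ---------------------------------------------------------------------------
# Multispecies coalescent gene trees
# ---------------------------------------------------------------------------

def simulate_gene_trees(species_tree: PhyloTree, cfg: SimConfig
                        ) -> list[PhyloTree]:
    """MSC gene trees with substitution branch lengths.

    One haploid sample per species.  Within each species-tree branch, the
    ``k`` resident gene lineages coalesce at rate ``k(k-1)/2 / pop_scale``;
    lineages entering the species root keep coalescing until one remains.
    ``pop_scale -> 0`` recovers the species-tree topology exactly.  Gene
    branch lengths are time multiplied by ``subs_rate`` times a per-locus
    lognormal factor (sd ``rate_sd`` on the log scale).
    """
    if species_tree.root.age is None:
        species_tree = species_tree.copy()
        species_tree.set_ages_from_lengths()
    rng = np.random.default_rng(cfg.seed)
    out = []
    for _ in range(cfg.n_loci):
        mult = float(np.exp(rng.normal(0.0, cfg.rate_sd)))
        gtree = _msc_one_locus(species_tree, cfg.pop_scale, rng)
        for nd in gtree.nodes:
            if nd is not gtree.root and nd.length is not None:
                nd.length *= cfg.subs_rate * mult
        gtree.units = "subs"
        out.append(gtree)
    return out


def _msc_one_locus(sp: PhyloTree, theta: float, rng) -> PhyloTree:
    # gene lineages per species-tree node, processed tip-to-root by age
    # each gene lineage: (Node, height of its top so far)
    pending: dict[int, list] = {}
    for leaf in sp.leaves():
        nd = Node(leaf.label)
        pending[leaf.id] = [(nd, leaf.age)]

    def coalesce(lins, t_start, t_end):
        """Coalesce within [t_start, t_end] (ages increasing root-ward);
        t_end=inf forces full coalescence."""
        t = t_start
        lins = list(lins)
        while len(lins) > 1:
            k = len(lins)
            if theta <= 0:
                wait = 0.0
            else:
                wait = rng.exponential(theta / (k * (k - 1) / 2.0))
            if t + wait > t_end:
                return lins, t_end
            t += wait
            i, j = rng.choice(k, size=2, replace=False)
            a, ha = lins[i]
            b, hb = lins[j]
            parent = Node()
            a.length = t - ha
            b.length = t - hb
            parent.add_child(a)
            parent.add_child(b)
            lins = [lins[m] for m in range(k) if m not in (i, j)]
            lins.append((parent, t))
        return lins, t

    for nd in sp.postorder():
        if nd.is_leaf:
            continue
        incoming = []
        for ch in nd.children:
            lins, _ = coalesce(pending[ch.id], ch.age, nd.age)
            incoming.extend(lins)
        pending[nd.id] = incoming
    root_lins, _ = coalesce(pending[sp.root.id], sp.root.age, math.inf)
    root_node, _h = root_lins[0]
    root_node.length = None
    tree = PhyloTree(root_node, units="myr")
    return tree


# ---------------------------------------------------------------------------
# Assignment tables
# ---------------------------------------------------------------------------

def make_assignment_table(tip_states: dict[str, int],
                          space: StateSpace) -> AssignmentTable:
    """Assignment table for simulated tip states; round-trips losslessly
    through the loader."""
    rows = []
    for sp_name in sorted(tip_states):
        st = space[tip_states[sp_name]]
        rows.append({"species": sp_name, "regions": st.regions,
                     "biome": st.biome.value})
    return AssignmentTable(pd.DataFrame(rows))


def random_assignment_table(n_alpine: int, n_non_alpine: int, n_both: int,
                            seed: int, max_range: int = 2
                            ) -> AssignmentTable:
    """Random valid assignments with exact biome-category counts.

    Region sets are drawn uniformly among nonempty subsets of size up to
    ``max_range``; Arctic-containing sets are never paired with the
    non-alpine biome.
    """
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for biome, n in ((Biome.ALPINE, n_alpine),
                     (Biome.NON_ALPINE, n_non_alpine),
                     (Biome.BOTH, n_both)):
        pool = [r for r in REGIONS
                if not (biome == Biome.NON_ALPINE and r == "Arctic")]
        for _ in range(n):
            size = int(rng.integers(1, max_range + 1))
            regs = frozenset(rng.choice(pool, size=min(size, len(pool)),
                                        replace=False).tolist())
            rows.append({"species": f"sp{i:04d}", "regions": regs,
                         "biome": biome.value})
            i += 1
    return AssignmentTable(pd.DataFrame(rows))
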