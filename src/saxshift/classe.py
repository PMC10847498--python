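"""ClaSSE diversification model over the joint biome-by-region state space.

The model assigns each lineage a state (biome category, region set) and
couples:

* state-dependent speciation ``lambda`` and extinction ``mu`` by biome
  category (alpine / non-alpine / generalist);
* anagenetic biome shifts along the generalist axis
  (non-alpine <-> both <-> alpine; direct alpine <-> non-alpine jumps are
  disallowed, so an upslope shift is by definition a generalist-to-alpine
  transition);
* anagenetic dispersal (region gained at rate ``d`` per reachable region,
  the Arctic being unreachable for non-alpine lineages) and extirpation
  (region lost at rate ``e``, ranges stay nonempty);
* cladogenetic range inheritance: sympatric (both daughters inherit the
  parent state), subset-sympatric (one daughter keeps the full range, the
  other a single region) and vicariant (the range is split into two
  nonempty parts) speciation, with mode weights on the simplex.  For
  single-region lineages only sympatric speciation is possible and carries
  the full speciation rate.

The likelihood follows the standard SSE pruning construction: per-state
extinction probabilities E and data probabilities D are integrated along
each branch,

    dE_i/dt = mu_i - (lam_i + mu_i) E_i + (Q E)_i + sum_w w E_j E_k
    dD_i/dt =      - (lam_i + mu_i) D_i + (Q D)_i + sum_w w (D_j E_k + D_k E_j)

with tip conditions ``D = rho * 1[observed]``, ``E = 1 - rho``; daughters
are combined at nodes through the cladogenetic tensor and the root is
conditioned on survival of both root lineages.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .states import ARCTIC, Biome, BiomeRegionState, StateSpace
from .trees import Node, PhyloTree

__all__ = [
    "ClasseParams",
    "ClasseGenerator",
    "build_generator",
    "classe_loglik",
    "mcmc_sample",
    "StochasticMap",
    "StochasticMapper",
    "stochastic_map",
    "simulate_ctmc_path",
    "MapEvent",
    "CladoEvent",
    "DEFAULT_RHO",
]

log = logging.getLogger(__name__)

#: Global sampling fraction used by default for empirical analyses.
DEFAULT_RHO = 0.62

#: Default exponential prior rate on all rates (events/lineage/Myr scale).
DEFAULT_PRIOR_RATE = 10.0

RATE_NAMES = (
    "lambda_alpine", "lambda_non_alpine", "lambda_both",
    "mu_alpine", "mu_non_alpine", "mu_both",
    "q_NB", "q_BN", "q_BA", "q_AB",
    "d", "e",
)


@dataclass(frozen=True)
class ClasseParams:
    """Rates of the joint biome-by-region ClaSSE process.

    Speciation/extinction are per biome category (events/lineage/Myr).
    ``q_NB``/``q_BN`` shift between non-alpine and generalist, ``q_BA``
    (the upslope shift rate) and ``q_AB`` between generalist and alpine.
    ``d`` and ``e`` are per-region dispersal and extirpation rates.
    ``w_sym``/``w_sub``/``w_vic`` are cladogenetic mode weights (simplex).
    """

    lambda_alpine: float = 0.1
    lambda_non_alpine: float = 0.1
    lambda_both: float = 0.1
    mu_alpine: float = 0.03
    mu_non_alpine: float = 0.03
    mu_both: float = 0.03
    q_NB: float = 0.05
    q_BN: float = 0.05
    q_BA: float = 0.05
    q_AB: float = 0.05
    d: float = 0.02
    e: float = 0.02
    w_sym: float = 1.0 / 3
    w_sub: float = 1.0 / 3
    w_vic: float = 1.0 / 3

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be nonnegative")
        w = self.w_sym + self.w_sub + self.w_vic
        if not math.isclose(w, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("cladogenetic mode weights must sum to 1")

    def speciation(self, biome: Biome) -> float:
        return {Biome.ALPINE: self.lambda_alpine,
                Biome.NON_ALPINE: self.lambda_non_alpine,
                Biome.BOTH: self.lambda_both}[biome]

    def extinction(self, biome: Biome) -> float:
        return {Biome.ALPINE: self.mu_alpine,
                Biome.NON_ALPINE: self.mu_non_alpine,
                Biome.BOTH: self.mu_both}[biome]

    def with_rates(self, **kw: float) -> "ClasseParams":
        return replace(self, **kw)

    def scaled(self, multipliers: dict[str, float]) -> "ClasseParams":
        """Multiply selected rates (epoch modifiers for simulations)."""
        kw = {k: getattr(self, k) * m for k, m in multipliers.items()}
        return replace(self, **kw)


# Anagenetic biome moves: (from, to, rate-field).  The alpine <-> non-alpine
# axis always passes through the generalist state.
_BIOME_MOVES = (
    (Biome.NON_ALPINE, Biome.BOTH, "q_NB"),
    (Biome.BOTH, Biome.NON_ALPINE, "q_BN"),
    (Biome.BOTH, Biome.ALPINE, "q_BA"),
    (Biome.ALPINE, Biome.BOTH, "q_AB"),
)


class ClasseGenerator:
    """Anagenetic rate matrix Q and cladogenetic event tensor for a state
    space under one parameterisation.

    Cladogenetic events are stored as unordered daughter-state pairs
    ``(i -> {j, k})`` with rate ``w``; row masses sum to the biome
    speciation rate of the parent state.
    """

    def __init__(self, space: StateSpace, params: ClasseParams) -> None:
        self.space = space
        self.params = params
        S = len(space)
        self.S = S
        self.lam = np.array(
            [params.speciation(s.biome) for s in space], dtype=float)
        self.mu = np.array(
            [params.extinction(s.biome) for s in space], dtype=float)

        # ---- anagenetic matrix -----------------------------------------
        Q = np.zeros((S, S))
        self.move_kind: dict[tuple[int, int], tuple] = {}
        for i, st in enumerate(space):
            # biome shifts preserving the region set
            for b_from, b_to, fieldname in _BIOME_MOVES:
                if st.biome != b_from:
                    continue
                try:
                    tgt = BiomeRegionState(b_to, st.regions)
                except ValueError:
                    continue  # e.g. both -> non_alpine with Arctic occupancy
                j = space.index.get(tgt)
                if j is None:
                    continue
                rate = getattr(params, fieldname)
                Q[i, j] += rate
                self.move_kind[(i, j)] = ("biome_shift", b_from.value,
                                          b_to.value)
            # dispersal: gain one region
            if len(st.regions) < space.max_range:
                for r in space.regions:
                    if r in st.regions:
                        continue
                    if r == ARCTIC and st.biome == Biome.NON_ALPINE:
                        continue
                    tgt = BiomeRegionState(st.biome, st.regions | {r})
                    j = space.index.get(tgt)
                    if j is None:
                        continue
                    Q[i, j] += params.d
                    self.move_kind[(i, j)] = ("dispersal", r)
            # extirpation: lose one region, range stays nonempty
            if len(st.regions) > 1:
                for r in st.regions:
                    tgt = BiomeRegionState(st.biome, st.regions - {r})
                    j = space.index.get(tgt)
                    if j is None:  # pragma: no cover - subsets always valid
                        raise RuntimeError("extirpation left the state space")
                    Q[i, j] += params.e
                    self.move_kind[(i, j)] = ("extirpation", r)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        self.Q = Q

        # ---- cladogenetic tensor ---------------------------------------
        ev_i: list[int] = []
        ev_j: list[int] = []
        ev_k: list[int] = []
        ev_w: list[float] = []
        ev_mode: list[str] = []
        for i, st in enumerate(space):
            lam_i = self.lam[i]
            if lam_i == 0:
                continue
            R = st.regions
            if len(R) == 1:
                outcomes = [(i, i, lam_i, "sympatric")]
            else:
                outcomes = [(i, i, params.w_sym * lam_i, "sympatric")]
                # subset-sympatric: one daughter keeps the range, the other
                # a single region
                subs = []
                for r in sorted(R):
                    tgt = space.index_of(
                        BiomeRegionState(st.biome, frozenset([r])))
                    subs.append((i, tgt))
                for (a, b) in subs:
                    outcomes.append(
                        (a, b, params.w_sub * lam_i / len(subs), "subset"))
                # vicariant: unordered partition into two nonempty sets
                regs = sorted(R)
                parts = []
                for size in range(1, len(regs)):
                    for combo in itertools.combinations(regs, size):
                        s1 = frozenset(combo)
                        s2 = R - s1
                        if min(combo) == min(regs):  # each partition once
                            parts.append((s1, s2))
                for s1, s2 in parts:
                    a = space.index_of(BiomeRegionState(st.biome, s1))
                    b = space.index_of(BiomeRegionState(st.biome, s2))
                    outcomes.append(
                        (a, b, params.w_vic * lam_i / len(parts), "vicariant"))
            for a, b, w, mode in outcomes:
                if w == 0:
                    continue
                ev_i.append(i)
                ev_j.append(min(a, b))
                ev_k.append(max(a, b))
                ev_w.append(w)
                ev_mode.append(mode)
        self.ev_i = np.array(ev_i, dtype=int)
        self.ev_j = np.array(ev_j, dtype=int)
        self.ev_k = np.array(ev_k, dtype=int)
        self.ev_w = np.array(ev_w, dtype=float)
        self.ev_mode = ev_mode
        # scatter matrix: (n_events, S), column = parent state
        P = np.zeros((len(ev_i), S))
        P[np.arange(len(ev_i)), self.ev_i] = 1.0
        self._scatter = P

        row_mass = ev_row_mass = (self.ev_w[:, None] * P).sum(axis=0)
        if not np.allclose(ev_row_mass, self.lam, atol=1e-10):
            raise RuntimeError("cladogenetic row masses != speciation rates")

        # per-state event lists for forward simulation / node sampling
        self.clado_by_state: list[list[tuple[int, int, float, str]]] = [
            [] for _ in range(S)]
        for m in range(len(self.ev_w)):
            self.clado_by_state[self.ev_i[m]].append(
                (self.ev_j[m], self.ev_k[m], self.ev_w[m], self.ev_mode[m]))
        self.anag_by_state: list[list[tuple[int, float]]] = [
            [(j, Q[i, j]) for j in range(S) if j != i and Q[i, j] > 0]
            for i in range(S)]

    # -- ODE right-hand sides (vectorised over a leading batch axis) -----

    def _EE(self, E: np.ndarray) -> np.ndarray:
        contrib = self.ev_w * E[..., self.ev_j] * E[..., self.ev_k]
        return contrib @ self._scatter

    def _DE(self, D: np.ndarray, E: np.ndarray) -> np.ndarray:
        contrib = self.ev_w * (D[..., self.ev_j] * E[..., self.ev_k]
                               + D[..., self.ev_k] * E[..., self.ev_j])
        return contrib @ self._scatter

    def combine(self, DL: np.ndarray, DR: np.ndarray) -> np.ndarray:
        """Cladogenetic node update: D_i = sum_w w/2 (DLj DRk + DLk DRj)."""
        contrib = 0.5 * self.ev_w * (DL[..., self.ev_j] * DR[..., self.ev_k]
                                     + DL[..., self.ev_k] * DR[..., self.ev_j])
        return contrib @ self._scatter

    def rhs(self, E: np.ndarray, D: np.ndarray):
        loss = self.lam + self.mu
        dE = self.mu - loss * E + E @ self.Q.T + self._EE(E)
        dD = -loss * D + D @ self.Q.T + self._DE(D, E)
        return dE, dD


def build_generator(space: StateSpace, params: ClasseParams) -> ClasseGenerator:
    """Construct Q and the cladogenetic tensor; row sums are verified."""
    return ClasseGenerator(space, params)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _root_prior(gen: ClasseGenerator, tip_states: dict[str, int],
                pi) -> np.ndarray:
    if isinstance(pi, np.ndarray):
        v = np.asarray(pi, dtype=float)
        if v.shape != (gen.S,) or v.min() < 0 or not math.isclose(v.sum(), 1.0):
            raise ValueError("root prior must be a probability vector over states")
        return v
    if pi is None or pi == "observed":
        v = np.zeros(gen.S)
        for s in set(tip_states.values()):
            v[s] = 1.0
        return v / v.sum()
    if pi == "flat":
        return np.full(gen.S, 1.0 / gen.S)
    raise ValueError(f"unknown root prior: {pi!r}")


def _check_inputs(tree: PhyloTree, tip_states: dict[str, int],
                  gen: ClasseGenerator, rho: float) -> None:
    if not tree.is_binary():
        raise ValueError("ClaSSE requires a binary species tree")
    if tree.root.age is None:
        tree.set_ages_from_lengths()
    if not 0 < rho <= 1:
        raise ValueError("sampling fraction must be in (0, 1]")
    for leaf in tree.leaves():
        if leaf.label not in tip_states:
            raise ValueError(f"no state for tip {leaf.label!r}")
        s = tip_states[leaf.label]
        if not 0 <= s < gen.S:
            raise ValueError(f"tip state index {s} out of range")


def _integrate_branch_adaptive(gen, E0, D0, dur, rtol=1e-8, atol=1e-10):
    S = gen.S

    def fun(_t, y):
        dE, dD = gen.rhs(y[:S], y[S:])
        return np.concatenate([dE, dD])

    sol = solve_ivp(fun, (0.0, dur), np.concatenate([E0, D0]),
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"branch ODE integration failed: {sol.message}")
    y = sol.y[:, -1]
    return y[:S], y[S:]


def _rk4_batch(gen, E, D, dur, nsteps):
    """Fixed-grid RK4 over a batch of branches (batch axis first)."""
    dt = (np.asarray(dur, dtype=float) / nsteps)[:, None]
    E = E.copy()
    D = D.copy()
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(nsteps):
            k1E, k1D = gen.rhs(E, D)
            k2E, k2D = gen.rhs(E + 0.5 * dt * k1E, D + 0.5 * dt * k1D)
            k3E, k3D = gen.rhs(E + 0.5 * dt * k2E, D + 0.5 * dt * k2D)
            k4E, k4D = gen.rhs(E + dt * k3E, D + dt * k3D)
            E = E + dt / 6.0 * (k1E + 2 * k2E + 2 * k3E + k4E)
            D = D + dt / 6.0 * (k1D + 2 * k2D + 2 * k3D + k4D)
    return E, D


def _check_E(E: np.ndarray) -> None:
    if np.min(E) < -1e-6 or np.max(E) > 1.0 + 1e-6:
        raise RuntimeError("extinction probability left [0, 1]: "
                           "integration unstable")


class _Pruning:
    """Post-order pass caching per-node E/D vectors for reuse by both the
    likelihood and stochastic mapping."""

    def __init__(self, tree: PhyloTree, tip_states: dict[str, int],
                 gen: ClasseGenerator, *, pi=None, rho: float = DEFAULT_RHO,
                 method: str = "adaptive", nsteps: int = 10) -> None:
        _check_inputs(tree, tip_states, gen, rho)
        self.tree = tree
        self.gen = gen
        self.rho = rho
        self.pi = _root_prior(gen, tip_states, pi)
        S = gen.S
        n = len(tree.nodes)
        self.E_node = np.zeros((n, S))
        self.D_node = np.zeros((n, S))
        self.E_top = np.zeros((n, S))
        self.D_top = np.zeros((n, S))
        self.logc = 0.0
        self._failed = False

        if method == "adaptive":
            self._run_sequential(tree, tip_states, gen, rho)
        elif method == "fast":
            self._run_waves(tree, tip_states, gen, rho, nsteps)
        else:
            raise ValueError(f"unknown integration method {method!r}")

        E_root = self.E_node[tree.root.id]
        D_root = self.D_node[tree.root.id]
        denom = float(self.pi @ (gen.lam * (1.0 - E_root) ** 2))
        num = float(self.pi @ D_root)
        if self._failed or num <= 0 or denom <= 0 or not math.isfinite(num):
            self.loglik = -np.inf
        else:
            self.loglik = math.log(num) - math.log(denom) + self.logc

    def _tip_init(self, nd, tip_states, gen, rho):
        D = np.zeros(gen.S)
        D[tip_states[nd.label]] = rho
        E = np.full(gen.S, 1.0 - rho)
        return E, D

    def _run_sequential(self, tree, tip_states, gen, rho):
        for nd in tree.postorder():
            if nd.is_leaf:
                E, D = self._tip_init(nd, tip_states, gen, rho)
            else:
                cl, cr = nd.children
                E = self.E_top[cl.id]
                D = gen.combine(self.D_top[cl.id], self.D_top[cr.id])
            self.E_node[nd.id] = E
            self.D_node[nd.id] = D
            if nd is tree.root:
                continue
            dur = nd.parent.age - nd.age
            Et, Dt = _integrate_branch_adaptive(gen, E, D, dur)
            _check_E(Et)
            c = Dt.sum()
            if c <= 0 or not np.isfinite(c):
                self._failed = True
                return
            self.E_top[nd.id] = Et
            self.D_top[nd.id] = Dt / c
            self.logc += math.log(c)

    def _run_waves(self, tree, tip_states, gen, rho, nsteps):
        level = {}
        for nd in tree.postorder():
            level[nd.id] = 0 if nd.is_leaf else 1 + max(
                level[c.id] for c in nd.children)
        max_level = level[tree.root.id]
        for lv in range(max_level + 1):
            nodes = [nd for nd in tree.nodes if level[nd.id] == lv]
            for nd in nodes:
                if nd.is_leaf:
                    E, D = self._tip_init(nd, tip_states, gen, rho)
                else:
                    cl, cr = nd.children
                    E = self.E_top[cl.id]
                    D = gen.combine(self.D_top[cl.id], self.D_top[cr.id])
                self.E_node[nd.id] = E
                self.D_node[nd.id] = D
            batch = [nd for nd in nodes if nd is not tree.root]
            if not batch:
                continue
            ids = np.array([nd.id for nd in batch])
            dur = np.array([nd.parent.age - nd.age for nd in batch])
            Et, Dt = _rk4_batch(gen, self.E_node[ids], self.D_node[ids],
                                dur, nsteps)
            if not (np.all(np.isfinite(Et)) and np.all(np.isfinite(Dt))):
                self._failed = True
                return
            _check_E(Et)
            c = Dt.sum(axis=1)
            if np.any(c <= 0):
                self._failed = True
                return
            self.E_top[ids] = Et
            self.D_top[ids] = Dt / c[:, None]
            self.logc += float(np.sum(np.log(c)))


def classe_loglik(tree: PhyloTree, tip_states: dict[str, int],
                  gen: ClasseGenerator, *, pi=None, rho: float = DEFAULT_RHO,
                  method: str = "adaptive", nsteps: int = 10) -> float:
    """Log-likelihood of tip states on a dated binary tree under ClaSSE.

    ``method="adaptive"`` integrates each branch with LSODA at rtol 1e-8 /
    atol 1e-10 (the reference path); ``method="fast"`` uses a vectorised
    fixed-grid RK4 (``nsteps`` per branch), the path used inside MCMC.
    The root prior defaults to uniform over the observed tip states; the
    likelihood is conditioned on survival of both root lineages.
    """
    return _Pruning(tree, tip_states, gen, pi=pi, rho=rho,
                    method=method, nsteps=nsteps).loglik


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

def _log_prior_rate(x: float, rate: float) -> float:
    # exponential prior, density on the rate scale
    return math.log(rate) - rate * x if x >= 0 else -np.inf


def mcmc_sample(tree: PhyloTree, tip_states: dict[str, int],
                space: StateSpace, *, n_iter: int, seed: int,
                params0: ClasseParams | None = None,
                free: list[str] | None = None,
                prior_rate: float = DEFAULT_PRIOR_RATE,
                rho: float = DEFAULT_RHO, pi=None,
                thin: int = 10, burnin_frac: float = 0.3,
                nsteps: int = 10, use_likelihood: bool = True,
                sample_weights: bool = False) -> pd.DataFrame:
    """Metropolis-Hastings sampling of ClaSSE rates (and, optionally, the
    cladogenetic mode weights).

    Single-component random-walk proposals on log-rates, with per-component
    proposal scales adapted toward ~30% acceptance during burn-in only.
    Priors: exponential(``prior_rate``) on every rate, flat simplex on
    weights.  Deterministic given ``seed``.  Setting
    ``use_likelihood=False`` targets the prior alone (sampler check).
    Returns one row per thinned post-burn-in draw with a log-posterior
    trace.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    params = params0 or ClasseParams()
    if free is None:
        free = list(RATE_NAMES)
    multi_region = any(len(s.regions) > 1 for s in space)
    if not multi_region:
        free = [f for f in free if f not in ("d", "e")]
        sample_weights = False

    def log_post(p: ClasseParams) -> float:
        lp = sum(_log_prior_rate(getattr(p, f), prior_rate) for f in free)
        if not np.isfinite(lp):
            return -np.inf
        if use_likelihood:
            gen = build_generator(space, p)
            lp += classe_loglik(tree, tip_states, gen, pi=pi, rho=rho,
                                method="fast", nsteps=nsteps)
        return lp

    # start strictly positive
    start = {f: max(getattr(params, f), 1e-4) for f in free}
    params = params.with_rates(**start)
    current_lp = log_post(params)
    if not np.isfinite(current_lp):
        raise RuntimeError("initial parameters have zero posterior density")

    comps = list(free) + (["weights"] if sample_weights else [])
    scales = {c: 0.4 for c in comps}
    acc = {c: [0, 0] for c in comps}
    burnin = int(burnin_frac * n_iter)
    rows = []
    for it in range(n_iter):
        comp = comps[rng.integers(len(comps))]
        if comp == "weights":
            w = np.array([params.w_sym, params.w_sub, params.w_vic])
            logits = np.log(np.maximum(w, 1e-12))
            prop_logits = logits + scales[comp] * rng.normal(size=3)
            wp = np.exp(prop_logits - prop_logits.max())
            wp = wp / wp.sum()
            cand = replace(params, w_sym=wp[0], w_sub=wp[1], w_vic=wp[2])
            # flat prior on the simplex; softmax RW Jacobian = prod(w)
            log_jac = float(np.sum(np.log(wp)) - np.sum(np.log(w)))
        else:
            x = getattr(params, comp)
            xp = x * math.exp(scales[comp] * rng.normal())
            cand = params.with_rates(**{comp: xp})
            log_jac = math.log(xp) - math.log(x)  # log-scale RW
        try:
            cand_lp = log_post(cand)
        except (RuntimeError, ValueError):
            cand_lp = -np.inf
        acc[comp][1] += 1
        if math.log(rng.random() + 1e-300) < cand_lp - current_lp + log_jac:
            params, current_lp = cand, cand_lp
            acc[comp][0] += 1
        if it < burnin and (it + 1) % 50 == 0:
            for c in comps:
                a, t = acc[c]
                if t >= 10:
                    rate = a / t
                    if rate == 0:
                        log.warning("zero acceptance for %s; shrinking scale", c)
                    scales[c] *= math.exp(1.0 * (rate - 0.30))
                    scales[c] = float(np.clip(scales[c], 1e-3, 5.0))
                    acc[c] = [0, 0]
        if it >= burnin and (it - burnin) % thin == 0:
            row = {f: getattr(params, f) for f in free}
            if sample_weights:
                row.update(w_sym=params.w_sym, w_sub=params.w_sub,
                           w_vic=params.w_vic)
            row["log_post"] = current_lp
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stochastic mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MapEvent:
    """One anagenetic event on a branch (identified by its child node)."""

    age: float               # Ma before present
    branch: int              # child-node id of the branch carrying the event
    kind: str                # biome_shift | dispersal | extirpation
    detail: tuple            # (from,to) biomes or (region,)
    state_before: int
    state_after: int


@dataclass(frozen=True)
class CladoEvent:
    node: int
    age: float
    mode: str                # sympatric | subset | vicariant
    parent_state: int
    left_state: int
    right_state: int


@dataclass
class StochasticMap:
    """A full sampled history: node states, branch-top daughter states and
    the timed anagenetic event list.  Segments tile each branch exactly."""

    tree: PhyloTree
    node_states: dict[int, int]
    branch_top_states: dict[int, int]
    events: list[MapEvent]
    clado_events: list[CladoEvent]
    space: StateSpace | None = None

    def segments(self, branch: int) -> list[tuple[float, float, int]]:
        """Piecewise-constant state history of one branch as
        (older age, younger age, state) segments, root-ward first."""
        nd = self.tree.nodes[branch]
        a_top = nd.parent.age
        a_bot = nd.age
        evs = sorted((e for e in self.events if e.branch == branch),
                     key=lambda e: -e.age)
        segs = []
        state = self.branch_top_states[branch]
        t = a_top
        for e in evs:
            segs.append((t, e.age, state))
            state = e.state_after
            t = e.age
        segs.append((t, a_bot, state))
        return segs

    def count(self, predicate) -> int:
        return sum(1 for e in self.events if predicate(e))


def simulate_ctmc_path(Q: np.ndarray, state: int, duration: float,
                       rng: np.random.Generator
                       ) -> list[tuple[float, int, int]]:
    """Unconditioned forward CTMC path; returns (time-from-start, from, to)
    jumps.  The expected number of events from state i over t is
    ``-Q[i,i] * t`` when i is quasi-stationary; this is the primitive the
    map calibration tests exercise."""
    t = 0.0
    out = []
    while True:
        rate = -Q[state, state]
        if rate <= 0:
            return out
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            return out
        probs = Q[state].copy()
        probs[state] = 0.0
        probs = probs / probs.sum()
        nxt = int(rng.choice(len(probs), p=probs))
        out.append((t, state, nxt))
        state = nxt


def _conditioned_path(Q, P_t, a, b, duration, rng, max_reject=50,
                      max_jumps=200):
    """Endpoint-conditioned CTMC path: rejection sampling from the top
    state with a uniformization fallback."""
    for _ in range(max_reject):
        path = simulate_ctmc_path(Q, a, duration, rng)
        end = path[-1][2] if path else a
        if end == b:
            return path
    # uniformization
    omega = max(-Q.diagonal().min(), 1e-12) * 1.05
    S = Q.shape[0]
    R = np.eye(S) + Q / omega
    p_ab = P_t[a, b]
    if p_ab <= 0:
        raise RuntimeError("endpoint conditioning impossible")
    # number of uniformized jumps
    Rpow = [np.eye(S)]
    log_pois = -omega * duration
    weights = []
    term = math.exp(log_pois)
    n = 0
    u = rng.random() * p_ab
    cum = term * Rpow[0][a, b]
    while cum < u and n < max_jumps:
        n += 1
        Rpow.append(Rpow[-1] @ R)
        term = term * omega * duration / n
        cum += term * Rpow[n][a, b]
    # jump-chain states given n
    states = [a]
    for m in range(1, n + 1):
        prev = states[-1]
        w = R[prev, :] * Rpow[n - m][:, b]
        if w.sum() <= 0:  # pragma: no cover - numerical corner
            w = np.maximum(R[prev, :], 0)
        states.append(int(rng.choice(S, p=w / w.sum())))
    times = np.sort(rng.random(n)) * duration
    path = []
    for tm, s_prev, s_next in zip(times, states[:-1], states[1:]):
        if s_prev != s_next:
            path.append((float(tm), s_prev, s_next))
    return path


class StochasticMapper:
    """Draw stochastic character maps conditional on tip data.

    Node states are sampled root-ward from the pruning-pass D vectors;
    cladogenetic outcomes from the tensor-conditional probabilities; branch
    interiors are endpoint-conditioned anagenetic paths.
    """

    def __init__(self, tree: PhyloTree, tip_states: dict[str, int],
                 gen: ClasseGenerator, *, pi=None, rho: float = DEFAULT_RHO,
                 method: str = "fast", nsteps: int = 20) -> None:
        self.pruning = _Pruning(tree, tip_states, gen, pi=pi, rho=rho,
                                method=method, nsteps=nsteps)
        self.tree = tree
        self.gen = gen
        self.tip_states = tip_states
        # per-branch anagenetic transition matrices
        self._P_branch: dict[int, np.ndarray] = {}
        for nd in tree.postorder():
            if nd is tree.root:
                continue
            self._P_branch[nd.id] = expm(gen.Q * (nd.parent.age - nd.age))

    def draw(self, rng: np.random.Generator) -> StochasticMap:
        tree, gen = self.tree, self.gen
        pr = self.pruning
        node_states: dict[int, int] = {}
        branch_top: dict[int, int] = {}
        events: list[MapEvent] = []
        clado: list[CladoEvent] = []

        w_root = pr.pi * pr.D_node[tree.root.id]
        if w_root.sum() <= 0:
            raise RuntimeError("root sampling failed: zero posterior mass")
        node_states[tree.root.id] = int(
            rng.choice(gen.S, p=w_root / w_root.sum()))

        for nd in tree.preorder():
            if nd.is_leaf:
                continue
            i = node_states[nd.id]
            cl, cr = nd.children
            # cladogenetic outcome, ordered daughters
            opts = []
            for (j, k, w, mode) in gen.clado_by_state[i]:
                if j == k:
                    opts.append((j, k, w * pr.D_top[cl.id][j]
                                 * pr.D_top[cr.id][k], mode))
                else:
                    opts.append((j, k, 0.5 * w * pr.D_top[cl.id][j]
                                 * pr.D_top[cr.id][k], mode))
                    opts.append((k, j, 0.5 * w * pr.D_top[cl.id][k]
                                 * pr.D_top[cr.id][j], mode))
            ws = np.array([o[2] for o in opts])
            if ws.sum() <= 0:
                raise RuntimeError("cladogenetic sampling failed")
            jL, kR, _, mode = opts[int(rng.choice(len(opts),
                                                  p=ws / ws.sum()))]
            clado.append(CladoEvent(nd.id, nd.age, mode, i, jL, kR))
            for child, top_state in ((cl, jL), (cr, kR)):
                branch_top[child.id] = top_state
                dur = nd.age - child.age
                P_t = self._P_branch[child.id]
                # bottom-state distribution weighted by the subtree data
                wbot = P_t[top_state, :] * pr.D_node[child.id]
                if wbot.sum() <= 0:
                    raise RuntimeError(
                        "branch endpoint conditioning impossible")
                bot = int(rng.choice(gen.S, p=wbot / wbot.sum()))
                node_states[child.id] = bot
                path = _conditioned_path(gen.Q, P_t, top_state, bot, dur, rng)
                for (tm, s_from, s_to) in path:
                    kind_info = gen.move_kind.get((s_from, s_to))
                    if kind_info is None:
                        # uniformization may propose composite moves only if
                        # Q allows them; single-event Q makes this unreachable
                        raise RuntimeError("non-elementary move sampled")
                    events.append(MapEvent(
                        age=nd.age - tm, branch=child.id,
                        kind=kind_info[0], detail=tuple(kind_info[1:]),
                        state_before=s_from, state_after=s_to))
        # tip contract
        for leaf in tree.leaves():
            assert node_states[leaf.id] == self.tip_states[leaf.label]
        return StochasticMap(tree, node_states, branch_top, events, clado,
                             space=gen.space)

    def draw_many(self, n_maps: int, seed: int) -> list[StochasticMap]:
        rng = np.random.default_rng(seed)
        return [self.draw(rng) for _ in range(n_maps)]


def stochastic_map(tree: PhyloTree, tip_states: dict[str, int],
                   gen: ClasseGenerator, seed: int, *, pi=None,
                   rho: float = DEFAULT_RHO) -> StochasticMap:
    """One stochastic map under fixed parameters (a single posterior draw)."""
    mapper = StochasticMapper(tree, tip_states, gen, pi=pi, rho=rho)
    return mapper.draw(np.random.default_rng(seed))
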