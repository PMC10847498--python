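"""Penalized-likelihood divergence-time estimation.

Substitution branch lengths are converted to approximate counts
``x_i = round(length_i * L)`` for an effective alignment length ``L``; the
model is a Poisson likelihood on each branch, ``x_i ~ Poisson(r_i t_i L)``
with per-branch rates ``r_i`` and durations ``t_i`` implied by node ages,
plus a roughness penalty ``kappa`` on among-branch rate variation: squared
rate differences between each branch and its parent branch, and the
variance of the root's child-branch rates.  Node ages are constrained by
min/max fossil calibrations; the smoothing value is chosen by
leave-one-terminal-out cross-validation.

Ages are optimised jointly with log-rates under a feasibility-preserving
reparameterization: each internal node age is a proportion of its allowed
interval (between the propagated minimum bound and its parent's current
age), so every iterate satisfies the calibrations and the parent>child
ordering by construction.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .trees import CalibrationSet, PhyloTree

__all__ = [
    "DatingConfig",
    "Chronogram",
    "pl_objective",
    "date_tree",
    "cross_validate",
]

log = logging.getLogger(__name__)

#: Default CV grid: log-spaced smoothing values spanning six orders.
DEFAULT_CV_GRID = tuple(10.0 ** k for k in range(-3, 4))


@dataclass
class DatingConfig:
    """Smoothing, site count, and optimizer settings for PL dating."""

    kappa: float = 1.0
    site_count: int = 100_000
    cv_grid: tuple[float, ...] = DEFAULT_CV_GRID
    root_age: float | None = None      # fix the root age (identifiability)
    ftol: float = 1e-10
    maxiter: int = 2000

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("smoothing kappa must be positive")
        if self.site_count < 1:
            raise ValueError("site_count must be >= 1")
        if not self.cv_grid:
            raise ValueError("CV grid must be nonempty")


@dataclass
class Chronogram:
    """A dated tree (ages in Ma, lengths in Myr) with per-branch
    substitution rates keyed by child-node id."""

    tree: PhyloTree
    rates: dict[int, float]
    objective: float = math.nan
    trace: list = field(default_factory=list, repr=False)

    def age_of(self, tips) -> float:
        return self.tree.mrca(tips).age


def _counts(tree: PhyloTree, L: int) -> dict[int, int]:
    x = {}
    for nd in tree.postorder():
        if nd is tree.root:
            continue
        if nd.length is None or math.isnan(nd.length):
            raise ValueError(
                "tree has missing branch lengths; impute before dating")
        x[nd.id] = max(int(round(nd.length * L)), 0)
    return x


def pl_objective(tree: PhyloTree, ages: dict[int, float],
                 rates: dict[int, float], cfg: DatingConfig) -> float:
    """Penalized log-likelihood (higher is better).

    ``ages`` maps node id -> age (Ma); ``rates`` maps child-node id -> rate
    (substitutions/site/Myr).  Branch counts are derived from the tree's
    substitution lengths and ``cfg.site_count``.
    """
    x = _counts(tree, cfg.site_count)
    ll = 0.0
    for nd in tree.postorder():
        if nd is tree.root:
            continue
        t = ages[nd.parent.id] - ages[nd.id]
        r = rates[nd.id]
        if t <= 0:
            raise ValueError(f"non-positive duration on branch {nd.id}")
        if r <= 0:
            raise ValueError(f"non-positive rate on branch {nd.id}")
        mean = r * t * cfg.site_count
        ll += x[nd.id] * math.log(mean) - mean - float(gammaln(x[nd.id] + 1))
    pen = 0.0
    root_child_rates = []
    for nd in tree.postorder():
        if nd is tree.root:
            continue
        if nd.parent is tree.root:
            root_child_rates.append(rates[nd.id])
        else:
            pen += (rates[nd.id] - rates[nd.parent.id]) ** 2
    if len(root_child_rates) > 1:
        pen += float(np.var(root_child_rates))
    return ll - cfg.kappa * pen


def _propagated_bounds(tree: PhyloTree, calib: CalibrationSet
                       ) -> dict[int, tuple[float, float]]:
    """Effective (min,max) per node: mins pushed root-ward, maxes tip-ward."""
    raw = calib.resolve(tree)
    lo = {nd.id: 0.0 for nd in tree.nodes}
    hi = {nd.id: math.inf for nd in tree.nodes}
    for nid, (mn, mx) in raw.items():
        lo[nid] = max(lo[nid], mn)
        hi[nid] = min(hi[nid], mx)
    for nd in tree.postorder():        # mins propagate to ancestors
        if nd is not tree.root:
            lo[nd.parent.id] = max(lo[nd.parent.id], lo[nd.id])
    for nd in tree.preorder():         # maxes propagate to descendants
        if nd is not tree.root:
            hi[nd.id] = min(hi[nd.id], hi[nd.parent.id])
    for nd in tree.nodes:
        if lo[nd.id] > hi[nd.id]:
            raise ValueError(
                f"infeasible calibrations along a root-to-tip path "
                f"(node {nd.id}: min {lo[nd.id]} > max {hi[nd.id]})")
    return {nd.id: (lo[nd.id], hi[nd.id]) for nd in tree.nodes}


def date_tree(tree: PhyloTree, calib: CalibrationSet,
              cfg: DatingConfig) -> Chronogram:
    """Jointly optimise node ages and branch rates under the PL objective.

    The tree must carry substitution branch lengths.  Identifiability
    requires either ``cfg.root_age`` or a finite maximum constraint at the
    root.  Returned chronograms always satisfy every calibration bound
    (hard assertion).
    """
    if not tree.has_lengths():
        raise ValueError("input tree needs branch lengths")
    bounds = _propagated_bounds(tree, calib)
    root = tree.root
    root_lo, root_hi = bounds[root.id]
    fixed_root = cfg.root_age
    if fixed_root is None and not math.isfinite(root_hi):
        raise ValueError("need a root maximum constraint or a fixed root age")
    if fixed_root is not None:
        if not root_lo <= fixed_root <= root_hi:
            raise ValueError("fixed root age violates calibrations")

    internals = [nd for nd in tree.preorder()
                 if not nd.is_leaf and nd is not root]
    branches = [nd for nd in tree.postorder() if nd is not root]
    L = cfg.site_count
    xmap = _counts(tree, L)
    x = np.array([xmap[nd.id] for nd in branches], dtype=float)
    lgx = gammaln(x + 1)

    # initial ages: substitution depths rescaled to an initial root age
    depth = {root.id: 0.0}
    for nd in tree.preorder():
        if nd is not root:
            depth[nd.id] = depth[nd.parent.id] + max(nd.length, 1e-10)
    max_depth = max(depth[lf.id] for lf in tree.leaves())
    root0 = fixed_root if fixed_root is not None else (
        root_hi if math.isfinite(root_hi) else max(2 * root_lo, 1.0))
    if fixed_root is None and math.isfinite(root_hi):
        root0 = root_lo + 0.75 * (root_hi - root_lo) if root_lo > 0 \
            else 0.75 * root_hi

    n_free_root = 0 if fixed_root is not None else 1

    def ages_from_theta(theta: np.ndarray) -> dict[int, float]:
        ages = {lf.id: 0.0 for lf in tree.leaves()}
        ages[root.id] = fixed_root if fixed_root is not None else theta[0]
        for idx, nd in enumerate(internals):
            lo, hi = bounds[nd.id]
            hi = min(hi, ages[nd.parent.id])
            lo = max(lo, 0.0)
            span = max(hi - lo, 1e-12)
            p = theta[n_free_root + idx]
            ages[nd.id] = lo + p * span
        return ages

    def unpack(theta):
        ages = ages_from_theta(theta)
        r = np.exp(theta[n_free_root + len(internals):])
        return ages, r

    def neg_obj(theta: np.ndarray) -> float:
        ages, r = unpack(theta)
        t = np.array([ages[nd.parent.id] - ages[nd.id] for nd in branches])
        t = np.maximum(t, 1e-12)
        mean = r * t * L
        ll = float(np.sum(x * np.log(mean) - mean - lgx))
        pen = 0.0
        rates = {nd.id: rv for nd, rv in zip(branches, r)}
        root_child = []
        for nd in branches:
            if nd.parent is root:
                root_child.append(rates[nd.id])
            else:
                pen += (rates[nd.id] - rates[nd.parent.id]) ** 2
        if len(root_child) > 1:
            pen += float(np.var(root_child))
        return -(ll - cfg.kappa * pen)

    # initial proportions consistent with depth-proportional ages
    theta0 = []
    if fixed_root is None:
        theta0.append(root0)
    ages0 = {root.id: root0}
    for lf in tree.leaves():
        ages0[lf.id] = 0.0
    for nd in internals:
        frac = 1.0 - depth[nd.id] / max_depth
        ages0[nd.id] = max(frac * root0, 1e-6)
    for nd in internals:
        lo, hi = bounds[nd.id]
        hi = min(hi, ages0[nd.parent.id])
        lo = max(lo, 0.0)
        span = max(hi - lo, 1e-12)
        p = (min(max(ages0[nd.id], lo + 1e-9 * span), hi - 1e-9 * span)
             - lo) / span
        theta0.append(min(max(p, 1e-4), 1 - 1e-4))
        ages0[nd.id] = lo + theta0[-1] * span
    total_time = sum(max(ages0[nd.parent.id] - ages0[nd.id], 1e-6)
                     for nd in branches)
    r0 = max(sum(xv for xv in x) / (total_time * L), 1e-10)
    theta0.extend([math.log(r0)] * len(branches))
    theta0 = np.array(theta0)

    opt_bounds = []
    if fixed_root is None:
        opt_bounds.append((max(root_lo, 1e-6), root_hi))
    opt_bounds.extend([(1e-6, 1 - 1e-6)] * len(internals))
    opt_bounds.extend([(-30.0, 5.0)] * len(branches))

    res = minimize(neg_obj, theta0, method="L-BFGS-B", bounds=opt_bounds,
                   options={"ftol": cfg.ftol, "maxiter": cfg.maxiter,
                            "maxfun": 10 * cfg.maxiter * len(theta0)})
    theta = res.x.copy()
    fval = res.fun

    # Alternating refinement: the joint fit can stall on the ridge that
    # couples rates to ages at large smoothing, so polish with coordinate
    # passes -- rates given ages (analytic gradient), then ages given rates.
    n_age = n_free_root + len(internals)
    parent_idx = []
    bindex = {nd.id: i for i, nd in enumerate(branches)}
    for nd in branches:
        parent_idx.append(-1 if nd.parent is root else bindex[nd.parent.id])
    parent_idx = np.array(parent_idx)
    root_child = np.array([i for i, nd in enumerate(branches)
                           if nd.parent is root])

    def rate_block(theta_r, t):
        r = np.exp(theta_r)
        mean = r * t * L
        ll = float(np.sum(x * np.log(mean) - mean - lgx))
        pen = 0.0
        g_pen = np.zeros_like(r)
        has_parent = parent_idx >= 0
        diff = r[has_parent] - r[parent_idx[has_parent]]
        pen += float(np.sum(diff ** 2))
        np.add.at(g_pen, np.where(has_parent)[0], 2 * diff)
        np.add.at(g_pen, parent_idx[has_parent], -2 * diff)
        if len(root_child) > 1:
            rc = r[root_child]
            pen += float(np.var(rc))
            g_pen[root_child] += 2 * (rc - rc.mean()) / len(rc)
        f = -(ll - cfg.kappa * pen)
        g = -((x - mean) - cfg.kappa * g_pen * r)
        return f, g

    for _ in range(40):
        ages_cur = ages_from_theta(theta)
        t_cur = np.maximum(
            np.array([ages_cur[nd.parent.id] - ages_cur[nd.id]
                      for nd in branches]), 1e-12)
        res_r = minimize(rate_block, theta[n_age:], args=(t_cur,),
                         jac=True, method="L-BFGS-B",
                         bounds=opt_bounds[n_age:],
                         options={"ftol": 1e-14, "maxiter": 500})
        theta[n_age:] = res_r.x

        def age_obj(theta_a):
            th = np.concatenate([theta_a, theta[n_age:]])
            return neg_obj(th)

        res_a = minimize(age_obj, theta[:n_age], method="L-BFGS-B",
                         bounds=opt_bounds[:n_age],
                         options={"ftol": 1e-12, "maxiter": 300})
        theta[:n_age] = res_a.x
        new_f = neg_obj(theta)
        if fval - new_f < 1e-9 * max(abs(new_f), 1.0):
            fval = min(fval, new_f)
            break
        fval = new_f

    ages, r = unpack(theta)

    out = tree.copy()
    for nd_out, nd_in in zip(out.postorder(), tree.postorder()):
        nd_out.age = ages[nd_in.id]
    out.set_lengths_from_ages()
    out.units = "myr"
    out.check_dated()
    rates = {nd_out.id: float(rv)
             for nd_out, rv in zip((nd for nd in out.postorder()
                                    if nd is not out.root), r)}
    # hard feasibility assertion against the *raw* calibrations
    for nid, (mn, mx) in calib.resolve(out).items():
        age = out.nodes[nid].age
        assert age >= mn - 1e-6 and age <= mx + 1e-6, \
            f"calibration violated at node {nid}: {age} not in [{mn},{mx}]"
    chron = Chronogram(out, rates, objective=-fval,
                       trace=[res.nit, res.message])
    return chron


def cross_validate(tree: PhyloTree, calib: CalibrationSet,
                   cfg: DatingConfig) -> tuple[float, list[dict]]:
    """Choose the smoothing value by leave-one-terminal-out CV.

    For each kappa on the grid, each terminal is pruned in turn, the PL fit
    is re-run on the pruned tree, and the terminal's substitution count is
    predicted as ``x_pred = r_hat * t_hat * L`` from the rate of the
    pruned-tree branch spanning the attachment point and the midpoint age
    of that branch.  Score per kappa is the chi-square-style sum
    ``(x_pred - x_obs)^2 / x_pred``; smallest kappa wins ties.
    """
    if tree.n_tips() < 5:
        raise ValueError("cross-validation needs at least 5 tips")
    if len(cfg.cv_grid) == 1:
        warnings.warn("CV grid has a single value; returning it")
        return cfg.cv_grid[0], [{"kappa": cfg.cv_grid[0],
                                 "score": math.nan}]
    L = cfg.site_count
    clades = tree.clades()
    table = []
    for kappa in sorted(cfg.cv_grid):
        score = 0.0
        n_used = 0
        for leaf in tree.leaves():
            parent = leaf.parent
            if parent is tree.root:
                continue   # no spanning branch after pruning
            sib_taxa = frozenset().union(
                *(clades[c.id] for c in parent.children if c is not leaf))
            keep = tree.taxa - {leaf.label}
            pruned = tree.pruned_to(keep)
            drop_cals = CalibrationSet(
                [c for c in calib
                 if c.clade_tips <= keep and len(c.clade_tips) > 0])
            sub_cfg = DatingConfig(
                kappa=kappa, site_count=L, cv_grid=(kappa,),
                root_age=cfg.root_age, ftol=cfg.ftol, maxiter=cfg.maxiter)
            chron = date_tree(pruned, drop_cals, sub_cfg)
            pclades = chron.tree.clades()
            target = None
            for nd in chron.tree.postorder():
                if nd is not chron.tree.root and pclades[nd.id] == sib_taxa:
                    target = nd
                    break
            if target is None:
                continue
            r_hat = chron.rates[target.id]
            t_hat = 0.5 * (target.parent.age + target.age)
            x_obs = round(leaf.length * L)
            x_pred = max(r_hat * t_hat * L, 1e-12)
            score += (x_pred - x_obs) ** 2 / x_pred
            n_used += 1
        table.append({"kappa": kappa, "score": score, "n_terminals": n_used})
        log.info("CV kappa=%g score=%.6g over %d terminals",
                 kappa, score, n_used)
    best = min(table, key=lambda row: (row["score"], row["kappa"]))
    return best["kappa"], table
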