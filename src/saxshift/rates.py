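"""Time-sliced rates of upslope biome shifts and mountain hopping.

Events are harvested from stochastic character maps:

* **upslope shift** — an anagenetic biome transition from the generalist
  ("both") state to the alpine-specialist state;
* **mountain hop** — an anagenetic dispersal event (region gained) on a
  lineage whose biome state at the moment of the event is alpine;
* everything else is labelled ``other``.

Counts per time window are divided by the window duration in Myr (the
whole-tree rate divides by the root age).  A per-lineage-time
normalisation — counts divided by the summed branch time inside the
window — is available behind a flag for interpretation checks; it is the
normalisation under which a time-homogeneous process yields a flat rate
series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classe import MapEvent, StochasticMap

__all__ = [
    "TimeWindows",
    "RatePosterior",
    "classify_events",
    "rates_through_time",
    "lineage_time_in_window",
]

EVENT_CLASSES = ("upslope", "mountain_hop", "other")


@dataclass(frozen=True)
class TimeWindows:
    """Ordered window boundaries in Ma (strictly decreasing).

    Boundaries ``(15, 10, 5)`` with a root age R define the windows
    ``>15`` (R to 15 Ma), ``15-10``, ``10-5`` and ``5-0``.  An event lying
    exactly on a boundary belongs to the younger window.
    """

    boundaries: tuple[float, ...] = (15.0, 10.0, 5.0)

    def __post_init__(self) -> None:
        b = self.boundaries
        if not b:
            raise ValueError("need at least one boundary")
        if any(x <= 0 for x in b):
            raise ValueError("boundaries must be positive ages")
        if any(b[i] <= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly decreasing")

    def labels(self) -> list[str]:
        out = [f">{self.boundaries[0]:g}"]
        for older, younger in zip(self.boundaries, self.boundaries[1:]):
            out.append(f"{older:g}-{younger:g}")
        out.append(f"{self.boundaries[-1]:g}-0")
        return out

    def edges(self, root_age: float) -> list[tuple[float, float]]:
        """(older, younger) age pair per window, tiling [0, root_age]."""
        if root_age <= self.boundaries[0]:
            raise ValueError("root age must exceed the oldest boundary")
        bs = (root_age,) + self.boundaries + (0.0,)
        return list(zip(bs, bs[1:]))

    def assign(self, age: float) -> int:
        """Window index for an event age; boundary ages go to the younger
        window."""
        for idx in range(len(self.boundaries), 0, -1):
            if age <= self.boundaries[idx - 1]:
                return idx
        return 0

    def durations(self, root_age: float) -> np.ndarray:
        return np.array([older - younger
                         for older, younger in self.edges(root_age)])


def classify_events(smap: StochasticMap) -> list[tuple[MapEvent, str]]:
    """Label every anagenetic event of a map.

    Dispersal by a generalist is ``other`` — hops are counted only for
    alpine specialists; cladogenetic range inheritance is not an event list
    entry and is never a hop.
    """
    if smap.space is None:
        raise ValueError("map lacks a state space annotation")
    out = []
    for e in smap.events:
        label = "other"
        if e.kind == "biome_shift" and e.detail == ("both", "alpine"):
            label = "upslope"
        elif e.kind == "dispersal" and \
                smap.space[e.state_before].biome.value == "alpine":
            label = "mountain_hop"
        out.append((e, label))
    return out


@dataclass
class RatePosterior:
    """Per-draw, per-window rates for each event class."""

    windows: TimeWindows
    root_age: float
    counts: np.ndarray          # (n_maps, n_windows, n_classes)
    rates: np.ndarray           # same shape, events per Myr
    whole_tree: np.ndarray      # (n_maps, n_classes)
    normalization: str

    def mean_series(self, event_class: str) -> np.ndarray:
        c = EVENT_CLASSES.index(event_class)
        return self.rates[:, :, c].mean(axis=0)

    def summary(self) -> pd.DataFrame:
        rows = []
        labels = self.windows.labels()
        for w, lbl in enumerate(labels):
            for c, cls in enumerate(EVENT_CLASSES):
                draws = self.rates[:, w, c]
                rows.append({
                    "window": lbl, "class": cls,
                    "mean": float(draws.mean()),
                    "q025": float(np.quantile(draws, 0.025)),
                    "q975": float(np.quantile(draws, 0.975)),
                })
        return pd.DataFrame(rows)


def lineage_time_in_window(tree, older: float, younger: float) -> float:
    """Total branch time (lineage-Myr) inside an age window."""
    total = 0.0
    for nd in tree.postorder():
        if nd is tree.root:
            continue
        a_top, a_bot = nd.parent.age, nd.age
        total += max(0.0, min(a_top, older) - max(a_bot, younger))
    return total


#: Biome category whose occupancy time normalises each event class under
#: the per-source normalisation (upslope shifts originate from generalists,
#: hops from alpine specialists).
_SOURCE_BIOME = {"upslope": "both", "mountain_hop": "alpine", "other": None}


def occupancy_time(smap: StochasticMap, windows: TimeWindows,
                   root_age: float, biome: str | None) -> np.ndarray:
    """Per-window lineage time spent in states of one biome category
    (``None``: any state), from the map's branch segments."""
    if smap.space is None:
        raise ValueError("map lacks a state space annotation")
    edges = windows.edges(root_age)
    out = np.zeros(len(edges))
    tree = smap.tree
    for nd in tree.postorder():
        if nd is tree.root:
            continue
        for older_s, younger_s, state in smap.segments(nd.id):
            if biome is not None and \
                    smap.space[state].biome.value != biome:
                continue
            for w, (o, y) in enumerate(edges):
                out[w] += max(0.0, min(older_s, o) - max(younger_s, y))
    return out


def rates_through_time(maps: list[StochasticMap], windows: TimeWindows,
                       normalization: str = "per_myr") -> RatePosterior:
    """Convert event counts from stochastic maps to time-sliced rates.

    ``normalization="per_myr"`` divides window counts by the window
    duration (and whole-tree counts by the root age);
    ``"per_lineage_myr"`` divides by the summed lineage time inside the
    window; ``"per_source_lineage_myr"`` divides each event class by the
    occupancy time of its source biome (generalist time for upslope
    shifts, alpine time for hops, pooled over maps) -- the estimator that
    is flat through time under a time-homogeneous process.
    """
    if not maps:
        raise ValueError("need at least one stochastic map")
    if normalization not in ("per_myr", "per_lineage_myr",
                             "per_source_lineage_myr"):
        raise ValueError(f"unknown normalization {normalization!r}")
    tree = maps[0].tree
    root_age = tree.root_age()
    n_w = len(windows.boundaries) + 1
    dur = windows.durations(root_age)
    if np.any(dur <= 0):
        raise ValueError("zero-duration window")
    if normalization == "per_lineage_myr":
        denom = np.array([lineage_time_in_window(tree, o, y)
                          for o, y in windows.edges(root_age)])
        whole_denom = lineage_time_in_window(tree, root_age, 0.0)
    else:
        denom = dur
        whole_denom = root_age
    counts = np.zeros((len(maps), n_w, len(EVENT_CLASSES)))
    for m, smap in enumerate(maps):
        for e, label in classify_events(smap):
            c = EVENT_CLASSES.index(label)
            w = windows.assign(e.age)
            counts[m, w, c] += 1
    if normalization == "per_source_lineage_myr":
        # pooled occupancy denominator per class and window
        rates = np.zeros_like(counts)
        whole = np.zeros((len(maps), len(EVENT_CLASSES)))
        for c, cls in enumerate(EVENT_CLASSES):
            occ = np.zeros(n_w)
            for smap in maps:
                occ += occupancy_time(smap, windows, root_age,
                                      _SOURCE_BIOME[cls])
            occ_mean = np.maximum(occ / len(maps), 1e-12)
            rates[:, :, c] = counts[:, :, c] / occ_mean[None, :]
            whole[:, c] = counts[:, :, c].sum(axis=1) / max(occ.sum()
                                                            / len(maps), 1e-12)
    else:
        rates = counts / denom[None, :, None]
        whole = counts.sum(axis=1) / whole_denom
    return RatePosterior(windows=windows, root_age=root_age, counts=counts,
                         rates=rates, whole_tree=whole,
                         normalization=normalization)
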