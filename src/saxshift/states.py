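"""Joint biome-by-region state space and the species assignment table.

Lineages occupy a nonempty set of regions drawn from five areas of the
Northern Hemisphere — Americas, Asia, Caucasus, Europe, Arctic — and one of
three biome categories: alpine specialist, non-alpine specialist, or
generalist ("both", occurring inside and outside the alpine zone).  The
Arctic is treated as ecologically equivalent to the alpine zone, so states
combining Arctic occupancy with the non-alpine biome are excluded from the
state space and rejected during validation of assignment tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .trees import PhyloTree

__all__ = [
    "Biome",
    "REGIONS",
    "ARCTIC",
    "BiomeRegionState",
    "StateSpace",
    "AssignmentTable",
    "enumerate_states",
    "load_assignments",
    "match_tree_to_assignments",
]


class Biome(str, Enum):
    ALPINE = "alpine"
    NON_ALPINE = "non_alpine"
    BOTH = "both"


#: Canonical region order used for deterministic state indexing.
REGIONS: tuple[str, ...] = ("Americas", "Asia", "Caucasus", "Europe", "Arctic")
ARCTIC = "Arctic"

_BIOME_ALIASES = {
    "alpine": Biome.ALPINE,
    "non_alpine": Biome.NON_ALPINE,
    "non-alpine": Biome.NON_ALPINE,
    "nonalpine": Biome.NON_ALPINE,
    "both": Biome.BOTH,
}


@dataclass(frozen=True)
class BiomeRegionState:
    """(biome category, nonempty region set), Arctic constraint enforced."""

    biome: Biome
    regions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("state must occupy at least one region")
        unknown = self.regions - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region(s): {sorted(unknown)}")
        if ARCTIC in self.regions and self.biome == Biome.NON_ALPINE:
            raise ValueError(
                "invalid state: Arctic occupancy with non-alpine biome")

    def sort_key(self) -> tuple:
        order = {r: i for i, r in enumerate(REGIONS)}
        biome_order = {Biome.ALPINE: 0, Biome.NON_ALPINE: 1, Biome.BOTH: 2}
        ridx = tuple(sorted(order[r] for r in self.regions))
        return (biome_order[self.biome], len(ridx), ridx)

    def __str__(self) -> str:
        regs = ";".join(r for r in REGIONS if r in self.regions)
        return f"{self.biome.value}|{regs}"


class StateSpace:
    """Ordered, indexable enumeration of valid biome-region states."""

    def __init__(self, states: Sequence[BiomeRegionState],
                 regions: Sequence[str], max_range: int) -> None:
        self.states = list(states)
        self.regions = tuple(regions)
        self.max_range = max_range
        self.index = {s: i for i, s in enumerate(self.states)}

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def __getitem__(self, i: int) -> BiomeRegionState:
        return self.states[i]

    def index_of(self, state: BiomeRegionState) -> int:
        try:
            return self.index[state]
        except KeyError:
            raise KeyError(f"state {state} outside this state space") from None


def enumerate_states(regions: Sequence[str] = REGIONS,
                     max_range: int = 2) -> StateSpace:
    """All valid (biome, region-set) states with range size <= max_range.

    Deterministic order: biome category (alpine, non-alpine, both), then
    range size, then lexicographic region indices.  The full 5-region,
    max_range=5 space has 77 states (3 x 31 subsets minus the 16
    Arctic-containing subsets paired with the non-alpine biome).
    """
    regions = tuple(regions)
    if not regions:
        raise ValueError("empty region list")
    unknown = set(regions) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown region(s): {sorted(unknown)}")
    if not 1 <= max_range <= len(regions):
        raise ValueError("max_range must be in [1, number of regions]")
    out: list[BiomeRegionState] = []
    for biome in (Biome.ALPINE, Biome.NON_ALPINE, Biome.BOTH):
        for size in range(1, max_range + 1):
            for combo in itertools.combinations(regions, size):
                if biome == Biome.NON_ALPINE and ARCTIC in combo:
                    continue
                out.append(BiomeRegionState(biome, frozenset(combo)))
    out.sort(key=BiomeRegionState.sort_key)
    return StateSpace(out, regions, max_range)


@dataclass
class AssignmentTable:
    """Validated species -> (regions, biome) assignments."""

    rows: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"species", "regions", "biome"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"assignment table missing columns: {missing}")
        if self.rows["species"].duplicated().any():
            dups = sorted(self.rows.loc[self.rows["species"].duplicated(),
                                        "species"])
            raise ValueError(f"duplicate species: {dups}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def species(self) -> list[str]:
        return list(self.rows["species"])

    def state_of(self, species: str) -> BiomeRegionState:
        row = self.rows.loc[self.rows["species"] == species]
        if row.empty:
            raise KeyError(f"species not in table: {species!r}")
        return BiomeRegionState(
            _BIOME_ALIASES[row.iloc[0]["biome"]],
            frozenset(row.iloc[0]["regions"]))

    def biome_counts(self) -> dict[str, int]:
        counts = {b.value: 0 for b in Biome}
        for b in self.rows["biome"]:
            counts[_BIOME_ALIASES[b].value] += 1
        return counts

    def to_csv(self, path) -> None:
        df = self.rows.copy()
        df["regions"] = df["regions"].map(
            lambda rs: ";".join(r for r in REGIONS if r in rs))
        df["biome"] = df["biome"].map(lambda b: _BIOME_ALIASES[b].value)
        df.to_csv(path, sep="\t", index=False)


def load_assignments(path_or_buf) -> AssignmentTable:
    """Read and validate a delimited assignment table.

    Expected columns: species, regions (semicolon-separated), biome.
    Every row must be a valid state; an Arctic + non-alpine row is rejected
    with the offending species named.
    """
    df = pd.read_csv(path_or_buf, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"species", "regions", "biome"}
    if not required <= set(df.columns):
        raise ValueError(
            f"assignment table must have columns {sorted(required)}")
    df["species"] = df["species"].astype(str).str.strip()
    parsed_regions = []
    for _, row in df.iterrows():
        sp = row["species"]
        regs = frozenset(r.strip() for r in str(row["regions"]).split(";")
                         if r.strip())
        biome_token = str(row["biome"]).strip().lower()
        if biome_token not in _BIOME_ALIASES:
            raise ValueError(f"species {sp!r}: unknown biome {row['biome']!r}")
        try:
            BiomeRegionState(_BIOME_ALIASES[biome_token], regs)
        except ValueError as exc:
            raise ValueError(f"species {sp!r}: {exc}") from exc
        parsed_regions.append(regs)
    df = df[["species", "regions", "biome"]].copy()
    df["regions"] = parsed_regions
    df["biome"] = df["biome"].astype(str).str.strip().str.lower()
    table = AssignmentTable(df.reset_index(drop=True))
    counts = table.biome_counts()
    import logging
    logging.getLogger(__name__).info(
        "assignments: %d species (%s)", len(table),
        ", ".join(f"{k}={v}" for k, v in counts.items()))
    return table


def match_tree_to_assignments(
    tree: PhyloTree, table: AssignmentTable, space: StateSpace
) -> tuple[PhyloTree, dict[str, int], list[str]]:
    """Prune the tree to assigned species and index the tip states.

    Species matching is exact after whitespace normalisation.  Returns the
    pruned tree, a tip-label -> state-index map, and the list of dropped
    tips.  States outside ``space`` (e.g. ranges wider than max_range)
    raise a KeyError naming the species.
    """
    assigned = {s.strip() for s in table.species}
    tips = {t.strip(): t for t in tree.taxa}
    shared = sorted(set(tips) & assigned)
    if not shared:
        raise ValueError("no overlap between tree tips and assignments")
    dropped = sorted(set(tips) - assigned)
    pruned = tree.pruned_to({tips[s] for s in shared})
    states: dict[str, int] = {}
    for s in shared:
        st = table.state_of(s)
        try:
            states[tips[s]] = space.index_of(st)
        except KeyError:
            raise KeyError(
                f"species {s!r} has state {st} outside the state space "
                f"(max_range={space.max_range})") from None
    return pruned, states, dropped
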