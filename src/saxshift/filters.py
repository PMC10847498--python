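"""Per-locus sequence and alignment cleaning filters.

Three cleaning rules are applied to target-capture exon data before and
after alignment: an absolute minimum sequence length, a minimum length
relative to the median for the locus, and removal of alignment columns in
which almost every taxon is missing.  "Length" always means the ungapped
base count (gap ``-`` and ambiguous ``N`` characters excluded), which is
the only definition valid both before and after alignment.

Boundary semantics are strict: sequences *fewer than* ``min_len`` bases are
dropped, and columns where *more than* ``max_missing`` of the taxa carry no
information are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceSet",
    "drop_short",
    "drop_relative_short",
    "strip_gappy_sites",
    "ungapped_length",
]

_ALPHABET = set("ACGTN-")
_MISSING = set("N-")


def ungapped_length(seq: str) -> int:
    """Number of informative bases (everything except '-' and 'N')."""
    s = seq.upper()
    return sum(1 for ch in s if ch not in _MISSING)


@dataclass
class SequenceSet:
    """An ordered set of named nucleotide sequences (possibly aligned)."""

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dup}")
        for rid, seq in self.records:
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {rid!r}: illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def is_aligned(self) -> bool:
        lengths = {len(seq) for _, seq in self.records}
        return len(lengths) <= 1

    @classmethod
    def from_fasta(cls, handle_or_path) -> "SequenceSet":
        recs = [(r.id, str(r.seq)) for r in SeqIO.parse(handle_or_path, "fasta")]
        return cls(recs)

    def to_fasta(self, handle_or_path) -> None:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in self),
            handle_or_path, "fasta")


def drop_short(seqs: SequenceSet, min_len: int = 300) -> SequenceSet:
    """Remove sequences with fewer than ``min_len`` ungapped bases."""
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    kept = [(rid, s) for rid, s in seqs if ungapped_length(s) >= min_len]
    return SequenceSet(kept)


def drop_relative_short(seqs: SequenceSet, frac: float = 0.4) -> SequenceSet:
    """Remove sequences shorter than ``frac`` of the median ungapped length.

    The median is computed over the input set (even n: mean of the central
    pair).  A single pass is applied, matching how the rule is used in a
    cleaning pipeline.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    if len(seqs) == 0:
        return SequenceSet([])
    lengths = [ungapped_length(s) for _, s in seqs]
    threshold = frac * median(lengths)
    kept = [(rid, s) for (rid, s), ln in zip(seqs, lengths) if ln >= threshold]
    return SequenceSet(kept)


def strip_gappy_sites(aln: SequenceSet, max_missing: float = 0.95) -> SequenceSet:
    """Remove alignment columns where more than ``max_missing`` of the taxa
    have no information ('-' or 'N').

    A column at exactly the threshold (e.g. 19 of 20 taxa missing at 0.95)
    is kept; strictly more is removed.  Relative order of kept columns is
    preserved.
    """
    if len(aln) == 0:
        return SequenceSet([])
    if not aln.is_aligned():
        raise ValueError("ragged alignment: sequences differ in length")
    n_taxa = len(aln)
    seqs = [s.upper() for _, s in aln]
    width = len(seqs[0])
    keep_cols = []
    for j in range(width):
        missing = sum(1 for s in seqs if s[j] in _MISSING)
        if missing / n_taxa <= max_missing:
            keep_cols.append(j)
    out = []
    for (rid, _), s in zip(aln, seqs):
        out.append((rid, "".join(s[j] for j in keep_cols)))
    return SequenceSet(out)
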