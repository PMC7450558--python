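"""Core data model: genomic intervals and segmental-duplication (SD) records.

All coordinates are 0-based half-open throughout the package, following the
UCSC genomicSuperDups convention.  An :class:`SDRecord` describes one
annotated duplication as a *pair* of intervals plus a relative-orientation
flag; tables typically list each duplication twice (once anchored at each
side), and :func:`canonical_pair_key` collapses such mirror rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def as_tuple(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class SDRecord:
    """One segmental-duplication annotation row.

    ``strand`` is the *relative* orientation of the two copies: ``'+'`` when
    they run parallel, ``'-'`` when one copy is the reverse complement of the
    other.  No absolute per-side strand is modeled.
    """

    side_a: GenomeInterval
    side_b: GenomeInterval
    strand: str
    frac_match: float
    record_id: str = ""
    extra: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0.0 <= self.frac_match <= 1.0):
            raise ValueError(f"frac_match outside [0,1]: {self.frac_match}")

    def mirror(self) -> "SDRecord":
        """The same duplication anchored at the other side."""
        return replace(self, side_a=self.side_b, side_b=self.side_a)


def canonical_pair_key(record: SDRecord) -> str:
    """Side-order-invariant key identifying the duplication a record denotes.

    A record and its mirror produce the same key; ``frac_match`` and
    ``record_id`` are deliberately excluded (coordinates and orientation
    define the pair).
    """
    a = record.side_a.as_tuple()
    b = record.side_b.as_tuple()
    lo, hi = (a, b) if a <= b else (b, a)
    return f"{lo[0]}:{lo[1]}-{lo[2]}|{hi[0]}:{hi[1]}-{hi[2]}|{record.strand}"


class SDTable:
    """Ordered collection of :class:`SDRecord` with unique ``record_id``."""

    def __init__(
        self,
        records: Iterable[SDRecord] = (),
        source_dialect: str = "bedpe_min",
    ) -> None:
        self.records: list[SDRecord] = []
        self.source_dialect = source_dialect
        self._ids: set[str] = set()
        for rec in records:
            self.append(rec)

    def append(self, rec: SDRecord) -> None:
        rid = rec.record_id
        if rid:
            if rid in self._ids:
                raise ValueError(f"duplicate record_id: {rid}")
            self._ids.add(rid)
        else:
            rid = f"sd{len(self.records)}"
            while rid in self._ids:
                rid = rid + "_"
            self._ids.add(rid)
            rec = replace(rec, record_id=rid)
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SDRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SDRecord:
        return self.records[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SDTable):
            return NotImplemented
        return self.records == other.records

    def unique_pair_keys(self) -> set[str]:
        return {canonical_pair_key(r) for r in self.records}
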