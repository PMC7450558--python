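"""Filter cascade producing the working set of unique SDs.

The cascade removes, in fixed order: (1) low-homology records, (2) records
with a side on a non-canonical chromosome, (3) records with a side
overlapping exclusion regions (assembly gaps, centromeres, telomere pads),
(4) records in high-density SD windows, (5) records whose side belongs to a
highly repeated duplicon (many distinct partner loci), and finally collapses
mirror rows so each duplication is counted once.

The density and repetition masks are windowing/clustering formalizations of
"high density SD regions" and "> 4 repetitions"; both are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .model import GenomeInterval, SDRecord, SDTable, canonical_pair_key

CANONICAL_CHROMS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")

STAGES = (
    "low_homology",
    "non_canonical_chrom",
    "exclusion_overlap",
    "high_density",
    "high_repetition",
)


@dataclass
class FilterConfig:
    min_frac_match: float = 0.93
    canonical_chroms: tuple[str, ...] = CANONICAL_CHROMS
    density_window_bp: int = 1_000_000
    max_sds_per_window: int = 10
    max_repetitions: int = 4
    telomere_pad_bp: int = 500_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_frac_match <= 1.0):
            raise ValueError("min_frac_match outside [0,1]")
        for name in ("density_window_bp", "max_sds_per_window", "max_repetitions", "telomere_pad_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FilterReport:
    input_records: int
    removed_per_stage: dict[str, int] = field(default_factory=dict)
    unique_sds: int = 0

    @property
    def survivors(self) -> int:
        return self.input_records - sum(self.removed_per_stage.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_records": self.input_records,
                "removed_per_stage": self.removed_per_stage,
                "survivors": self.survivors,
                "unique_sds": self.unique_sds,
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"input records: {self.input_records}"]
        for stage, n in self.removed_per_stage.items():
            lines.append(f"  removed at {stage}: {n}")
        lines.append(f"survivors (before mirror collapse): {self.survivors}")
        lines.append(f"unique SDs: {self.unique_sds}")
        return "\n".join(lines)


def merge_intervals(intervals: Sequence[GenomeInterval]) -> list[GenomeInterval]:
    """Union of intervals, merged per chromosome, sorted."""
    out: list[GenomeInterval] = []
    by_chrom: dict[str, list[GenomeInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: x.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomeInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomeInterval(chrom, cur_s, cur_e))
    return out


def build_exclusion_regions(
    chrom_sizes: Mapping[str, int],
    gap_bed: Sequence[GenomeInterval] | None = None,
    config: FilterConfig | None = None,
) -> list[GenomeInterval]:
    """Exclusion set = provided gap/centromere intervals + telomere pads.

    Telomere pads ``[0, pad)`` and ``[len - pad, len)`` are added per
    chromosome only at ends where ``gap_bed`` supplies no telomeric entry
    (an interval anchored at the chromosome end in question).
    """
    config = config or FilterConfig()
    gaps = list(gap_bed or [])
    for iv in gaps:
        if iv.chrom not in chrom_sizes:
            raise ValueError(f"gap interval references unknown chromosome {iv.chrom}")
    pad = config.telomere_pad_bp
    out = list(gaps)
    for chrom, size in chrom_sizes.items():
        chrom_gaps = [g for g in gaps if g.chrom == chrom]
        has_start = any(g.start == 0 for g in chrom_gaps)
        has_end = any(g.end == size for g in chrom_gaps)
        if not has_start:
            out.append(GenomeInterval(chrom, 0, min(pad, size)))
        if not has_end:
            out.append(GenomeInterval(chrom, max(0, size - pad), size))
    return merge_intervals(out)


def _exclusion_trees(exclusions: Sequence[GenomeInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in exclusions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _overlaps_exclusion(trees: dict[str, IntervalTree], iv: GenomeInterval) -> bool:
    tree = trees.get(iv.chrom)
    return bool(tree and tree.overlap(iv.start, iv.end))


def _density_mask(records: list[SDRecord], config: FilterConfig) -> set[int]:
    """Indices of records with a side midpoint in an over-dense window.

    Windows of ``density_window_bp`` tile each chromosome with step
    window/2; a window counts the SD-side midpoints it contains.
    """
    w = config.density_window_bp
    step = w // 2
    mids: dict[str, list[tuple[int, int]]] = {}  # chrom -> [(midpoint, rec_idx)]
    for i, rec in enumerate(records):
        for side in (rec.side_a, rec.side_b):
            mids.setdefault(side.chrom, []).append((side.midpoint, i))
    masked: set[int] = set()
    for chrom, points in mids.items():
        counts: dict[int, int] = {}
        for pos, _ in points:
            for wi in _windows_of(pos, w, step):
                counts[wi] = counts.get(wi, 0) + 1
        hot = {wi for wi, n in counts.items() if n > config.max_sds_per_window}
        if not hot:
            continue
        for pos, i in points:
            if any(wi in hot for wi in _windows_of(pos, w, step)):
                masked.add(i)
    return masked


def _windows_of(pos: int, w: int, step: int) -> list[int]:
    """Window start indices (in units of step) whose window contains pos."""
    hi = pos // step
    lo = max(0, (pos - w) // step + 1)
    return [wi for wi in range(lo, hi + 1) if wi * step <= pos < wi * step + w]


def _reciprocal_overlap(a: GenomeInterval, b: GenomeInterval) -> bool:
    if a.chrom != b.chrom:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    return ov >= 0.5 * len(a) and ov >= 0.5 * len(b)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _repetition_mask(records: list[SDRecord], config: FilterConfig) -> set[int]:
    """Indices of records whose side belongs to a duplicon recurring too often.

    SD sides are clustered by >= 50% reciprocal overlap; a cluster's
    repetition count is the number of distinct partner-side clusters it
    pairs with.  Records with a side in a cluster exceeding
    ``max_repetitions`` are masked.
    """
    sides: list[tuple[GenomeInterval, int]] = []  # (interval, rec idx)
    for i, rec in enumerate(records):
        sides.append((rec.side_a, i))
        sides.append((rec.side_b, i))
    n = len(sides)
    uf = _UnionFind(n)
    # sweep per chromosome to avoid all-pairs comparison
    order = sorted(range(n), key=lambda j: (sides[j][0].chrom, sides[j][0].start))
    for a_pos, ja in enumerate(order):
        iv_a = sides[ja][0]
        for jb in order[a_pos + 1:]:
            iv_b = sides[jb][0]
            if iv_b.chrom != iv_a.chrom or iv_b.start >= iv_a.end:
                break
            if _reciprocal_overlap(iv_a, iv_b):
                uf.union(ja, jb)
    partners: dict[int, set[int]] = {}
    for i in range(len(records)):
        ca = uf.find(2 * i)
        cb = uf.find(2 * i + 1)
        partners.setdefault(ca, set()).add(cb)
        partners.setdefault(cb, set()).add(ca)
    hot_clusters = {c for c, p in partners.items() if len(p) > config.max_repetitions}
    masked = set()
    for i in range(len(records)):
        if uf.find(2 * i) in hot_clusters or uf.find(2 * i + 1) in hot_clusters:
            masked.add(i)
    return masked


def apply_filters(
    table: SDTable,
    config: FilterConfig | None = None,
    exclusions: Sequence[GenomeInterval] | None = None,
) -> tuple[SDTable, FilterReport]:
    """Run the filter cascade; returns surviving unique SDs and a stage report."""
    config = config or FilterConfig()
    report = FilterReport(input_records=len(table))
    records = list(table.records)

    keep = [r for r in records if r.frac_match >= config.min_frac_match]
    report.removed_per_stage["low_homology"] = len(records) - len(keep)
    records = keep

    canon = set(config.canonical_chroms)
    keep = [r for r in records if r.side_a.chrom in canon and r.side_b.chrom in canon]
    report.removed_per_stage["non_canonical_chrom"] = len(records) - len(keep)
    records = keep

    trees = _exclusion_trees(exclusions or [])
    keep = [
        r for r in records
        if not (_overlaps_exclusion(trees, r.side_a) or _overlaps_exclusion(trees, r.side_b))
    ]
    report.removed_per_stage["exclusion_overlap"] = len(records) - len(keep)
    records = keep

    masked = _density_mask(records, config)
    keep = [r for i, r in enumerate(records) if i not in masked]
    report.removed_per_stage["high_density"] = len(records) - len(keep)
    records = keep

    masked = _repetition_mask(records, config)
    keep = [r for i, r in enumerate(records) if i not in masked]
    report.removed_per_stage["high_repetition"] = len(records) - len(keep)
    records = keep

    seen: set[str] = set()
    out = SDTable(source_dialect=table.source_dialect)
    for rec in records:
        key = canonical_pair_key(rec)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    report.unique_sds = len(out)
    return out, report
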