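"""Scan for SD pairs carrying the circular-intermediate block-order flip.

A duplication produced through a circular DNA intermediate turns the donor
block order A-B/C-D into B-A/D-C in the derivative copy: the donor sides of
the two SD records are adjacent at the opening point B/C, while their
derivative sides are adjacent in *swapped* order, fusing the donor ends at
the A/D junction.  :func:`scan_pairs` tests every SD pair for this
geometry, :func:`extend_blocks` grows hits into full duplication clusters,
and :func:`summarize_clusters` emits the per-cluster size/distance summary.

Decoy rearrangements are rejected by construction: a tandem duplication
yields plain (unswapped) adjacency, and a transposition followed by a single
inversion yields B-A/C-D order with mixed orientation flags.
"""

from __future__ import annotations

import statistics
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import GenomeInterval, SDRecord, SDTable, canonical_pair_key


@dataclass
class ScanConfig:
    gap_tol_bp: int = 10_000
    overlap_tol_bp: int = 100
    min_block_bp: int = 1_000
    merge_tol_bp: int = 50_000

    def __post_init__(self) -> None:
        for name in ("gap_tol_bp", "overlap_tol_bp", "min_block_bp", "merge_tol_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class FlipCandidate:
    """An SD pair satisfying the B/C flip predicate.

    ``p`` anchors the A-B block and ``q`` the C-D block, both re-anchored so
    ``side_a`` is the (arbitrarily assigned) donor side.  Polarity is not
    resolved here; cross-species evidence is needed for that.
    """

    p: SDRecord
    q: SDRecord
    donor_junction: GenomeInterval
    derivative_junction: GenomeInterval
    orientation: str  # parallel | inverted
    donor_gap_bp: int
    derivative_gap_bp: int

    @property
    def rank_score(self) -> int:
        return abs(self.donor_gap_bp) + abs(self.derivative_gap_bp)


@dataclass
class CSDPCluster:
    donor_span: GenomeInterval
    derivative_span: GenomeInterval
    blocks_ab: list[SDRecord] = field(default_factory=list)
    blocks_cd: list[SDRecord] = field(default_factory=list)
    bc_point: int = 0
    ad_point: int = 0
    alpha_beta: GenomeInterval | None = None
    orientation: str = "parallel"
    inter_chromosomal: bool = False
    distance_mb: float | None = None
    pattern_call: object | None = None
    cluster_id: str = ""

    @property
    def size_kb(self) -> float:
        return len(self.donor_span) / 1000.0


def _point_interval(chrom: str, a: int, b: int) -> GenomeInterval:
    lo, hi = (a, b) if a <= b else (b, a)
    if hi == lo:
        hi = lo + 1
    return GenomeInterval(chrom, max(0, lo), hi)


def _views(record: SDRecord) -> list[tuple[GenomeInterval, GenomeInterval, SDRecord]]:
    """Both donor-side assignments of a record: (donor, derivative, anchored record)."""
    return [
        (record.side_a, record.side_b, record),
        (record.side_b, record.side_a, record.mirror()),
    ]


def flip_predicate(
    p_donor: GenomeInterval,
    p_deriv: GenomeInterval,
    q_donor: GenomeInterval,
    q_deriv: GenomeInterval,
    strand_p: str,
    strand_q: str,
    config: ScanConfig,
) -> bool:
    """The B/C flip geometry test for an ordered view pair (P=A-B, Q=C-D)."""
    if strand_p != strand_q:
        return False
    if p_donor.chrom != q_donor.chrom or p_deriv.chrom != q_deriv.chrom:
        return False
    donor_gap = q_donor.start - p_donor.end
    if not (-config.overlap_tol_bp <= donor_gap <= config.gap_tol_bp):
        return False
    if strand_p == "+":
        deriv_gap = p_deriv.start - q_deriv.end
    else:
        deriv_gap = q_deriv.start - p_deriv.end
    return -config.overlap_tol_bp <= deriv_gap <= config.gap_tol_bp


def _make_candidate(
    p_donor: GenomeInterval,
    p_deriv: GenomeInterval,
    q_donor: GenomeInterval,
    q_deriv: GenomeInterval,
    p_rec: SDRecord,
    q_rec: SDRecord,
) -> FlipCandidate:
    orientation = "parallel" if p_rec.strand == "+" else "inverted"
    donor_gap = q_donor.start - p_donor.end
    if orientation == "parallel":
        deriv_gap = p_deriv.start - q_deriv.end
        deriv_junction = _point_interval(p_deriv.chrom, q_deriv.end, p_deriv.start)
    else:
        deriv_gap = q_deriv.start - p_deriv.end
        deriv_junction = _point_interval(p_deriv.chrom, p_deriv.end, q_deriv.start)
    return FlipCandidate(
        p=p_rec,
        q=q_rec,
        donor_junction=_point_interval(p_donor.chrom, p_donor.end, q_donor.start),
        derivative_junction=deriv_junction,
        orientation=orientation,
        donor_gap_bp=donor_gap,
        derivative_gap_bp=deriv_gap,
    )


def _candidate_sort_key(c: FlipCandidate):
    return (
        c.donor_junction.chrom, c.donor_junction.start,
        c.derivative_junction.chrom, c.derivative_junction.start,
    )


def scan_pairs(table: SDTable, config: ScanConfig | None = None) -> list[FlipCandidate]:
    """All SD pairs satisfying the flip predicate, mirror hits collapsed.

    Both side assignments of every record are tested (donor/derivative
    labelling is symmetric at this stage).  Records with a side shorter than
    ``min_block_bp`` are ignored.  Candidates are returned ranked by junction
    tightness (|donor gap| + |derivative gap|), ties broken by coordinates.
    """
    config = config or ScanConfig()
    views: list[tuple[GenomeInterval, GenomeInterval, SDRecord]] = []
    for rec in table:
        if len(rec.side_a) < config.min_block_bp or len(rec.side_b) < config.min_block_bp:
            continue
        views.extend(_views(rec))

    # index views by donor chromosome, sorted by donor start
    by_chrom: dict[str, list[tuple[GenomeInterval, GenomeInterval, SDRecord]]] = {}
    for v in views:
        by_chrom.setdefault(v[0].chrom, []).append(v)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda v: v[0].start)

    best: dict[frozenset, FlipCandidate] = {}
    for p_donor, p_deriv, p_rec in views:
        group = by_chrom.get(p_donor.chrom, [])
        starts = [v[0].start for v in group]
        lo = bisect_left(starts, p_donor.end - config.overlap_tol_bp)
        hi = bisect_right(starts, p_donor.end + config.gap_tol_bp)
        for q_donor, q_deriv, q_rec in group[lo:hi]:
            if canonical_pair_key(p_rec) == canonical_pair_key(q_rec):
                continue  # p != q: a record never pairs with itself/its mirror
            if not flip_predicate(
                p_donor, p_deriv, q_donor, q_deriv, p_rec.strand, q_rec.strand, config
            ):
                continue
            cand = _make_candidate(p_donor, p_deriv, q_donor, q_deriv, p_rec, q_rec)
            key = frozenset((canonical_pair_key(p_rec), canonical_pair_key(q_rec)))
            prev = best.get(key)
            if prev is None or _candidate_sort_key(cand) < _candidate_sort_key(prev):
                best[key] = cand
    out = sorted(best.values(), key=lambda c: (c.rank_score,) + _candidate_sort_key(c))
    return out


def scan_pairs_bruteforce(table: SDTable, config: ScanConfig | None = None) -> list[FlipCandidate]:
    """Naive all-ordered-pairs evaluation of the flip predicate (reference path)."""
    config = config or ScanConfig()
    views = []
    for rec in table:
        if len(rec.side_a) < config.min_block_bp or len(rec.side_b) < config.min_block_bp:
            continue
        views.extend(_views(rec))
    best: dict[frozenset, FlipCandidate] = {}
    for p_donor, p_deriv, p_rec in views:
        for q_donor, q_deriv, q_rec in views:
            if canonical_pair_key(p_rec) == canonical_pair_key(q_rec):
                continue
            if not flip_predicate(
                p_donor, p_deriv, q_donor, q_deriv, p_rec.strand, q_rec.strand, config
            ):
                continue
            cand = _make_candidate(p_donor, p_deriv, q_donor, q_deriv, p_rec, q_rec)
            key = frozenset((canonical_pair_key(p_rec), canonical_pair_key(q_rec)))
            prev = best.get(key)
            if prev is None or _candidate_sort_key(cand) < _candidate_sort_key(prev):
                best[key] = cand
    return sorted(best.values(), key=lambda c: (c.rank_score,) + _candidate_sort_key(c))


def _hull(intervals: Iterable[GenomeInterval]) -> GenomeInterval:
    ivs = list(intervals)
    return GenomeInterval(ivs[0].chrom, min(i.start for i in ivs), max(i.end for i in ivs))


def _near(iv: GenomeInterval, span: GenomeInterval, tol: int) -> bool:
    if iv.chrom != span.chrom:
        return False
    return iv.start <= span.end + tol and span.start <= iv.end + tol


def extend_blocks(
    candidate: FlipCandidate, table: SDTable, config: ScanConfig | None = None
) -> CSDPCluster:
    """Grow a candidate into a cluster by absorbing co-local member SDs.

    A record is absorbed only when its donor-side interval lies within
    ``merge_tol_bp`` of the current donor span AND its mate lies within the
    tolerance of the current derivative span (both-sides condition).  Runs to
    a fixed point; re-running on the output adds nothing.
    """
    config = config or ScanConfig()
    members = {canonical_pair_key(candidate.p), canonical_pair_key(candidate.q)}
    blocks_ab = [candidate.p]
    blocks_cd = [candidate.q]
    donor_span = _hull([candidate.p.side_a, candidate.q.side_a])
    deriv_span = _hull([candidate.p.side_b, candidate.q.side_b])
    bc_point = candidate.donor_junction.midpoint
    ad_point = candidate.derivative_junction.midpoint

    changed = True
    while changed:
        changed = False
        for rec in table:
            key = canonical_pair_key(rec)
            if key in members:
                continue
            for d_iv, m_iv, anchored in _views(rec):
                if _near(d_iv, donor_span, config.merge_tol_bp) and _near(
                    m_iv, deriv_span, config.merge_tol_bp
                ):
                    if d_iv.midpoint < bc_point:
                        blocks_ab.append(anchored)
                    else:
                        blocks_cd.append(anchored)
                    members.add(key)
                    donor_span = _hull([donor_span, d_iv])
                    deriv_span = _hull([deriv_span, m_iv])
                    changed = True
                    break

    inter = donor_span.chrom != deriv_span.chrom
    if inter:
        dist = None
    else:
        gap = max(donor_span.start, deriv_span.start) - min(donor_span.end, deriv_span.end)
        dist = max(0, gap) / 1e6
    return CSDPCluster(
        donor_span=donor_span,
        derivative_span=deriv_span,
        blocks_ab=blocks_ab,
        blocks_cd=blocks_cd,
        bc_point=bc_point,
        ad_point=ad_point,
        alpha_beta=deriv_span,
        orientation=candidate.orientation,
        inter_chromosomal=inter,
        distance_mb=dist,
    )


def summarize_clusters(clusters: Sequence[CSDPCluster]) -> dict:
    """Per-cluster size/distance rows plus aggregate statistics.

    Sizes are donor-span lengths in Kb; distances are donor-derivative
    separations in Mb for intra-chromosomal clusters (inter-chromosomal
    clusters are flagged and excluded from distance aggregates).
    """
    if not clusters:
        raise ValueError("no clusters to summarize")
    rows = []
    for i, c in enumerate(clusters):
        rows.append(
            {
                "cluster": c.cluster_id or f"cluster{i + 1}",
                "size_kb": c.size_kb,
                "distance_mb": None if c.inter_chromosomal else c.distance_mb,
                "inter_chromosomal": c.inter_chromosomal,
            }
        )
    sizes = [r["size_kb"] for r in rows]
    dists = [r["distance_mb"] for r in rows if r["distance_mb"] is not None]
    summary = {
        "n_clusters": len(rows),
        "size_kb_median": statistics.median(sizes),
        "size_kb_min": min(sizes),
        "size_kb_max": max(sizes),
        "n_intra_chromosomal": len(dists),
        "rows": rows,
    }
    if dists:
        summary.update(
            distance_mb_mean=sum(dists) / len(dists),
            distance_mb_min=min(dists),
            distance_mb_max=max(dists),
        )
    return summary
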