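"""Flip-pair scan, cluster extension and summary statistics."""

from __future__ import annotations

import numpy as np
import pytest

from cdip import (
    CSDPCluster,
    GenomeInterval,
    ScanConfig,
    SDRecord,
    SDTable,
    extend_blocks,
    scan_pairs,
    summarize_clusters,
)

P = SDRecord(GenomeInterval("chr1", 1_000, 5_000), GenomeInterval("chr1", 95_000, 99_000),
             "+", 0.95, "P")
Q_FLIP = SDRecord(GenomeInterval("chr1", 5_010, 9_000), GenomeInterval("chr1", 91_000, 94_990),
                  "+", 0.95, "Q")
Q_PLAIN = SDRecord(GenomeInterval("chr1", 5_010, 9_000), GenomeInterval("chr1", 99_010, 103_000),
                   "+", 0.95, "Qp")
Q_MIXED = SDRecord(GenomeInterval("chr1", 5_010, 9_000), GenomeInterval("chr1", 91_000, 94_990),
                   "-", 0.95, "Qm")


class TestFlipPredicate:
    def test_swapped_adjacency_detected(self):
        cands = scan_pairs(SDTable([P, Q_FLIP]))
        assert len(cands) == 1
        c = cands[0]
        assert c.donor_gap_bp == 10
        assert c.derivative_gap_bp == 10
        assert c.donor_junction.midpoint == 5_005
        assert c.derivative_junction.midpoint == 94_995
        assert c.orientation == "parallel"

    def test_plain_adjacency_is_not_a_flip(self):
        # derivative order A-B then C-D: an ordinary duplication, no swap
        assert scan_pairs(SDTable([P, Q_PLAIN])) == []

    def test_mixed_orientation_rejected(self):
        # transposition + single inversion geometry (B-A/C-D): mixed flags
        assert scan_pairs(SDTable([P, Q_MIXED])) == []

    def test_inverted_pair_uses_reversed_derivative_adjacency(self):
        p = SDRecord(GenomeInterval("chr1", 1_000, 5_000),
                     GenomeInterval("chr2", 50_000, 54_000), "-", 0.95, "pi")
        q = SDRecord(GenomeInterval("chr1", 5_000, 9_000),
                     GenomeInterval("chr2", 54_000, 58_000), "-", 0.95, "qi")
        cands = scan_pairs(SDTable([p, q]))
        assert len(cands) == 1
        assert cands[0].orientation == "inverted"

    def test_record_never_pairs_with_its_own_mirror(self):
        rec = SDRecord(GenomeInterval("chr1", 1_000, 5_000),
                       GenomeInterval("chr1", 5_010, 9_000), "+", 0.95, "solo")
        assert scan_pairs(SDTable([rec, rec.mirror().__class__(
            rec.side_b, rec.side_a, rec.strand, rec.frac_match, "solo_m")])) == []

    def test_short_blocks_ignored(self):
        short = SDRecord(GenomeInterval("chr1", 4_500, 5_000),
                         GenomeInterval("chr1", 95_000, 95_500), "+", 0.95, "s")
        assert scan_pairs(SDTable([P, short])) == []


def _random_table(n, seed, chroms=("chr1", "chr2")):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        ca, cb = rng.choice(list(chroms), size=2)
        sa = int(rng.integers(0, 60)) * 1_000
        sb = int(rng.integers(0, 60)) * 1_000
        la = int(rng.integers(1, 6)) * 1_000
        lb = int(rng.integers(1, 6)) * 1_000
        recs.append(SDRecord(GenomeInterval(ca, sa, sa + la), GenomeInterval(cb, sb, sb + lb),
                             str(rng.choice(["+", "-"])), 0.95, f"r{i}"))
    return SDTable(recs)


def _oracle_pair_set(table, gap_tol=10_000, overlap_tol=100, min_block=1_000):
    """Independent all-ordered-pairs evaluation of the flip geometry."""

    def key(rec):
        sides = sorted([rec.side_a.as_tuple(), rec.side_b.as_tuple()])
        return (tuple(sides[0]), tuple(sides[1]), rec.strand)

    views = []
    for rec in table:
        if len(rec.side_a) < min_block or len(rec.side_b) < min_block:
            continue
        views.append((rec.side_a, rec.side_b, rec))
        views.append((rec.side_b, rec.side_a, rec))
    hits = set()
    for pd, pv, pr in views:
        for qd, qv, qr in views:
            if key(pr) == key(qr) or pr.strand != qr.strand:
                continue
            if pd.chrom != qd.chrom or pv.chrom != qv.chrom:
                continue
            if not (-overlap_tol <= qd.start - pd.end <= gap_tol):
                continue
            gap2 = pv.start - qv.end if pr.strand == "+" else qv.start - pv.end
            if not (-overlap_tol <= gap2 <= gap_tol):
                continue
            hits.add(frozenset((key(pr), key(qr))))
    return hits


class TestScanOracleEquivalence:
    @pytest.mark.parametrize("n,seed", [(60, 0), (200, 1), (500, 2)])
    def test_scan_matches_bruteforce_predicate(self, n, seed):
        table = _random_table(n, seed)
        cands = scan_pairs(table)

        def key(rec):
            sides = sorted([rec.side_a.as_tuple(), rec.side_b.as_tuple()])
            return (tuple(sides[0]), tuple(sides[1]), rec.strand)

        got = {frozenset((key(c.p), key(c.q))) for c in cands}
        assert got == _oracle_pair_set(table)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_mirrored_table_yields_same_candidates(self, seed):
        table = _random_table(150, seed)
        mirrored = SDTable(
            [SDRecord(r.side_b, r.side_a, r.strand, r.frac_match, r.record_id) for r in table]
        )

        def sig(c):
            return (c.donor_junction.as_tuple(), c.derivative_junction.as_tuple(),
                    c.orientation)

        assert sorted(map(sig, scan_pairs(table))) == sorted(map(sig, scan_pairs(mirrored)))


class TestExtension:
    def test_isolated_candidate_is_a_fixed_point(self):
        table = SDTable([P, Q_FLIP])
        cluster = extend_blocks(scan_pairs(table)[0], table)
        assert {r.record_id for r in cluster.blocks_ab} == {"P"}
        assert {r.record_id for r in cluster.blocks_cd} == {"Q"}
        assert cluster.donor_span == GenomeInterval("chr1", 1_000, 9_000)

    def test_abutting_sd_with_consistent_mate_absorbed(self):
        extra = SDRecord(GenomeInterval("chr1", 200, 990),
                         GenomeInterval("chr1", 99_010, 99_800), "+", 0.95, "X")
        table = SDTable([P, Q_FLIP, extra])
        cluster = extend_blocks(scan_pairs(table)[0], table)
        assert "X" in {r.record_id for r in cluster.blocks_ab}
        assert cluster.donor_span.start == 200

    def test_donor_side_only_neighbor_not_absorbed(self):
        # mate on an unrelated chromosome: the both-sides condition fails
        stray = SDRecord(GenomeInterval("chr1", 200, 990),
                         GenomeInterval("chr2", 500_000, 500_800), "+", 0.95, "S")
        table = SDTable([P, Q_FLIP, stray])
        cluster = extend_blocks(scan_pairs(table)[0], table)
        assert "S" not in {r.record_id for r in cluster.blocks_ab + cluster.blocks_cd}

    def test_extension_fixed_point(self):
        extra = SDRecord(GenomeInterval("chr1", 200, 990),
                         GenomeInterval("chr1", 99_010, 99_800), "+", 0.95, "X")
        table = SDTable([P, Q_FLIP, extra])
        c1 = extend_blocks(scan_pairs(table)[0], table)
        c2 = extend_blocks(scan_pairs(table)[0], table)
        assert c1.donor_span == c2.donor_span
        assert c1.derivative_span == c2.derivative_span
        # transitive-closure oracle: repeated naive passes reach the same hull
        members = {"P", "Q", "X"}
        assert {r.record_id for r in c1.blocks_ab + c1.blocks_cd} == members


def _cluster(size_kb, distance_mb=None, chrom="chr1"):
    donor = GenomeInterval(chrom, 1_000_000, 1_000_000 + int(size_kb * 1000))
    if distance_mb is None:
        deriv = GenomeInterval("chr9", 500_000, 500_000 + int(size_kb * 1000))
    else:
        start = donor.end + int(distance_mb * 1e6)
        deriv = GenomeInterval(chrom, start, start + int(size_kb * 1000))
    return CSDPCluster(donor_span=donor, derivative_span=deriv,
                       inter_chromosomal=distance_mb is None,
                       distance_mb=distance_mb)


# the 16 ancestral sizes (Kb) and the 12 intra-chromosomal distances (Mb)
# of the characterized duplication pairs
SIZES_KB = [107, 131, 244, 82, 250, 3918, 22, 83, 40, 91, 84, 203, 152, 145, 76, 57]
DISTANCES_MB = [1.83, 2.45, 58.48, 13.12, 9.40, 51.60, 1.09, 1.26, 8.18, 0.09, 45.74, 2.13]


class TestClusterSummary:
    def test_reference_size_and_distance_statistics(self):
        dist_iter = iter(DISTANCES_MB)
        clusters = []
        inter = {244, 3918, 203, 152}
        for size in SIZES_KB:
            clusters.append(_cluster(size, None if size in inter else next(dist_iter)))
        summary = summarize_clusters(clusters)
        assert summary["size_kb_median"] == pytest.approx(99.0)
        assert summary["size_kb_min"] == pytest.approx(22.0)
        assert summary["size_kb_max"] == pytest.approx(3918.0)
        assert summary["distance_mb_mean"] == pytest.approx(16.28, abs=0.005)
        assert summary["distance_mb_min"] == pytest.approx(0.09)
        assert summary["distance_mb_max"] == pytest.approx(58.48)

    def test_median_agrees_with_sorting_oracle(self):
        rng = np.random.default_rng(9)
        sizes = [float(x) for x in rng.integers(20, 4000, size=17)]
        clusters = [_cluster(s, float(rng.uniform(0.1, 60))) for s in sizes]
        summary = summarize_clusters(clusters)
        ordered = sorted(sizes)
        assert summary["size_kb_median"] == pytest.approx(ordered[len(ordered) // 2])
        dists = [c.distance_mb for c in clusters]
        assert summary["distance_mb_mean"] == pytest.approx(sum(dists) / len(dists))

    def test_single_cluster_degenerate(self):
        summary = summarize_clusters([_cluster(100, 5.0)])
        assert summary["size_kb_median"] == summary["size_kb_min"] == summary["size_kb_max"] == 100

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_clusters([])
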