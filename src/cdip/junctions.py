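"""Single-nucleotide resolution of duplication breakpoint junctions.

A circular-intermediate duplication leaves three informative seams: the
fusion of the donor ends (A/D) inside the derivative copy, and the two
insertion junctions at the acceptor site (β-C and B-α).  Each junction is
resolved by splitting a derivative window (the *junction read*) into a part
explained by the left reference and a part explained by the right reference,
minimizing mismatches plus gap penalties over all split assignments.  The
scar vocabulary follows breakpoint genomics: blunt join, junctional
microhomology (bases attributable to both references), untemplated
insertion, and flank deletions.  Microhomology and insertion are mutually
exclusive at one junction.

The module also provides the ±500 bp flank homology screen that excludes a
non-allelic homologous recombination origin (flanks sharing long homology or
harbouring short inverted repeats would be NAHR-compatible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._seq import encode, revcomp, validate_dna
from .model import GenomeInterval

SCAR_CLASSES = ("blunt", "microhomology", "insertion", "deletion", "complex")

#: gap penalty per gap base, in units of one mismatch.  Chosen strictly
#: between 0.5 and 1.0 so a single flank mismatch is never reinterpreted as
#: a 1 bp deletion + 1 bp insertion (cost 2*gp > 1) while a true m bp
#: insertion is never absorbed as mismatches (gp*m < m).
GAP_PENALTY = 0.75
_GP4 = 3  # gap penalty in quarter-mismatch integer units (4 * 0.75)


class AnchorError(ValueError):
    """The junction read does not align to the references at this locus."""


@dataclass
class JunctionInput:
    """References and derivative read around one breakpoint junction.

    ``left_reference`` runs up to and beyond the left-side breakpoint (e.g.
    the ancestral D end followed by its external downstream flank);
    ``left_break`` is the 0-based index of that nominal breakpoint, so
    ``left_reference[:left_break]`` is breakpoint-proximal.  Symmetrically
    ``right_reference[right_break:]`` starts at the right-side breakpoint
    (e.g. the ancestral A start), preceded by external upstream flank.
    ``junction_read`` is the derivative window spanning the junction.
    """

    left_reference: str
    right_reference: str
    junction_read: str
    left_break: int
    right_break: int

    def __post_init__(self) -> None:
        validate_dna(self.left_reference, "left_reference")
        validate_dna(self.right_reference, "right_reference")
        validate_dna(self.junction_read, "junction_read")
        if not (0 < self.left_break <= len(self.left_reference)):
            raise ValueError("left_break outside left_reference")
        if not (0 <= self.right_break < len(self.right_reference)):
            raise ValueError("right_break outside right_reference")

    def mirrored(self) -> "JunctionInput":
        """The reverse-complemented junction (left/right roles swap)."""
        return JunctionInput(
            left_reference=revcomp(self.right_reference),
            right_reference=revcomp(self.left_reference),
            junction_read=revcomp(self.junction_read),
            left_break=len(self.right_reference) - self.right_break,
            right_break=len(self.left_reference) - self.left_break,
        )


@dataclass
class JunctionScar:
    split_left: int
    split_right: int
    mh_len: int = 0
    ins_seq: str = ""
    del_left_bp: int = 0
    del_right_bp: int = 0
    scar_class: str = "blunt"
    alignment_mismatches: int = 0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mh_len > 0 and self.ins_seq:
            raise ValueError("microhomology and insertion are mutually exclusive")


def _classify(mh: int, ins: str, del_l: int, del_r: int) -> str:
    if mh > 0 and ins:
        return "complex"
    if ins:
        return "insertion"
    if mh > 0:
        return "microhomology"
    if del_l > 0 or del_r > 0:
        return "deletion"
    return "blunt"


def _left_costs(read: np.ndarray, ref: np.ndarray, brk: int, max_del: int):
    """Best cost of explaining each read prefix by the left reference.

    Returns ``(cost4, dels)`` where ``cost4[s]`` is the minimal quarter-unit
    cost (4*mismatches + 3*deletion) of aligning ``read[:s]`` gap-free to a
    reference window ending at ``brk - dels[s]``, over deletions 0..max_del.
    Unreachable splits hold a sentinel max value.  Work is organised by
    diagonal offset d (read[i] vs ref[i+d]) so one prefix-sum serves all s.
    """
    n = len(read)
    big = np.iinfo(np.int64).max
    best = np.full(n + 1, big, dtype=np.int64)
    best_del = np.zeros(n + 1, dtype=np.int64)
    s_all = np.arange(n + 1)
    d_lo = max(0, brk - max_del - n)
    # descending d = ascending deletion, so ties keep the smallest deletion
    for d in range(min(brk, len(ref)), d_lo - 1, -1):
        m = min(n, len(ref) - d)  # longest prefix comparable at this offset
        if m < 0:
            continue
        mism = np.concatenate(
            ([0], np.cumsum((read[:m] != ref[d : d + m]).astype(np.int64)))
        )
        s = s_all[: m + 1]
        dl = brk - s - d  # deletion implied by ending the alignment at s + d
        valid = (dl >= 0) & (dl <= max_del)
        cost = np.where(valid, 4 * mism + _GP4 * np.maximum(dl, 0), big)
        upd = cost < best[: m + 1]
        best[: m + 1][upd] = cost[upd]
        best_del[: m + 1][upd] = dl[upd]
    return best, best_del


def _right_costs(read: np.ndarray, ref: np.ndarray, brk: int, max_del: int):
    """Best cost of explaining each read suffix by the right reference.

    ``cost4[s]`` is the minimal cost of aligning ``read[s:]`` gap-free to the
    reference starting at ``brk + dels[s]``, over deletions 0..max_del.
    """
    n = len(read)
    big = np.iinfo(np.int64).max
    best = np.full(n + 1, big, dtype=np.int64)
    best_del = np.zeros(n + 1, dtype=np.int64)
    s_all = np.arange(n + 1)
    # ascending d = ascending deletion at fixed s: ties keep the smallest
    for d in range(brk - n, brk + max_del + 1):
        if n + d > len(ref):
            continue  # the suffix alignment would run past the reference end
        lo_i = max(0, -d)  # first comparable read index at this offset
        diff = (read[lo_i:n] != ref[lo_i + d : n + d]).astype(np.int64)
        ssum = np.concatenate((np.cumsum(diff[::-1])[::-1], [0]))
        s = s_all[lo_i:]
        dr = s + d - brk
        valid = (dr >= 0) & (dr <= max_del)
        cost = np.where(valid, 4 * ssum + _GP4 * np.maximum(dr, 0), big)
        upd = cost < best[lo_i:]
        best[lo_i:][upd] = cost[upd]
        best_del[lo_i:][upd] = dr[upd]
    return best, best_del


def resolve_junction(
    inp: JunctionInput,
    min_anchor: int = 20,
    max_ins: int = 50,
    max_del: int = 100,
) -> JunctionScar:
    """Resolve one junction into a scar call.

    Over all split pairs ``s_l <= s_r`` with ``s_r - s_l <= max_ins`` and all
    flank deletions up to ``max_del``, minimizes flank mismatches plus gap
    penalties; ties are broken deterministically toward the leftmost split
    and the smallest deletions.  An apparent flank deletion whose skipped
    reference bases are all present in the read adjacent to the breakpoint
    (i.e. they align perfectly to *both* references) is reclaimed as
    junctional microhomology.
    """
    L = inp.left_reference.upper()
    R = inp.right_reference.upper()
    read = inp.junction_read.upper()
    n = len(read)
    if n < 2 * min_anchor:
        raise AnchorError(f"junction read shorter than 2 x min_anchor ({n} < {2 * min_anchor})")

    er = encode(read)
    el = encode(L)
    err = encode(R)
    lcost, ldel = _left_costs(er, el, inp.left_break, max_del)
    rcost, rdel = _right_costs(er, err, inp.right_break, max_del)

    big = np.iinfo(np.int64).max
    best = (big, -1, -1)
    for s_l in range(0, n + 1):
        if lcost[s_l] >= big:
            continue
        hi = min(n, s_l + max_ins)
        for s_r in range(s_l, hi + 1):
            if rcost[s_r] >= big:
                continue
            c = lcost[s_l] + rcost[s_r] + _GP4 * (s_r - s_l)
            if (c, s_l, s_r) < best:
                best = (c, s_l, s_r)
    cost, s_l, s_r = best
    if s_l < 0:
        raise AnchorError("no feasible split (references too short for this read)")

    del_l = int(ldel[s_l])
    del_r = int(rdel[s_r])
    e_l = inp.left_break - del_l  # left alignment end in L
    b_r = inp.right_break + del_r  # right alignment start in R
    ins = read[s_l:s_r]
    mism = (int(cost) - _GP4 * (del_l + del_r + len(ins))) // 4

    # anchor sanity: the outer min_anchor bases of the read must match their
    # reference windows within a 25% mismatch budget
    left_anchor = sum(
        1 for t in range(min(min_anchor, s_l)) if read[t] != L[e_l - s_l + t]
    )
    right_anchor = sum(
        1
        for t in range(min(min_anchor, n - s_r))
        if read[n - 1 - t] != R[b_r + (n - s_r) - 1 - t]
    )
    if s_l < min_anchor or n - s_r < min_anchor:
        raise AnchorError("breakpoint too close to the read edge to anchor both flanks")
    if left_anchor > 0.25 * min_anchor or right_anchor > 0.25 * min_anchor:
        raise AnchorError("flank anchors do not align to the references at this locus")

    # microhomology reclaim: an apparent deletion fully explained by read
    # bases matching both references is a junctional microhomology
    mh = 0
    if not ins:
        s = s_l
        if del_l > 0:
            m_f = 0
            while (
                m_f < del_l and s + m_f < n and e_l + m_f < len(L)
                and read[s + m_f] == L[e_l + m_f]
            ):
                m_f += 1
            if m_f == del_l:
                mh += del_l
                del_l = 0
        if del_r > 0:
            m_b = 0
            while (
                m_b < del_r and s - 1 - m_b >= 0 and b_r - 1 - m_b >= 0
                and read[s - 1 - m_b] == R[b_r - 1 - m_b]
            ):
                m_b += 1
            if m_b == del_r:
                mh += del_r
                del_r = 0

    scar_class = _classify(mh, ins, del_l, del_r)
    return JunctionScar(
        split_left=s_l,
        split_right=s_r,
        mh_len=mh,
        ins_seq=ins,
        del_left_bp=del_l,
        del_right_bp=del_r,
        scar_class=scar_class,
        alignment_mismatches=mism,
        diagnostics={"cost4": int(cost), "e_l": e_l, "b_r": b_r},
    )


# ---------------------------------------------------------------------------
# cluster-level junction extraction
# ---------------------------------------------------------------------------


@dataclass
class JunctionGeometry:
    """Breakpoint-level geometry of one duplication event.

    ``donor`` is the ancestral A..D span, ``opening`` the B/C point inside
    it, ``derivative`` the inserted copy's span, ``orientation`` whether the
    copy is inserted parallel or reverse-complemented.  ``ad_offset`` is the
    position of the A/D seam within the derivative (bp from its start); when
    omitted it is inferred from the opening point.
    """

    donor: GenomeInterval
    opening: int
    derivative: GenomeInterval
    orientation: str = "parallel"
    ad_offset: int | None = None

    def __post_init__(self) -> None:
        if not (self.donor.start < self.opening < self.donor.end):
            raise ValueError("opening point must lie strictly inside the donor span")


def geometry_from_cluster(cluster) -> JunctionGeometry:
    """Derive junction geometry from a detected cluster."""
    ad_off = cluster.ad_point - cluster.derivative_span.start
    return JunctionGeometry(
        donor=cluster.donor_span,
        opening=cluster.bc_point,
        derivative=cluster.derivative_span,
        orientation=cluster.orientation,
        ad_offset=ad_off if 0 < ad_off < len(cluster.derivative_span) else None,
    )


def _fetch(fasta, chrom: str, start: int, end: int) -> str:
    """Slice [start, end) from a genome accessor (pyfaidx.Fasta or mapping)."""
    start = max(0, start)
    if hasattr(fasta, "sequences"):  # SyntheticGenome
        return fasta.sequences[chrom][start:end]
    if isinstance(fasta, Mapping):
        return fasta[chrom][start:end]
    return str(fasta[chrom][start:end])  # pyfaidx.Fasta


def resolve_cluster_junctions(
    geometry: JunctionGeometry,
    fasta,
    window: int = 150,
    min_anchor: int = 20,
    max_ins: int = 50,
    max_del: int = 100,
) -> dict[str, JunctionScar | None]:
    """Resolve the A/D, β-C and B-α junctions of one event.

    References are taken from the ancestral loci in the supplied genome (the
    acceptor reference is reconstructed by excising the derivative span);
    junction reads come from the derivative.  A junction whose windows
    contain an N run, or whose anchors fail to align, is reported as ``None``
    (unresolvable) while the others are still returned.

    Exact scar recovery requires breakpoint-accurate spans; with jittered
    annotations the calls degrade gracefully to approximate/unresolvable.
    """
    g = geometry
    d_chrom = g.donor.chrom
    v_chrom = g.derivative.chrom
    dA, dD, bc = g.donor.start, g.donor.end, g.opening
    vs, ve = g.derivative.start, g.derivative.end
    w2 = window  # read half-window
    # references must extend beyond their breakpoints by at least the
    # read half-window plus the indel search budget, or shifted suffix
    # alignments cannot fit
    w = window + max_del + max_ins + 20

    acc_left = _fetch(fasta, v_chrom, vs - w, vs)
    acc_right = _fetch(fasta, v_chrom, ve, ve + w)
    acceptor_ref = acc_left + acc_right
    acc_break = len(acc_left)

    donor_end_ref = _fetch(fasta, d_chrom, dD - w, dD + w)  # D terminus at w
    donor_start_ref = _fetch(fasta, d_chrom, dA - w, dA + w)  # A start at w
    opening_ref = _fetch(fasta, d_chrom, bc - w, bc + w)  # B/C at w
    d_end_break = min(w, dD)
    d_start_break = min(w, dA)
    bc_break = min(w, bc)

    if g.ad_offset is not None:
        ad_pos = vs + g.ad_offset
    elif g.orientation == "parallel":
        ad_pos = vs + (dD - bc)
    else:
        ad_pos = vs + (bc - dA)

    if g.orientation == "parallel":
        specs = {
            "AD": (
                donor_end_ref, d_end_break, donor_start_ref, d_start_break,
                _fetch(fasta, v_chrom, ad_pos - w2, ad_pos + w2), False,
            ),
            "betaC": (
                acceptor_ref, acc_break, opening_ref, bc_break,
                _fetch(fasta, v_chrom, vs - w2, vs + w2), False,
            ),
            "Balpha": (
                opening_ref, bc_break, acceptor_ref, acc_break,
                _fetch(fasta, v_chrom, ve - w2, ve + w2), False,
            ),
        }
    else:
        # derivative = revcomp((C..D)(A..B)): reads are flipped back into the
        # donor frame; the acceptor reference mirrors accordingly
        rc_acc = revcomp(acceptor_ref)
        rc_acc_break = len(acc_right)
        specs = {
            "AD": (
                donor_end_ref, d_end_break, donor_start_ref, d_start_break,
                _fetch(fasta, v_chrom, ad_pos - w2, ad_pos + w2), True,
            ),
            "betaC": (
                rc_acc, rc_acc_break, opening_ref, bc_break,
                _fetch(fasta, v_chrom, ve - w2, ve + w2), True,
            ),
            "Balpha": (
                opening_ref, bc_break, rc_acc, rc_acc_break,
                _fetch(fasta, v_chrom, vs - w2, vs + w2), True,
            ),
        }

    out: dict[str, JunctionScar | None] = {}
    for name, (lref, lbrk, rref, rbrk, read, rc_read) in specs.items():
        if rc_read:
            read = revcomp(read)
        if "N" in lref.upper() or "N" in rref.upper() or "N" in read.upper():
            out[name] = None
            continue
        try:
            out[name] = resolve_junction(
                JunctionInput(lref, rref, read, lbrk, rbrk),
                min_anchor=min_anchor, max_ins=max_ins, max_del=max_del,
            )
        except (AnchorError, ValueError):
            out[name] = None
    return out


# ---------------------------------------------------------------------------
# flank homology screen
# ---------------------------------------------------------------------------


@dataclass
class FlankScreenResult:
    pair_scores: list[dict]
    inverted_repeats: list[dict]

    @property
    def homology_positive(self) -> bool:
        return any(p["flagged"] for p in self.pair_scores)

    @property
    def inverted_repeat_positive(self) -> bool:
        return bool(self.inverted_repeats)


def _local_identity_score(a: str, b: str) -> float:
    """Best local-alignment score (match +1, mismatch -1, gap -2)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    if not a or not b:
        return 0.0
    return float(aligner.score(a, b))


def find_inverted_repeats(
    seq: str, arm: int = 10, max_spacer: int = 100
) -> list[tuple[int, int, int]]:
    """(arm_start, partner_start, arm_len) for inverted-repeat seeds.

    Seeds are exact ``arm``-mers whose reverse complement occurs downstream
    within ``max_spacer`` bp.
    """
    seq = seq.upper()
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - arm + 1):
        word = seq[i : i + arm]
        if "N" not in word:
            index.setdefault(word, []).append(i)
    hits = []
    for i in range(len(seq) - arm + 1):
        word = seq[i : i + arm]
        if "N" in word:
            continue
        for j in index.get(revcomp(word), ()):
            spacer = j - (i + arm)
            if 0 <= spacer <= max_spacer:
                hits.append((i, j, arm))
    return hits


def flank_homology_screen(
    fasta,
    points: Sequence[tuple[str, int]],
    window: int = 500,
    min_score: float = 50.0,
    ir_arm: int = 10,
    ir_spacer: int = 100,
) -> FlankScreenResult:
    """Screen breakpoint flanks for homology that would suggest NAHR.

    For every pair of breakpoints, the ±``window`` flanks are compared by
    local alignment (direct and reverse-complement); pairs scoring at least
    ``min_score`` are flagged as homology-positive.  Each flank is also
    scanned for short inverted repeats (arm >= ``ir_arm``, spacer <=
    ``ir_spacer``).
    """
    flanks = []
    for chrom, pos in points:
        seq = _fetch(fasta, chrom, pos - window, pos + window + 1)
        flanks.append((chrom, pos, seq))
    pair_scores = []
    for i in range(len(flanks)):
        for j in range(i + 1, len(flanks)):
            a, b = flanks[i][2], flanks[j][2]
            score = max(_local_identity_score(a, b), _local_identity_score(a, revcomp(b)))
            pair_scores.append(
                {
                    "point_a": flanks[i][:2],
                    "point_b": flanks[j][:2],
                    "score": score,
                    "flagged": score >= min_score,
                }
            )
    ir_hits = []
    for chrom, pos, seq in flanks:
        for a_start, b_start, arm_len in find_inverted_repeats(seq, ir_arm, ir_spacer):
            ir_hits.append(
                {"point": (chrom, pos), "arm_start": a_start,
                 "partner_start": b_start, "arm_len": arm_len}
            )
    return FlankScreenResult(pair_scores=pair_scores, inverted_repeats=ir_hits)
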