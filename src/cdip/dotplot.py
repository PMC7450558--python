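"""k-mer dot-matrix homology plots and rearrangement-signature calls.

A duplication generated through a circular intermediate leaves a diagnostic
dot-plot signature when the donor locus is plotted against the derivative:
*two parallel same-slope diagonals with offsets of opposite sign*, because
the two block halves swap order while keeping orientation.  This module
computes the match matrix by exact k-mer seeding (deterministic and
sufficient in the 90-99% identity regime of recent duplications), merges
collinear seeds into diagonal runs, and classifies the resulting geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from ._seq import revcomp, validate_dna


class Run(NamedTuple):
    """A maximal merged diagonal run of k-mer seeds.

    Covers ``x in [x_start, x_start + length)`` and
    ``y in [y_start, y_start + length)``.  For ``slope == +1`` position
    ``x_start + t`` pairs with ``y_start + t``; for ``slope == -1`` it pairs
    with ``y_start + length - 1 - t`` (reverse-complement match).
    """

    x_start: int
    y_start: int
    length: int
    slope: int

    @property
    def offset(self) -> int:
        """Diagonal offset y - x (slope +1) or anti-diagonal x + y (slope -1)."""
        if self.slope == 1:
            return self.y_start - self.x_start
        return self.x_start + (self.y_start + self.length - 1)


@dataclass
class DotMatrix:
    seq_x_len: int
    seq_y_len: int
    k: int
    matches: set[tuple[int, int, int]] = field(default_factory=set)  # (x, y, strand)
    merged_runs: list[Run] = field(default_factory=list)


@dataclass
class PatternCall:
    label: str  # single_diagonal | flip_parallel | inverted | complex | none
    runs_used: list[Run] = field(default_factory=list)
    coverage_x: float = 0.0
    coverage_y: float = 0.0


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if "N" in word:
            continue
        index.setdefault(word, []).append(i)
    return index


def _merge_diagonal(seeds: list[int], k: int, max_gap: int) -> list[tuple[int, int]]:
    """Merge sorted seed starts on one diagonal into (start, length) blocks."""
    blocks = []
    start = prev = seeds[0]
    for s in seeds[1:]:
        if s - (prev + k) <= max_gap:
            prev = s
        else:
            blocks.append((start, prev + k - start))
            start = prev = s
    blocks.append((start, prev + k - start))
    return blocks


def dot_matrix(
    seq_x: str, seq_y: str, k: int = 16, max_hits_per_word: int = 10
) -> DotMatrix:
    """Exact k-mer match matrix between two sequences.

    A forward match ``(i, j, +1)`` means ``seq_x[i:i+k] == seq_y[j:j+k]``;
    a reverse match ``(i, j, -1)`` means
    ``seq_x[i:i+k] == revcomp(seq_y[j:j+k])``.  k-mers containing N and
    k-mers occurring more than ``max_hits_per_word`` times in either sequence
    are excluded.  Collinear seeds separated by at most ``2k`` bp are merged
    into maximal runs.
    """
    validate_dna(seq_x, "seq_x")
    validate_dna(seq_y, "seq_y")
    if k < 4:
        raise ValueError("k must be >= 4")
    if k > len(seq_x) or k > len(seq_y):
        raise ValueError("k larger than a sequence")
    seq_x = seq_x.upper()
    seq_y = seq_y.upper()

    x_index = _kmer_positions(seq_x, k)
    y_counts: dict[str, int] = {}
    for j in range(len(seq_y) - k + 1):
        w = seq_y[j : j + k]
        if "N" not in w:
            y_counts[w] = y_counts.get(w, 0) + 1

    def allowed(word_x: str, word_y: str) -> bool:
        return (
            len(x_index.get(word_x, ())) <= max_hits_per_word
            and y_counts.get(word_y, 0) <= max_hits_per_word
        )

    matches: set[tuple[int, int, int]] = set()
    for j in range(len(seq_y) - k + 1):
        w = seq_y[j : j + k]
        if "N" in w:
            continue
        if w in x_index and allowed(w, w):
            for i in x_index[w]:
                matches.add((i, j, 1))
        wr = revcomp(w)
        if wr in x_index and allowed(wr, w):
            for i in x_index[wr]:
                matches.add((i, j, -1))

    # merge seeds into runs
    runs: list[Run] = []
    fwd: dict[int, list[int]] = {}
    rev: dict[int, list[int]] = {}
    for i, j, strand in matches:
        if strand == 1:
            fwd.setdefault(j - i, []).append(i)
        else:
            rev.setdefault(i + j, []).append(i)
    max_gap = 2 * k
    for d, seeds in sorted(fwd.items()):
        for x0, length in _merge_diagonal(sorted(seeds), k, max_gap):
            runs.append(Run(x0, x0 + d, length, 1))
    for s, seeds in sorted(rev.items()):
        for x0, length in _merge_diagonal(sorted(seeds), k, max_gap):
            # seeds on anti-diagonal s: x0..x0+length-k, y = s - x
            y_lo = s - (x0 + length - k)
            runs.append(Run(x0, y_lo, length, -1))
    runs.sort()
    return DotMatrix(
        seq_x_len=len(seq_x),
        seq_y_len=len(seq_y),
        k=k,
        matches=matches,
        merged_runs=runs,
    )


def _union_len(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _coverage(runs: list[Run], len_x: int, len_y: int) -> tuple[float, float]:
    cx = _union_len([(r.x_start, r.x_start + r.length) for r in runs]) / len_x
    cy = _union_len([(r.y_start, r.y_start + r.length) for r in runs]) / len_y
    return cx, cy


@dataclass
class _RunGroup:
    """Collinear run fragments sharing (approximately) one diagonal offset.

    Post-duplication divergence fragments a block's diagonal into many short
    runs at the same offset; the group hull, not the individual fragments,
    is the evidence for the block.
    """

    runs: list[Run]

    @property
    def total(self) -> int:
        return sum(r.length for r in self.runs)

    @property
    def x_extent(self) -> tuple[int, int]:
        return (min(r.x_start for r in self.runs),
                max(r.x_start + r.length for r in self.runs))

    @property
    def y_extent(self) -> tuple[int, int]:
        return (min(r.y_start for r in self.runs),
                max(r.y_start + r.length for r in self.runs))

    @property
    def offset(self) -> float:
        return sum((r.y_start - r.x_start) * r.length for r in self.runs) / self.total


def _group_by_offset(runs: list[Run], tol: int) -> list[_RunGroup]:
    groups: list[_RunGroup] = []
    for run in sorted(runs, key=lambda r: r.y_start - r.x_start):
        d = run.y_start - run.x_start
        if groups and abs(d - groups[-1].offset) <= tol:
            groups[-1].runs.append(run)
        else:
            groups.append(_RunGroup([run]))
    return groups


def _extent_cov(extents: list[tuple[int, int]], axis_len: int) -> float:
    return _union_len(list(extents)) / axis_len


def classify_pattern(
    matrix: DotMatrix, min_run_bp: int = 1000, min_coverage: float = 0.5
) -> PatternCall:
    """Classify the rearrangement signature of a dot matrix.

    Slope-+1 runs are grouped by diagonal offset (fragments of one block
    share an offset even when divergence breaks the diagonal into pieces); a
    group is significant when its summed run length reaches ``min_run_bp``.
    ``flip_parallel`` requires significant forward groups at offsets of both
    signs whose hulls jointly cover at least ``min_coverage`` of both axes
    and approximately partition them (the block-swap geometry).  A single
    dominant near-zero-offset forward group is ``single_diagonal``; dominant
    reverse runs are ``inverted``; anything else with significant runs is
    ``complex``; no significant evidence, ``none``.
    """
    lx, ly = matrix.seq_x_len, matrix.seq_y_len
    fwd_runs = [r for r in matrix.merged_runs if r.slope == 1]
    rev_runs = [r for r in matrix.merged_runs if r.slope == -1]
    tol = 2 * matrix.k
    fwd = [g for g in _group_by_offset(fwd_runs, tol) if g.total >= min_run_bp]
    rev_sig = [r for r in rev_runs if r.length >= min_run_bp]
    rev_total_sig = sum(r.length for r in rev_sig)
    if not fwd and not rev_sig:
        return PatternCall("none")

    pos = [g for g in fwd if g.offset > 0]
    neg = [g for g in fwd if g.offset < 0]
    if pos and neg:
        gp = max(pos, key=lambda g: g.total)
        gn = max(neg, key=lambda g: g.total)
        cx = _extent_cov([gp.x_extent, gn.x_extent], lx)
        cy = _extent_cov([gp.y_extent, gn.y_extent], ly)

        def _ov(a, b):
            return max(0, min(a[1], b[1]) - max(a[0], b[0]))

        min_x_len = min(gp.x_extent[1] - gp.x_extent[0], gn.x_extent[1] - gn.x_extent[0])
        min_y_len = min(gp.y_extent[1] - gp.y_extent[0], gn.y_extent[1] - gn.y_extent[0])
        partition_ok = (
            _ov(gp.x_extent, gn.x_extent) <= 0.25 * min_x_len
            and _ov(gp.y_extent, gn.y_extent) <= 0.25 * min_y_len
        )
        if cx >= min_coverage and cy >= min_coverage and partition_ok:
            return PatternCall("flip_parallel", sorted(gp.runs + gn.runs), cx, cy)

    fwd_total = sum(g.total for g in fwd)
    if fwd and fwd_total >= rev_total_sig:
        main = max(fwd, key=lambda g: g.total)
        cx = _extent_cov([main.x_extent], lx)
        cy = _extent_cov([main.y_extent], ly)
        near_zero = abs(main.offset) <= max(2 * matrix.k, int(0.02 * min(lx, ly)))
        if cx >= min_coverage and cy >= min_coverage and near_zero:
            return PatternCall("single_diagonal", sorted(main.runs), cx, cy)
    if rev_sig and rev_total_sig > fwd_total:
        cx, cy = _coverage(rev_sig, lx, ly)
        if cx >= min_coverage and cy >= min_coverage:
            return PatternCall("inverted", sorted(rev_sig), cx, cy)
    used = sorted([r for g in fwd for r in g.runs] + rev_sig)
    cx, cy = _coverage(used, lx, ly)
    return PatternCall("complex", used, cx, cy)


def render_dotplot(matrix: DotMatrix, path: str) -> None:
    """Render merged runs as line segments (ancestral on X, derivative on Y)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for r in matrix.merged_runs:
        if r.slope == 1:
            ax.plot([r.x_start, r.x_start + r.length], [r.y_start, r.y_start + r.length],
                    color="tab:blue", lw=1.2)
        else:
            ax.plot([r.x_start, r.x_start + r.length], [r.y_start + r.length, r.y_start],
                    color="tab:red", lw=1.2)
    ax.set_xlim(0, matrix.seq_x_len)
    ax.set_ylim(0, matrix.seq_y_len)
    ax.set_xlabel("ancestral (bp)")
    ax.set_ylabel("derivative (bp)")
    ax.set_title(f"dot matrix, k={matrix.k}")
    kwargs = {}
    if str(path).endswith(".svg"):
        kwargs["metadata"] = {"Date": None}
    fig.savefig(path, dpi=100, **kwargs)
    plt.close(fig)
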