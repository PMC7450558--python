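"""Synthetic genomes with planted circular-intermediate duplications.

The generator plants duplication events whose geometry matches the
circular-intermediate model exactly: a donor segment A..D is circularized by
fusing its ends (junction A/D), the circle opens at a distinct internal
point B/C, and the opened fragment integrates at an acceptor site α/β —
yielding a derivative copy in (C..D)(A..B) block order, optionally inserted
in reverse complement.  Junction scars are drawn from the observed spectrum
of such events: 1-2 bp microhomologies, short untemplated insertions, and
short flank deletions (1-27 bp).  Decoy rearrangements (tandem duplication;
transposition followed by a single inversion) provide negative controls that
the flip scan must reject.

Every planted event carries a :class:`TruthRecord` in final-genome
coordinates, and :func:`emulate_sd_annotation` emits the SD records an
annotation pipeline would report for it, so the whole detection stack is
testable without external data.

Scar canonicality: the generator edits the ancestral bases so each drawn
scar is the uniquely parsimonious read of its junction (microhomology motifs
are made identical on both flanks; a deleted boundary base is never equal to
the base joined across it).  Without this, a drawn "deletion" could be
indistinguishable from a microhomology at single-base resolution and no
resolver could recover the drawn truth.  Divergence mutations are likewise
never applied inside a microhomology motif or an inserted sequence — a
mutated motif is, by definition, no longer a microhomology, so the
observable truth itself would change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seq import revcomp
from .model import GenomeInterval, SDRecord, SDTable
from .timing import OLDER_THAN_LADDER, PresenceTable, SpeciesLadder

BASES = np.frombuffer(b"ACGT", dtype="S1")

JUNCTIONS = ("AD", "betaC", "Balpha")


class SyntheticGenome:
    """A small in-memory multi-chromosome genome."""

    def __init__(self, sequences: dict[str, str]) -> None:
        self.sequences = dict(sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def get(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][max(0, start):end]

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom in self.sequences:
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def generate_genome(
    chrom_lengths: dict[str, int], gc: float = 0.41, seed: int = 0
) -> SyntheticGenome:
    """Reproducible random genome with the requested G+C fraction."""
    if not (0.0 < gc < 1.0):
        raise ValueError(f"gc must be in (0,1), got {gc}")
    for chrom, length in chrom_lengths.items():
        if length < 1000:
            raise ValueError(f"{chrom}: length must be >= 1 kb")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = {}
    for chrom, length in chrom_lengths.items():
        arr = rng.choice(BASES, size=length, p=p)
        seqs[chrom] = arr.tobytes().decode("ascii")
    return SyntheticGenome(seqs)


@dataclass(frozen=True)
class Scar:
    """Drawn scar at one junction: microhomology XOR insertion, plus dels."""

    mh: int = 0
    ins: str = ""
    del_left: int = 0
    del_right: int = 0

    def __post_init__(self) -> None:
        if self.mh > 0 and self.ins:
            raise ValueError("a junction has a microhomology OR an insertion, not both")

    @property
    def scar_class(self) -> str:
        if self.ins:
            return "insertion"
        if self.mh > 0:
            return "microhomology"
        if self.del_left or self.del_right:
            return "deletion"
        return "blunt"


BLUNT = Scar()


@dataclass
class ScarModel:
    """Distributions over junction scars (bounded by the observed spectrum)."""

    mh_lengths: tuple[int, ...] = (1, 2)
    ins_lengths: tuple[int, ...] = tuple(range(1, 28))
    del_lengths: tuple[int, ...] = tuple(range(1, 28))
    class_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    allow_del_cooccurrence: bool = False

    def draw(self, rng: np.random.Generator) -> Scar:
        kind = rng.choice(["blunt", "microhomology", "insertion", "deletion"],
                          p=np.asarray(self.class_weights) / sum(self.class_weights))
        if kind == "blunt":
            return BLUNT
        if kind == "microhomology":
            return Scar(mh=int(rng.choice(self.mh_lengths)))
        if kind == "insertion":
            n = int(rng.choice(self.ins_lengths))
            ins = rng.choice(BASES, size=n).tobytes().decode("ascii")
            return Scar(ins=ins)
        n = int(rng.choice(self.del_lengths))
        if rng.random() < 0.5:
            return Scar(del_left=n)
        return Scar(del_right=n)

    def draw_junctions(self, rng: np.random.Generator) -> dict[str, Scar]:
        return {j: self.draw(rng) for j in JUNCTIONS}


@dataclass
class TruthRecord:
    """Ground truth for one planted event, in final-genome coordinates."""

    event_id: str
    event_type: str  # csdp | tandem_dup | transposition_inversion
    donor_span: GenomeInterval
    opening_point: int
    acceptor_point: int
    derivative_span: GenomeInterval
    orientation: str = "parallel"
    scars: dict[str, Scar] = field(default_factory=dict)
    divergence: float = 0.0
    donor_block_ab: GenomeInterval | None = None
    donor_block_cd: GenomeInterval | None = None
    derivative_block_ab: GenomeInterval | None = None
    derivative_block_cd: GenomeInterval | None = None
    ad_offset: int | None = None  # A/D seam position within the derivative

    def junction_geometry(self):
        """Breakpoint-exact junction geometry for this event.

        Junction scars resolved from this geometry recover the drawn truth
        exactly; geometry derived from emulated SD records instead carries
        the scar bases into the block boundaries (annotation trims the
        unaligned scar), which yields an equivalent but blunt-shifted
        parameterization of the same junctions.
        """
        from .junctions import JunctionGeometry

        return JunctionGeometry(
            donor=self.donor_span,
            opening=self.opening_point,
            derivative=self.derivative_span,
            orientation=self.orientation,
            ad_offset=self.ad_offset,
        )

    def shift(self, chrom: str, pos: int, delta: int) -> None:
        """Adjust coordinates after an insertion of ``delta`` bp at ``pos``."""

        def mv(iv: GenomeInterval | None) -> GenomeInterval | None:
            if iv is None or iv.chrom != chrom or iv.start < pos:
                return iv
            return GenomeInterval(iv.chrom, iv.start + delta, iv.end + delta)

        if self.donor_span.chrom == chrom and self.opening_point >= pos:
            self.opening_point += delta
        if self.derivative_span.chrom == chrom and self.acceptor_point >= pos:
            self.acceptor_point += delta
        self.donor_span = mv(self.donor_span)
        self.derivative_span = mv(self.derivative_span)
        self.donor_block_ab = mv(self.donor_block_ab)
        self.donor_block_cd = mv(self.donor_block_cd)
        self.derivative_block_ab = mv(self.derivative_block_ab)
        self.derivative_block_cd = mv(self.derivative_block_cd)


def _mutate_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _edit(seq: str, start: int, new: str) -> str:
    return seq[:start] + new + seq[start + len(new):]


def _canonicalize_del(genome: SyntheticGenome, left_chrom: str, left_end: int,
                      right_chrom: str, right_start: int, scar: Scar,
                      rng: np.random.Generator) -> None:
    """Edit deleted boundary bases so the drawn deletion is unambiguous.

    ``left_end``/``right_start`` are the nominal breakpoints (left reference
    ends at left_end; right reference starts at right_start).  Deleted bases
    live only in the ancestral references, so editing them never changes the
    derivative.
    """
    lseq = genome.sequences[left_chrom]
    rseq = genome.sequences[right_chrom]
    if scar.del_left > 0:
        first_deleted = lseq[left_end - scar.del_left]
        first_joined = rseq[right_start + scar.del_right]
        if first_deleted == first_joined:
            genome.sequences[left_chrom] = _edit(
                lseq, left_end - scar.del_left, _mutate_base(first_deleted, rng)
            )
            lseq = genome.sequences[left_chrom]
    if scar.del_right > 0:
        rseq = genome.sequences[right_chrom]
        last_deleted = rseq[right_start + scar.del_right - 1]
        last_joined = lseq[left_end - scar.del_left - 1]
        if last_deleted == last_joined:
            genome.sequences[right_chrom] = _edit(
                rseq, right_start + scar.del_right - 1, _mutate_base(last_deleted, rng)
            )


def plant_csdp(
    genome: SyntheticGenome,
    donor: GenomeInterval,
    opening: int,
    acceptor: tuple[str, int],
    orientation: str = "parallel",
    scars: dict[str, Scar] | ScarModel | None = None,
    divergence: float = 0.0,
    seed: int = 0,
    event_id: str = "csdp1",
) -> TruthRecord:
    """Plant one circular-intermediate duplication; mutates the genome.

    The donor A..D is conceptually circularized (A/D fusion), opened at
    ``opening`` (B/C) and inserted at the acceptor, so the derivative reads
    (C..D)(A..B) — reverse-complemented when ``orientation='inverted'``.
    Scars are applied at the three seams; point mutations at rate
    ``divergence`` are applied to the inserted copy only.  Returns a
    :class:`TruthRecord` in post-insertion coordinates.
    """
    rng = np.random.default_rng(seed)
    if not (donor.start < opening < donor.end):
        raise ValueError("opening point must lie strictly inside the donor span")
    a_chrom, p = acceptor
    if donor.contains_point(a_chrom, p):
        raise ValueError("acceptor point must lie outside the donor span")
    if orientation not in ("parallel", "inverted"):
        raise ValueError(f"bad orientation {orientation!r}")
    if isinstance(scars, ScarModel):
        scars = scars.draw_junctions(rng)
    elif scars is None:
        scars = {j: BLUNT for j in JUNCTIONS}
    scars = {j: scars.get(j, BLUNT) for j in JUNCTIONS}
    ad, bc, ba = scars["AD"], scars["betaC"], scars["Balpha"]

    d_chrom = donor.chrom
    dA, dD, O = donor.start, donor.end, opening

    # --- canonicality edits in the ancestral genome --------------------
    if ad.mh:  # D terminus motif := A start motif
        motif = genome.sequences[d_chrom][dA : dA + ad.mh]
        genome.sequences[d_chrom] = _edit(genome.sequences[d_chrom], dD - ad.mh, motif)
    if bc.mh:  # acceptor upstream motif := C start motif
        motif = genome.sequences[d_chrom][O : O + bc.mh]
        genome.sequences[a_chrom] = _edit(genome.sequences[a_chrom], p - bc.mh, motif)
    if ba.mh:  # acceptor downstream motif := B end motif
        motif = genome.sequences[d_chrom][O - ba.mh : O]
        genome.sequences[a_chrom] = _edit(genome.sequences[a_chrom], p, motif)
    # deletions: left/right reference breakpoints per junction
    _canonicalize_del(genome, d_chrom, dD, d_chrom, dA, ad, rng)
    _canonicalize_del(genome, a_chrom, p, d_chrom, O, bc, rng)
    _canonicalize_del(genome, d_chrom, O, a_chrom, p, ba, rng)

    donor_seq = genome.sequences[d_chrom][dA:dD]
    ab = donor_seq[: O - dA]
    cd = donor_seq[O - dA :]

    # --- apply seam trims (donor frame) --------------------------------
    # A/D: left = D end, right = A start; the kept microhomology copy is D's
    cd_trim_end = ad.del_left
    ab_trim_start = ad.del_right + ad.mh
    # beta-C: left = acceptor upstream, right = C start; kept copy acceptor's
    cd_trim_start = bc.del_right + bc.mh
    acc_del_left = bc.del_left
    # B-alpha: left = B end, right = acceptor downstream; kept copy acceptor's
    ab_trim_end = ba.del_left + ba.mh
    acc_del_right = ba.del_right

    cd_part = cd[cd_trim_start : len(cd) - cd_trim_end]
    ab_part = ab[ab_trim_start : len(ab) - ab_trim_end]
    content = bc.ins + cd_part + ad.ins + ab_part + ba.ins

    # --- divergence (protect untemplated/microhomology bases) ----------
    protected = set()
    pos = 0
    protected.update(range(pos, pos + len(bc.ins)))
    pos += len(bc.ins) + len(cd_part)
    if ad.mh:
        protected.update(range(pos - ad.mh, pos))  # kept A/D motif copy (D end)
    protected.update(range(pos, pos + len(ad.ins)))
    pos += len(ad.ins) + len(ab_part)
    protected.update(range(pos, pos + len(ba.ins)))
    n_content = len(content)
    if divergence > 0:
        hits = np.flatnonzero(rng.random(n_content) < divergence)
        if hits.size:
            chars = list(content)
            for i in hits:
                if int(i) not in protected:
                    chars[i] = _mutate_base(chars[i], rng)
            content = "".join(chars)

    ad_offset_df = len(bc.ins) + len(cd_part) + len(ad.ins) // 2
    cd_span_df = (len(bc.ins), len(bc.ins) + len(cd_part))
    ab_span_df = (
        len(bc.ins) + len(cd_part) + len(ad.ins),
        len(bc.ins) + len(cd_part) + len(ad.ins) + len(ab_part),
    )
    if orientation == "inverted":
        content = revcomp(content)
        ad_offset_df = n_content - ad_offset_df
        cd_span_df = (n_content - cd_span_df[1], n_content - cd_span_df[0])
        ab_span_df = (n_content - ab_span_df[1], n_content - ab_span_df[0])

    # --- insert at the acceptor ----------------------------------------
    vs = p - acc_del_left
    chrom_seq = genome.sequences[a_chrom]
    genome.sequences[a_chrom] = chrom_seq[:vs] + content + chrom_seq[p + acc_del_right :]
    delta = len(content) - acc_del_left - acc_del_right
    ve = vs + len(content)

    # --- final coordinates ----------------------------------------------
    sh = delta if (a_chrom == d_chrom and p <= dA) else 0
    truth = TruthRecord(
        event_id=event_id,
        event_type="csdp",
        donor_span=GenomeInterval(d_chrom, dA + sh, dD + sh),
        opening_point=O + sh,
        acceptor_point=vs,
        derivative_span=GenomeInterval(a_chrom, vs, ve),
        orientation=orientation,
        scars=scars,
        divergence=divergence,
        donor_block_ab=GenomeInterval(d_chrom, dA + ab_trim_start + sh, O - ab_trim_end + sh),
        donor_block_cd=GenomeInterval(d_chrom, O + cd_trim_start + sh, dD - cd_trim_end + sh),
        derivative_block_ab=GenomeInterval(a_chrom, vs + ab_span_df[0], vs + ab_span_df[1]),
        derivative_block_cd=GenomeInterval(a_chrom, vs + cd_span_df[0], vs + cd_span_df[1]),
        ad_offset=ad_offset_df,
    )
    return truth


def plant_decoy(
    genome: SyntheticGenome,
    kind: str,
    donor: GenomeInterval,
    acceptor: tuple[str, int] | None = None,
    internal_point: int | None = None,
    divergence: float = 0.0,
    seed: int = 0,
    event_id: str = "decoy1",
) -> TruthRecord:
    """Plant a decoy rearrangement that must NOT look circular-mediated.

    ``tandem_dup`` copies the donor immediately after itself (derivative
    block order A-B/A-B adjacency, no swap).  ``transposition_inversion``
    copies the donor to a distant acceptor and inverts the sub-segment on
    one side of ``internal_point``, producing B-A/C-D block order with mixed
    orientation — the alternative mechanism the flip predicate rejects.
    """
    rng = np.random.default_rng(seed)
    d_chrom = donor.chrom
    donor_seq = genome.sequences[d_chrom][donor.start : donor.end]

    def diverge(seq: str) -> str:
        if divergence <= 0:
            return seq
        hits = np.flatnonzero(rng.random(len(seq)) < divergence)
        if not hits.size:
            return seq
        chars = list(seq)
        for i in hits:
            chars[i] = _mutate_base(chars[i], rng)
        return "".join(chars)

    if kind == "tandem_dup":
        content = diverge(donor_seq)
        vs = donor.end
        chrom_seq = genome.sequences[d_chrom]
        genome.sequences[d_chrom] = chrom_seq[:vs] + content + chrom_seq[vs:]
        return TruthRecord(
            event_id=event_id,
            event_type="tandem_dup",
            donor_span=donor,
            opening_point=donor.start,
            acceptor_point=vs,
            derivative_span=GenomeInterval(d_chrom, vs, vs + len(content)),
            orientation="parallel",
            divergence=divergence,
        )
    if kind == "transposition_inversion":
        if acceptor is None or internal_point is None:
            raise ValueError("transposition_inversion needs acceptor and internal_point")
        if not (donor.start < internal_point < donor.end):
            raise ValueError("internal point must lie strictly inside the donor span")
        a_chrom, p = acceptor
        if donor.contains_point(a_chrom, p):
            raise ValueError("acceptor point must lie outside the donor span")
        off = internal_point - donor.start
        ab, cd = donor_seq[:off], donor_seq[off:]
        content = diverge(revcomp(ab) + cd)  # invert the A-B side: B-A / C-D
        vs = p
        chrom_seq = genome.sequences[a_chrom]
        genome.sequences[a_chrom] = chrom_seq[:vs] + content + chrom_seq[vs:]
        sh = len(content) if (a_chrom == d_chrom and p <= donor.start) else 0
        return TruthRecord(
            event_id=event_id,
            event_type="transposition_inversion",
            donor_span=GenomeInterval(d_chrom, donor.start + sh, donor.end + sh),
            opening_point=internal_point + sh,
            acceptor_point=vs,
            derivative_span=GenomeInterval(a_chrom, vs, vs + len(content)),
            orientation="parallel",
            divergence=divergence,
            donor_block_ab=GenomeInterval(d_chrom, donor.start + sh, internal_point + sh),
            donor_block_cd=GenomeInterval(d_chrom, internal_point + sh, donor.end + sh),
            derivative_block_ab=GenomeInterval(a_chrom, vs, vs + off),
            derivative_block_cd=GenomeInterval(a_chrom, vs + off, vs + len(content)),
        )
    raise ValueError(f"unknown decoy kind {kind!r}")


def _jitter_interval(iv: GenomeInterval, noise: int, rng: np.random.Generator,
                     chrom_len: int) -> GenomeInterval:
    if noise <= 0:
        return iv
    s = iv.start + int(rng.integers(-noise, noise + 1))
    e = iv.end + int(rng.integers(-noise, noise + 1))
    s = max(0, min(s, chrom_len - 2))
    e = max(s + 1, min(e, chrom_len))
    return GenomeInterval(iv.chrom, s, e)


def emulate_sd_annotation(
    genome: SyntheticGenome,
    truths: Sequence[TruthRecord],
    noise: int = 0,
    seed: int = 0,
) -> SDTable:
    """Emit the SD records an annotation pipeline would report.

    A circular-intermediate event yields two records (the A-B and C-D block
    pairs) with the event's relative orientation and
    ``frac_match = 1 - divergence``; a tandem duplication yields one record;
    a transposition+inversion yields two records with *mixed* orientation
    flags (the inverted block pairs as '-', the other as '+').  Endpoints
    are jittered by at most ``noise`` bp.
    """
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    table = SDTable(source_dialect="bedpe_min")

    def jit(iv: GenomeInterval) -> GenomeInterval:
        return _jitter_interval(iv, noise, rng, lengths[iv.chrom])

    for truth in truths:
        frac = round(1.0 - truth.divergence, 6)
        if truth.event_type == "csdp":
            strand = "+" if truth.orientation == "parallel" else "-"
            table.append(SDRecord(jit(truth.donor_block_ab), jit(truth.derivative_block_ab),
                                  strand, frac, f"{truth.event_id}_ab"))
            table.append(SDRecord(jit(truth.donor_block_cd), jit(truth.derivative_block_cd),
                                  strand, frac, f"{truth.event_id}_cd"))
        elif truth.event_type == "tandem_dup":
            table.append(SDRecord(jit(truth.donor_span), jit(truth.derivative_span),
                                  "+", frac, f"{truth.event_id}_td"))
        elif truth.event_type == "transposition_inversion":
            table.append(SDRecord(jit(truth.donor_block_ab), jit(truth.derivative_block_ab),
                                  "-", frac, f"{truth.event_id}_ab"))
            table.append(SDRecord(jit(truth.donor_block_cd), jit(truth.derivative_block_cd),
                                  "+", frac, f"{truth.event_id}_cd"))
        else:  # pragma: no cover - defensive
            raise ValueError(f"unknown event type {truth.event_type!r}")
    return table


def make_presence_table(
    origin_branch: str,
    ladder: SpeciesLadder | None = None,
    unknown_rate: float = 0.0,
    seed: int = 0,
    ancestral_locus: int = 1,
) -> PresenceTable:
    """Fabricate a presence table for a duplication arising on a known branch.

    The derivative locus is present in every species strictly closer to
    human than ``origin_branch`` and absent from ``origin_branch`` outward
    (``older_than_ladder`` makes it present everywhere); the ancestral locus
    is present in all species.  Non-human entries are flipped to unknown at
    ``unknown_rate``.
    """
    ladder = ladder or SpeciesLadder()
    species = list(ladder)
    if origin_branch == OLDER_THAN_LADDER:
        cutoff = len(species)
    else:
        cutoff = species.index(origin_branch)
        if cutoff == 0:
            raise ValueError("origin branch cannot be human itself")
    rng = np.random.default_rng(seed)
    entries = {}
    for i, sp in enumerate(species):
        anc = "yes"
        der = "yes" if i < cutoff else "no"
        if sp != "human" and unknown_rate > 0:
            if rng.random() < unknown_rate:
                anc = "unknown"
            if rng.random() < unknown_rate:
                der = "unknown"
        pair = (anc, der) if ancestral_locus == 1 else (der, anc)
        entries[sp] = pair
    return PresenceTable(entries)


def simulate_junction(
    scar: Scar,
    flank: int = 150,
    divergence: float = 0.0,
    seed: int = 0,
):
    """One synthetic junction with a known scar, ready for resolution.

    Builds random left/right reference flanks, applies the scar canonically
    (microhomology motif copied onto both flanks; deleted boundary bases
    forced to differ from the bases joined across them) and returns the
    :class:`~cdip.junctions.JunctionInput` together with the drawn scar.
    Divergence mutates read bases at the given rate, sparing microhomology
    and inserted bases (mutating those would change the observable truth).
    """
    from .junctions import JunctionInput

    rng = np.random.default_rng(seed)

    def rand(n: int) -> str:
        return rng.choice(BASES, size=n).tobytes().decode("ascii") if n else ""

    left_core = rand(flank)
    left_ext = rand(flank)
    right_core = rand(flank)
    right_ext = rand(flank)

    if scar.mh:
        motif = right_core[: scar.mh]
        left_core = left_core[: flank - scar.mh] + motif
    dl, dr = scar.del_left, scar.del_right
    if dl > 0 and left_core[flank - dl] == right_core[dr]:
        left_core = _edit(left_core, flank - dl, _mutate_base(left_core[flank - dl], rng))
    if dr > 0 and right_core[dr - 1] == left_core[flank - dl - 1]:
        right_core = _edit(right_core, dr - 1, _mutate_base(right_core[dr - 1], rng))

    left_ref = left_core + left_ext
    right_ref = right_ext + right_core

    read_left = left_core[: flank - dl]
    read_right = right_core[dr + scar.mh :]
    read = read_left + scar.ins + read_right

    if divergence > 0:
        protected = set(range(len(read_left), len(read_left) + len(scar.ins)))
        if scar.mh:
            protected.update(range(len(read_left) - scar.mh, len(read_left)))
        chars = list(read)
        for i in np.flatnonzero(rng.random(len(read)) < divergence):
            if int(i) not in protected:
                chars[i] = _mutate_base(chars[i], rng)
        read = "".join(chars)

    return JunctionInput(left_ref, right_ref, read, flank, flank), scar


# ---------------------------------------------------------------------------
# dataset orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for a full synthetic dataset.

    Defaults emulate the regime the detection pipeline targets: donors of
    20-500 kb, post-duplication divergence up to 7% (pair identity
    93-100%), the full observed scar spectrum, both insert orientations,
    and a mix of intra- and inter-chromosomal acceptors.
    """

    n_chromosomes: int = 4
    chrom_length: int = 12_000_000
    gc: float = 0.41
    n_csdp: int = 20
    n_decoys: int = 20
    size_range: tuple[int, int] = (20_000, 500_000)
    decoy_size_range: tuple[int, int] = (20_000, 100_000)
    divergence_range: tuple[float, float] = (0.0, 0.07)
    inter_chromosomal_fraction: float = 0.25
    inverted_fraction: float = 0.5
    noise: int = 0
    margin: int = 260_000  # inter-locus spacing, clears density masking
    edge_pad: int = 600_000  # keep clear of telomere-pad exclusions
    scar_model: ScarModel = field(default_factory=ScarModel)


@dataclass
class SimulatedDataset:
    genome: SyntheticGenome
    truths: list[TruthRecord]
    sd_table: SDTable
    config: SimulationConfig


def simulate_dataset(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedDataset:
    """Generate a genome, plant events, and emulate their SD annotation.

    Loci are pre-planned with generous spacing so events never interact;
    each insertion shifts the coordinates of previously planted truths and
    pending plans downstream of it.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    genome = generate_genome(
        {c: cfg.chrom_length for c in chroms}, gc=cfg.gc,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    cursors = {c: cfg.edge_pad for c in chroms}
    limit = cfg.chrom_length - cfg.edge_pad

    def take(chrom: str, length: int) -> int:
        start = cursors[chrom]
        if start + length + cfg.margin > limit:
            raise ValueError(
                "genome too small for the requested events; increase chrom_length"
            )
        cursors[chrom] = start + length + cfg.margin
        return start

    def log_uniform(lo: int, hi: int) -> int:
        return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    plans = []
    chrom_cycle = 0
    for i in range(cfg.n_csdp):
        size = log_uniform(*cfg.size_range)
        d_chrom = chroms[chrom_cycle % len(chroms)]
        chrom_cycle += 1
        d_start = take(d_chrom, size)
        inter = rng.random() < cfg.inter_chromosomal_fraction and len(chroms) > 1
        a_chrom = chroms[chrom_cycle % len(chroms)] if inter else d_chrom
        if inter:
            chrom_cycle += 1
        a_pos = take(a_chrom, size)  # reserve room for the inserted copy
        plans.append(
            {
                "kind": "csdp",
                "event_id": f"csdp{i + 1}",
                "donor": GenomeInterval(d_chrom, d_start, d_start + size),
                "opening": d_start + int(rng.uniform(0.3, 0.7) * size),
                "acceptor": (a_chrom, a_pos),
                "orientation": "inverted" if rng.random() < cfg.inverted_fraction else "parallel",
                "divergence": float(rng.uniform(*cfg.divergence_range)),
                "scars": cfg.scar_model.draw_junctions(rng),
            }
        )
    for i in range(cfg.n_decoys):
        size = log_uniform(*cfg.decoy_size_range)
        kind = "tandem_dup" if i % 2 == 0 else "transposition_inversion"
        d_chrom = chroms[chrom_cycle % len(chroms)]
        chrom_cycle += 1
        d_start = take(d_chrom, 2 * size if kind == "tandem_dup" else size)
        plan = {
            "kind": kind,
            "event_id": f"decoy{i + 1}",
            "donor": GenomeInterval(d_chrom, d_start, d_start + size),
            "divergence": float(rng.uniform(*cfg.divergence_range)),
        }
        if kind == "transposition_inversion":
            a_chrom = chroms[chrom_cycle % len(chroms)]
            chrom_cycle += 1
            plan["acceptor"] = (a_chrom, take(a_chrom, size))
            plan["internal_point"] = d_start + int(rng.uniform(0.3, 0.7) * size)
        plans.append(plan)

    def shift_plans(pending: list[dict], chrom: str, pos: int, delta: int) -> None:
        for pl in pending:
            iv = pl["donor"]
            if iv.chrom == chrom and iv.start >= pos:
                pl["donor"] = GenomeInterval(iv.chrom, iv.start + delta, iv.end + delta)
                if "opening" in pl:
                    pl["opening"] += delta
                if "internal_point" in pl:
                    pl["internal_point"] += delta
            if "acceptor" in pl and pl["acceptor"][0] == chrom and pl["acceptor"][1] >= pos:
                pl["acceptor"] = (chrom, pl["acceptor"][1] + delta)

    truths: list[TruthRecord] = []
    for idx, plan in enumerate(plans):
        before = genome.lengths
        if plan["kind"] == "csdp":
            truth = plant_csdp(
                genome,
                donor=plan["donor"],
                opening=plan["opening"],
                acceptor=plan["acceptor"],
                orientation=plan["orientation"],
                scars=plan["scars"],
                divergence=plan["divergence"],
                seed=int(rng.integers(0, 2**31 - 1)),
                event_id=plan["event_id"],
            )
        else:
            truth = plant_decoy(
                genome,
                kind=plan["kind"],
                donor=plan["donor"],
                acceptor=plan.get("acceptor"),
                internal_point=plan.get("internal_point"),
                divergence=plan["divergence"],
                seed=int(rng.integers(0, 2**31 - 1)),
                event_id=plan["event_id"],
            )
        chrom = truth.derivative_span.chrom
        delta = genome.lengths[chrom] - before[chrom]
        pos = truth.derivative_span.start
        for t in truths:
            t.shift(chrom, pos, delta)
        shift_plans(plans[idx + 1 :], chrom, pos, delta)
        truths.append(truth)

    sd_table = emulate_sd_annotation(
        genome, truths, noise=cfg.noise, seed=int(rng.integers(0, 2**31 - 1))
    )
    return SimulatedDataset(genome=genome, truths=truths, sd_table=sd_table, config=cfg)
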