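"""Readers and writers for SD annotation tables.

Two dialects are supported:

``genomicSuperDups``
    The UCSC schema (tab-separated, no header): ``bin, chrom, chromStart,
    chromEnd, name, score, strand, otherChrom, otherStart, otherEnd, ...,
    fracMatch, ...``.  Coordinates are 0-based half-open and are used as-is.
    Columns not needed by the data model are preserved opaquely and written
    back verbatim on round-trip.

``bedpe_min``
    A reduced dialect: ``chromA, startA, endA, chromB, startB, endB, name,
    fracMatch, strand`` (tab-separated, ``#`` comments).  Coordinates in this
    dialect are 1-based fully-closed and are converted to the internal
    0-based half-open convention at parse time.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .model import GenomeInterval, SDRecord, SDTable

log = logging.getLogger(__name__)

DIALECTS = ("genomicSuperDups", "bedpe_min")

#: Column order of the UCSC genomicSuperDups table dump.
GSD_COLUMNS = (
    "bin", "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "otherChrom", "otherStart", "otherEnd", "otherSize", "uid",
    "posBasesHit", "testResult", "verdict", "chits", "ccov", "alignfile",
    "alignL", "indelN", "indelS", "alignB", "matchB", "mismatchB",
    "transitionsB", "transversionsB", "fracMatch", "fracMatchIndel",
    "jcK", "k2K",
)
_GSD_FRACMATCH = GSD_COLUMNS.index("fracMatch")

BEDPE_HEADER = "#chromA\tstartA\tendA\tchromB\tstartB\tendB\tname\tfracMatch\tstrand"


class MalformedRowError(ValueError):
    pass


def _parse_gsd_row(fields: list[str], idx: int) -> SDRecord:
    if len(fields) < _GSD_FRACMATCH + 1:
        raise MalformedRowError(f"expected >= {_GSD_FRACMATCH + 1} columns, got {len(fields)}")
    side_a = GenomeInterval(fields[1], int(fields[2]), int(fields[3]))
    side_b = GenomeInterval(fields[7], int(fields[8]), int(fields[9]))
    strand = fields[6]
    frac = float(fields[_GSD_FRACMATCH])
    return SDRecord(
        side_a=side_a,
        side_b=side_b,
        strand=strand,
        frac_match=frac,
        record_id=f"gsd{idx}",
        extra=tuple(fields),
    )


def _parse_bedpe_row(fields: list[str], idx: int) -> SDRecord:
    if len(fields) < 9:
        raise MalformedRowError(f"expected 9 columns, got {len(fields)}")
    # 1-based fully-closed -> 0-based half-open
    side_a = GenomeInterval(fields[0], int(fields[1]) - 1, int(fields[2]))
    side_b = GenomeInterval(fields[3], int(fields[4]) - 1, int(fields[5]))
    name = fields[6] or f"bedpe{idx}"
    return SDRecord(
        side_a=side_a,
        side_b=side_b,
        strand=fields[8],
        frac_match=float(fields[7]),
        record_id=name,
    )


def read_sd_table(path: str | Path, dialect: str = "genomicSuperDups") -> SDTable:
    """Parse an SD table; malformed rows are skipped and counted.

    The number of skipped rows is exposed as ``table.n_skipped`` and logged.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; supported: {DIALECTS}")
    path = Path(path)
    parse = _parse_gsd_row if dialect == "genomicSuperDups" else _parse_bedpe_row
    table = SDTable(source_dialect=dialect)
    skipped = 0
    with open(path) as fh:
        idx = 0
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                table.append(parse(fields, idx))
            except (MalformedRowError, ValueError) as exc:
                skipped += 1
                log.warning("skipping malformed row %d: %s", idx, exc)
            idx += 1
    table.n_skipped = skipped
    if skipped:
        log.warning("%d malformed row(s) skipped in %s", skipped, path)
    return table


def _gsd_row(rec: SDRecord) -> str:
    if rec.extra and len(rec.extra) >= _GSD_FRACMATCH + 1:
        fields = list(rec.extra)
    else:
        fields = ["0"] * len(GSD_COLUMNS)
        fields[4] = rec.record_id or rec.side_b.chrom
        fields[11] = rec.record_id or "0"
    fields[1] = rec.side_a.chrom
    fields[2] = str(rec.side_a.start)
    fields[3] = str(rec.side_a.end)
    fields[6] = rec.strand
    fields[7] = rec.side_b.chrom
    fields[8] = str(rec.side_b.start)
    fields[9] = str(rec.side_b.end)
    fields[_GSD_FRACMATCH] = repr(rec.frac_match)
    return "\t".join(fields)


def _bedpe_row(rec: SDRecord) -> str:
    return "\t".join(
        [
            rec.side_a.chrom, str(rec.side_a.start + 1), str(rec.side_a.end),
            rec.side_b.chrom, str(rec.side_b.start + 1), str(rec.side_b.end),
            rec.record_id, repr(rec.frac_match), rec.strand,
        ]
    )


def write_sd_table(table: SDTable, path: str | Path, dialect: str = "genomicSuperDups") -> None:
    """Write a table in the requested dialect; bit-stable for identical input."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; supported: {DIALECTS}")
    rowfn = _gsd_row if dialect == "genomicSuperDups" else _bedpe_row
    with open(path, "w") as fh:
        if dialect == "bedpe_min":
            fh.write(BEDPE_HEADER + "\n")
        for rec in table:
            fh.write(rowfn(rec) + "\n")
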