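"""Polarization and evolutionary dating on a primate species ladder.

Which copy is ancestral and which derivative, and how old the duplication
is, are inferred from a presence/absence table of the two loci across a
ladder of species ordered from the human ingroup outward.  The locus found
in more outgroup species is the ancestral one; the age is bracketed by the
nearest species lacking the derivative locus.  Presence here means "locus
alignable in that assembly" and is an input, not computed from genomes;
``unknown`` entries (assembly gaps) are skipped, not treated as absence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

DEFAULT_SPECIES = (
    "human",
    "chimpanzee",
    "gorilla",
    "orangutan",
    "gibbon",
    "green_monkey",
    "marmoset",
)

PRESENCE_VALUES = ("yes", "no", "unknown")

OLDER_THAN_LADDER = "older_than_ladder"


@dataclass(frozen=True)
class SpeciesLadder:
    species: tuple[str, ...] = DEFAULT_SPECIES

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("ladder is empty")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in ladder")
        if self.species[0] != "human":
            raise ValueError("ladder must start at human")

    def __iter__(self):
        return iter(self.species)

    def __len__(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        return self.species.index(name)


class PresenceTable:
    """Per-species presence of the two loci of a duplication pair."""

    def __init__(self, entries: Mapping[str, tuple[str, str]]) -> None:
        self.entries: dict[str, tuple[str, str]] = {}
        for sp, (l1, l2) in entries.items():
            if l1 not in PRESENCE_VALUES or l2 not in PRESENCE_VALUES:
                raise ValueError(f"bad presence value for {sp}: {(l1, l2)}")
            self.entries[sp] = (l1, l2)
        if "human" not in self.entries:
            raise ValueError("human row missing")
        if self.entries["human"] != ("yes", "yes"):
            raise ValueError("human row must be yes/yes for a valid duplication pair")

    def locus(self, locus_id: int, species: str) -> str:
        return self.entries[species][locus_id - 1]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("species\tlocus1\tlocus2\n")
            for sp, (l1, l2) in self.entries.items():
                fh.write(f"{sp}\t{l1}\t{l2}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceTable":
        entries = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("species"):
                raise ValueError("presence table must start with a 'species' header line")
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                sp, l1, l2 = line.rstrip("\n").split("\t")
                entries[sp] = (l1, l2)
        return cls(entries)


def polarize(presence: PresenceTable, ladder: SpeciesLadder | None = None) -> dict:
    """Assign ancestral/derivative labels from outgroup presence counts.

    The locus present ("yes") in strictly more non-human ladder species is
    ancestral; unknown entries are ignored.  Identical presence profiles
    leave the pair unpolarized.
    """
    ladder = ladder or SpeciesLadder()
    counts = [0, 0]
    profiles: list[list[str]] = [[], []]
    for sp in ladder:
        if sp == "human" or sp not in presence.entries:
            continue
        for locus in (1, 2):
            val = presence.locus(locus, sp)
            profiles[locus - 1].append(val)
            if val == "yes":
                counts[locus - 1] += 1
    if profiles[0] == profiles[1] or counts[0] == counts[1]:
        return {"polarized": False, "ancestral": None, "derivative": None}
    if counts[0] > counts[1]:
        return {"polarized": True, "ancestral": 1, "derivative": 2}
    return {"polarized": True, "ancestral": 2, "derivative": 1}


def closest_without_derivative(
    presence: PresenceTable,
    ladder: SpeciesLadder | None = None,
    derivative_locus: int | None = None,
) -> str:
    """Nearest species to human whose derivative-locus entry is "no".

    The duplication arose on the branch between that species' split and the
    previous one.  Unknown entries are skipped.  If the derivative is
    present in every informative species the sentinel
    ``"older_than_ladder"`` is returned; a table with no informative
    non-human entries at all is unresolvable and raises.
    """
    ladder = ladder or SpeciesLadder()
    if derivative_locus is None:
        pol = polarize(presence, ladder)
        if not pol["polarized"]:
            raise ValueError("pair is unpolarized; pass derivative_locus explicitly")
        derivative_locus = pol["derivative"]
    informative = 0
    for sp in list(ladder)[1:]:
        if sp not in presence.entries:
            continue
        val = presence.locus(derivative_locus, sp)
        if val == "no":
            return sp
        if val == "yes":
            informative += 1
    if informative == 0:
        raise ValueError("presence table has no informative outgroup entries")
    return OLDER_THAN_LADDER


def identity_age_consistency(
    entries: list[tuple[str, str, float]],
    ladder: SpeciesLadder | None = None,
) -> dict:
    """Check that pair identity decreases (weakly) with origin age.

    ``entries`` are ``(cluster_id, origin_species, percent_identity)``
    tuples, origin as returned by :func:`closest_without_derivative`.
    Reports violations; never fails.
    """
    ladder = ladder or SpeciesLadder()
    order = {sp: i for i, sp in enumerate(ladder)}
    order[OLDER_THAN_LADDER] = len(ladder)
    ranked = sorted(entries, key=lambda e: order[e[1]])
    by_rank: dict[int, list[float]] = {}
    for _, origin, ident in ranked:
        by_rank.setdefault(order[origin], []).append(ident)
    medians = []
    for rank in sorted(by_rank):
        vals = sorted(by_rank[rank])
        mid = len(vals) // 2
        med = vals[mid] if len(vals) % 2 else (vals[mid - 1] + vals[mid]) / 2
        medians.append((rank, med))
    violations = []
    for (r1, m1), (r2, m2) in zip(medians, medians[1:]):
        if m2 > m1:
            violations.append({"younger_rank": r1, "older_rank": r2,
                               "younger_median": m1, "older_median": m2})
    return {"consistent": not violations, "violations": violations,
            "medians_by_rank": medians}
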