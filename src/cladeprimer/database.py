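"""Reference databases: unaligned sequences with ranked taxonomic lineages.

A reference database pairs each nucleotide sequence with a SILVA-style
lineage (``Domain;Phylum;Class;Order;Family;Genus``).  Databases support
grouping and in-group/out-group partitioning at any rank, which is what
the coverage/specificity machinery consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .iupac import normalize

#: Fixed rank order, shallowest to deepest.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class NucleotideSequence:
    """An unaligned nucleotide sequence (uppercase IUPAC, no gaps)."""

    id: str
    residues: str

    def __post_init__(self):
        seq = normalize(self.residues)
        if not seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DbRecord:
    sequence: NucleotideSequence
    lineage: tuple[str, ...]

    def __post_init__(self):
        if not self.lineage:
            raise ValueError(f"record {self.sequence.id!r} has an empty lineage")
        if len(self.lineage) > len(RANKS):
            raise ValueError(
                f"record {self.sequence.id!r}: lineage deeper than {len(RANKS)} ranks"
            )

    @property
    def id(self) -> str:
        return self.sequence.id

    def name_at(self, rank: str) -> str | None:
        """Taxon name at a rank, or None if the lineage is too shallow."""
        i = RANKS.index(rank)
        return self.lineage[i] if i < len(self.lineage) else None

    def in_taxon(self, taxon: str) -> bool:
        """True if ``taxon`` appears at any rank of this record's lineage."""
        return taxon in self.lineage


class ReferenceDatabase:
    """A taxonomically labelled collection of unaligned sequences."""

    def __init__(self, records: list[DbRecord]):
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in database: {dup[:5]}")
        self.records = list(records)

    @classmethod
    def from_pairs(cls, seqs, lineages: dict[str, tuple[str, ...]]) -> "ReferenceDatabase":
        """Build from (id, residues) pairs and an id -> lineage map."""
        records = []
        for sid, residues in seqs:
            if sid not in lineages:
                raise KeyError(f"no lineage for sequence {sid!r}")
            records.append(DbRecord(NucleotideSequence(sid, residues), tuple(lineages[sid])))
        return cls(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def taxa(self, rank: str) -> list[str]:
        """Distinct taxon names at a rank, in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            name = r.name_at(rank)
            if name is not None:
                seen.setdefault(name, None)
        return list(seen)

    def group_by(self, rank: str) -> dict[str, list[DbRecord]]:
        groups: dict[str, list[DbRecord]] = {}
        for r in self.records:
            name = r.name_at(rank)
            if name is not None:
                groups.setdefault(name, []).append(r)
        return groups

    def partition(self, taxon: str) -> tuple[list[DbRecord], list[DbRecord]]:
        """Split into (in-group, out-group) by membership of ``taxon`` at any rank."""
        ins = [r for r in self.records if r.in_taxon(taxon)]
        outs = [r for r in self.records if not r.in_taxon(taxon)]
        if not ins:
            raise ValueError(f"taxon {taxon!r} not present in the database")
        return ins, outs
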