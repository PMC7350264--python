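"""Core data containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator


@dataclass(frozen=True)
class PurificationRecord:
    """One AP-MS purification: a bait and the set of identified proteins.

    The bait is always a member of its own identified set (matrix-model
    convention: bait–prey and prey–prey pairs count alike).
    """

    purification_id: str
    bait: str
    proteins: frozenset[str]

    def __post_init__(self) -> None:
        if self.bait not in self.proteins:
            object.__setattr__(self, "proteins", self.proteins | {self.bait})


@dataclass
class PurificationTable:
    """A collection of purification records (one AP-MS experiment each)."""

    records: list[PurificationRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[PurificationRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def N(self) -> int:
        """Number of purifications."""
        return len(self.records)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for record in self.records:
            out.update(record.proteins)
        return frozenset(out)


@dataclass(frozen=True)
class ProteoformRecord:
    """All accessions of one gene: canonical, splice variants, master form."""

    gene: str
    canonical: str
    splices: tuple[str, ...] = ()
    master: str | None = None

    @property
    def accessions(self) -> tuple[str, ...]:
        acc = (self.canonical,) + self.splices
        if self.master is not None:
            acc = acc + (self.master,)
        return acc


class ProteoformMap:
    """Gene → proteoform accessions, with reverse lookup by accession."""

    def __init__(self, records: Iterable[ProteoformRecord]):
        self.by_gene: dict[str, ProteoformRecord] = {}
        self.canonical_of: dict[str, str] = {}
        self.gene_of: dict[str, str] = {}
        self.form_of: dict[str, str] = {}
        for rec in records:
            if rec.gene in self.by_gene:
                raise ValueError(f"duplicate gene in proteoform map: {rec.gene}")
            self.by_gene[rec.gene] = rec
            self.canonical_of[rec.canonical] = rec.canonical
            self.gene_of[rec.canonical] = rec.gene
            self.form_of[rec.canonical] = "canonical"
            for splice in rec.splices:
                self.canonical_of[splice] = splice  # splice forms stay distinct
                self.gene_of[splice] = rec.gene
                self.form_of[splice] = "splice"
            if rec.master is not None:
                self.canonical_of[rec.master] = rec.canonical
                self.gene_of[rec.master] = rec.gene
                self.form_of[rec.master] = "master"

    def __len__(self) -> int:
        return len(self.by_gene)

    def __iter__(self) -> Iterator[ProteoformRecord]:
        return iter(self.by_gene.values())

    def genes_with_splices(self) -> list[str]:
        return sorted(g for g, rec in self.by_gene.items() if rec.splices)
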