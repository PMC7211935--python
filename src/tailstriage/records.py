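"""Protein records and proteome containers.

A :class:`ProteinRecord` is the anchor object of the pipeline: every peptide
observation is resolved against a record by accession + 1-based start
position, and every cleavage site is expressed as the 1-based index of its P1
residue on the full precursor sequence.  Records carry the annotations the
triage stages need — species (for cross-species consensus), contaminant class
(immunoglobulins and crystallins are excluded wholesale), and domain
intervals (for mapping cleavage sites onto protein architecture).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CONTAMINANT_CLASSES = ("none", "immunoglobulin", "crystallin")


@dataclass(frozen=True)
class Domain:
    """A named interval on a protein, 1-based inclusive endpoints."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid domain interval {self.name}: [{self.start}, {self.end}]"
            )

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class ProteinRecord:
    """An annotated precursor sequence.

    Parameters
    ----------
    accession:
        Unique identifier within a :class:`ProteinSet`.
    gene_symbol:
        Symbol used for cross-species matching (compared case-insensitively).
    species:
        Free-text species tag, e.g. ``"rabbit"`` or ``"monkey"``.
    sequence:
        Uppercase amino-acid string over the standard 20-letter alphabet.
    contaminant_class:
        ``"none"``, ``"immunoglobulin"`` or ``"crystallin"``.
    domains:
        Annotated intervals in 1-based precursor coordinates.
    """

    accession: str
    gene_symbol: str
    species: str
    sequence: str
    contaminant_class: str = "none"
    domains: Tuple[Domain, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"{self.accession}: sequence must be uppercase")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"{self.accession}: non-standard residues {sorted(bad)}"
            )
        if self.contaminant_class not in CONTAMINANT_CLASSES:
            raise ValueError(
                f"{self.accession}: unknown contaminant class "
                f"{self.contaminant_class!r}"
            )
        object.__setattr__(self, "domains", tuple(self.domains))
        for d in self.domains:
            if d.end > len(self.sequence):
                raise ValueError(
                    f"{self.accession}: domain {d.name} exceeds sequence length"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_contaminant(self) -> bool:
        return self.contaminant_class != "none"


class ProteinSet:
    """An accession-keyed collection of :class:`ProteinRecord` objects."""

    def __init__(self, records: Iterable[ProteinRecord]):
        self._by_accession: Dict[str, ProteinRecord] = {}
        for rec in records:
            if rec.accession in self._by_accession:
                raise ValueError(f"duplicate accession {rec.accession}")
            self._by_accession[rec.accession] = rec

    def __len__(self) -> int:
        return len(self._by_accession)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._by_accession.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def __getitem__(self, accession: str) -> ProteinRecord:
        try:
            return self._by_accession[accession]
        except KeyError:
            raise KeyError(f"accession {accession!r} not in proteome") from None

    def get(self, accession: str) -> Optional[ProteinRecord]:
        return self._by_accession.get(accession)

    def records(self) -> List[ProteinRecord]:
        return list(self._by_accession.values())

    def subset(self, species: Optional[str] = None) -> "ProteinSet":
        recs = [r for r in self if species is None or r.species == species]
        return ProteinSet(recs)

    # ------------------------------------------------------------------ FASTA

    def to_fasta(self, path) -> None:
        """Write records as FASTA.

        The header id packs ``accession|gene_symbol|species|contaminant_class``;
        domain intervals are serialized in the description as
        ``domains=name:start-end,...`` so a round trip is lossless.
        """
        seqrecords = []
        for rec in self:
            header = "|".join(
                [rec.accession, rec.gene_symbol, rec.species, rec.contaminant_class]
            )
            desc = ""
            if rec.domains:
                desc = "domains=" + ",".join(
                    f"{d.name}:{d.start}-{d.end}" for d in rec.domains
                )
            seqrecords.append(
                SeqRecord(Seq(rec.sequence), id=header, description=desc)
            )
        SeqIO.write(seqrecords, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "ProteinSet":
        records = []
        for sr in SeqIO.parse(str(path), "fasta"):
            parts = sr.id.split("|")
            if len(parts) != 4:
                raise ValueError(
                    f"FASTA header {sr.id!r} does not match "
                    "accession|gene_symbol|species|contaminant_class"
                )
            accession, gene, species, contam = parts
            domains = []
            m = re.search(r"domains=(\S+)", sr.description)
            if m:
                for chunk in m.group(1).split(","):
                    name, span = chunk.rsplit(":", 1)
                    start, end = span.split("-")
                    domains.append(Domain(name, int(start), int(end)))
            records.append(
                ProteinRecord(
                    accession=accession,
                    gene_symbol=gene,
                    species=species,
                    sequence=str(sr.seq).upper(),
                    contaminant_class=contam,
                    domains=tuple(domains),
                )
            )
        return cls(records)

    def residue_composition(self) -> Dict[str, float]:
        """Relative frequency of each of the 20 residues over all sequences."""
        counts = {aa: 0 for aa in AMINO_ACIDS}
        total = 0
        for rec in self:
            for aa in rec.sequence:
                counts[aa] += 1
                total += 1
        if total == 0:
            raise ValueError("empty proteome")
        return {aa: c / total for aa, c in counts.items()}
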