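"""Per-species concatenated core-genome reference sequences.

A clade's core genome — the genes shared by every strain of the clade —
serves here as a condensed reference sequence for one species. Each
species' core genes are concatenated into a single record so that a read
mapping anywhere in the core genome counts toward that species.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_IUPAC_STRICT = set("ACGTN")


@dataclass(frozen=True)
class SpeciesGeneSet:
    """Ordered core-gene catalogue for one reference species."""

    species_id: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if len(self.genes) == 0:
            raise ValueError(
                f"species {self.species_id!r} has an empty gene list"
            )
        cleaned = []
        for idx, gene in enumerate(self.genes):
            if len(gene) < 1:
                raise ValueError(
                    f"species {self.species_id!r}: gene {idx} is empty"
                )
            up = gene.upper()
            bad = set(up) - _IUPAC_STRICT
            if bad:
                raise ValueError(
                    f"species {self.species_id!r}: gene {idx} contains "
                    f"non-ACGTN characters {sorted(bad)}"
                )
            cleaned.append(up)
        object.__setattr__(self, "genes", tuple(cleaned))


@dataclass(frozen=True)
class ReferenceEntry:
    """One concatenated core-genome sequence g_i of base length l_i."""

    species_id: str
    sequence: str
    offsets: tuple[int, ...]  # start of each gene within the concatenation

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceSet:
    """The M reference species G = {g_1..g_M} with base lengths l_i."""

    entries: tuple[ReferenceEntry, ...]

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError("reference set must contain at least one species")
        ids = [e.species_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate species ids: {dupes}")

    @property
    def M(self) -> int:
        return len(self.entries)

    @property
    def species_ids(self) -> list[str]:
        return [e.species_id for e in self.entries]

    @property
    def lengths(self) -> list[int]:
        return [e.length for e in self.entries]

    def index_of(self, species_id: str) -> int:
        for i, e in enumerate(self.entries):
            if e.species_id == species_id:
                return i
        raise KeyError(species_id)

    def __len__(self) -> int:
        return self.M

    def __iter__(self):
        return iter(self.entries)


def build_reference(
    gene_sets: Sequence[SpeciesGeneSet], spacer_n: int = 0
) -> ReferenceSet:
    """Concatenate each species' core genes into one reference sequence.

    Gene order is preserved and genes are joined directly; ``spacer_n``
    inserts a run of N characters between consecutive genes for users who
    want to suppress alignments spanning gene junctions (default 0, i.e.
    plain concatenation). l_i counts all bases including N and spacers.
    """
    if len(gene_sets) == 0:
        raise ValueError("no gene sets provided")
    if spacer_n < 0:
        raise ValueError("spacer_n must be >= 0")
    spacer = "N" * spacer_n
    entries = []
    for gs in gene_sets:
        offsets = []
        pos = 0
        parts = []
        for j, gene in enumerate(gs.genes):
            if j > 0 and spacer_n:
                parts.append(spacer)
                pos += spacer_n
            offsets.append(pos)
            parts.append(gene)
            pos += len(gene)
        entries.append(
            ReferenceEntry(gs.species_id, "".join(parts), tuple(offsets))
        )
    return ReferenceSet(tuple(entries))


def write_reference_fasta(
    refset: ReferenceSet, path: str | Path, lengths_path: str | Path | None = None
) -> None:
    """Write one FASTA record per species; optionally a lengths TSV."""
    records = [
        SeqRecord(Seq(e.sequence), id=e.species_id, description="")
        for e in refset
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    if lengths_path is not None:
        with open(lengths_path, "w") as fh:
            fh.write("species_id\tlength\n")
            for e in refset:
                fh.write(f"{e.species_id}\t{e.length}\n")


def load_reference(path: str | Path) -> ReferenceSet:
    """Load a reference set from a one-record-per-species FASTA.

    Gene boundaries are not recoverable from the FASTA; each loaded entry
    carries a single offset 0.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    entries = []
    with opener(path, "rt") as fh:
        for lineno, rec in enumerate(SeqIO.parse(fh, "fasta"), start=1):
            seq = str(rec.seq).upper()
            if len(seq) == 0:
                raise ValueError(f"empty sequence for record {rec.id!r}")
            bad = set(seq) - _IUPAC_STRICT
            if bad:
                raise ValueError(
                    f"record {rec.id!r} contains non-ACGTN characters "
                    f"{sorted(bad)}"
                )
            entries.append(ReferenceEntry(rec.id, seq, (0,)))
    if not entries:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceSet(tuple(entries))


def read_gene_sets(
    fasta_path: str | Path,
    species_map: Mapping[str, str] | str | Path | None = None,
) -> list[SpeciesGeneSet]:
    """Read core-gene catalogues from a multi-FASTA.

    With no ``species_map`` every record is its own species (record id =
    species id). A map — either a dict or a two-column TSV path of
    (gene_id, species_id) — groups gene records into species, preserving
    record order within each species and species order of first appearance.
    """
    if species_map is not None and not isinstance(species_map, Mapping):
        mapping: dict[str, str] = {}
        with open(species_map) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                gene_id, _, species_id = line.partition("\t")
                if not species_id:
                    raise ValueError(
                        f"species map line without two columns: {line!r}"
                    )
                mapping[gene_id] = species_id
        species_map = mapping

    opener = gzip.open if str(fasta_path).endswith(".gz") else open
    grouped: dict[str, list[str]] = {}
    with opener(fasta_path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if species_map is None:
                sp = rec.id
            else:
                try:
                    sp = species_map[rec.id]
                except KeyError:
                    raise KeyError(
                        f"gene {rec.id!r} missing from the species map"
                    ) from None
            grouped.setdefault(sp, []).append(str(rec.seq))
    if not grouped:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return [SpeciesGeneSet(sp, tuple(genes)) for sp, genes in grouped.items()]
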