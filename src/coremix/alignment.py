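"""SAM parsing, hit filtering, read deduplication and Φ estimation.

The mixture model needs, for every reference g_m, a read-composition
distribution φ over the distinct read sequences. With no prior on Φ it is
approximated directly from alignment results: φ_{k,m} is the fraction of
the read occurrences hitting g_m with high quality whose sequence is r_k.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
import scipy.sparse as sp
from Bio import SeqIO

from .reference import ReferenceSet

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


@dataclass(frozen=True)
class HitRecord:
    """One mapped alignment of a read occurrence against a reference."""

    read_occurrence_id: str
    reference_id: str
    edit_distance: int
    alignment_length: int
    is_mapped: bool = True
    position: int = -1  # 0-based reference start when known

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if not 0 <= self.edit_distance <= self.alignment_length:
            raise ValueError("edit_distance must lie in [0, alignment_length]")

    @property
    def error_rate(self) -> float:
        return self.edit_distance / self.alignment_length


@dataclass
class ReadTable:
    """The N read occurrences collapsed to K distinct sequences.

    ``occurrence_index[i]`` is the distinct-sequence index k of the i-th
    occurrence; ``multiplicity[k]`` counts the occurrences of sequence k.
    """

    sequences: list[str]
    multiplicity: np.ndarray
    occurrence_ids: list[str]
    occurrence_index: np.ndarray

    @property
    def K(self) -> int:
        return len(self.sequences)

    @property
    def N(self) -> int:
        return len(self.occurrence_ids)

    def occurrence_of(self, occurrence_id: str) -> int:
        return self._id_lookup[occurrence_id]

    def __post_init__(self) -> None:
        self._id_lookup = {oid: i for i, oid in enumerate(self.occurrence_ids)}
        if len(self._id_lookup) != len(self.occurrence_ids):
            raise ValueError("duplicate read occurrence ids")
        if int(self.multiplicity.sum()) != self.N:
            raise ValueError("multiplicities do not sum to N")

    @classmethod
    def from_sequences(
        cls, seqs: Sequence[str], ids: Sequence[str] | None = None
    ) -> "ReadTable":
        if len(seqs) == 0:
            raise ValueError("no reads provided")
        if ids is None:
            ids = [f"read_{i}" for i in range(len(seqs))]
        distinct: dict[str, int] = {}
        occ_index = np.empty(len(seqs), dtype=np.int64)
        for i, s in enumerate(seqs):
            k = distinct.setdefault(s, len(distinct))
            occ_index[i] = k
        mult = np.bincount(occ_index, minlength=len(distinct)).astype(np.int64)
        return cls(list(distinct), mult, list(ids), occ_index)


def build_read_table(reads: str | Path | Iterable[str]) -> ReadTable:
    """Collapse reads to distinct sequences by exact string identity.

    ``reads`` is a FASTA/FASTQ path (gzip accepted, format sniffed from the
    extension), an object with ``ids`` and ``sequences`` attributes (e.g. a
    simulated read set), or any iterable of sequence strings.
    """
    if hasattr(reads, "ids") and hasattr(reads, "sequences"):
        return ReadTable.from_sequences(list(reads.sequences), list(reads.ids))
    if isinstance(reads, (str, Path)):
        path = str(reads)
        stem = path[:-3] if path.endswith(".gz") else path
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
        opener = gzip.open if path.endswith(".gz") else open
        seqs, ids = [], []
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, fmt):
                seqs.append(str(rec.seq).upper())
                ids.append(rec.id)
        if not seqs:
            raise ValueError(f"no reads found in {path}")
        return ReadTable.from_sequences(seqs, ids)
    seqs = list(reads)
    return ReadTable.from_sequences(seqs)


def _edit_distance_from_md(aln: pysam.AlignedSegment) -> int:
    """NM fallback: mismatches from MD plus insertions from CIGAR."""
    try:
        md = aln.get_tag("MD")
    except KeyError:
        raise ValueError(
            f"alignment {aln.query_name!r} carries neither NM nor MD; "
            "cannot determine edit distance"
        ) from None
    mismatches = 0
    deletions = 0
    for num, dele, sub in _MD_TOKEN.findall(str(md)):
        if dele:
            deletions += len(dele) - 1
        elif sub:
            mismatches += 1
    insertions = sum(
        length for op, length in (aln.cigartuples or []) if op == 1
    )
    return mismatches + deletions + insertions


def parse_sam(path: str | Path, refset: ReferenceSet) -> list[HitRecord]:
    """Read mapped alignment lines (primary, secondary and supplementary)
    into HitRecords; unmapped lines yield no record.

    Reference names in the SAM must be a subset of the reference set's
    species ids. Edit distance comes from the NM tag when present, else
    from MD+CIGAR.
    """
    known = set(refset.species_ids)
    hits: list[HitRecord] = []
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped:
                    continue
                rname = aln.reference_name
                if rname not in known:
                    raise ValueError(
                        f"SAM reference {rname!r} is not in the reference set"
                    )
                try:
                    nm = int(aln.get_tag("NM"))
                except KeyError:
                    nm = _edit_distance_from_md(aln)
                alen = aln.query_alignment_length
                if alen == 0:  # CIGAR absent; fall back to read length
                    alen = aln.query_length or 1
                hits.append(
                    HitRecord(
                        read_occurrence_id=aln.query_name,
                        reference_id=rname,
                        edit_distance=nm,
                        alignment_length=alen,
                        position=aln.reference_start,
                    )
                )
    except OSError as exc:
        raise ValueError(f"cannot parse SAM {path}: {exc}") from exc
    return hits


def filter_high_quality(
    hits: Iterable[HitRecord], max_error_rate: float = 0.10
) -> list[HitRecord]:
    """Keep hits whose edit-distance rate is within ``max_error_rate``.

    This is the operational definition of a "high-quality" hit used by the
    Φ estimate; with threshold 0 only exact matches survive.
    """
    if not 0.0 <= max_error_rate <= 1.0:
        raise ValueError("max_error_rate must lie in [0, 1]")
    return [h for h in hits if h.error_rate <= max_error_rate]


@dataclass
class PhiMatrix:
    """Sparse K×M matrix of read-composition probabilities φ_{k,m}.

    Every reference column with at least one high-quality hit sums to 1;
    columns of references nobody hits are all zero.
    """

    matrix: sp.csr_matrix
    ref_ids: list[str]
    column_occurrences: np.ndarray  # per-reference denominator of the ratio

    @property
    def K(self) -> int:
        return self.matrix.shape[0]

    @property
    def M(self) -> int:
        return self.matrix.shape[1]

    def candidate_refs(self, k: int) -> np.ndarray:
        """Indices of references with φ_{k,m} > 0 for distinct read k."""
        row = self.matrix.getrow(k)
        return row.indices[row.data > 0]

    def row_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(indptr, ref indices, φ values) in CSR layout over rows."""
        m = self.matrix
        return (
            m.indptr.astype(np.int64),
            m.indices.astype(np.int64),
            m.data.astype(np.float64),
        )

    @classmethod
    def from_dense(cls, phi: np.ndarray, ref_ids: Sequence[str] | None = None):
        phi = np.asarray(phi, dtype=np.float64)
        if ref_ids is None:
            ref_ids = [f"ref_{m}" for m in range(phi.shape[1])]
        return cls(
            sp.csr_matrix(phi),
            list(ref_ids),
            np.zeros(phi.shape[1], dtype=np.int64),
        )


def estimate_phi(
    read_table: ReadTable,
    hits: Sequence[HitRecord],
    refset: ReferenceSet,
) -> PhiMatrix:
    """Estimate φ_{k,m} from high-quality hits.

    φ_{k,m} = (# occurrences of distinct read k with ≥1 hit on g_m)
            / (# occurrences with ≥1 hit on g_m).

    Multiple alignments of the same occurrence to the same reference count
    once (set semantics per (occurrence, reference) pair), so the estimate
    is invariant to hit order and to duplicated alignment lines.
    """
    K, M = read_table.K, refset.M
    ref_col = {sid: m for m, sid in enumerate(refset.species_ids)}
    pairs: set[tuple[int, int]] = set()
    for h in hits:
        occ = read_table.occurrence_of(h.read_occurrence_id)
        pairs.add((occ, ref_col[h.reference_id]))
    if pairs:
        occ_arr = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
        col_arr = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
        row_arr = read_table.occurrence_index[occ_arr]
        counts = sp.coo_matrix(
            (np.ones(len(pairs)), (row_arr, col_arr)), shape=(K, M)
        ).tocsr()
        denom = np.asarray(counts.sum(axis=0)).ravel()
    else:
        counts = sp.csr_matrix((K, M))
        denom = np.zeros(M)
    scale = np.divide(1.0, denom, out=np.zeros(M), where=denom > 0)
    phi = counts @ sp.diags(scale)
    return PhiMatrix(phi.tocsr(), list(refset.species_ids), denom.astype(np.int64))


def write_phi_tsv(phi: PhiMatrix, path: str | Path) -> None:
    """Debug dump: one line per nonzero φ entry."""
    coo = phi.matrix.tocoo()
    with open(path, "w") as fh:
        fh.write("distinct_read_index\treference_id\tphi\n")
        order = np.lexsort((coo.col, coo.row))
        for idx in order:
            fh.write(
                f"{coo.row[idx]}\t{phi.ref_ids[coo.col[idx]]}\t"
                f"{coo.data[idx]:.10g}\n"
            )
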