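"""Synthetic communities, shotgun reads, and a built-in read matcher.

The generative model is simulated directly: a community with preset
relative abundances a yields mixture weights θ_i ∝ a_i·l_i; each read
picks a species from Mult(θ), a uniform start position on that species'
concatenated core genome, and suffers i.i.d. base substitutions. A seeded
k-mer matcher then reports, for every read, all references carrying an
ungapped placement within a mismatch budget — the multi-mapping hit sets
the inference step consumes — so the whole pipeline runs with no external
mapper.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._kernels import count_mismatches
from .alignment import HitRecord, ReadTable
from .gibbs import theta_to_abundance
from .reference import ReferenceSet, SpeciesGeneSet, build_reference

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

#: Default preset community profile for ten-species fixtures: a decaying
#: abundance spread from dominant (25%) to rare (2%).
DEFAULT_ABUNDANCES = (
    0.25, 0.18, 0.14, 0.11, 0.09, 0.07, 0.06, 0.05, 0.03, 0.02,
)


def encode_sequence(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def abundance_to_theta(
    abundance: Sequence[float], lengths: Sequence[float]
) -> np.ndarray:
    """Mixture weights from relative abundances: θ_i ∝ a_i · l_i.

    Exact inverse of :func:`coremix.gibbs.theta_to_abundance`.
    """
    a = np.asarray(abundance, dtype=np.float64)
    ln = np.asarray(lengths, dtype=np.float64)
    if a.shape != ln.shape:
        raise ValueError("abundance and lengths must have equal length")
    if np.any(ln <= 0):
        raise ValueError("reference lengths must be positive")
    if not np.isclose(a.sum(), 1.0, atol=1e-9):
        raise ValueError("abundances must sum to 1")
    w = a * ln
    return w / w.sum()


@dataclass(frozen=True)
class CommunityTruth:
    """Preset relative abundances and the implied mixture weights."""

    ref_ids: tuple[str, ...]
    abundance: np.ndarray
    theta: np.ndarray

    @classmethod
    def from_abundance(
        cls, abundance: Sequence[float], refset: ReferenceSet
    ) -> "CommunityTruth":
        a = np.asarray(abundance, dtype=np.float64)
        if a.shape[0] != refset.M:
            raise ValueError("abundance length must match reference count")
        theta = abundance_to_theta(a, refset.lengths)
        return cls(tuple(refset.species_ids), a, theta)


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution noise for fixed-length single-ended reads.

    ``rate_profile`` optionally supplies a position-dependent substitution
    rate (array of length ``read_length``); by default the rate is uniform
    along the read. Indels are not modelled.
    """

    substitution_rate: float = 0.01
    read_length: int = 100
    rate_profile: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must lie in [0, 1)")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.rate_profile is not None and (
            len(self.rate_profile) != self.read_length
            or any(not 0.0 <= r < 1.0 for r in self.rate_profile)
        ):
            raise ValueError(
                "rate_profile must give one rate in [0, 1) per position"
            )

    def per_base_rates(self) -> np.ndarray:
        if self.rate_profile is not None:
            return np.asarray(self.rate_profile, dtype=np.float64)
        return np.full(self.read_length, self.substitution_rate)


@dataclass
class SimulatedReads:
    """Simulated read set with per-read ground-truth origin labels."""

    ids: list[str]
    sequences: list[str]
    origin: np.ndarray       # int64: source species index per read
    strand: np.ndarray       # int8: 0 forward, 1 reverse-complement
    start: np.ndarray        # int64: 0-based template start on the origin

    @property
    def n(self) -> int:
        return len(self.ids)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, self.sequences):
                fh.write(f">{rid}\n{seq}\n")

    def write_fastq(self, path: str | Path, quality_char: str = "I") -> None:
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, self.sequences):
                fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")

    def write_truth_tsv(self, path: str | Path, ref_ids: Sequence[str]) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\torigin_species\n")
            for rid, o in zip(self.ids, self.origin):
                fh.write(f"{rid}\t{ref_ids[o]}\n")


def simulate_reads(
    refset: ReferenceSet,
    truth: CommunityTruth,
    n_reads: int,
    error_model: ErrorModel = ErrorModel(),
    seed: int = 0,
    sample_reverse_strand: bool = False,
) -> SimulatedReads:
    """Draw reads from the generative model.

    Each read draws a species from Mult(θ), a uniform 0-based start in
    [0, l_i − read_length], copies ``read_length`` bases and applies
    independent substitutions. Reads come from the forward strand unless
    ``sample_reverse_strand`` flips a fair coin per read.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    L = error_model.read_length
    for e in refset:
        if e.length < L:
            raise ValueError(
                f"reference {e.species_id!r} (length {e.length}) is shorter "
                f"than the read length {L}"
            )
    rng = np.random.default_rng(seed)
    origin = rng.choice(refset.M, size=n_reads, p=truth.theta).astype(np.int64)
    starts = np.empty(n_reads, dtype=np.int64)
    reads = np.empty((n_reads, L), dtype=np.uint8)
    codes = [encode_sequence(e.sequence) for e in refset]
    for m in range(refset.M):
        sel = np.flatnonzero(origin == m)
        if sel.size == 0:
            continue
        s = rng.integers(0, refset.entries[m].length - L + 1, size=sel.size)
        starts[sel] = s
        reads[sel] = codes[m][s[:, None] + np.arange(L)[None, :]]
    if sample_reverse_strand:
        strand = rng.integers(0, 2, size=n_reads).astype(np.int8)
        flip = strand == 1
        reads[flip] = _COMPLEMENT[reads[flip][:, ::-1]]
    else:
        strand = np.zeros(n_reads, dtype=np.int8)
    rates = error_model.per_base_rates()
    sub_mask = (rng.random((n_reads, L)) < rates[None, :]) & (reads < 4)
    shift = rng.integers(1, 4, size=(n_reads, L), dtype=np.uint8)
    reads = np.where(sub_mask, (reads + shift) % 4, reads)
    width = max(1, len(str(n_reads - 1)))
    ids = [f"r{i:0{width}d}" for i in range(n_reads)]
    seqs = [decode_sequence(reads[i]) for i in range(n_reads)]
    return SimulatedReads(ids, seqs, origin, strand, starts)


# ---------------------------------------------------------------------------
# Built-in matcher: seeded k-mer index, provably equal to an exhaustive
# ungapped scan. For a mismatch budget t, t+1 disjoint seeds are taken from
# each read; any placement with <= t mismatches must match at least one seed
# exactly (pigeonhole), so every qualifying (read, offset) is enumerated.
# ---------------------------------------------------------------------------

_MAX_SEED_LEN = 13  # 4^13 fits comfortably in int64 k-mer codes


def _ranges(lo: np.ndarray, cnt: np.ndarray) -> np.ndarray:
    """Concatenate arange(lo_i, lo_i + cnt_i) for all i."""
    total = int(cnt.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    offs = np.arange(total, dtype=np.int64) - np.repeat(
        np.cumsum(cnt) - cnt, cnt
    )
    return np.repeat(lo, cnt) + offs


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-window; -1 where the window contains N."""
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    clean = codes.astype(np.int64)
    for j in range(k):
        vals = vals * 4 + np.minimum(clean[j : j + n], 3)
    has_n = np.cumsum(np.concatenate(([0], (codes >= 4).astype(np.int64))))
    bad = (has_n[k:] - has_n[:-k]) > 0
    vals[bad] = -1
    return vals


class _RefIndex:
    def __init__(self, refset: ReferenceSet):
        self.codes = np.concatenate(
            [encode_sequence(e.sequence) for e in refset]
        )
        self.bounds = np.concatenate(
            ([0], np.cumsum([e.length for e in refset]))
        ).astype(np.int64)
        self._kmer_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def sorted_kmers(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        if k not in self._kmer_cache:
            vals = _kmer_codes(self.codes, k)
            # windows crossing a reference boundary are not substrings of
            # any single reference
            pos = np.arange(vals.shape[0], dtype=np.int64)
            ridx = np.searchsorted(self.bounds, pos, side="right") - 1
            vals = vals.copy()
            vals[pos + k > self.bounds[ridx + 1]] = -1
            order = np.argsort(vals, kind="stable")
            self._kmer_cache[k] = (vals[order], pos[order])
        return self._kmer_cache[k]


def _match_group(
    index: _RefIndex, seq_codes: np.ndarray, L: int, t: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All (read, ref, start, mismatches) with mismatches <= t for a batch
    of equal-length reads, best placement per (read, ref)."""
    n_reads = seq_codes.shape[0]
    n_seeds = t + 1
    slen = min(L // n_seeds, _MAX_SEED_LEN)
    total_len = index.codes.shape[0]

    if total_len - L + 1 <= 0:
        e = np.empty(0, dtype=np.int64)
        return e, e, e, e
    if slen >= 1:
        sorted_vals, sorted_pos = index.sorted_kmers(slen)
        cand_read: list[np.ndarray] = []
        cand_start: list[np.ndarray] = []
        for j in range(n_seeds):
            off = j * slen
            sc = np.zeros(n_reads, dtype=np.int64)
            valid = np.ones(n_reads, dtype=bool)
            for x in range(slen):
                col = seq_codes[:, off + x].astype(np.int64)
                valid &= col < 4
                sc = sc * 4 + np.minimum(col, 3)
            sc[~valid] = -2  # never matches (index uses -1 for masked)
            lo = np.searchsorted(sorted_vals, sc, side="left")
            hi = np.searchsorted(sorted_vals, sc, side="right")
            cnt = (hi - lo).astype(np.int64)
            flat = _ranges(lo.astype(np.int64), cnt)
            cand_read.append(np.repeat(np.arange(n_reads, dtype=np.int64), cnt))
            cand_start.append(sorted_pos[flat] - off)
        reads_c = np.concatenate(cand_read)
        starts_c = np.concatenate(cand_start)
    else:
        # reads shorter than the seed budget allows: exhaustive offsets
        all_starts = np.arange(total_len - L + 1, dtype=np.int64)
        reads_c = np.repeat(np.arange(n_reads, dtype=np.int64), all_starts.size)
        starts_c = np.tile(all_starts, n_reads)

    if reads_c.size == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e, e, e
    ridx = np.searchsorted(index.bounds, starts_c, side="right") - 1
    ok = (
        (starts_c >= 0)
        & (starts_c + L <= index.bounds[np.minimum(ridx + 1, index.bounds.size - 1)])
        & (ridx >= 0)
        & (ridx < index.bounds.size - 1)
    )
    reads_c, starts_c = reads_c[ok], starts_c[ok]
    key = reads_c * np.int64(total_len) + starts_c
    _, first = np.unique(key, return_index=True)
    reads_c, starts_c = reads_c[first], starts_c[first]

    mm = np.empty(reads_c.shape[0], dtype=np.int64)
    read_ptr = (np.arange(n_reads + 1, dtype=np.int64)) * L
    count_mismatches(
        index.codes, seq_codes.reshape(-1), starts_c, reads_c, read_ptr, mm
    )
    keep = mm <= t
    reads_c, starts_c, mm = reads_c[keep], starts_c[keep], mm[keep]
    ridx = np.searchsorted(index.bounds, starts_c, side="right") - 1

    # best hit per (read, ref): minimal mismatches, then leftmost start
    pair = reads_c * np.int64(index.bounds.size) + ridx
    order = np.lexsort((starts_c, mm, pair))
    pair_s = pair[order]
    firsts = np.ones(pair_s.shape[0], dtype=bool)
    firsts[1:] = pair_s[1:] != pair_s[:-1]
    sel = order[firsts]
    local = starts_c[sel] - index.bounds[ridx[sel]]
    return reads_c[sel], ridx[sel], local, mm[sel]


def match_reads(
    sequences: Sequence[str],
    refset: ReferenceSet,
    max_error_rate: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Ungapped all-hits matching of reads against the reference set.

    Returns parallel arrays (read_index, ref_index, start, mismatches)
    giving, for every read and every reference, the best placement with
    mismatch count ≤ floor(max_error_rate · read_length), when one exists.
    Identical in output to scanning every offset of every reference.
    """
    if not 0.0 <= max_error_rate <= 1.0:
        raise ValueError("max_error_rate must lie in [0, 1]")
    index = _RefIndex(refset)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(sequences):
        by_len.setdefault(len(s), []).append(i)
    out_read, out_ref, out_start, out_mm = [], [], [], []
    for L, members in sorted(by_len.items()):
        t = int(np.floor(max_error_rate * L + 1e-12))
        mat = np.stack([encode_sequence(sequences[i]) for i in members])
        r, g, s, m = _match_group(index, mat, L, t)
        out_read.append(np.asarray(members, dtype=np.int64)[r])
        out_ref.append(g)
        out_start.append(s)
        out_mm.append(m)
    def cat(xs):
        return np.concatenate(xs) if xs else np.empty(0, dtype=np.int64)

    read_idx, ref_idx = cat(out_read), cat(out_ref)
    start_arr, mm_arr = cat(out_start), cat(out_mm)
    order = np.lexsort((ref_idx, read_idx))
    return read_idx[order], ref_idx[order], start_arr[order], mm_arr[order]


def simulate_alignment(
    reads: SimulatedReads | ReadTable | Sequence[str],
    refset: ReferenceSet,
    max_error_rate: float = 0.10,
    seed: int = 0,
) -> list[HitRecord]:
    """Produce the hit records an all-hits mapper would report.

    Distinct sequences are matched once and the hits replicated across
    identical occurrences. ``seed`` is accepted for interface symmetry;
    the matcher is deterministic.
    """
    if isinstance(reads, SimulatedReads):
        ids, seqs = reads.ids, reads.sequences
    elif isinstance(reads, ReadTable):
        ids, seqs = reads.occurrence_ids, [
            reads.sequences[k] for k in reads.occurrence_index
        ]
    else:
        seqs = list(reads)
        ids = [f"read_{i}" for i in range(len(seqs))]
    distinct: dict[str, int] = {}
    occ_k = [distinct.setdefault(s, len(distinct)) for s in seqs]
    uniq = list(distinct)
    r, g, s, m = match_reads(uniq, refset, max_error_rate)
    per_k: dict[int, list[tuple[int, int, int]]] = {}
    for ri, gi, si, mi in zip(r, g, s, m):
        per_k.setdefault(int(ri), []).append((int(gi), int(si), int(mi)))
    hits: list[HitRecord] = []
    ref_ids = refset.species_ids
    for i, (oid, k) in enumerate(zip(ids, occ_k)):
        L = len(seqs[i])
        for gi, si, mi in per_k.get(k, ()):
            hits.append(
                HitRecord(
                    read_occurrence_id=oid,
                    reference_id=ref_ids[gi],
                    edit_distance=mi,
                    alignment_length=L,
                    position=si,
                )
            )
    return hits


def write_sam(
    reads: SimulatedReads | tuple[Sequence[str], Sequence[str]],
    hits: Sequence[HitRecord],
    refset: ReferenceSet,
    path: str | Path,
) -> None:
    """Write hit records as a plain SAM file with @SQ headers and NM tags.

    The first hit of each read is primary (flag 0); further hits are
    secondary (flag 256). Reads without hits are emitted unmapped (flag 4).
    """
    if isinstance(reads, SimulatedReads):
        ids, seqs = reads.ids, reads.sequences
    else:
        ids, seqs = list(reads[0]), list(reads[1])
    seq_of = dict(zip(ids, seqs))
    by_read: dict[str, list[HitRecord]] = {rid: [] for rid in ids}
    for h in hits:
        by_read[h.read_occurrence_id].append(h)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for e in refset:
            fh.write(f"@SQ\tSN:{e.species_id}\tLN:{e.length}\n")
        for rid in ids:
            seq = seq_of[rid]
            recs = by_read[rid]
            if not recs:
                fh.write(f"{rid}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
                continue
            for j, h in enumerate(recs):
                flag = 0 if j == 0 else 256
                fh.write(
                    f"{rid}\t{flag}\t{h.reference_id}\t{h.position + 1}\t"
                    f"255\t{len(seq)}M\t*\t0\t0\t{seq}\t*\t"
                    f"NM:i:{h.edit_distance}\n"
                )


@dataclass
class Fixture:
    """A reproducible synthetic community: references, reads and truth."""

    refset: ReferenceSet
    reads: SimulatedReads
    truth: CommunityTruth


def make_fixture(
    n_species: int = 10,
    genes_per_species: int = 50,
    gene_length: int = 1000,
    shared_fraction: float = 0.2,
    abundances: Sequence[float] | None = None,
    n_reads: int = 50_000,
    error_model: ErrorModel = ErrorModel(),
    seed: int = 0,
    shared_pool_size: int | None = None,
) -> Fixture:
    """Generate a synthetic community emulating core-genome references.

    Each species' reference is a concatenation of ``genes_per_species``
    genes of ``gene_length`` bases; a fraction ``shared_fraction`` of them
    is drawn (without replacement, per species) from a common gene pool,
    emulating core genes shared between related clades, and the rest are
    species-private random sequence. Reads from shared genes are the
    ambiguous, multi-mapping part of the dataset. Fully reproducible from
    ``seed``; defaults give ten ~50 kb references with the preset
    abundance profile :data:`DEFAULT_ABUNDANCES`.
    """
    if not 0.0 <= shared_fraction < 1.0:
        raise ValueError("shared_fraction must lie in [0, 1)")
    if abundances is None:
        if n_species == len(DEFAULT_ABUNDANCES):
            abundances = DEFAULT_ABUNDANCES
        else:  # geometric decay, normalised
            w = 0.75 ** np.arange(n_species)
            abundances = tuple(w / w.sum())
    rng = np.random.default_rng(seed)
    n_shared = int(round(shared_fraction * genes_per_species))
    pool_size = (
        shared_pool_size
        if shared_pool_size is not None
        else max(n_shared, int(round(1.5 * n_shared)))
    )
    pool = [
        decode_sequence(rng.integers(0, 4, gene_length).astype(np.uint8))
        for _ in range(pool_size)
    ]
    gene_sets = []
    for s in range(n_species):
        genes = []
        if n_shared:
            picks = rng.choice(pool_size, size=n_shared, replace=False)
            genes.extend(pool[p] for p in picks)
        for _ in range(genes_per_species - n_shared):
            genes.append(
                decode_sequence(rng.integers(0, 4, gene_length).astype(np.uint8))
            )
        order = rng.permutation(len(genes))
        gene_sets.append(
            SpeciesGeneSet(f"species_{s:02d}", tuple(genes[i] for i in order))
        )
    refset = build_reference(gene_sets)
    truth = CommunityTruth.from_abundance(abundances, refset)
    reads = simulate_reads(
        refset,
        truth,
        n_reads,
        error_model=error_model,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return Fixture(refset=refset, reads=reads, truth=truth)
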