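"""Collapsed Gibbs inference of mixture parameters and relative abundances.

Model: a metagenome is a finite mixture of M reference species with
mixture weights θ ~ Dir(α); each read occurrence i carries a hidden origin
index z_i ~ Mult(θ) and a sequence drawn from the origin's
read-composition distribution φ. Integrating θ out (Dirichlet-multinomial
conjugacy) leaves the collapsed full conditional

    p(z_i = t | z_¬i, R) ∝ φ_{r_i, g_t} · (n_{t,¬i} + α_t)

which the sampler visits in a systematic scan. Posterior mean counts n̄
give θ̂_k = (n̄_k + α_k) / Σ(n̄ + α), and length normalisation converts θ̂
to relative abundances a_i = (θ_i / l_i) / Σ_s (θ_s / l_s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from ._kernels import gibbs_sweeps
from .alignment import PhiMatrix, ReadTable

__all__ = [
    "GibbsConfig",
    "AssignmentState",
    "PosteriorSummary",
    "resolve_alpha",
    "initialize_state",
    "full_conditional",
    "run_gibbs",
    "estimate_theta",
    "theta_to_abundance",
    "exact_posterior_oracle",
    "ExactPosterior",
    "aggregate_abundance",
]


def resolve_alpha(alpha: float | Sequence[float], M: int) -> np.ndarray:
    """Broadcast a scalar Dirichlet hyperparameter to M species."""
    arr = np.asarray(alpha, dtype=np.float64)
    if arr.ndim == 0:
        arr = np.full(M, float(arr))
    if arr.shape != (M,):
        raise ValueError(f"alpha must be scalar or length {M}")
    if not np.all(arr > 0):
        raise ValueError("all alpha_i must be > 0")
    return arr


@dataclass(frozen=True)
class GibbsConfig:
    """Sampler schedule: sweeps to discard, samples to keep, thinning."""

    burn_in_sweeps: int = 1000
    kept_samples: int = 1000
    thinning: int = 1
    seed: int = 0
    convergence_tolerance: float | None = None
    keep_trace: bool = False

    def __post_init__(self) -> None:
        if self.burn_in_sweeps < 0:
            raise ValueError("burn_in_sweeps must be >= 0")
        if self.kept_samples < 1:
            raise ValueError("kept_samples must be >= 1")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if (
            self.convergence_tolerance is not None
            and self.convergence_tolerance <= 0
        ):
            raise ValueError("convergence_tolerance must be positive")


@dataclass
class AssignmentState:
    """Hidden origin indices z and per-species occurrence counts n."""

    z: np.ndarray        # int64[N], species index per occurrence
    n: np.ndarray        # float64[M], counts consistent with z
    occ_row: np.ndarray  # int64[N], distinct-read row of each occurrence

    def recount(self, M: int) -> np.ndarray:
        return np.bincount(self.z, minlength=M).astype(np.float64)


@dataclass
class PosteriorSummary:
    """Averaged counts, mixture estimate θ̂ and relative abundances â."""

    ref_ids: list[str]
    mean_counts: np.ndarray
    theta_hat: np.ndarray
    abundance_hat: np.ndarray
    seed: int
    alpha: np.ndarray
    n_reads_total: int
    n_assigned: int
    kept_samples: int
    sample_trace: np.ndarray | None = None

    @property
    def unassigned_fraction(self) -> float:
        return 1.0 - self.n_assigned / self.n_reads_total

    def detected_only(self) -> "PosteriorSummary":
        """Zero out species that received no reads and renormalise.

        Undetected species otherwise keep prior-driven θ̂ mass; this is a
        reporting convenience, not part of the model.
        """
        mask = self.mean_counts > 0
        if not mask.any():
            raise ValueError("no species received any reads")
        theta = np.where(mask, self.theta_hat, 0.0)
        theta /= theta.sum()
        abund = np.where(mask, self.abundance_hat, 0.0)
        abund /= abund.sum()
        return PosteriorSummary(
            self.ref_ids,
            self.mean_counts,
            theta,
            abund,
            self.seed,
            self.alpha,
            self.n_reads_total,
            self.n_assigned,
            self.kept_samples,
            self.sample_trace,
        )


def _included_occurrences(
    read_table: ReadTable, phi: PhiMatrix
) -> np.ndarray:
    """Indices of occurrences whose distinct read has ≥1 candidate."""
    row_nnz = np.diff(phi.matrix.indptr)
    return np.flatnonzero(row_nnz[read_table.occurrence_index] > 0)


def initialize_state(
    read_table: ReadTable, phi: PhiMatrix, seed: int
) -> AssignmentState:
    """Draw each z_i uniformly at random among its read's candidates.

    Every occurrence must have at least one candidate reference;
    occurrences without high-quality hits are excluded before inference.
    """
    rng = np.random.default_rng(seed)
    occ_row = read_table.occurrence_index
    indptr, indices, _ = phi.row_csr()
    z = np.empty(read_table.N, dtype=np.int64)
    for i, k in enumerate(occ_row):
        a, b = indptr[k], indptr[k + 1]
        if b == a:
            raise ValueError(
                f"occurrence {read_table.occurrence_ids[i]!r} has no "
                "candidate references; exclude unassigned reads upstream"
            )
        z[i] = indices[rng.integers(a, b)]
    n = np.bincount(z, minlength=phi.M).astype(np.float64)
    return AssignmentState(z=z, n=n, occ_row=occ_row.astype(np.int64))


def full_conditional(
    i: int,
    state: AssignmentState,
    phi: PhiMatrix,
    alpha: float | Sequence[float],
) -> np.ndarray:
    """Collapsed full conditional over species for occurrence i.

    ``state.n`` must already exclude occurrence i (the n_{t,¬i} counts).
    Returns a dense length-M probability vector, zero outside the
    candidate set, proportional to φ_{r_i,t} · (n_{t,¬i} + α_t).
    """
    alpha_vec = resolve_alpha(alpha, phi.M)
    k = int(state.occ_row[i])
    row = phi.matrix.getrow(k).toarray().ravel()
    weights = row * (state.n + alpha_vec)
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"occurrence {i} has no positive candidate weight")
    return weights / total


def estimate_theta(
    mean_counts: Sequence[float], alpha: float | Sequence[float]
) -> np.ndarray:
    """Posterior-mean mixture estimate θ̂_k = (n̄_k + α_k) / Σ(n̄ + α)."""
    n = np.asarray(mean_counts, dtype=np.float64)
    if np.any(n < 0):
        raise ValueError("mean counts must be non-negative")
    a = resolve_alpha(alpha, n.shape[0])
    v = n + a
    return v / v.sum()


def theta_to_abundance(
    theta: Sequence[float], lengths: Sequence[float]
) -> np.ndarray:
    """Convert mixture weights to relative abundances.

    θ_i is proportional to a_i · l_i — longer references attract
    proportionally more reads — so a_i = (θ_i / l_i) / Σ_s (θ_s / l_s).
    """
    th = np.asarray(theta, dtype=np.float64)
    ln = np.asarray(lengths, dtype=np.float64)
    if th.shape != ln.shape:
        raise ValueError("theta and lengths must have equal length")
    if np.any(ln <= 0):
        raise ValueError("reference lengths must be positive")
    w = th / ln
    return w / w.sum()


def run_gibbs(
    read_table: ReadTable,
    phi: PhiMatrix,
    alpha: float | Sequence[float],
    config: GibbsConfig,
    lengths: Sequence[float],
) -> PosteriorSummary:
    """Run the collapsed sampler and summarise the posterior.

    Occurrences without candidates are excluded and reported through
    ``unassigned_fraction``. A fixed seed makes the output bit-identical
    across runs. When ``config.convergence_tolerance`` is set, sampling
    may stop early once the running-mean θ̂ moves less than the tolerance
    between successive 100-sample checkpoints (at least 200 samples are
    always kept).
    """
    alpha_vec = resolve_alpha(alpha, phi.M)
    included = _included_occurrences(read_table, phi)
    if included.size == 0:
        raise ValueError("no read occurrence has a candidate reference")
    occ_row = read_table.occurrence_index[included].astype(np.int64)
    indptr, indices, data = phi.row_csr()
    conv = (
        float(config.convergence_tolerance)
        if config.convergence_tolerance is not None
        else -1.0
    )
    trace, z, n = gibbs_sweeps(
        occ_row,
        indptr,
        indices,
        data,
        alpha_vec,
        phi.M,
        config.burn_in_sweeps,
        config.kept_samples,
        config.thinning,
        config.seed % (2**32),
        conv,
    )
    mean_counts = trace.mean(axis=0)
    theta_hat = estimate_theta(mean_counts, alpha_vec)
    abundance_hat = theta_to_abundance(theta_hat, lengths)
    return PosteriorSummary(
        ref_ids=list(phi.ref_ids),
        mean_counts=mean_counts,
        theta_hat=theta_hat,
        abundance_hat=abundance_hat,
        seed=config.seed,
        alpha=alpha_vec,
        n_reads_total=read_table.N,
        n_assigned=int(included.size),
        kept_samples=trace.shape[0],
        sample_trace=trace if config.keep_trace else None,
    )


@dataclass
class ExactPosterior:
    """Exhaustive-enumeration posterior for tiny instances."""

    expected_counts: np.ndarray   # float64[M]
    assignments: np.ndarray       # int8[M^N valid rows... (n_assign, N)]
    probabilities: np.ndarray     # float64[n_assign], sums to 1

    def prob_of(self, assignment: Sequence[int]) -> float:
        target = np.asarray(assignment, dtype=self.assignments.dtype)
        match = np.all(self.assignments == target, axis=1)
        return float(self.probabilities[match].sum())


def exact_posterior_oracle(
    read_table: ReadTable,
    phi: PhiMatrix,
    alpha: float | Sequence[float],
    max_states: int = 10**6,
) -> ExactPosterior:
    """Enumerate all M^N assignments z and compute the exact posterior.

    The unnormalised weight of an assignment is
    Π_i φ_{r_i, g_{z_i}} · Δ(n(z) + α) / Δ(α) with
    Δ(α) = Π_k Γ(α_k) / Γ(Σ α_k); the constant Δ(α) cancels under
    normalisation. Intended as an independent check of the sampler on
    instances with M^N ≤ ``max_states``.
    """
    M = phi.M
    N = read_table.N
    alpha_vec = resolve_alpha(alpha, M)
    n_states = M**N
    if n_states > max_states:
        raise ValueError(
            f"M^N = {n_states} exceeds {max_states}; use run_gibbs instead"
        )
    rows = phi.matrix[read_table.occurrence_index].toarray()  # N x M
    # mixed-radix decode of state index -> assignment matrix (n_states, N)
    idx = np.arange(n_states)
    Z = np.empty((n_states, N), dtype=np.int8)
    for i in range(N):
        Z[:, N - 1 - i] = (idx // (M**i)) % M
    with np.errstate(divide="ignore"):
        logphi = np.log(rows)
    lp = logphi[np.arange(N)[None, :], Z].sum(axis=1)
    counts = np.stack([(Z == m).sum(axis=1) for m in range(M)], axis=1)
    lp += gammaln(counts + alpha_vec).sum(axis=1) - gammaln(
        (counts + alpha_vec).sum(axis=1)
    )
    finite = lp > -np.inf
    if not finite.any():
        raise ValueError("every assignment has zero probability")
    lp -= lp[finite].max()
    w = np.where(finite, np.exp(lp), 0.0)
    probs = w / w.sum()
    expected = probs @ counts
    return ExactPosterior(
        expected_counts=expected.astype(np.float64),
        assignments=Z,
        probabilities=probs,
    )


def aggregate_abundance(
    abundance: Mapping[str, float],
    taxonomy_map: Mapping[str, str],
) -> dict[str, float]:
    """Roll strain/species abundances up to higher taxa.

    Every reference id must appear in the taxonomy map; taxon abundance is
    the sum of its members', so a normalised input stays normalised.
    Output taxa follow first-appearance order of the references.
    """
    out: dict[str, float] = {}
    for ref_id, value in abundance.items():
        try:
            taxon = taxonomy_map[ref_id]
        except KeyError:
            raise KeyError(
                f"reference {ref_id!r} missing from the taxonomy map"
            ) from None
        out[taxon] = out.get(taxon, 0.0) + float(value)
    return out
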