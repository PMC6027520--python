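"""Evaluation metrics and between-sample distances."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.stats import spearmanr


def evaluate_rrmse(
    estimated: Sequence[float], truth: Sequence[float]
) -> float:
    """Relative root-mean-square error of abundance estimates, in percent.

    100 · sqrt( (1/M) Σ_i ((â_i − a_i) / a_i)² ). Every true abundance
    must be strictly positive. Invariant under a common permutation of
    both vectors.
    """
    est = np.asarray(estimated, dtype=np.float64)
    tru = np.asarray(truth, dtype=np.float64)
    if est.shape != tru.shape:
        raise ValueError("estimated and truth must have equal length")
    if np.any(tru <= 0):
        raise ValueError("true abundances must be strictly positive")
    rel = (est - tru) / tru
    return 100.0 * float(np.sqrt(np.mean(rel**2)))


def sample_distance_matrix(profiles: Sequence[Sequence[float]]) -> np.ndarray:
    """Pairwise 1 − Spearman-ρ distances between abundance profiles.

    Ranks make the distance robust to the heavy skew of abundance
    vectors; identical rankings give distance 0, exactly reversed
    rankings give 2. Constant profiles have no defined rank correlation
    and are rejected.
    """
    mat = np.asarray(profiles, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need at least two profiles of equal dimension")
    for s, row in enumerate(mat):
        if np.all(row == row[0]):
            raise ValueError(
                f"profile {s} is constant; rank correlation is undefined"
            )
    S = mat.shape[0]
    dist = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            rho = spearmanr(mat[i], mat[j]).statistic
            dist[i, j] = dist[j, i] = 1.0 - rho
    return dist
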