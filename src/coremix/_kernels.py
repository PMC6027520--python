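"""Numba-compiled inner loops for the Gibbs sampler and read matcher."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_sweeps(
    occ_row,      # int64[N]: distinct-read row of each included occurrence
    row_ptr,      # int64[K+1]: CSR indptr over distinct reads
    row_ref,      # int64[nnz]: candidate reference indices
    row_phi,      # float64[nnz]: phi values for the candidates
    alpha,        # float64[M]
    M,
    burn_in,
    kept,
    thin,
    seed,
    conv_tol,     # <= 0 disables the running-mean convergence check
):
    """Systematic-scan collapsed Gibbs over read-origin indices.

    Initializes each z_i uniformly among its read's candidate references,
    then sweeps occurrences in index order: decrement the current species
    count, sample z_i proportional to phi_{r_i,t} * (n_t + alpha_t) over
    candidates, increment the new count. After burn-in the count vector is
    recorded every `thin` sweeps. Returns (trace[:kept_used], z, n).
    """
    np.random.seed(seed)
    N = occ_row.shape[0]
    K = row_ptr.shape[0] - 1

    maxc = 1
    for k in range(K):
        c = row_ptr[k + 1] - row_ptr[k]
        if c > maxc:
            maxc = c
    cum = np.empty(maxc, np.float64)

    z = np.empty(N, np.int64)
    n = np.zeros(M, np.float64)
    for i in range(N):
        a = row_ptr[occ_row[i]]
        b = row_ptr[occ_row[i] + 1]
        j = a + np.int64(np.random.random() * (b - a))
        if j >= b:
            j = b - 1
        t = row_ref[j]
        z[i] = t
        n[t] += 1.0

    trace = np.zeros((kept, M), np.float64)
    run_sum = np.zeros(M, np.float64)
    prev_theta = np.zeros(M, np.float64)
    alpha_tot = 0.0
    for m in range(M):
        alpha_tot += alpha[m]

    s_kept = 0
    total_sweeps = burn_in + kept * thin
    for sweep in range(total_sweeps):
        for i in range(N):
            k = occ_row[i]
            a = row_ptr[k]
            b = row_ptr[k + 1]
            if b - a == 1:
                continue  # forced assignment never moves
            t_old = z[i]
            n[t_old] -= 1.0
            tot = 0.0
            for j in range(a, b):
                t = row_ref[j]
                tot += row_phi[j] * (n[t] + alpha[t])
                cum[j - a] = tot
            u = np.random.random() * tot
            t_new = row_ref[b - 1]
            for j in range(a, b):
                if u < cum[j - a]:
                    t_new = row_ref[j]
                    break
            z[i] = t_new
            n[t_new] += 1.0
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            trace[s_kept, :] = n
            run_sum += n
            s_kept += 1
            if conv_tol > 0.0 and s_kept % 100 == 0:
                denom = float(N) + alpha_tot
                delta = 0.0
                for m in range(M):
                    th = (run_sum[m] / s_kept + alpha[m]) / denom
                    d = abs(th - prev_theta[m])
                    if d > delta:
                        delta = d
                    prev_theta[m] = th
                if delta < conv_tol and s_kept >= 200:
                    break
            if s_kept == kept:
                break
    return trace[:s_kept], z, n


@njit(cache=True)
def count_mismatches(ref_codes, read_codes, starts, read_ids, read_ptr, out):
    """Ungapped mismatch counts for candidate (read, offset) placements.

    read_ptr delimits each read's code slice in read_codes; candidate c
    places read read_ids[c] at global offset starts[c] in ref_codes.
    Codes >= 4 (N or other ambiguity) always count as mismatches.
    """
    for c in range(starts.shape[0]):
        r = read_ids[c]
        a = read_ptr[r]
        b = read_ptr[r + 1]
        s = starts[c]
        mm = 0
        for j in range(b - a):
            rc = read_codes[a + j]
            gc = ref_codes[s + j]
            if rc != gc or rc >= 4:
                mm += 1
        out[c] = mm
    return out
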