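"""Numba kernels for the hot loops: tabular A, gene dropping, Gibbs sampling.

All kernels take plain arrays; wrapping, validation and bookkeeping live in
the calling modules.  Pedigree arrays use 1-based animal codes with 0 for an
unknown parent, matching the on-disk convention.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def tabular_a(sire, dam):
    """Dense numerator relationship matrix by the recursive tabular method.

    sire/dam are 1-based parent codes (0 = unknown), topologically ordered
    (parents precede offspring).  Returns the full n x n matrix A.
    """
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s = sire[i] - 1
        d = dam[i] - 1
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = a
            A[j, i] = a
        aii = 1.0
        if s >= 0 and d >= 0:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return A


@njit(cache=True)
def inbreeding_tabular(sire, dam):
    """Per-animal inbreeding coefficients F_i = A_ii - 1 (tabular method)."""
    return np.diag(tabular_a(sire, dam)) - 1.0


@njit(cache=True)
def gibbs_chain(
    y,
    level_idx,
    n_levels,
    x_cov,
    animal_idx,
    n_animals,
    k_indptr,
    k_indices,
    k_data,
    rec_indptr,
    rec_indices,
    focal_idx,
    n_iter,
    burn_in,
    thin,
    seed,
    init_sigma_a2,
    init_sigma_e2,
):
    """Single-site Gibbs sampler for the animal model y = Xb + Zu + e.

    Fixed part: one categorical factor (level_idx into n_levels cells, no
    explicit intercept) plus one centred covariate x_cov.  Random part: u with
    prior N(0, K sigma_a2) supplied through the sparse CSR of K^-1.  Flat
    priors on fixed effects and both variances (scaled-inv-chi-square with
    nu = -2, S = 0), so variances are drawn as quadratic-form / chi2(df - 2).

    rec_indptr/rec_indices map each animal to its record rows (CSR layout);
    animals without records are still sampled from their pedigree conditional.

    Returns (sigma_a2 draws, sigma_e2 draws, focal u draws, posterior-mean u),
    all over retained (post burn-in, thinned) iterations.
    """
    np.random.seed(seed)
    n_rec = y.shape[0]
    n_keep = (n_iter - burn_in) // thin
    keep_a = np.empty(n_keep)
    keep_e = np.empty(n_keep)
    keep_u_focal = np.empty((n_keep, focal_idx.shape[0]))
    u_sum = np.zeros(n_animals)

    b = np.zeros(n_levels)
    beta = 0.0
    u = np.zeros(n_animals)
    sigma_a2 = init_sigma_a2
    sigma_e2 = init_sigma_e2

    # residuals e = y - Xb - beta*x - Zu (all effects start at zero)
    e = y.copy()

    # per-level record lists
    lev_count = np.zeros(n_levels, dtype=np.int64)
    for r in range(n_rec):
        lev_count[level_idx[r]] += 1
    lev_indptr = np.zeros(n_levels + 1, dtype=np.int64)
    for l in range(n_levels):
        lev_indptr[l + 1] = lev_indptr[l] + lev_count[l]
    lev_indices = np.empty(n_rec, dtype=np.int64)
    cursor = lev_indptr[:-1].copy()
    for r in range(n_rec):
        l = level_idx[r]
        lev_indices[cursor[l]] = r
        cursor[l] += 1

    sxx = 0.0
    for r in range(n_rec):
        sxx += x_cov[r] * x_cov[r]

    kept = 0
    for it in range(n_iter):
        # --- factor levels ---
        for l in range(n_levels):
            lo = lev_indptr[l]
            hi = lev_indptr[l + 1]
            nl = hi - lo
            if nl == 0:
                continue
            old = b[l]
            s = 0.0
            for t in range(lo, hi):
                r = lev_indices[t]
                e[r] += old
                s += e[r]
            mean = s / nl
            new = mean + np.sqrt(sigma_e2 / nl) * np.random.standard_normal()
            for t in range(lo, hi):
                e[lev_indices[t]] -= new
            b[l] = new

        # --- covariate slope ---
        if sxx > 0.0:
            sxe = 0.0
            for r in range(n_rec):
                e[r] += beta * x_cov[r]
                sxe += x_cov[r] * e[r]
            mean = sxe / sxx
            beta = mean + np.sqrt(sigma_e2 / sxx) * np.random.standard_normal()
            for r in range(n_rec):
                e[r] -= beta * x_cov[r]

        # --- breeding values, single site ---
        lam = sigma_e2 / sigma_a2
        for i in range(n_animals):
            old = u[i]
            rhs = 0.0
            nrec_i = rec_indptr[i + 1] - rec_indptr[i]
            for t in range(rec_indptr[i], rec_indptr[i + 1]):
                r = rec_indices[t]
                e[r] += old
                rhs += e[r]
            kii = 0.0
            koff = 0.0
            for t in range(k_indptr[i], k_indptr[i + 1]):
                j = k_indices[t]
                if j == i:
                    kii += k_data[t]
                else:
                    koff += k_data[t] * u[j]
            prec = nrec_i + kii * lam
            mean = (rhs - koff * lam) / prec
            new = mean + np.sqrt(sigma_e2 / prec) * np.random.standard_normal()
            for t in range(rec_indptr[i], rec_indptr[i + 1]):
                e[rec_indices[t]] -= new
            u[i] = new

        # --- variances ---
        uku = 0.0
        for i in range(n_animals):
            for t in range(k_indptr[i], k_indptr[i + 1]):
                uku += u[i] * k_data[t] * u[k_indices[t]]
        if uku <= 0.0:
            uku = 1e-12
        sigma_a2 = uku / np.random.chisquare(n_animals - 2)
        see = 0.0
        for r in range(n_rec):
            see += e[r] * e[r]
        sigma_e2 = see / np.random.chisquare(n_rec - 2)
        if not np.isfinite(sigma_a2) or not np.isfinite(sigma_e2):
            return keep_a[:0], keep_e[:0], keep_u_focal[:0], u_sum

        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            keep_a[kept] = sigma_a2
            keep_e[kept] = sigma_e2
            for t in range(focal_idx.shape[0]):
                keep_u_focal[kept, t] = u[focal_idx[t]]
            u_sum += u
            kept += 1

    if kept > 0:
        u_sum /= kept
    return keep_a[:kept], keep_e[:kept], keep_u_focal[:kept], u_sum
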