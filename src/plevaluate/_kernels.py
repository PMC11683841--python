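"""Numba kernels for pedigree algebra and Gibbs sampling sweeps.

Everything here works on plain integer/float arrays; id handling and
bookkeeping live in the calling modules.  Pedigrees are encoded as two
int64 arrays (sire, dam) holding positional indices, -1 for unknown, with
parents always preceding offspring.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def inbreeding_ml(sire, dam):
    """Meuwissen & Luo inbreeding coefficients.

    Returns (F, D) where D[i] is the Mendelian-sampling variance share
    used by Henderson's A-inverse rules (unknown parents enter as F=-1,
    so D=1 for founders, 0.75-0.25*F_known with a single known parent).
    """
    n = sire.size
    F = np.zeros(n)
    D = np.zeros(n)
    L = np.zeros(n)
    for i in range(n):
        s = sire[i]
        d = dam[i]
        fs = F[s] if s >= 0 else -1.0
        fd = F[d] if d >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        fi = -1.0
        L[i] = 1.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            fi += lj * lj * D[j]
            sj = sire[j]
            dj = dam[j]
            if sj >= 0:
                L[sj] += 0.5 * lj
            if dj >= 0:
                L[dj] += 0.5 * lj
            L[j] = 0.0
        F[i] = fi
    return F, D


@njit(cache=False)
def a_matvec(sire, dam, D, v):
    """A @ v by Colleau's indirect method (A = T D T')."""
    n = v.size
    x = v.copy()
    for j in range(n - 1, -1, -1):
        xj = x[j]
        if xj != 0.0:
            if sire[j] >= 0:
                x[sire[j]] += 0.5 * xj
            if dam[j] >= 0:
                x[dam[j]] += 0.5 * xj
    x = x * D
    for i in range(n):
        t = x[i]
        if sire[i] >= 0:
            t += 0.5 * x[sire[i]]
        if dam[i] >= 0:
            t += 0.5 * x[dam[i]]
        x[i] = t
    return x


@njit(cache=False)
def gibbs_sweep_rep(
    theta,
    resid,
    indptr,
    indices,
    data,
    wtw,
    ainv_indptr,
    ainv_indices,
    ainv_data,
    u_start,
    n_u,
    p_start,
    n_p,
    c_start,
    n_c,
    var_u,
    var_p,
    var_c,
    var_e,
    z,
):
    """One single-site Gibbs sweep over all location effects (REP model).

    theta/resid are updated in place.  The record design matrix W is given
    column-wise (CSC: indptr/indices/data), wtw holds the column sums of
    squares, ainv_* is the CSR additive-precision structure over the n_u
    animal effects, z is a vector of standard-normal draws (one per effect).
    Effects in [0, u_start) are fixed (flat prior).
    """
    n_eff = theta.size
    inv_e = 1.0 / var_e
    for j in range(n_eff):
        lo = indptr[j]
        hi = indptr[j + 1]
        dot = 0.0
        for k in range(lo, hi):
            dot += data[k] * resid[indices[k]]
        prior_prec = 0.0
        prior_rhs = 0.0
        if u_start <= j < u_start + n_u:
            r = j - u_start
            inv_u = 1.0 / var_u
            alo = ainv_indptr[r]
            ahi = ainv_indptr[r + 1]
            for k in range(alo, ahi):
                cc = ainv_indices[k]
                if cc == r:
                    prior_prec = ainv_data[k] * inv_u
                else:
                    prior_rhs -= ainv_data[k] * inv_u * theta[u_start + cc]
        elif p_start <= j < p_start + n_p:
            prior_prec = 1.0 / var_p
        elif c_start <= j < c_start + n_c:
            prior_prec = 1.0 / var_c
        q = wtw[j] * inv_e + prior_prec
        if q <= 0.0:
            continue
        rhs = (dot + wtw[j] * theta[j]) * inv_e + prior_rhs
        new = rhs / q + z[j] / np.sqrt(q)
        delta = theta[j] - new
        if delta != 0.0:
            for k in range(lo, hi):
                resid[indices[k]] += data[k] * delta
            theta[j] = new


@njit(cache=False)
def gibbs_sweep_rrm(
    theta,
    resid,
    indptr,
    indices,
    data,
    wtw,
    ainv_indptr,
    ainv_indices,
    ainv_data,
    u_start,
    n_u,
    p_start,
    n_p,
    c_start,
    n_c,
    ginv_u,
    ginv_p,
    ginv_c,
    var_e,
    z,
):
    """Single-site sweep for the random-regression model.

    Random effects come in (intercept, slope) pairs stored contiguously:
    effect columns u_start + 2*level + coef.  Priors are Kronecker
    products: Ginv_u (x) Ainv for animals, Ginv_p (x) I and Ginv_c (x) I
    for permanent-environment and contemporary-group effects.
    """
    n_eff = theta.size
    inv_e = 1.0 / var_e
    for j in range(n_eff):
        lo = indptr[j]
        hi = indptr[j + 1]
        dot = 0.0
        for k in range(lo, hi):
            dot += data[k] * resid[indices[k]]
        prior_prec = 0.0
        prior_rhs = 0.0
        if u_start <= j < u_start + 2 * n_u:
            r = (j - u_start) // 2
            kc = (j - u_start) % 2
            alo = ainv_indptr[r]
            ahi = ainv_indptr[r + 1]
            for k in range(alo, ahi):
                cc = ainv_indices[k]
                av = ainv_data[k]
                for lc in range(2):
                    g = ginv_u[kc, lc]
                    if cc == r and lc == kc:
                        prior_prec = av * g
                    else:
                        prior_rhs -= av * g * theta[u_start + 2 * cc + lc]
        elif p_start <= j < p_start + 2 * n_p:
            kc = (j - p_start) % 2
            prior_prec = ginv_p[kc, kc]
            prior_rhs = -ginv_p[kc, 1 - kc] * theta[j + (1 if kc == 0 else -1)]
        elif c_start <= j < c_start + 2 * n_c:
            kc = (j - c_start) % 2
            prior_prec = ginv_c[kc, kc]
            prior_rhs = -ginv_c[kc, 1 - kc] * theta[j + (1 if kc == 0 else -1)]
        q = wtw[j] * inv_e + prior_prec
        if q <= 0.0:
            continue
        rhs = (dot + wtw[j] * theta[j]) * inv_e + prior_rhs
        new = rhs / q + z[j] / np.sqrt(q)
        delta = theta[j] - new
        if delta != 0.0:
            for k in range(lo, hi):
                resid[indices[k]] += data[k] * delta
            theta[j] = new
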