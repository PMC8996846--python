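"""Numba kernel for the single-site Gibbs location sweep.

The sweep visits every location coefficient in index order, forms its normal
full conditional from the current residual vector and the prior precision
contribution of its term, draws the update using a pre-generated standard
normal, and keeps the residual vector e = y - X theta consistent in place.
Keeping the sweep in one jitted function is what makes chain lengths of the
order used in practice (tens of thousands of iterations) affordable.

Coefficient coding (per index j):
  kind_code  0 fixed (no prior), 1 IID, 2 pedigree-structured scalar term,
             3 random-regression coefficient, 4 skipped (the coefficient is
             updated outside the sweep, e.g. the parent of a hierarchically
             centered term)
  var_index  slot into scalar_var for kinds 1-2
  rr_term_of kind 3: random-regression term id; kind 2: -2 - structure id
  rr_coef_of kind 3: which basis coefficient
  rr_level_of     : level (pedigree row) within the term
prior_mean holds the (possibly nonzero) prior mean of IID coefficients —
used by hierarchically centered terms whose prior centers on a parent
reaction norm.  Pedigree precision structures are concatenated CSR arrays;
structure `sid` row q starts at ainv_indptr[struct_row_start[sid] + q].
"""

import numpy as np
from numba import njit


@njit(cache=True)
def location_sweep(
    theta, resid, z, prior_mean,
    indptr, xrows, xvals, rprec,
    kind_code, var_index, scalar_var,
    rr_term_of, rr_coef_of, rr_level_of,
    rr_offsets, rr_nlev, g0_inv,
    struct_of_rr, struct_row_start, ainv_indptr, ainv_idx, ainv_val,
):
    p = theta.shape[0]
    for j in range(p):
        if kind_code[j] == 4:
            continue
        # data part: lhs = x_j' R^-1 x_j, rhs = x_j' R^-1 (e + x_j theta_j)
        lhs = 0.0
        rhs = 0.0
        old = theta[j]
        for ptr in range(indptr[j], indptr[j + 1]):
            i = xrows[ptr]
            v = xvals[ptr]
            w = v * rprec[i]
            lhs += w * v
            rhs += w * (resid[i] + v * old)

        kind = kind_code[j]
        if kind == 1:  # IID (prior mean nonzero for centered terms)
            lam = 1.0 / scalar_var[var_index[j]]
            lhs += lam
            rhs += lam * prior_mean[j]
        elif kind == 2:  # pedigree-structured scalar
            sid = -2 - rr_term_of[j]
            q = rr_level_of[j]
            off = j - q
            lam = 1.0 / scalar_var[var_index[j]]
            row0 = struct_row_start[sid] + q
            for ptr in range(ainv_indptr[row0], ainv_indptr[row0 + 1]):
                qq = ainv_idx[ptr]
                a = ainv_val[ptr]
                if qq == q:
                    lhs += a * lam
                else:
                    rhs -= a * lam * theta[off + qq]
        elif kind == 3:  # random-regression coefficient
            r = rr_term_of[j]
            t = rr_coef_of[j]
            q = rr_level_of[j]
            off = rr_offsets[r]
            nlev = rr_nlev[r]
            sid = struct_of_rr[r]
            m = g0_inv.shape[1]
            if sid >= 0:
                row0 = struct_row_start[sid] + q
                for ptr in range(ainv_indptr[row0], ainv_indptr[row0 + 1]):
                    qq = ainv_idx[ptr]
                    a = ainv_val[ptr]
                    for tt in range(m):
                        g = g0_inv[r, t, tt]
                        if g == 0.0:
                            continue
                        if qq == q and tt == t:
                            lhs += a * g
                        else:
                            rhs -= a * g * theta[off + tt * nlev + qq]
            else:
                for tt in range(m):
                    g = g0_inv[r, t, tt]
                    if g == 0.0:
                        continue
                    if tt == t:
                        lhs += g
                    else:
                        rhs -= g * theta[off + tt * nlev + q]

        mean = rhs / lhs
        new = mean + z[j] / np.sqrt(lhs)
        if new != old:
            delta = new - old
            for ptr in range(indptr[j], indptr[j + 1]):
                resid[xrows[ptr]] -= xvals[ptr] * delta
            theta[j] = new


@njit(cache=True)
def parent_block_update(
    theta, z,
    parent_offset, nlev, m,
    child_offset, child_prior_mean_unused,
    cow_ptr, cow_idx, x_child,
    inv_var_child,
    g0_inv_m,
    has_ainv, ainv_indptr, ainv_idx, ainv_val,
):
    """Joint draw of each parent level's coefficient block (intercept[, slope])
    given the centered child effects.

    The child effects eta_c act as the parent's data: eta_c ~ N(u0_q + u1_q
    x_c, var_child) for the children c of level q.  Levels are visited in
    order with pedigree cross terms evaluated at current values (blocked
    single-site Gibbs); each block is drawn exactly from its bivariate (or
    scalar) normal full conditional.
    """
    for q in range(nlev):
        # prior precision and cross contribution
        if has_ainv:
            aqq = 0.0
            s0 = 0.0
            s1 = 0.0
            for ptr in range(ainv_indptr[q], ainv_indptr[q + 1]):
                qq = ainv_idx[ptr]
                a = ainv_val[ptr]
                if qq == q:
                    aqq = a
                else:
                    s0 += a * theta[parent_offset + qq]
                    if m == 2:
                        s1 += a * theta[parent_offset + nlev + qq]
        else:
            aqq = 1.0
            s0 = 0.0
            s1 = 0.0
        c00 = g0_inv_m[0, 0] * aqq
        r0 = -(g0_inv_m[0, 0] * s0)
        if m == 2:
            c01 = g0_inv_m[0, 1] * aqq
            c11 = g0_inv_m[1, 1] * aqq
            r0 -= g0_inv_m[0, 1] * s1
            r1 = -(g0_inv_m[1, 0] * s0 + g0_inv_m[1, 1] * s1)
        else:
            c01 = 0.0
            c11 = 1.0
            r1 = 0.0
        # child pseudo-data
        for ptr in range(cow_ptr[q], cow_ptr[q + 1]):
            c = cow_idx[ptr]
            eta = theta[child_offset + c]
            c00 += inv_var_child
            r0 += inv_var_child * eta
            if m == 2:
                xc = x_child[c]
                c01 += inv_var_child * xc
                c11 += inv_var_child * xc * xc
                r1 += inv_var_child * xc * eta
        if m == 1:
            mu = r0 / c00
            theta[parent_offset + q] = mu + z[q] / np.sqrt(c00)
        else:
            # 2x2 Cholesky: C = L L', draw u = C^-1 r + L'^-1 xi
            l00 = np.sqrt(c00)
            l10 = c01 / l00
            l11 = np.sqrt(c11 - l10 * l10)
            # solve L w = r
            w0 = r0 / l00
            w1 = (r1 - l10 * w0) / l11
            # solve L' mu = w
            mu1 = w1 / l11
            mu0 = (w0 - l10 * mu1) / l00
            # L'^-1 xi
            xi0 = z[q]
            xi1 = z[nlev + q]
            e1 = xi1 / l11
            e0 = (xi0 - l10 * e1) / l00
            theta[parent_offset + q] = mu0 + e0
            theta[parent_offset + nlev + q] = mu1 + e1
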