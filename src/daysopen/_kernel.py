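"""Numba kernel for single-site Gibbs location updates.

One call performs a full sweep over all location effects (fixed, additive
genetic, permanent environment) for 1 or 2 traits sharing the same
incidence structure.  The sweep works on the residual-precision-scaled
mixed-model equations: for site (j, t) the full conditional is normal with
precision C_jj and mean (RHS - C theta)_jt / C_jj, where

  C[(j,t),(l,s)] = Rinv[t,s] * M[j,l]                 (data part, M = T'T)
                 + Ginv[t,s] * Ainv[j,l]              (additive block)
                 + Pinv[t,s] * I[j,l]                 (pe block)

Standard-normal innovations are pre-drawn by the caller so that all
randomness flows through one seeded numpy Generator.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def location_sweep(
    theta,            # (n_eff, nt) in-place
    m_indptr, m_indices, m_data,      # CSR of M = T'T, (n_eff x n_eff)
    rhs_raw,          # (n_eff, nt): raw T'y_s per trait
    a_indptr, a_indices, a_data,      # CSR of A-inverse (q x q, local idx)
    u_start, q, pe_start, n_pe,
    Rinv, Ginv, Pinv,                 # (nt, nt)
    z,                # (n_eff, nt) standard normals
):
    n_eff, nt = theta.shape
    m_dot = np.zeros(nt)
    p_dot = np.zeros(nt)
    for j in range(n_eff):
        # data part: m_dot[s] = sum_l M[j,l] theta[l,s]; remember M_jj
        m_jj = 0.0
        for s in range(nt):
            m_dot[s] = 0.0
            p_dot[s] = 0.0
        for k in range(m_indptr[j], m_indptr[j + 1]):
            l = m_indices[k]
            v = m_data[k]
            if l == j:
                m_jj = v
            for s in range(nt):
                m_dot[s] += v * theta[l, s]
        # prior part
        in_u = (j >= u_start) and (j < u_start + q)
        in_pe = (j >= pe_start) and (j < pe_start + n_pe)
        d_jj = 0.0
        if in_u:
            ja = j - u_start
            for k in range(a_indptr[ja], a_indptr[ja + 1]):
                l = a_indices[k]
                v = a_data[k]
                if l == ja:
                    d_jj = v
                for s in range(nt):
                    p_dot[s] += v * theta[u_start + l, s]
        elif in_pe:
            d_jj = 1.0
            for s in range(nt):
                p_dot[s] = theta[j, s]

        for t in range(nt):
            if in_u:
                prior_tt = Ginv[t, t]
            elif in_pe:
                prior_tt = Pinv[t, t]
            else:
                prior_tt = 0.0
            c_jj = Rinv[t, t] * m_jj + prior_tt * d_jj
            num = c_jj * theta[j, t]
            for s in range(nt):
                num += Rinv[t, s] * (rhs_raw[j, s] - m_dot[s])
            if in_u:
                for s in range(nt):
                    num -= Ginv[t, s] * p_dot[s]
            elif in_pe:
                for s in range(nt):
                    num -= Pinv[t, s] * p_dot[s]
            new = num / c_jj + z[j, t] / np.sqrt(c_jj)
            delta = new - theta[j, t]
            if delta != 0.0:
                m_dot[t] += m_jj * delta
                p_dot[t] += d_jj * delta
                theta[j, t] = new


@njit(cache=True)
def quad_form_ainv(a_indptr, a_indices, a_data, U):
    """U' Ainv U for U of shape (q, nt); returns (nt, nt)."""
    q, nt = U.shape
    out = np.zeros((nt, nt))
    for i in range(q):
        for k in range(a_indptr[i], a_indptr[i + 1]):
            l = a_indices[k]
            v = a_data[k]
            for t in range(nt):
                for s in range(nt):
                    out[t, s] += v * U[i, t] * U[l, s]
    return out
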