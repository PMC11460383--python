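"""Hot pairwise loops (numba-compiled).

All engines reduce to three O(N²) passes over atom pairs: typed distance
histograms, per-type-pair sinc sums, and deposition of analytic Gaussian
PDDF kernels.  The binning rule everywhere is bin = round(r / dr), i.e.
bins centred on m·dr, and the bin-centre abscissa is what enters the sinc
and Gaussian kernels.

The Gaussian PDDF kernel for one product term c·exp(−d·q²) of a pair at
distance a is the closed-form inverse sine transform

    K(r; a, d) = c·r / (2·a·sqrt(π·d)) · [exp(−(r−a)²/4d) − exp(−(r+a)²/4d)]

with the a→0 (self-pair) limit  c·r²/(2·d·sqrt(π·d))·exp(−r²/4d).  Both
integrate to c over r ∈ [0, ∞), matching the forward-scattering identity.
Terms are deposited only within |r−a| ≤ sqrt(EXP_CUT·4d) (relative tail
mass < e⁻⁴⁰); consecutive grid values of the Gaussian are generated by the
two-multiply recurrence e_{i+1} = e_i·g_i, g_{i+1} = g_i·h, and uniform-q
sinc values by the three-term sine recurrence, so the inner loops are
multiply–add only.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["typed_histogram", "weighted_pair_histogram", "pair_sinc_sums",
           "deposit_gaussian_terms", "deposit_self_terms"]

EXP_CUT = 40.0


@njit(cache=True)
def typed_histogram(pos, tidx, n_types, dr, n_bins):
    """Ordered pair counts H[t, u, m] over distance bins (self pairs excluded).

    Returns (H, self_counts) where self_counts[t] is the number of atoms of
    type t (the j == k diagonal of the double sum).
    """
    n = pos.shape[0]
    H = np.zeros((n_types, n_types, n_bins), dtype=np.float64)
    self_counts = np.zeros(n_types, dtype=np.float64)
    for j in range(n):
        self_counts[tidx[j]] += 1.0
    for j in range(n):
        xj, yj, zj = pos[j, 0], pos[j, 1], pos[j, 2]
        tj = tidx[j]
        for k in range(j + 1, n):
            dx = pos[k, 0] - xj
            dy = pos[k, 1] - yj
            dz = pos[k, 2] - zj
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            m = int(round(r / dr))
            if m >= n_bins:
                m = n_bins - 1
            H[tj, tidx[k], m] += 1.0
            H[tidx[k], tj, m] += 1.0
    return H, self_counts


@njit(cache=True)
def weighted_pair_histogram(pos, w, dr, n_bins):
    """Point-charge PDDF accumulation: sum of w_j·w_k over ordered pairs
    per distance bin; returns (bin weights, self mass = sum w²)."""
    n = pos.shape[0]
    out = np.zeros(n_bins, dtype=np.float64)
    self_mass = 0.0
    for j in range(n):
        self_mass += w[j] * w[j]
    for j in range(n):
        xj, yj, zj = pos[j, 0], pos[j, 1], pos[j, 2]
        wj = w[j]
        for k in range(j + 1, n):
            dx = pos[k, 0] - xj
            dy = pos[k, 1] - yj
            dz = pos[k, 2] - zj
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            m = int(round(r / dr))
            if m >= n_bins:
                m = n_bins - 1
            out[m] += 2.0 * wj * w[k]
    return out, self_mass


@njit(cache=True)
def _sinc_row(r, q, uniform_dq, out_row):
    """Add sinc(q_i·r) to out_row; three-term recurrence on uniform grids."""
    nq = q.shape[0]
    if uniform_dq > 0.0 and nq > 2:
        th = uniform_dq * r
        c2 = 2.0 * math.cos(th)
        s_prev = math.sin(q[0] * r)
        s_cur = math.sin(q[1] * r)
        x = q[0] * r
        out_row[0] += 1.0 if abs(x) < 1e-12 else s_prev / x
        x = q[1] * r
        out_row[1] += 1.0 if abs(x) < 1e-12 else s_cur / x
        for i in range(2, nq):
            s_next = c2 * s_cur - s_prev
            s_prev = s_cur
            s_cur = s_next
            out_row[i] += s_cur / (q[i] * r)
    else:
        for i in range(nq):
            x = q[i] * r
            out_row[i] += 1.0 if abs(x) < 1e-12 else math.sin(x) / x


@njit(cache=True)
def pair_sinc_sums(pos, tidx, n_types, q, uniform_dq):
    """S[t, u, iq] = Σ_{ordered pairs j≠k of types t,u} sinc(q·r_jk).

    ``uniform_dq`` is the grid spacing if q is uniform, else 0 (generic path).
    """
    n = pos.shape[0]
    nq = q.shape[0]
    S = np.zeros((n_types, n_types, nq), dtype=np.float64)
    row = np.zeros(nq, dtype=np.float64)
    for j in range(n):
        xj, yj, zj = pos[j, 0], pos[j, 1], pos[j, 2]
        tj = tidx[j]
        for k in range(j + 1, n):
            dx = pos[k, 0] - xj
            dy = pos[k, 1] - yj
            dz = pos[k, 2] - zj
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            tk = tidx[k]
            for i in range(nq):
                row[i] = 0.0
            _sinc_row(r, q, uniform_dq, row)
            for i in range(nq):
                S[tj, tk, i] += row[i]
                S[tk, tj, i] += row[i]
    return S


@njit(cache=True)
def deposit_self_terms(weight, cs, ds, dr, out):
    """Self-pair (a → 0) limit: weight·Σ_l c_l·r²/(2 d_l √(π d_l))·e^(−r²/4d_l)."""
    n_r = out.shape[0]
    for l in range(cs.shape[0]):
        c = cs[l] * weight
        d = ds[l]
        pref = c / (2.0 * d * math.sqrt(math.pi * d))
        hw = math.sqrt(4.0 * EXP_CUT * d)
        i1 = min(n_r - 1, int(math.floor(hw / dr)))
        # recurrence for exp(-(i*dr)^2 / 4d)
        e = 1.0
        g = math.exp(-dr * dr / (4.0 * d))
        h = g * g
        for i in range(i1 + 1):
            r = i * dr
            out[i] += pref * r * r * e
            e *= g
            g *= h
    return out


@njit(cache=True)
def deposit_gaussian_terms(dists, weights, cs, ds, dr, out):
    """Add Σ_pairs Σ_l weight·K(r_i; a, d_l) onto the uniform grid r_i = i·dr."""
    n_r = out.shape[0]
    for ip in range(dists.shape[0]):
        a = dists[ip]
        wgt = weights[ip]
        if a < 1e-9:  # degenerate pair distance: use the a→0 limit
            deposit_self_terms(wgt, cs, ds, dr, out)
            continue
        for l in range(cs.shape[0]):
            c = cs[l] * wgt
            d = ds[l]
            pref = c / (2.0 * a * math.sqrt(math.pi * d))
            hw = math.sqrt(4.0 * EXP_CUT * d)
            i0 = int(math.ceil((a - hw) / dr))
            if i0 < 0:
                i0 = 0
            i1 = int(math.floor((a + hw) / dr))
            if i1 > n_r - 1:
                i1 = n_r - 1
            if i1 < i0:
                continue
            inv4d = 1.0 / (4.0 * d)
            # main Gaussian exp(-(r-a)^2/4d) by recurrence along the grid
            x0 = i0 * dr - a
            e = math.exp(-x0 * x0 * inv4d)
            g = math.exp(-dr * (2.0 * x0 + dr) * inv4d)
            h = math.exp(-2.0 * dr * dr * inv4d)
            mirror_i1 = int(math.floor((hw - a) / dr))  # where (r+a)² < cut
            if mirror_i1 > i1:
                mirror_i1 = i1
            for i in range(i0, i1 + 1):
                v = e
                if i <= mirror_i1:
                    rp = i * dr + a
                    v -= math.exp(-rp * rp * inv4d)
                out[i] += pref * (i * dr) * v
                e *= g
                g *= h
    return out
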