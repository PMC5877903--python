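"""Numba-compiled inner loops: table-driven LR1 stepping and crossing detection.

All voltage-dependent rate quantities are linearly interpolated from tables
(see :func:`myopace.lr1.make_tables`); gates use the Rush-Larsen exponential
update, V and Cai forward Euler.  The tissue reaction kernel updates node
arrays in place; diffusion is applied outside (implicit sparse solve).
"""

import numba
import numpy as np

__all__ = ["simulate_cell_kernel", "reaction_step", "detect_crossings"]


@numba.njit(cache=False, fastmath=True)
def _interp_row(tabs, row, idx, w):
    return tabs[row, idx] * (1.0 - w) + tabs[row, idx + 1] * w


@numba.njit(cache=False, fastmath=True)
def simulate_cell_kernel(y, ibias, dt, nsteps, record_stride, v_rec,
                         tabs, vmin, inv_step,
                         gna, ena, gsi, gk, ek, gk1, ek1, gkp, ekp, cm, kca,
                         thresh, act_out, max_act):
    """Single-cell integration; fills v_rec and act_out, updates y in place.

    Returns (n_activations, ok) with ok = -1 on voltage blow-up.
    """
    V, m, h, j, d, f, X, Cai = y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7]
    npts = tabs.shape[1]
    n_act = 0
    rec_idx = 0
    v_rec[0] = V
    t = 0.0
    for step in range(nsteps):
        pos = (V - vmin) * inv_step
        if pos < 0.0:
            pos = 0.0
        elif pos > npts - 2:
            pos = float(npts - 2)
        idx = int(pos)
        w = pos - idx

        m = _interp_row(tabs, 0, idx, w) + (m - _interp_row(tabs, 0, idx, w)) * _interp_row(tabs, 6, idx, w)
        h = _interp_row(tabs, 1, idx, w) + (h - _interp_row(tabs, 1, idx, w)) * _interp_row(tabs, 7, idx, w)
        j = _interp_row(tabs, 2, idx, w) + (j - _interp_row(tabs, 2, idx, w)) * _interp_row(tabs, 8, idx, w)
        d = _interp_row(tabs, 3, idx, w) + (d - _interp_row(tabs, 3, idx, w)) * _interp_row(tabs, 9, idx, w)
        f = _interp_row(tabs, 4, idx, w) + (f - _interp_row(tabs, 4, idx, w)) * _interp_row(tabs, 10, idx, w)
        X = _interp_row(tabs, 5, idx, w) + (X - _interp_row(tabs, 5, idx, w)) * _interp_row(tabs, 11, idx, w)

        e_si = 7.7 - 13.0287 * np.log(Cai)
        i_si = gsi * d * f * (V - e_si)
        i_ion = (gna * m * m * m * h * j * (V - ena)
                 + i_si
                 + gk * X * _interp_row(tabs, 12, idx, w) * (V - ek)
                 + gk1 * _interp_row(tabs, 13, idx, w) * (V - ek1)
                 + gkp * _interp_row(tabs, 14, idx, w) * (V - ekp)
                 + 0.03921 * (V + 59.87))
        Cai = Cai + dt * (-1e-4 * i_si + kca * (1e-4 - Cai))
        v_new = V + dt * (-(i_ion - ibias) / cm)
        if abs(v_new) > 200.0:
            y[0], y[1], y[2], y[3] = v_new, m, h, j
            y[4], y[5], y[6], y[7] = d, f, X, Cai
            return n_act, -1
        if V < thresh and v_new >= thresh and n_act < act_out.shape[0]:
            act_out[n_act] = t + dt * (thresh - V) / (v_new - V)
            n_act += 1
            if max_act > 0 and n_act >= max_act:
                V = v_new
                break
        V = v_new
        t += dt
        if (step + 1) % record_stride == 0:
            rec_idx += 1
            if rec_idx < v_rec.shape[0]:
                v_rec[rec_idx] = V
    y[0], y[1], y[2], y[3] = V, m, h, j
    y[4], y[5], y[6], y[7] = d, f, X, Cai
    return n_act, 0


@numba.njit(cache=False, fastmath=True, parallel=False)
def reaction_step(V, m, h, j, d, f, X, Cai, ibias, dt,
                  tabs, vmin, inv_step,
                  gna, ena, gsi, gk, ek, gk1, ek1, gkp, ekp, cm, kca):
    """One reaction sub-step for all nodes (in place).  Returns the index of
    the first blown-up node, or -1 if the state is sane."""
    npts = tabs.shape[1]
    bad = -1
    for i in range(V.shape[0]):
        v = V[i]
        pos = (v - vmin) * inv_step
        if pos < 0.0:
            pos = 0.0
        elif pos > npts - 2:
            pos = float(npts - 2)
        idx = int(pos)
        w = pos - idx

        mi = _interp_row(tabs, 0, idx, w) + (m[i] - _interp_row(tabs, 0, idx, w)) * _interp_row(tabs, 6, idx, w)
        hi = _interp_row(tabs, 1, idx, w) + (h[i] - _interp_row(tabs, 1, idx, w)) * _interp_row(tabs, 7, idx, w)
        ji = _interp_row(tabs, 2, idx, w) + (j[i] - _interp_row(tabs, 2, idx, w)) * _interp_row(tabs, 8, idx, w)
        di = _interp_row(tabs, 3, idx, w) + (d[i] - _interp_row(tabs, 3, idx, w)) * _interp_row(tabs, 9, idx, w)
        fi = _interp_row(tabs, 4, idx, w) + (f[i] - _interp_row(tabs, 4, idx, w)) * _interp_row(tabs, 10, idx, w)
        Xi_ = _interp_row(tabs, 5, idx, w) + (X[i] - _interp_row(tabs, 5, idx, w)) * _interp_row(tabs, 11, idx, w)

        cai = Cai[i]
        e_si = 7.7 - 13.0287 * np.log(cai)
        i_si = gsi * di * fi * (v - e_si)
        i_ion = (gna * mi * mi * mi * hi * ji * (v - ena)
                 + i_si
                 + gk * Xi_ * _interp_row(tabs, 12, idx, w) * (v - ek)
                 + gk1 * _interp_row(tabs, 13, idx, w) * (v - ek1)
                 + gkp * _interp_row(tabs, 14, idx, w) * (v - ekp)
                 + 0.03921 * (v + 59.87))
        Cai[i] = cai + dt * (-1e-4 * i_si + kca * (1e-4 - cai))
        vn = v + dt * (-(i_ion - ibias[i]) / cm)
        if abs(vn) > 200.0 and bad < 0:
            bad = i
        V[i] = vn
        m[i], h[i], j[i] = mi, hi, ji
        d[i], f[i], X[i] = di, fi, Xi_
    return bad


@numba.njit(cache=False, fastmath=True)
def detect_crossings(v_old, v_new, t0, dt, thresh, armed, counts, times):
    """Per-node upward threshold crossings over one full step, with
    refractory lockout until the node repolarizes below the threshold."""
    max_beats = times.shape[1]
    for i in range(v_old.shape[0]):
        vo, vn = v_old[i], v_new[i]
        if armed[i]:
            if vn >= thresh:
                if counts[i] < max_beats:
                    frac = (thresh - vo) / (vn - vo) if vn > vo else 0.0
                    if frac < 0.0:
                        frac = 0.0
                    elif frac > 1.0:
                        frac = 1.0
                    times[i, counts[i]] = t0 + dt * frac
                    counts[i] += 1
                armed[i] = False
        elif vn < thresh:
            armed[i] = True
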