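"""Luo-Rudy phase-1 (LR1) ventricular myocyte with a constant inward bias current.

The LR1 model describes the ventricular action potential with six ionic
currents (fast sodium ``INa``, slow inward ``Isi``, time-dependent potassium
``IK``, inward rectifier ``IK1``, plateau potassium ``IKp`` and a linear
background current ``Ib``) gated by six Hodgkin-Huxley variables
(``m, h, j, d, f, X``) plus the intracellular calcium concentration ``Cai``.
A quiescent LR1 cell is excitable but silent; adding a constant inward
(depolarizing) bias current ``Ibias`` destabilizes the resting equilibrium
and produces sustained spontaneous oscillation over a finite ``Ibias``
window bounded by two cycle folds, with subcritical Hopf bifurcations of the
fixed-point branches just inside.  This module provides

* the exact right-hand side (:func:`cell_rhs`) and steady-state relations,
* a fast table-driven Rush-Larsen / forward-Euler integrator
  (:func:`simulate_cell`),
* equilibrium continuation and eigenvalue stability (:func:`find_equilibria`),
* bisection scans for the Hopf points (:func:`hopf_scan`) and for the folds
  of the stable-cycle branch with its cycle-length curve
  (:func:`cycle_fold_scan`).

Voltages are in mV, time in ms, currents in uA/cm^2, Cai in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._kernels import simulate_cell_kernel

__all__ = [
    "CellParams",
    "canonical_lr1",
    "CellState",
    "CellTrace",
    "Equilibrium",
    "BifurcationResult",
    "STATE_NAMES",
    "GATE_NAMES",
    "cell_rhs",
    "ionic_current",
    "gate_rates",
    "steady_gates",
    "steady_cai",
    "resting_state",
    "simulate_cell",
    "steady_cycle_length",
    "find_equilibria",
    "jacobian",
    "hopf_scan",
    "cycle_fold_scan",
    "cycle_length_curve",
    "make_tables",
]

STATE_NAMES = ("V", "m", "h", "j", "d", "f", "X", "Cai")
GATE_NAMES = ("m", "h", "j", "d", "f", "X")

#: physical constants (Nernst factor RT/F at 310 K, mV)
_RTF = 8.314 * 310.0 / 96.4846

_KO, _KI = 5.4, 145.0
_NAO, _NAI = 140.0, 18.0


@dataclass(frozen=True)
class CellParams:
    """LR1 maximal conductances (mS/cm^2), reversal potentials (mV) and bias.

    ``ibias`` is the constant inward bias current density in uA/cm^2
    (0 for quiescent cells, 2.6-4.7 for pacemaker cells).

    The default K+/Ca2+ conductances are an automaticity-enabled variant of
    the 1991 set (``g_si`` 0.09 -> 0.0703, ``g_k`` 0.282 -> 0.821, ``g_k1``
    0.6047 -> 0.695), calibrated once so that the biased cell reproduces the
    reference bifurcation structure: sustained oscillation on
    Ibias ~ [2.553, 4.69] uA/cm^2 bounded by cycle folds, subcritical Hopf
    points of the fixed-point branches at ~2.554 and ~4.47, and steady cycle
    lengths of ~1428 ms at Ibias = 2.6 and ~599 ms at 3.5.  With the
    unmodified 1991 values the depolarized equilibrium is stable and a
    biased cell fires once and halts instead of oscillating; see
    docs/methods.md.  Pass :func:`canonical_lr1` for the published 1991 set.
    """

    g_na: float = 23.0
    e_na: float = 54.4
    g_si: float = 0.0703
    g_k: float = 0.821
    e_k: float = -77.0
    g_k1: float = 0.695
    e_k1: float = _RTF * np.log(_KO / _KI)
    g_kp: float = 0.0183
    x_speed: float = 1.0  # scale on the X-gate rates (tau_X / x_speed)
    ca_removal: float = 0.07  # Cai relaxation rate (1/ms)
    cm: float = 1.0  # uF/cm^2
    ibias: float = 0.0

    @property
    def e_kp(self) -> float:
        return self.e_k1

    def with_bias(self, ibias: float) -> "CellParams":
        if ibias < 0:
            raise ValueError("ibias must be >= 0 (inward bias convention)")
        return replace(self, ibias=ibias)


def canonical_lr1(**overrides) -> "CellParams":
    """The published 1991 LR1 parameter set (no automaticity calibration)."""
    return CellParams(
        g_si=0.09,
        g_k=0.282 * float(np.sqrt(_KO / 5.4)),
        g_k1=0.6047 * float(np.sqrt(_KO / 5.4)),
        **overrides,
    )


@dataclass
class CellState:
    """One LR1 state vector; gates dimensionless in [0, 1], Cai > 0 (mM)."""

    V: float
    m: float
    h: float
    j: float
    d: float
    f: float
    X: float
    Cai: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.V, self.m, self.h, self.j, self.d, self.f, self.X, self.Cai]
        )

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "CellState":
        return cls(*[float(v) for v in y])

    def validate(self) -> None:
        y = self.to_array()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite cell state")
        gates = y[1:7]
        if np.any(gates < -1e-9) or np.any(gates > 1 + 1e-9):
            raise ValueError("gating variables must lie in [0, 1]")
        if self.Cai <= 0:
            raise ValueError("Cai must be positive")


# ---------------------------------------------------------------------------
# rate formulas
# ---------------------------------------------------------------------------

def _safe_ratio(num, den, limit):
    """num/den with the removable singularity den -> 0 replaced by its limit."""
    num, den = np.asarray(num, float), np.asarray(den, float)
    small = np.abs(den) < 1e-9
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


def gate_rates(V, x_speed: float = 1.0):
    """alpha/beta (1/ms) of the six LR1 gates at potential ``V`` (mV).

    Returns a dict name -> (alpha, beta); accepts scalars or arrays.
    ``x_speed`` scales both X-gate rates (steady state unchanged, time
    constant divided by ``x_speed``).
    """
    V = np.asarray(V, float)
    a_m = 0.32 * _safe_ratio(V + 47.13, 1.0 - np.exp(-0.1 * (V + 47.13)), 10.0)
    b_m = 0.08 * np.exp(-V / 11.0)

    lo = V < -40.0
    a_h = np.where(lo, 0.135 * np.exp(-(80.0 + V) / 6.8), 0.0)
    b_h = np.where(
        lo,
        3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
        1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
    )
    a_j = np.where(
        lo,
        (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
        * (V + 37.78)
        / (1.0 + np.exp(0.311 * (V + 79.23))),
        0.0,
    )
    b_j = np.where(
        lo,
        0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
    )

    a_d = 0.095 * np.exp(-0.01 * (V - 5.0)) / (1.0 + np.exp(-0.072 * (V - 5.0)))
    b_d = 0.07 * np.exp(-0.017 * (V + 44.0)) / (1.0 + np.exp(0.05 * (V + 44.0)))
    a_f = 0.012 * np.exp(-0.008 * (V + 28.0)) / (1.0 + np.exp(0.15 * (V + 28.0)))
    b_f = 0.0065 * np.exp(-0.02 * (V + 30.0)) / (1.0 + np.exp(-0.2 * (V + 30.0)))
    a_x = x_speed * 0.0005 * np.exp(0.083 * (V + 50.0)) / (1.0 + np.exp(0.057 * (V + 50.0)))
    b_x = x_speed * 0.0013 * np.exp(-0.06 * (V + 20.0)) / (1.0 + np.exp(-0.04 * (V + 20.0)))

    return {
        "m": (a_m, b_m),
        "h": (a_h, b_h),
        "j": (a_j, b_j),
        "d": (a_d, b_d),
        "f": (a_f, b_f),
        "X": (a_x, b_x),
    }


def steady_gates(V):
    """Voltage-dependent gate steady states g_inf = alpha/(alpha+beta)."""
    r = gate_rates(V)
    return {g: a / (a + b) for g, (a, b) in r.items()}


def _xi(V):
    """Inactivation-like factor of IK (algebraic, with its V=-77 limit)."""
    V = np.asarray(V, float)
    hi = V > -100.0
    num = np.exp(0.04 * (V + 77.0)) - 1.0
    xi = 2.837 * _safe_ratio(num, (V + 77.0) * np.exp(0.04 * (V + 35.0)),
                             0.04 / np.exp(0.04 * (-77.0 + 35.0)))
    return np.where(hi, xi, 1.0)


def _k1_inf(V, e_k1):
    dv = np.asarray(V, float) - e_k1
    a = 1.02 / (1.0 + np.exp(0.2385 * (dv - 59.215)))
    b = (
        0.49124 * np.exp(0.08032 * (dv + 5.476))
        + np.exp(0.06175 * (dv - 594.31))
    ) / (1.0 + np.exp(-0.5143 * (dv + 4.753)))
    return a / (a + b)


def _kp(V):
    return 1.0 / (1.0 + np.exp((7.488 - np.asarray(V, float)) / 5.98))


def ionic_current(V, m, h, j, d, f, X, Cai, p: CellParams):
    """Total outward ionic current (uA/cm^2), bias not included."""
    e_si = 7.7 - 13.0287 * np.log(Cai)
    i_na = p.g_na * m ** 3 * h * j * (V - p.e_na)
    i_si = p.g_si * d * f * (V - e_si)
    i_k = p.g_k * X * _xi(V) * (V - p.e_k)
    i_k1 = p.g_k1 * _k1_inf(V, p.e_k1) * (V - p.e_k1)
    i_kp = p.g_kp * _kp(V) * (V - p.e_kp)
    i_b = 0.03921 * (V + 59.87)
    return i_na + i_si + i_k + i_k1 + i_kp + i_b


def cell_rhs(state: CellState, params: CellParams) -> CellState:
    """Time derivative of the LR1 state (per ms).

    The bias current enters the voltage equation as an inward term:
    ``dV/dt = -(I_ion - Ibias)/Cm``.
    """
    state.validate()
    V, m, h, j, d, f, X, Cai = state.to_array()
    rates = gate_rates(V, params.x_speed)
    dgates = {g: a * (1.0 - x) - b * x
              for (g, (a, b)), x in zip(rates.items(), (m, h, j, d, f, X))}
    i_ion = ionic_current(V, m, h, j, d, f, X, Cai, params)
    dV = -(i_ion - params.ibias) / params.cm
    e_si = 7.7 - 13.0287 * np.log(Cai)
    i_si = params.g_si * d * f * (V - e_si)
    dCai = -1e-4 * i_si + params.ca_removal * (1e-4 - Cai)
    return CellState(float(dV), float(dgates["m"]), float(dgates["h"]),
                     float(dgates["j"]), float(dgates["d"]), float(dgates["f"]),
                     float(dgates["X"]), float(dCai))


# ---------------------------------------------------------------------------
# steady-state relations (gates and Cai eliminated at fixed V)
# ---------------------------------------------------------------------------

def steady_cai(V: float, p: CellParams) -> float:
    """Equilibrium Cai at clamped V: -1e-4*Isi(V, Cai) + 0.07*(1e-4 - Cai) = 0.

    Isi increases with Cai (through its reversal potential), so the balance
    has a unique root; solved by bracketed bisection (brentq).
    """
    from scipy.optimize import brentq

    g = steady_gates(V)
    df = float(g["d"]) * float(g["f"])

    def bal(cai):
        e_si = 7.7 - 13.0287 * np.log(cai)
        return 0.07 * (1e-4 - cai) - 1e-4 * p.g_si * df * (V - e_si)

    lo, hi = 1e-9, 50.0
    return float(brentq(bal, lo, hi, xtol=1e-16, rtol=1e-14))


def _steady_state(V: float, p: CellParams) -> CellState:
    g = steady_gates(V)
    return CellState(V, float(g["m"]), float(g["h"]), float(g["j"]),
                     float(g["d"]), float(g["f"]), float(g["X"]),
                     steady_cai(V, p))


def _steady_current(V: float, p: CellParams) -> float:
    s = _steady_state(V, p)
    return float(ionic_current(*s.to_array(), p)) - p.ibias


@dataclass
class Equilibrium:
    state: CellState
    eigvals: np.ndarray
    ibias: float

    @property
    def stable(self) -> bool:
        return bool(np.max(self.eigvals.real) < 0)

    @property
    def max_eig_real(self) -> float:
        return float(np.max(self.eigvals.real))


def jacobian(state: CellState, params: CellParams, rel_step: float = 1e-6
             ) -> np.ndarray:
    """Jacobian of the full 8-D right-hand side by central finite differences."""
    y0 = state.to_array()
    n = y0.size
    J = np.empty((n, n))
    for k in range(n):
        h = rel_step * max(1.0, abs(y0[k]))
        yp, ym = y0.copy(), y0.copy()
        yp[k] += h
        ym[k] -= h
        # keep gates/Cai legal for the validator
        if 1 <= k <= 6:
            yp[k] = min(yp[k], 1.0)
            ym[k] = max(ym[k], 0.0)
            h2 = yp[k] - ym[k]
        else:
            h2 = 2 * h
        fp = cell_rhs(CellState.from_array(yp), params).to_array()
        fm = cell_rhs(CellState.from_array(ym), params).to_array()
        J[:, k] = (fp - fm) / h2
    return J


def find_equilibria(ibias: float, v_grid: np.ndarray | None = None,
                    params: CellParams | None = None) -> list[Equilibrium]:
    """All equilibria of the biased cell on a voltage bracket grid.

    Gates and Cai are eliminated at their steady state given V, reducing the
    8-D problem to 1-D root bracketing of the steady-state current balance.
    Each root is returned with the eigenvalues of the full Jacobian.
    """
    from scipy.optimize import brentq

    p = (params or CellParams()).with_bias(ibias)
    if v_grid is None:
        v_grid = np.arange(-90.0, 20.0 + 1e-9, 0.25)
    vals = np.array([_steady_current(v, p) for v in v_grid])
    out: list[Equilibrium] = []
    for k in range(len(v_grid) - 1):
        if vals[k] == 0.0:
            v_eq = float(v_grid[k])
        elif vals[k] * vals[k + 1] < 0:
            v_eq = float(brentq(lambda v: _steady_current(v, p),
                                v_grid[k], v_grid[k + 1],
                                xtol=1e-12, rtol=1e-14))
        else:
            continue
        s = _steady_state(v_eq, p)
        eig = np.linalg.eigvals(jacobian(s, p))
        out.append(Equilibrium(s, eig, ibias))
    out.sort(key=lambda e: e.state.V)
    return out


def resting_state(params: CellParams | None = None) -> CellState:
    """Stable resting equilibrium of the quiescent (Ibias = 0) cell."""
    eqs = find_equilibria(0.0, params=params)
    stable = [e for e in eqs if e.stable]
    if not stable:
        raise RuntimeError("no stable resting equilibrium found")
    return stable[0].state


# ---------------------------------------------------------------------------
# fast integration (Rush-Larsen gates + forward-Euler V/Cai, table-driven)
# ---------------------------------------------------------------------------

#: table layout rows: m,h,j,d,f,X steady states (0-5), Rush-Larsen factors
#: exp(-dt/tau) (6-11), then Xi (12), K1inf (13), Kp (14).
TAB_VMIN, TAB_VMAX, TAB_STEP = -110.0, 70.0, 0.02


def make_tables(dt: float, params: CellParams | None = None) -> np.ndarray:
    """Voltage lookup tables for the Rush-Larsen integrator at time step dt."""
    p = params or CellParams()
    V = np.arange(TAB_VMIN, TAB_VMAX + TAB_STEP / 2, TAB_STEP)
    rates = gate_rates(V, p.x_speed)
    tabs = np.empty((15, V.size))
    for i, g in enumerate(GATE_NAMES):
        a, b = rates[g]
        tabs[i] = a / (a + b)
        tabs[6 + i] = np.exp(-dt * (a + b))
    tabs[12] = _xi(V)
    tabs[13] = _k1_inf(V, p.e_k1)
    tabs[14] = _kp(V)
    return np.ascontiguousarray(tabs)


@dataclass
class CellTrace:
    """Sampled voltage trace plus sub-step-interpolated activation times."""

    t: np.ndarray            # ms, sampled
    V: np.ndarray            # mV
    activation_times: np.ndarray  # ms, upward -40 mV crossings
    dt: float
    final_state: CellState

    @property
    def cycle_lengths(self) -> np.ndarray:
        return np.diff(self.activation_times)


class IntegrationError(RuntimeError):
    pass


ACTIVATION_THRESHOLD = -40.0  # mV, upstroke detection


def simulate_cell(params: CellParams, duration: float, dt: float = 0.01,
                  initial: CellState | None = None,
                  record_stride: int = 100,
                  max_activations: int | None = None) -> CellTrace:
    """Integrate a single LR1 cell for ``duration`` ms.

    Rush-Larsen exponential update for the gates, forward Euler for V and
    Cai.  Activation times are the upward crossings of -40 mV, located by
    linear interpolation between the bracketing samples.  If
    ``max_activations`` is given the run stops early once that many
    activations have been detected.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be positive")
    if initial is None:
        initial = resting_state(params)
    initial.validate()
    tabs = make_tables(dt, params)
    nsteps = int(round(duration / dt))
    nrec = nsteps // record_stride + 1
    v_rec = np.empty(nrec)
    cap = max(64, int(duration / 300) + 8)
    act = np.empty(cap)
    y = initial.to_array()
    n_act, ok = simulate_cell_kernel(
        y, params.ibias, dt, nsteps, record_stride, v_rec,
        tabs, TAB_VMIN, 1.0 / TAB_STEP,
        params.g_na, params.e_na, params.g_si, params.g_k, params.e_k,
        params.g_k1, params.e_k1, params.g_kp, params.e_kp, params.cm,
        params.ca_removal, ACTIVATION_THRESHOLD, act,
        -1 if max_activations is None else int(max_activations),
    )
    if ok < 0:
        raise IntegrationError(
            f"voltage blow-up (|V| > 200 mV) at dt={dt} ms; reduce dt")
    t_rec = np.arange(nrec) * (dt * record_stride)
    return CellTrace(t=t_rec, V=v_rec, activation_times=act[:n_act].copy(),
                     dt=dt, final_state=CellState.from_array(y))


def steady_cycle_length(ibias: float, duration: float = 20_000.0,
                        dt: float = 0.01, discard: int = 1,
                        params: CellParams | None = None,
                        initial: CellState | None = None) -> float:
    """Steady cycle length (ms): mean interval after discarding early beats."""
    p = (params or CellParams()).with_bias(ibias)
    tr = simulate_cell(p, duration, dt=dt, initial=initial)
    cls = np.diff(tr.activation_times[discard:])
    if cls.size < 2:
        raise RuntimeError(
            f"fewer than 3 post-transient activations at Ibias={ibias}")
    return float(np.mean(cls[-min(cls.size, 5):]))


# ---------------------------------------------------------------------------
# bifurcation-structure tooling
# ---------------------------------------------------------------------------

@dataclass
class BifurcationResult:
    """Hopf points, stable-cycle folds and the cycle-length curve vs Ibias."""

    hopf_points: list[float] = field(default_factory=list)
    cycle_folds: tuple[float, float] | None = None
    cl_ibias: np.ndarray | None = None
    cl_ms: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)


def _branch_eig(ibias: float, branch: str, params: CellParams | None) -> float | None:
    eqs = find_equilibria(ibias, params=params)
    if not eqs:
        return None
    eq = eqs[0] if branch == "lower" else eqs[-1]
    return eq.max_eig_real


def hopf_scan(ibias_range: tuple[float, float], tol: float = 1e-3,
              branch: str = "lower", n_coarse: int = 30,
              params: CellParams | None = None) -> BifurcationResult:
    """Locate Hopf points by bisection on the leading eigenvalue real part.

    Scans the requested fixed-point branch ('lower' = smallest-V root,
    'upper' = largest-V root) over ``ibias_range``; every sign change of the
    maximal eigenvalue real part is refined to within ``tol``.  If the branch
    disappears inside the range, the partial result is flagged.
    """
    if tol > 1e-3:
        raise ValueError("tol must be <= 0.001 uA/cm^2")
    lo, hi = ibias_range
    grid = np.linspace(lo, hi, n_coarse)
    res = BifurcationResult()
    vals = []
    for ib in grid:
        vals.append(_branch_eig(float(ib), branch, params))
    for k in range(len(grid) - 1):
        a, b = vals[k], vals[k + 1]
        if a is None or b is None:
            if (a is None) != (b is None) and "branch-lost" not in res.flags:
                res.flags.append("branch-lost")
            continue
        if a == 0.0 or a * b < 0:
            x0, x1 = float(grid[k]), float(grid[k + 1])
            f0 = a
            while x1 - x0 > tol:
                xm = 0.5 * (x0 + x1)
                fm = _branch_eig(xm, branch, params)
                if fm is None:
                    res.flags.append("branch-lost")
                    break
                if f0 * fm <= 0:
                    x1 = xm
                else:
                    x0, f0 = xm, fm
            res.hopf_points.append(0.5 * (x0 + x1))
    return res


def _oscillates(ibias: float, carry: CellState, params: CellParams | None,
                dt: float, transient: float, window: float,
                min_beats: int = 3) -> tuple[bool, CellState]:
    """Sustained-oscillation probe: integrate a carried state through a
    transient, then count activations in a test window (>= min_beats)."""
    p = (params or CellParams()).with_bias(ibias)
    tr = simulate_cell(p, transient, dt=dt, initial=carry, record_stride=10_000)
    tr2 = simulate_cell(p, window, dt=dt, initial=tr.final_state,
                        record_stride=10_000)
    n = tr2.activation_times.size
    if 0 < n < 2:
        # ambiguous: lengthen the window once before deciding
        tr3 = simulate_cell(p, window, dt=dt, initial=tr2.final_state,
                            record_stride=10_000)
        n += tr3.activation_times.size
        return n >= min_beats, tr3.final_state
    return n >= min_beats, tr2.final_state


def cycle_fold_scan(tol: float = 1e-3, dt: float = 0.01,
                    seed_ibias: float = 3.5,
                    search: tuple[float, float] = (2.0, 5.2),
                    transient: float = 5_000.0, window: float = 10_000.0,
                    params: CellParams | None = None) -> BifurcationResult:
    """Bracket the two folds of the stable-cycle branch by a hysteresis
    protocol: an oscillating state is carried from the previous Ibias and the
    persistence of sustained oscillation (>= 3 activations in the test
    window after the transient) is bisected to within ``tol``.
    """
    if tol > 1e-3:
        raise ValueError("tol must be <= 0.001 uA/cm^2")
    p0 = (params or CellParams()).with_bias(seed_ibias)
    rest = resting_state(params)
    osc = simulate_cell(p0, 8_000.0, dt=dt, initial=rest,
                        record_stride=10_000).final_state
    res = BifurcationResult()
    folds = []
    for direction in (-1, +1):
        step = 0.1 * direction
        x_osc, carry = seed_ibias, osc
        x = seed_ibias + step
        x_dead = None
        while search[0] <= x <= search[1]:
            alive, state = _oscillates(x, carry, params, dt, transient, window)
            if alive:
                x_osc, carry = x, state
                x += step
            else:
                x_dead = x
                break
        if x_dead is None:
            res.flags.append("fold-outside-search-range")
            folds.append(x_osc)
            continue
        lo, hi = (x_dead, x_osc) if direction < 0 else (x_osc, x_dead)
        # bisect: keep carried state from the oscillating side
        while hi - lo > tol:
            xm = 0.5 * (lo + hi)
            alive, state = _oscillates(xm, carry, params, dt, transient, window)
            if alive:
                carry = state
                if direction < 0:
                    hi = xm
                else:
                    lo = xm
            else:
                if direction < 0:
                    lo = xm
                else:
                    hi = xm
        folds.append(0.5 * (lo + hi))
    res.cycle_folds = (min(folds), max(folds))
    return res


def cycle_length_curve(fold_lo: float, fold_hi: float, step: float = 0.005,
                       dt: float = 0.01, margin: float = 1e-3,
                       params: CellParams | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Stable cycle length vs Ibias across [fold_lo, fold_hi].

    Sweeps upward carrying the oscillating state between grid points
    (hysteresis continuation of the stable cycle); at each point at least 5
    cycles are simulated, >= 3 transient cycles are discarded and the cycle
    length is the mean of the last measured intervals.
    """
    p = params or CellParams()
    grid = np.arange(fold_lo + margin, fold_hi - margin / 2, step)
    rest = resting_state(p)
    carry = simulate_cell(p.with_bias(float(grid[0]) + 0.05), 8_000.0, dt=dt,
                          initial=rest, record_stride=10_000).final_state
    cls = np.full(grid.size, np.nan)
    for i, ib in enumerate(grid):
        pb = p.with_bias(float(ib))
        tr = simulate_cell(pb, 16_000.0, dt=dt, initial=carry,
                           record_stride=10_000, max_activations=7)
        acts = tr.activation_times
        if acts.size >= 5:
            ivals = np.diff(acts)[3:]
            cls[i] = float(np.mean(ivals))
        carry = tr.final_state
    keep = np.isfinite(cls)
    return grid[keep], cls[keep]
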