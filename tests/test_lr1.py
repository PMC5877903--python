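"""Single biased-cell model: transcription, equilibria, oscillation."""

import numpy as np
import pytest

from myopace import lr1


# --------------------------------------------------------------------------
# an independently written transcription of the ionic equations, kept
# deliberately monolithic (different structure from the package's vectorized
# implementation) to catch transcription slips
# --------------------------------------------------------------------------
def _reference_rhs(V, m, h, j, d, f, X, Cai, p):
    e = np.exp
    am = 0.32 * (V + 47.13) / (1 - e(-0.1 * (V + 47.13)))
    bm = 0.08 * e(-V / 11)
    if V < -40:
        ah = 0.135 * e((80 + V) / -6.8)
        bh = 3.56 * e(0.079 * V) + 3.1e5 * e(0.35 * V)
        aj = ((-1.2714e5 * e(0.2444 * V) - 3.474e-5 * e(-0.04391 * V))
              * (V + 37.78) / (1 + e(0.311 * (V + 79.23))))
        bj = 0.1212 * e(-0.01052 * V) / (1 + e(-0.1378 * (V + 40.14)))
    else:
        ah = 0.0
        bh = 1 / (0.13 * (1 + e((V + 10.66) / -11.1)))
        aj = 0.0
        bj = 0.3 * e(-2.535e-7 * V) / (1 + e(-0.1 * (V + 32)))
    ad = 0.095 * e(-0.01 * (V - 5)) / (1 + e(-0.072 * (V - 5)))
    bd = 0.07 * e(-0.017 * (V + 44)) / (1 + e(0.05 * (V + 44)))
    af = 0.012 * e(-0.008 * (V + 28)) / (1 + e(0.15 * (V + 28)))
    bf = 0.0065 * e(-0.02 * (V + 30)) / (1 + e(-0.2 * (V + 30)))
    ax = 0.0005 * e(0.083 * (V + 50)) / (1 + e(0.057 * (V + 50)))
    bx = 0.0013 * e(-0.06 * (V + 20)) / (1 + e(-0.04 * (V + 20)))

    esi = 7.7 - 13.0287 * np.log(Cai)
    ina = p.g_na * m ** 3 * h * j * (V - p.e_na)
    isi = p.g_si * d * f * (V - esi)
    xi = (2.837 * (e(0.04 * (V + 77)) - 1)
          / ((V + 77) * e(0.04 * (V + 35)))) if V > -100 else 1.0
    ik = p.g_k * X * xi * (V - p.e_k)
    dvk1 = V - p.e_k1
    ak1 = 1.02 / (1 + e(0.2385 * (dvk1 - 59.215)))
    bk1 = ((0.49124 * e(0.08032 * (dvk1 + 5.476))
            + e(0.06175 * (dvk1 - 594.31)))
           / (1 + e(-0.5143 * (dvk1 + 4.753))))
    ik1 = p.g_k1 * ak1 / (ak1 + bk1) * dvk1
    kp = 1 / (1 + e((7.488 - V) / 5.98))
    ikp = p.g_kp * kp * (V - p.e_kp)
    ib = 0.03921 * (V + 59.87)
    itot = ina + isi + ik + ik1 + ikp + ib
    return np.array([
        -(itot - p.ibias) / p.cm,
        am * (1 - m) - bm * m,
        ah * (1 - h) - bh * h,
        aj * (1 - j) - bj * j,
        ad * (1 - d) - bd * d,
        af * (1 - f) - bf * f,
        ax * (1 - X) - bx * X,
        -1e-4 * isi + 0.07 * (1e-4 - Cai),
    ])


def test_rhs_matches_independent_transcription():
    """dV/dt at a probe state agrees with a second transcription to 1e-10."""
    p = lr1.CellParams().with_bias(3.0)
    V = -40.0
    g = lr1.steady_gates(V)
    state = lr1.CellState(V, float(g["m"]), float(g["h"]), float(g["j"]),
                          float(g["d"]), float(g["f"]), float(g["X"]),
                          1.78e-4)
    got = lr1.cell_rhs(state, p).to_array()
    want = _reference_rhs(*state.to_array(), p)
    assert np.allclose(got, want, rtol=1e-10, atol=1e-14)


def test_gate_steady_state_has_zero_gate_derivatives():
    p = lr1.CellParams()
    for V in (-80.0, -55.0, -20.0, 10.0):
        g = lr1.steady_gates(V)
        s = lr1.CellState(V, float(g["m"]), float(g["h"]), float(g["j"]),
                          float(g["d"]), float(g["f"]), float(g["X"]), 2e-4)
        dy = lr1.cell_rhs(s, p).to_array()
        assert np.max(np.abs(dy[1:7])) < 1e-12


def test_resting_equilibrium_is_fixed_point():
    """The quiescent rest state has ~zero derivatives and negative eigenvalues."""
    p = lr1.CellParams()
    rest = lr1.resting_state(p)
    dy = lr1.cell_rhs(rest, p).to_array()
    assert np.linalg.norm(dy) < 1e-8
    eig = np.linalg.eigvals(lr1.jacobian(rest, p))
    assert np.max(eig.real) < 0
    # settling oracle: a nearby state relaxes back to the same equilibrium
    start = lr1.CellState(rest.V + 3.0, rest.m, rest.h, rest.j, rest.d,
                          rest.f, rest.X, rest.Cai)
    tr = lr1.simulate_cell(p, 3_000.0, dt=0.02, initial=start)
    assert abs(tr.final_state.V - rest.V) < 0.01
    assert tr.activation_times.size == 0


def test_equilibrium_consistency_across_bias():
    """Steady-state elimination: equilibria give |rhs| < 1e-8 at any bias."""
    p = lr1.CellParams()
    for ibias in (0.0, 2.0, 3.5, 5.0):
        for eq in lr1.find_equilibria(ibias, params=p):
            dy = lr1.cell_rhs(eq.state, p.with_bias(ibias)).to_array()
            assert np.linalg.norm(dy) < 1e-8, f"ibias={ibias}"


def test_quiescent_cell_never_fires():
    tr = lr1.simulate_cell(lr1.CellParams(), 10_000.0, dt=0.02)
    assert tr.activation_times.size == 0


def test_depolarized_equilibrium_unstable_inside_window():
    """Between the Hopf points the depolarized branch cannot hold the cell."""
    eqs = lr1.find_equilibria(3.5)
    assert eqs, "no equilibrium found at Ibias=3.5"
    assert not eqs[-1].stable


def test_no_hopf_crossing_at_low_bias():
    res = lr1.hopf_scan((0.0, 1.0), tol=1e-3, branch="lower", n_coarse=8)
    assert res.hopf_points == []


def test_integrator_dt_refinement_converges():
    """Halving dt changes the steady cycle length by < 0.1%."""
    cl_a = lr1.steady_cycle_length(3.5, duration=8_000.0, dt=0.02)
    cl_b = lr1.steady_cycle_length(3.5, duration=8_000.0, dt=0.01)
    assert abs(cl_a - cl_b) / cl_b < 1e-3


def test_blowup_raises_with_dt_in_message():
    runaway = lr1.CellState(500.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 2e-4)
    with pytest.raises(lr1.IntegrationError, match="dt"):
        lr1.simulate_cell(lr1.CellParams(), 100.0, dt=0.01, initial=runaway)


def test_lookup_tables_match_exact_rates():
    """Table interpolation reproduces the closed-form rate quantities."""
    p = lr1.CellParams()
    dt = 0.01
    tabs = lr1.make_tables(dt, p)
    rng = np.random.default_rng(0)
    V = rng.uniform(-95, 50, size=200)
    pos = (V - lr1.TAB_VMIN) / lr1.TAB_STEP
    idx = pos.astype(int)
    w = pos - idx
    rates = lr1.gate_rates(V)
    for row, gate in enumerate(lr1.GATE_NAMES):
        a, b = rates[gate]
        interp = tabs[row, idx] * (1 - w) + tabs[row, idx + 1] * w
        assert np.allclose(interp, a / (a + b), atol=5e-7)
        interp_rl = tabs[6 + row, idx] * (1 - w) + tabs[6 + row, idx + 1] * w
        assert np.allclose(interp_rl, np.exp(-dt * (a + b)), atol=5e-7)


def test_state_validation_rejects_bad_values():
    s = lr1.CellState(np.nan, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 2e-4)
    with pytest.raises(ValueError):
        lr1.cell_rhs(s, lr1.CellParams())
    s2 = lr1.CellState(-80.0, 1.5, 0.5, 0.5, 0.5, 0.5, 0.5, 2e-4)
    with pytest.raises(ValueError):
        s2.validate()
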