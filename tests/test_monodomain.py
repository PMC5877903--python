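"""Tissue solver: quiescence, uniformity, conservation, propagation."""

import numpy as np
import pytest
from scipy.sparse import identity
from scipy.sparse.linalg import splu

from myopace import lr1
from myopace.microstructure import (GridSpec, build_coupling_graph,
                                    generate_tessellation)
from myopace.monodomain import (ActivationRecord, SolverConfig,
                                classify_occurrence, make_strip_graph,
                                measure_cv, run_strip, run_tissue)


@pytest.fixture(scope="module")
def tiny_graph():
    tess = generate_tessellation(GridSpec(20, 20), 20, seed=1)
    return build_coupling_graph(tess)


def test_all_quiescent_tissue_stays_silent(tiny_graph):
    cfg = SolverConfig(dt=0.02, duration=500.0)
    rec = run_tissue(tiny_graph, np.zeros(tiny_graph.n_nodes), cfg)
    assert rec.counts.sum() == 0


def test_uniform_all_pm_tissue_reproduces_single_cell_cl(tiny_graph):
    """With identical bias everywhere the coupling term vanishes: every
    node's cycle length equals the isolated cell's to < 0.5%."""
    cfg = SolverConfig(dt=0.02, duration=3_000.0)
    rec = run_tissue(tiny_graph, np.full(tiny_graph.n_nodes, 3.5), cfg)
    assert rec.counts.min() >= 3
    last_cl = rec.times[:, rec.counts.min() - 1] \
        - rec.times[:, rec.counts.min() - 2]
    tr = lr1.simulate_cell(lr1.CellParams().with_bias(3.5), 3_000.0, dt=0.02)
    cell_cl = np.diff(tr.activation_times)[-1]
    assert np.all(np.abs(last_cl - cell_cl) / cell_cl < 5e-3)
    # spatial uniformity is preserved to near machine precision
    assert np.ptp(last_cl) < 1e-6


def test_diffusion_conserves_area_weighted_voltage(tiny_graph):
    """The implicit diffusion operator alone conserves sum(A_i V_i)."""
    dt = 0.02
    K = tiny_graph.laplacian_rate(1.0)
    lu = splu((identity(tiny_graph.n_nodes, format="csc") - dt * K).tocsc())
    rng = np.random.default_rng(0)
    V = rng.uniform(-90, 20, tiny_graph.n_nodes)
    total0 = float(tiny_graph.area_cm2 @ V)
    for _ in range(200):
        V = lu.solve(V)
    total = float(tiny_graph.area_cm2 @ V)
    assert abs(total - total0) / abs(total0) < 1e-8
    # and it smooths: variance must shrink
    assert V.std() < 25.0


def test_plane_wave_cv_short_strip_matches_calibration():
    _, graph = make_strip_graph(2.0, 0.3, 1.0, "x", seed=5)
    rec = run_strip(graph, "x", duration=30.0, dt=0.01)
    cv = measure_cv(rec, "x")
    assert cv == pytest.approx(15.0, rel=0.10)


def test_cv_scales_as_sqrt_of_coupling():
    """Doubling every conductance raises CV by ~sqrt(2) (continuum limit)."""
    from myopace.microstructure import COUPLING_SCALE

    cvs = []
    for scale in (COUPLING_SCALE, 2 * COUPLING_SCALE):
        _, graph = make_strip_graph(2.0, 0.3, 1.0, "x", seed=5,
                                    coupling_scale=scale)
        rec = run_strip(graph, "x", duration=30.0, dt=0.01)
        cvs.append(measure_cv(rec, "x"))
    assert cvs[1] / cvs[0] == pytest.approx(np.sqrt(2), rel=0.10)


def test_activation_times_converge_under_dt_refinement():
    """Halving dt moves activation times by < 0.5 ms on a small strip."""
    _, graph = make_strip_graph(1.0, 0.24, 1.0, "x", seed=2)
    t_half = []
    for dt in (0.02, 0.01):
        rec = run_strip(graph, "x", duration=16.0, dt=dt)
        assert rec.counts.min() >= 1
        t_half.append(rec.times[:, 0])
    assert np.max(np.abs(t_half[0] - t_half[1])) < 0.5


def test_record_validation_and_beat_counts(tiny_graph):
    cfg = SolverConfig(dt=0.02, duration=2_000.0)
    rec = run_tissue(tiny_graph, np.full(tiny_graph.n_nodes, 3.5), cfg)
    rec.validate()
    assert rec.beat_count_map().shape == (20, 20)


def test_classify_occurrence_rules(make_record):
    grid = GridSpec(10, 10)
    silent = make_record(grid, [])
    assert classify_occurrence(silent) == (False, 0)
    one = make_record(grid, [np.full((10, 10), 100.0)])
    assert classify_occurrence(one) == (False, 1)
    five = make_record(grid, [np.full((10, 10), 100.0 + 600 * k)
                              for k in range(5)])
    assert classify_occurrence(five) == (True, 5)
    # a local, non-propagating repetitive firing is not a network beat
    partial = np.full((10, 10), np.nan)
    partial[0, 0] = 100.0
    local = make_record(grid, [partial, np.full((10, 10), 700.0),
                               np.full((10, 10), 1300.0)])
    assert classify_occurrence(local) == (True, 2)


def test_measure_cv_rejects_broken_wave(make_record):
    grid = GridSpec(50, 10)
    t = np.tile(np.arange(50.0), (10, 1))
    t[:, 20:30] = t[:, 20:30][:, ::-1]  # scrambled center
    rec = make_record(grid, [t])
    with pytest.raises(ValueError):
        measure_cv(rec, "x")


def test_record_save_load_roundtrip(tmp_path, tiny_graph):
    cfg = SolverConfig(dt=0.02, duration=300.0)
    rec = run_tissue(tiny_graph, np.zeros(tiny_graph.n_nodes), cfg)
    p = tmp_path / "rec.h5"
    rec.save(p)
    back = ActivationRecord.load(p)
    assert back.grid.nx == rec.grid.nx
    assert np.array_equal(back.counts, rec.counts)
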