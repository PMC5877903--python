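"""Activation-map metrics: maps, gradients, foci, group aggregation."""

import numpy as np
import pandas as pd
import pytest

from myopace.metrics import (FocusInfo, SimSummary, beat_maps,
                             foci_anisotropy, gradient_maps, group_beats,
                             group_stats, locate_focus, occurrence_map,
                             range_percent, summarize_simulation)
from myopace.microstructure import GridSpec


GRID = GridSpec(40, 40)


def _plane_wave(v_um_per_ms: float, t0: float = 0.0) -> np.ndarray:
    x = np.arange(GRID.nx) * GRID.resolution
    return t0 + np.tile(x / v_um_per_ms, (GRID.ny, 1))


def test_synchronous_beat_has_zero_sync_map(make_record):
    rec = make_record(GRID, [np.full((40, 40), 50.0),
                             np.full((40, 40), 850.0)])
    bm = beat_maps(rec)
    for tau in bm.tau_maps:
        assert np.nanmax(tau) == 0.0


def test_plane_wave_sync_map_is_inverse_velocity(make_record):
    """t(x) = x/v: the gradient magnitude is 1/v everywhere interior and
    the transverse component vanishes."""
    v = 1500.0  # um/ms = 150 cm/s
    gx, gy, g = gradient_maps(_plane_wave(v), GRID.resolution)
    inv_v_s_per_cm = 1.0 / 150.0
    interior = np.isfinite(g)
    assert interior.sum() > 400
    assert np.allclose(g[interior], inv_v_s_per_cm, rtol=1e-6)
    assert np.allclose(gy[interior], 0.0, atol=1e-12)


def test_sync_time_matches_measured_cv(make_record):
    """Cross-module consistency: tau of a rigid plane wave equals the
    conduction-velocity fit's inverse within 5%."""
    from myopace.monodomain import measure_cv

    v = 150.0  # um/ms = 15 cm/s
    rec = make_record(GRID, [_plane_wave(v), _plane_wave(v, 800.0)])
    cv = measure_cv(rec, "x")
    bm = beat_maps(rec)
    assert np.nanmedian(bm.tau_maps[0]) == pytest.approx(1.0 / cv, rel=0.05)


def test_cycle_length_maps_and_normalization(make_record):
    """Two beats 800 ms apart: dM = 800 everywhere; Eq-1 minimum is 0."""
    m0 = _plane_wave(300.0, 10.0)
    rec = make_record(GRID, [m0, m0 + 800.0, m0 + 1600.0])
    bm = beat_maps(rec)
    assert bm.dt_act == pytest.approx([800.0, 800.0])
    for i in range(bm.n_beats):
        assert np.nanmin(bm.normalized(i)) == 0.0
    s = summarize_simulation(rec)
    assert s.spontaneous and s.dt_act_ms == pytest.approx(800.0)


def test_median_cycle_length_ignores_nodes_missing_both_beats(make_record):
    m0 = _plane_wave(300.0, 10.0)
    m1 = m0 + 700.0
    dead = np.zeros((40, 40), bool)
    dead[:2, :] = True  # 5% of nodes never activate
    m0[dead] = np.nan
    m1[dead] = np.nan
    rec = make_record(GRID, [m0, m1])
    bm = beat_maps(rec, complete_fraction=0.9)
    assert bm.dt_act == pytest.approx([700.0])


def test_beat_grouping_matches_by_rank_with_missing_beats(make_record):
    """A node that skips the middle beat must not shift its later beats."""
    full = np.full((40, 40), 0.0)
    m0, m1, m2 = full + 100, full + 900, full + 1700
    m1[0, 0] = np.nan
    rec = make_record(GRID, [m0, m1, m2])
    beats = group_beats(rec)
    assert len(beats) == 3
    assert np.isnan(beats[1][0])
    assert beats[2][0] == pytest.approx(1700.0)


@pytest.mark.parametrize("xy,klass", [
    ((20, 20), "central"),
    ((1, 20), "border_L"), ((38, 20), "border_L"),
    ((20, 1), "border_T"), ((20, 38), "border_T"),
    ((1, 1), "corner"), ((38, 38), "corner"),
])
def test_focus_classification_regions(xy, klass):
    t = np.ones((40, 40))
    x, y = xy
    t[y, x] = 0.0
    f = locate_focus(t, GRID)
    assert f.node_xy == (x, y)
    assert f.klass == klass


def test_focus_tie_breaks_to_centroid():
    t = np.ones((40, 40))
    t[10, 10] = t[10, 14] = 0.0  # tie; centroid at x=12
    f = locate_focus(t, GRID)
    assert f.node_xy[1] == 10 and f.node_xy[0] in (10, 14)


def test_group_stats_identical_summaries_have_zero_sd():
    s = SimSummary(True, 4, 800.0, 0.06, 0.04, 0.04,
                   FocusInfo(0, 0, (0, 0), "central"))
    g = group_stats([s, s, s])
    assert g.dt_act_sd == 0.0 and g.tau_sync_sd == 0.0
    assert g.n_spontaneous == 3


def test_group_stats_single_spontaneous_sd_undefined():
    s = SimSummary(True, 4, 800.0, 0.06, 0.04, 0.04, None)
    g = group_stats([s, SimSummary(False)])
    assert np.isnan(g.dt_act_sd)
    assert g.n_spontaneous == 1 and g.n_total == 2


def test_range_percent_definition():
    assert range_percent([500.0, 600.0]) == pytest.approx(20.0)
    assert range_percent([700.0, 700.0]) == 0.0
    with pytest.raises(ValueError):
        range_percent([0.0, 5.0])


def test_foci_anisotropy_ratio_and_flags():
    mk = lambda k: FocusInfo(0, 0, (0, 0), k)
    foci = [mk("border_L")] * 4 + [mk("border_T")] * 2 + [mk("corner")] * 9
    eta_l, eta_t, r = foci_anisotropy(foci)
    assert (eta_l, eta_t) == (4, 2) and r == 2.0
    _, _, r_inf = foci_anisotropy([mk("border_L")])
    assert np.isinf(r_inf)


def test_occurrence_map_and_transition_curves():
    rows = []
    for pq in (0.2, 0.8):
        for da in (0.1, 0.5, 0.9):
            for r in range(4):
                # monotone synthetic boundary: fires iff da exceeds a
                # pq-dependent threshold
                rows.append({"p_thr_quarter": pq, "d_aut": da,
                             "spontaneous": da >= (0.5 if pq < 0.5 else 0.9)})
    pivot, curves = occurrence_map(pd.DataFrame(rows), n_realizations=4)
    assert pivot.loc[0.2, 0.5] == 4 and pivot.loc[0.8, 0.5] == 0
    c = curves.set_index("p_thr_quarter")
    assert c.loc[0.2, "d_aut_any"] == 0.5 and c.loc[0.8, "d_aut_any"] == 0.9
    assert c.loc[0.2, "d_aut_all"] == 0.5


def test_non_automatic_record_summary(make_record):
    rec = make_record(GRID, [np.full((40, 40), 100.0)])
    s = summarize_simulation(rec)
    assert not s.spontaneous and np.isnan(s.dt_act_ms)
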