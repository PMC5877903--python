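"""Sweep orchestration: groups, scale presets, seeds, result tables.

The reference experiment crosses four groups — isotropic or anisotropic
geometry x weak (2.6 uA/cm^2) or strong (3.5) pacemaker bias — with a grid
of pacemaker density ``d_aut`` and homogeneity ``p_thr^(1/4)`` values and
several stochastic realizations per pair.  Every simulation is fully
reproducible: the tessellation and placement RNG streams are spawned from
(base_seed, group, pair, realization) via numpy SeedSequence, and every
output row carries its provenance.

Scale presets keep the pipeline runnable on a laptop: ``full`` is the
reference 920x920-node monolayer (cluster-scale; geometry and placement are
fast, tissue electrophysiology at this size is not), ``desk`` a 1.1 mm
monolayer, ``mini`` a 0.24 mm monolayer for smoke runs and trend checks.
Intensive quantities (conduction velocity, cycle length, synchronization
time) are comparable across presets; extensive ones (cluster sizes) are
not.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as mx
from . import monodomain as md
from . import patterns as pt
from .lr1 import CellParams
from .microstructure import (G_ISO, G_LONG_ANISO, G_TRANS_ANISO, GridSpec,
                             build_coupling_graph, generate_tessellation)

__all__ = [
    "GroupSpec", "GROUPS", "ScalePreset", "PRESETS",
    "SweepConfig", "run_sweep", "simulate_one", "reproduce_anchors",
]


@dataclass(frozen=True)
class GroupSpec:
    """Geometry/strength combination (fixes AR, couplings and PM bias)."""

    name: str
    target_ar: float
    g_long: float
    g_trans: float
    ibias_pm: float


GROUPS = {
    "ISO-2.6": GroupSpec("ISO-2.6", 1.0, G_ISO, G_ISO, 2.6),
    "ISO-3.5": GroupSpec("ISO-3.5", 1.0, G_ISO, G_ISO, 3.5),
    "ANISO-2.6": GroupSpec("ANISO-2.6", 3.0, G_LONG_ANISO, G_TRANS_ANISO, 2.6),
    "ANISO-3.5": GroupSpec("ANISO-3.5", 3.0, G_LONG_ANISO, G_TRANS_ANISO, 3.5),
}


@dataclass(frozen=True)
class ScalePreset:
    name: str
    nx: int
    ny: int
    n_cells: int
    duration_ms: float
    dt_ms: float = 0.02


PRESETS = {
    "full": ScalePreset("full", 920, 920, 42642, 10_000.0, 0.01),
    "desk": ScalePreset("desk", 184, 184, 1705, 6_000.0),
    "mini": ScalePreset("mini", 40, 40, 81, 5_000.0),
    "micro": ScalePreset("micro", 24, 24, 29, 2_000.0),
}


@dataclass
class SweepConfig:
    """Declarative sweep description (see module docstring)."""

    group: str = "ISO-3.5"
    d_aut_grid: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    p_thr_quarter_grid: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    n_realizations: int = 4
    preset: str = "mini"
    base_seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        for v in (*self.d_aut_grid, *self.p_thr_quarter_grid):
            if not 0 < v <= 1:
                raise ValueError("grids must lie in (0, 1]")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


def _sim_seed(base_seed: int, group: str, i: int, j: int, r: int
              ) -> np.random.SeedSequence:
    gi = sorted(GROUPS).index(group)
    return np.random.SeedSequence((base_seed, gi, i, j, r))


def simulate_one(group: GroupSpec, preset: ScalePreset, d_aut: float,
                 p_thr_quarter: float, seed_seq: np.random.SeedSequence,
                 params: CellParams | None = None) -> mx.SimSummary:
    """One realization: tessellation -> pattern -> tissue -> summary."""
    tess_ss, pat_ss = seed_seq.spawn(2)
    tess_seed = int(tess_ss.generate_state(1)[0] % (2 ** 31))
    grid = GridSpec(preset.nx, preset.ny)
    tess = generate_tessellation(grid, preset.n_cells,
                                 target_ar=group.target_ar, seed=tess_seed)
    pattern = pt.place_pacemakers(
        tess, pt.PatternParams(d_aut, p_thr_quarter, group.ibias_pm),
        rng=np.random.default_rng(pat_ss))
    if pattern.n_pm == 0:
        return mx.SimSummary(spontaneous=False, n_beats=0)
    graph = build_coupling_graph(tess, g_long=group.g_long,
                                 g_trans=group.g_trans)
    cfg = md.SolverConfig(dt=preset.dt_ms, duration=preset.duration_ms)
    rec = md.run_tissue(graph, pattern.node_bias(tess), cfg, params)
    return mx.summarize_simulation(rec)


def _summary_row(cfg: SweepConfig, i, j, r, s: mx.SimSummary) -> dict:
    f = s.focus_last
    return {
        "group": cfg.group,
        "d_aut": cfg.d_aut_grid[i],
        "p_thr_quarter": cfg.p_thr_quarter_grid[j],
        "realization": r,
        "base_seed": cfg.base_seed,
        "preset": cfg.preset,
        "spontaneous": bool(s.spontaneous),
        "n_beats": s.n_beats,
        "dt_act_ms": s.dt_act_ms,
        "tau_sync_s_per_cm": s.tau_sync,
        "tau_sync_x": s.tau_sync_x,
        "tau_sync_y": s.tau_sync_y,
        "focus_x_um": np.nan if f is None else f.x_um,
        "focus_y_um": np.nan if f is None else f.y_um,
        "focus_class": "" if f is None else f.klass,
    }


def run_sweep(cfg: SweepConfig, resume: bool = True,
              verbose: bool = False) -> pd.DataFrame:
    """Run (or resume) a sweep; returns the per-simulation summary table.

    With an ``out_dir``, summary.csv is rewritten after every simulation so
    an interrupted sweep can resume: rows whose (group, pair, realization)
    key already exists are not recomputed.  Reruns with the same config are
    deterministic.
    """
    group = GROUPS[cfg.group]
    preset = PRESETS[cfg.preset]
    out = Path(cfg.out_dir) if cfg.out_dir else None
    done: set[tuple] = set()
    rows: list[dict] = []
    if out:
        out.mkdir(parents=True, exist_ok=True)
        f = out / "summary.csv"
        if resume and f.exists():
            prev = pd.read_csv(f, keep_default_na=False,
                               na_values=["nan", ""])
            rows = prev.to_dict("records")
            done = {(rr["group"], round(rr["d_aut"], 10),
                     round(rr["p_thr_quarter"], 10), rr["realization"])
                    for rr in rows}
    for i, da in enumerate(cfg.d_aut_grid):
        for j, pq in enumerate(cfg.p_thr_quarter_grid):
            for r in range(cfg.n_realizations):
                key = (cfg.group, round(da, 10), round(pq, 10), r)
                if key in done:
                    continue
                t0 = time.time()
                s = simulate_one(group, preset, da, pq,
                                 _sim_seed(cfg.base_seed, cfg.group, i, j, r))
                rows.append(_summary_row(cfg, i, j, r, s))
                if verbose:
                    print(f"{cfg.group} d={da} pq={pq} r={r}: "
                          f"spont={s.spontaneous} n={s.n_beats} "
                          f"({time.time() - t0:.1f}s)", flush=True)
                if out:
                    _write_csv(pd.DataFrame(rows), out / "summary.csv")
    df = pd.DataFrame(rows)
    if out:
        _write_csv(df, out / "summary.csv")
        _write_csv(group_table(df), out / "groups.csv")
    return df


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def group_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-(group, d_aut, p_thr_quarter) aggregates of a summary table."""
    rows = []
    for (g, da, pq), sub in summary.groupby(
            ["group", "d_aut", "p_thr_quarter"]):
        sims = [
            mx.SimSummary(
                spontaneous=bool(rr.spontaneous), n_beats=int(rr.n_beats),
                dt_act_ms=rr.dt_act_ms, tau_sync=rr.tau_sync_s_per_cm,
                tau_sync_x=rr.tau_sync_x, tau_sync_y=rr.tau_sync_y,
                focus_last=None if not rr.focus_class else mx.FocusInfo(
                    rr.focus_x_um, rr.focus_y_um, (0, 0), rr.focus_class))
            for rr in sub.itertuples()
        ]
        gs = mx.group_stats(sims)
        eta_l, eta_t, rfoci = mx.foci_anisotropy(gs.foci_last)
        rows.append({
            "group": g, "d_aut": da, "p_thr_quarter": pq,
            "n": gs.n_spontaneous, "N": gs.n_total,
            "dt_act_mean_ms": gs.dt_act_mean, "dt_act_sd_ms": gs.dt_act_sd,
            "tau_sync_mean": gs.tau_sync_mean, "tau_sync_sd": gs.tau_sync_sd,
            "tau_x_mean": gs.tau_x_mean, "tau_y_mean": gs.tau_y_mean,
            "eta_L": eta_l, "eta_T": eta_t, "r": rfoci,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference-anchor recomputation (the package's verification surface)
# ---------------------------------------------------------------------------

def reproduce_anchors(seed: int = 1, which: tuple[str, ...] = ("all",),
                      verbose: bool = True) -> dict[str, dict]:
    """Recompute the printed reference anchors from scratch.

    Returns {name: {"value": float, "n": int, "runtime_s": float}} for the
    maximum/minimum stable single-cell cycle length over the oscillation
    window, the three plane-wave conduction velocities and the full-scale
    tessellation statistics.  ``seed`` drives every stochastic component.
    """
    from . import lr1
    from .metrics import COMPLETE_FRACTION  # noqa: F401  (doc cross-link)
    from .microstructure import cell_shape_stats
    from .monodomain import make_strip_graph, measure_cv, run_strip

    def want(key):
        return "all" in which or key in which

    out: dict[str, dict] = {}

    def log(msg):
        if verbose:
            print(msg, flush=True)

    if want("cl_extremes"):
        t0 = time.time()
        res = lr1.cycle_fold_scan(tol=1e-3, dt=0.01)
        flo, fhi = res.cycle_folds
        ib, cl = lr1.cycle_length_curve(flo, fhi, step=0.005, dt=0.01)
        n = int(cl.size)
        out["cl_max_ms"] = {"value": float(cl.max()), "n": n,
                            "runtime_s": round(time.time() - t0, 1)}
        out["cl_min_ms"] = {"value": float(cl.min()), "n": n,
                            "runtime_s": round(time.time() - t0, 1)}
        out["cycle_folds"] = {"value": (float(flo), float(fhi)), "n": n,
                              "runtime_s": round(time.time() - t0, 1)}
        log(f"cycle-length sweep: folds {flo:.3f}/{fhi:.3f}, "
            f"CL {cl.max():.0f}..{cl.min():.0f} ms over {n} points")

    rng = np.random.default_rng(seed)
    strip_seeds = [int(s) for s in rng.integers(2 ** 31, size=9)]
    cv_specs = {
        "cv_iso_cm_s": ("x", 1.0, G_ISO, G_ISO, 90.0),
        "cv_aniso_long_cm_s": ("x", 3.0, G_LONG_ANISO, G_TRANS_ANISO, 60.0),
        "cv_aniso_trans_cm_s": ("y", 3.0, G_LONG_ANISO, G_TRANS_ANISO, 120.0),
    }
    for k, (axis, ar, gl, gt, dur) in cv_specs.items():
        if not want(k):
            continue
        t0 = time.time()
        cvs = []
        for _ in range(3):
            s = strip_seeds.pop(0)
            _, graph = make_strip_graph(5.0, 0.5, ar, axis, seed=s,
                                        g_long=gl, g_trans=gt)
            rec = run_strip(graph, axis, duration=dur, dt=0.01)
            cvs.append(measure_cv(rec, axis))
        out[k] = {"value": float(np.mean(cvs)), "n": 3,
                  "runtime_s": round(time.time() - t0, 1)}
        log(f"{k}: {np.mean(cvs):.2f} cm/s over 3 strips")

    if want("tessellation"):
        t0 = time.time()
        grid = GridSpec(920, 920)
        tseed = int(np.random.default_rng(seed + 1).integers(2 ** 31))
        tess = generate_tessellation(grid, 42642, target_ar=1.0, seed=tseed)
        st = cell_shape_stats(tess)
        out["nodes_per_cell"] = {
            "value": float(round(st.n_nodes.mean())), "n": 42642,
            "runtime_s": round(time.time() - t0, 1)}
        out["neighbors_per_cell"] = {
            "value": float(round(st.n_neighbors.mean())), "n": 42642,
            "runtime_s": round(time.time() - t0, 1)}
        log(f"tessellation: {st.n_nodes.mean():.2f} nodes/cell, "
            f"{st.n_neighbors.mean():.2f} neighbors")
    return out
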