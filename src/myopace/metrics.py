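"""Activation-map analytics for spontaneous monolayer activity.

From a tissue :class:`~myopace.monodomain.ActivationRecord` this module
builds, per network beat,

* the activation map ``M_tact`` (per-node activation time, ms) and its
  normalized form ``M_tact - min`` (minimum exactly 0),
* cycle-length maps ``dM_i = M_i - M_{i-1}`` whose per-beat spatial median
  is the beat's cycle length; the simulation cycle length is the mean of
  those medians with the first action potential discarded,
* synchronization-time maps: the magnitude of the spatial gradient of the
  activation map (inverse local conduction velocity, s/cm), estimated by
  local least-squares plane fits over a circular node window; a perfectly
  synchronous beat has a zero map, a rigid plane wave a uniform 1/v.

It also locates the focus (first-activated site) of each beat and
classifies it as central / longitudinal-border / transverse-border / corner
with respect to a centered square of half the domain side, and aggregates
per-simulation summaries into per-(density, homogeneity) group statistics:
occurrence counts, means and standard deviations over realizations,
min-to-max percentage ranges across pairs, and the border-foci anisotropy
ratio r = eta_L / eta_T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .microstructure import GridSpec

__all__ = [
    "group_beats",
    "BeatMaps",
    "beat_maps",
    "gradient_maps",
    "locate_focus",
    "FocusInfo",
    "SimSummary",
    "summarize_simulation",
    "GroupSummary",
    "group_stats",
    "range_percent",
    "occurrence_map",
    "foci_anisotropy",
]

#: per-node activation coverage below which a beat is excluded from the
#: cycle-length / synchronization statistics
COMPLETE_FRACTION = 0.9

#: gradient-estimation window radius in nodes (30 um at 6 um resolution)
GRADIENT_RADIUS = 5


def group_beats(record, gap_ms: float | None = None) -> list[np.ndarray]:
    """Split per-node activation times into network beats.

    Beats are temporal clusters of the pooled activation times separated by
    gaps larger than ``gap_ms`` (default: 40% of the median per-node
    inter-activation interval, at least 100 ms).  Returns one (n_nodes,)
    array per beat with the node's activation time or NaN.
    """
    counts = record.counts
    times = record.times
    pooled = times[np.isfinite(times)]
    if pooled.size == 0:
        return []
    if gap_ms is None:
        node_cls = np.diff(times, axis=1)
        node_cls = node_cls[np.isfinite(node_cls)]
        gap_ms = max(100.0, 0.4 * float(np.median(node_cls))) \
            if node_cls.size else 100.0
    pooled = np.sort(pooled)
    cuts = np.nonzero(np.diff(pooled) > gap_ms)[0]
    starts = np.concatenate([[pooled[0]], pooled[cuts + 1]])
    ends = np.concatenate([pooled[cuts], [pooled[-1]]])
    n = times.shape[0]
    beats = []
    for s, e in zip(starts, ends):
        m = np.full(n, np.nan)
        inwin = (times >= s) & (times <= e)
        rows, cols = np.nonzero(inwin)
        # first activation of a node inside the window wins
        first = {}
        for r, c in zip(rows, cols):
            if r not in first:
                first[r] = times[r, c]
        if first:
            ridx = np.fromiter(first.keys(), int)
            m[ridx] = np.fromiter(first.values(), float)
        beats.append(m)
    return beats


def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    dy, dx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    keep = dx ** 2 + dy ** 2 <= radius ** 2
    return dx[keep], dy[keep]


def gradient_maps(tact: np.ndarray, resolution_um: float,
                  radius: int = GRADIENT_RADIUS
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """|dt/dx|, |dt/dy| and |grad t| (s/cm) by windowed plane fits.

    Only nodes whose full circular window lies inside the domain and
    contains no undefined activation times get a value; everything else is
    NaN.  1 ms/um = 10 s/cm.
    """
    dx, dy = _disc_offsets(radius)
    kx = np.zeros((2 * radius + 1,) * 2)
    ky = np.zeros_like(kx)
    kx[dy + radius, dx + radius] = dx
    ky[dy + radius, dx + radius] = dy
    sxx = float((dx ** 2).sum())
    syy = float((dy ** 2).sum())
    kin = np.zeros_like(kx)
    kin[dy + radius, dx + radius] = 1.0

    finite = np.isfinite(tact)
    t0 = np.where(finite, tact, 0.0)
    n_ok = ndi.convolve(finite.astype(float), kin, mode="constant", cval=0.0)
    full = np.abs(n_ok - kin.sum()) < 0.5
    # exclude windows clipped by the boundary
    full[:radius, :] = full[-radius:, :] = False
    full[:, :radius] = full[:, -radius:] = False

    bx = ndi.convolve(t0, kx[::-1, ::-1], mode="constant", cval=0.0) / sxx
    by = ndi.convolve(t0, ky[::-1, ::-1], mode="constant", cval=0.0) / syy
    conv = 10.0 / resolution_um  # (ms/node) -> s/cm
    gx = np.where(full, np.abs(bx) * conv, np.nan)
    gy = np.where(full, np.abs(by) * conv, np.nan)
    g = np.hypot(gx, gy)
    return gx, gy, g


@dataclass
class FocusInfo:
    """First-initiation site of one beat."""

    x_um: float
    y_um: float
    node_xy: tuple[int, int]
    klass: str  # central | border_L | border_T | corner


def locate_focus(tact: np.ndarray, grid: GridSpec) -> FocusInfo:
    """Earliest-activated node of a beat map, with border classification.

    Ties are broken by the centroid of the minimal-time set snapped to its
    nearest member.  The central region is the axis-aligned centered square
    (rectangle for non-square domains) of half the domain side; exclusive
    left/right borders are longitudinal (border_L), exclusive top/bottom
    transverse (border_T), overlaps are corners.
    """
    if not np.isfinite(tact).any():
        raise ValueError("beat map has no activated node")
    tmin = np.nanmin(tact)
    ys, xs = np.nonzero(tact <= tmin + 1e-9)
    cx, cy = xs.mean(), ys.mean()
    k = int(np.argmin((xs - cx) ** 2 + (ys - cy) ** 2))
    x, y = int(xs[k]), int(ys[k])

    nx, ny = grid.nx, grid.ny
    in_x = nx / 4 <= x < 3 * nx / 4
    in_y = ny / 4 <= y < 3 * ny / 4
    if in_x and in_y:
        klass = "central"
    elif in_y:
        klass = "border_L"
    elif in_x:
        klass = "border_T"
    else:
        klass = "corner"
    return FocusInfo(x * grid.resolution, y * grid.resolution, (x, y), klass)


@dataclass
class BeatMaps:
    """Per-beat activation, cycle-length and synchronization maps."""

    grid: GridSpec
    tact: list[np.ndarray]            # (ny, nx) per complete beat, ms
    dt_act: list[float]               # spatial-median cycle length per beat i>=2
    tau_maps: list[np.ndarray]        # |grad t| per beat, s/cm
    tau_medians: list[float]
    tau_x_medians: list[float]
    tau_y_medians: list[float]
    foci: list[FocusInfo]

    @property
    def n_beats(self) -> int:
        return len(self.tact)

    def normalized(self, i: int) -> np.ndarray:
        m = self.tact[i]
        return m - np.nanmin(m)


def beat_maps(record, gradient_radius: int = GRADIENT_RADIUS,
              complete_fraction: float = COMPLETE_FRACTION) -> BeatMaps:
    """All per-beat maps of a spontaneous simulation.

    Beats covering fewer than ``complete_fraction`` of the nodes (partial
    beats clipped by the simulation window, local non-propagating firing)
    are dropped before any statistic is computed; beats are then matched
    across nodes by rank.
    """
    grid = record.grid
    beats = group_beats(record)
    maps = [b.reshape(grid.ny, grid.nx) for b in beats
            if np.isfinite(b).mean() > complete_fraction]
    if len(maps) < 2:
        raise ValueError("fewer than two complete beats; simulation is "
                         "non-automatic, no maps")
    dt_act = []
    for i in range(1, len(maps)):
        dm = maps[i] - maps[i - 1]
        if np.isfinite(dm).mean() <= 0.5:
            raise ValueError("cycle-length map defined on <50% of nodes")
        dt_act.append(float(np.nanmedian(dm)))
    tau_maps, tau_med, tx_med, ty_med, foci = [], [], [], [], []
    for m in maps:
        gx, gy, g = gradient_maps(m, grid.resolution, gradient_radius)
        tau_maps.append(g)
        tau_med.append(float(np.nanmedian(g)))
        tx_med.append(float(np.nanmedian(gx)))
        ty_med.append(float(np.nanmedian(gy)))
        foci.append(locate_focus(m, grid))
    return BeatMaps(grid, maps, dt_act, tau_maps, tau_med, tx_med, ty_med,
                    foci)


@dataclass
class SimSummary:
    """Scalar summary of one tissue simulation."""

    spontaneous: bool
    n_beats: int = 0
    dt_act_ms: float = np.nan       # mean of per-beat median cycle lengths
    tau_sync: float = np.nan        # s/cm, mean of per-beat medians (beat 1
    tau_sync_x: float = np.nan      # excluded)
    tau_sync_y: float = np.nan
    focus_last: FocusInfo | None = None
    meta: dict = field(default_factory=dict)


def summarize_simulation(record, **kwargs) -> SimSummary:
    """Occurrence classification plus cycle-length / synchronization scalars.

    The first action potential is excluded from every average; a simulation
    with fewer than two complete network beats is non-automatic and carries
    no scalars.
    """
    try:
        bm = beat_maps(record, **kwargs)
    except ValueError:
        beats = group_beats(record)
        n = sum(1 for b in beats
                if np.isfinite(b).mean() > COMPLETE_FRACTION)
        return SimSummary(spontaneous=False, n_beats=n)
    return SimSummary(
        spontaneous=True,
        n_beats=bm.n_beats,
        dt_act_ms=float(np.mean(bm.dt_act)),
        tau_sync=float(np.mean(bm.tau_medians[1:])),
        tau_sync_x=float(np.mean(bm.tau_x_medians[1:])),
        tau_sync_y=float(np.mean(bm.tau_y_medians[1:])),
        focus_last=bm.foci[-1],
    )


@dataclass
class GroupSummary:
    """Aggregates over the realizations of one (D_aut, p_thr) pair."""

    n_spontaneous: int
    n_total: int
    dt_act_mean: float = np.nan
    dt_act_sd: float = np.nan
    tau_sync_mean: float = np.nan
    tau_sync_sd: float = np.nan
    tau_x_mean: float = np.nan
    tau_y_mean: float = np.nan
    foci_last: list[FocusInfo] = field(default_factory=list)

    @property
    def all_spontaneous(self) -> bool:
        return self.n_spontaneous == self.n_total


def group_stats(summaries: Sequence[SimSummary]) -> GroupSummary:
    """Eq-style aggregation over realizations (spontaneous ones only).

    Standard deviations use the n-1 denominator and are NaN for n <= 1.
    """
    spont = [s for s in summaries if s.spontaneous]
    g = GroupSummary(n_spontaneous=len(spont), n_total=len(summaries))
    if not spont:
        return g
    dt = np.array([s.dt_act_ms for s in spont])
    ts = np.array([s.tau_sync for s in spont])
    g.dt_act_mean = float(dt.mean())
    g.tau_sync_mean = float(ts.mean())
    g.tau_x_mean = float(np.mean([s.tau_sync_x for s in spont]))
    g.tau_y_mean = float(np.mean([s.tau_sync_y for s in spont]))
    if len(spont) > 1:
        g.dt_act_sd = float(dt.std(ddof=1))
        g.tau_sync_sd = float(ts.std(ddof=1))
    g.foci_last = [s.focus_last for s in spont if s.focus_last is not None]
    return g


def range_percent(values: Iterable[float]) -> float:
    """100 * (max - min) / min over pair-level means (dissimilar patterns)."""
    v = np.asarray(list(values), float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no values to range over")
    if v.min() == 0:
        raise ValueError("range undefined: minimum is 0")
    return float(100.0 * (v.max() - v.min()) / v.min())


def foci_anisotropy(foci: Iterable[FocusInfo]) -> tuple[int, int, float]:
    """(eta_L, eta_T, r): exclusive longitudinal vs transverse border foci.

    Corner foci are excluded; r is inf when eta_T = 0 and eta_L > 0, NaN
    when both are 0.
    """
    eta_l = sum(1 for f in foci if f.klass == "border_L")
    eta_t = sum(1 for f in foci if f.klass == "border_T")
    if eta_t == 0:
        r = np.inf if eta_l else np.nan
    else:
        r = eta_l / eta_t
    return eta_l, eta_t, float(r)


def occurrence_map(table: pd.DataFrame, n_realizations: int | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """n-of-N occurrence per (d_aut, p_thr_quarter) pair plus transition curves.

    ``table`` needs columns d_aut, p_thr_quarter, spontaneous (bool).
    Returns (pivot of n, curves) where curves holds, per p_thr_quarter, the
    minimum d_aut reaching [n > 0] and [n = N] (NaN where never reached).
    """
    grp = table.groupby(["p_thr_quarter", "d_aut"])["spontaneous"]
    n = grp.sum().rename("n").reset_index()
    tot = grp.size().rename("N").reset_index()
    df = n.merge(tot)
    if n_realizations is not None:
        df["N"] = n_realizations
    pivot = df.pivot(index="p_thr_quarter", columns="d_aut", values="n")
    rows = []
    for pq, sub in df.groupby("p_thr_quarter"):
        any_d = sub.loc[sub.n > 0, "d_aut"]
        all_d = sub.loc[sub.n >= sub.N, "d_aut"]
        rows.append({
            "p_thr_quarter": pq,
            "d_aut_any": any_d.min() if len(any_d) else np.nan,
            "d_aut_all": all_d.min() if len(all_d) else np.nan,
        })
    curves = pd.DataFrame(rows)
    curves["difference"] = curves.d_aut_all - curves.d_aut_any
    return pivot, curves
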