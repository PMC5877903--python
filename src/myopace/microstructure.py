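"""Semi-discrete 2D monolayer microstructure on a regular node grid.

A monolayer is a fine regular grid of nodes (default 6 um spacing) fully
partitioned into contiguous "cells" of ~20 nodes each.  Isotropic monolayers
have cells of aspect ratio ~1; anisotropic monolayers have cells elongated
~3:1 along x (the longitudinal axis).  The tessellation is generated by
jittered stratified seeding followed by nearest-seed assignment in an
anisotropy-scaled metric (a stochastic Voronoi mosaic), with a contiguity
repair pass; this reproduces the reference statistics (mean nodes/cell set
by grid size over cell count, ~6 neighbors per cell, mean aspect ratio
within ~10% of target).

From a tessellation, :func:`build_coupling_graph` assembles the symmetric
node-to-node conductance graph: ohmic intracellular links between same-cell
neighbor nodes (slab of resistivity ``rho_intra``) and gap-junction links
between cells, ``g_long`` per x-crossing border edge and ``g_trans`` per
y-crossing edge.  Membrane area per node is the node footprint
(resolution^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = [
    "GridSpec",
    "CellTessellation",
    "CouplingGraph",
    "generate_tessellation",
    "cell_shape_stats",
    "build_coupling_graph",
    "COUPLING_SCALE",
]

#: dimensionless scale applied to the printed per-edge gap-junction
#: conductances when they enter the voltage equation; the single free
#: geometric scalar of the tissue model, calibrated once so that the
#: isotropic plane-wave conduction velocity is ~15 cm/s (see docs/methods.md)
COUPLING_SCALE = 252.0

# Table-1 coupling constants (nS per 6 um border edge)
G_ISO = 0.04
G_LONG_ANISO = 0.062
G_TRANS_ANISO = 0.034
RHO_INTRA = 200.0  # Ohm cm
MONOLAYER_THICKNESS_UM = 10.0


@dataclass(frozen=True)
class GridSpec:
    """Node grid: ``nx`` columns by ``ny`` rows at ``resolution`` um spacing."""

    nx: int
    ny: int
    resolution: float = 6.0
    seed: int | None = None

    def __post_init__(self):
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid must be at least 2x2 nodes")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def extent_um(self) -> tuple[float, float]:
        return self.nx * self.resolution, self.ny * self.resolution


@dataclass
class CellTessellation:
    """Node->cell assignment plus directed border-edge counts per cell pair.

    ``cell_of_node`` is an (ny, nx) int array of cell ids in [0, n_cells).
    ``adjacency`` maps each unordered cell pair (a < b) to the number of
    shared border edges crossing in x and in y.
    """

    grid: GridSpec
    cell_of_node: np.ndarray
    adjacency: dict[tuple[int, int], tuple[int, int]]
    seed: int | None = None
    target_ar: float = 1.0

    @property
    def n_cells(self) -> int:
        return int(self.cell_of_node.max()) + 1

    @property
    def cell_sizes(self) -> np.ndarray:
        return np.bincount(self.cell_of_node.ravel(), minlength=self.n_cells)

    def neighbor_counts(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=int)
        for (a, b) in self.adjacency:
            deg[a] += 1
            deg[b] += 1
        return deg

    def cell_adjacency_lists(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_cells)]
        for (a, b) in self.adjacency:
            out[a].append(b)
            out[b].append(a)
        return out

    def cell_graph(self) -> sp.csr_matrix:
        """Unweighted symmetric cell-adjacency matrix (CSR)."""
        if not self.adjacency:
            return sp.csr_matrix((self.n_cells, self.n_cells))
        ab = np.array(list(self.adjacency.keys()))
        rows = np.concatenate([ab[:, 0], ab[:, 1]])
        cols = np.concatenate([ab[:, 1], ab[:, 0]])
        dat = np.ones(rows.size, dtype=np.int8)
        return sp.csr_matrix((dat, (rows, cols)),
                             shape=(self.n_cells, self.n_cells))

    def boundary_cells(self) -> np.ndarray:
        lab = self.cell_of_node
        edge = np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
        return np.unique(edge)

    def validate(self) -> None:
        lab = self.cell_of_node
        n = self.n_cells
        sizes = self.cell_sizes
        if (sizes == 0).any():
            raise ValueError("tessellation has empty cells")
        # contiguity by per-cell flood fill
        for cid, sl in enumerate(ndi.find_objects(lab + 1)):
            _, ncomp = ndi.label(lab[sl] == cid)
            if ncomp != 1:
                raise ValueError(f"cell {cid} is not contiguous")
        for (a, b), (ex, ey) in self.adjacency.items():
            if not (0 <= a < b < n) or ex + ey <= 0:
                raise ValueError("malformed adjacency entry")

    # -- serialization ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write label image (.npz) and adjacency table (.csv) side by side."""
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            cell_of_node=self.cell_of_node.astype(np.int32),
            nx=self.grid.nx, ny=self.grid.ny,
            resolution=self.grid.resolution,
            seed=-1 if self.seed is None else self.seed,
            target_ar=self.target_ar,
        )
        rows = [(a, b, ex, ey) for (a, b), (ex, ey) in
                sorted(self.adjacency.items())]
        pd.DataFrame(rows, columns=["cell_a", "cell_b", "n_edges_x",
                                    "n_edges_y"]
                     ).to_csv(path.with_suffix(".csv"), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "CellTessellation":
        path = Path(path)
        z = np.load(path.with_suffix(".npz"))
        lab = z["cell_of_node"]
        grid = GridSpec(int(z["nx"]), int(z["ny"]), float(z["resolution"]),
                        None if int(z["seed"]) < 0 else int(z["seed"]))
        adj = _adjacency_from_labels(lab)
        return cls(grid, lab, adj, grid.seed, float(z["target_ar"]))


def _adjacency_from_labels(lab: np.ndarray
                           ) -> dict[tuple[int, int], tuple[int, int]]:
    n = int(lab.max()) + 1
    out: dict[tuple[int, int], tuple[int, int]] = {}
    for axis, slot in ((1, 0), (0, 1)):  # x-crossing edges, then y-crossing
        if axis == 1:
            a, b = lab[:, :-1].ravel(), lab[:, 1:].ravel()
        else:
            a, b = lab[:-1, :].ravel(), lab[1:, :].ravel()
        m = a != b
        lo = np.minimum(a[m], b[m]).astype(np.int64)
        hi = np.maximum(a[m], b[m]).astype(np.int64)
        keys, counts = np.unique(lo * n + hi, return_counts=True)
        for k, c in zip(keys, counts):
            pair = (int(k // n), int(k % n))
            ex, ey = out.get(pair, (0, 0))
            if slot == 0:
                out[pair] = (ex + int(c), ey)
            else:
                out[pair] = (ex, ey + int(c))
    return out


def _stratified_seeds(grid: GridSpec, n_cells: int, target_ar: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Jittered lattice of exactly ``n_cells`` seed points (node coords).

    Lattice spacing is sqrt(area * AR) along x and sqrt(area / AR) along y so
    that nearest-seed cells in the scaled metric come out near the target
    aspect ratio.
    """
    area = grid.n_nodes / n_cells
    sy = np.sqrt(area / target_ar)
    n_rows = max(1, int(round(grid.ny / sy)))
    base, extra = divmod(n_cells, n_rows)
    counts = np.full(n_rows, base)
    counts[rng.choice(n_rows, size=extra, replace=False)] += 1
    row_h = grid.ny / n_rows
    pts = np.empty((n_cells, 2))
    k = 0
    for r in range(n_rows):
        c = counts[r]
        if c == 0:
            continue
        col_w = grid.nx / c
        x = (np.arange(c) + rng.uniform(0.15, 0.85, size=c)) * col_w
        y = (r + rng.uniform(0.15, 0.85, size=c)) * row_h
        pts[k:k + c, 0] = x
        pts[k:k + c, 1] = y
        k += c
    return pts


def _repair_contiguity(lab: np.ndarray, n_cells: int) -> None:
    """Keep each cell's largest 4-connected component; reassign the rest to
    adjacent cells (in place)."""
    orphan = np.zeros(lab.shape, dtype=bool)
    for cid, sl in enumerate(ndi.find_objects(lab + 1)):
        if sl is None:
            continue
        sub = lab[sl] == cid
        comp, ncomp = ndi.label(sub)
        if ncomp <= 1:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        orphan[sl] |= sub & (comp != keep)
    if not orphan.any():
        return
    lab[orphan] = -1
    # peel orphans layer by layer onto neighboring cells
    while True:
        ys, xs = np.nonzero(lab == -1)
        if ys.size == 0:
            break
        progress = False
        for y, x in zip(ys, xs):
            cand = []
            if y > 0 and lab[y - 1, x] >= 0:
                cand.append(lab[y - 1, x])
            if y < lab.shape[0] - 1 and lab[y + 1, x] >= 0:
                cand.append(lab[y + 1, x])
            if x > 0 and lab[y, x - 1] >= 0:
                cand.append(lab[y, x - 1])
            if x < lab.shape[1] - 1 and lab[y, x + 1] >= 0:
                cand.append(lab[y, x + 1])
            if cand:
                vals, cnts = np.unique(cand, return_counts=True)
                lab[y, x] = vals[np.argmax(cnts)]
                progress = True
        if not progress:  # isolated orphan pocket: give to cell 0 arbitrarily
            lab[lab == -1] = 0
            break


def generate_tessellation(grid: GridSpec, n_cells: int, target_ar: float = 1.0,
                          seed: int | None = None) -> CellTessellation:
    """Stochastic full-coverage tessellation of the node grid into cells.

    Parameters
    ----------
    grid:
        node grid specification.
    n_cells:
        number of cells; mean cell size is ``grid.n_nodes / n_cells`` nodes.
    target_ar:
        target mean aspect ratio (bounding-box x-extent over y-extent);
        1 for isotropic, ~3 for anisotropic monolayers.
    seed:
        RNG seed (falls back to ``grid.seed``).

    The same (grid, n_cells, target_ar, seed) always yields the identical
    tessellation.
    """
    if n_cells < 1 or n_cells > grid.n_nodes // 4:
        raise ValueError("n_cells must be in [1, nx*ny/4]")
    if target_ar < 1:
        raise ValueError("target_ar must be >= 1 (elongation along x)")
    area = grid.n_nodes / n_cells
    if np.sqrt(area / target_ar) < 1.5 and n_cells > 1:
        raise ValueError(
            f"target_ar={target_ar} unattainable: mean cell width would be "
            f"{np.sqrt(area / target_ar):.2f} nodes (< 1.5) on this grid")
    seed = grid.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    if n_cells == 1:
        lab = np.zeros((grid.ny, grid.nx), dtype=np.int32)
        return CellTessellation(grid, lab, {}, seed, target_ar)

    seeds = _stratified_seeds(grid, n_cells, target_ar, rng)
    # nearest seed in the anisotropy-scaled metric (x compressed by AR)
    scale = np.array([1.0 / target_ar, 1.0])
    tree = cKDTree(seeds * scale)
    xs, ys = np.meshgrid(np.arange(grid.nx) + 0.5, np.arange(grid.ny) + 0.5)
    pts = np.column_stack([xs.ravel() / target_ar, ys.ravel()])
    _, owner = tree.query(pts, workers=-1)
    lab = owner.astype(np.int32).reshape(grid.ny, grid.nx)

    # guard: a seed may capture no node; steal its nearest node
    sizes = np.bincount(lab.ravel(), minlength=n_cells)
    for cid in np.nonzero(sizes == 0)[0]:
        iy = min(grid.ny - 1, max(0, int(seeds[cid, 1])))
        ix = min(grid.nx - 1, max(0, int(seeds[cid, 0])))
        lab[iy, ix] = cid

    _repair_contiguity(lab, n_cells)
    adj = _adjacency_from_labels(lab)
    return CellTessellation(grid, lab, adj, seed, target_ar)


def cell_shape_stats(tess: CellTessellation) -> pd.DataFrame:
    """Per-cell geometry: node count, length/width (um) and aspect ratio.

    Length is the bounding-box x extent times the resolution, width the y
    extent; AR = length / width (longitudinal axis along x).
    """
    lab = tess.cell_of_node
    n = tess.n_cells
    res = tess.grid.resolution
    ys, xs = np.nonzero(lab >= 0)
    cid = lab[ys, xs]
    xmin = np.full(n, np.iinfo(np.int64).max)
    xmax = np.full(n, -1)
    ymin = np.full(n, np.iinfo(np.int64).max)
    ymax = np.full(n, -1)
    np.minimum.at(xmin, cid, xs)
    np.maximum.at(xmax, cid, xs)
    np.minimum.at(ymin, cid, ys)
    np.maximum.at(ymax, cid, ys)
    length = (xmax - xmin + 1) * res
    width = (ymax - ymin + 1) * res
    return pd.DataFrame({
        "n_nodes": tess.cell_sizes,
        "length_um": length,
        "width_um": width,
        "aspect_ratio": length / width,
        "n_neighbors": tess.neighbor_counts(),
    })


@dataclass
class CouplingGraph:
    """Symmetric node-level conductance graph plus per-node membrane area.

    ``conductance`` is CSR in siemens (gap-junction entries already carry the
    calibrated coupling scale); ``area_cm2`` the membrane area per node.
    Node order is row-major over the grid.
    """

    grid: GridSpec
    conductance: sp.csr_matrix
    area_cm2: np.ndarray
    node_cell: np.ndarray  # flat node -> cell id

    @property
    def n_nodes(self) -> int:
        return self.conductance.shape[0]

    def laplacian_rate(self, cm_uf_per_cm2: float = 1.0) -> sp.csr_matrix:
        """K such that (dV/dt)_diffusion = K V in mV/ms.

        K = (G - diag(G 1)) * 1e-3 / (Cm * A) with G in S, Cm in F/cm^2.
        """
        G = self.conductance
        rowsum = np.asarray(G.sum(axis=1)).ravel()
        L = G - sp.diags(rowsum)
        cap = cm_uf_per_cm2 * 1e-6 * self.area_cm2  # F
        return sp.diags(1e-3 / cap) @ L


def build_coupling_graph(tess: CellTessellation,
                         rho_intra: float = RHO_INTRA,
                         g_long: float = G_ISO,
                         g_trans: float = G_ISO,
                         thickness_um: float = MONOLAYER_THICKNESS_UM,
                         coupling_scale: float = COUPLING_SCALE,
                         ) -> CouplingGraph:
    """Node conductance graph from a tessellation.

    Same-cell grid edges get the ohmic slab conductance ``thickness/rho``
    (cross-section thickness x resolution over path length resolution);
    between-cell edges get ``g_long`` (x-crossing) or ``g_trans``
    (y-crossing) nS per 6 um border edge.  ``coupling_scale`` is the single
    calibrated scalar mapping the printed per-edge conductances onto the
    per-area membrane normalization (see docs/methods.md); it multiplies the
    gap-junction links only.
    """
    if min(rho_intra, g_long, g_trans, thickness_um) <= 0:
        raise ValueError("all physical parameters must be positive")
    grid = tess.grid
    lab = tess.cell_of_node
    nx, ny = grid.nx, grid.ny
    n = nx * ny
    idx = np.arange(n).reshape(ny, nx)

    g_intra = (thickness_um * 1e-4) / rho_intra  # S per same-cell link

    rows, cols, vals = [], [], []
    for axis in (1, 0):
        if axis == 1:
            a, b = idx[:, :-1].ravel(), idx[:, 1:].ravel()
            ca, cb = lab[:, :-1].ravel(), lab[:, 1:].ravel()
            g_inter = g_long
        else:
            a, b = idx[:-1, :].ravel(), idx[1:, :].ravel()
            ca, cb = lab[:-1, :].ravel(), lab[1:, :].ravel()
            g_inter = g_trans
        same = ca == cb
        g = np.where(same, g_intra, g_inter * 1e-9 * coupling_scale)
        rows.append(a)
        cols.append(b)
        vals.append(g)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    G = sp.coo_matrix((np.concatenate([vals, vals]),
                       (np.concatenate([rows, cols]),
                        np.concatenate([cols, rows]))), shape=(n, n)).tocsr()

    ncomp, _ = sp.csgraph.connected_components(G, directed=False)
    if ncomp != 1:
        raise ValueError("coupling graph is disconnected (tessellation bug)")

    area = np.full(n, (grid.resolution * 1e-4) ** 2)  # cm^2 node footprint
    return CouplingGraph(grid, G, area, lab.ravel().copy())
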