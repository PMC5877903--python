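"""Shared fixtures: small tessellations and synthetic activation records."""

import numpy as np
import pytest

from myopace.microstructure import GridSpec, generate_tessellation
from myopace.monodomain import ActivationRecord


@pytest.fixture(scope="session")
def small_iso_tess():
    """120x120-node isotropic tessellation, ~725 cells of ~20 nodes."""
    return generate_tessellation(GridSpec(120, 120), 725, target_ar=1.0,
                                 seed=3)


@pytest.fixture(scope="session")
def small_aniso_tess():
    return generate_tessellation(GridSpec(120, 120), 725, target_ar=3.0,
                                 seed=4)


@pytest.fixture(scope="session")
def lattice_adjacency():
    """Plain w x h square-lattice cell adjacency (neighbor lists)."""

    def make(w: int, h: int) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(w * h)]
        for y in range(h):
            for x in range(w):
                i = y * w + x
                if x + 1 < w:
                    out[i].append(i + 1)
                    out[i + 1].append(i)
                if y + 1 < h:
                    out[i].append(i + w)
                    out[i + w].append(i)
        return out

    return make


def synthetic_record(grid: GridSpec, beat_maps: list[np.ndarray],
                     duration: float = 10_000.0) -> ActivationRecord:
    """Activation record with prescribed per-beat node times (NaN = silent)."""
    n = grid.n_nodes
    nb = len(beat_maps)
    times = np.full((n, max(nb, 1)), np.nan)
    counts = np.zeros(n, dtype=np.int64)
    for b, m in enumerate(beat_maps):
        flat = np.asarray(m, float).ravel()
        ok = np.isfinite(flat)
        times[ok, counts[ok]] = flat[ok]
        counts[ok] += 1
    return ActivationRecord(grid, times, counts, duration, 0.01)


@pytest.fixture
def make_record():
    return synthetic_record
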