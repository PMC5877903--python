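"""Aggregation/nucleation placement and cluster analytics."""

import numpy as np
import pytest
from scipy import stats

from myopace.patterns import (ClusterReport, PacemakerPattern, PatternParams,
                              find_clusters, place_pacemakers, porosity)


def _union_find_components(is_pm, adjacency):
    """Independent oracle: classic union-find over PM cells."""
    parent = {i: i for i in np.nonzero(is_pm)[0]}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in parent:
        for nb in adjacency[i]:
            if is_pm[nb]:
                parent[find(i)] = find(nb)
    comps = {}
    for i in parent:
        comps.setdefault(find(i), []).append(i)
    return sorted(sorted(c) for c in comps.values())


@pytest.mark.parametrize("d_aut", [0.05, 0.33, 0.77, 1.0])
def test_pm_count_is_exact(lattice_adjacency, d_aut):
    adj = lattice_adjacency(15, 15)
    pat = place_pacemakers(adj, PatternParams(d_aut, 0.5, 2.6, seed=5))
    assert pat.n_pm == round(d_aut * 225)
    assert np.all(pat.ibias_cell[pat.is_pm] == 2.6)
    assert np.all(pat.ibias_cell[~pat.is_pm] == 0.0)


def test_saturation_is_single_full_cluster(lattice_adjacency):
    adj = lattice_adjacency(8, 8)
    pat = place_pacemakers(adj, PatternParams(1.0, 0.9, 2.6, seed=1))
    rep = find_clusters(pat, adj, boundary_cells=np.arange(64))
    assert rep.n_cluster == 1 and rep.s_cluster == 64


def test_pure_aggregation_always_one_cluster(lattice_adjacency):
    """p_thr = 0: every placement is adjacent to the cluster; 100 seeds."""
    adj = lattice_adjacency(20, 20)
    boundary = np.array([i for i in range(400)
                         if i % 20 in (0, 19) or i // 20 in (0, 19)])
    for seed in range(100):
        pat = place_pacemakers(adj, PatternParams(0.3, 0.0, 2.6, seed=seed))
        rep = find_clusters(pat, adj, boundary_cells=boundary)
        assert rep.n_cluster == 1


def test_pure_nucleation_support_on_3x3(lattice_adjacency):
    """p_thr = 1 on a 3x3 lattice: the 2nd cell is never adjacent to the
    1st, and all non-adjacent pairs are reachable (exhaustive support)."""
    adj = lattice_adjacency(3, 3)
    observed = set()
    for seed in range(400):
        pat = place_pacemakers(adj, PatternParams(2 / 9, 1.0, 2.6, seed=seed))
        a, b = sorted(np.nonzero(pat.is_pm)[0])
        assert b not in adj[a], "nucleation placed an adjacent pair"
        observed.add((a, b))
    expected = {(a, b) for a in range(9) for b in range(a + 1, 9)
                if b not in adj[a]}
    assert observed == expected


def test_second_placement_is_uniform_over_nucleation_set(lattice_adjacency):
    """Conditioned on the first cell, the second is uniform over M2
    (chi-squared over 10,000 draws on the 3x3 toy)."""
    adj = lattice_adjacency(3, 3)
    # for the center-first subpopulation, M2 is exactly the 4 corners
    counts = {}
    for seed in range(10_000):
        rng = np.random.default_rng((7, seed))
        pat = place_pacemakers(adj, PatternParams(2 / 9, 1.0, 2.6), rng)
        cells = set(np.nonzero(pat.is_pm)[0])
        if 4 in cells:  # center involved; partner must be a corner
            partner = (cells - {4}).pop()
            counts[partner] = counts.get(partner, 0) + 1
    freq = np.array([counts.get(c, 0) for c in (0, 2, 6, 8)])
    assert freq.sum() > 500  # enough center-first draws
    _, p = stats.chisquare(freq)
    assert p > 1e-3, f"corner frequencies {freq} not uniform"


def test_cluster_labels_match_union_find_oracle(lattice_adjacency):
    adj = lattice_adjacency(30, 30)
    boundary = np.array([i for i in range(900)
                         if i % 30 in (0, 29) or i // 30 in (0, 29)])
    for seed in (0, 1, 2):
        pat = place_pacemakers(adj, PatternParams(0.4, 0.7, 2.6, seed=seed))
        rep = find_clusters(pat, adj, boundary_cells=boundary)
        got = {}
        for i in np.nonzero(pat.is_pm)[0]:
            got.setdefault(rep.labels[i], []).append(int(i))
        got_comps = sorted(sorted(c) for c in got.values())
        assert got_comps == _union_find_components(pat.is_pm, adj)
        assert rep.sizes.sum() == pat.n_pm


def test_two_pm_separated_by_quiescent_are_two_clusters(lattice_adjacency):
    adj = lattice_adjacency(3, 1)
    is_pm = np.array([True, False, True])
    pat = PacemakerPattern(is_pm, np.where(is_pm, 2.6, 0.0),
                           PatternParams(2 / 3, 0.5, 2.6))
    rep = find_clusters(pat, adj, boundary_cells=np.array([0, 2]))
    assert rep.n_cluster == 2 and rep.s_cluster == 1


def test_porosity_of_closed_ring(lattice_adjacency):
    """8 PM cells enclosing 1 quiescent cell: porosity = 1/9."""
    adj = lattice_adjacency(3, 3)
    is_pm = np.ones(9, bool)
    is_pm[4] = False
    pat = PacemakerPattern(is_pm, np.where(is_pm, 2.6, 0.0),
                           PatternParams(8 / 9, 0.0, 2.6))
    rep = find_clusters(pat, adj,
                        boundary_cells=np.array([0, 1, 2, 3, 5, 6, 7, 8]))
    assert rep.s_cluster == 8 and rep.s_t_cluster == 9
    assert porosity([rep]) == pytest.approx(1 / 9)


def test_porosity_zero_without_enclosed_cells(lattice_adjacency):
    adj = lattice_adjacency(4, 4)
    is_pm = np.zeros(16, bool)
    is_pm[[0, 1]] = True
    pat = PacemakerPattern(is_pm, np.where(is_pm, 2.6, 0.0),
                           PatternParams(2 / 16, 0.0, 2.6))
    rep = find_clusters(pat, adj, boundary_cells=np.arange(16))
    assert porosity([rep]) == 0.0
    assert porosity([rep]) < 1.0


def test_porosity_undefined_without_pm_cells(lattice_adjacency):
    adj = lattice_adjacency(3, 3)
    pat = PacemakerPattern(np.zeros(9, bool), np.zeros(9),
                           PatternParams(0.0, 0.5, 2.6))
    rep = find_clusters(pat, adj, boundary_cells=np.arange(9))
    with pytest.raises(ValueError, match="no PM"):
        porosity([rep])


def test_largest_cluster_grows_monotonically_with_density(lattice_adjacency):
    """Same RNG stream: patterns are nested in d_aut, so S_cluster is
    non-decreasing."""
    adj = lattice_adjacency(20, 20)
    boundary = np.array([i for i in range(400)
                         if i % 20 in (0, 19) or i // 20 in (0, 19)])
    prev = 0
    for d in (0.1, 0.2, 0.4, 0.6, 0.8):
        pat = place_pacemakers(adj, PatternParams(d, 0.6, 2.6, seed=33))
        rep = find_clusters(pat, adj, boundary_cells=boundary)
        assert rep.s_cluster >= prev
        prev = rep.s_cluster


def test_d_aut_max_recorded_when_nucleation_exhausts(lattice_adjacency):
    adj = lattice_adjacency(10, 10)
    pat = place_pacemakers(adj, PatternParams(0.9, 1.0, 2.6, seed=2))
    assert pat.d_aut_max_hit is not None
    assert 0.1 < pat.d_aut_max_hit < 0.6
    low = place_pacemakers(adj, PatternParams(0.1, 1.0, 2.6, seed=2))
    assert low.d_aut_max_hit is None


def test_geometry_independence_of_cluster_statistics(small_iso_tess,
                                                     small_aniso_tess):
    """Isotropic and anisotropic adjacency graphs give similar S_cluster
    (cell orientation does not enter the placement process)."""
    means = []
    for tess in (small_iso_tess, small_aniso_tess):
        vals = []
        for seed in range(6):
            pat = place_pacemakers(tess, PatternParams(0.4, 0.5, 2.6,
                                                       seed=seed))
            vals.append(find_clusters(pat, tess).s_cluster)
        means.append(np.mean(vals))
    assert abs(means[0] - means[1]) / max(means) < 0.25


def test_empty_pattern_for_zero_density(lattice_adjacency):
    adj = lattice_adjacency(5, 5)
    pat = place_pacemakers(adj, PatternParams(0.0, 0.5, 2.6, seed=0))
    assert pat.n_pm == 0
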