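"""NEB paths, snippet graphs, ranking, 1D projection, and barriers."""

import numpy as np
import pytest

from pmfpath import landscapes as L
from pmfpath import mfep
from pmfpath.errors import ConnectivityError, ProfileError
from pmfpath.surface_tools import Minimum
from pmfpath.wham import PMFGrid
from pmfpath.surface_tools import interpolate

from conftest import minimax_barrier_oracle


def surface_minima(surface):
    return [Minimum(np.array(p.location), p.energy, i)
            for i, p in enumerate(surface.minima)]


class TestNeb:
    def test_separable_surface_path_is_axis_aligned(self):
        """F = f(z1) + const: the MFEP is a straight segment along z1."""
        surf = L.make_surface(
            [(-15.0, (-0.5, 0.0), (0.2, 50.0)),
             (-15.0, (0.5, 0.0), (0.2, 50.0))],
            ((-1.2, 1.2), (-0.5, 0.5)))
        mins = surface_minima(surf)
        path = mfep.neb(surf, mins[0], mins[1])
        assert path.converged
        assert np.max(np.abs(path.nodes[:, 1] - mins[0].location[1])) < 1e-3

    def test_barrier_matches_minimax_oracle(self, two_well_surface):
        mins = surface_minima(two_well_surface)
        path = mfep.neb(two_well_surface, mins[0], mins[1])
        assert path.converged
        oracle = minimax_barrier_oracle(
            two_well_surface, mins[0].location, mins[1].location, n_grid=300)
        assert float(path.energies.max()) == pytest.approx(oracle, abs=0.5)

    def test_identical_endpoints_rejected(self, two_well_surface):
        m = surface_minima(two_well_surface)[0]
        with pytest.raises(ValueError):
            mfep.neb(two_well_surface, m, m)

    def test_neb_barrier_bounded_below_by_minimax(self, conduction_surface):
        """The NEB maximum can never undercut the minimax barrier."""
        mins = surface_minima(conduction_surface)
        a = min(mins, key=lambda m: m.location[1])  # deepest staircase ends
        b = max(mins, key=lambda m: np.linalg.norm(m.location - a.location))
        level = mfep.grid_minimax_barrier(conduction_surface, a.location,
                                          b.location, n_grid=300)
        # snippet a->nearest neighbor along the chain
        near = sorted(mins, key=lambda m: np.linalg.norm(
            m.location - a.location))[1]
        path = mfep.neb(conduction_surface, a, near)
        pair_level = mfep.grid_minimax_barrier(
            conduction_surface, a.location, near.location, n_grid=300)
        assert path.energies.max() >= pair_level - 0.5
        assert level >= pair_level - 1e-9


class TestGridMinimax:
    def test_agrees_with_independent_flooding_oracle(self, two_well_surface):
        mins = surface_minima(two_well_surface)
        mine = mfep.grid_minimax_barrier(two_well_surface, mins[0].location,
                                         mins[1].location, n_grid=300)
        oracle = minimax_barrier_oracle(two_well_surface, mins[0].location,
                                        mins[1].location, n_grid=300)
        assert mine == pytest.approx(oracle, abs=0.1)


class TestPathGraph:
    def test_two_minima_one_edge(self, two_well_surface):
        mins = surface_minima(two_well_surface)
        g = mfep.build_path_graph(two_well_surface, mins)
        assert g.number_of_edges() == 1

    def test_collinear_wells_give_chain(self):
        terms = [(-20.0, (x, 0.0), (0.12, 0.12)) for x in
                 (-1.0, -0.5, 0.0, 0.5, 1.0)]
        surf = L.make_surface(terms, ((-1.4, 1.4), (-0.4, 0.4)))
        mins = surface_minima(surf)
        g = mfep.build_path_graph(surf, mins)
        degrees = sorted(d for _, d in g.degree())
        assert g.number_of_edges() == 4
        assert degrees == [1, 1, 2, 2, 2]

    def test_masked_region_excludes_blocked_pair(self):
        """Three wells; an unsampled wall between two of them removes that
        snippet but keeps the detour edges."""
        edges = [np.linspace(-1.2, 1.2, 81), np.linspace(-0.8, 0.8, 81)]
        centers = [0.5 * (e[1:] + e[:-1]) for e in edges]
        zz = np.meshgrid(*centers, indexing="ij")

        def f(x, y):
            return (-20 * np.exp(-((x + 0.8) ** 2 + y ** 2) / 0.045)
                    - 20 * np.exp(-((x - 0.8) ** 2 + y ** 2) / 0.045)
                    - 20 * np.exp(-(x ** 2 + (y - 0.5) ** 2) / 0.045))

        fe = f(zz[0], zz[1])
        fe -= fe.min()
        counts = np.full(fe.shape, 50.0)
        # wall of unsampled bins on the direct x-axis corridor
        wall = (np.abs(zz[0]) < 0.08) & (zz[1] < 0.2)
        fe[wall] = np.nan
        counts[wall] = 0.0
        pmf = PMFGrid(edges=edges, free_energy=fe, counts=counts,
                      temperature=310.0)
        interp = interpolate(pmf)
        mins = [Minimum(np.array([-0.8, 0.0]), 0.0, 0),
                Minimum(np.array([0.8, 0.0]), 0.0, 1),
                Minimum(np.array([0.0, 0.5]), 0.0, 2)]
        g = mfep.build_path_graph(interp, mins, cutoff=5.0,
                                  neb_settings=mfep.NebSettings(
                                      force_tolerance=5.0))
        assert not g.has_edge(0, 1)
        assert g.has_edge(0, 2) and g.has_edge(1, 2)


class TestEnumeratePaths:
    def test_chain_graph_single_route(self, conduction_surface):
        mins = surface_minima(conduction_surface)
        g = mfep.build_path_graph(conduction_surface, mins)
        ends = [m for m in mins if g.degree(m.index) == 1]
        paths = mfep.enumerate_paths(g, ends[0], ends[1])
        assert len(paths) == 1
        assert paths[0].converged

    def test_diamond_prefers_low_saddle_branch(self):
        """Two routes around a central ridge: the lower saddle wins."""
        surf = L.make_surface(
            [(-25.0, (-0.8, 0.0), (0.15, 0.15)),
             (-25.0, (0.8, 0.0), (0.15, 0.15)),
             (-18.0, (0.0, 0.45), (0.15, 0.15)),
             (-10.0, (0.0, -0.45), (0.15, 0.15)),
             (40.0, (0.0, 0.0), (0.18, 0.18))],
            ((-1.3, 1.3), (-0.9, 0.9)))
        mins = surface_minima(surf)
        left = min(mins, key=lambda m: m.location[0])
        right = max(mins, key=lambda m: m.location[0])
        g = mfep.build_path_graph(surf, mins, cutoff=1.5)
        paths = mfep.enumerate_paths(g, left, right, max_paths=4)
        assert len(paths) >= 2
        assert paths[0].energies.max() <= paths[-1].energies.max() + 1e-6
        # the winning route passes through the deeper (lower-saddle) side well
        via = paths[0].nodes[np.argmin(np.abs(paths[0].nodes[:, 0]))]
        assert via[1] > 0

    def test_max_paths_one_returns_only_mfep(self, two_well_surface):
        mins = surface_minima(two_well_surface)
        g = mfep.build_path_graph(two_well_surface, mins)
        paths = mfep.enumerate_paths(g, mins[0], mins[1], max_paths=1)
        assert len(paths) == 1

    def test_ranking_invariant_to_minima_order(self, conduction_surface):
        mins = surface_minima(conduction_surface)
        g1 = mfep.build_path_graph(conduction_surface, mins)
        relabeled = [Minimum(m.location, m.energy, len(mins) - 1 - m.index)
                     for m in reversed(mins)]
        g2 = mfep.build_path_graph(conduction_surface, relabeled)
        ends1 = [m.index for m in mins if g1.degree(m.index) == 1]
        ends2 = [m.index for m in relabeled if g2.degree(m.index) == 1]
        p1 = mfep.enumerate_paths(g1, ends1[0], ends1[1])[0]
        p2 = mfep.enumerate_paths(g2, sorted(ends2)[1], sorted(ends2)[0])[0]
        assert p1.energies.max() == pytest.approx(p2.energies.max(), abs=0.1)

    def test_disconnected_raises(self, two_well_surface):
        mins = surface_minima(two_well_surface)
        g = mfep.build_path_graph(two_well_surface, mins)
        g.remove_edge(mins[0].index, mins[1].index)
        with pytest.raises(ConnectivityError):
            mfep.enumerate_paths(g, mins[0], mins[1])


class TestProject1d:
    def test_straight_path_arc_length(self):
        nodes = np.stack([np.linspace(0, 1, 11), np.zeros(11)], axis=-1)
        path = mfep.Path(nodes=nodes, energies=np.zeros(11) + 1.0,
                         converged=True, max_force_residual=0.0)
        prof = mfep.project_1d(path, min_prominence=0.1)
        assert prof.lam[0] == 0.0
        assert prof.lam[-1] == pytest.approx(1.0)

    def test_symmetric_double_well_peak_at_midpoint(self, two_well_surface):
        mins = surface_minima(two_well_surface)
        path = mfep.neb(two_well_surface, mins[0], mins[1])
        prof = mfep.project_1d(path)
        (peak,) = prof.peak_indices
        assert prof.lam[peak] == pytest.approx(prof.lam[-1] / 2, abs=0.05)

    def test_five_well_profile_alternates(self, conduction_surface):
        mins = surface_minima(conduction_surface)
        g = mfep.build_path_graph(conduction_surface, mins)
        ends = [m for m in mins if g.degree(m.index) == 1]
        (path,) = mfep.enumerate_paths(g, ends[0], ends[1])
        prof = mfep.project_1d(path, min_prominence=1.0)
        assert len(prof.valley_indices) == 5
        assert len(prof.peak_indices) == 4
        kinds = [k for k, _ in prof.markers]
        assert kinds == ["valley", "peak"] * 4 + ["valley"]

    def test_endpoint_energies_preserved_exactly(self, two_well_surface):
        mins = surface_minima(two_well_surface)
        path = mfep.neb(two_well_surface, mins[0], mins[1])
        prof = mfep.project_1d(path)
        assert prof.free_energy[0] == path.energies[0]
        assert prof.free_energy[-1] == path.energies[-1]

    def test_unconverged_path_rejected(self):
        path = mfep.Path(nodes=np.zeros((5, 2)), energies=np.zeros(5),
                         converged=False, max_force_residual=99.0)
        with pytest.raises(ValueError):
            mfep.project_1d(path)


def _profile_from_points(lam, f):
    """Dense piecewise-linear profile whose control points alternate
    valley, peak, valley, ..."""
    lam = np.asarray(lam, float)
    f = np.asarray(f, float)
    dense_lam = np.linspace(lam[0], lam[-1], 2001)
    dense_f = np.interp(dense_lam, lam, f)
    markers = [("valley" if j % 2 == 0 else "peak",
                int(np.argmin(np.abs(dense_lam - x))))
               for j, x in enumerate(lam)]
    return mfep.Profile1D(lam=dense_lam, free_energy=dense_f, markers=markers)


class TestBarrier:
    def test_forward_barrier_is_peak_minus_valley(self):
        prof = _profile_from_points([0.0, 0.5, 1.0], [0.0, 10.0, 2.0])
        assert mfep.barrier(prof, 0, 1) == pytest.approx(10.0, abs=0.05)

    def test_cyclic_reentry_includes_net_drop(self):
        """Profile dropping 25 kJ/mol with a 5 kJ/mol maximum before its
        first state: re-entry over the periodic boundary costs 30."""
        lam = [0.0, 0.1, 0.2, 0.5, 0.8, 1.0, 1.3, 1.6, 2.0]
        f = [2.0, 5.0, 0.0, 12.0, -8.0, 6.0, -15.0, -5.0, -25.0]
        # valleys at f=0 (state 0) ... f=-25 (last); the max before state 0
        # sits at +5
        dense_lam = np.linspace(0, 2.0, 4001)
        dense_f = np.interp(dense_lam, lam, f)

        def at(x):
            return int(np.argmin(np.abs(dense_lam - x)))

        markers = [("valley", at(0.2)), ("peak", at(0.5)),
                   ("valley", at(0.8)), ("peak", at(1.0)),
                   ("valley", at(1.3)), ("peak", at(1.6)),
                   ("valley", at(2.0))]
        prof = mfep.Profile1D(lam=dense_lam, free_energy=dense_f,
                              markers=markers)
        assert mfep.barrier(prof, 3, 0) == pytest.approx(30.0, abs=0.05)

    def test_same_state_barrier_is_zero(self):
        prof = _profile_from_points([0.0, 0.5, 1.0], [0.0, 10.0, 2.0])
        assert mfep.barrier(prof, 1, 1) == 0.0

    def test_unknown_state_raises(self):
        prof = _profile_from_points([0.0, 0.5, 1.0], [0.0, 10.0, 2.0])
        with pytest.raises(LookupError):
            mfep.barrier(prof, 0, 7)
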