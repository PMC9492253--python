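"""Minimum free-energy paths: NEB snippets, path joining, 1D projection.

Paths between free-energy minima are relaxed with the nudged elastic band
method (improved tangent, climbing image on the highest interior node during
the final quarter of the iteration budget).  Snippets between all nearby
minima form a graph; simple start-to-end routes through it are joined,
re-relaxed as a whole, and ranked by their highest energy (the quantity that
controls rates).  The chosen path is projected onto its arc length λ to give
the 1D profile F(λ) whose valleys and peaks feed the rate chain, including
the cyclic re-entry barrier over the "periodic boundary" from the last state
back to the first.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .errors import ConnectivityError, MaskedRegionError, ProfileError
from .surface_tools import Minimum, PMFInterpolant

logger = logging.getLogger(__name__)

__all__ = ["Path", "Profile1D", "NebSettings", "neb", "build_path_graph",
           "enumerate_paths", "project_1d", "barrier", "grid_minimax_barrier"]


@dataclass
class Path:
    """An ordered chain of CV-space nodes with their free energies."""

    nodes: np.ndarray  # (n, ndim) nm
    energies: np.ndarray  # (n,) kJ/mol
    endpoints: tuple = (None, None)  # minimum indices when known
    converged: bool = False
    max_force_residual: float = np.inf  # kJ/mol/nm

    @property
    def barrier_height(self):
        """Max energy along the path minus the lower endpoint energy."""
        return float(self.energies.max() -
                     min(self.energies[0], self.energies[-1]))

    @property
    def arc_length(self):
        seg = np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def action(self):
        """Trapezoidal integral of F over arc length (ranking tie-break)."""
        lam = self.arc_length
        return float(np.trapezoid(self.energies, lam))


@dataclass
class NebSettings:
    n_images: int = 32
    spring_constant: float = 500.0  # kJ/mol/nm^2
    max_iterations: int = 5000
    force_tolerance: float = 0.5  # kJ/mol/nm


@dataclass
class Profile1D:
    """1D projection F(λ) of a path over cumulative arc length λ (nm)."""

    lam: np.ndarray  # dense, strictly increasing from 0
    free_energy: np.ndarray
    markers: list = field(default_factory=list)  # (kind, dense index), λ-ordered

    @property
    def valley_indices(self):
        return [i for k, i in self.markers if k == "valley"]

    @property
    def peak_indices(self):
        return [i for k, i in self.markers if k == "peak"]

    def state_lambda(self, state):
        return float(self.lam[self.valley_indices[state]])

    def state_energy(self, state):
        return float(self.free_energy[self.valley_indices[state]])


def _as_point(x):
    if isinstance(x, Minimum):
        return np.asarray(x.location, dtype=float)
    return np.atleast_1d(np.asarray(x, dtype=float))


def _tangents(r, e):
    """Improved NEB tangents (upwinded by neighbor energies)."""
    n = len(r)
    tau = np.zeros_like(r)
    for i in range(1, n - 1):
        dplus = r[i + 1] - r[i]
        dminus = r[i] - r[i - 1]
        if e[i + 1] > e[i] > e[i - 1]:
            t = dplus
        elif e[i + 1] < e[i] < e[i - 1]:
            t = dminus
        else:
            dmax = max(abs(e[i + 1] - e[i]), abs(e[i - 1] - e[i]))
            dmin = min(abs(e[i + 1] - e[i]), abs(e[i - 1] - e[i]))
            if e[i + 1] > e[i - 1]:
                t = dplus * dmax + dminus * dmin
            else:
                t = dplus * dmin + dminus * dmax
        norm = np.linalg.norm(t)
        tau[i] = t / norm if norm > 0 else 0.0
    return tau


def neb(surface, start, end, n_images=32, spring_constant=500.0,
        max_iterations=5000, force_tolerance=0.5, seed_nodes=None,
        endpoints=(None, None)) -> Path:
    """Relax a nudged-elastic-band path between two minima on a surface.

    ``surface`` needs ``value``/``gradient``/``in_domain`` (an analytic
    surface or a PMF interpolant).  The band starts from the straight
    segment (or ``seed_nodes``); images move by adaptive steepest descent on
    the projected NEB force; the highest interior image climbs (spring force
    replaced by inverted parallel force) during the final 25% of the
    iteration budget.  ``converged`` requires the residual below
    ``force_tolerance`` (kJ/mol/nm) in the climbing phase.

    Raises :class:`MaskedRegionError` if the band cannot stay inside the
    sampled region.
    """
    a, b = _as_point(start), _as_point(end)
    if np.allclose(a, b, atol=1e-12):
        raise ValueError("start and end minima coincide")
    if seed_nodes is None:
        frac = np.linspace(0.0, 1.0, n_images)[:, None]
        r = a[None, :] * (1 - frac) + b[None, :] * frac
        try:
            surface.value(r)
        except MaskedRegionError:
            r = _masked_seed(surface, a, b, n_images)
    else:
        r = _resample_polyline(np.asarray(seed_nodes, dtype=float), n_images)
        r[0], r[-1] = a, b

    lo = np.array([d[0] for d in surface.domain])
    hi = np.array([d[1] for d in surface.domain])
    max_disp = 0.02  # nm per image per iteration
    climb_start = int(np.ceil(0.75 * max_iterations))
    residual = np.inf

    # FIRE minimizer on the projected NEB force
    dt0, dt_max = 2e-4, 4e-3
    dt, alpha = dt0, 0.1
    n_pos = 0
    v = np.zeros_like(r)

    for it in range(max_iterations):
        climbing = it >= climb_start
        e = surface.value(r)
        g = surface.gradient(r)
        tau = _tangents(r, e)
        gpar = np.sum(g * tau, axis=1, keepdims=True) * tau
        f_perp = -(g - gpar)
        seg = np.linalg.norm(np.diff(r, axis=0), axis=1)
        f_spring = np.zeros_like(r)
        f_spring[1:-1] = (spring_constant *
                          (seg[1:] - seg[:-1])[:, None] * tau[1:-1])
        force = f_perp + f_spring
        force[0] = force[-1] = 0.0
        ci = None
        if climbing:
            ci = 1 + int(np.argmax(e[1:-1]))
            force[ci] = -g[ci] + 2.0 * gpar[ci]

        res_perp = float(np.max(np.linalg.norm(f_perp[1:-1], axis=1))) \
            if len(r) > 2 else 0.0
        residual = res_perp
        if ci is not None:
            residual = max(res_perp, float(np.linalg.norm(force[ci])))
        if residual < force_tolerance:
            if climbing or len(r) <= 2:
                break
            climb_start = it + 1  # move on to the climbing phase
            v[:] = 0.0
            dt, alpha, n_pos = dt0, 0.1, 0
            continue

        power = float(np.sum(force * v))
        if power > 0:
            n_pos += 1
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
            fnorm = np.linalg.norm(force)
            vnorm = np.linalg.norm(v)
            if fnorm > 0:
                v = (1.0 - alpha) * v + alpha * (force / fnorm) * vnorm
        else:
            v[:] = 0.0
            dt, alpha, n_pos = max(dt * 0.5, 1e-6), 0.1, 0
        v = v + dt * force
        step = dt * v
        norms = np.linalg.norm(step, axis=1, keepdims=True)
        scale = np.where(norms > max_disp,
                         max_disp / np.maximum(norms, 1e-300), 1.0)
        r = np.clip(r + step * scale, lo, hi)

    e = surface.value(r)
    return Path(nodes=r, energies=np.asarray(e, dtype=float),
                endpoints=tuple(endpoints),
                converged=bool(residual < force_tolerance),
                max_force_residual=float(residual))


def _resample_polyline(nodes, n):
    lam = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(nodes, axis=0), axis=1))])
    keep = np.concatenate([[True], np.diff(lam) > 1e-12])
    nodes, lam = nodes[keep], lam[keep]
    t = np.linspace(0, lam[-1], n)
    return np.stack([np.interp(t, lam, nodes[:, d])
                     for d in range(nodes.shape[1])], axis=-1)


def _masked_seed(surface, a, b, n_images):
    """Seed a band through sampled low-energy grid cells (minimax route)."""
    if not isinstance(surface, PMFInterpolant):
        raise MaskedRegionError("straight-line seed leaves the surface domain")
    pmf = surface.pmf
    centers = pmf.centers
    f = np.where(pmf.sampled, pmf.free_energy, np.inf)
    # restrict to bins safe for spline queries
    f = np.where(surface._safe, f, np.inf)
    shape = f.shape

    def cell(z):
        return tuple(int(np.argmin(np.abs(centers[d] - z[d])))
                     for d in range(len(shape)))

    ca, cb = cell(a), cell(b)
    if not (np.isfinite(f[ca]) and np.isfinite(f[cb])):
        raise MaskedRegionError("path endpoints lie in the unsampled region")
    best = np.full(shape, np.inf)
    best[ca] = f[ca]
    prev = {}
    heap = [(f[ca], ca)]
    moves = [m for m in itertools.product((-1, 0, 1), repeat=len(shape))
             if any(m)]
    while heap:
        cost, c = heapq.heappop(heap)
        if c == cb:
            break
        if cost > best[c]:
            continue
        for m in moves:
            nb = tuple(np.add(c, m))
            if any(not 0 <= nb[d] < shape[d] for d in range(len(shape))):
                continue
            new = max(cost, f[nb])
            if new < best[nb]:
                best[nb] = new
                prev[nb] = c
                heapq.heappush(heap, (new, nb))
    if not np.isfinite(best[cb]):
        raise MaskedRegionError(
            "no sampled corridor connects the path endpoints")
    chain = [cb]
    while chain[-1] != ca:
        chain.append(prev[chain[-1]])
    chain.reverse()
    pts = np.array([[centers[d][c[d]] for d in range(len(shape))]
                    for c in chain])
    pts[0], pts[-1] = a, b
    return _resample_polyline(pts, n_images)


def grid_minimax_barrier(surface, a, b, n_grid=500, domain=None):
    """Minimax-path barrier between two points on a dense evaluation grid.

    Independent of NEB: the surface is tabulated on an ``n_grid`` per-axis
    grid and the smallest energy level at which the two points become
    8-connected in the sublevel set {F <= level} is found by bisection over
    the sorted cell energies.  Returns that level (the max energy along the
    best minimax path) in kJ/mol.
    """
    a, b = _as_point(a), _as_point(b)
    if domain is None:
        domain = surface.domain
    axes = [np.linspace(lo, hi, n_grid) for lo, hi in domain]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    f = surface.value(mesh.reshape(-1, len(axes))).reshape(mesh.shape[:-1])
    ia = tuple(int(np.argmin(np.abs(axes[d] - a[d]))) for d in range(len(axes)))
    ib = tuple(int(np.argmin(np.abs(axes[d] - b[d]))) for d in range(len(axes)))
    levels = np.unique(f.ravel())
    structure = np.ones((3,) * f.ndim, dtype=bool)

    def connected(level):
        lab, _ = ndimage.label(f <= level, structure=structure)
        return lab[ia] != 0 and lab[ia] == lab[ib]

    lo_i, hi_i = 0, len(levels) - 1
    if not connected(levels[hi_i]):
        raise ConnectivityError("points not connected on the evaluation grid")
    while lo_i < hi_i:
        mid = (lo_i + hi_i) // 2
        if connected(levels[mid]):
            hi_i = mid
        else:
            lo_i = mid + 1
    return float(levels[hi_i])


def build_path_graph(surface, minima, neb_settings=None, cutoff=None,
                     exclusion_radius=0.15):
    """NEB snippets between all nearby minima pairs, as an undirected graph.

    Pairs farther apart than ``cutoff`` (default: 3x the median
    nearest-neighbor distance) are skipped; snippets that fail to converge,
    leave the sampled region, or relax through a third minimum's basin
    (interior node within ``exclusion_radius`` nm of another minimum — such
    a snippet merely duplicates a multi-hop route) are excluded with a
    logged reason.  Edge attributes: ``path`` (the snippet) and ``barrier``
    (max snippet energy minus the lower endpoint energy).
    """
    if len(minima) < 2:
        raise ValueError("need at least two minima")
    settings = neb_settings or NebSettings()
    locs = np.stack([m.location for m in minima])
    dists = np.linalg.norm(locs[:, None] - locs[None, :], axis=2)
    np.fill_diagonal(dists, np.inf)
    if cutoff is None:
        cutoff = 3.0 * float(np.median(dists.min(axis=1)))

    graph = nx.Graph(surface=surface, neb_settings=settings)
    for m in minima:
        graph.add_node(m.index, minimum=m)
    for i, j in itertools.combinations(range(len(minima)), 2):
        if dists[i, j] >= cutoff:
            continue
        mi, mj = minima[i], minima[j]
        try:
            path = neb(surface, mi, mj, n_images=settings.n_images,
                       spring_constant=settings.spring_constant,
                       max_iterations=settings.max_iterations,
                       force_tolerance=settings.force_tolerance,
                       endpoints=(mi.index, mj.index))
        except MaskedRegionError as err:
            logger.info("snippet %d-%d excluded: %s", mi.index, mj.index, err)
            continue
        if not path.converged:
            logger.info("snippet %d-%d excluded: NEB residual %.3g above "
                        "tolerance", mi.index, mj.index,
                        path.max_force_residual)
            continue
        others = [k for k in range(len(minima)) if k not in (i, j)]
        if others and len(path.nodes) > 2:
            d_other = np.linalg.norm(
                path.nodes[1:-1, None, :] - locs[others][None, :, :], axis=2)
            if d_other.min() < exclusion_radius:
                k = others[int(np.unravel_index(d_other.argmin(),
                                                d_other.shape)[1])]
                logger.info("snippet %d-%d excluded: passes through the "
                            "basin of minimum %d", mi.index, mj.index,
                            minima[k].index)
                continue
        graph.add_edge(mi.index, mj.index, path=path,
                       barrier=path.barrier_height)
    return graph


def _join_snippets(graph, node_route):
    pieces = []
    for u, v in zip(node_route[:-1], node_route[1:]):
        p = graph.edges[u, v]["path"]
        nodes = p.nodes
        if p.endpoints[0] == v:  # snippet stored in the opposite direction
            nodes = nodes[::-1]
        pieces.append(nodes if not pieces else nodes[1:])
    return np.concatenate(pieces, axis=0)


def enumerate_paths(graph, start, end, max_paths=10, relax=True):
    """Joined start-to-end paths through the snippet graph, ranked.

    Simple paths (no repeated minima) are enumerated; each is joined from
    its snippets and, when ``relax`` is set, re-relaxed as a whole band.
    Ranking: lowest highest-energy first, ties broken by path action
    (integral of F over arc length).  The first entry is the MFEP.
    """
    s = start.index if isinstance(start, Minimum) else int(start)
    t = end.index if isinstance(end, Minimum) else int(end)
    if s not in graph or t not in graph:
        raise ConnectivityError("start or end minimum not in the graph")
    surface = graph.graph["surface"]
    settings = graph.graph["neb_settings"]
    routes = list(nx.all_simple_paths(graph, s, t))
    if not routes:
        raise ConnectivityError(
            f"no route connects minima {s} and {t} in the snippet graph")

    paths = []
    for route in routes:
        nodes = _join_snippets(graph, route)
        n_total = max(settings.n_images,
                      settings.n_images * (len(route) - 1) // 2)
        if relax and len(route) > 2:
            p = neb(surface, nodes[0], nodes[-1], n_images=n_total,
                    spring_constant=settings.spring_constant,
                    max_iterations=settings.max_iterations,
                    force_tolerance=settings.force_tolerance,
                    seed_nodes=nodes, endpoints=(s, t))
            if not p.converged:
                # every snippet converged individually; fall back to their
                # concatenation rather than discarding the route
                logger.info("joint re-relaxation of route %s did not "
                            "converge (residual %.3g); using the joined "
                            "snippets", route, p.max_force_residual)
                p = None
        else:
            p = graph.edges[route[0], route[1]]["path"] \
                if len(route) == 2 else None
            if p is not None and p.endpoints[0] == route[1]:
                p = Path(nodes=p.nodes[::-1], energies=p.energies[::-1],
                         endpoints=(s, t), converged=p.converged,
                         max_force_residual=p.max_force_residual)
        if p is None:
            nodes = _resample_polyline(nodes, n_total)
            residual = max(graph.edges[u, v]["path"].max_force_residual
                           for u, v in zip(route[:-1], route[1:]))
            p = Path(nodes=nodes, energies=np.asarray(surface.value(nodes)),
                     endpoints=(s, t), converged=True,
                     max_force_residual=residual)
        paths.append(p)

    # primary key quantized to 0.1 kJ/mol: maxima closer than typical
    # histogram noise count as ties and fall through to the action
    paths.sort(key=lambda p: (round(float(p.energies.max()), 1),
                              round(p.action, 9)))
    return paths[:max_paths]


def project_1d(path: Path, n_dense=1024, min_prominence=0.5) -> Profile1D:
    """Project a converged path onto arc length λ and mark its extrema.

    F(λ) is re-interpolated with a cubic spline through the node energies and
    evaluated on ``n_dense`` points.  Interior extrema come from derivative
    sign changes; wiggles with prominence below ``min_prominence`` (kJ/mol)
    are removed; endpoints count as valleys.  Markers must alternate
    valley/peak or a :class:`ProfileError` is raised.
    """
    if not path.converged:
        raise ValueError("refusing to project an unconverged path")
    lam_nodes = path.arc_length
    keep = np.concatenate([[True], np.diff(lam_nodes) > 1e-12])
    spline = CubicSpline(lam_nodes[keep], path.energies[keep])
    lam = np.linspace(0.0, float(lam_nodes[-1]), n_dense)
    f = spline(lam)
    f[0], f[-1] = path.energies[0], path.energies[-1]  # exact endpoints

    df = np.diff(f)
    markers = [("valley", 0)]
    for i in range(1, n_dense - 1):
        if df[i - 1] < 0 <= df[i]:
            markers.append(("valley", i))
        elif df[i - 1] > 0 >= df[i]:
            markers.append(("peak", i))
    markers.append(("valley", n_dense - 1))

    def merge_same_kind(mk):
        out = []
        for kind, i in mk:
            if out and out[-1][0] == kind:
                j = out[-1][1]
                if kind == "valley":
                    i = i if f[i] < f[j] else j
                else:
                    i = i if f[i] > f[j] else j
                out[-1] = (kind, i)
            else:
                out.append((kind, i))
        return out

    markers = merge_same_kind(markers)
    # prominence filtering: drop the shallowest adjacent pair, re-merge, repeat
    while len(markers) > 2:
        amps = [abs(f[markers[k + 1][1]] - f[markers[k][1]])
                for k in range(len(markers) - 1)]
        k_min = int(np.argmin(amps))
        if amps[k_min] >= min_prominence:
            break
        # removing an endpoint marker is not allowed; drop the interior one(s)
        drop = {k_min, k_min + 1} - {0, len(markers) - 1}
        if not drop:
            break
        markers = [m for k, m in enumerate(markers) if k not in drop]
        markers = merge_same_kind(markers)

    kinds = [k for k, _ in markers]
    if any(a == b for a, b in zip(kinds, kinds[1:])) or kinds[0] != "valley" \
            or kinds[-1] != "valley":
        raise ProfileError(
            f"extrema do not alternate after noise filtering: {kinds}")
    return Profile1D(lam=lam, free_energy=f, markers=markers)


def barrier(profile: Profile1D, from_state: int, to_state: int) -> float:
    """Directed barrier ΔF‡ between two valley states of a profile (kJ/mol).

    Forward (``to_state`` after ``from_state``): the maximum of F on the λ
    segment between them minus F(from_state).  When ``to_state`` precedes
    ``from_state`` the profile is continued cyclically *without* energy
    shift — in a finite simulation box the first and last states are
    distinct configurations of one system, so re-entry over the periodic
    boundary pays back the full net drop of the profile on top of the
    maximum preceding the target state.
    """
    valleys = profile.valley_indices
    n = len(valleys)
    if not (0 <= from_state < n and 0 <= to_state < n):
        raise LookupError(
            f"states ({from_state}, {to_state}) not on the profile "
            f"({n} valleys)")
    if from_state == to_state:
        return 0.0
    i, j = valleys[from_state], valleys[to_state]
    f = profile.free_energy
    if to_state > from_state:
        segment = f[i:j + 1]
    else:
        segment = np.concatenate([f[i:], f[:j + 1]])
    return float(segment.max() - f[i])
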