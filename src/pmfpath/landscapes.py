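"""Analytic free-energy landscapes and biased sampling from them.

The module builds Gaussian-mixture free-energy surfaces F(z) over one or two
collective variables (CVs, in nm) with *exactly known* stationary points, plans
umbrella-sampling window grids over them, and draws Boltzmann-distributed
samples from harmonically biased windows by Metropolis Monte Carlo.  The
surfaces stand in for MD-derived umbrella data: the statistics are right
(harmonic bias ``U = 1/2 k (z - z0)^2`` per CV, k in kJ/mol/nm², thermal
energy at 310 K), while every minimum, saddle and barrier height is available
in closed form as ground truth for the downstream unbiasing, path-finding and
rate stages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constants import DEFAULT_TEMPERATURE, kt
from .errors import ConfigurationError, GenerationError

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianTerm",
    "StationaryPoint",
    "SyntheticSurface",
    "UmbrellaWindow",
    "WindowPlan",
    "make_surface",
    "plan_windows",
    "plan_windows_adaptive",
    "sample_window",
    "sample_windows",
    "double_well_1d",
    "two_well_2d",
    "conduction_preset",
]


@dataclass(frozen=True)
class GaussianTerm:
    """One Gaussian component of a surface: ``a * exp(-sum (z-c)^2 / 2w^2)``.

    Negative amplitude digs a well, positive amplitude raises a bump.
    """

    amplitude: float  # kJ/mol
    center: tuple[float, ...]  # nm per CV
    widths: tuple[float, ...]  # nm per CV (standard-deviation-like)

    def __post_init__(self):
        if len(self.center) != len(self.widths):
            raise ConfigurationError("center and widths must have equal length")
        if any(w <= 0 for w in self.widths):
            raise ConfigurationError("Gaussian widths must be positive")


@dataclass(frozen=True)
class StationaryPoint:
    """A known stationary point of the analytic surface."""

    location: tuple[float, ...]  # nm
    energy: float  # kJ/mol, after normalization (global min = 0)
    kind: str  # "min" or "saddle"


class SyntheticSurface:
    """Gaussian-mixture free-energy surface with analytic derivatives.

    Energies are normalized so the global minimum is exactly 0 kJ/mol; the
    constant ``offset`` absorbing that shift is stored so ``value`` stays an
    exact closed form.
    """

    def __init__(self, terms, domain, baseline=0.0, offset=0.0, ground_truth=()):
        self.terms = tuple(terms)
        self.domain = tuple((float(lo), float(hi)) for lo, hi in domain)
        self.baseline = float(baseline)
        self.offset = float(offset)
        self.ground_truth = tuple(ground_truth)
        if not self.terms:
            raise ConfigurationError("surface needs at least one Gaussian term")
        self.ndim = len(self.terms[0].center)
        if len(self.domain) != self.ndim:
            raise ConfigurationError("domain dimensionality mismatch")
        for lo, hi in self.domain:
            if not hi > lo:
                raise ConfigurationError(f"degenerate domain interval ({lo}, {hi})")
        # precompute term arrays for vectorized evaluation
        self._amp = np.array([t.amplitude for t in self.terms])
        self._ctr = np.array([t.center for t in self.terms])  # (T, d)
        self._inv2w2 = 1.0 / (2.0 * np.array([t.widths for t in self.terms]) ** 2)

    # -- evaluation ----------------------------------------------------------

    def _exponents(self, z):
        # z: (..., d) -> (..., T)
        dz = z[..., None, :] - self._ctr  # (..., T, d)
        return np.exp(-np.sum(dz * dz * self._inv2w2, axis=-1))

    def value(self, z):
        """F(z) in kJ/mol; ``z`` is (..., ndim) or (ndim,)."""
        z = np.asarray(z, dtype=float)
        scalar = z.ndim == 1
        if scalar:
            z = z[None, :]
        v = self.baseline + self.offset + self._exponents(z) @ self._amp
        return v[0] if scalar else v

    def gradient(self, z):
        """dF/dz, shape like ``z``."""
        z = np.asarray(z, dtype=float)
        scalar = z.ndim == 1
        if scalar:
            z = z[None, :]
        dz = z[:, None, :] - self._ctr
        e = np.exp(-np.sum(dz * dz * self._inv2w2, axis=-1))  # (N, T)
        g = np.einsum("t,nt,ntd->nd", self._amp, e, -2.0 * self._inv2w2 * dz)
        return g[0] if scalar else g

    def hessian(self, z):
        """d²F/dz² at a single point, shape (ndim, ndim)."""
        z = np.asarray(z, dtype=float)
        dz = z[None, :] - self._ctr  # (T, d)
        e = np.exp(-np.sum(dz * dz * self._inv2w2, axis=-1))  # (T,)
        u = -2.0 * self._inv2w2 * dz  # (T, d)  d(log term)/dz
        h = np.einsum("t,t,td,te->de", self._amp, e, u, u)
        h -= np.einsum("t,t,td,de->de", self._amp, e, 2.0 * self._inv2w2,
                       np.eye(self.ndim))
        return h

    def in_domain(self, z):
        z = np.atleast_2d(np.asarray(z, dtype=float))
        lo = np.array([d[0] for d in self.domain])
        hi = np.array([d[1] for d in self.domain])
        return np.all((z >= lo) & (z <= hi), axis=1)

    # -- ground-truth accessors ----------------------------------------------

    @property
    def minima(self):
        return [p for p in self.ground_truth if p.kind == "min"]

    @property
    def saddles(self):
        return [p for p in self.ground_truth if p.kind == "saddle"]


def _locate_stationary_points(surface: SyntheticSurface, n_grid=12):
    """Multi-start search for minima and index-1 saddles on the analytic form."""
    lo = np.array([d[0] for d in surface.domain])
    hi = np.array([d[1] for d in surface.domain])
    d = surface.ndim
    # starts: term centers, pairwise midpoints, and a coarse grid
    starts = [np.asarray(t.center, float) for t in surface.terms]
    ctrs = list(starts)
    for i in range(len(ctrs)):
        for j in range(i + 1, len(ctrs)):
            starts.append(0.5 * (ctrs[i] + ctrs[j]))
    axes = [np.linspace(lo[k], hi[k], n_grid) for k in range(d)]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d)
    starts.extend(mesh)

    found = []  # (location, kind)

    def _register(z):
        if not surface.in_domain(z)[0]:
            return
        # discard points glued to the domain edge (artifacts of bounded opts)
        if np.any(z - lo < 1e-6) or np.any(hi - z < 1e-6):
            return
        for zk, _ in found:
            if np.linalg.norm(zk - z) < 2e-3:
                return
        hess = surface.hessian(z)
        eig = np.linalg.eigvalsh(np.atleast_2d(hess))
        # |eig| threshold discards numerically flat tail artifacts far from wells
        if np.all(eig > 1e-5):
            kind = "min"
        elif d > 1 and eig[0] < -1e-5 and np.all(eig[1:] > 1e-5):
            kind = "saddle"
        elif d == 1 and eig[0] < -1e-5:
            kind = "saddle"  # 1D maximum separates basins
        else:
            return
        found.append((np.array(z), kind))

    for z0 in starts:
        z0 = np.clip(z0, lo, hi)
        res = optimize.minimize(
            lambda z: surface.value(z), z0, jac=lambda z: surface.gradient(z),
            method="L-BFGS-B", bounds=list(zip(lo, hi)),
            options={"gtol": 1e-12, "ftol": 1e-15},
        )
        if res.success or np.linalg.norm(surface.gradient(res.x)) < 1e-7:
            _register(res.x)
        # saddles: root of the gradient from the same start
        sol = optimize.root(
            lambda z: np.atleast_1d(surface.gradient(z)), z0, method="hybr",
            options={"xtol": 1e-12},
        )
        if sol.success and np.linalg.norm(surface.gradient(sol.x)) < 1e-8:
            _register(np.atleast_1d(sol.x))

    if not any(k == "min" for _, k in found):
        raise GenerationError("no stationary minimum found on the surface")
    return found


def make_surface(terms, domain, baseline=0.0) -> SyntheticSurface:
    """Build a normalized surface and locate its ground-truth stationary points.

    Parameters
    ----------
    terms : sequence of GaussianTerm (or (amplitude, center, widths) tuples)
    domain : per-CV (low, high) rectangle in nm
    baseline : constant background in kJ/mol

    The returned surface is shifted so its global minimum is exactly 0, and
    ``ground_truth`` lists every interior minimum and (in 2D) index-1 saddle.
    """
    terms = [t if isinstance(t, GaussianTerm) else GaussianTerm(*t) for t in terms]
    if not any(t.amplitude < 0 for t in terms):
        raise ConfigurationError("need at least one well (negative amplitude) term")
    raw = SyntheticSurface(terms, domain, baseline=baseline)
    points = _locate_stationary_points(raw)
    e_min = min(raw.value(z) for z, k in points if k == "min")
    surface = SyntheticSurface(terms, domain, baseline=baseline, offset=-e_min)
    gt = [
        StationaryPoint(tuple(z), float(surface.value(z)), k)
        for z, k in sorted(points, key=lambda p: float(raw.value(p[0])))
    ]
    return SyntheticSurface(terms, domain, baseline=baseline, offset=-e_min,
                            ground_truth=gt)


# -- presets -----------------------------------------------------------------

def double_well_1d(depth=33.5, centers=(0.25, 1.25), width=0.28,
                   domain=((-0.35, 1.85),)) -> SyntheticSurface:
    """1D double well spanning the 23-window umbrella range.

    Defaults give an inter-well barrier of ~20 kJ/mol; the exact value is on
    ``surface.ground_truth`` (saddle energy, global minimum at 0).
    """
    terms = [GaussianTerm(-depth, (c,), (width,)) for c in centers]
    return make_surface(terms, domain)


def two_well_2d() -> SyntheticSurface:
    """Two Gaussian wells plus an off-axis bump; the MFEP bends around it."""
    terms = [
        GaussianTerm(-20.0, (-0.5, 0.0), (0.25, 0.25)),
        GaussianTerm(-20.0, (0.5, 0.0), (0.25, 0.25)),
        GaussianTerm(8.0, (0.0, 0.25), (0.20, 0.20)),
    ]
    return make_surface(terms, ((-1.1, 1.1), (-0.8, 0.8)))


def conduction_preset() -> SyntheticSurface:
    """Five wells emulating the staged two-CV ion-conduction landscape.

    Wells are laid out as a staircase in (z1, z2) within the umbrella
    boundaries (-0.35..1.85, -1.55..0.55) nm with saddle barriers in the
    10-25 kJ/mol range, mimicking sequential single-ion moves.
    """
    terms = [
        GaussianTerm(-30.0, (1.40, 0.20), (0.16, 0.16)),
        GaussianTerm(-26.0, (0.80, 0.10), (0.15, 0.15)),
        GaussianTerm(-24.0, (0.70, -0.60), (0.15, 0.15)),
        GaussianTerm(-28.0, (0.15, -0.75), (0.15, 0.15)),
        GaussianTerm(-34.0, (0.05, -1.35), (0.16, 0.16)),
    ]
    return make_surface(terms, ((-0.35, 1.85), (-1.55, 0.55)))


# -- window planning ---------------------------------------------------------

@dataclass(frozen=True)
class WindowPlan:
    """Regular grid of umbrella-window centers."""

    boundaries: tuple  # per-CV (low, high) nm
    spacing: float  # nm
    centers: np.ndarray = field(repr=False)  # (n_windows, ndim)

    @property
    def n_windows(self):
        return len(self.centers)


def _axis_centers(low, high, spacing):
    n = int(math.floor((high - low) / spacing + 1e-9)) + 1
    return low + spacing * np.arange(n)


def plan_windows(boundaries, spacing) -> WindowPlan:
    """Regular window grid with the given per-CV boundaries and spacing (nm).

    Both bounds are included when grid-aligned, matching a 0.1 nm umbrella
    interval tiling e.g. -0.35..1.85 nm with 23 centers.
    """
    boundaries = tuple((float(lo), float(hi)) for lo, hi in boundaries)
    spacing = float(spacing)
    if spacing <= 0:
        raise ConfigurationError("spacing must be positive")
    for lo, hi in boundaries:
        if not hi > lo:
            raise ConfigurationError(f"boundary ({lo}, {hi}) is not increasing")
        if spacing > hi - lo:
            raise ConfigurationError("spacing exceeds the boundary range")
    axes = [_axis_centers(lo, hi, spacing) for lo, hi in boundaries]
    centers = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    centers = centers.reshape(-1, len(boundaries))
    return WindowPlan(boundaries, spacing, centers)


def plan_windows_adaptive(surface: SyntheticSurface, start, energy_cutoff,
                          spacing) -> WindowPlan:
    """Breadth-first window planning below an energy cutoff.

    Starting from the grid center nearest ``start``, neighbors (4-neighborhood
    per CV) are added iff the *true* surface value at the candidate center is
    below ``energy_cutoff``.  This is a planning heuristic usable only when
    the surface can be evaluated directly (synthetic data); on real data the
    full regular grid applies.
    """
    full = plan_windows(surface.domain, spacing)
    axes = [_axis_centers(lo, hi, spacing) for lo, hi in surface.domain]
    shape = tuple(len(a) for a in axes)
    start = np.asarray(start, dtype=float)
    if not surface.in_domain(start)[0]:
        raise ConfigurationError("start lies outside the surface domain")
    idx0 = tuple(int(np.argmin(np.abs(a - s))) for a, s in zip(axes, start))
    z0 = np.array([axes[k][idx0[k]] for k in range(surface.ndim)])
    if surface.value(z0) >= energy_cutoff:
        raise ConfigurationError(
            f"energy cutoff {energy_cutoff} is below F(start) = {surface.value(z0):.3f}")
    visited = {idx0}
    frontier = [idx0]
    while frontier:
        nxt = []
        for idx in frontier:
            for k in range(surface.ndim):
                for dstep in (-1, 1):
                    nb = list(idx)
                    nb[k] += dstep
                    nb = tuple(nb)
                    if nb in visited or not (0 <= nb[k] < shape[k]):
                        continue
                    z = np.array([axes[j][nb[j]] for j in range(surface.ndim)])
                    if surface.value(z) < energy_cutoff:
                        visited.add(nb)
                        nxt.append(nb)
        frontier = nxt
    order = sorted(visited)
    centers = np.array([[axes[j][i[j]] for j in range(surface.ndim)] for i in order])
    return WindowPlan(tuple(surface.domain), float(spacing), centers)


# -- biased sampling ---------------------------------------------------------

@dataclass
class UmbrellaWindow:
    """One biased run: bias centers, force constant, and CV samples."""

    centers: np.ndarray  # (ndim,) nm
    force_constant: np.ndarray  # (ndim,) kJ/mol/nm², per CV
    samples: np.ndarray  # (n_samples, ndim) nm
    seed: int | None = None

    def __post_init__(self):
        self.centers = np.atleast_1d(np.asarray(self.centers, dtype=float))
        self.force_constant = np.broadcast_to(
            np.asarray(self.force_constant, dtype=float), self.centers.shape
        ).copy()
        if np.any(self.force_constant < 0):
            raise ConfigurationError("force constant must be >= 0")
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))

    @property
    def n_samples(self):
        return len(self.samples)

    @property
    def ndim(self):
        return len(self.centers)

    def bias_energy(self, z):
        """U_bias(z) = sum_d 1/2 k_d (z_d - z0_d)^2, kJ/mol."""
        z = np.asarray(z, dtype=float)
        dz = z - self.centers
        return 0.5 * np.sum(self.force_constant * dz * dz, axis=-1)


def sample_windows(surface, centers, force_constant=1000.0, n_samples=5000,
                   burn_in=None, step_size=0.05, temperature=DEFAULT_TEMPERATURE,
                   seed=0):
    """Metropolis-sample all umbrella windows of a plan in one vectorized sweep.

    Each window runs its own Markov chain targeting
    ``exp(-(F(z) + U_bias(z)) / kBT)`` with a Gaussian random-walk proposal of
    scale ``step_size`` (nm).  Chains start at the window center; ``burn_in``
    samples (default 10% of ``n_samples``) are discarded.  Window ``i`` draws
    from its own generator seeded ``seed + i``, so any subset of windows is
    bit-identical whether sampled alone or in the batch.

    Returns a list of :class:`UmbrellaWindow`.
    """
    if n_samples <= 0:
        raise ConfigurationError("n_samples must be positive")
    if step_size <= 0:
        raise ConfigurationError("step_size must be positive")
    if isinstance(centers, WindowPlan):
        centers = centers.centers
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n_win, d = centers.shape
    if d != surface.ndim:
        raise ConfigurationError("window centers dimensionality mismatch")
    if burn_in is None:
        burn_in = max(1, n_samples // 10)
    kvec = np.broadcast_to(np.asarray(force_constant, dtype=float), (d,))
    beta = 1.0 / kt(temperature)
    steps = n_samples + burn_in

    # per-window pregenerated streams keep chains independently reproducible
    props = np.empty((steps, n_win, d))
    unif = np.empty((steps, n_win))
    for i in range(n_win):
        rng = np.random.default_rng(None if seed is None else seed + i)
        props[:, i, :] = rng.normal(0.0, step_size, size=(steps, d))
        unif[:, i] = rng.random(steps)

    lo = np.array([b[0] for b in surface.domain])
    hi = np.array([b[1] for b in surface.domain])
    z = centers.copy()
    np.clip(z, lo, hi, out=z)

    def total_energy(pts):
        dz = pts - centers
        return surface.value(pts) + 0.5 * np.sum(kvec * dz * dz, axis=-1)

    e = total_energy(z)
    out = np.empty((n_samples, n_win, d))
    accepted = np.zeros(n_win)
    for t in range(steps):
        znew = z + props[t]
        inside = np.all((znew >= lo) & (znew <= hi), axis=1)
        enew = np.where(inside, total_energy(np.clip(znew, lo, hi)), np.inf)
        acc = unif[t] < np.exp(np.minimum(0.0, -beta * (enew - e)))
        acc &= inside
        z = np.where(acc[:, None], znew, z)
        e = np.where(acc, enew, e)
        if t >= burn_in:
            out[t - burn_in] = z
            accepted += acc

    rate = accepted / n_samples
    for i in range(n_win):
        if rate[i] < 0.01:
            logger.warning(
                "window %d at %s: acceptance rate %.4f < 1%% "
                "(step_size %.3g nm likely too large)", i, centers[i], rate[i],
                step_size)
    return [
        UmbrellaWindow(centers[i], kvec, out[:, i, :],
                       seed=None if seed is None else seed + i)
        for i in range(n_win)
    ]


def sample_window(surface, center, force_constant=1000.0, n_samples=5000,
                  burn_in=None, step_size=0.05,
                  temperature=DEFAULT_TEMPERATURE, seed=0) -> UmbrellaWindow:
    """Sample a single umbrella window (see :func:`sample_windows`).

    ``seed`` here is the window's own seed: ``sample_window(..., seed=s)``
    equals window 0 of a batch rooted at ``s``.
    """
    (window,) = sample_windows(surface, np.atleast_2d(center), force_constant,
                               n_samples, burn_in, step_size, temperature, seed)
    return window
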