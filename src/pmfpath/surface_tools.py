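"""PMF-grid post-processing: interpolation, minima, basin assignment.

A WHAM grid is a noisy, possibly partially sampled tabulation of F.  This
module turns it into a smooth surface (bicubic spline with analytic
gradients), locates its local minima (grid detection refined by descent on
the interpolant), and clusters CV samples into basins of attraction — the
step that picks representative configurations for each free-energy state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.interpolate import CubicSpline, RectBivariateSpline

from .errors import MaskedRegionError
from .wham import PMFGrid

logger = logging.getLogger(__name__)

__all__ = ["Minimum", "BasinAssignment", "PMFInterpolant", "interpolate",
           "find_minima", "assign_basins", "representative_snapshot"]

#: marker index for samples left unassigned (above the energy ceiling)
UNASSIGNED = -1


@dataclass
class Minimum:
    """A local free-energy minimum on the interpolated PMF."""

    location: np.ndarray  # (ndim,) nm
    energy: float  # kJ/mol
    index: int = 0
    label: str | None = None  # user-assignable state name, e.g. "[p23, s4]"

    def __post_init__(self):
        self.location = np.atleast_1d(np.asarray(self.location, dtype=float))


@dataclass
class BasinAssignment:
    """Per-sample basin membership; UNASSIGNED marks samples above the ceiling."""

    labels: np.ndarray  # (n_samples,) int, minimum index or UNASSIGNED
    minima: list = field(default_factory=list)

    def members(self, minimum_index):
        return np.nonzero(self.labels == minimum_index)[0]


class PMFInterpolant:
    """Continuous value/gradient view of a PMF grid (bicubic, or cubic in 1D).

    Unsampled bins are excluded: queries whose 4x4 spline support touches a
    masked bin raise :class:`MaskedRegionError`.  The spline itself is fitted
    on the grid with masked bins filled by a high plateau; those values are
    never returned because of the support check.
    """

    def __init__(self, pmf: PMFGrid, smoothing=0.0):
        self.pmf = pmf
        self.ndim = pmf.ndim
        if smoothing == "auto":
            # expected total squared statistical error of -kT ln(n_b),
            # per-bin variance ~ (kT)^2 / n_b; the factor 3 accounts for
            # the spatial correlation of WHAM errors (shared window
            # offsets), which makes the independent-error chi^2 target an
            # underestimate
            from .constants import kt as _kt
            kbt = _kt(pmf.temperature)
            n_b = pmf.counts[pmf.sampled]
            smoothing = 3.0 * float(np.sum(kbt ** 2 / np.maximum(n_b, 1)))
        self.smoothing = float(smoothing)
        centers = pmf.centers
        f = pmf.free_energy.copy()
        self._mask = ~pmf.sampled
        if self._mask.any():
            fill = np.nanmax(f) + 50.0
            f[self._mask] = fill
            # safe where a 4x4 neighborhood contains no masked bin
            self._safe = ~ndimage.maximum_filter(
                self._mask.astype(np.uint8), size=4, mode="constant", cval=1
            ).astype(bool)
        else:
            self._safe = np.ones(f.shape, dtype=bool)
        self._lo = np.array([c[0] for c in centers])
        self._hi = np.array([c[-1] for c in centers])
        self._centers = centers
        if self.ndim == 2:
            self._spline = RectBivariateSpline(centers[0], centers[1], f,
                                               kx=3, ky=3, s=self.smoothing)
        elif self.ndim == 1:
            if self.smoothing:
                from scipy.interpolate import UnivariateSpline
                self._spline = UnivariateSpline(centers[0], f, k=3,
                                                s=self.smoothing)
            else:
                self._spline = CubicSpline(centers[0], f)
        else:
            raise ValueError("only 1D and 2D PMF grids are supported")

    @property
    def domain(self):
        return tuple((float(lo), float(hi))
                     for lo, hi in zip(self._lo, self._hi))

    def _check(self, z):
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if np.any(z < self._lo) or np.any(z > self._hi):
            raise MaskedRegionError(
                "query outside the interior bin-center region of the grid")
        if not self._safe.all():
            idx = tuple(
                np.clip(np.searchsorted(self._centers[d], z[:, d]) - 1,
                        0, len(self._centers[d]) - 1)
                for d in range(self.ndim))
            if not self._safe[idx].all():
                raise MaskedRegionError(
                    "query in or adjacent to an unsampled region of the PMF")
        return z

    def value(self, z):
        z = np.asarray(z, dtype=float)
        scalar = z.ndim == 1
        pts = self._check(z)
        if self.ndim == 2:
            v = self._spline(pts[:, 0], pts[:, 1], grid=False)
        else:
            v = self._spline(pts[:, 0])
        return float(v[0]) if scalar else v

    def gradient(self, z):
        z = np.asarray(z, dtype=float)
        scalar = z.ndim == 1
        pts = self._check(z)
        if self.ndim == 2:
            g = np.stack([self._spline(pts[:, 0], pts[:, 1], dx=1, grid=False),
                          self._spline(pts[:, 0], pts[:, 1], dy=1, grid=False)],
                         axis=-1)
        else:
            g = self._spline(pts[:, 0], 1)[:, None]
        return g[0] if scalar else g

    def in_domain(self, z):
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return np.all((z >= self._lo) & (z <= self._hi), axis=1)


def interpolate(pmf: PMFGrid, smoothing=0.0) -> PMFInterpolant:
    """Bicubic interpolant of a PMF grid with analytic gradient.

    ``smoothing`` > 0 fits a least-squares smoothing spline instead of the
    exact interpolant (FITPACK ``s`` parameter: target sum of squared
    residuals in (kJ/mol)²).  Histogram-estimated PMFs carry per-bin
    statistical noise whose spline gradients dwarf the physical ones; for
    path optimization choose ``s ≈ n_bins_total · σ_bin²``.  With the
    default 0 the spline reproduces grid values exactly.
    """
    return PMFInterpolant(pmf, smoothing=smoothing)


def _persistent_minima(f, threshold):
    """Bin indices of local minima with topological persistence >= threshold.

    Bins are flooded in ascending order of value with 8-connectivity
    union-find; when two basins meet, the shallower one dies at the meeting
    level and survives only if (death - birth) >= threshold.  The global
    minimum always survives.
    """
    shape = f.shape
    flat = f.ravel()
    order = np.argsort(flat, kind="stable")
    order = order[np.isfinite(flat[order])]
    parent = {}
    birth = {}  # root -> (birth value, birth flat index)
    persistent = set()
    moves = [m for m in np.ndindex(*(3,) * f.ndim)
             if any(d != 1 for d in m)]

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for fi in order:
        idx = np.unravel_index(fi, shape)
        level = flat[fi]
        roots = set()
        for m in moves:
            nb = tuple(i + d - 1 for i, d in zip(idx, m))
            if any(not 0 <= nb[d] < shape[d] for d in range(len(shape))):
                continue
            nfi = int(np.ravel_multi_index(nb, shape))
            if nfi in parent:
                roots.add(find(nfi))
        if not roots:
            parent[fi] = fi
            birth[fi] = (level, fi)
            continue
        roots = sorted(roots, key=lambda r: birth[r][0])
        winner = roots[0]
        parent[fi] = winner
        for r in roots[1:]:
            bval, bidx = birth[r]
            if level - bval >= threshold:
                persistent.add(bidx)
            parent[r] = winner
    live_roots = {find(r) for r in birth if parent.get(r) is not None}
    for r in {find(fi) for fi in order[:1]} | live_roots:
        persistent.add(birth[r][1])
    return [np.unravel_index(i, shape) for i in sorted(persistent)]


def find_minima(pmf, min_separation=0.1, max_energy=None,
                min_persistence=0.0):
    """Local minima of the PMF, refined on the interpolant.

    A bin is a candidate iff its value is strictly below all (8-)neighbors;
    with ``min_persistence`` > 0 (kJ/mol) candidates are instead the minima
    whose topological persistence — depth below the lowest saddle connecting
    them to a deeper basin — reaches that threshold, which suppresses
    histogram-noise dimples on estimated PMFs.  Candidates above
    ``max_energy`` (default: global minimum + 50 kJ/mol) are dropped; each
    candidate is refined by bounded gradient descent on the bicubic
    interpolant; minima closer than ``min_separation`` (nm) merge, keeping
    the lower.  Returned sorted by energy with ordinal indices.  Accepts a
    PMFGrid or an existing PMFInterpolant.
    """
    if isinstance(pmf, PMFInterpolant):
        interp = pmf
        pmf = interp.pmf
    else:
        interp = PMFInterpolant(pmf)
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    f = np.where(pmf.sampled, pmf.free_energy, np.inf)
    if max_energy is None:
        max_energy = float(np.min(f)) + 50.0
    if min_persistence > 0:
        cand = [idx for idx in _persistent_minima(f, min_persistence)
                if f[idx] <= max_energy]
    else:
        footprint = np.ones((3,) * pmf.ndim, dtype=bool)
        footprint[(1,) * pmf.ndim] = False
        neigh_min = ndimage.minimum_filter(f, footprint=footprint,
                                           mode="constant", cval=np.inf)
        cand = np.argwhere((f < neigh_min) & (f <= max_energy))

    centers = pmf.centers
    lo = np.array([c[0] for c in centers])
    hi = np.array([c[-1] for c in centers])
    eps = 1e-9
    refined = []
    for idx in cand:
        z0 = np.array([centers[d][i] for d, i in enumerate(idx)])
        try:
            z0_val = float(interp.value(z0))
        except MaskedRegionError:
            # rim artifact: an isolated sampled bin bordering the mask
            logger.info("dropping candidate minimum at %s next to the "
                        "unsampled region", np.round(z0, 4))
            continue
        try:
            res = optimize.minimize(
                interp.value, z0, jac=interp.gradient, method="L-BFGS-B",
                bounds=list(zip(lo + eps, hi - eps)),
                options={"gtol": 1e-10, "ftol": 1e-14})
            z, e = res.x, float(res.fun)
        except MaskedRegionError:
            z, e = z0, z0_val
        refined.append((z, e))

    refined.sort(key=lambda p: p[1])
    kept = []
    for z, e in refined:
        if e > max_energy:
            continue
        if all(np.linalg.norm(z - zk) >= min_separation for zk, _ in kept):
            kept.append((z, e))
    return [Minimum(location=z, energy=e, index=i)
            for i, (z, e) in enumerate(kept)]


def assign_basins(samples, minima, surface, max_energy=None, n_steps=50,
                  step=0.02) -> BasinAssignment:
    """Cluster CV samples into basins of attraction of the given minima.

    Each sample takes ``n_steps`` coarse normalized gradient-descent steps of
    ``step`` nm on ``surface`` (stopping early outside the surface domain)
    and is assigned to the nearest minimum of the endpoint — so a sample just
    past a saddle goes to the basin it would relax into, not the Euclidean
    nearest minimum.  Samples with F above ``max_energy`` stay UNASSIGNED.
    """
    if not minima:
        raise ValueError("need at least one minimum")
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    locs = np.stack([m.location for m in minima])
    z = samples.copy()
    active = np.ones(len(z), dtype=bool)
    for _ in range(n_steps):
        if not active.any():
            break
        try:
            g = surface.gradient(z[active])
        except MaskedRegionError:
            # fall back to per-sample stepping, freezing offending samples
            g = np.zeros((int(active.sum()), z.shape[1]))
            for j, zi in enumerate(z[active]):
                try:
                    g[j] = surface.gradient(zi)
                except MaskedRegionError:
                    pass
        norm = np.linalg.norm(g, axis=1, keepdims=True)
        move = np.where(norm > 1e-8, g / np.maximum(norm, 1e-30), 0.0) * step
        znew = z[active] - move
        ok = surface.in_domain(znew)
        upd = np.nonzero(active)[0][ok]
        z[upd] = znew[ok]
        still = np.linalg.norm(move, axis=1) > 1e-10
        active[np.nonzero(active)[0][~(ok & still)]] = False

    labels = np.argmin(
        np.linalg.norm(z[:, None, :] - locs[None, :, :], axis=2), axis=1)
    labels = np.array([minima[j].index for j in labels])
    if max_energy is not None:
        energies = np.array([_safe_value(surface, s) for s in samples])
        labels[energies > max_energy] = UNASSIGNED
    return BasinAssignment(labels=labels, minima=list(minima))


def _safe_value(surface, z):
    try:
        return float(surface.value(z))
    except MaskedRegionError:
        return np.inf


def representative_snapshot(assignment, minimum, samples):
    """Index of the basin member closest to the basin centroid (ties: lowest).

    ``minimum`` may be a Minimum or its integer index.
    """
    idx = minimum.index if isinstance(minimum, Minimum) else int(minimum)
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    members = assignment.members(idx)
    if len(members) == 0:
        raise LookupError(f"basin {idx} has no member samples")
    pts = samples[members]
    centroid = pts.mean(axis=0)
    return int(members[np.argmin(np.linalg.norm(pts - centroid, axis=1))])
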