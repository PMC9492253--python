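"""Weighted histogram analysis method for 1D/2D umbrella windows.

Harmonically biased window samples are histogrammed on a shared grid and
combined into one unbiased potential of mean force by the standard WHAM
self-consistency equations,

    p_b   = (sum_k n_kb) / (sum_k N_k exp[(f_k - c_kb) / kBT])
    f_k   = -kBT ln sum_b exp(-c_kb / kBT) p_b

with c_kb the bias energy of window k at the center of bin b.  All sums run
in log space, so arbitrarily large bias energies are safe.  The fixed point
is first located by minimizing the (convex) WHAM negative log-likelihood
with L-BFGS, then polished by direct iteration until the largest change of
any window offset f_k drops below the convergence tolerance (default 1e-6
kJ/mol), which is the reported convergence metric.

The PMF is F_b = -kBT ln p_b, shifted so its minimum over sampled bins is 0;
unsampled bins carry NaN and are never interpolated here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, kt
from .errors import ConvergenceError, EmptyHistogramError
from .landscapes import UmbrellaWindow

logger = logging.getLogger(__name__)

__all__ = ["PMFGrid", "WhamResult", "wham", "histogram_windows", "make_bin_edges"]


@dataclass
class PMFGrid:
    """Free energy on a rectangular CV grid.

    ``free_energy`` is NaN on unsampled bins (explicit missing marker);
    finite values are normalized so the sampled minimum is exactly 0.
    """

    edges: list  # per-CV bin edges (nm), strictly increasing
    free_energy: np.ndarray  # kJ/mol, shape = bin counts per CV
    counts: np.ndarray  # total samples per bin
    temperature: float  # K

    @property
    def ndim(self):
        return len(self.edges)

    @property
    def centers(self):
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    @property
    def sampled(self):
        return self.counts > 0


@dataclass
class WhamResult:
    pmf: PMFGrid
    window_offsets: np.ndarray  # f_k in kJ/mol, f_0 = 0
    n_iterations: int
    final_change: float  # kJ/mol
    reliable_offsets: bool = True  # False when window clusters do not overlap


def make_bin_edges(windows, n_bins=100, bin_range=None):
    """Shared bin edges per CV: uniform over the union of window boundaries.

    The range is the span of window centers padded by half the median
    nearest-neighbor center spacing, so runs with different seeds share a
    grid.  Falls back to the data extent when centers are degenerate (e.g. a
    single unbiased window).
    """
    ndim = windows[0].ndim
    edges = []
    for d in range(ndim):
        if bin_range is not None:
            lo, hi = bin_range[d]
        else:
            ctr = np.unique(np.round([w.centers[d] for w in windows], 12))
            if len(ctr) > 1:
                pad = 0.5 * float(np.median(np.diff(ctr)))
                lo, hi = ctr[0] - pad, ctr[-1] + pad
            else:
                data = np.concatenate([w.samples[:, d] for w in windows])
                lo, hi = float(data.min()), float(data.max())
                span = hi - lo or 1.0
                lo, hi = lo - 1e-3 * span, hi + 1e-3 * span
        edges.append(np.linspace(lo, hi, n_bins + 1))
    return edges


def histogram_windows(windows, bin_edges):
    """Per-window count arrays on shared edges (half-open bins, last closed).

    Out-of-range samples are clipped away (dropped) and logged; if every
    sample of every window is out of range an :class:`EmptyHistogramError`
    is raised.
    """
    hists = []
    total_dropped = 0
    for i, w in enumerate(windows):
        h, _ = np.histogramdd(w.samples, bins=bin_edges)
        dropped = w.n_samples - int(h.sum())
        if dropped:
            logger.info("window %d: %d of %d samples outside the bin range",
                        i, dropped, w.n_samples)
            total_dropped += dropped
        hists.append(h)
    if hists and sum(int(h.sum()) for h in hists) == 0:
        raise EmptyHistogramError("all samples fall outside the bin range")
    return hists


def _bias_matrix(windows, centers_flat):
    """c_kb: bias energy of window k at flat bin center b, (K, B)."""
    return np.stack([w.bias_energy(centers_flat) for w in windows])


def _overlap_components(hists):
    """Number of window clusters connected through shared sampled bins."""
    k = len(hists)
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    occupied = np.stack([h.ravel() > 0 for h in hists])  # (K, B)
    for b in np.nonzero(occupied.any(axis=0))[0]:
        ks = np.nonzero(occupied[:, b])[0]
        for other in ks[1:]:
            ra, rb = find(int(ks[0])), find(int(other))
            if ra != rb:
                parent[rb] = ra
    return len({find(i) for i in range(k)})


def wham(windows, n_bins=100, tolerance=1e-6, max_iterations=100_000,
         temperature=DEFAULT_TEMPERATURE, bin_range=None) -> WhamResult:
    """Unbias umbrella windows into a PMF grid.

    Parameters
    ----------
    windows : list of UmbrellaWindow sharing CV dimensionality and bias
        convention ``U = 1/2 k (z - z0)^2`` per CV.
    n_bins : bins per CV (default 100).
    tolerance : convergence tolerance on max |Δf_k| in kJ/mol (default 1e-6).
    max_iterations : direct-iteration budget after the L-BFGS warm start.
    temperature : sampling temperature in K.
    bin_range : optional explicit per-CV (low, high); default from windows.
    """
    if not windows:
        raise ValueError("need at least one window")
    ndim = windows[0].ndim
    if any(w.ndim != ndim for w in windows):
        raise ValueError("windows mix CV dimensionalities")
    if any(w.n_samples == 0 for w in windows):
        raise ValueError("windows with empty samples are not allowed")

    kbt = kt(temperature)
    edges = make_bin_edges(windows, n_bins=n_bins, bin_range=bin_range)
    hists = histogram_windows(windows, edges)
    shape = tuple(len(e) - 1 for e in edges)

    counts = np.sum(hists, axis=0)
    n_b = counts.ravel()
    sampled = n_b > 0
    centers_mesh = np.meshgrid(*[0.5 * (e[1:] + e[:-1]) for e in edges],
                               indexing="ij")
    centers_flat = np.stack([c.ravel() for c in centers_mesh], axis=-1)

    n_clusters = _overlap_components(hists)
    reliable = n_clusters == 1
    if not reliable:
        logger.warning(
            "windows form %d non-overlapping clusters; relative offsets "
            "between clusters are unreliable", n_clusters)

    c_kb = _bias_matrix(windows, centers_flat[sampled])  # (K, S) kJ/mol
    u = c_kb / kbt
    n_k = np.array([float(h.sum()) for h in hists])  # in-range counts
    ln_nb = np.log(n_b[sampled])
    ln_nk = np.log(n_k)

    # convex negative log-likelihood in g = f/kBT; gradient is the WHAM residual
    def neg_loglik(g):
        log_d = logsumexp(ln_nk[:, None] + g[:, None] - u, axis=0)  # (S,)
        val = float(np.sum(n_b[sampled] * log_d) - np.dot(n_k, g))
        w_kb = np.exp(ln_nk[:, None] + g[:, None] - u - log_d[None, :])
        grad = w_kb @ n_b[sampled] - n_k
        return val, grad

    g0 = np.zeros(len(windows))
    res = optimize.minimize(neg_loglik, g0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-15,
                                     "gtol": 1e-10})
    g = res.x - res.x[0]

    # polish by direct iteration; convergence metric is max |Δf| in kJ/mol
    final_change = np.inf
    iteration = 0
    for iteration in range(1, max_iterations + 1):
        log_d = logsumexp(ln_nk[:, None] + g[:, None] - u, axis=0)
        ln_p = ln_nb - log_d
        g_new = -logsumexp(-u + ln_p[None, :], axis=1)
        g_new -= g_new[0]
        final_change = float(np.max(np.abs(g_new - g))) * kbt
        g = g_new
        if final_change < tolerance:
            break
    else:
        iteration = max_iterations

    log_d = logsumexp(ln_nk[:, None] + g[:, None] - u, axis=0)
    ln_p = ln_nb - log_d
    ln_p -= logsumexp(ln_p)  # normalize over sampled bins

    free = np.full(n_b.shape, np.nan)
    free[sampled] = -kbt * ln_p
    free[sampled] -= np.nanmin(free[sampled])
    pmf = PMFGrid(edges=edges, free_energy=free.reshape(shape),
                  counts=counts.reshape(shape), temperature=temperature)
    result = WhamResult(pmf=pmf, window_offsets=g * kbt,
                        n_iterations=iteration, final_change=final_change,
                        reliable_offsets=reliable)
    if final_change >= tolerance:
        raise ConvergenceError(
            f"WHAM did not reach {tolerance} kJ/mol in {max_iterations} "
            f"iterations (last change {final_change:.3g})", last_result=result)
    logger.info("WHAM converged in %d iterations (final change %.2e kJ/mol)",
                iteration, final_change)
    return result
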