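"""Kramers rate chains on 1D free-energy profiles.

Each hop between neighboring valleys i and j of a projected MFEP gets an
overdamped Kramers rate

    r_ij = ω(λ_i) ω(λ_j) / (2 π γ) · exp(-ΔF‡_ij / kBT)

with ω = sqrt(|d²F/dλ²|) from local cubic fits at the extrema and γ the
friction coefficient.  γ is identical across compared systems and cancels in
ratios, so all rates here are *friction-scaled* (γ ≡ 1); only relative rates
between systems are physically meaningful.  The hops are chained into a
linear ODE system with the last state absorbing; the total transition rate
is the inverse mean first-passage time of that chain.  When a chain's rate
dynamic range exceeds 64-bit floating point, the ODE is refused and the
single-step rate over the highest forward barrier serves as a flagged upper
bound — ratios against it are reported as "≤".

Also provided: transition-state-theory conversions between unitary
conductance, ion rate, and an effective Eyring barrier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .constants import (DEFAULT_TEMPERATURE, ELEMENTARY_CHARGE, KB, KB_SI,
                        PLANCK, kt)
from .errors import (ChainOverflowError, ClassificationError, FitError,
                     HorizonError, ProfileError)
from .mfep import Profile1D

logger = logging.getLogger(__name__)

__all__ = ["Extremum", "RateChain", "ChainOccupancy", "RateValue",
           "fit_curvature", "kramers_rate", "build_chain", "solve_chain",
           "total_rate", "rate_limiting_bound", "relative_rate",
           "conductance_to_rate", "rate_to_barrier_tst", "barrier_to_rate_tst"]

#: largest tolerable log10 spread between chain rates before the ODE solve
#: loses meaning in 64-bit arithmetic
LOG10_RATE_RANGE_LIMIT = 15.0


@dataclass
class Extremum:
    """A fitted valley or peak of a 1D profile."""

    kind: str  # "valley" or "peak"
    lam: float  # nm
    free_energy: float  # kJ/mol
    curvature_omega: float  # sqrt(kJ/mol)/nm, omega = sqrt(|F''|)
    fit_window: float  # nm
    fit_residual: float  # kJ/mol (RMS)


@dataclass
class RateValue:
    """A rate in friction-scaled units, carried with its logarithm.

    ``is_bound`` marks upper bounds (from :func:`rate_limiting_bound`);
    the flag propagates into relative rates.
    """

    log_value: float
    is_bound: bool = False

    @property
    def value(self):
        return float(np.exp(self.log_value))


@dataclass
class RateChain:
    """Alternating valleys/peaks with pairwise Kramers rates (γ ≡ 1)."""

    valleys: list  # Extremum, λ-ordered
    peaks: list  # Extremum, between consecutive valleys
    log_forward: np.ndarray  # ln r_{i,i+1}, length n-1
    log_backward: np.ndarray  # ln r_{i+1,i}, length n-1
    kT: float  # kJ/mol
    barriers_forward: np.ndarray = field(default=None)
    barriers_backward: np.ndarray = field(default=None)

    @property
    def n_states(self):
        return len(self.valleys)

    @property
    def forward_rates(self):
        return np.exp(self.log_forward)

    @property
    def backward_rates(self):
        return np.exp(self.log_backward)

    @classmethod
    def from_rates(cls, forward, backward, kT=1.0):
        """Build a bare chain directly from rate arrays (for analysis/tests)."""
        forward = np.asarray(forward, dtype=float)
        backward = np.asarray(backward, dtype=float)
        if forward.shape != backward.shape:
            raise ValueError("forward/backward rate arrays differ in length")
        n = len(forward) + 1
        dummy = [Extremum("valley", float(i), 0.0, 1.0, 0.0, 0.0)
                 for i in range(n)]
        peaks = [Extremum("peak", i + 0.5, 0.0, 1.0, 0.0, 0.0)
                 for i in range(n - 1)]
        return cls(valleys=dummy, peaks=peaks,
                   log_forward=np.log(forward),
                   log_backward=np.log(backward), kT=kT)


@dataclass
class ChainOccupancy:
    """Time-resolved state occupancies p_i(t) of a solved chain."""

    times: np.ndarray
    occupancies: np.ndarray  # (n_states, n_times)
    mfpt: float  # mean first-passage time into the last state
    absorbed: bool  # p_n(t_end) > 1 - tolerance
    tolerance: float


def fit_curvature(profile: Profile1D, extremum_lambda, window=None,
                  kind=None) -> Extremum:
    """Local cubic fit of F(λ) around an extremum; ω = sqrt(|F''|).

    ``window`` is the half-width in nm (default: 0.05 nm or the span of 7
    profile points, whichever is larger).  The cubic's own stationary point
    must stay inside the window (else :class:`FitError`); its second
    derivative fixes ω and, by sign, the extremum kind — a mismatch with a
    declared ``kind`` raises :class:`ClassificationError`.
    """
    lam, f = profile.lam, profile.free_energy
    lam0 = float(extremum_lambda)
    if window is None:
        dlam = float(np.median(np.diff(lam)))
        window = max(0.05, 3.5 * dlam)
    sel = np.abs(lam - lam0) <= window
    if sel.sum() < 5:
        raise FitError(f"fewer than 5 profile points within ±{window} nm")
    x = lam[sel] - lam0
    # one-sided windows (profile endpoints) underdetermine a cubic; a
    # quadratic pinned at the extremum is far more stable there
    one_sided = x.min() > -0.25 * window or x.max() < 0.25 * window
    degree = 2 if one_sided else 3
    coeffs = np.polynomial.polynomial.polyfit(x, f[sel], degree)
    if degree == 2:
        coeffs = np.append(coeffs, 0.0)
    c0, c1, c2, c3 = coeffs
    # stationary point of the cubic nearest the nominal extremum
    if degree == 2:
        if abs(c2) < 1e-12:
            raise FitError("one-sided fit is effectively linear; no "
                           "stationary point")
        xs = -c1 / (2 * c2)
    else:
        roots = np.roots([3 * c3, 2 * c2, c1])
        roots = roots[np.abs(roots.imag) < 1e-9].real
        if len(roots) == 0:
            raise FitError("fitted cubic has no real stationary point")
        xs = roots[np.argmin(np.abs(roots))]
    if abs(xs) > window:
        raise FitError(
            f"fitted stationary point {lam0 + xs:.4f} escaped the ±{window} "
            "nm window")
    second = 2 * c2 + 6 * c3 * xs
    found_kind = "valley" if second > 0 else "peak"
    if kind is not None and kind != found_kind:
        raise ClassificationError(
            f"expected a {kind} at λ={lam0:.4f} but the fit is a {found_kind}")
    fitval = c0 + c1 * x + c2 * x**2 + c3 * x**3
    residual = float(np.sqrt(np.mean((fitval - f[sel]) ** 2)))
    fs = c0 + c1 * xs + c2 * xs**2 + c3 * xs**3
    return Extremum(kind=found_kind, lam=lam0 + float(xs),
                    free_energy=float(fs),
                    curvature_omega=float(np.sqrt(abs(second))),
                    fit_window=float(window), fit_residual=residual)


def _log_kramers(omega_start, omega_barrier, barrier, kT):
    if barrier < 0:
        raise ValueError(
            f"negative barrier {barrier}; re-identify the extrema")
    if omega_start <= 0 or omega_barrier <= 0:
        raise ValueError("curvatures must be positive")
    return (np.log(omega_start) + np.log(omega_barrier)
            - np.log(2.0 * np.pi) - barrier / kT)


def kramers_rate(omega_start, omega_barrier, barrier, kT) -> float:
    """Overdamped Kramers rate ω_i ω_j / (2π) · exp(-ΔF‡/kBT), γ ≡ 1.

    Evaluated in log space; underflows to 0.0 only below exp(-745).
    """
    return float(np.exp(_log_kramers(omega_start, omega_barrier, barrier, kT)))


def build_chain(profile: Profile1D, kT=None, fit_window=None,
                convention="peak") -> RateChain:
    """Kramers rates between every adjacent valley pair of a profile.

    For the hop i→j over the intervening peak, the barrier is the hop's own
    ΔF‡ = F(peak) − F(i).  ``convention`` picks the second curvature in the
    prefactor: ``"peak"`` (default, standard overdamped Kramers) pairs the
    starting valley with the intervening peak; ``"valley"`` pairs the two
    valleys (the literal peak-free reading).
    """
    if kT is None:
        kT = kt(DEFAULT_TEMPERATURE)
    if convention not in ("peak", "valley"):
        raise ValueError(f"unknown curvature convention {convention!r}")
    markers = profile.markers
    v_idx = profile.valley_indices
    if len(v_idx) < 2:
        raise ProfileError("profile needs at least two valleys")
    dlam = float(np.median(np.diff(profile.lam)))
    base_window = fit_window if fit_window is not None \
        else max(0.05, 3.5 * dlam)
    valleys, peaks = [], []
    for kind, i in markers:
        last_err = None
        for mult in (1, 2, 4):  # widen on noisy/one-sided fits
            try:
                ext = fit_curvature(profile, profile.lam[i],
                                    window=base_window * mult, kind=kind)
                break
            except (FitError, ClassificationError) as err:
                last_err = err
        else:
            raise last_err
        (valleys if kind == "valley" else peaks).append(ext)
    if len(peaks) != len(valleys) - 1:
        raise ProfileError("expected one peak between each valley pair")

    n = len(valleys)
    log_f = np.empty(n - 1)
    log_b = np.empty(n - 1)
    bar_f = np.empty(n - 1)
    bar_b = np.empty(n - 1)
    for i in range(n - 1):
        vi, vj, pk = valleys[i], valleys[i + 1], peaks[i]
        bar_f[i] = pk.free_energy - vi.free_energy
        bar_b[i] = pk.free_energy - vj.free_energy
        if convention == "peak":
            log_f[i] = _log_kramers(vi.curvature_omega, pk.curvature_omega,
                                    bar_f[i], kT)
            log_b[i] = _log_kramers(vj.curvature_omega, pk.curvature_omega,
                                    bar_b[i], kT)
        else:
            log_f[i] = _log_kramers(vi.curvature_omega, vj.curvature_omega,
                                    bar_f[i], kT)
            log_b[i] = _log_kramers(vj.curvature_omega, vi.curvature_omega,
                                    bar_b[i], kT)
    return RateChain(valleys=valleys, peaks=peaks, log_forward=log_f,
                     log_backward=log_b, kT=kT, barriers_forward=bar_f,
                     barriers_backward=bar_b)


def _check_overflow(chain: RateChain, absorbing_last=True):
    logs = list(chain.log_forward) + list(chain.log_backward[:-1]
                                          if absorbing_last
                                          else chain.log_backward)
    logs = np.asarray(logs)
    span = (logs.max() - logs.min()) / np.log(10.0)
    if span > LOG10_RATE_RANGE_LIMIT:
        raise ChainOverflowError(
            f"rate dynamic range spans 1e{span:.0f}, beyond 64-bit ODE "
            "integration; report rate_limiting_bound instead")


def solve_chain(chain: RateChain, absorbing_last=True, horizon=None,
                tolerance=1e-6) -> ChainOccupancy:
    """Integrate the linear master equation of the chain from p_1 = 1.

    Only hops between adjacent states are allowed; with ``absorbing_last``
    the final state has no outflow and integration continues (doubling the
    horizon) until p_n > 1 - ``tolerance`` or ``horizon`` is reached.  The
    mean first-passage time is accumulated by the integrator itself as
    ∫ (1 - p_n) dt, plus an exponential tail correction for the remaining
    survival mass.

    Raises :class:`ChainOverflowError` when the rate dynamic range exceeds
    floating-point capability (use :func:`rate_limiting_bound` then).
    """
    _check_overflow(chain, absorbing_last)
    n = chain.n_states
    rf, rb = chain.forward_rates, chain.backward_rates
    q = np.zeros((n, n))
    for i in range(n - 1):
        q[i + 1, i] += rf[i]
        q[i, i] -= rf[i]
        back = rb[i]
        if absorbing_last and i == n - 2:
            back = 0.0
        q[i, i + 1] += back
        q[i + 1, i + 1] -= back

    qa = np.zeros((n + 1, n + 1))
    qa[:n, :n] = q
    qa[n, n - 1] = -1.0  # m' = 1 - p_n  accumulates the MFPT

    fastest = float(np.max(np.concatenate([rf, rb])))
    t_end = 10.0 / fastest
    hard_cap = horizon if horizon is not None else np.inf
    y0 = np.zeros(n + 1)
    y0[0] = 1.0
    y0[n] = 0.0

    def rhs(t, y):
        out = qa @ y
        out[n] += 1.0  # the +1 of m' = 1 - p_n
        return out

    sol = None
    for _ in range(80):
        t_end = min(t_end, hard_cap)
        sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                        jac=lambda t, y: qa, rtol=1e-10, atol=1e-13,
                        dense_output=True)
        if not sol.success:
            raise HorizonError(f"ODE integration failed: {sol.message}")
        absorbed = absorbing_last and sol.y[n - 1, -1] > 1.0 - tolerance
        if absorbed or t_end >= hard_cap:
            break
        t_end *= 10.0

    times = sol.t
    p = sol.y[:n]
    mfpt = float(sol.y[n, -1])
    absorbed = bool(absorbing_last and p[n - 1, -1] > 1.0 - tolerance)
    if absorbing_last:
        survival = max(0.0, 1.0 - float(p[n - 1, -1]))
        if survival > 0 and len(times) > 2:
            # exponential tail from the terminal log-slope of the survival
            s_prev = max(1e-300, 1.0 - float(p[n - 1, -2]))
            dtail = times[-1] - times[-2]
            lam_tail = np.log(s_prev / max(survival, 1e-300)) / dtail \
                if dtail > 0 else 0.0
            if lam_tail > 0:
                mfpt += survival / lam_tail
    return ChainOccupancy(times=times, occupancies=p, mfpt=mfpt,
                          absorbed=absorbed, tolerance=tolerance)


def total_rate(occupancy: ChainOccupancy) -> RateValue:
    """Total transition rate 1/MFPT of an absorbed chain solution."""
    if not occupancy.absorbed:
        raise HorizonError(
            "final state not sufficiently absorbed at the horizon; extend "
            "the horizon or loosen the tolerance")
    return RateValue(log_value=float(-np.log(occupancy.mfpt)), is_bound=False)


def rate_limiting_bound(chain: RateChain) -> RateValue:
    """Single-step rate over the highest forward barrier (upper bound).

    Computed in log space, so it stays finite where the full ODE solve
    overflows; the result is flagged as an upper bound on the total rate.
    """
    if chain.barriers_forward is not None:
        i = int(np.argmax(chain.barriers_forward))
    else:
        i = int(np.argmin(chain.log_forward))
    return RateValue(log_value=float(chain.log_forward[i]), is_bound=True)


def relative_rate(system_a, system_b) -> RateValue:
    """Dimensionless ratio rate_a / rate_b, evaluated in log space.

    Accepts :class:`RateValue` or plain positive floats.  If ``system_a`` is
    an upper bound the ratio is one too (the "≤" flag propagates).
    """
    def _log(x):
        if isinstance(x, RateValue):
            return x.log_value, x.is_bound
        x = float(x)
        if x <= 0:
            raise ZeroDivisionError("rates must be positive")
        return np.log(x), False

    la, ba = _log(system_a)
    lb, _ = _log(system_b)
    return RateValue(log_value=float(la - lb), is_bound=ba)


# -- transition-state-theory conversions -------------------------------------

def conductance_to_rate(conductance_pS, voltage_mV, charge_per_event=1.0):
    """Ion rate (1/s) carried by a unitary conductance at a driving voltage.

    rate = g·V / (q·e) with g in pS, V in mV, q in elementary charges.
    """
    if conductance_pS <= 0 or voltage_mV <= 0 or charge_per_event <= 0:
        raise ValueError("conductance, voltage and charge must be positive")
    current = conductance_pS * 1e-12 * voltage_mV * 1e-3  # ampere
    return current / (charge_per_event * ELEMENTARY_CHARGE)


def rate_to_barrier_tst(rate, temperature=298.0):
    """Effective Eyring barrier (kJ/mol) for an observed rate (1/s).

    Inverts k = (kB·T/h)·exp(-ΔF‡/kB·T).  A rate above the prefactor gives
    a negative barrier and a warning.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    prefactor = KB_SI * temperature / PLANCK  # 1/s
    dg = KB * temperature * np.log(prefactor / rate)
    if dg < 0:
        warnings.warn("rate exceeds the Eyring prefactor: negative barrier",
                      stacklevel=2)
    return float(dg)


def barrier_to_rate_tst(barrier_kj_mol, temperature=298.0):
    """Eyring rate (1/s) for a single barrier; inverse of rate_to_barrier_tst."""
    prefactor = KB_SI * temperature / PLANCK
    return float(prefactor * np.exp(-barrier_kj_mol / (KB * temperature)))
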