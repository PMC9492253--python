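"""Kramers rates, curvature fits, chain ODEs, MFPTs, TST conversions."""

import math
import warnings

import numpy as np
import pytest
from scipy.linalg import expm

from pmfpath import rates as R
from pmfpath.constants import kt
from pmfpath.errors import ChainOverflowError, FitError
from pmfpath.mfep import Profile1D

KBT = kt(310.0)


def quadratic_profile(a=100.0, lam0=0.5, span=1.0, n=2001, noise=0.0,
                      seed=None):
    lam = np.linspace(0.0, span, n)
    f = 0.5 * a * (lam - lam0) ** 2
    if noise:
        f = f + np.random.default_rng(seed).normal(0.0, noise, n)
    return Profile1D(lam=lam, free_energy=f,
                     markers=[("valley", int(np.argmin(np.abs(lam - lam0))))])


def alternating_profile(valleys, peaks, width=0.2):
    """Smooth profile through given valley/peak energies (quadratic arcs)."""
    energies = []
    lams = []
    seq = []
    for i, v in enumerate(valleys):
        seq.append(("valley", v))
        if i < len(peaks):
            seq.append(("peak", peaks[i]))
    lam = np.linspace(0.0, width * (len(seq) - 1), 4001)
    pts_lam = np.arange(len(seq)) * width
    pts_f = [e for _, e in seq]
    from scipy.interpolate import CubicSpline
    spl = CubicSpline(pts_lam, pts_f, bc_type="clamped")
    f = spl(lam)
    markers = [(kind, int(np.argmin(np.abs(lam - x))))
               for (kind, _), x in zip(seq, pts_lam)]
    return Profile1D(lam=lam, free_energy=f, markers=markers)


def birth_death_mfpt(forward, backward):
    """Closed-form mean first-passage time 1 -> n of a birth-death chain."""
    n = len(forward) + 1
    total = 0.0
    for j in range(n - 1):
        for i in range(j + 1):
            prod = 1.0
            for k in range(i, j):
                prod *= backward[k] / forward[k]
            total += prod / forward[j]
    return total


class TestFitCurvature:
    def test_exact_quadratic(self):
        prof = quadratic_profile(a=100.0)
        ext = R.fit_curvature(prof, 0.5, window=0.1)
        assert ext.kind == "valley"
        assert ext.curvature_omega == pytest.approx(10.0, abs=1e-6)
        assert ext.fit_residual < 1e-9

    def test_quartic_perturbation_converges_with_window(self):
        lam = np.linspace(0.0, 1.0, 4001)
        a = 100.0
        f = 0.5 * a * (lam - 0.5) ** 2 + 400.0 * (lam - 0.5) ** 4
        prof = Profile1D(lam=lam, free_energy=f, markers=[("valley", 2000)])
        omegas = [R.fit_curvature(prof, 0.5, window=w).curvature_omega
                  for w in (0.2, 0.1, 0.05)]
        errors = [abs(o - math.sqrt(a)) for o in omegas]
        assert errors[0] > errors[1] > errors[2]

    def test_noisy_profile_within_ten_percent(self):
        prof = quadratic_profile(a=100.0, noise=0.1, seed=4)
        ext = R.fit_curvature(prof, 0.5, window=0.15)
        assert ext.curvature_omega == pytest.approx(10.0, rel=0.1)

    def test_escaped_stationary_point_raises(self):
        lam = np.linspace(0.0, 1.0, 501)
        prof = Profile1D(lam=lam, free_energy=3.0 * lam,
                         markers=[("valley", 250)])
        with pytest.raises(FitError):
            R.fit_curvature(prof, 0.5, window=0.05)


class TestKramersRate:
    def test_zero_barrier_prefactor(self):
        assert R.kramers_rate(1.0, 1.0, 0.0, KBT) == \
            pytest.approx(1.0 / (2 * np.pi))

    def test_unit_barrier(self):
        assert R.kramers_rate(1.0, 1.0, KBT, KBT) == \
            pytest.approx(np.exp(-1.0) / (2 * np.pi))

    def test_log_space_matches_direct_evaluation(self):
        direct = 2.0 * 3.0 / (2 * math.pi) * math.exp(-44.0 / 2.577)
        assert R.kramers_rate(2.0, 3.0, 44.0, 2.577) == \
            pytest.approx(direct, rel=1e-12)

    def test_negative_barrier_rejected(self):
        with pytest.raises(ValueError):
            R.kramers_rate(1.0, 1.0, -0.1, KBT)


class TestBuildChain:
    def test_symmetric_double_well_equal_rates(self):
        prof = alternating_profile([0.0, 0.0], [12.0])
        chain = R.build_chain(prof, kT=KBT, fit_window=0.08)
        # equal to within the discretization of the profile grid
        assert chain.log_forward[0] == pytest.approx(chain.log_backward[0],
                                                     abs=0.01)

    def test_asymmetry_identity(self):
        """r_fwd / r_bwd = (omega_1/omega_2) exp(-(F_2 - F_1)/kT)."""
        prof = alternating_profile([0.0, -4.0], [11.0])
        chain = R.build_chain(prof, kT=KBT, fit_window=0.08)
        o1 = chain.valleys[0].curvature_omega
        o2 = chain.valleys[1].curvature_omega
        f1 = chain.valleys[0].free_energy
        f2 = chain.valleys[1].free_energy
        expected = np.log(o1 / o2) - (f2 - f1) / KBT
        assert chain.log_forward[0] - chain.log_backward[0] == \
            pytest.approx(expected, abs=1e-6)

    def test_five_valley_profile_rate_count(self):
        prof = alternating_profile([0, 2, 1, 3, 0.5], [10, 12, 11, 9])
        chain = R.build_chain(prof, kT=KBT, fit_window=0.08)
        assert len(chain.log_forward) == 4
        assert len(chain.log_backward) == 4
        assert chain.n_states == 5

    def test_valley_convention_flag(self):
        prof = alternating_profile([0.0, -2.0], [10.0])
        peak_conv = R.build_chain(prof, kT=KBT, fit_window=0.08)
        valley_conv = R.build_chain(prof, kT=KBT, fit_window=0.08,
                                    convention="valley")
        o_p = peak_conv.peaks[0].curvature_omega
        o_2 = valley_conv.valleys[1].curvature_omega
        diff = peak_conv.log_forward[0] - valley_conv.log_forward[0]
        assert diff == pytest.approx(np.log(o_p) - np.log(o_2), abs=1e-9)


class TestSolveChain:
    def test_two_state_closed_form(self):
        r = 0.37
        chain = R.RateChain.from_rates([r], [0.11])
        occ = R.solve_chain(chain, tolerance=1e-9)
        p2 = occ.occupancies[1]
        expected = 1.0 - np.exp(-r * occ.times)
        np.testing.assert_allclose(p2, expected, atol=1e-7)

    def test_three_state_matches_matrix_exponential(self):
        chain = R.RateChain.from_rates([1.0, 1.0], [1.0, 1.0])
        occ = R.solve_chain(chain, tolerance=1e-9)
        q = np.array([[-1.0, 1.0, 0.0],
                      [1.0, -2.0, 0.0],
                      [0.0, 1.0, 0.0]])
        for ti in (5, len(occ.times) // 2, -1):
            t = occ.times[ti]
            ref = expm(q * t) @ np.array([1.0, 0.0, 0.0])
            np.testing.assert_allclose(occ.occupancies[:, ti], ref,
                                       atol=1e-8)

    def test_probability_conserved(self):
        chain = R.RateChain.from_rates([0.5, 2.0, 0.1], [1.0, 0.3, 0.7])
        occ = R.solve_chain(chain, tolerance=1e-8)
        np.testing.assert_allclose(occ.occupancies.sum(axis=0), 1.0,
                                   atol=1e-6)

    def test_non_absorbing_reaches_detailed_balance(self):
        rf = np.array([0.8, 0.3])
        rb = np.array([0.4, 0.6])
        chain = R.RateChain.from_rates(rf, rb)
        occ = R.solve_chain(chain, absorbing_last=False, horizon=500.0)
        p = occ.occupancies[:, -1]
        # stationary ratios p_{i+1}/p_i = r_f,i / r_b,i
        assert p[1] / p[0] == pytest.approx(rf[0] / rb[0], rel=1e-4)
        assert p[2] / p[1] == pytest.approx(rf[1] / rb[1], rel=1e-4)


class TestTotalRate:
    def test_two_state_exact(self):
        chain = R.RateChain.from_rates([0.37], [5.0])
        occ = R.solve_chain(chain, tolerance=1e-10)
        assert R.total_rate(occ).value == pytest.approx(0.37, rel=1e-5)

    def test_three_state_analytic_formula(self):
        r12, r21, r23 = 0.9, 0.4, 0.2
        chain = R.RateChain.from_rates([r12, r23], [r21, 1.0])
        occ = R.solve_chain(chain, tolerance=1e-9)
        expected = 1.0 / (1 / r12 + 1 / r23 + r21 / (r12 * r23))
        assert R.total_rate(occ).value == pytest.approx(expected, rel=0.01)

    def test_deep_middle_well_limited_by_escape(self):
        """With a deep trap in the middle, the total rate approaches the
        slow escape rate out of it."""
        slow = 1e-4
        chain = R.RateChain.from_rates([5.0, slow], [1e-6, 1.0])
        occ = R.solve_chain(chain, tolerance=1e-8)
        assert R.total_rate(occ).value == pytest.approx(slow, rel=0.05)

    def test_random_chains_match_birth_death_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            rf = np.exp(rng.uniform(-7, 1, n - 1))
            rb = np.exp(rng.uniform(-7, 1, n - 1))
            chain = R.RateChain.from_rates(rf, rb)
            total = R.total_rate(R.solve_chain(chain, tolerance=1e-8))
            exact = 1.0 / birth_death_mfpt(rf, rb)
            assert total.value == pytest.approx(exact, rel=0.01)
            bound = R.rate_limiting_bound(chain)
            assert bound.value >= total.value * (1 - 1e-9)
            assert bound.is_bound

    def test_monotone_in_barrier_height(self):
        """Raising any forward barrier monotonically slows the chain."""
        prev = np.inf
        for barrier in (4.0, 6.0, 8.0, 10.0):
            rf = [R.kramers_rate(10.0, 10.0, barrier, KBT), 0.5]
            chain = R.RateChain.from_rates(rf, [0.2, 0.2])
            total = R.total_rate(R.solve_chain(chain, tolerance=1e-8)).value
            assert total < prev
            prev = total


class TestOverflowPolicy:
    def test_100kt_barrier_raises_and_bound_stays_finite(self):
        rf = [1.0, R.kramers_rate(10.0, 10.0, 100 * KBT, KBT)]
        chain = R.RateChain.from_rates(rf, [1.0, 1.0])
        with pytest.raises(ChainOverflowError):
            R.solve_chain(chain)
        bound = R.rate_limiting_bound(chain)
        assert np.isfinite(bound.log_value)
        assert bound.is_bound

    def test_relative_rate_flags_bound(self):
        bound = R.RateValue(log_value=-50.0, is_bound=True)
        total = R.RateValue(log_value=-2.0, is_bound=False)
        rel = R.relative_rate(bound, total)
        assert rel.is_bound
        assert rel.value == pytest.approx(np.exp(-48.0))

    def test_ratio_finite_for_huge_barrier_differences(self):
        a = R.RateValue(log_value=-500.0)
        b = R.RateValue(log_value=-2.0)
        rel = R.relative_rate(a, b)
        assert np.isfinite(rel.log_value)
        assert rel.value == 0.0 or rel.value > 0  # underflow to 0 is fine


class TestRelativeRate:
    def test_identical_chains_give_unity(self):
        r = R.RateValue(log_value=-3.21)
        assert R.relative_rate(r, r).value == pytest.approx(1.0)

    def test_kt_peak_ladder_identity(self):
        """Raising every peak by +kT (so both directions' barriers grow by
        kT) scales the total rate by exactly exp(-1) when curvatures
        match."""
        base_barriers = [6.0, 9.0, 7.5]

        def chain_for(extra):
            rf = [R.kramers_rate(10.0, 8.0, b + extra, KBT)
                  for b in base_barriers]
            rb = [R.kramers_rate(10.0, 8.0, b + 3.0 + extra, KBT)
                  for b in base_barriers]
            return R.RateChain.from_rates(rf, rb)

        t0 = R.total_rate(R.solve_chain(chain_for(0.0), tolerance=1e-9))
        t1 = R.total_rate(R.solve_chain(chain_for(KBT), tolerance=1e-9))
        rel = R.relative_rate(t1, t0)
        assert rel.value == pytest.approx(np.exp(-1.0), rel=0.02)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            R.relative_rate(1.0, 0.0)


class TestTstConversions:
    def test_conductance_to_rate_arithmetic(self):
        # 1.602 pS at 100 mV moves almost exactly 1e6 charges per second
        assert R.conductance_to_rate(1.602, 100.0, 1.0) == \
            pytest.approx(1.0e6, rel=1e-3)

    def test_zero_conductance_rejected(self):
        with pytest.raises(ValueError):
            R.conductance_to_rate(0.0, 100.0, 1.0)

    def test_round_trip_identity(self):
        for barrier in (5.0, 40.0, 80.0):
            k = R.barrier_to_rate_tst(barrier, 310.0)
            assert R.rate_to_barrier_tst(k, 310.0) == \
                pytest.approx(barrier, rel=1e-10)

    def test_prefactor_rate_gives_zero_barrier(self):
        from pmfpath.constants import KB_SI, PLANCK
        prefactor = KB_SI * 298.0 / PLANCK
        assert R.rate_to_barrier_tst(prefactor, 298.0) == \
            pytest.approx(0.0, abs=1e-9)

    def test_rate_above_prefactor_warns_negative(self):
        from pmfpath.constants import KB_SI, PLANCK
        prefactor = KB_SI * 298.0 / PLANCK
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            barrier = R.rate_to_barrier_tst(prefactor * 10, 298.0)
        assert barrier < 0
        assert any("prefactor" in str(w.message) for w in caught)
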