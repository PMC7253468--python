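"""ODE integration, pulse perturbations, return times, recovery phases."""

import numpy as np
import pytest

from randlv import (
    BlowupError,
    InfeasiblePulseError,
    ParameterError,
    Trajectory,
    community_matrix,
    generate_gaussian,
    generate_uniform,
    integrate,
    pulse_perturb,
    recovery_phases,
    return_time,
    solve_equilibrium,
    spectrum,
    tail_decay_rate,
)


def logistic(t, N0=0.5):
    # closed form of dN/dt = N(1 - N)
    return 1.0 / (1.0 + (1.0 / N0 - 1.0) * np.exp(-t))


def feasible_stable_gaussian(n=10, m=0.1, sigma=0.05, seed=0):
    rng = np.random.default_rng(seed)
    while True:
        im = generate_gaussian(
            n, m, sigma, positive_only=m > 0, seed=int(rng.integers(0, 2**31 - 1))
        )
        eq = solve_equilibrium(im)
        if not eq.feasible:
            continue
        spec = spectrum(community_matrix(im, eq.Nstar), eq.Nstar)
        if spec.locally_stable:
            return im, eq, spec


class TestIntegrate:
    def test_single_species_matches_logistic_closed_form(self):
        traj = integrate(np.array([[-1.0]]), np.array([1.0]), np.array([0.5]),
                         t_end=10.0)
        assert np.max(np.abs(traj.N[:, 0] - logistic(traj.times))) < 1e-6

    def test_equilibrium_is_a_fixed_point(self, feasible_community):
        im, eq = feasible_community(n=8, seed=1)
        traj = integrate(im, eq.r, eq.Nstar.copy(), t_end=20.0)
        assert np.max(np.abs(traj.N - eq.Nstar)) < 1e-8

    def test_decay_along_equilibrium_eigendirection(self, feasible_community):
        # N* is the eigenvector of Lambda = -1; a perturbation along it
        # contracts at rate |Lambda| = 1.
        im, eq = feasible_community(n=8, P=0.8, C=1.0, seed=5)
        delta = 1e-3 * eq.Nstar / np.linalg.norm(eq.Nstar)
        traj = integrate(im, eq.r, eq.Nstar + delta, t_end=15.0,
                         t_eval=np.linspace(0, 15, 2000))
        rate = tail_decay_rate(traj, eq.Nstar, dist_range=(1e-6, 1e-4))
        assert rate == pytest.approx(1.0, rel=0.02)

    def test_divergent_run_raises_blowup_naming_species(self):
        im = generate_uniform(6, m=0.5)
        with pytest.raises(BlowupError, match="species"):
            integrate(im, np.ones(6), 2.0 * np.ones(6), t_end=200.0)

    def test_input_validation(self):
        A = -np.eye(2)
        with pytest.raises(ParameterError):
            integrate(A, N0=None)
        with pytest.raises(ParameterError):
            integrate(A, N0=np.array([-0.1, 1.0]))
        with pytest.raises(ParameterError):
            integrate(A, N0=np.ones(2), t_end=0.0)

    def test_positivity_preserved(self, feasible_community):
        im, eq = feasible_community(n=8, seed=2)
        N0 = pulse_perturb(eq.Nstar, [0], 0.5 * eq.Nstar[0])
        traj = integrate(im, eq.r, N0, t_end=30.0)
        assert traj.N.min() > -1e-9


class TestPulsePerturb:
    def test_zero_depth_is_identity(self):
        Nstar = np.array([2.0, 2.0])
        assert np.array_equal(pulse_perturb(Nstar, [0], 0.0), Nstar)

    def test_standard_pulse(self):
        N0 = pulse_perturb(np.array([2.0, 2.0]), [0], 0.4)
        assert np.allclose(N0, [1.6, 2.0])

    def test_depth_equal_to_density_rejected(self):
        with pytest.raises(InfeasiblePulseError):
            pulse_perturb(np.array([2.0, 1.0]), [0], 2.0)

    def test_negative_depth_rejected(self):
        with pytest.raises(ParameterError):
            pulse_perturb(np.array([2.0]), [0], -0.1)


class TestReturnTime:
    def test_unperturbed_trajectory_returns_zero(self, feasible_community):
        im, eq = feasible_community(n=8, seed=3)
        traj = integrate(im, eq.r, eq.Nstar.copy(), t_end=10.0)
        rt = return_time(traj, eq.Nstar)
        assert rt.time == 0.0 and not rt.censored

    def test_logistic_band_crossing_time(self):
        # from N0=0.6, |N-1| = eps=0.01 at t = ln(66)
        traj = integrate(np.array([[-1.0]]), np.array([1.0]), np.array([0.6]),
                         t_end=10.0, t_eval=np.linspace(0, 10, 4000))
        rt = return_time(traj, np.array([1.0]), eps=0.01)
        assert rt.time == pytest.approx(np.log(66.0), abs=0.02)

    def test_censoring_flagged_when_band_never_reached(self):
        traj = integrate(np.array([[-1.0]]), np.array([1.0]), np.array([0.5]),
                         t_end=1.0)
        rt = return_time(traj, np.array([1.0]), eps=0.01)
        assert rt.censored and rt.time == 1.0


class TestRecoveryPhases:
    def synthetic(self, rates, amps=None, t_end=12.0, npts=600):
        t = np.linspace(0, t_end, npts)
        Nstar = np.ones(len(rates))
        amps = np.ones(len(rates)) if amps is None else np.asarray(amps)
        N = Nstar + amps * np.exp(-np.outer(t, np.asarray(rates)))
        return Trajectory(times=t, N=N, A=-np.eye(len(rates)),
                          r=np.ones(len(rates)), N0=N[0]), Nstar

    def test_two_decoupled_exponentials_recovered(self):
        # the fast mode must start with the larger amplitude for the norm
        # to show a fast phase at all
        traj, Nstar = self.synthetic([5.0, 1.0], amps=[1.0, 1e-3])
        rep = recovery_phases(traj, Nstar)
        assert rep.two_phase
        assert rep.phase2_rate == pytest.approx(1.0, rel=0.1)
        assert 3.0 < rep.phase1_rate < 5.5
        assert rep.phase1_rate > rep.phase2_rate

    def test_single_mode_reports_single_phase(self):
        traj, Nstar = self.synthetic([1.0])
        rep = recovery_phases(traj, Nstar)
        assert not rep.two_phase
        assert rep.phase1_rate == pytest.approx(rep.phase2_rate)
        assert rep.phase2_rate == pytest.approx(1.0, rel=0.05)

    def test_mutualistic_pulse_separates_fast_and_slow_phases(self):
        # bulk at ~ -<N*> ~ -10 vs outlier at -1: phase 1 must be faster
        im, eq, spec = feasible_stable_gaussian(seed=7)
        N0 = pulse_perturb(eq.Nstar, [0], 0.4)
        traj = integrate(im, eq.r, N0, t_end=25.0,
                         t_eval=np.linspace(0, 25, 4000))
        rep = recovery_phases(traj, eq.Nstar, Lambda=spec.Lambda,
                              bulk_center=spec.bulk_center)
        assert rep.two_phase
        assert rep.phase1_rate > rep.phase2_rate
        assert rep.phase2_vs_Lambda == pytest.approx(1.0, rel=0.15)


def test_linearisation_consistency_as_pulse_shrinks():
    """Tail decay rate converges to |Lambda| as the pulse depth -> 0."""
    im, eq, spec = feasible_stable_gaussian(seed=1)
    errs = []
    for depth in (0.1, 0.01, 0.001):
        N0 = pulse_perturb(eq.Nstar, [0], depth)
        # tight tolerances so the fit resolves the nonlinear bias rather
        # than integration round-off
        traj = integrate(im, eq.r, N0, t_end=30.0,
                         t_eval=np.linspace(0, 30, 6000),
                         rtol=1e-11, atol=1e-13)
        rate = tail_decay_rate(traj, eq.Nstar,
                               dist_range=(depth * 1e-3, depth * 1e-1))
        errs.append(abs(rate - abs(spec.Lambda)))
    assert errs[2] <= errs[0]
    assert errs[2] / abs(spec.Lambda) < 0.02
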