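"""Discretized action, analytic gradient, trial paths, optimizer, ensemble."""

import numpy as np
import pytest

from admdpath.action import (
    ActionParams, discretized_action, action_gradient, init_trial_path,
    minimize_action, pathway_barrier, run_ensemble,
)
from admdpath.potentials import DoubleWell, HarmonicWell, PotentialModel
from admdpath.structures import Path
from admdpath.synthetic import particle2d


class ZeroPotential(HarmonicWell):
    def __init__(self):
        super().__init__(k=0.0)


class SeriesPotential(PotentialModel):
    """V depends only on the frame's x coordinate: table lookup for tests."""

    def __init__(self, table):
        self.table = np.asarray(table, float)

    def energy(self, positions):
        return float(np.interp(positions[0, 0], np.arange(len(self.table)),
                               self.table))

    def gradient(self, positions):
        return np.zeros_like(positions)


def _params(P, **kw):
    defaults = dict(n_segments=P, delta_t=1.0, seed=0, noise_amplitude=0.0,
                    penalty_weight=0.0, max_iterations=3000,
                    gradient_tolerance=1e-10)
    defaults.update(kw)
    return ActionParams(**defaults)


def _line_path(positions_1d, delta_t=1.0):
    """1-D frames at given x values (single unit-mass particle)."""
    top = particle2d(0, 0).topology
    coords = np.zeros((len(positions_1d), 1, 3))
    coords[:, 0, 0] = positions_1d
    return Path(coords, top, delta_t=delta_t)


class TestDiscretizedAction:
    def test_identical_frames_zero_potential_gives_zero(self):
        path = _line_path([2.0, 2.0, 2.0])
        val = discretized_action(path, ZeroPotential(), _params(2))
        assert val.total_action == 0.0

    def test_uniform_1d_motion_closed_form(self):
        # x_j = j d, P = 2: each segment contributes (d²/2Δ²)Δ → S = d²/Δ
        d, dt = 1.7, 0.3
        path = _line_path([0.0, d, 2 * d], delta_t=dt)
        val = discretized_action(path, ZeroPotential(), _params(2, delta_t=dt))
        assert abs(val.total_action - d * d / dt) < 1e-12

    def test_random_path_matches_term_by_term_sum(self, rng):
        P, dt = 5, 0.7
        xs = rng.normal(size=P + 1)
        path = _line_path(xs, delta_t=dt)
        pot = HarmonicWell(k=2.0)
        mu, et = 0.8, 0.3
        val = discretized_action(
            path, pot, _params(P, delta_t=dt, penalty_weight=mu,
                               target_energy=et))
        # independent term-by-term oracle
        S = 0.0
        penalty = 0.0
        for j in range(P):
            K = 0.5 * (xs[j] - xs[j + 1]) ** 2 / dt ** 2
            V = pot.energy(path.coords[j])
            S += (K - V) * dt
            penalty += mu * (K + V - et) ** 2
        assert abs(val.total_action - (S + penalty)) < 1e-10
        assert abs(val.total_action
                   - (val.per_frame_lagrangian.sum() * dt + val.penalty_part)) < 1e-10

    def test_frame_count_mismatch_rejected(self):
        path = _line_path([0, 1, 2, 3])
        with pytest.raises(ValueError):
            discretized_action(path, ZeroPotential(), _params(2))


class TestActionGradient:
    @pytest.mark.parametrize("mu", [0.0, 1.3])
    def test_matches_central_finite_differences(self, mu, rng):
        P, dt = 6, 0.45
        pot = HarmonicWell(k=1.7)
        params = _params(P, delta_t=dt, penalty_weight=mu, target_energy=0.9)
        for _ in range(25):
            path = _line_path(rng.normal(size=P + 1), delta_t=dt)
            path.coords[:, 0, 1:] = rng.normal(size=(P + 1, 2))
            g = action_gradient(path, pot, params)
            h = 1e-6
            num = np.zeros_like(g)
            for k in range(1, P):
                for a in range(3):
                    for s, sign in ((h, 1), (-h, -1)):
                        path.coords[k, 0, a] += s
                        val = discretized_action(path, pot, params).total_action
                        num[k - 1, 0, a] += sign * val
                        path.coords[k, 0, a] -= s
            num /= 2 * h
            scale = max(1.0, np.abs(num).max())
            assert np.abs(g - num).max() / scale < 1e-5

    def test_free_particle_uniform_path_is_stationary(self):
        path = _line_path(np.linspace(0, 5, 9))
        g = action_gradient(path, ZeroPotential(), _params(8))
        assert np.abs(g).max() < 1e-10

    def test_gradient_has_exactly_interior_frame_entries(self):
        path = _line_path(np.linspace(0, 1, 7))
        g = action_gradient(path, ZeroPotential(), _params(6))
        assert g.shape[0] == 5  # P − 1


class TestInitTrialPath:
    def test_zero_noise_is_linear_interpolation(self):
        a, b = particle2d(0, 0), particle2d(4, 8)
        path = init_trial_path((a, b), _params(4))
        np.testing.assert_allclose(path.coords[1][0], [1, 2, 0], atol=1e-14)
        np.testing.assert_allclose(path.coords[3][0], [3, 6, 0], atol=1e-14)

    def test_same_seed_is_bitwise_identical(self):
        a, b = particle2d(0, 0), particle2d(4, 8)
        p1 = init_trial_path((a, b), _params(10, noise_amplitude=0.5, seed=42))
        p2 = init_trial_path((a, b), _params(10, noise_amplitude=0.5, seed=42))
        assert np.array_equal(p1.coords, p2.coords)
        p3 = init_trial_path((a, b), _params(10, noise_amplitude=0.5, seed=43))
        assert not np.array_equal(p2.coords, p3.coords)

    def test_endpoints_exact_and_noise_statistics(self):
        a, b = particle2d(0, 0), particle2d(4, 8)
        amp = 0.7
        devs = []
        for seed in range(300):
            p = init_trial_path((a, b), _params(6, noise_amplitude=amp,
                                                seed=seed))
            assert np.array_equal(p.coords[0], a.positions)
            assert np.array_equal(p.coords[-1], b.positions)
            frac = np.arange(7)[:, None, None] / 6
            lin = (1 - frac) * a.positions + frac * b.positions
            devs.append(np.linalg.norm((p.coords - lin)[1:6], axis=2))
        # per-atom displacement is a 3-D Gaussian: E|d| = amp √(8/π) ... for
        # the Monte-Carlo check the rms is cleaner: E|d|² = 3 amp²
        rms = np.sqrt(np.mean(np.concatenate(devs) ** 2))
        assert abs(rms - amp * np.sqrt(3)) < 0.05 * amp * np.sqrt(3)


class TestMinimizeAction:
    def test_free_particle_converges_to_uniform_line(self):
        a, b = particle2d(0, 0), particle2d(3, 4)
        params = _params(12, noise_amplitude=0.4, seed=7,
                         max_iterations=20000, gradient_tolerance=1e-13)
        path, report = minimize_action(init_trial_path((a, b), params),
                                       ZeroPotential(), params)
        frac = np.arange(13)[:, None, None] / 12
        lin = (1 - frac) * a.positions + frac * b.positions
        assert np.abs(path.coords - lin).max() < 1e-8
        assert np.array_equal(path.coords[0], a.positions)
        assert np.array_equal(path.coords[-1], b.positions)

    def test_harmonic_oscillator_matches_analytic_bvp(self):
        # boundary-value solution x(t) = A cos ωt + B sin ωt, τ off-resonance
        w, tau, x0, x1 = 1.0, 2.0, 1.0, 0.5
        A = x0
        B = (x1 - x0 * np.cos(w * tau)) / np.sin(w * tau)
        prev_dev = None
        for P in (25, 50, 100):
            dt = tau / P
            params = _params(P, delta_t=dt, noise_amplitude=0.1, seed=2,
                             max_iterations=20000, gradient_tolerance=1e-12)
            pa, pb = particle2d(x0, 0), particle2d(x1, 0)
            path, _ = minimize_action(init_trial_path((pa, pb), params),
                                      HarmonicWell(k=w * w), params)
            t = np.arange(P + 1) * dt
            exact = A * np.cos(w * t) + B * np.sin(w * t)
            dev = np.abs(path.coords[:, 0, 0] - exact).max()
            if prev_dev is not None:
                assert dev < prev_dev
            prev_dev = dev
        assert prev_dev < 1e-3

    def test_penalized_action_non_increasing_over_iterates(self):
        pa, pb = particle2d(1, 0), particle2d(0.5, 0)
        params = _params(30, delta_t=0.05, noise_amplitude=0.2, seed=5,
                         penalty_weight=1.0, target_margin=0.2,
                         max_iterations=2000, gradient_tolerance=1e-9)
        _, report = minimize_action(init_trial_path((pa, pb), params),
                                    HarmonicWell(k=1.0), params)
        hist = np.array(report.action_history)
        assert len(hist) > 3
        assert np.all(np.diff(hist) <= 1e-9)


class TestPathwayBarrier:
    def test_downhill_path_has_zero_barrier_at_start(self):
        path = _line_path(np.arange(5.0))
        barrier, j = pathway_barrier(path, SeriesPotential([4, 3, 2, 1, 0]))
        assert barrier == 0.0 and j == 0

    def test_crafted_series_maximum(self):
        path = _line_path(np.arange(5.0))
        barrier, j = pathway_barrier(path, SeriesPotential([0, 2, 5, 1, 0]))
        assert barrier == 5.0 and j == 2

    def test_tie_broken_by_smallest_index(self):
        path = _line_path(np.arange(5.0))
        _, j = pathway_barrier(path, SeriesPotential([0, 3, 1, 3, 0]))
        assert j == 1

    def test_random_series_matches_scan_oracle(self, rng):
        for _ in range(50):
            table = rng.normal(size=8)
            path = _line_path(np.arange(8.0))
            barrier, j = pathway_barrier(path, SeriesPotential(table))
            assert barrier == pytest.approx(max(table) - table[0])
            assert j == int(np.argmax(table))


class TestRunEnsemble:
    def test_singleton_run_is_selected(self):
        pa, pb = particle2d(-1, 0), particle2d(1, 0)
        params = _params(20, delta_t=0.2, noise_amplitude=0.1, seed=3,
                         penalty_weight=1.0, max_iterations=2000,
                         gradient_tolerance=1e-8)
        ens = run_ensemble((pa, pb), DoubleWell(barrier=2.0), params, n_runs=1)
        assert ens.selected_index == 0
        assert ens.selected.seed == 3

    def test_selection_equals_exhaustive_barrier_comparison(self):
        pa, pb = particle2d(-1, 0), particle2d(1, 0)
        params = _params(20, delta_t=0.2, noise_amplitude=0.3, seed=0,
                         penalty_weight=1.0, max_iterations=2000,
                         gradient_tolerance=1e-8)
        pot = DoubleWell(barrier=2.0)
        ens = run_ensemble((pa, pb), pot, params, n_runs=5)
        # oracle: recompute each barrier and compare orderings
        barriers = [pathway_barrier(r.path, pot)[0] for r in ens.runs]
        best = min(range(5), key=lambda k: (barriers[k],
                                            ens.runs[k].mean_potential, k))
        assert ens.selected_index == best

    def test_duplicate_seeds_rejected(self, mimic):
        pa, pb = particle2d(-1, 0), particle2d(1, 0)
        with pytest.raises(ValueError):
            run_ensemble((pa, pb), DoubleWell(), _params(10), n_runs=2,
                         seeds=[1, 1])

    def test_deterministic_for_identical_seeds(self):
        pa, pb = particle2d(-1, 0), particle2d(1, 0)
        params = _params(16, delta_t=0.2, noise_amplitude=0.2, seed=0,
                         penalty_weight=1.0, max_iterations=1500,
                         gradient_tolerance=1e-8)
        e1 = run_ensemble((pa, pb), DoubleWell(), params, n_runs=2)
        e2 = run_ensemble((pa, pb), DoubleWell(), params, n_runs=2)
        assert e1.selected_index == e2.selected_index
        assert np.array_equal(e1.selected.path.coords, e2.selected.path.coords)


class TestRefinementConsistency:
    def test_doubling_p_changes_barrier_under_5_percent(self):
        # re-interpolate a converged double-well path at 2P and re-optimize
        pa, pb = particle2d(-1, 0), particle2d(1, 0)
        pot = DoubleWell(barrier=2.0)
        P = 24
        params = _params(P, delta_t=0.2, noise_amplitude=0.1, seed=1,
                         penalty_weight=1.0, max_iterations=4000,
                         gradient_tolerance=1e-9)
        path, _ = minimize_action(init_trial_path((pa, pb), params), pot,
                                  params)
        b1, _ = pathway_barrier(path, pot)
        fine = np.empty((2 * P + 1, 1, 3))
        fine[::2] = path.coords
        fine[1::2] = 0.5 * (path.coords[:-1] + path.coords[1:])
        params2 = _params(2 * P, delta_t=0.1, noise_amplitude=0.0,
                          penalty_weight=1.0, max_iterations=4000,
                          gradient_tolerance=1e-9)
        path2, _ = minimize_action(Path(fine, path.topology, delta_t=0.1),
                                   pot, params2)
        b2, _ = pathway_barrier(path2, pot)
        assert abs(b2 - b1) / b1 < 0.05
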