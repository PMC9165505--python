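import numpy as np
import pytest
from dataclasses import replace

from nemaflow.dielectric import DielectricParams, delta_eps
from nemaflow.simulator import (
    QTensorField,
    SimulationConfig,
    SimulationDivergedError,
    bulk_energy_density,
    free_energy,
    init_random,
    mean_director_angle,
    protocol_schedule,
    run_protocol,
    senescence_sweep,
    site_order,
    step,
)


def small_config(**kw):
    defaults = dict(grid_nx=8, grid_ny=8, seed=1)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def uniform_uniaxial_field(config, s, theta_deg):
    th = np.radians(theta_deg)
    n = np.array([np.cos(th), np.sin(th), 0.0])
    q0 = s * (np.outer(n, n) - np.eye(3) / 3.0)
    q = np.broadcast_to(q0, (config.grid_ny, config.grid_nx, 3, 3)).copy()
    b = np.full((config.grid_ny, config.grid_nx), -1.0)
    return QTensorField(q=q, b_site=b)


class TestInitRandom:
    def test_deterministic(self):
        cfg = small_config(seed=42)
        f1, f2 = init_random(cfg), init_random(cfg)
        assert np.array_equal(f1.q, f2.q)
        assert np.array_equal(f1.b_site, f2.b_site)

    def test_disk_fraction_counts(self):
        n = 8 * 8
        for p, expect in ((0.0, 0), (1.0, n), (0.5, 32), (0.3, round(0.3 * n))):
            f = init_random(small_config(disk_fraction=p))
            assert int((f.b_site == 1).sum()) == expect

    def test_traceless_symmetric(self):
        f = init_random(small_config())
        assert np.abs(np.einsum("...ii->...", f.q)).max() < 1e-12
        assert np.abs(f.q - np.swapaxes(f.q, -1, -2)).max() == 0

    def test_initial_order_magnitude(self):
        cfg = small_config(s_init=0.05)
        s, _ = site_order(init_random(cfg))
        assert np.allclose(s, 0.05, atol=1e-10)


class TestFreeEnergy:
    def test_zero_field_zero_energy(self):
        cfg = small_config()
        f = uniform_uniaxial_field(cfg, 0.0, 0.0)
        assert free_energy(f, cfg, cfg.omega_zero) == pytest.approx(0.0, abs=1e-15)

    def test_uniform_uniaxial_matches_scalar_oracle(self):
        # E decoupled at the zero-crossing frequency; elastic term vanishes
        cfg = small_config()
        s = 0.4
        f = uniform_uniaxial_field(cfg, s, 30.0)
        expected = 64 * cfg.dx**2 * bulk_energy_density(
            s, cfg.A_coef, -1.0, cfg.C_coef
        )
        assert free_energy(f, cfg, cfg.omega_zero) == pytest.approx(expected, rel=1e-12)

    def test_gradient_flow_decreases_energy(self):
        cfg = small_config()
        f = init_random(cfg)
        before = free_energy(f, cfg, 1.1)
        after = free_energy(step(f, cfg, 1.1), cfg, 1.1)
        assert after <= before

    def test_lyapunov_over_run(self):
        cfg = small_config(grid_nx=12, grid_ny=12)
        f = init_random(cfg)
        prev = free_energy(f, cfg, 6.3)
        for _ in range(1500):
            f = step(f, cfg, 6.3)
            cur = free_energy(f, cfg, 6.3)
            assert cur <= prev + 1e-8 * abs(prev) + 1e-12
            prev = cur


class TestStep:
    def test_zero_is_fixed_point_without_field(self):
        cfg = small_config(E_vec=(0.0, 0.0, 0.0))
        f = uniform_uniaxial_field(cfg, 0.0, 0.0)
        out = step(f, cfg, 1.1)
        assert np.abs(out.q).max() == 0.0

    def test_preserves_symmetric_traceless(self):
        cfg = small_config()
        f = init_random(cfg)
        for _ in range(50):
            f = step(f, cfg, 1.1)
        assert np.abs(np.einsum("...ii->...", f.q)).max() < 1e-10
        assert np.abs(f.q - np.swapaxes(f.q, -1, -2)).max() < 1e-14

    def test_trace_preserved_over_long_run(self):
        cfg = SimulationConfig(grid_nx=4, grid_ny=4, seed=3)
        f = init_random(cfg)
        worst = 0.0
        for _ in range(10_000):
            f = step(f, cfg, 1.1)
            worst = max(worst, np.abs(np.einsum("...ii->...", f.q)).max())
        assert worst < 1e-9

    def test_divergence_error_names_dt(self):
        cfg = small_config(dt=50.0)
        f = init_random(cfg)
        with pytest.raises(SimulationDivergedError, match="dt"):
            for _ in range(100):
                f = step(f, cfg, 1.1)

    def test_single_site_converges_to_bulk_minimizer(self):
        # rod-like, no field: S relaxes to the positive minimizer of the
        # scalar bulk energy, found independently by 1D minimization
        cfg = SimulationConfig(grid_nx=1, grid_ny=1, seed=5, E_vec=(0, 0, 0))
        f = init_random(cfg)
        for _ in range(4000):
            f = step(f, cfg, 1.1)
        s_grid = np.linspace(0.01, 1.0, 20000)
        oracle = s_grid[
            np.argmin(bulk_energy_density(s_grid, cfg.A_coef, -1.0, cfg.C_coef))
        ]
        s, _ = site_order(f)
        assert s[0, 0] == pytest.approx(oracle, abs=1e-4)


class TestScalarODEOracle:
    """On a 1x1 lattice the dynamics reduce to a scalar ODE in S."""

    def _oracle(self, s0, steps, dt, A, B, C, gamma, drive):
        s = s0
        for _ in range(steps):
            s = s + dt * gamma * (-(A * s + B * s * s / 3 + 2 * C * s**3 / 3) + drive)
        return s

    def test_no_field(self):
        cfg = SimulationConfig(grid_nx=1, grid_ny=1, seed=2, E_vec=(0, 0, 0))
        f = init_random(cfg)
        for _ in range(2000):
            f = step(f, cfg, 1.1)
        s_oracle = self._oracle(
            cfg.s_init, 2000, cfg.dt, cfg.A_coef, -1.0, cfg.C_coef, cfg.Gamma, 0.0
        )
        s, _ = site_order(f)
        assert abs(s[0, 0] - s_oracle) < 1e-6

    def test_with_field_aligned(self):
        # director along x = field axis: uniaxiality is preserved and the
        # field adds a constant drive delta_eps * |E|^2 / 2
        cfg = SimulationConfig(grid_nx=1, grid_ny=1, seed=2)
        de = delta_eps(cfg.dielectric, 1.1)
        f = uniform_uniaxial_field(replace(cfg, grid_nx=1, grid_ny=1), 0.1, 0.0)
        for _ in range(3000):
            f = step(f, cfg, 1.1)
        s_oracle = self._oracle(
            0.1, 3000, cfg.dt, cfg.A_coef, -1.0, cfg.C_coef, cfg.Gamma, de / 2.0
        )
        s, _ = site_order(f)
        assert abs(s[0, 0] - s_oracle) < 1e-6

    def test_director_angle_constant_without_field(self):
        cfg = SimulationConfig(grid_nx=1, grid_ny=1, seed=9, E_vec=(0, 0, 0))
        f = init_random(cfg)
        _, n0 = site_order(f)
        for _ in range(1000):
            f = step(f, cfg, 1.1)
        _, n1 = site_order(f)
        cosang = abs(np.dot(n0[0, 0], n1[0, 0]))
        assert cosang == pytest.approx(1.0, abs=1e-8)


class TestSiteOrder:
    def test_round_trip_prolate(self):
        cfg = small_config()
        f = uniform_uniaxial_field(cfg, 0.6, 0.0)
        s, n = site_order(f)
        assert np.allclose(s, 0.6, atol=1e-12)
        assert np.allclose(np.abs(n[..., 0]), 1.0, atol=1e-12)

    def test_round_trip_random_uniaxial(self, rng):
        for _ in range(20):
            s_true = rng.uniform(-0.45, 0.9)
            th = rng.uniform(0, np.pi)
            n_true = np.array([np.cos(th), np.sin(th), 0.0])
            q = s_true * (np.outer(n_true, n_true) - np.eye(3) / 3.0)
            f = QTensorField(
                q=q[None, None], b_site=np.full((1, 1), -1.0)
            )
            s, n = site_order(f)
            assert abs(s[0, 0] - s_true) < 1e-10
            if s_true > 0.01:
                assert abs(abs(np.dot(n[0, 0], n_true)) - 1.0) < 1e-10

    def test_zero_tensor_flagged(self):
        f = QTensorField(q=np.zeros((1, 1, 3, 3)), b_site=np.full((1, 1), -1.0))
        s, n = site_order(f)
        assert s[0, 0] == 0.0
        assert np.all(np.isnan(n[0, 0]))

    def test_oblate_state_reports_negative_order_and_no_director(self):
        # oblate uniaxial: top eigenvalues degenerate
        f = uniform_uniaxial_field(small_config(grid_nx=1, grid_ny=1), -0.3, 0.0)
        s, n = site_order(f)
        assert s[0, 0] == pytest.approx(-0.3, abs=1e-12)
        assert np.all(np.isnan(n[0, 0]))


class TestProtocols:
    def test_schedule_validation(self):
        cfg = small_config()
        with pytest.raises(ValueError):
            run_protocol(cfg, [])
        with pytest.raises(ValueError):
            run_protocol(cfg, [(1.1, 10.0), (6.3, 5.0)])
        with pytest.raises(ValueError, match="unknown protocol"):
            protocol_schedule("fig9z", cfg)

    def test_canned_schedules(self):
        cfg = small_config()
        sched = protocol_schedule("fig4a", cfg)
        assert [t for _, t in sched] == [100.0, 250.0, 500.0]
        assert sched[1][0] == cfg.omega_low
        assert sched[2][0] == cfg.omega_high

    def test_trace_shapes_consistent(self):
        cfg = small_config(snapshot_interval=2.0)
        tr = run_protocol(cfg, [(cfg.omega_zero, 5.0), (1.1, 10.0)])
        n = len(tr.times)
        assert len(tr.mean_S) == n
        assert len(tr.free_energy) == n
        assert len(tr.director_angle) == n
        assert tr.S_heatmaps.shape[0] == n
        assert np.all(np.isfinite(tr.free_energy))
        assert tr.switch_times == (pytest.approx(5.0),)

    def test_zero_anisotropy_schedule_ignores_field_direction(self):
        cfg = small_config(seed=4)
        tr_x = run_protocol(cfg, [(cfg.omega_zero, 10.0)])
        cfg_y = replace(cfg, E_vec=(0.0, 1.0, 0.0))
        tr_y = run_protocol(cfg_y, [(cfg_y.omega_zero, 10.0)])
        assert np.allclose(tr_x.mean_S, tr_y.mean_S, atol=1e-12)

    def test_bistability_small_lattice(self):
        # reduced-size version of the fig3 contract: same seeded start,
        # omega_low -> parallel, omega_high -> perpendicular
        cfg = SimulationConfig(grid_nx=16, grid_ny=16, seed=3)
        w0 = cfg.omega_zero
        tr_l = run_protocol(cfg, [(w0, 40.0), (cfg.omega_low, 120.0)])
        tr_h = run_protocol(cfg, [(w0, 40.0), (cfg.omega_high, 120.0)])
        assert tr_l.director_angle[-1] < 5.0
        assert tr_h.director_angle[-1] > 85.0
        assert tr_l.mean_S[-1] > 0.5 * tr_l.mean_S.max()
        assert tr_h.mean_S[-1] > 0.5 * tr_h.mean_S.max()

    def test_deterministic_given_seed(self):
        cfg = small_config(seed=8)
        tr1 = run_protocol(cfg, [(cfg.omega_zero, 5.0), (1.1, 15.0)])
        tr2 = run_protocol(cfg, [(cfg.omega_zero, 5.0), (1.1, 15.0)])
        assert np.array_equal(tr1.mean_S, tr2.mean_S)
        assert np.array_equal(tr1.free_energy, tr2.free_energy)


class TestRobustnessGrid:
    """Bistable outcomes across field strengths and anisotropy magnitudes.

    Exercised on a single site starting from a tilted ordered state; the
    weak-coupling corner is checked for monotone drift toward the target
    orientation rather than full convergence.
    """

    @pytest.mark.parametrize("ex", [0.3, 1.5])
    @pytest.mark.parametrize("de_mag", [0.02, 0.36])
    @pytest.mark.parametrize("sign", [+1, -1])
    def test_corner(self, ex, de_mag, sign):
        if sign > 0:
            diel = DielectricParams(
                eps_par_0=0.5, eps_par_inf=0.01, eps_perp=0.5 - de_mag, tau=0.6
            )
            omega = 0.0
        else:
            diel = DielectricParams(
                eps_par_0=0.5, eps_par_inf=0.01, eps_perp=0.01 + de_mag, tau=0.6
            )
            omega = 1e9
        assert delta_eps(diel, omega) == pytest.approx(sign * de_mag, abs=1e-6)
        cfg = SimulationConfig(
            grid_nx=1,
            grid_ny=1,
            seed=1,
            dt=0.1,
            E_vec=(ex, 0.0, 0.0),
            dielectric=diel,
        )
        f = uniform_uniaxial_field(cfg, 0.45, 20.0)
        drive = de_mag * ex**2
        t_total = min(60.0 / drive, 4000.0)
        start = mean_director_angle(f)
        for _ in range(int(t_total / cfg.dt)):
            f = step(f, cfg, omega)
        ang = mean_director_angle(f)
        s, _ = site_order(f)
        assert s[0, 0] > 0.3  # stays ordered
        if drive >= 0.01:
            # strong corners converge outright
            assert (ang < 5.0) if sign > 0 else (ang > 85.0)
        else:
            # weakest corner: clear monotone progress toward the target
            assert (ang < 0.5 * start) if sign > 0 else (ang > 90.0 - 0.5 * (90.0 - start))


class TestSenescence:
    def test_pure_disks_fail_to_order(self):
        cfg = SimulationConfig(grid_nx=12, grid_ny=12, seed=7)
        tab = senescence_sweep(
            cfg, [0.0, 1.0], omega=1.1, replicates=1,
            equilibration_time=40.0, field_time=80.0,
        )
        s0, s1 = tab.mean_S.iloc[0], tab.mean_S.iloc[1]
        assert s0 > 0.4
        assert s1 <= 0.5 * s0

    def test_decoupled_mixture_linearity(self):
        cfg = SimulationConfig(
            grid_nx=12, grid_ny=12, seed=7, coupling_mode="decoupled"
        )
        fr = [0.0, 0.5, 1.0]
        tab = senescence_sweep(
            cfg, fr, omega=1.1, replicates=1,
            equilibration_time=40.0, field_time=80.0,
        )
        s0, s1 = tab.mean_S.iloc[0], tab.mean_S.iloc[-1]
        n = 12 * 12
        p_real = round(0.5 * n) / n
        predicted = (1 - p_real) * s0 + p_real * s1
        assert tab.mean_S.iloc[1] == pytest.approx(predicted, abs=5e-3)

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            senescence_sweep(small_config(), [0.5, 1.2], omega=1.1)


class TestConfigValidation:
    def test_bad_values(self):
        with pytest.raises(ValueError):
            SimulationConfig(C_coef=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(disk_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(coupling_mode="sideways")
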