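import numpy as np
import pytest
from scipy.special import j0, j1, jn_zeros

from retortsim import (
    CanGeometry,
    SolverConfig,
    StateField,
    ThermoPhysicalProperties,
    advance,
    analytic_cylinder_temperature,
    build_mesh,
    chestnut_puree,
    constant_properties,
    default_can,
    initialize_state,
    interp_temperature,
    parse_schedule,
    simulate,
)
from retortsim.lethality import lethal_rate
from retortsim.schedule import Phase, RetortSchedule
from retortsim.solver import _divergence_rms, _get_disc, _stokes_step


def step_schedule(T_wall, hold_s=20_000.0):
    """Wall stepped to T_wall at t = 0+ (for analytic-conduction oracles)."""
    return RetortSchedule(
        phases=(Phase("come_up", 1e-6, T_wall),
                Phase("hold", hold_s, T_wall),
                Phase("cool", 60.0, 298.15)),
        come_up_start_temperature=T_wall,
        cooling_water_temperature=298.15,
    )


class TestInitializeState:
    def test_uniform_and_quiescent(self, coarse_config):
        st = initialize_state(coarse_config)
        assert np.all(st.T == coarse_config.initial_temperature)
        assert st.max_speed() == 0.0
        mesh = coarse_config.mesh
        assert mesh.volume_average(st.T) == pytest.approx(341.15)

    def test_initial_temperature_outside_property_range(self, coarse_mesh, puree):
        with pytest.raises(ValueError):
            SolverConfig(mesh=coarse_mesh, properties=puree,
                         initial_temperature=200.0)


class TestAdvance:
    def test_isothermal_fixed_point(self, coarse_mesh, puree):
        """Uniform temperature equal to the wall temperature is a fixed
        point: no gradients, no buoyancy differential, no flow."""
        cfg = SolverConfig(mesh=coarse_mesh, properties=puree,
                          mode="convection", dt=5.0)
        sched = step_schedule(cfg.initial_temperature)
        st = initialize_state(cfg)
        for _ in range(3):
            st = advance(st, sched, cfg)
        assert st.T == pytest.approx(
            np.full_like(st.T, cfg.initial_temperature), abs=1e-9)
        assert st.max_speed() < 1e-12

    def test_zero_gravity_means_zero_velocity(self, coarse_mesh, puree):
        cfg = SolverConfig(mesh=coarse_mesh, properties=puree,
                          mode="convection", dt=2.0, gravity=0.0)
        sched = parse_schedule("10-86-24/121")
        st = initialize_state(cfg)
        for _ in range(10):
            st = advance(st, sched, cfg)
        assert st.max_speed() < 1e-14
        assert st.T.max() > 341.2  # it is heating, just not flowing

    def test_divergence_free_and_bounded(self, coarse_config):
        sched = parse_schedule("10-86-24/121")
        st = initialize_state(coarse_config)
        disc = _get_disc(coarse_config)
        for _ in range(30):
            st = advance(st, sched, coarse_config)
            assert _divergence_rms(disc, st.u_r, st.u_z) <= 1e-6
            # discrete maximum principle
            assert st.T.min() >= 298.15 - 0.5
            assert st.T.max() <= 394.15 + 0.5


class TestConductionOracle:
    def test_matches_fourier_bessel_series(self, puree):
        """Conduction solve vs the separable series at Fourier number 0.1:
        agreement within 1 % of the imposed temperature difference."""
        props = constant_properties(density=1070.0, viscosity=35.0,
                                    conductivity=0.58, specific_heat=3860.0)
        alpha = 0.58 / (1070.0 * 3860.0)
        can = default_can()
        R, H = can.inner_radius, can.inner_height
        t_end = 0.1 * R ** 2 / alpha
        mesh = build_mesh(can, nr=48, nz=96, include_headspace=False)
        cfg = SolverConfig(mesh=mesh, properties=props, mode="conduction",
                          dt=t_end / 350.0, initial_temperature=341.15)
        T_wall, T_0 = 394.15, 341.15
        sched = step_schedule(T_wall)
        st = initialize_state(cfg)
        while st.time < t_end - 1e-9:
            st = advance(st, sched, cfg, dt=min(cfg.dt, t_end - st.time))
        for (r, z) in [(0.0, H / 2), (R / 2, H / 2), (0.0, H / 4),
                       (R / 3, 2 * H / 3)]:
            exact = analytic_cylinder_temperature(
                r, z, t_end, alpha, T_wall, T_0, R, H, n_terms=60)
            num = interp_temperature(mesh, st.T, r, z)
            assert abs(num - exact) < 0.01 * (T_wall - T_0)

    def test_oracle_limits(self):
        alpha, R, H = 1.4e-7, 0.05, 0.12
        assert analytic_cylinder_temperature(
            0.01, 0.05, 0.0, alpha, 394.0, 341.0, R, H) == 341.0
        assert analytic_cylinder_temperature(
            0.01, 0.05, 1e9, alpha, 394.0, 341.0, R, H) == pytest.approx(394.0)
        with pytest.raises(ValueError):
            analytic_cylinder_temperature(0.0, 0.0, -1.0, alpha, 394.0,
                                          341.0, R, H)

    def test_oracle_against_fine_grid_solve(self):
        """Series center value at Fo = 0.2 vs a 96x192 brute-force solve."""
        props = constant_properties(density=1070.0, conductivity=0.58,
                                    specific_heat=3860.0)
        alpha = 0.58 / (1070.0 * 3860.0)
        can = default_can()
        R, H = can.inner_radius, can.inner_height
        t_end = 0.2 * R ** 2 / alpha
        mesh = build_mesh(can, nr=96, nz=192, include_headspace=False)
        cfg = SolverConfig(mesh=mesh, properties=props, mode="conduction",
                          dt=t_end / 400.0, initial_temperature=341.15)
        T_wall = 394.15
        sched = step_schedule(T_wall)
        st = initialize_state(cfg)
        while st.time < t_end - 1e-9:
            st = advance(st, sched, cfg, dt=min(cfg.dt, t_end - st.time))
        exact = analytic_cylinder_temperature(
            0.0, H / 2, t_end, alpha, T_wall, 341.15, R, H, n_terms=60)
        num = interp_temperature(mesh, st.T, 0.0, H / 2)
        assert abs(num - exact) < 0.005 * (T_wall - 341.15)


class TestConservationAndSymmetry:
    def test_insulated_energy_conservation(self):
        """Zero-flux boundaries, no source: total rho*Cp*T drifts < 0.1 %
        over 1000 conduction steps with constant properties."""
        props = constant_properties()
        mesh = build_mesh(default_can(), nr=12, nz=24)
        cfg = SolverConfig(mesh=mesh, properties=props, mode="conduction",
                          dt=10.0, boundary="insulated",
                          initial_temperature=341.15)
        st = initialize_state(cfg)
        # non-uniform start: a smooth hot blob
        rr, zz = np.meshgrid(mesh.r_centers, mesh.z_centers, indexing="ij")
        st.T = 341.15 + 20.0 * np.exp(
            -((rr / 0.02) ** 2 + ((zz - 0.06) / 0.03) ** 2))
        rhocp = np.where(mesh.puree_mask, 1070.0 * 3860.0, 0.8 * 2000.0)
        sched = step_schedule(394.15)  # irrelevant under insulated walls
        e0 = float((rhocp * mesh.cell_volumes * st.T).sum())
        for _ in range(1000):
            st = advance(st, sched, cfg)
        e1 = float((rhocp * mesh.cell_volumes * st.T).sum())
        assert abs(e1 - e0) / e0 < 1e-3

    def test_midplane_symmetry_without_headspace(self):
        props = constant_properties()
        mesh = build_mesh(default_can(), nr=10, nz=24, include_headspace=False)
        cfg = SolverConfig(mesh=mesh, properties=props, mode="conduction",
                          dt=20.0, initial_temperature=341.15)
        sched = step_schedule(394.15)
        st = initialize_state(cfg)
        for _ in range(40):
            st = advance(st, sched, cfg)
        assert st.T == pytest.approx(st.T[:, ::-1], rel=1e-9)


class TestStokesOracles:
    def test_uniform_buoyancy_stays_quiescent(self):
        """A uniformly buoyant (hydrostatically balanced) fill must not
        flow; splitting errors would show up here as spurious currents."""
        geom = CanGeometry(inner_radius=0.05, inner_height=0.3,
                           headspace_height=0.01)
        mesh = build_mesh(geom, 12, 40, include_headspace=False)
        props = ThermoPhysicalProperties(
            name="lin", density_coeffs=(-1.0, 1341.15),
            viscosity_coeffs=(10.0,), conductivity_coeffs=(0.6,),
            specific_heat=4000.0, valid_range=(1.0, 1e4),
            extrapolation_policy="extrapolate")
        cfg = SolverConfig(mesh=mesh, properties=props, mode="convection",
                          dt=100.0, initial_temperature=341.15)
        disc = _get_disc(cfg)
        st = initialize_state(cfg)
        st.T[:, :] = 342.15
        for _ in range(3):
            u_r, u_z, P = _stokes_step(disc, cfg, st, cfg.dt)
            st = StateField(T=st.T, u_r=u_r, u_z=u_z, P=P, time=0.0)
        assert st.max_speed() < 1e-12

    def test_bessel_mode_velocity_profile(self):
        """Steady creeping flow under a two-mode Bessel body force with zero
        net axial flux has the closed-form profile u_z(r) = A1 J0(l1 r/R)
        + A2 J0(l2 r/R); checked at mid-height of a tall can."""
        R, H, mu_v, g = 0.05, 0.5, 10.0, 9.81
        l1, l2 = jn_zeros(0, 2)
        A1 = 1e-4
        A2 = -A1 * (j1(l1) / l1) / (j1(l2) / l2)
        geom = CanGeometry(inner_radius=R, inner_height=H,
                           headspace_height=0.01)
        mesh = build_mesh(geom, 24, 120, include_headspace=False)
        props = ThermoPhysicalProperties(
            name="lin", density_coeffs=(-1.0, 1341.15),
            viscosity_coeffs=(mu_v,), conductivity_coeffs=(0.6,),
            specific_heat=4000.0, valid_range=(1.0, 1e4),
            extrapolation_policy="extrapolate")
        cfg = SolverConfig(mesh=mesh, properties=props, mode="convection",
                          dt=1e6, initial_temperature=341.15)
        disc = _get_disc(cfg)
        st = initialize_state(cfg)
        r = mesh.r_centers
        force = mu_v * (A1 * (l1 / R) ** 2 * j0(l1 * r / R)
                        + A2 * (l2 / R) ** 2 * j0(l2 * r / R))
        st.T[:, :] = 341.15 + force[:, None] / g  # encode force via buoyancy
        for _ in range(3):
            u_r, u_z, P = _stokes_step(disc, cfg, st, cfg.dt)
            st = StateField(T=st.T, u_r=u_r, u_z=u_z, P=P, time=0.0)
        jmid = mesh.nz // 2
        exact = A1 * j0(l1 * r / R) + A2 * j0(l2 * r / R)
        err = np.abs(st.u_z[:, jmid] - exact).max() / np.abs(exact).max()
        assert err < 0.02


class TestSimulate:
    def test_probe_outside_puree_rejected(self, coarse_config):
        sched = parse_schedule("10-86-24/121")
        with pytest.raises(ValueError):
            simulate(coarse_config, sched, probes=[(0.0, 0.2)])

    def test_cool_only_schedule_bounds_lethal_rate(self, puree):
        """Holds below the initial temperature can never push the lethal
        rate above its initial-temperature value (maximum principle)."""
        mesh = build_mesh(default_can(), nr=8, nz=16)
        cfg = SolverConfig(mesh=mesh, properties=puree, mode="conduction",
                          dt=10.0)
        sched = parse_schedule("5-10-5/60")  # 60 degC holds, below T_0
        res = simulate(cfg, sched, probes=[])
        cap = 10.0 ** ((341.15 - 394.25) / 10.0)
        for snap in res.snapshots:
            assert lethal_rate(snap.T).max() <= cap * 1.0001

    def test_velocity_rises_then_relaxes_and_reverses(self, puree):
        """Buoyant flow weakens as gradients relax through the hold, and
        the circulation reverses shortly after cooling begins."""
        mesh = build_mesh(default_can(), nr=16, nz=32)
        cfg = SolverConfig(mesh=mesh, properties=puree, mode="convection",
                          dt=2.0, snapshot_interval=60.0)
        sched = parse_schedule("5-25-10/121")
        res = simulate(cfg, sched, probes=[])
        t = res.probe_times
        speed = res.speed_history
        hold_start, hold_end = 300.0, 1800.0
        early = speed[(t > hold_start + 100) & (t < hold_start + 300)].mean()
        late = speed[(t > hold_end - 300) & (t < hold_end - 100)].mean()
        assert late < early
        # direction reversal: near-wall mid-height axial velocity is upward
        # during the hold and downward within 5 min of cooling onset
        jmid = mesh.n_puree_rows // 2
        def near_wall_uz(time_s):
            k = int(np.argmin(np.abs(res.snapshot_times - time_s)))
            return res.snapshots[k].u_z[-1, jmid]
        assert near_wall_uz(1500.0) > 0
        assert near_wall_uz(hold_end + 240.0) < 0

    def test_probe_series_and_interp(self, puree):
        mesh = build_mesh(default_can(), nr=8, nz=16)
        cfg = SolverConfig(mesh=mesh, properties=puree, mode="conduction",
                          dt=30.0)
        sched = parse_schedule("2-5-2/121")
        res = simulate(cfg, sched, probes=[(0.0, 0.02), (0.02, 0.06)])
        assert res.probe_temperatures.shape == (2, res.probe_times.size)
        assert np.all(np.diff(res.probe_times) > 0)
        # probes heat monotonically during come-up + hold
        heat_sel = res.probe_times <= 420.0
        assert np.all(np.diff(res.probe_temperatures[0][heat_sel]) >= -1e-9)
        # fmin history is non-decreasing (F accumulates)
        assert np.all(np.diff(res.fmin_history) >= 0)

    def test_interp_temperature_reproduces_bilinear_field(self, coarse_mesh):
        T = 2.0 + 3.0 * coarse_mesh.r_centers[:, None] \
            + 5.0 * coarse_mesh.z_centers[None, :]
        for (r, z) in [(0.01, 0.03), (0.02, 0.09), (0.041, 0.0501)]:
            assert interp_temperature(coarse_mesh, T, r, z) == pytest.approx(
                2.0 + 3.0 * r + 5.0 * z, rel=1e-9)
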