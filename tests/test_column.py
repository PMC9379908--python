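"""Soil-column physics: initialization, water flow, transport, reactions,
root uptake and full-season ledgers, each against an independent oracle
where one exists (steady states, closed-form transport, scalar ODEs)."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.special import erfc

from splitfert import units
from splitfert.column import (
    ColumnState,
    FertilizerSchedule,
    GridConfig,
    InitialPools,
    ModelConfig,
    ReactionParams,
    TransportParams,
    UptakeParams,
    WaterFluxes,
    init_column,
    richards_step,
    simulate_season,
    transport_react_step,
)
from splitfert.hydraulics import SoilHydraulics
from splitfert.precip import SeasonForcing, extract_season
from splitfert.roots import root_profile
from splitfert.weather import generate_record, historic_like, wet_scenario


# ---------------------------------------------------------------------------
# Initialization


def test_initial_pools_integrate_exactly():
    cfg = ModelConfig()
    state = init_column(cfg)
    inv = state.n_inventory_kg_ha(cfg.transport)
    assert inv["no3"] == pytest.approx(41.6, rel=1e-12)
    assert inv["nh4"] == pytest.approx(6.6, rel=1e-12)
    assert inv["org"] == pytest.approx(191.0, rel=1e-12)


def test_zero_inventory_config():
    cfg = ModelConfig(pools=InitialPools(0.0, 0.0, 0.0))
    state = init_column(cfg)
    assert (state.c_no3 == 0).all() and (state.c_nh4 == 0).all() and (state.c_org == 0).all()


def test_node_halving_preserves_integrals():
    base = ModelConfig()
    fine = ModelConfig(grid=dataclasses.replace(base.grid, n_nodes=base.grid.n_nodes * 2))
    inv_a = init_column(base).n_inventory_kg_ha(base.transport)
    inv_b = init_column(fine).n_inventory_kg_ha(fine.transport)
    for k in inv_a:
        assert inv_b[k] == pytest.approx(inv_a[k], rel=1e-10)


def test_invalid_grid_rejected():
    with pytest.raises(ValueError):
        GridConfig(depth_cm=-1.0)
    with pytest.raises(ValueError):
        GridConfig(n_nodes=2)


# ---------------------------------------------------------------------------
# Water flow


def test_dry_hydrostatic_profile_is_stationary():
    """Equilibrium head profile (total head constant) with zero surface flux
    and negligible bottom conductivity stays put."""
    cfg = ModelConfig()
    hyd = cfg.hydraulics
    state = init_column(cfg)
    state.psi = -2500.0 + state.z  # hydrostatic: psi - z = const
    state.theta = hyd.theta(state.psi)
    psi0 = state.psi.copy()
    for _ in range(8):
        state, wf = richards_step(state, 0.25, hyd, 0.0)
    assert np.max(np.abs(state.psi - psi0)) < 1.0  # cm, solver tolerance scale
    assert abs(wf.drainage_cm) < 1e-4


def test_constant_rain_reaches_uniform_flux_steady_state():
    """Sustained rain q < Ks drives the column to the gravity-flow profile
    where K(theta) = q; the oracle inverts the conductivity curve."""
    cfg = ModelConfig()
    hyd = cfg.hydraulics
    q = 0.2 * hyd.Ks  # cm/day
    state = init_column(cfg)
    drain = 0.0
    for _ in range(30 * 4):  # 30 days at dt = 0.25
        state, wf = richards_step(state, 0.25, hyd, q)
        drain = wf.drainage_cm / 0.25
    theta_expected = hyd.theta_at_flux(q)
    interior = slice(2, -2)
    assert np.allclose(state.theta[interior], theta_expected, atol=2e-3)
    assert drain == pytest.approx(q, rel=0.01)


def test_season_water_ledger_closes(one_season):
    res = simulate_season(one_season, FertilizerSchedule(t1=20, t2=40))
    assert abs(res.balance_residual_water) < 0.005 * res.rain_mm + 1e-9


def test_infiltration_capacity_produces_runoff():
    cfg = ModelConfig()
    hyd = cfg.hydraulics
    state = init_column(cfg)
    rain = np.zeros(122)
    rain[:3] = 30 * hyd.Ks  # absurd storm, mm/day
    res = simulate_season(
        SeasonForcing(year=2000, rain=rain), FertilizerSchedule(t1=20, t2=40), cfg
    )
    assert res.runoff_mm > 0
    assert abs(res.balance_residual_water) < 0.005 * res.rain_mm


# ---------------------------------------------------------------------------
# Transport and reactions


def _saturated_state(cfg: ModelConfig) -> ColumnState:
    g, hyd = cfg.grid, cfg.hydraulics
    n = g.n_nodes
    return ColumnState(
        z=g.z, dz=g.dz, theta=np.full(n, hyd.theta_s), psi=np.zeros(n),
        c_no3=np.zeros(n), c_nh4=np.zeros(n), c_org=np.zeros(n),
    )


def test_breakthrough_matches_ogata_banks():
    """Saturated column, constant pore velocity, continuous inlet at c0:
    nitrate breakthrough reproduces the closed-form advection-dispersion
    solution within 2% of the inlet concentration at all output times."""
    hyd = SoilHydraulics()
    q, lam, c0 = 4.5, 2.0, 1.0
    v, D = q / hyd.theta_s, 2.0 * q / hyd.theta_s
    cfg = ModelConfig(
        hydraulics=hyd,
        transport=TransportParams(
            molecular_diffusion=0.0, dispersivity=lam,
            kd_ammonium=0.0, rain_n_concentration=c0,
        ),
        reactions=ReactionParams(0, 0, 0, 0, 0),
        uptake=UptakeParams(vmax_n=0.0),
        grid=GridConfig(depth_cm=60.0, n_nodes=240),
    )
    state = _saturated_state(cfg)
    z = state.z
    wf = WaterFluxes(np.full(241, q), 0, 0, 0, 0, 0)
    dt, t = 0.002, 0.0
    theta_old = state.theta
    for t_out in (1.0, 2.0, 3.0):
        while t < t_out - 1e-9:
            state, _ = transport_react_step(
                state, dt, wf, theta_old, cfg, dirichlet_inlet=True
            )
            t += dt
        with np.errstate(over="ignore"):
            tail = np.exp(np.minimum(v * z / D, 700.0)) * erfc(
                (z + v * t_out) / (2 * np.sqrt(D * t_out))
            )
        analytic = c0 * 0.5 * (
            erfc((z - v * t_out) / (2 * np.sqrt(D * t_out))) + tail
        )
        assert np.max(np.abs(state.c_no3 - analytic)) < 0.02 * c0


def test_no_flow_no_reaction_conserves_mass():
    cfg = ModelConfig(
        reactions=ReactionParams(0, 0, 0, 0, 0), uptake=UptakeParams(vmax_n=0.0)
    )
    state = init_column(cfg)
    wf = WaterFluxes(np.zeros(cfg.grid.n_nodes + 1), 0, 0, 0, 0, 0)
    before = state.n_inventory_mg_cm2(cfg.transport)
    for _ in range(200):
        state, _ = transport_react_step(state, 0.25, wf, state.theta, cfg)
    after = state.n_inventory_mg_cm2(cfg.transport)
    for k in before:
        assert after[k] == pytest.approx(before[k], rel=1e-8)


def test_reaction_only_organic_decay_matches_scalar_ode():
    """Well-mixed limit with a single rate k (org -> NH4, all reverse rates
    zero): the organic pool decays as exp(-k t); cross-checked against a
    scipy ODE solve of the full three-pool system."""
    k = 0.05
    cfg = ModelConfig(
        reactions=ReactionParams(k_org_to_nh4=k, k_nh4_to_org=0.0,
                                 k_org_to_no3=0.0, k_no3_to_org=0.0,
                                 k_nitrification=0.0),
        uptake=UptakeParams(vmax_n=0.0),
    )
    state = init_column(cfg)
    inv0 = state.n_inventory_mg_cm2(cfg.transport)
    org0 = inv0["org"]
    wf = WaterFluxes(np.zeros(cfg.grid.n_nodes + 1), 0, 0, 0, 0, 0)
    t_end, dt = 30.0, 0.25
    for _ in range(int(t_end / dt)):
        state, _ = transport_react_step(state, dt, wf, state.theta, cfg)
    inv = state.n_inventory_mg_cm2(cfg.transport)
    assert inv["org"] == pytest.approx(org0 * np.exp(-k * t_end), rel=1e-9)

    A = cfg.reactions.generator_matrix()
    sol = solve_ivp(
        lambda _, y: A @ y, (0, t_end), [inv0["no3"], inv0["nh4"], org0],
        rtol=1e-10, atol=1e-12,
    )
    assert inv["org"] == pytest.approx(sol.y[2, -1], rel=1e-5)
    assert inv["nh4"] == pytest.approx(sol.y[1, -1], rel=1e-5)


def test_ammonium_retardation_slows_ammonium():
    """With linear sorption, an ammonium pulse travels behind a nitrate
    pulse under identical advection."""
    cfg = ModelConfig(
        reactions=ReactionParams(0, 0, 0, 0, 0), uptake=UptakeParams(vmax_n=0.0)
    )
    state = _saturated_state(cfg)
    state.c_no3[:3] = 1.0
    state.c_nh4[:3] = 1.0
    q = 4.0
    wf = WaterFluxes(np.full(cfg.grid.n_nodes + 1, q), 0, 0, 0, 0, 0)
    for _ in range(40):
        state, _ = transport_react_step(state, 0.05, wf, state.theta, cfg)
    com_no3 = np.sum(state.z * state.c_no3) / np.sum(state.c_no3)
    com_nh4 = np.sum(state.z * state.c_nh4) / np.sum(state.c_nh4)
    assert com_no3 > com_nh4 + 1.0


# ---------------------------------------------------------------------------
# Full season


def test_applied_n_integrates_to_144(one_season):
    res = simulate_season(one_season, FertilizerSchedule(t1=17.3, t2=41.9))
    assert res.applied_n == pytest.approx(144.0, rel=1e-9)


def test_fractional_pulse_times_apply_exactly():
    sched = FertilizerSchedule(t1=20.5, t2=20.9)  # overlapping off-grid pulses
    total = sum(sched.flux_at(k * 0.25, (k + 1) * 0.25) for k in range(488))
    assert total == pytest.approx(144.0, rel=1e-12)


def test_season_nitrogen_ledger_closes(one_season):
    res = simulate_season(one_season, FertilizerSchedule(t1=20, t2=40))
    assert abs(res.balance_residual_n) < 0.01 * (res.initial_n + res.applied_n)
    assert res.uptake_n <= res.initial_n + res.applied_n
    assert res.uptake_n >= 0 and res.leached_n >= 0


def test_no_fertilizer_bounds_uptake(one_season):
    sched = FertilizerSchedule(t1=20, t2=40, total_n=0.0)
    res = simulate_season(one_season, sched)
    assert res.applied_n == 0.0
    assert res.uptake_n <= res.initial_n  # nothing applied, only soil N


def test_doubled_rainfall_increases_leaching():
    rec = generate_record(wet_scenario(n_years=1, seed=9))
    season = extract_season(rec, 1950)
    sched = FertilizerSchedule(t1=20, t2=40)
    base = simulate_season(season, sched)
    doubled = simulate_season(
        SeasonForcing(year=1950, rain=2.0 * season.rain), sched
    )
    assert doubled.leached_n > base.leached_n


def test_state_bounds_every_recorded_day(one_season):
    cfg = ModelConfig()
    res = simulate_season(one_season, FertilizerSchedule(t1=10, t2=30), cfg,
                          record_daily=True)
    d = res.daily
    assert (d["no3_kg_ha"] >= 0).all() and (d["nh4_kg_ha"] >= 0).all()
    assert (d["org_kg_ha"] >= 0).all()
    max_storage = units.cm_to_mm(cfg.hydraulics.theta_s * cfg.grid.depth_cm)
    min_storage = units.cm_to_mm(cfg.hydraulics.theta_r * cfg.grid.depth_cm)
    assert (d["storage_mm"] <= max_storage + 1e-6).all()
    assert (d["storage_mm"] >= min_storage - 1e-6).all()


def test_refining_grid_and_step_changes_uptake_under_2pct(one_season):
    sched = FertilizerSchedule(t1=20, t2=40)
    base = ModelConfig()
    fine = ModelConfig(
        grid=dataclasses.replace(
            base.grid, n_nodes=base.grid.n_nodes * 2, dt_days=base.grid.dt_days / 2
        )
    )
    u0 = simulate_season(one_season, sched, base).uptake_n
    u1 = simulate_season(one_season, sched, fine).uptake_n
    assert abs(u1 - u0) / u1 < 0.02


def test_invalid_schedule_rejected():
    with pytest.raises(ValueError):
        FertilizerSchedule(t1=40, t2=20)
    with pytest.raises(ValueError):
        FertilizerSchedule(t1=0.0, t2=20)
    with pytest.raises(ValueError):
        FertilizerSchedule(t1=20, t2=80)
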