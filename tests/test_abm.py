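import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import dijkstra

from conftest import make_flat_landscape, make_two_patch_water
from hydrorefugia.abm import (
    Agent,
    SimulationConfig,
    STATUS_ARRIVED,
    STATUS_DEAD,
    STATUS_RETURNED,
    STATUS_TRAVELLING,
    build_cost_layer,
    hatch_agents,
    naismith_penalty,
    run_simulation,
    step_agent,
    turn_angle_sweep,
)
from hydrorefugia.landscape import Landscape, WaterLayer
import oracles as oc


# -- cost layer ------------------------------------------------------------------

def test_flat_terrain_costs_exactly_one():
    land = make_flat_landscape()
    assert np.all(build_cost_layer(land, "roughness") == 1.0)
    assert np.all(build_cost_layer(land, "slope") == 1.0)


def test_naismith_600m_ascent_costs_six():
    # one extra hour per 600 m climb on a 5 km/h base pace: cost 1 + 5 = 6
    assert naismith_penalty(600.0) == pytest.approx(5.0)
    shape = (4, 4)
    slope = np.full(shape, 0.6)  # 600 m rise per 1-km cell
    land = Landscape(elevation=np.zeros(shape), roughness=np.zeros(shape),
                     slope=slope)
    cost = build_cost_layer(land, "slope")
    assert np.allclose(cost, 6.0)


def test_cost_monotone_in_roughness():
    shape = (3, 5)
    rough = np.tile(np.linspace(0, 2, 5), (3, 1))
    land = Landscape(elevation=np.zeros(shape), roughness=rough,
                     slope=np.zeros(shape))
    cost = build_cost_layer(land, "roughness")
    assert np.all(np.diff(cost, axis=1) >= 0)
    assert cost[0, 0] == 1.0
    with pytest.raises(ValueError):
        naismith_penalty(-1.0)


# -- hatching --------------------------------------------------------------------

def test_even_split_across_patches():
    shape = (30, 30)
    patch = np.zeros(shape, dtype=int)
    for pid, pos in enumerate([(5, 5), (5, 25), (25, 5), (25, 25)], start=1):
        patch[pos] = pid
    water = WaterLayer(patch_id=patch, registry=pd.DataFrame({
        "patch_id": [1, 2, 3, 4],
        "feature_class": ["perennial_spring"] * 4}))
    cohort = hatch_agents(water, 4000, np.random.default_rng(0))
    counts = np.bincount(cohort["natal"], minlength=5)[1:]
    assert np.all(counts == 1000)
    assert np.all(cohort["energy"] == 150.0)
    assert np.all(cohort["status"] == STATUS_TRAVELLING)


def test_outward_heading_points_away_from_centroid():
    shape = (9, 9)
    patch = np.zeros(shape, dtype=int)
    patch[4, 3:6] = 1  # centroid at column 4; east edge cell at column 5
    water = WaterLayer(patch_id=patch, registry=pd.DataFrame({
        "patch_id": [1], "feature_class": ["fresh_lake"]}))
    rng = np.random.default_rng(1)
    cohort = hatch_agents(water, 200, rng)
    east = cohort["col"] == 5.5
    assert east.any()
    assert np.allclose(cohort["heading"][east], 90.0)
    west = cohort["col"] == 3.5
    assert np.allclose(cohort["heading"][west], 270.0)


def test_hatching_requires_patches():
    water = WaterLayer(patch_id=np.zeros((5, 5), dtype=int),
                       registry=pd.DataFrame({"patch_id": [],
                                              "feature_class": []}))
    with pytest.raises(ValueError):
        hatch_agents(water, 10, np.random.default_rng(0))


# -- stepping and reach ----------------------------------------------------------

def _straight_agent(col_start=2.5, row=2.5):
    return Agent(row=row, col=col_start, heading=90.0, energy=150.0, natal=1)


def _corridor(target_col):
    shape = (5, 400)
    land = make_flat_landscape(shape)
    patch = np.zeros(shape, dtype=int)
    patch[2, 2] = 1
    patch[2, target_col] = 2
    water = WaterLayer(patch_id=patch, registry=pd.DataFrame({
        "patch_id": [1, 2],
        "feature_class": ["perennial_spring", "perennial_spring"]}))
    return land, water


def test_straight_run_reaches_exactly_150_cells():
    """Energy 150 on cost-1 terrain covers exactly 150 cells: a patch 150
    cells away is reached with energy 0; one cell farther is unreachable."""
    land, water = _corridor(2 + 150)
    agent = _straight_agent()
    rng = np.random.default_rng(0)
    for _ in range(200):
        if agent.status != STATUS_TRAVELLING:
            break
        step_agent(agent, land, water, max_turn=0.0, rng=rng)
    assert agent.status == STATUS_ARRIVED
    assert agent.energy == pytest.approx(0.0)

    land, water = _corridor(2 + 151)
    agent = _straight_agent()
    for _ in range(200):
        if agent.status != STATUS_TRAVELLING:
            break
        step_agent(agent, land, water, max_turn=0.0, rng=rng)
    assert agent.status == STATUS_DEAD
    assert int(agent.col) == 2 + 150  # died on the last affordable cell


def test_uniform_cost_two_halves_the_reach():
    land, water = _corridor(2 + 75)
    land.cost = np.full(land.shape, 2.0)
    agent = _straight_agent()
    rng = np.random.default_rng(0)
    for _ in range(100):
        if agent.status != STATUS_TRAVELLING:
            break
        step_agent(agent, land, water, max_turn=0.0, rng=rng)
    assert agent.status == STATUS_ARRIVED
    assert agent.energy == pytest.approx(0.0)

    land, water = _corridor(2 + 76)
    land.cost = np.full(land.shape, 2.0)
    agent = _straight_agent()
    for _ in range(100):
        if agent.status != STATUS_TRAVELLING:
            break
        step_agent(agent, land, water, max_turn=0.0, rng=rng)
    assert agent.status == STATUS_DEAD


def test_zero_turn_agent_never_returns_home():
    land = make_flat_landscape((41, 41))
    patch = np.zeros((41, 41), dtype=int)
    patch[20, 20] = 1
    water = WaterLayer(patch_id=patch, registry=pd.DataFrame({
        "patch_id": [1], "feature_class": ["perennial_spring"]}))
    jm = run_simulation(land, water, SimulationConfig(
        n_per_tick=200, ticks=1, max_turn_deg=0.0, seed=5))
    assert jm.status_counts["returned"] == 0
    assert jm.successes() == 0  # single patch: nowhere to arrive


def test_energy_ledger_exact_bookkeeping():
    rng = np.random.default_rng(7)
    shape = (60, 60)
    rough = rng.uniform(0, 1, shape)
    land = Landscape(elevation=np.zeros(shape), roughness=rough,
                     slope=np.zeros(shape))
    land.cost = build_cost_layer(land, "roughness")
    water = make_two_patch_water(shape, (30, 10), (30, 50))
    jm = run_simulation(land, water, SimulationConfig(
        n_per_tick=300, ticks=2, seed=3, track_ledger=True))
    led = jm.ledger
    assert np.allclose(led["initial_energy"] - led["cost_paid"],
                       led["final_energy"], atol=1e-9)


def test_attempts_conservation_and_determinism():
    land = make_flat_landscape((50, 50))
    water = make_two_patch_water((50, 50), (25, 10), (25, 40))
    cfg = SimulationConfig(n_per_tick=400, ticks=3, seed=11)
    jm1 = run_simulation(land, water, cfg)
    jm2 = run_simulation(land, water, cfg)
    assert jm1.attempts == 1200
    assert sum(jm1.status_counts.values()) == jm1.attempts
    assert jm1.status_counts["travelling"] == 0
    assert np.array_equal(jm1.counts, jm2.counts)
    assert np.array_equal(jm1.traversal, jm2.traversal)
    jm3 = run_simulation(land, water, SimulationConfig(
        n_per_tick=400, ticks=3, seed=12))
    assert not np.array_equal(jm1.counts, jm3.counts)


def test_no_journeys_beyond_least_cost_reach():
    """No success is ever recorded between patches whose cost-weighted
    shortest path exceeds the energy budget (checked against an independent
    Dijkstra on the cell graph)."""
    rng = np.random.default_rng(19)
    shape = (40, 40)
    rough = rng.uniform(0.5, 1.0, shape)  # expensive terrain
    land = Landscape(elevation=np.zeros(shape), roughness=rough,
                     slope=np.zeros(shape))
    land.cost = build_cost_layer(land, "roughness", max_ascent_m=1800.0)
    water = make_two_patch_water(shape, (5, 5), (35, 35))
    # independent oracle: 8-neighbour graph, edge cost = entered cell's cost
    n = shape[0] * shape[1]
    rows, cols, vals = [], [], []
    for i in range(shape[0]):
        for j in range(shape[1]):
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if (di, dj) == (0, 0):
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < shape[0] and 0 <= jj < shape[1]:
                        rows.append(i * shape[1] + j)
                        cols.append(ii * shape[1] + jj)
                        vals.append(land.cost[ii, jj])
    from scipy.sparse import coo_matrix

    graph = coo_matrix((vals, (rows, cols)), shape=(n, n))
    dist = dijkstra(graph, indices=[5 * shape[1] + 5])[0]
    least_cost = dist[35 * shape[1] + 35]
    jm = run_simulation(land, water, SimulationConfig(
        n_per_tick=500, ticks=4, seed=2))
    if least_cost > 150.0:
        assert jm.counts[1, 2] == 0 and jm.counts[2, 1] == 0
    else:  # sanity: keep the test meaningful
        pytest.skip("terrain draw left the patches within reach")


def test_adjacent_patches_on_flat_terrain_connect_reliably():
    """Agents hatched on the edge facing a neighbouring patch two cells away
    arrive almost surely despite the random turn jitter."""
    shape = (20, 20)
    land = make_flat_landscape(shape)
    patch = np.zeros(shape, dtype=int)
    patch[8:12, 4:6] = 1
    patch[8:12, 7:9] = 2
    water = WaterLayer(patch_id=patch, registry=pd.DataFrame({
        "patch_id": [1, 2], "feature_class": ["fresh_lake", "fresh_lake"]}))
    rng = np.random.default_rng(21)
    arrived = 0
    n = 200
    for _ in range(n):
        agent = Agent(row=9.5 + rng.uniform(-1, 1), col=5.5, heading=90.0,
                      natal=1)
        for _step in range(160):
            if agent.status != STATUS_TRAVELLING:
                break
            step_agent(agent, land, water, max_turn=20.0, rng=rng)
        arrived += agent.status == STATUS_ARRIVED
    assert arrived / n > 0.9
    # and the full simulation records journeys both ways
    jm = run_simulation(land, water, SimulationConfig(
        n_per_tick=400, ticks=2, seed=21))
    assert jm.counts[1, 2] > 0 and jm.counts[2, 1] > 0


def test_homing_grows_with_turn_angle():
    land = make_flat_landscape((41, 41))
    patch = np.zeros((41, 41), dtype=int)
    patch[20, 20] = 1
    water = WaterLayer(patch_id=patch, registry=pd.DataFrame({
        "patch_id": [1], "feature_class": ["perennial_spring"]}))
    sweep = turn_angle_sweep(land, water, [0.0, 20.0, 150.0],
                             SimulationConfig(n_per_tick=300, ticks=2, seed=9))
    ret = sweep["returned_fraction"].to_numpy()
    assert ret[0] == 0.0
    assert ret[2] > ret[1]
    assert ret[2] > 0.3  # near-uncorrelated walk wanders home often


def test_step_requires_cost_layer(flat_corridor):
    land, water = flat_corridor
    land2 = Landscape(elevation=land.elevation, roughness=land.roughness,
                      slope=land.slope)
    with pytest.raises(ValueError):
        step_agent(_straight_agent(), land2, water)
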