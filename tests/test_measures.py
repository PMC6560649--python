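import numpy as np
import pytest

from ditras.engine import SampledMobilityTrajectory, SimulationConfig, run_ditras
from ditras.measures import (
    MEASURE_NAMES,
    EmpiricalDistribution,
    MeasureSuite,
    StayRecord,
    compare_suites,
    extract_stays_and_trips,
    kl_divergence,
    mobility_entropy,
    population_measures,
    radius_of_gyration,
    rmse,
)
from ditras.tessellation import Location, WeightedSpatialTessellation, distance

KM_PER_DEG = 6371.0 * np.pi / 180.0


def traj_from_ids(ids, tess, agent_id=0):
    entries = tuple(
        (tess.by_id(i).lat, tess.by_id(i).lon, slot + 1, i) for slot, i in enumerate(ids)
    )
    return SampledMobilityTrajectory(agent_id=agent_id, entries=entries)


def stays_with_counts(counts, tess):
    """One synthetic stay record per visit, locations taken from tess."""
    out = []
    slot = 1
    for loc_id, n in counts.items():
        for _ in range(n):
            out.append(StayRecord(0, loc_id, slot, 1))
            slot += 1
    return out


class TestStaysAndTrips:
    def test_constant_trajectory(self, toy_tess):
        stays, trips = extract_stays_and_trips(traj_from_ids(["L0"] * 5, toy_tess))
        assert len(stays) == 1 and stays[0].length_slots == 5
        assert trips == []

    def test_hand_trace(self, toy_tess):
        stays, trips = extract_stays_and_trips(
            traj_from_ids(["L0", "L0", "L1", "L0"], toy_tess)
        )
        assert [(s.location_id, s.length_slots) for s in stays] == [
            ("L0", 2), ("L1", 1), ("L0", 1)
        ]
        assert trips == [("L0", "L1", 3), ("L1", "L0", 4)]

    def test_trips_always_stays_minus_one(self, toy_tess):
        rng = np.random.default_rng(0)
        ids = [f"L{i}" for i in rng.integers(0, len(toy_tess), size=60)]
        stays, trips = extract_stays_and_trips(traj_from_ids(ids, toy_tess))
        assert len(trips) == len(stays) - 1


class TestRadiusOfGyration:
    def test_single_location_is_zero(self, toy_tess):
        assert radius_of_gyration(stays_with_counts({"L0": 3}, toy_tess), toy_tess) == 0.0

    def test_two_equal_locations_half_distance(self):
        d = 10.0
        tess = WeightedSpatialTessellation(
            [
                Location("a", 0.0, 0.0, 1.0),
                Location("b", d / KM_PER_DEG, 0.0, 1.0),
                Location("pad", 1.0, 1.0, 1.0),
            ]
        )
        rg = radius_of_gyration(stays_with_counts({"a": 2, "b": 2}, tess), tess)
        assert rg == pytest.approx(d / 2, rel=1e-6)

    def test_matches_brute_force_on_random_agents(self, toy_tess):
        rng = np.random.default_rng(1)
        for _ in range(100):
            ks = rng.integers(1, 6, size=5)
            counts = {f"L{i}": int(k) for i, k in enumerate(ks)}
            stays = stays_with_counts(counts, toy_tess)
            # independent brute force: explicit sums over the definition
            n = np.array(list(counts.values()), dtype=float)
            p = n / n.sum()
            locs = [toy_tess.by_id(i) for i in counts]
            cm_lat = sum(pi * l.lat for pi, l in zip(p, locs))
            cm_lon = sum(pi * l.lon for pi, l in zip(p, locs))
            cm = Location("cm", cm_lat, cm_lon, 1.0)
            expected = np.sqrt(sum(pi * distance(l, cm) ** 2 for pi, l in zip(p, locs)))
            assert radius_of_gyration(stays, toy_tess) == pytest.approx(expected, abs=1e-9)


class TestEntropy:
    def test_single_location_zero(self, toy_tess):
        assert mobility_entropy(stays_with_counts({"L0": 7}, toy_tess)) == 0.0

    @pytest.mark.parametrize("k", [2, 5, 9])
    def test_uniform_is_one(self, toy_tess, k):
        counts = {f"L{i}": 3 for i in range(k)}
        assert mobility_entropy(stays_with_counts(counts, toy_tess)) == pytest.approx(1.0)

    def test_direct_evaluation(self, toy_tess):
        # p = (0.5, 0.25, 0.25) => S = 1.5*ln2 / ln3 ~ 0.9464
        counts = {"L0": 2, "L1": 1, "L2": 1}
        s = mobility_entropy(stays_with_counts(counts, toy_tess))
        assert s == pytest.approx(1.5 * np.log(2) / np.log(3), abs=1e-12)
        assert s == pytest.approx(0.9464, abs=1e-4)


class TestComparison:
    def test_rmse_identity_and_symmetry(self):
        y = np.array([0.2, 0.3, 0.5])
        assert rmse(y, y) == 0.0
        yh = np.array([0.5, 0.2, 0.3])
        assert rmse(y, yh) == rmse(yh, y) > 0

    def test_rmse_direct_formula(self):
        assert rmse([0.0, 1.0], [1.0, 1.0]) == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert rmse([0.0, 1.0], [1.0, 1.0]) == pytest.approx(0.7071, abs=1e-4)

    def test_kl_identity_and_positivity(self):
        p = np.array([0.1, 0.4, 0.5])
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-9)
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = rng.dirichlet(np.ones(6))
            b = rng.dirichlet(np.ones(6))
            assert kl_divergence(a, b) >= 0

    def test_kl_direct_formula(self):
        # 0.5 ln(0.5/0.75) + 0.5 ln(0.5/0.25) = 0.5 ln(4/3)
        got = kl_divergence([0.5, 0.5], [0.75, 0.25])
        assert got == pytest.approx(0.5 * np.log(4 / 3), abs=1e-9)
        assert got == pytest.approx(0.1438, abs=1e-4)

    def test_rejects_mismatched_bins(self):
        d1 = EmpiricalDistribution((0.0, 1.0, 2.0), (0.5, 0.5))
        d2 = EmpiricalDistribution((0.0, 1.0, 3.0), (0.5, 0.5))
        with pytest.raises(ValueError, match="different edges"):
            rmse(d1, d2)


class TestPopulationMeasures:
    def test_stationary_agent(self, toy_tess):
        suite = population_measures([traj_from_ids(["L3"] * 24, toy_tess)], toy_tess)
        npu = suite["locations_per_user"]
        probs = np.asarray(npu.probabilities)
        assert probs[0] == 1.0  # point mass at one location
        assert suite["trips_per_day"].probabilities[0] == 1.0  # zero trips
        assert suite["radius_of_gyration"].probabilities[0] == 1.0  # r_g = 0 bin

    def test_hand_built_cohort(self, toy_tess):
        # 3 agents: stationary; A-B commuter; three-location walker
        trajs = [
            traj_from_ids(["L0"] * 4, toy_tess, 0),
            traj_from_ids(["L0", "L1", "L1", "L0"], toy_tess, 1),
            traj_from_ids(["L2", "L3", "L4", "L2"], toy_tess, 2),
        ]
        suite = population_measures(trajs, toy_tess)
        # distinct locations per user: 1, 2, 3 -> uniform over those bins
        npu = np.asarray(suite["locations_per_user"].probabilities)
        np.testing.assert_allclose(npu[:3], [1 / 3, 1 / 3, 1 / 3])
        assert npu[3:].sum() == 0
        # trips: agent1 arrives at slots 2 and 4; agent2 at 2, 3, 4 -> hours 1,1,2,3,3
        th = np.asarray(suite["trips_per_hour"].probabilities)
        np.testing.assert_allclose(th[[1, 2, 3]], [2 / 5, 1 / 5, 2 / 5])
        assert th[[0] + list(range(4, 24))].sum() == 0
        # all stays are 1 or 2 hours: 2h stay only for agent 1 at L1
        stays_all = [s for t in trajs for s in extract_stays_and_trips(t)[0]]
        assert sorted(s.length_slots for s in stays_all) == [1, 1, 1, 1, 1, 1, 2, 4]

    def test_all_present_and_normalized(self, toy_tess):
        cfg = SimulationConfig(n_agents=8, n_slots=72, diary="wt", traj="depr", seed=3)
        suite = population_measures(run_ditras(cfg, toy_tess), toy_tess)
        for name in MEASURE_NAMES:
            probs = np.asarray(suite[name].probabilities)
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(probs >= 0)

    def test_invariant_to_agent_order(self, toy_tess):
        cfg = SimulationConfig(n_agents=6, n_slots=48, diary="rd", traj="latp", seed=4)
        trajs = run_ditras(cfg, toy_tess)
        a = population_measures(trajs, toy_tess)
        b = population_measures(list(reversed(trajs)), toy_tess)
        for name in MEASURE_NAMES:
            np.testing.assert_allclose(a[name].probabilities, b[name].probabilities)

    def test_empty_cohort_rejected(self, toy_tess):
        with pytest.raises(ValueError, match="empty"):
            population_measures([], toy_tess)


def test_plot_suite_writes_figure(toy_tess, tmp_path):
    from ditras.measures import plot_suite

    cfg = SimulationConfig(n_agents=4, n_slots=48, diary="rd", traj="depr", seed=8)
    suite = population_measures(run_ditras(cfg, toy_tess), toy_tess)
    out = tmp_path / "suite.png"
    plot_suite({"cohort": suite}, out)
    assert out.exists() and out.stat().st_size > 0


class TestSuiteIO:
    def test_json_round_trip_and_compare(self, toy_tess, tmp_path):
        cfg = SimulationConfig(n_agents=5, n_slots=48, diary="rd", traj="depr", seed=6)
        suite = population_measures(run_ditras(cfg, toy_tess), toy_tess)
        p = tmp_path / "suite.json"
        suite.to_json(p)
        back = MeasureSuite.from_json(p)
        table = compare_suites(suite, back)
        assert (table["rmse"] == 0).all()
        assert (table["kl"].abs() < 1e-9).all()
        assert set(table.index) == set(MEASURE_NAMES)
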