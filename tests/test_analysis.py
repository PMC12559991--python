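import numpy as np
import pytest

from svtether.analysis import (first_passage_below,
                               first_tether_type_probabilities,
                               median_distance, occupancy_histogram,
                               reweight_without_repulsion,
                               state_dwell_proportions, summarize,
                               tethered_lifetimes, time_below,
                               time_to_first_tether)
from svtether.dynamics import SimConfig, Trajectory, simulate
from svtether.errors import ContractError
from svtether.io import read_trajectory, write_trajectory


def make_traj(t, d, n, t_end=50.0):
    return Trajectory(t=np.asarray(t, float), d=np.asarray(d, float),
                      n=np.asarray(n, np.int16).reshape(len(t), 3),
                      t_end=t_end, seed=0)


class TestDwellStatistics:
    def test_single_dwell_concentrates_histogram(self):
        traj = make_traj([0.0], [3.0], [[0, 0, 0]])
        edges, props = occupancy_histogram(traj)
        assert props.sum() == pytest.approx(1.0)
        k = np.searchsorted(edges, 3.0, side="right") - 1
        assert props[k] == pytest.approx(1.0)

    def test_constant_trajectory_median(self):
        traj = make_traj([0.0], [3.0], [[0, 0, 0]])
        assert median_distance(traj) == pytest.approx(3.0)

    def test_time_below_thresholds(self):
        traj = make_traj([0.0], [3.0], [[0, 0, 0]])
        assert time_below(traj, 10.0) == pytest.approx(50.0)
        assert time_below(traj, 0.0) == 0.0
        traj2 = make_traj([0.0, 10.0], [12.0, 3.0], [[0, 0, 0], [0, 0, 0]])
        ts = [time_below(traj2, x) for x in (1.0, 5.0, 20.0)]
        assert ts == sorted(ts)

    def test_histogram_and_time_below_agree(self, model):
        traj = simulate(model, SimConfig(t_end=2.0, base_seed=6), 0)
        edges, props = occupancy_histogram(traj, d_max=100.0)
        k = np.searchsorted(edges, 7.5)
        assert (props[:k].sum() * traj.t_end
                == pytest.approx(time_below(traj, 7.5), abs=1e-12 * traj.t_end))

    def test_empty_trajectory_rejected(self):
        bad = Trajectory(t=np.array([]), d=np.array([]),
                         n=np.zeros((0, 3), np.int16), t_end=1.0, seed=0)
        with pytest.raises(ContractError):
            median_distance(bad)


class TestEventStatistics:
    def test_first_passage(self):
        below = make_traj([0.0], [3.0], [[0, 0, 0]])
        assert first_passage_below(below, 5.0) == 0.0
        above = make_traj([0.0], [30.0], [[0, 0, 0]])
        assert first_passage_below(above, 5.0) is None
        late = make_traj([0.0, 7.0], [30.0, 3.0], np.zeros((2, 3)))
        assert first_passage_below(late, 5.0) == 7.0

    def test_time_to_first_tether(self):
        never = make_traj([0.0], [3.0], [[0, 0, 0]])
        assert time_to_first_tether(never) is None
        traj = make_traj([0.0, 2.5], [3.0, 3.0], [[0, 0, 0], [0, 1, 0]])
        assert time_to_first_tether(traj) == 2.5

    def test_tethered_lifetimes(self):
        never = make_traj([0.0], [3.0], [[0, 0, 0]])
        assert len(tethered_lifetimes(never)) == 0
        # bind at 1, add one, drop both by t=4: one episode of length 3
        traj = make_traj([0.0, 1.0, 2.0, 3.0, 4.0], [3.0] * 5,
                         [[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 0, 0], [0, 0, 0]])
        assert tethered_lifetimes(traj) == pytest.approx([3.0])
        # an episode still open at t_end counts at its observed length
        open_ended = make_traj([0.0, 1.0], [3.0, 3.0], [[0, 0, 0], [0, 0, 1]])
        assert tethered_lifetimes(open_ended) == pytest.approx([49.0])

    def test_first_tether_type_probabilities(self):
        traj = make_traj([0.0, 1.0, 2.0, 3.0], [3.0] * 4,
                         [[0, 0, 0], [1, 0, 0], [0, 0, 0], [1, 0, 0]])
        probs = first_tether_type_probabilities(traj)
        assert probs == pytest.approx([1.0, 0.0, 0.0])
        untethered = make_traj([0.0], [3.0], [[0, 0, 0]])
        assert first_tether_type_probabilities(untethered) is None

    def test_state_proportions_sum_to_one(self, model):
        traj = simulate(model, SimConfig(t_end=1.0, base_seed=2), 0)
        props = state_dwell_proportions(traj)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)


class TestReweighting:
    def test_untethered_trajectory_gives_uniform(self, model):
        traj = make_traj([0.0], [30.0], [[0, 0, 0]])
        pdf = reweight_without_repulsion(traj, model)
        assert np.allclose(pdf.density, 1.0 / model.geometry.d_max)

    def test_mixture_normalized(self, model):
        traj = simulate(model, SimConfig(t_end=2.0, base_seed=8), 0)
        pdf = reweight_without_repulsion(traj, model)
        assert abs(pdf.area - 1.0) < 1e-6


class TestSummaryAndIO:
    def test_summarize_reports_consistent_metrics(self, model):
        trajs = [simulate(model, SimConfig(t_end=2.0, base_seed=10), r)
                 for r in range(3)]
        s = summarize(trajs)
        assert s.n_reps == 3
        assert 0.0 <= s.prop_below_10 <= 1.0
        assert s.time_below_10 == pytest.approx(s.prop_below_10 * 2.0)
        assert s.first_tether_probs is None or \
            sum(s.first_tether_probs) == pytest.approx(1.0)
        assert set(s.sem) >= {"time_below_5", "time_below_10"}

    def test_trajectory_round_trip_is_bit_exact(self, model, tmp_path):
        traj = simulate(model, SimConfig(t_end=0.5, base_seed=11), 0)
        path = write_trajectory(traj, tmp_path / "rep000")
        back = read_trajectory(path)
        assert np.array_equal(back.t, traj.t)
        assert np.array_equal(back.d, traj.d)
        assert np.array_equal(back.n, traj.n)
        assert back.seed == traj.seed and back.t_end == traj.t_end
        # dwell-derived statistics survive the round trip exactly
        assert median_distance(back) == median_distance(traj)
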