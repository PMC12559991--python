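import numpy as np
import pytest

from svtether import default_specs, mean_tethers
from svtether.analysis import occupancy_histogram
from svtether.dynamics import (RateVector, SimConfig, SimState,
                               build_rate_vector, gillespie_step,
                               run_replicates, simulate)
from svtether.errors import AbsorbingStateError, ContractError
from svtether.model import DockingModel
from svtether.scenarios import build_model, builtin_scenarios


class _ScriptedRNG:
    """Feeds a fixed sequence of uniforms to gillespie_step."""

    def __init__(self, values):
        self._values = list(values)

    def random(self):
        return self._values.pop(0)


class TestRateVector:
    def test_saturation_and_depletion(self, model):
        full = tuple(s.n_total for s in model.specs)
        rates = build_rate_vector(SimState(0.0, 4.0, full), model)
        assert np.all(rates.b[2:5] == 0.0)      # no free copies left
        empty = build_rate_vector(SimState(0.0, 4.0, (0, 0, 0)), model)
        assert np.all(empty.b[5:] == 0.0)       # nothing to unbind
        assert np.all(empty.b[2:5] > 0.0)

    def test_binding_closed_beyond_reach(self, model):
        rates = build_rate_vector(SimState(0.0, 50.0, (0, 0, 0)), model)
        assert np.all(rates.b[2:5] == 0.0)      # 50 nm exceeds every height

    def test_reflecting_boundaries(self, model):
        bottom = build_rate_vector(SimState(0.0, 0.0, (0, 0, 0)), model)
        assert bottom.b[0] == 0.0
        assert bottom.b[1] == pytest.approx(16000.0)
        top = build_rate_vector(SimState(0.0, 100.0, (0, 0, 0)), model)
        assert top.b[1] == 0.0

    def test_off_grid_distance_rejected(self, model):
        with pytest.raises(ContractError):
            build_rate_vector(SimState(0.0, 4.3, (0, 0, 0)), model)


class TestGillespieStep:
    def test_waiting_time_and_first_reaction(self):
        rates = RateVector(np.array([1.0, 1.0, 0, 0, 0, 0, 0, 0]), 2.0)
        tau, j = gillespie_step(rates, _ScriptedRNG([np.exp(-1.0), 1e-12]))
        assert tau == pytest.approx(0.5)        # ln(1/q1)/b0 with q1 = 1/e
        assert j == 0

    def test_reaction_selection_by_cumulative_rate(self):
        rates = RateVector(np.array([1.0, 3.0, 0, 0, 0, 0, 0, 0]), 4.0)
        _, j = gillespie_step(rates, _ScriptedRNG([0.5, 0.26]))
        assert j == 1                           # 0.26·4 = 1.04 > b[0]

    def test_mean_waiting_time_is_inverse_total_rate(self):
        rates = RateVector(np.array([2.0, 3.0, 0, 0, 0, 0, 0, 0]), 5.0)
        rng = np.random.default_rng(0)
        taus = [gillespie_step(rates, rng)[0] for _ in range(20000)]
        assert np.mean(taus) == pytest.approx(1 / 5.0, rel=0.03)

    def test_absorbing_state_rejected(self):
        with pytest.raises(AbsorbingStateError):
            gillespie_step(RateVector(np.zeros(8), 0.0), _ScriptedRNG([0.5]))


class TestSimulate:
    def test_same_seed_reproduces_bitwise(self, model):
        cfg = SimConfig(t_end=1.0, base_seed=9)
        a = simulate(model, cfg, rep_index=2)
        b = simulate(model, cfg, rep_index=2)
        assert np.array_equal(a.t, b.t)
        assert np.array_equal(a.d, b.d)
        assert np.array_equal(a.n, b.n)

    def test_distinct_replicates_differ(self, model):
        cfg = SimConfig(t_end=0.5, base_seed=9)
        a = simulate(model, cfg, rep_index=0)
        b = simulate(model, cfg, rep_index=1)
        assert not np.array_equal(a.t, b.t)

    def test_each_event_changes_one_coordinate_by_one_step(self, model):
        traj = simulate(model, SimConfig(t_end=2.0, base_seed=4), 0)
        assert np.all(np.diff(traj.t) > 0)
        assert traj.t[-1] <= traj.t_end
        dd = np.abs(np.diff(traj.d))
        dn = np.abs(np.diff(traj.n.astype(np.int32), axis=0)).sum(axis=1)
        moved = (dd > 0).astype(int) + dn
        assert np.all(moved == 1)
        assert np.all(np.isin(dd[dd > 0], [0.5]))

    def test_no_assembly_channels_keeps_vesicle_untethered(self):
        mdl = DockingModel(default_specs(kon_max=(0.0, 0.0, 0.0)))
        traj = simulate(mdl, SimConfig(t_end=0.5, base_seed=1), 0)
        assert np.all(traj.n == 0)

    def test_control_run_shows_untethering_events(self, model):
        # the last tether is occasionally lost and re-formed
        traj = simulate(model, SimConfig(t_end=20.0, base_seed=5), 0)
        total = traj.n.sum(axis=1)
        untether = (total[:-1] == 1) & (total[1:] == 0)
        first_bind = np.argmax(total > 0)
        assert untether[first_bind:].sum() >= 1


class TestStationaryLaws:
    def test_untethered_occupancy_matches_detailed_balance(self):
        # telescoping the up/down rates gives the exact stationary
        # distribution of the spatial birth-death chain; the empirical
        # dwell-time occupancy of a tether-free vesicle must match it
        mdl = build_model(builtin_scenarios()["no_tethers"])
        grid = mdl.sim.d_grid
        nd = len(grid)
        down = np.array([build_rate_vector(SimState(0, g, (0, 0, 0)), mdl).b[0]
                         for g in grid])
        up = np.array([build_rate_vector(SimState(0, g, (0, 0, 0)), mdl).b[1]
                       for g in grid])
        pi = np.zeros(nd)
        k0 = nd // 2
        pi[k0] = 1.0
        for k in range(k0 + 1, nd):
            pi[k] = pi[k - 1] * up[k - 1] / down[k]
        for k in range(k0 - 1, -1, -1):
            pi[k] = pi[k + 1] * down[k + 1] / up[k]
        pi /= pi.sum()

        trajs = run_replicates(
            mdl, SimConfig(t_end=2.0, n_reps=10, base_seed=3, d_start=50.0))
        occ = np.array([occupancy_histogram(t, d_max=100.0)[1] for t in trajs])
        mean = occ.mean(axis=0)
        sem = occ.std(axis=0, ddof=1) / np.sqrt(len(occ))
        checked = pi > 1e-4
        assert checked.sum() > 150
        assert np.all(np.abs(mean - pi)[checked] <= (3 * sem + 2e-4)[checked])

    def test_frozen_distance_counts_match_binomial_mean(self, model):
        # with movement disabled each copy binds independently, so the
        # stationary count is Binomial(n_total, kon/(kon+koff))
        d_probe = 4.0
        idx = int(round(d_probe / 0.5))
        trajs = run_replicates(
            model, SimConfig(mobility_rate=0.0, d_start=d_probe,
                             t_end=50.0, n_reps=10, base_seed=42))
        for i, spec in enumerate(model.specs):
            kon = model.sim.profiles[i].values[idx] * spec.kon_max
            expected = mean_tethers(spec.n_total, kon, spec.koff)
            means = np.array([np.average(t.n[:, i], weights=t.dwell_times())
                              for t in trajs])
            sem = means.std(ddof=1) / np.sqrt(len(means))
            assert abs(means.mean() - expected) <= 3 * sem + 0.02
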