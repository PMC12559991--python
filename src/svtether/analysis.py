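"""Dwell-time-exact summary statistics of simulated trajectories.

All statistics weight each recorded state by the time the SV actually spent
in it (trajectories are event-sparse, so dwell times are exact, not
time-sampled).  Threshold statistics use strict ``d < threshold`` on the
0.5 nm grid.  Functions accept a single :class:`~svtether.dynamics.Trajectory`
or a list of them; pooled variants concatenate dwells across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import DistancePDF, normalized, uniform_pdf
from .dynamics import Trajectory
from .errors import ContractError
from .model import SIM_STEP, DockingModel

__all__ = [
    "occupancy_histogram",
    "median_distance",
    "time_below",
    "first_passage_below",
    "time_to_first_tether",
    "tethered_lifetimes",
    "first_tether_type_probabilities",
    "state_dwell_proportions",
    "reweight_without_repulsion",
    "SummaryMetrics",
    "summarize",
]


def _as_list(traj) -> list[Trajectory]:
    trajs = [traj] if isinstance(traj, Trajectory) else list(traj)
    if not trajs:
        raise ContractError("no trajectories given")
    for t in trajs:
        if len(t.t) == 0:
            raise ContractError("empty trajectory")
    return trajs


def _pooled_dwells(trajs: list[Trajectory]) -> tuple[np.ndarray, np.ndarray]:
    d = np.concatenate([t.d for t in trajs])
    w = np.concatenate([t.dwell_times() for t in trajs])
    return d, w


def occupancy_histogram(traj, bin_width: float = SIM_STEP,
                        d_max: float | None = None):
    """Proportion of time spent in each distance bin.

    Returns ``(bin_edges, proportions)``; proportions sum to 1.  Bins are
    ``[k·w, (k+1)·w)`` so with the default width each bin holds exactly one
    grid position.
    """
    trajs = _as_list(traj)
    d, w = _pooled_dwells(trajs)
    top = (d_max if d_max is not None else float(d.max())) + bin_width
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    idx = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    hist = np.bincount(idx, weights=w, minlength=len(edges) - 1)
    return edges, hist / hist.sum()


def median_distance(traj) -> float:
    """Dwell-time-weighted median gap, interpolated within the median bin.

    Each grid position ``d`` is treated as the bin ``[d − Δ/2, d + Δ/2)`` and
    the median is placed linearly within the bin where the cumulative dwell
    crosses half the total time.
    """
    trajs = _as_list(traj)
    d, w = _pooled_dwells(trajs)
    order = np.argsort(d, kind="stable")
    d, w = d[order], w[order]
    uniq, start = np.unique(d, return_index=True)
    dwell = np.add.reduceat(w, start)
    cum = np.cumsum(dwell)
    half = 0.5 * cum[-1]
    k = int(np.searchsorted(cum, half))
    before = cum[k - 1] if k else 0.0
    frac = (half - before) / dwell[k]
    return float(uniq[k] - SIM_STEP / 2 + frac * SIM_STEP)


def time_below(traj, threshold: float) -> float:
    """Total dwell time (s) with gap strictly below ``threshold`` nm."""
    trajs = _as_list(traj)
    d, w = _pooled_dwells(trajs)
    return float(w[d < threshold].sum())


def first_passage_below(traj: Trajectory, threshold: float) -> float | None:
    """Time of the first event with gap below ``threshold``; None if never.

    A trajectory that starts below the threshold returns 0.
    """
    below = np.nonzero(traj.d < threshold)[0]
    if len(below) == 0:
        return None
    return float(traj.t[below[0]])


def time_to_first_tether(traj: Trajectory) -> float | None:
    """Time of the first binding event (total count 0 → 1); None if never."""
    total = traj.n.sum(axis=1)
    bound = np.nonzero(total > 0)[0]
    if len(bound) == 0:
        return None
    return float(traj.t[bound[0]])


def tethered_lifetimes(traj: Trajectory) -> np.ndarray:
    """Durations of maximal intervals with at least one tether formed.

    An episode still running at ``t_end`` contributes its observed length.
    """
    tethered = traj.n.sum(axis=1) > 0
    trans = np.diff(tethered.astype(np.int8))
    starts = np.nonzero(trans == 1)[0] + 1
    ends = np.nonzero(trans == -1)[0] + 1
    start_times = traj.t[starts]
    end_times = traj.t[ends]
    if tethered[0]:
        start_times = np.concatenate([[traj.t[0]], start_times])
    if tethered[-1]:
        end_times = np.concatenate([end_times, [traj.t_end]])
    return end_times - start_times


def first_tether_type_probabilities(traj) -> np.ndarray | None:
    """Fraction of untethered→tethered transitions initiated by each species.

    Every 0→1 total-count transition (including the first) contributes; the
    three proportions sum to 1.  Returns None if the SV never tethered.
    """
    trajs = _as_list(traj)
    counts = np.zeros(3)
    for t in trajs:
        total = t.n.sum(axis=1)
        starts = np.nonzero((total[1:] == 1) & (total[:-1] == 0))[0] + 1
        for k in starts:
            counts[np.argmax(t.n[k] - t.n[k - 1])] += 1
    if counts.sum() == 0:
        return None
    return counts / counts.sum()


def tether_count_occupancy(traj, type_index: int, n_max: int) -> np.ndarray:
    """Proportion of time with each count 0..n_max of one species formed."""
    trajs = _as_list(traj)
    occ = np.zeros(n_max + 1)
    for t in trajs:
        w = t.dwell_times()
        occ += np.bincount(t.n[:, type_index], weights=w, minlength=n_max + 1)[:n_max + 1]
    return occ / occ.sum()


def state_dwell_proportions(traj) -> dict[tuple[int, int, int], float]:
    """Proportion of total time spent in each tether occupancy (n₁, n₂, n₃)."""
    trajs = _as_list(traj)
    n = np.concatenate([t.n for t in trajs])
    w = np.concatenate([t.dwell_times() for t in trajs])
    if n.max() >= 64:
        raise ContractError("state packing supports counts below 64")
    keys = n[:, 0].astype(np.int32) * 4096 + n[:, 1] * 64 + n[:, 2]
    dwell = np.bincount(keys, weights=w, minlength=4096 * 64)
    occupied = np.nonzero(dwell)[0]
    total = dwell.sum()
    return {(int(k // 4096), int((k // 64) % 64), int(k % 64)):
            float(dwell[k] / total) for k in occupied}


def reweight_without_repulsion(traj, model: DockingModel,
                               grid: str = "fine") -> DistancePDF:
    """Gap distribution implied by the visited states with repulsion zeroed.

    For every visited occupancy the composite density is recomputed with the
    membrane-repulsion energies set to zero (uniform base density for the
    untethered state); the densities are mixed by the proportion of time the
    SV spent in each occupancy and renormalized.  This mimics distance
    distributions measured on dehydrated (freeze-substituted) EM samples,
    where the hydration and electrostatic repulsions are absent.
    """
    props = state_dwell_proportions(traj)
    d_grid = model._tables(grid).d_grid
    mix = np.zeros_like(d_grid)
    for counts, p in props.items():
        if all(c == 0 for c in counts):
            pdf = uniform_pdf(d_grid)
        else:
            pdf = model.composite_pdf(counts, grid=grid, repulsion=False)
        mix += p * pdf.density
    return normalized(d_grid, mix)


@dataclass
class SummaryMetrics:
    """Pooled summary of one scenario's replicates.

    Per-replicate metrics that are undefined for some replicates (a vesicle
    that never tethered, say) are averaged over the defined ones, with the
    exclusion count recorded in ``n_excluded``.
    """

    n_reps: int
    median_d: float
    time_below_5: float
    time_below_10: float
    prop_below_5: float
    prop_below_10: float
    t_first_below_5: float | None
    t_first_tether: float | None
    mean_tethered_lifetime: float | None
    first_tether_probs: list[float] | None
    sem: dict[str, float] = field(default_factory=dict)
    n_excluded: dict[str, int] = field(default_factory=dict)


def _mean_sem(values: list[float | None]) -> tuple[float | None, float, int]:
    ok = np.array([v for v in values if v is not None], dtype=float)
    excluded = len(values) - len(ok)
    if len(ok) == 0:
        return None, float("nan"), excluded
    sem = float(ok.std(ddof=1) / np.sqrt(len(ok))) if len(ok) > 1 else 0.0
    return float(ok.mean()), sem, excluded


def summarize(trajs) -> SummaryMetrics:
    """Mean ± SEM of the standard per-replicate metrics, plus pooled medians."""
    trajs = _as_list(trajs)
    t_end = trajs[0].t_end
    per = {
        "time_below_5": [time_below(t, 5.0) for t in trajs],
        "time_below_10": [time_below(t, 10.0) for t in trajs],
        "t_first_below_5": [first_passage_below(t, 5.0) for t in trajs],
        "t_first_tether": [time_to_first_tether(t) for t in trajs],
        "mean_tethered_lifetime": [
            (float(lt.mean()) if len(lt := tethered_lifetimes(t)) else None)
            for t in trajs],
    }
    sem: dict[str, float] = {}
    excl: dict[str, int] = {}
    means: dict[str, float | None] = {}
    for key, vals in per.items():
        means[key], sem[key], n_ex = _mean_sem(vals)
        if n_ex:
            excl[key] = n_ex
    return SummaryMetrics(
        n_reps=len(trajs),
        median_d=median_distance(trajs),
        time_below_5=means["time_below_5"],
        time_below_10=means["time_below_10"],
        prop_below_5=means["time_below_5"] / t_end,
        prop_below_10=means["time_below_10"] / t_end,
        t_first_below_5=means["t_first_below_5"],
        t_first_tether=means["t_first_tether"],
        mean_tethered_lifetime=means["mean_tethered_lifetime"],
        first_tether_probs=(p.tolist() if (p := first_tether_type_probabilities(trajs))
                            is not None else None),
        sem=sem,
        n_excluded=excl,
    )
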