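"""Exact stochastic simulation of SV movement and tether turnover.

The state of the system is ``(d, n₁, n₂, n₃)``: the SV–PM gap on a 0.5 nm
grid plus the number of formed tethers of each species.  Eight reactions are
possible — a 0.5 nm step toward or away from the PM, binding of each species
and unbinding of each species — with rates

* down:  mobility · m(d, n)          with  m = φ(d−Δ)/(φ(d−Δ)+φ(d)),
* up:    mobility · (1 − m(d, n)),
* bindᵢ:   g_onᵢ(d) · k_on,maxᵢ · (n_totalᵢ − nᵢ),
* unbindᵢ: k_offᵢ · nᵢ   (distance-independent),

and reflecting boundaries (the downward channel is closed at d = 0, the
upward channel at d_max).  Waiting times and reaction indices follow the
Gillespie algorithm: τ = ln(1/q₁)/b₀ and the first index whose cumulative
rate reaches q₂·b₀.

The event loop is compiled with numba; states are recorded event-sparse, so
downstream statistics are dwell-time exact.  One step *into* a region where
φ vanishes is legal (the up-rate never consults φ(d+Δ)); the next move from
there is forced downhill.  Reaching a state where φ vanishes at the current
position *and* one step below aborts with :class:`ModelInconsistencyError`
rather than corrupting the trajectory silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import (AbsorbingStateError, ContractError,
                     ModelInconsistencyError)
from .model import SIM_STEP, DockingModel
from .presets import MOBILITY_RATE

__all__ = ["SimConfig", "SimState", "RateVector", "Trajectory",
           "build_rate_vector", "gillespie_step", "simulate", "run_replicates"]

#: log-densities below this are treated as exact zeros of φ.
_LOG_ZERO_THRESH = -1.0e5

_STATUS_DONE = 0
_STATUS_FULL = 1
_STATUS_DEAD_STATE = 2
_STATUS_ABSORBED = 3


@dataclass(frozen=True)
class SimConfig:
    """Settings of one simulation campaign.

    ``mobility_rate`` is the total rate of 0.5 nm spatial steps (s⁻¹); the
    model's absolute time scale is set only by the ratio of this rate to the
    tether rate constants, so times are model-time, not calibrated
    biological time.
    """

    mobility_rate: float = MOBILITY_RATE
    step: float = SIM_STEP
    d_start: float = 100.0
    d_max: float = 100.0
    t_end: float = 50.0
    n_reps: int = 100
    base_seed: int = 0
    n_start: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.step != SIM_STEP:
            raise ContractError(f"simulation step is fixed at {SIM_STEP} nm")
        if not (0 <= self.d_start <= self.d_max):
            raise ContractError("d_start must lie in [0, d_max]")
        if abs(self.d_start / self.step - round(self.d_start / self.step)) > 1e-9:
            raise ContractError("d_start must be a multiple of the step")
        if self.t_end <= 0:
            raise ContractError("t_end must be positive")


@dataclass(frozen=True)
class SimState:
    """Instantaneous state: time (s), gap (nm, on-grid) and tether counts."""

    t: float
    d: float
    n: tuple[int, int, int]


@dataclass(frozen=True)
class RateVector:
    """The eight reaction rates (down, up, bind×3, unbind×3) and their sum."""

    b: np.ndarray
    b0: float


@dataclass
class Trajectory:
    """Event-ordered history of one replicate.

    Arrays hold the state *after* each event; the state is piecewise constant
    between events and the final dwell is truncated at ``t_end``.
    """

    t: np.ndarray                 # event times, s; t[0] == 0
    d: np.ndarray                 # gap after each event, nm
    n: np.ndarray                 # (N, 3) tether counts after each event
    t_end: float
    seed: int                     # per-replicate RNG seed actually used
    rep_index: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.t) - 1

    def dwell_times(self) -> np.ndarray:
        """Duration each recorded state was occupied, closing at t_end."""
        return np.diff(np.concatenate([self.t, [self.t_end]]))


def _log_phi(model: DockingModel, idx: int, n) -> float:
    t = model.sim
    lp = t.log_boltz[idx]
    for i in range(3):
        lp += n[i] * t.log_g[i, idx]
    return lp


def build_rate_vector(state: SimState, model: DockingModel,
                      mobility_rate: float = MOBILITY_RATE) -> RateVector:
    """Reference (pure-Python) rate evaluation for a legal state."""
    grid = model.sim.d_grid
    ratio = state.d / SIM_STEP
    idx = int(round(ratio))
    if abs(ratio - idx) > 1e-9 or not (0 <= idx < len(grid)):
        raise ContractError(f"distance {state.d} nm is off the simulation grid")
    b = np.zeros(8)
    if idx == 0:
        m = 0.0
    else:
        lp_here = _log_phi(model, idx, state.n)
        lp_down = _log_phi(model, idx - 1, state.n)
        here_zero = lp_here < _LOG_ZERO_THRESH
        down_zero = lp_down < _LOG_ZERO_THRESH
        if here_zero and down_zero:
            raise ModelInconsistencyError(
                f"φ vanishes at d={state.d} and d−Δ for occupancy {state.n}")
        if down_zero:
            m = 0.0
        elif here_zero:
            m = 1.0
        else:
            diff = np.clip(lp_here - lp_down, -700.0, 700.0)
            m = 1.0 / (1.0 + np.exp(diff))
        b[0] = mobility_rate * m
    b[1] = 0.0 if idx == len(grid) - 1 else mobility_rate * (1.0 - m)
    for i, spec in enumerate(model.specs):
        gon = model.sim.profiles[i].values[idx]
        b[2 + i] = gon * spec.kon_max * (spec.n_total - state.n[i])
        b[5 + i] = spec.koff * state.n[i]
    return RateVector(b, float(b.sum()))


def gillespie_step(rates: RateVector, rng) -> tuple[float, int]:
    """Draw the waiting time and reaction index for the next event.

    Returns ``(τ, j)`` with τ = ln(1/q₁)/b₀ and ``j`` the first index whose
    cumulative rate reaches q₂·b₀ (0-based, in the order down, up, bind×3,
    unbind×3).
    """
    if rates.b0 <= 0:
        raise AbsorbingStateError("total reaction rate is zero")
    q1 = rng.random()
    while q1 == 0.0:
        q1 = rng.random()
    tau = np.log(1.0 / q1) / rates.b0
    target = rng.random() * rates.b0
    acc = 0.0
    for j, bj in enumerate(rates.b):
        acc += bj
        if acc >= target:
            return tau, j
    return tau, len(rates.b) - 1


@njit(cache=True)
def _event_loop(seed, do_seed, t0, t_end, idx0, n0, nd,
                mobility, log_boltz, log_g, gon, konmax, koff, ntot,
                out_t, out_d, out_n):  # pragma: no cover - compiled
    if do_seed:
        np.random.seed(seed)
    cap = out_t.shape[0]
    t = t0
    idx = idx0
    n = n0.copy()
    rec = 0
    b = np.zeros(8)
    status = _STATUS_DONE
    while True:
        # movement probability m(d, n)
        if idx == 0:
            m = 0.0
        else:
            lp_here = log_boltz[idx]
            lp_down = log_boltz[idx - 1]
            for i in range(3):
                lp_here += n[i] * log_g[i, idx]
                lp_down += n[i] * log_g[i, idx - 1]
            here_zero = lp_here < _LOG_ZERO_THRESH
            down_zero = lp_down < _LOG_ZERO_THRESH
            if here_zero and down_zero:
                status = _STATUS_DEAD_STATE
                break
            if down_zero:
                m = 0.0
            elif here_zero:
                m = 1.0
            else:
                diff = lp_here - lp_down
                if diff > 700.0:
                    m = 0.0
                elif diff < -700.0:
                    m = 1.0
                else:
                    m = 1.0 / (1.0 + np.exp(diff))
        b[0] = mobility * m
        b[1] = 0.0 if idx == nd - 1 else mobility * (1.0 - m)
        b0 = b[0] + b[1]
        for i in range(3):
            b[2 + i] = gon[i, idx] * konmax[i] * (ntot[i] - n[i])
            b[5 + i] = koff[i] * n[i]
            b0 += b[2 + i] + b[5 + i]
        if b0 <= 0.0:
            status = _STATUS_ABSORBED
            break
        q1 = np.random.random()
        while q1 == 0.0:
            q1 = np.random.random()
        t = t + np.log(1.0 / q1) / b0
        if t > t_end:
            status = _STATUS_DONE
            break
        target = np.random.random() * b0
        acc = 0.0
        j = 7
        for jj in range(8):
            acc += b[jj]
            if acc >= target:
                j = jj
                break
        if j == 0:
            idx -= 1
        elif j == 1:
            idx += 1
        elif j < 5:
            n[j - 2] += 1
        else:
            n[j - 5] -= 1
        out_t[rec] = t
        out_d[rec] = idx
        out_n[rec, 0] = n[0]
        out_n[rec, 1] = n[1]
        out_n[rec, 2] = n[2]
        rec += 1
        if rec == cap:
            status = _STATUS_FULL
            break
    return rec, status, t, idx, n[0], n[1], n[2]


def replicate_seed(base_seed: int, rep_index: int) -> int:
    """Derive an independent 32-bit stream seed for one replicate."""
    return int(np.random.SeedSequence([base_seed, rep_index]).generate_state(1)[0])


def simulate(model: DockingModel, cfg: SimConfig, rep_index: int = 0) -> Trajectory:
    """Run one replicate of the jump process and return its trajectory.

    The replicate starts at ``(t=0, d=d_start, n=n_start)``; iteration stops
    once the next event would fall beyond ``t_end`` (the final dwell is
    truncated there by downstream analyses).  The RNG stream is derived from
    ``(base_seed, rep_index)``, so the same pair reproduces the trajectory
    bit for bit.
    """
    if abs(model.geometry.d_max - cfg.d_max) > 1e-9:
        raise ContractError("model d_max and SimConfig d_max disagree")
    tables = model.sim
    nd = len(tables.d_grid)
    gon = np.vstack([p.values for p in tables.profiles])
    konmax = np.array([s.kon_max for s in model.specs])
    koff = np.array([s.koff for s in model.specs])
    ntot = np.array([s.n_total for s in model.specs], dtype=np.int64)
    if any(cfg.n_start[i] > ntot[i] for i in range(3)):
        raise ContractError("n_start exceeds a species' copy number")
    seed = replicate_seed(cfg.base_seed, rep_index)

    cap = int(cfg.mobility_rate * cfg.t_end * 1.1) + 100_000
    chunks_t, chunks_d, chunks_n = [], [], []
    t0, idx = 0.0, int(round(cfg.d_start / SIM_STEP))
    n_cur = np.array(cfg.n_start, dtype=np.int64)
    do_seed = True
    while True:
        out_t = np.empty(cap)
        out_d = np.empty(cap, dtype=np.int32)
        out_n = np.empty((cap, 3), dtype=np.int16)
        rec, status, t0, idx, n1, n2, n3 = _event_loop(
            np.uint32(seed), do_seed, t0, cfg.t_end, idx, n_cur, nd,
            cfg.mobility_rate, tables.log_boltz, tables.log_g,
            gon, konmax, koff, ntot, out_t, out_d, out_n)
        chunks_t.append(out_t[:rec])
        chunks_d.append(out_d[:rec])
        chunks_n.append(out_n[:rec])
        if status == _STATUS_FULL:
            n_cur = np.array([n1, n2, n3], dtype=np.int64)
            do_seed = False
            continue
        if status == _STATUS_DEAD_STATE:
            raise ModelInconsistencyError(
                f"φ vanished at grid index {idx} and below for counts "
                f"({n1}, {n2}, {n3}) at t={t0:.6f} s")
        if status == _STATUS_ABSORBED:
            raise AbsorbingStateError(
                f"total rate dropped to zero at grid index {idx}, t={t0:.6f} s")
        break

    t = np.concatenate([[0.0]] + chunks_t)
    d = tables.d_grid[np.concatenate(
        [[int(round(cfg.d_start / SIM_STEP))]] + chunks_d).astype(np.int64)]
    n = np.vstack([[cfg.n_start]] + chunks_n).astype(np.int16)
    return Trajectory(t=t, d=d, n=n, t_end=cfg.t_end, seed=seed,
                      rep_index=rep_index,
                      meta={"config": {**cfg.__dict__,
                                       "n_start": list(cfg.n_start)},
                            "model": model.describe(),
                            "rng": "numba MT19937, np.random.seed(seed)"})


def run_replicates(model: DockingModel, cfg: SimConfig,
                   n_reps: int | None = None) -> list[Trajectory]:
    """Simulate ``n_reps`` independent replicates (defaults to cfg.n_reps)."""
    reps = cfg.n_reps if n_reps is None else n_reps
    return [simulate(model, cfg, rep) for rep in range(reps)]
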