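"""Gillespie direct-method event loop and trajectory recording.

One event of the simulation draws two uniform variates: the first sets the
exponentially distributed waiting time ``tau = ln(1/u1) / sum(alpha)``, the
second picks the reaction channel with probability proportional to its
propensity.  The state is advanced by the channel's change vector and the
cycle repeats until the time horizon, an absorbing state (zero total
propensity), or the event budget is reached.

Two interchangeable backends execute the loop: a compiled kernel
(:mod:`mablabel._core`) used by default, and a pure-Python reference used in
tests.  Both consume the same random stream and are bit-identical for a
given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import _core
from .reaction_network import (
    STATE_FIELDS,
    RateConstants,
    SystemState,
)

__all__ = [
    "AbsorbingStateError",
    "EventRecord",
    "EventLog",
    "RecordingPolicy",
    "Trajectory",
    "sample_waiting_time",
    "select_channel",
    "step",
    "run",
]

#: Trajectory status codes (shared with the compiled kernel).
STATUS_REACHED_T_END = 0
STATUS_ABSORBED = 1
STATUS_TRUNCATED = 2


class AbsorbingStateError(RuntimeError):
    """Total propensity is zero: no further reaction can ever fire."""


@dataclass(frozen=True)
class EventRecord:
    """A single reaction event: absolute time, channel index, waiting interval."""

    t: float
    channel_index: int
    tau: float


@dataclass(frozen=True)
class EventLog:
    """Columnar per-event records (time, channel, waiting interval)."""

    t: np.ndarray
    channel: np.ndarray
    tau: np.ndarray
    overflowed: bool = False

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self) -> Iterator[EventRecord]:
        for i in range(len(self.t)):
            yield EventRecord(float(self.t[i]), int(self.channel[i]),
                              float(self.tau[i]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "channel": self.channel,
                             "tau": self.tau})


@dataclass(frozen=True)
class RecordingPolicy:
    """What to record along a run.

    ``snapshot_times`` is a monotone grid; each grid point receives the state
    that held at that instant (the last state before the next event).  Full
    event logs are opt-in -- a labeling run generates millions of events --
    and are capped at ``log_capacity`` records.
    """

    snapshot_times: np.ndarray | None = None
    keep_event_log: bool = False
    max_events: int = 10 ** 8
    log_capacity: int = 8_000_000

    def __post_init__(self) -> None:
        if self.max_events < 1:
            raise ValueError("max_events must be >= 1")
        if self.snapshot_times is not None:
            st = np.asarray(self.snapshot_times, dtype=np.float64)
            if st.ndim != 1 or (len(st) > 1 and not np.all(np.diff(st) > 0)):
                raise ValueError("snapshot_times must be strictly increasing")
            object.__setattr__(self, "snapshot_times", st)

    @staticmethod
    def uniform(t_end: float, n_points: int = 300, t0: float = 0.0,
                **kwargs) -> "RecordingPolicy":
        """Uniform grid of ``n_points`` intervals over [t0, t_end]."""
        return RecordingPolicy(
            snapshot_times=np.linspace(t0, t_end, n_points + 1), **kwargs)

    @staticmethod
    def logarithmic(t_end: float, t_min: float = 1e-6, n_points: int = 300,
                    **kwargs) -> "RecordingPolicy":
        """Log-spaced grid, suited to wash runs spanning many decades."""
        grid = np.concatenate(([0.0], np.geomspace(t_min, t_end, n_points)))
        return RecordingPolicy(snapshot_times=grid, **kwargs)


@dataclass(frozen=True)
class Trajectory:
    """Recorded snapshots and final state of one stochastic run."""

    times: np.ndarray
    counts: np.ndarray          # shape (n_snapshots, 6), STATE_FIELDS order
    A_s: int
    initial_state: SystemState
    final_state: SystemState
    event_count: int
    status: int
    seed: int
    event_log: EventLog | None = None

    @property
    def truncated(self) -> bool:
        return self.status == STATUS_TRUNCATED

    @property
    def absorbed(self) -> bool:
        return self.status == STATUS_ABSORBED

    def series(self, name: str) -> np.ndarray:
        """Snapshot trace of one state field (or the derived ``ABC``)."""
        if name == "ABC":
            return (self.counts[:, STATE_FIELDS.index("AR")]
                    + self.counts[:, STATE_FIELDS.index("ARR")])
        return self.counts[:, STATE_FIELDS.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(STATE_FIELDS))
        df.insert(0, "t", self.times)
        df["ABC"] = df["AR"] + df["ARR"]
        return df


def sample_waiting_time(total_propensity: float, u1: float) -> float:
    """Waiting time to the next reaction: ``ln(1/u1) / total_propensity``.

    ``u1`` must lie in (0, 1]; the engine resamples a raw draw of exactly 0
    before calling.  A non-positive total propensity means the system is
    absorbing and no waiting time exists.
    """
    if total_propensity <= 0:
        raise AbsorbingStateError("total propensity is zero: no next event")
    if not 0.0 < u1 <= 1.0:
        raise ValueError("u1 must lie in (0, 1]")
    return np.log(1.0 / u1) / total_propensity


def select_channel(alpha: Sequence[float], u2: float) -> int:
    """Pick the reaction channel: smallest j with cum(alpha)_j > u2 * total.

    Zero-propensity channels occupy zero-length segments and are never
    selected.
    """
    a = np.asarray(alpha, dtype=np.float64)
    total = a.sum()
    if total <= 0:
        raise AbsorbingStateError("all propensities are zero")
    if not 0.0 <= u2 < 1.0:
        raise ValueError("u2 must lie in [0, 1)")
    r = u2 * total
    cum = 0.0
    last_nonzero = 0
    for j, aj in enumerate(a):
        if aj > 0:
            last_nonzero = j
        cum += aj
        if cum > r:
            return j
    return last_nonzero  # guards against round-off at u2 -> 1


def step(state: SystemState, channels, rng: np.random.RandomState
         ) -> tuple[SystemState, EventRecord]:
    """Execute one direct-method event (two uniform draws) on a state object."""
    from .reaction_network import apply_channel, propensities

    alpha = propensities(state, channels)
    total = float(alpha.sum())
    u1 = rng.random_sample()
    while u1 == 0.0:
        u1 = rng.random_sample()
    tau = sample_waiting_time(total, u1)
    ch = select_channel(alpha, rng.random_sample())
    new = apply_channel(state, channels[ch], tau)
    return new, EventRecord(new.t, ch, tau)


def _run_python(counts, A_s, rates, t0, t_end, snap_times, seed,
                max_events, log_capacity):
    """Pure-Python mirror of the compiled kernel (same stream, same logic)."""
    rng = np.random.RandomState(seed)
    c = counts.copy()
    change = _core.CHANGE_MATRIX
    t = t0
    n_snap = len(snap_times)
    snaps = np.zeros((n_snap, 6), dtype=np.int64)
    si = 0
    log_t, log_tau, log_ch = [], [], []
    log_overflow = False
    n_events = 0
    status = STATUS_REACHED_T_END
    alpha = np.empty(10)

    while True:
        if n_events >= max_events:
            status = STATUS_TRUNCATED
            break
        alpha[0] = rates[0] * A_s
        alpha[1] = rates[1] * c[0]
        alpha[2] = rates[2] * c[0]
        alpha[3] = rates[3] * c[1]
        alpha[4] = rates[4] * c[1]
        alpha[5] = rates[5] * c[2]
        alpha[6] = rates[6] * c[2] * c[5]
        alpha[7] = rates[7] * c[3]
        alpha[8] = rates[8] * c[3] * c[5]
        alpha[9] = rates[9] * c[4]
        total = 0.0
        for j in range(10):  # sequential accumulation, as in the kernel
            total += alpha[j]
        if total <= 0.0:
            status = STATUS_ABSORBED
            break
        u1 = rng.random_sample()
        while u1 == 0.0:
            u1 = rng.random_sample()
        tau = np.log(1.0 / u1) / total
        t_next = t + tau
        while si < n_snap and snap_times[si] < t_next:
            snaps[si] = c
            si += 1
        if t_next > t_end:
            t = t_end
            break
        u2 = rng.random_sample()
        r = u2 * total
        cum = 0.0
        ch = 9
        for j in range(10):
            cum += alpha[j]
            if cum > r:
                ch = j
                break
        c += change[ch]
        t = t_next
        n_events += 1
        if log_capacity > 0:
            if len(log_t) < log_capacity:
                log_t.append(t)
                log_tau.append(tau)
                log_ch.append(ch)
            else:
                log_overflow = True

    snaps[si:] = c
    return (snaps, c, t, n_events, status,
            np.array(log_t), np.array(log_tau),
            np.array(log_ch, dtype=np.int8), log_overflow)


def run(initial: SystemState, rates: RateConstants, t_end: float,
        policy: RecordingPolicy | None = None, seed: int = 0,
        backend: str = "compiled") -> Trajectory:
    """Simulate the reaction network from ``initial`` until ``t_end``.

    Parameters
    ----------
    initial : SystemState
        Starting counts, including the constant source count ``A_s``.
    rates : RateConstants
        The ten channel rate constants.
    t_end : float
        Time horizon (s); must exceed ``initial.t``.
    policy : RecordingPolicy, optional
        Snapshot grid and event-log options.  Defaults to 300 uniform
        intervals over [initial.t, t_end] with no event log.
    seed : int
        Seed for the Mersenne-Twister stream; identical inputs and seed give
        a bit-identical trajectory.
    backend : {"compiled", "python"}
        The compiled kernel is the default; the Python path is a slow
        reference that produces the identical trajectory.

    Returns
    -------
    Trajectory
        Snapshots on the grid, the final state, the event count, and the
        event log when requested.
    """
    if t_end <= initial.t:
        raise ValueError("t_end must exceed the initial time")
    if policy is None:
        policy = RecordingPolicy.uniform(t_end, t0=initial.t)
    snap_times = (policy.snapshot_times if policy.snapshot_times is not None
                  else np.linspace(initial.t, t_end, 301))
    log_capacity = policy.log_capacity if policy.keep_event_log else 0

    args = (initial.as_array(), initial.A_s, rates.as_array(),
            float(initial.t), float(t_end), snap_times, int(seed),
            int(policy.max_events), int(log_capacity))
    if backend == "compiled":
        out = _core.run_direct(*args, _core.CHANGE_MATRIX)
    elif backend == "python":
        out = _run_python(*args)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    snaps, final_counts, t_final, n_events, status, lt, ltau, lch, overflow = out
    if status == STATUS_TRUNCATED:
        warnings.warn(
            f"run stopped after max_events={policy.max_events} events at "
            f"t={t_final:.6g} s (horizon {t_end} s)", RuntimeWarning,
            stacklevel=2)
    final_state = SystemState.from_array(final_counts, initial.A_s, t_final)
    log = None
    if policy.keep_event_log:
        log = EventLog(t=lt, channel=lch.astype(np.int64), tau=ltau,
                       overflowed=bool(overflow))
    return Trajectory(times=snap_times.copy(), counts=snaps,
                      A_s=initial.A_s, initial_state=initial,
                      final_state=final_state, event_count=int(n_events),
                      status=int(status), seed=int(seed), event_log=log)
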