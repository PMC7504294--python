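"""Output writers, run configuration, interval histograms, equilibrium detection.

Outputs are plain text by contract: trajectory and ensemble CSVs (RFC-4180,
header row, UTF-8, '.' decimal separator) and a summary JSON carrying the
mean/SD/CV% block plus full provenance (parameters, seeds, package version).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .population_ensemble import CellResult, EnsembleSummary
from .reaction_network import CHANNEL_ORDER, RateConstants
from .ssa_engine import EventLog, Trajectory

__all__ = [
    "RunConfig",
    "IntervalHistogram",
    "interval_histogram",
    "detect_equilibrium",
    "write_trajectory_csv",
    "write_ensemble_csv",
    "write_event_log_csv",
    "write_summary_json",
    "read_summary_json",
]

CONFIG_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run; round-trips through YAML."""

    scenario: str = "labeling"
    preset: str = "similar"
    R0: int = 100_000
    A_s: int = 3000
    t_end: float = 30.0
    seed: int = 0
    n_cells: int = 25
    rate_overrides: dict = field(default_factory=dict)
    keep_event_log: bool = False
    out_dir: str = "."
    schema_version: int = CONFIG_SCHEMA_VERSION

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("schema_version", 1) != CONFIG_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported config schema_version {data.get('schema_version')}")
        return cls(**data)


@dataclass(frozen=True)
class IntervalHistogram:
    """Log-spaced histogram of waiting intervals between reactions."""

    bin_edges: np.ndarray       # length n_bins + 1, strictly increasing (s)
    counts: np.ndarray          # length n_bins
    n_events: int
    per_group: dict | None = None  # channel-group name -> counts array

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "count": self.counts,
        })
        if self.per_group:
            for name, c in self.per_group.items():
                df[f"count_{name}"] = c
        return df


#: Channel groups used for the optional histogram breakdown.
_CHANNEL_GROUPS = {
    "diffusion": (0, 1, 2, 3),      # layer hops
    "adsorption": (4, 5),           # on/off the surface
    "binding": (6, 7, 8, 9),        # receptor reactions
}


def interval_histogram(event_log: EventLog, bins_per_decade: int = 5,
                       time_window: tuple[float, float] | None = None,
                       by_group: bool = False) -> IntervalHistogram:
    """Histogram the waiting intervals of an event log on a log-time axis.

    ``time_window`` restricts to events with absolute time in [t0, t1],
    which supports early-vs-late comparisons of a wash run.  Bin edges are
    decade-aligned with ``bins_per_decade`` bins per decade, spanning the
    observed tau range.
    """
    if len(event_log) == 0:
        raise ValueError("event log is empty")
    mask = np.ones(len(event_log), dtype=bool)
    if time_window is not None:
        t0, t1 = time_window
        mask = (event_log.t >= t0) & (event_log.t <= t1)
    taus = event_log.tau[mask]
    if taus.size == 0:
        raise ValueError("no events in the requested time window")
    lo = np.floor(np.log10(taus.min()))
    hi = np.ceil(np.log10(taus.max()))
    if hi <= lo:
        hi = lo + 1
    n_bins = int(round((hi - lo) * bins_per_decade))
    edges = np.logspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(taus, bins=edges)
    per_group = None
    if by_group:
        ch = event_log.channel[mask]
        per_group = {}
        for name, members in _CHANNEL_GROUPS.items():
            gmask = np.isin(ch, members)
            per_group[name], _ = np.histogram(taus[gmask], bins=edges)
    return IntervalHistogram(bin_edges=edges, counts=counts,
                             n_events=int(taus.size), per_group=per_group)


def detect_equilibrium(trajectory: Trajectory, fields: Sequence[str],
                       window: float = 5.0, rel_tol: float = 0.05
                       ) -> float | None:
    """Earliest time at which the named fields settle onto their final value.

    Scans the snapshot grid for the earliest time ``t*`` such that, for
    every named field, every snapshot in ``[t*, t* + window]`` stays within
    ``rel_tol`` of the field's final value (absolute tolerance 1 count for
    near-zero finals).  The final value is estimated as the mean over the
    trailing ``window`` seconds rather than the last snapshot alone, so the
    reference is not biased by a single counting fluctuation.  Returns
    ``None`` if no window qualifies.
    """
    times = trajectory.times
    if len(times) < 2 or times[-1] - times[0] < window:
        raise ValueError("trajectory must span at least the window")
    ok = np.ones(len(times), dtype=bool)
    tail = times >= times[-1] - window
    for name in fields:
        trace = trajectory.series(name).astype(float)
        final = trace[tail].mean()
        tol = max(abs(final) * rel_tol, 1.0)
        ok &= np.abs(trace - final) <= tol
    ends = np.searchsorted(times, times + window, side="right")
    horizon = times[-1] + 1e-12
    for i in range(len(times)):
        if times[i] + window > horizon:
            break  # window would extend past the recorded horizon
        if ok[i:ends[i]].all():
            return float(times[i])
    return None


def _rates_dict(rates: RateConstants) -> dict:
    return {name: getattr(rates, name) for name in CHANNEL_ORDER}


def write_trajectory_csv(trajectory: Trajectory, path: str | Path) -> Path:
    """Trajectory snapshots as CSV with header t, A_b, ..., R, ABC."""
    path = Path(path)
    trajectory.to_dataframe().to_csv(path, index=False)
    return path


def write_event_log_csv(event_log: EventLog, path: str | Path) -> Path:
    path = Path(path)
    event_log.to_dataframe().to_csv(path, index=False)
    return path


def write_ensemble_csv(results: Sequence[CellResult], path: str | Path
                       ) -> Path:
    """One row per cell: cell_id, seed, R_init, k_bp, AR, ARR, R_free, ABC."""
    path = Path(path)
    pd.DataFrame([{
        "cell_id": r.cell_id, "seed": r.seed, "R_init": r.R_init,
        "k_bp": r.k_bp_used, "AR": r.AR, "ARR": r.ARR,
        "R_free": r.R_free, "ABC": r.abc,
    } for r in results]).to_csv(path, index=False)
    return path


def write_summary_json(path: str | Path, *, summary: EnsembleSummary | None
                       = None, rates: RateConstants | None = None,
                       config: RunConfig | None = None,
                       extra: dict | None = None) -> Path:
    """Summary JSON: mean/SD/CV% block plus full provenance."""
    payload: dict = {"version": __version__}
    if summary is not None:
        payload["summary"] = summary.to_dict()
        payload["n_cells"] = summary.n_cells
    if rates is not None:
        payload["rates"] = _rates_dict(rates)
    if config is not None:
        payload["config"] = asdict(config)
    if extra:
        payload["extra"] = extra
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_summary_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
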