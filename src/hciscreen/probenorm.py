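"""Probe normalization by beta-lactamase activity.

Recombinant ectodomain probes carry a beta-lactamase tag; hydrolysis of the
colorimetric substrate nitrocefin, read as absorbance at 485 nm over time,
quantifies the active probe in a sample.  Equalizing hydrolysis rates by
dilution equalizes probe activity before screening.  The slowest probe is
the reference by default, so every prescription is a dilution (factor >= 1):
concentrating a sample is a wet-lab step this module does not prescribe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress


class ActivityInputError(ValueError):
    """An activity series or rate map is invalid."""


@dataclass
class ActivitySeries:
    """A485 time course for one probe at one dilution."""

    probe_id: str
    dilution: float
    times: np.ndarray  # seconds, strictly increasing
    a485: np.ndarray  # absorbance units

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.a485 = np.asarray(self.a485, dtype=np.float64)
        if self.times.size < 3:
            raise ActivityInputError("activity series needs >= 3 points")
        if self.times.size != self.a485.size:
            raise ActivityInputError("times and a485 must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ActivityInputError("times must be strictly increasing")
        if not np.all(np.isfinite(self.a485)) or np.any(self.a485 < 0):
            raise ActivityInputError("a485 readings must be finite and >= 0")


@dataclass
class NormalizationPlan:
    """Dilution prescription equalizing one probe to the reference."""

    probe_id: str
    rate: float  # AU/s
    relative_activity: float
    dilution_factor: float
    below_reference: bool = False


def hydrolysis_rate(
    series: ActivitySeries, linear_window: tuple[float, float] | None = None
) -> float:
    """Ordinary-least-squares slope of A485 vs time (AU/s).

    ``linear_window`` restricts the fit to times in ``[t0, t1]`` (inclusive);
    the default is the full series.  A constant series has rate 0.
    """
    t, y = series.times, series.a485
    if linear_window is not None:
        t0, t1 = linear_window
        sel = (t >= t0) & (t <= t1)
        t, y = t[sel], y[sel]
        if t.size < 3:
            raise ActivityInputError("fewer than 3 points in the linear window")
    if np.ptp(y) == 0:
        return 0.0
    return float(linregress(t, y).slope)


def normalize_probes(
    rates: Mapping[str, float], reference: str | None = None
) -> list[NormalizationPlan]:
    """Turn per-probe rates into dilution factors relative to a reference.

    The reference is the slowest probe by default, so all factors are >= 1.
    With an explicit reference, probes slower than it cannot be equalized by
    dilution: they get factor 1 and the ``below_reference`` flag.
    """
    if not rates:
        raise ActivityInputError("empty rate map")
    for pid, r in rates.items():
        if not np.isfinite(r) or r <= 0:
            raise ActivityInputError(f"rate for {pid!r} must be positive, got {r}")
    if reference is None:
        ref_rate = min(rates.values())
    else:
        if reference not in rates:
            raise ActivityInputError(f"unknown reference probe {reference!r}")
        ref_rate = rates[reference]
    plans = []
    for pid in rates:
        rel = rates[pid] / ref_rate
        below = rel < 1.0
        plans.append(
            NormalizationPlan(
                probe_id=pid,
                rate=float(rates[pid]),
                relative_activity=float(rel),
                dilution_factor=1.0 if below else float(rel),
                below_reference=below,
            )
        )
    return plans


def dilution_series(fold: float = 2.0, steps: int = 7) -> list[float]:
    """Serial dilution factors, e.g. fold=2, steps=7 -> 2, 4, ..., 128."""
    if fold <= 1 or steps < 1:
        raise ActivityInputError("fold must be > 1 and steps >= 1")
    return [float(fold**k) for k in range(1, steps + 1)]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def load_activity_csv(path: str | Path) -> list[ActivitySeries]:
    """Read an activity table (probe_id, dilution, time_s, a485)."""
    df = pd.read_csv(path)
    required = {"probe_id", "dilution", "time_s", "a485"}
    missing = required - set(df.columns)
    if missing:
        raise ActivityInputError(f"activity CSV missing columns: {sorted(missing)}")
    out = []
    for (pid, dil), grp in df.groupby(["probe_id", "dilution"], sort=True):
        grp = grp.sort_values("time_s")
        out.append(
            ActivitySeries(
                probe_id=str(pid),
                dilution=float(dil),
                times=grp["time_s"].to_numpy(),
                a485=grp["a485"].to_numpy(),
            )
        )
    return out


def plans_to_frame(plans: Sequence[NormalizationPlan]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "probe_id": p.probe_id,
                "rate": p.rate,
                "relative_activity": p.relative_activity,
                "dilution_factor": p.dilution_factor,
                "below_reference": p.below_reference,
            }
            for p in plans
        ]
    )
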