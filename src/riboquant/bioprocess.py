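"""Bioprocess metrics from batch-culture time series: specific growth
rate, integral viable cell density (IVCD), and specific productivity.

Specific productivity (qp) is the least-squares slope of titer against
IVCD within a growth-phase window, converted to pg/cell/day.  The value
is invariant to consistent unit rescaling of VCD and titer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

REQUIRED_COLUMNS = ("time_d", "vcd_per_ml", "viability_pct", "titer_ug_ml")


@dataclass(frozen=True)
class PhaseWindow:
    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("t_start must be < t_end")


EARLY_PHASE = PhaseWindow("early", 1.0, 4.0)
LATE_PHASE = PhaseWindow("late", 5.0, 7.0)


@dataclass
class QpResult:
    qp_pg_per_cell_day: float
    intercept: float
    r_squared: float
    n_points: int


def load_culture_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"culture CSV missing columns: {missing}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    for _, sub in df.groupby("replicate"):
        t = sub["time_d"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing per replicate")
    if (df["vcd_per_ml"] < 0).any() or (df["titer_ug_ml"] < 0).any():
        raise ValueError("vcd and titer must be non-negative")
    return df


def _window_mask(time: np.ndarray, window: PhaseWindow | None) -> np.ndarray:
    if window is None:
        return np.ones(len(time), dtype=bool)
    return (time >= window.t_start) & (time <= window.t_end)


def specific_growth_rate(
    time: Sequence[float], vcd: Sequence[float], window: PhaseWindow | None = None
) -> float:
    """Least-squares slope of ln(VCD) versus time (1/day)."""
    t = np.asarray(time, dtype=float)
    v = np.asarray(vcd, dtype=float)
    mask = _window_mask(t, window)
    t, v = t[mask], v[mask]
    if len(t) < 2:
        raise ValueError("need >= 2 points in the window")
    if np.any(v <= 0):
        raise ValueError("vcd must be > 0 for growth-rate estimation")
    return float(sps.linregress(t, np.log(v)).slope)


def ivcd(time: Sequence[float], vcd: Sequence[float]) -> np.ndarray:
    """Cumulative trapezoidal integral of VCD over time (cell*day/mL)."""
    t = np.asarray(time, dtype=float)
    v = np.asarray(vcd, dtype=float)
    if len(t) < 2:
        raise ValueError("need >= 2 points")
    return integrate.cumulative_trapezoid(v, t, initial=0.0)


def specific_productivity(
    time: Sequence[float],
    vcd: Sequence[float],
    titer: Sequence[float],
    window: PhaseWindow | None = None,
) -> QpResult:
    """qp as the slope of titer (ug/mL) vs IVCD (cell*day/mL), in pcd."""
    t = np.asarray(time, dtype=float)
    v = np.asarray(vcd, dtype=float)
    p = np.asarray(titer, dtype=float)
    x_all = ivcd(t, v)
    mask = _window_mask(t, window)
    x, y, n = x_all[mask], p[mask], int(mask.sum())
    if n < 2:
        raise ValueError("need >= 2 points in the window")
    if np.ptp(x) == 0:
        raise ValueError("degenerate IVCD: no cell-time accumulated in window")
    fit = sps.linregress(x, y)
    return QpResult(
        qp_pg_per_cell_day=float(fit.slope * 1e6),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=n,
    )


def phase_metrics(
    df: pd.DataFrame,
    windows: Sequence[PhaseWindow] = (EARLY_PHASE, LATE_PHASE),
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-phase growth rate and qp, per replicate or pooled.

    With ``pooled=True`` all replicates enter one regression per phase;
    otherwise each replicate is fit separately (mean +/- SD is then the
    caller's summary of choice).
    """
    rows = []
    groups = [("pooled", df)] if pooled else list(df.groupby("replicate"))
    for rep, sub in groups:
        sub = sub.sort_values("time_d")
        t = sub["time_d"].to_numpy()
        v = sub["vcd_per_ml"].to_numpy()
        p = sub["titer_ug_ml"].to_numpy()
        for w in windows:
            qp = specific_productivity(t, v, p, window=w)
            rows.append(
                {
                    "replicate": rep,
                    "phase": w.label,
                    "mu_per_day": specific_growth_rate(t, v, window=w),
                    "qp_pg_per_cell_day": qp.qp_pg_per_cell_day,
                    "r_squared": qp.r_squared,
                    "n_points": qp.n_points,
                }
            )
    return pd.DataFrame(rows)
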