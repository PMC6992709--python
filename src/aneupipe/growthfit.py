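"""Doubling-time estimation from OD600 time series.

A smoothing spline is fitted to log2(OD) vs time; the maximum of its
derivative is the maximum specific growth rate (doublings per minute)
and its reciprocal the doubling time.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

#: initial equilibration period discarded by default (minutes)
DISCARD_MINUTES = 30.0
#: minimum dynamic range (max OD / min OD) required for a fit
MIN_RANGE = 2.0


@dataclass
class GrowthCurve:
    time: np.ndarray  # minutes
    od: np.ndarray
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.time) != len(self.od):
            raise ValueError("time and OD must have equal length")
        if not (np.diff(self.time) > 0).all():
            raise ValueError("time must be strictly increasing")


@dataclass
class DoublingEstimate:
    doubling_time: float  # minutes
    max_specific_growth: float  # log2 units per minute
    fit_window: tuple[float, float]
    replicate: str = "rep1"


def doubling_time(curve: GrowthCurve, smoothing: float | None = None,
                  discard_min: float = DISCARD_MINUTES) -> DoublingEstimate:
    """Doubling time = 1 / max slope of the log2(OD) smoothing spline.

    ``smoothing`` is the spline penalty; None selects it by generalized
    cross-validation. The first ``discard_min`` minutes are dropped.
    """
    keep = curve.time >= curve.time[0] + discard_min
    t = curve.time[keep]
    od = curve.od[keep]
    if len(t) < 8:
        raise ValueError("need at least 8 points after equilibration discard")
    if (od <= 0).any():
        raise ValueError("nonpositive OD reading")
    if od.max() / od.min() < MIN_RANGE:
        raise ValueError("insufficient dynamic range (max/min OD < 2)")
    y = np.log2(od)
    spl = make_smoothing_spline(t, y, lam=smoothing)
    slope = spl.derivative()(t)
    mu = float(slope.max())
    if mu <= 0:
        raise ValueError("no positive growth detected")
    return DoublingEstimate(
        doubling_time=1.0 / mu,
        max_specific_growth=mu,
        fit_window=(float(t[0]), float(t[-1])),
        replicate=curve.replicate,
    )


def relative_change(ancestor: DoublingEstimate, evolved: DoublingEstimate) -> float:
    """Percent decrease in doubling time; positive = faster evolved growth."""
    a, e = ancestor.doubling_time, evolved.doubling_time
    if a <= 0 or e <= 0:
        raise ValueError("doubling times must be positive")
    return 100.0 * (a - e) / a


def summarize_replicates(estimates: list[DoublingEstimate]) -> dict:
    times = np.array([e.doubling_time for e in estimates])
    return {
        "mean_doubling_time": float(times.mean()),
        "sd_doubling_time": float(times.std(ddof=1)) if len(times) > 1 else 0.0,
        "n": len(times),
    }


def read_plate_tsv(path) -> dict[str, GrowthCurve]:
    """Plate-reader long-format TSV: columns well, time_min, od."""
    df = pd.read_csv(path, sep="\t")
    curves = {}
    for well, g in df.groupby("well"):
        g = g.sort_values("time_min")
        curves[str(well)] = GrowthCurve(time=g["time_min"].to_numpy(),
                                        od=g["od"].to_numpy(), replicate=str(well))
    return curves


def write_estimates_tsv(estimates: dict[str, DoublingEstimate], path) -> None:
    rows = [
        {"sample": k, "doubling_time_min": e.doubling_time,
         "max_specific_growth": e.max_specific_growth}
        for k, e in estimates.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
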