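"""Size metrics and time normalisation of staged trials.

Vessel size is quantified by height, maximal diameter and the exterior
surface area (ESA) of the surface of revolution swept by the profile;
ESA serves as the overall size measure.  Trial time courses are mapped
onto a common scale by dividing the span between the first and last
fashioning gesture into a fixed number (default 20) of equally spaced
time bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .outline import GeometryError, Profile
from .synthetic import Trial

__all__ = [
    "SizeMetrics",
    "size_metrics",
    "coefficient_of_variation",
    "assign_time_bins",
    "trial_size_table",
]


@dataclass(frozen=True)
class SizeMetrics:
    height_cm: float
    max_diameter_cm: float
    esa_cm2: float


def size_metrics(p: Profile) -> SizeMetrics:
    """Height, maximal diameter and exterior surface area of a profile.

    ESA is the lateral area of the surface of revolution: the sum of
    frustum areas ``pi * (x_i + x_{i+1}) * slant_i`` over consecutive
    profile points.  Base and rim discs are excluded; the estimator is
    exact for cylinders and cones and second-order accurate otherwise.
    """
    if p.n_points < 2:
        raise GeometryError("size metrics need at least 2 profile points")
    x, y = p.x, p.y
    slant = np.hypot(np.diff(x), np.diff(y))
    esa = float(np.pi * np.sum((x[:-1] + x[1:]) * slant))
    return SizeMetrics(
        height_cm=float(y.max() - y.min()),
        max_diameter_cm=float(2.0 * x.max()),
        esa_cm2=esa,
    )


def coefficient_of_variation(values) -> float:
    """Coefficient of variation in percent: ``100 * SD / mean`` with the
    sample (n-1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    m = v.mean()
    if m == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


def assign_time_bins(t: Trial, n_bins: int = 20) -> pd.DataFrame:
    """Assign each stage of a trial to one of ``n_bins`` equal time bins.

    The span between the first and last gesture is split into left-closed
    bins; the first stage falls in bin 1 and the last is clamped into bin
    ``n_bins``.  Returns a frame with trial_id, stage_index, time_s, bin.
    """
    times = np.array([s.time_s for s in t.stages], dtype=float)
    if times.size < 2 or times[-1] <= times[0]:
        raise GeometryError(f"degenerate trial time span in {t.trial_id}")
    frac = (times - times[0]) / (times[-1] - times[0])
    bins = np.minimum(n_bins, np.floor(n_bins * frac).astype(int) + 1)
    return pd.DataFrame(
        {
            "trial_id": t.trial_id,
            "stage_index": [s.gesture_index for s in t.stages],
            "time_s": times,
            "bin": bins,
        }
    )


def trial_size_table(trials, n_bins: int = 20) -> pd.DataFrame:
    """Tidy per-stage size metrics with time bins for a set of trials.

    Columns: trial_id, potter_id, community, vessel_type, stage_index,
    time_s, bin, height_cm, max_diameter_cm, esa_cm2.
    """
    frames = []
    for tr in trials:
        binned = assign_time_bins(tr, n_bins=n_bins)
        metrics = [size_metrics(s.profile) for s in tr.stages]
        binned["potter_id"] = tr.potter_id
        binned["community"] = tr.community
        binned["vessel_type"] = tr.vessel_type
        binned["height_cm"] = [m.height_cm for m in metrics]
        binned["max_diameter_cm"] = [m.max_diameter_cm for m in metrics]
        binned["esa_cm2"] = [m.esa_cm2 for m in metrics]
        frames.append(binned)
    return pd.concat(frames, ignore_index=True)
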