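"""Phenotype readouts used as fitness proxies.

Three measurements: lysis time extracted from OD600 time courses of an
infected culture, plate-growth fitness as doublings per hour from titer
change over a fixed growth window, and endpoint transcription activity
from a fluorescence time course (which feeds the activity landscape).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError

#: Sentinel returned when a culture never lyses within the recorded window.
NO_LYSIS = "no lysis"

#: Default horizon of plate-growth fitness assays, hours.
DEFAULT_GROWTH_HOURS = 3.0


@dataclass
class GrowthCurve:
    """An OD600 (or fluorescence) time course.

    ``times`` in minutes, strictly increasing; at least three points.
    """

    times: np.ndarray
    od600: np.ndarray
    moi: float = 0.01
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.od600.shape:
            raise InputError("times and od600 must be 1-D arrays of equal length")
        if len(self.times) < 3:
            raise InputError("a growth curve needs at least 3 points")
        if not np.all(np.diff(self.times) > 0):
            raise InputError("times must be strictly increasing")
        if np.any(self.od600 < 0):
            raise InputError("OD values must be non-negative")


def lysis_time(
    curve: GrowthCurve,
    method: str = "threshold",
    threshold_fraction: float = 0.5,
) -> float | str:
    """Time (minutes) at which the infected culture lyses, or ``"no lysis"``.

    ``"threshold"``: first time after the OD maximum at which OD falls
    below ``threshold_fraction`` of that maximum. ``"max-decline"``: the
    midpoint of the sampling interval with the steepest negative slope
    after the maximum. Both are invariant to uniform positive scaling of
    the OD values; on an idealised sharp drop they agree to within the
    sampling interval.
    """
    t, od = curve.times, curve.od600
    i_max = int(np.argmax(od))
    peak = od[i_max]
    if method == "threshold":
        if not 0 < threshold_fraction < 1:
            raise InputError("threshold_fraction must be in (0, 1)")
        below = np.nonzero(od[i_max:] < threshold_fraction * peak)[0]
        if below.size == 0:
            return NO_LYSIS
        return float(t[i_max + below[0]])
    if method == "max-decline":
        if i_max >= len(t) - 1:
            return NO_LYSIS
        slopes = np.diff(od[i_max:]) / np.diff(t[i_max:])
        j = int(np.argmin(slopes))
        if slopes[j] >= 0:
            return NO_LYSIS
        return float(0.5 * (t[i_max + j] + t[i_max + j + 1]))
    raise InputError(f"unknown lysis-time method {method!r}")


def doublings_per_hour(initial_titer: float, final_titer: float, hours: float) -> float:
    """Plate-growth fitness: ``log2(final/initial) / hours``.

    Antisymmetric under swapping the titers and inversely proportional
    to the growth window. An 8-fold increase over 3 h is 1.0.
    """
    if initial_titer <= 0 or final_titer <= 0:
        raise InputError("titers must be positive")
    if hours <= 0:
        raise InputError("hours must be positive")
    return float(np.log2(final_titer / initial_titer) / hours)


def endpoint_activity(
    times: Sequence[float], values: Sequence[float], t_end: float = 60.0
) -> float:
    """Raw fluorescence at the sample closest to ``t_end`` minutes.

    This is the endpoint readout that, taken over replicates, feeds
    :func:`promoterpath.landscape.normalize_activity`.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1 or len(t) == 0:
        raise InputError("times and values must be 1-D arrays of equal length")
    if not t.min() <= t_end <= t.max():
        raise InputError(
            f"t_end={t_end} outside recorded range [{t.min()}, {t.max()}]"
        )
    return float(v[np.argmin(np.abs(t - t_end))])


# ---------------------------------------------------------------------------
# Curve I/O: long-format TSV (time_min, value, label)
# ---------------------------------------------------------------------------

def read_curves_tsv(path: str | FilePath, moi: float = 0.01) -> list[GrowthCurve]:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("time_min", "value", "label"):
        if col not in df.columns:
            raise InputError(f"curve table {path} lacks column {col!r}")
    curves = []
    for label, grp in df.groupby("label", sort=True):
        grp = grp.sort_values("time_min")
        curves.append(
            GrowthCurve(grp["time_min"].to_numpy(), grp["value"].to_numpy(),
                        moi=moi, label=str(label))
        )
    return curves


def write_curves_tsv(curves: Sequence[GrowthCurve], path: str | FilePath) -> None:
    rows = [
        {"time_min": t, "value": v, "label": c.label}
        for c in curves
        for t, v in zip(c.times, c.od600)
    ]
    pd.DataFrame(rows, columns=["time_min", "value", "label"]).to_csv(
        path, sep="\t", index=False
    )
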