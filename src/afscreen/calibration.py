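"""Linear RR calibration between a low-cost device and a gold standard.

A single-lead consumer recorder systematically mis-measures RR intervals
relative to a 12-lead reference.  The correction is an ordinary
least-squares affine map rr_gold ~ a + b * rr_lowcost fitted on paired
simultaneous measurements, then applied per patient.  Because an affine
map with b > 0 is strictly increasing, it cannot change any
ordinal-pattern (symbolic recurrence) feature of the series — only the
plain distribution moments move.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .core import RRSeries

__all__ = ["CalibrationModel", "fit_calibration", "apply_calibration", "mse"]

#: floor for calibrated intervals that would come out non-positive, seconds
EPS_RR = 1e-3


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted affine calibration rr_gold = intercept + slope * rr_lowcost."""

    intercept: float  # seconds
    slope: float  # dimensionless
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("calibration needs n >= 2")
        if not 0 <= self.r_squared <= 1:
            raise ValueError("r_squared must lie in [0, 1]")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["a"], d["b"] = d.pop("intercept"), d.pop("slope")
        path.write_text(json.dumps(d, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(intercept=d["a"], slope=d["b"], r_squared=d["r_squared"], n=d["n"])


def fit_calibration(pairs: Sequence[Tuple[float, float]]) -> CalibrationModel:
    """Ordinary least squares of gold-standard RR on low-cost RR.

    Parameters
    ----------
    pairs
        Sequence of (rr_lowcost, rr_gold) in seconds, n >= 2, with
        non-degenerate low-cost values.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("pairs must be an n x 2 sequence with n >= 2")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("low-cost RR values are all equal; cannot fit a slope")
    res = stats.linregress(x, y)
    return CalibrationModel(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        n=arr.shape[0],
    )


def apply_calibration(rr: RRSeries, model: CalibrationModel) -> RRSeries:
    """Map each interval to intercept + slope * value, preserving the label.

    A calibrated interval that comes out non-positive (possible with a
    negative intercept on extreme inputs) is clipped to a small positive
    floor with a warning rather than failing the whole batch.
    """
    values = model.intercept + model.slope * rr.values
    if np.any(values <= 0):
        warnings.warn(
            "calibration produced non-positive RR intervals; clipping to "
            f"{EPS_RR} s",
            stacklevel=2,
        )
        values = np.maximum(values, EPS_RR)
    return RRSeries(values, label=rr.label)


def mse(x: Sequence[float], y: Sequence[float]) -> float:
    """Mean squared difference (1/n) * sum (x_i - y_i)^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 1:
        raise ValueError("need at least one pair")
    return float(np.mean((x - y) ** 2))
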