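"""Age-depth interpolation from calibrated control points.

Bayesian age-depth modelling is out of scope here: the module consumes
already-calibrated point estimates (depth, age CE, age sd) and interpolates
them, linearly or with a shape-preserving monotone cubic.  The derivative of
the age-depth mapping gives the deposition time (years of accumulation per
cm of sediment) needed to convert charcoal concentrations into influx.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .records import ValidationError

__all__ = [
    "AgeModelMethod",
    "ChronologyTable",
    "AgeDepthModel",
    "build_age_model",
    "deposition_time",
    "read_chronology",
]

#: Finite-difference step for deposition time (cm); below typical sampling
#: resolution of the cores this package targets.
FD_STEP_CM = 0.1

#: Age ties finer than this (years) are treated as monotonicity violations.
AGE_TIE_RESOLUTION_YR = 0.01


class AgeModelMethod(enum.Enum):
    LINEAR = "LINEAR"
    MONOTONE_SPLINE = "MONOTONE_SPLINE"


@dataclass(frozen=True)
class ChronologyTable:
    """Ordered calibrated control points: (depth cm, age CE, age sd years)."""

    depths: tuple[float, ...]
    ages: tuple[float, ...]
    age_sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.depths) == len(self.ages) == len(self.age_sds)):
            raise ValidationError("control-point columns have unequal lengths")
        for i in range(1, len(self.depths)):
            if self.depths[i] <= self.depths[i - 1]:
                raise ValidationError("control-point depths must strictly increase")
            if self.ages[i] >= self.ages[i - 1]:
                raise ValidationError(
                    "control-point ages must strictly decrease with depth"
                )
        if any(sd < 0 for sd in self.age_sds):
            raise ValidationError("age_sd must be >= 0")

    def __len__(self) -> int:
        return len(self.depths)

    def perturbed(self, rng: np.random.Generator, max_tries: int = 1000) -> "ChronologyTable":
        """Gaussian age perturbation (sd = age_sd), monotone by rejection.

        Supports Monte-Carlo sensitivity runs that propagate chronological
        uncertainty into the downstream classification.
        """
        ages = np.asarray(self.ages)
        sds = np.asarray(self.age_sds)
        for _ in range(max_tries):
            draw = ages + rng.normal(0.0, 1.0, ages.size) * sds
            if np.all(np.diff(draw) < -AGE_TIE_RESOLUTION_YR):
                return ChronologyTable(self.depths, tuple(draw), self.age_sds)
        raise ValidationError("could not draw a monotone age perturbation")


@dataclass(frozen=True)
class AgeDepthModel:
    """Evaluable monotone mapping depth (cm) -> age (years CE)."""

    method: AgeModelMethod
    depths: tuple[float, ...]
    ages: tuple[float, ...]
    _interp: object

    @property
    def domain(self) -> tuple[float, float]:
        return (self.depths[0], self.depths[-1])

    def predict(self, depth) -> np.ndarray | float:
        """Age at ``depth``; beyond the control range, extrapolates with the
        terminal segment's slope (check :meth:`extrapolated`)."""
        d = np.asarray(depth, dtype=float)
        lo, hi = self.domain
        out = np.asarray(self._interp(np.clip(d, lo, hi)), dtype=float)
        # linear extrapolation with the end-segment slope
        slope_top = (self.ages[1] - self.ages[0]) / (self.depths[1] - self.depths[0])
        slope_bot = (self.ages[-1] - self.ages[-2]) / (self.depths[-1] - self.depths[-2])
        out = np.where(d < lo, self.ages[0] + (d - lo) * slope_top, out)
        out = np.where(d > hi, self.ages[-1] + (d - hi) * slope_bot, out)
        return float(out) if np.isscalar(depth) else out

    def extrapolated(self, depth) -> np.ndarray | bool:
        d = np.asarray(depth, dtype=float)
        lo, hi = self.domain
        flag = (d < lo) | (d > hi)
        return bool(flag) if np.isscalar(depth) else flag


def build_age_model(
    table: ChronologyTable, method: AgeModelMethod = AgeModelMethod.LINEAR
) -> AgeDepthModel:
    """Interpolate control points into an evaluable age-depth model.

    LINEAR joins consecutive points; MONOTONE_SPLINE uses a shape-preserving
    piecewise cubic (PCHIP), which cannot overshoot and therefore preserves
    the strict age decrease of the table.
    """
    if len(table) < 2:
        raise ValidationError("an age model needs at least 2 control points")
    d = np.asarray(table.depths)
    a = np.asarray(table.ages)
    if method is AgeModelMethod.LINEAR:
        interp = lambda x: np.interp(x, d, a)  # noqa: E731 - a closure suffices
    else:
        interp = PchipInterpolator(d, a)
    return AgeDepthModel(method=method, depths=table.depths, ages=table.ages, _interp=interp)


def deposition_time(model: AgeDepthModel, depth: float, h: float = FD_STEP_CM) -> float:
    """Years of deposition per cm of sediment at ``depth``.

    |d(age)/d(depth)| by central finite difference (one-sided at the domain
    boundaries).  Raises on a degenerate (zero-slope) segment, which would
    imply instantaneous deposition.
    """
    lo, hi = model.domain
    if depth < lo or depth > hi:
        raise ValidationError(f"depth {depth} outside model domain [{lo}, {hi}]")
    d0 = max(depth - h, lo)
    d1 = min(depth + h, hi)
    slope = (model.predict(d1) - model.predict(d0)) / (d1 - d0)
    dt = abs(slope)
    if dt <= 0.0:
        raise ValidationError(f"degenerate sedimentation (zero slope) at depth {depth}")
    return float(dt)


def read_chronology(path: str | Path) -> ChronologyTable:
    """Read a control-point CSV with columns depth, age, age_sd."""
    frame = pd.read_csv(path, encoding="utf-8")
    need = {"depth", "age", "age_sd"}
    if not need <= set(frame.columns):
        raise ValidationError(f"{path}: chronology CSV needs columns {sorted(need)}")
    frame = frame.sort_values("depth", kind="stable")
    return ChronologyTable(
        depths=tuple(float(x) for x in frame["depth"]),
        ages=tuple(float(x) for x in frame["age"]),
        age_sds=tuple(float(x) for x in frame["age_sd"]),
    )
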