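"""Weighted linear calibration curves and detection limits.

Curves are fitted by 1/x² weighted linear least squares on the analyte/IS
area ratio versus nominal concentration, the standard weighting for
bioanalytical LC-MS/MS assays where assay error is proportional to
concentration.  The correlation coefficient is the weighted Pearson r with
the same weights as the fit.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DegenerateDesignError, FitError, SchemaError

WEIGHTING_LABEL = "1/x^2"

#: back-calculation flags
IN_RANGE = "in_range"
BELOW_LLOQ = "below_lloq"
ABOVE_RANGE = "above_range"


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted weighted-linear response curve for one compound in one tissue.

    ``forward`` maps concentration (ng/mL) to area ratio, ``inverse`` the
    other way; the two are exact inverses of each other.
    """

    compound: str
    tissue: str
    slope: float
    intercept: float
    r: float
    range_low: float
    range_high: float
    lloq: float
    llod: float | None = None
    weighting: str = WEIGHTING_LABEL

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise FitError(f"slope must be > 0, got {self.slope}")
        if not 0 < self.range_low <= self.range_high:
            raise FitError(f"invalid range [{self.range_low}, {self.range_high}]")

    def forward(self, x: float) -> float:
        return self.slope * x + self.intercept

    def inverse(self, y: float) -> float:
        return (y - self.intercept) / self.slope

    def equation(self) -> str:
        """Display form with coefficients at 3 significant figures."""
        sign = "+" if self.intercept >= 0 else "-"
        return f"Y = {self.slope:.2e}X {sign} {abs(self.intercept):.2e}"


@dataclass(frozen=True)
class BackCalcResult:
    """Back-calculated concentration with its range flag."""

    value: float
    flag: str

    @property
    def in_range(self) -> bool:
        return self.flag == IN_RANGE


@dataclass(frozen=True)
class DetectionLimits:
    """LLOQ/LLOD estimates; ``None`` means no candidate level qualified."""

    lloq: float | None
    llod: float | None

    @property
    def determined(self) -> bool:
        return self.lloq is not None and self.llod is not None


def fit_weighted_linear(points: Sequence[tuple[float, float]],
                        compound: str = "", tissue: str = "",
                        weights: Sequence[float] | None = None) -> CalibrationCurve:
    """Fit ``y = slope*x + intercept`` minimising ``sum w_i (y_i - a x_i - b)^2``.

    Default weights are ``1/x_i^2``.  Requires at least three distinct
    positive concentration levels.  The curve's working range is
    ``[min x, max x]`` and its LLOQ is the lowest calibration level.
    """
    if len(points) < 3:
        raise FitError(f"need >= 3 calibration points, got {len(points)}")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.any(x <= 0):
        raise FitError("all calibration concentrations must be > 0")
    n_distinct = np.unique(x).size
    if n_distinct == 1:
        raise DegenerateDesignError("zero variance in calibration concentrations")
    if n_distinct < 3:
        raise FitError(f"need >= 3 distinct concentration levels, got {n_distinct}")
    w = np.asarray(weights, dtype=float) if weights is not None else 1.0 / x**2
    if w.shape != x.shape or np.any(w <= 0):
        raise FitError("weights must be positive and match the number of points")

    sw = np.sqrt(w)
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])

    r = weighted_pearson(x, y, w)
    low, high = float(x.min()), float(x.max())
    return CalibrationCurve(compound=compound, tissue=tissue,
                            slope=slope, intercept=intercept, r=r,
                            range_low=low, range_high=high, lloq=low)


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation coefficient, clipped to [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    cov = (w * (x - mx) * (y - my)).sum() / wsum
    vx = (w * (x - mx) ** 2).sum() / wsum
    vy = (w * (y - my) ** 2).sum() / wsum
    if vx == 0 or vy == 0:
        return math.nan
    return float(np.clip(cov / math.sqrt(vx * vy), -1.0, 1.0))


def back_calculate(curve: CalibrationCurve, y: float) -> BackCalcResult:
    """Invert the curve at area ratio *y* and flag the result against the range.

    Values below the LLOQ (including negative inversions) are returned
    as-is with the ``below_lloq`` flag — censoring is a downstream policy
    decision, never applied here.
    """
    value = curve.inverse(y)
    if value < curve.lloq:
        flag = BELOW_LLOQ
    elif value > curve.range_high:
        flag = ABOVE_RANGE
    else:
        flag = IN_RANGE
    return BackCalcResult(value=value, flag=flag)


def estimate_lloq_llod(blank_noise: float, curve: CalibrationCurve,
                       candidate_levels: Sequence[float],
                       sn_lloq: float = 10.0, sn_llod: float = 3.0) -> DetectionLimits:
    """Signal-to-noise detection limits over candidate concentration levels.

    The predicted net analyte signal at level ``x`` is ``slope * x``; the
    LLOQ is the lowest level with S/N >= 10 and the LLOD the lowest with
    S/N >= 3.  Returns ``None`` components when no level qualifies.
    """
    if not blank_noise > 0:
        raise ValueError(f"blank_noise must be > 0, got {blank_noise}")
    levels = list(candidate_levels)
    if any(b < a for a, b in zip(levels, levels[1:])):
        raise ValueError("candidate levels must be sorted ascending")
    lloq = llod = None
    for level in levels:
        sn = curve.slope * level / blank_noise
        if llod is None and sn >= sn_llod:
            llod = float(level)
        if lloq is None and sn >= sn_lloq:
            lloq = float(level)
            break
    return DetectionLimits(lloq=lloq, llod=llod)


# ---------------------------------------------------------------------------
# curve table CSV

CURVE_COLUMNS = ("compound", "tissue", "slope", "intercept", "r",
                 "range_low", "range_high", "lloq", "llod", "weighting", "equation")


def write_curves(curves: Iterable[CalibrationCurve], path) -> None:
    """Write a curve table; numeric columns keep full precision, the
    ``equation`` column shows coefficients at 3 significant figures and
    ``r`` is reported with 4 decimals."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CURVE_COLUMNS)
        for c in curves:
            writer.writerow([
                c.compound, c.tissue, repr(c.slope), repr(c.intercept),
                f"{c.r:.4f}", repr(c.range_low), repr(c.range_high),
                repr(c.lloq), "" if c.llod is None else repr(c.llod),
                c.weighting, c.equation(),
            ])


def read_curves(path) -> dict[tuple[str, str], CalibrationCurve]:
    """Read a curve table into a ``(compound, tissue) -> curve`` map."""
    curves: dict[tuple[str, str], CalibrationCurve] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        missing = {"compound", "tissue", "slope", "intercept", "r",
                   "range_low", "range_high", "lloq"} - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"curve table {path} missing column(s): {sorted(missing)}")
        for row in reader:
            llod = row.get("llod")
            curve = CalibrationCurve(
                compound=row["compound"], tissue=row["tissue"],
                slope=float(row["slope"]), intercept=float(row["intercept"]),
                r=float(row["r"]),
                range_low=float(row["range_low"]), range_high=float(row["range_high"]),
                lloq=float(row["lloq"]),
                llod=float(llod) if llod else None,
                weighting=row.get("weighting") or WEIGHTING_LABEL,
            )
            curves[(curve.compound, curve.tissue)] = curve
    return curves
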