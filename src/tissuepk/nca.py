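"""Noncompartmental AUC for destructive (sparse) sampling designs.

Each animal contributes a single time point, so no per-animal AUC exists;
the AUC is the linear trapezoid over the time-point means with C(0) = 0
prepended (oral dosing, no predose samples), and its standard error is the
Bailer sparse-sampling estimate

    se^2 = sum_i c_i^2 * sd_i^2 / n_i

with ``c_i`` the trapezoidal weight of point i.  Group comparison uses the
z statistic on the AUC difference over the pooled Bailer SE.  The AUC is
computed over [0, t_last] only — no terminal-slope extrapolation, which is
fragile with seven destructive points; a log-linear-down variant of the
integral is available but off by default.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .datamodel import ConcentrationProfile
from .errors import SchemaError, TissuePKError

METHOD_LABEL = "linear trapezoid, sparse"


@dataclass(frozen=True)
class AUCResult:
    compound: str
    tissue: str
    group: str
    auc: float  # ng*min/mL over [0, t_last]
    se: float
    n_points: int
    method: str = METHOD_LABEL

    def __post_init__(self) -> None:
        if self.auc < 0 or self.se < 0:
            raise TissuePKError(f"negative AUC/SE: {self.auc}, {self.se}")


def trapezoid_weights(times: Sequence[float], prepend_zero: bool = True) -> np.ndarray:
    """Bailer weight c_i of each observed time point's mean in the AUC.

    With a fixed C(0)=0 anchor, point i gets (t_{i+1} - t_{i-1}) / 2 (using
    t_0 = 0) and the last point (t_m - t_{m-1}) / 2.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("need at least one time point")
    if prepend_zero and t[0] > 0:
        t = np.concatenate([[0.0], t])
        observed = slice(1, None)
    else:
        observed = slice(None)
    m = t.size
    w = np.empty(m)
    for i in range(m):
        left = t[i] - t[i - 1] if i > 0 else 0.0
        right = t[i + 1] - t[i] if i < m - 1 else 0.0
        w[i] = (left + right) / 2.0
    return w[observed]


def auc_trapezoid(profile: ConcentrationProfile, prepend_zero: bool = True,
                  method: str = "linear") -> AUCResult:
    """Linear-trapezoid AUC of the profile means with Bailer sparse-design SE.

    Time points with n = 0 (censoring gaps) are skipped.  ``method`` may be
    ``"linear"`` or ``"linlog"`` (log trapezoid on declining positive
    segments; the SE always uses linear weights).
    """
    usable = profile.usable_points()
    if len(usable) < 2:
        raise TissuePKError(
            f"{profile.compound}/{profile.tissue}/{profile.group}: "
            f"need >= 2 usable time points, got {len(usable)}")
    times = [p.time_min for p in usable]
    means = [p.mean for p in usable]
    if any(m < 0 for m in means):
        raise TissuePKError("negative mean concentration")

    if prepend_zero and times[0] > 0:
        t_full = [0.0] + times
        c_full = [0.0] + means
    else:
        t_full = list(times)
        c_full = list(means)

    if method == "linear":
        auc = float(np.trapezoid(c_full, t_full))
    elif method == "linlog":
        auc = 0.0
        for (t0, c0), (t1, c1) in zip(zip(t_full, c_full), zip(t_full[1:], c_full[1:])):
            if c1 < c0 and c1 > 0 and c0 > 0:
                auc += (t1 - t0) * (c0 - c1) / math.log(c0 / c1)
            else:
                auc += (t1 - t0) * (c0 + c1) / 2.0
        auc = float(auc)
    else:
        raise ValueError(f"unknown AUC method {method!r}")

    weights = trapezoid_weights(times, prepend_zero=prepend_zero and times[0] > 0)
    var = 0.0
    for w, point in zip(weights, usable):
        if point.n > 0 and not math.isnan(point.sd):
            var += w**2 * point.sd**2 / point.n
    return AUCResult(compound=profile.compound, tissue=profile.tissue,
                     group=profile.group, auc=auc, se=math.sqrt(var),
                     n_points=len(usable),
                     method=METHOD_LABEL if method == "linear" else "linlog trapezoid, sparse")


@dataclass(frozen=True)
class GroupComparison:
    z: float
    p: float
    flag: str  # "ns", "*", "**"
    degenerate: bool = False


def compare_groups(a: AUCResult, b: AUCResult,
                   alpha: float = 0.05, alpha_strong: float = 0.01) -> GroupComparison:
    """Bailer z-test on the AUC difference between two groups.

    Both results must refer to the same compound and tissue.  With both SEs
    zero the comparison is degenerate: equal AUCs give z = 0 (ns), unequal
    AUCs an infinite z flagged significant.
    """
    if (a.compound, a.tissue) != (b.compound, b.tissue):
        raise ValueError(f"cannot compare {a.compound}/{a.tissue} with "
                         f"{b.compound}/{b.tissue}")
    pooled = math.hypot(a.se, b.se)
    diff = a.auc - b.auc
    if pooled == 0:
        if diff == 0:
            return GroupComparison(z=0.0, p=1.0, flag="ns", degenerate=True)
        return GroupComparison(z=math.copysign(math.inf, diff), p=0.0,
                               flag="**", degenerate=True)
    z = diff / pooled
    p = 2.0 * float(stats.norm.sf(abs(z)))
    if p < alpha_strong:
        flag = "**"
    elif p < alpha:
        flag = "*"
    else:
        flag = "ns"
    return GroupComparison(z=z, p=p, flag=flag)


# ---------------------------------------------------------------------------
# AUC table CSV

AUC_COLUMNS = ("compound", "tissue", "group", "auc", "se", "n_points",
               "method", "significance")


def write_auc_table(results: Iterable[AUCResult], path,
                    comparisons: dict[tuple[str, str], GroupComparison] | None = None,
                    ) -> None:
    comparisons = comparisons or {}
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(AUC_COLUMNS)
        for r in results:
            cmp_ = comparisons.get((r.compound, r.tissue))
            writer.writerow([r.compound, r.tissue, r.group, repr(r.auc),
                             repr(r.se), r.n_points, r.method,
                             cmp_.flag if cmp_ else ""])


def read_auc_table(path) -> list[AUCResult]:
    results = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        missing = {"compound", "tissue", "group", "auc", "se", "n_points"} \
            - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"AUC table {path} missing column(s): {sorted(missing)}")
        for row in reader:
            results.append(AUCResult(
                compound=row["compound"], tissue=row["tissue"], group=row["group"],
                auc=float(row["auc"]), se=float(row["se"]),
                n_points=int(row["n_points"]),
                method=row.get("method") or METHOD_LABEL))
    return results
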