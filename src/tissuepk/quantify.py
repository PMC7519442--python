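"""Back-calculate study peak records into concentration-time profiles.

Censoring of below-LLOQ values is a policy choice applied here, after
back-calculation: ``zero`` substitutes 0 (the conservative default for
tissue-distribution AUCs), ``lloq2`` substitutes LLOQ/2, ``drop`` removes
the value.  Above-range values are kept but the time point is flagged —
they are never silently extrapolated away.
"""

from __future__ import annotations

import math
import statistics
from typing import Iterable, Mapping, Sequence

from .calibration import ABOVE_RANGE, BELOW_LLOQ, CalibrationCurve, back_calculate
from .datamodel import ConcentrationProfile, PeakRecord, StudyDesign, TimePointStats
from .errors import QuantifyError

CENSOR_POLICIES = ("zero", "lloq2", "drop")


def _censor(value: float, lloq: float, policy: str) -> float | None:
    if policy == "zero":
        return 0.0
    if policy == "lloq2":
        return lloq / 2.0
    if policy == "drop":
        return None
    raise ValueError(f"unknown censoring policy {policy!r}")


def quantify_study(records: Iterable[PeakRecord],
                   curves: Mapping[tuple[str, str], CalibrationCurve],
                   policy: str = "zero",
                   design: StudyDesign | None = None,
                   sex: str | None = None) -> list[ConcentrationProfile]:
    """Convert study peak records to per-group concentration profiles.

    Sexes are pooled within each group; pass ``sex`` to restrict to one sex
    (shared organs then use half the animals).  Every (compound, tissue)
    present in the records must have a calibration curve.
    """
    if policy not in CENSOR_POLICIES:
        raise ValueError(f"unknown censoring policy {policy!r}; "
                         f"choose from {CENSOR_POLICIES}")
    study = [r for r in records if r.sample_kind == "study"]
    if sex is not None:
        study = [r for r in study if r.sex == sex]

    missing = sorted({(r.compound, r.tissue) for r in study} - set(curves))
    if missing:
        raise QuantifyError(f"no calibration curve for: {missing}")

    grouped: dict[tuple[str, str, str], dict[float, list[tuple[float, str]]]] = {}
    for record in study:
        curve = curves[(record.compound, record.tissue)]
        result = back_calculate(curve, record.area_ratio())
        key = (record.compound, record.tissue, record.group)
        grouped.setdefault(key, {}).setdefault(record.time_min, []).append(
            (result.value, result.flag))

    profiles: list[ConcentrationProfile] = []
    for key in sorted(grouped):
        compound, tissue, group = key
        curve = curves[(compound, tissue)]
        points: list[TimePointStats] = []
        times = sorted(grouped[key])
        if design is not None:
            times = [t for t in design.time_points_min if t in grouped[key]]
        for t in times:
            kept: list[float] = []
            flag = ""
            for value, bc_flag in grouped[key][t]:
                if bc_flag == BELOW_LLOQ:
                    replacement = _censor(value, curve.lloq, policy)
                    if replacement is not None:
                        kept.append(replacement)
                    continue
                if bc_flag == ABOVE_RANGE:
                    flag = "above_range"
                kept.append(value)
            if not kept:
                points.append(TimePointStats(time_min=t, values=(), mean=math.nan,
                                             sd=math.nan, n=0, flag="gap"))
                continue
            mean = statistics.fmean(kept)
            sd = statistics.stdev(kept) if len(kept) > 1 else 0.0
            points.append(TimePointStats(time_min=t, values=tuple(kept),
                                         mean=mean, sd=sd, n=len(kept), flag=flag))
        profiles.append(ConcentrationProfile(compound=compound, tissue=tissue,
                                             group=group, points=tuple(points)))
    return profiles
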