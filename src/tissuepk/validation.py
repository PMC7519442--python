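"""Bioanalytical method validation: precision, accuracy, recovery,
matrix effect and storage stability.

Acceptance follows the usual regulatory thresholds: |RE| <= 15 % and
RSD <= 15 % at all QC levels, relaxed to 20 % at the LLOQ level.
"""

from __future__ import annotations

import csv
import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

LEVELS = ("lloq", "low", "mid", "high")
CONDITIONS = ("fresh", "freeze_thaw", "short_term", "long_term", "preinjection")

RE_LIMIT = 15.0
RSD_LIMIT = 15.0
LLOQ_RE_LIMIT = 20.0
LLOQ_RSD_LIMIT = 20.0


def relative_error(measured_mean: float, nominal: float) -> float:
    """Accuracy as RE% = 100 * (measured - nominal) / nominal."""
    if not nominal > 0:
        raise ValueError(f"nominal must be > 0, got {nominal}")
    return 100.0 * (measured_mean - nominal) / nominal


def rsd(values: Sequence[float] | None = None, *,
        mean: float | None = None, sd: float | None = None) -> float:
    """Relative standard deviation in percent.

    Call either with a sequence of replicate values (sample SD, ddof=1) or
    with a printed ``mean=``/``sd=`` pair.
    """
    if values is not None:
        if mean is not None or sd is not None:
            raise TypeError("pass either values or (mean, sd), not both")
        values = list(values)
        if len(values) < 2:
            raise ValueError("need >= 2 values for an RSD")
        mean = statistics.fmean(values)
        sd = statistics.stdev(values)
    if mean is None or sd is None:
        raise TypeError("rsd() needs values or both mean= and sd=")
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * sd / mean


@dataclass(frozen=True)
class RatioStat:
    """Mean +/- SD (both %) of a paired peak-area ratio, with its RSD."""

    mean_pct: float
    sd_pct: float
    rsd_pct: float
    n: int


def _paired_ratio(numerator: Sequence[float], denominator: Sequence[float],
                  what: str) -> RatioStat:
    num = list(numerator)
    den = list(denominator)
    if not num or not den:
        raise ValueError(f"{what}: both area lists must be non-empty")
    if len(num) != len(den):
        raise ValueError(f"{what}: area lists must pair up, got {len(num)} vs {len(den)}")
    mean_den = statistics.fmean(den)
    if mean_den == 0:
        raise ValueError(f"{what}: reference areas have zero mean")
    if any(d == 0 for d in den):
        raise ValueError(f"{what}: reference area of 0 in pairing")
    mean_pct = 100.0 * statistics.fmean(num) / mean_den
    ratios = [100.0 * a / b for a, b in zip(num, den)]
    sd_pct = statistics.stdev(ratios) if len(ratios) > 1 else 0.0
    mean_ratio = statistics.fmean(ratios)
    rsd_pct = 100.0 * sd_pct / mean_ratio if mean_ratio else math.nan
    return RatioStat(mean_pct=mean_pct, sd_pct=sd_pct, rsd_pct=rsd_pct, n=len(ratios))


def recovery(extracted_qc_areas: Sequence[float],
             neat_standard_areas: Sequence[float]) -> RatioStat:
    """Extraction recovery: extracted-QC areas against neat standard areas.

    The mean is the ratio of the list means; the SD is taken across
    replicate pairs in input order.
    """
    return _paired_ratio(extracted_qc_areas, neat_standard_areas, "recovery")


def matrix_effect(postextraction_spiked_areas: Sequence[float],
                  neat_standard_areas: Sequence[float]) -> RatioStat:
    """Matrix effect: post-extraction spiked blank areas against neat standards."""
    return _paired_ratio(postextraction_spiked_areas, neat_standard_areas,
                         "matrix_effect")


@dataclass(frozen=True)
class QCBatch:
    """Back-calculated replicate concentrations of one QC run."""

    compound: str
    tissue: str
    level: str  # one of LEVELS
    nominal: float
    replicates: tuple[float, ...]
    day: int = 1
    condition: str = "fresh"

    def __post_init__(self) -> None:
        if not self.nominal > 0:
            raise ValueError(f"nominal must be > 0, got {self.nominal}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown QC level {self.level!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        object.__setattr__(self, "replicates", tuple(float(v) for v in self.replicates))

    def mean(self) -> float:
        return statistics.fmean(self.replicates)


def stability_re(condition_batches: Iterable[QCBatch]) -> dict[tuple[str, str], float]:
    """RE% per (condition, level) from pooled replicates, storage conditions only."""
    pools: dict[tuple[str, str], list[float]] = {}
    nominals: dict[tuple[str, str], float] = {}
    for batch in condition_batches:
        if batch.condition == "fresh":
            raise ValueError("stability_re expects storage-condition batches, got 'fresh'")
        key = (batch.condition, batch.level)
        pools.setdefault(key, []).extend(batch.replicates)
        nominals[key] = batch.nominal
    return {key: relative_error(statistics.fmean(vals), nominals[key])
            for key, vals in pools.items()}


@dataclass(frozen=True)
class LevelMetrics:
    """Intra-/inter-day precision and accuracy for one compound/tissue/level."""

    compound: str
    tissue: str
    level: str
    nominal: float
    intra_mean: float | None
    intra_rsd: float | None
    intra_re: float | None
    inter_mean: float | None
    inter_rsd: float | None
    inter_re: float | None
    n_days: int
    flags: tuple[str, ...] = ()

    def limits(self) -> tuple[float, float]:
        if self.level == "lloq":
            return LLOQ_RE_LIMIT, LLOQ_RSD_LIMIT
        return RE_LIMIT, RSD_LIMIT

    def passes(self) -> bool:
        re_lim, rsd_lim = self.limits()
        checks = [(self.intra_re, re_lim), (self.inter_re, re_lim)]
        spreads = [(self.intra_rsd, rsd_lim), (self.inter_rsd, rsd_lim)]
        for value, limit in checks:
            if value is not None and abs(value) > limit:
                return False
        for value, limit in spreads:
            if value is not None and value > limit:
                return False
        return True


@dataclass
class ValidationReport:
    """Assembled method-validation report."""

    levels: list[LevelMetrics] = field(default_factory=list)
    stability: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    recovery: dict[tuple[str, str, str], RatioStat] = field(default_factory=dict)
    matrix_effect: dict[tuple[str, str, str], RatioStat] = field(default_factory=dict)

    def all_pass(self) -> bool:
        ok = all(m.passes() for m in self.levels)
        ok = ok and all(abs(re) <= RE_LIMIT for re in self.stability.values())
        return ok

    def write_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(["compound", "tissue", "level", "nominal_ng_ml",
                             "intra_mean", "intra_rsd_pct", "intra_re_pct",
                             "inter_mean", "inter_rsd_pct", "inter_re_pct",
                             "n_days", "pass", "flags"])
            fmt = lambda v: "" if v is None else f"{v:.4f}"
            for m in self.levels:
                writer.writerow([m.compound, m.tissue, m.level, m.nominal,
                                 fmt(m.intra_mean), fmt(m.intra_rsd), fmt(m.intra_re),
                                 fmt(m.inter_mean), fmt(m.inter_rsd), fmt(m.inter_re),
                                 m.n_days, m.passes(), "|".join(m.flags)])

    def write_stability_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(["compound", "tissue", "level", "condition",
                             "re_pct", "pass"])
            for (compound, tissue, level, condition), re in sorted(self.stability.items()):
                writer.writerow([compound, tissue, level, condition,
                                 f"{re:.4f}", abs(re) <= RE_LIMIT])

    def write_markdown(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("# Method validation summary\n\n")
            handle.write(f"- accuracy/precision rows: {len(self.levels)}\n")
            handle.write(f"- stability cells: {len(self.stability)}\n")
            handle.write(f"- overall: {'PASS' if self.all_pass() else 'FAIL'}\n\n")
            handle.write("| compound | tissue | level | intra RSD% | intra RE% "
                         "| inter RSD% | inter RE% | pass |\n")
            handle.write("|---|---|---|---|---|---|---|---|\n")
            fmt = lambda v: "-" if v is None else f"{v:.2f}"
            for m in self.levels:
                handle.write(f"| {m.compound} | {m.tissue} | {m.level} "
                             f"| {fmt(m.intra_rsd)} | {fmt(m.intra_re)} "
                             f"| {fmt(m.inter_rsd)} | {fmt(m.inter_re)} "
                             f"| {'yes' if m.passes() else 'no'} |\n")


def assess(batches: Iterable[QCBatch],
           recovery_results: Mapping[tuple[str, str, str], RatioStat] | None = None,
           matrix_results: Mapping[tuple[str, str, str], RatioStat] | None = None,
           ) -> ValidationReport:
    """Build the validation report from QC batches.

    Intra-day metrics come from the replicates of the first day carrying at
    least two; inter-day metrics pool all replicates across days (grand
    mean/SD, matching a single printed inter-day value per level) and need
    at least two distinct days.  Storage-condition batches feed the
    stability section.  Gaps are flagged, not fatal.
    """
    fresh: dict[tuple[str, str, str], dict[int, list[float]]] = {}
    nominal: dict[tuple[str, str, str], float] = {}
    stability_batches: list[QCBatch] = []
    stability_meta: dict[tuple[str, str], tuple[str, str]] = {}
    for batch in batches:
        key = (batch.compound, batch.tissue, batch.level)
        nominal[key] = batch.nominal
        if batch.condition == "fresh":
            fresh.setdefault(key, {}).setdefault(batch.day, []).extend(batch.replicates)
        else:
            stability_batches.append(batch)

    report = ValidationReport()
    for key, by_day in sorted(fresh.items()):
        compound, tissue, level = key
        flags: list[str] = []
        intra_mean = intra_rsd = intra_re = None
        for day in sorted(by_day):
            reps = by_day[day]
            if len(reps) >= 2:
                intra_mean = statistics.fmean(reps)
                intra_rsd = rsd(reps)
                intra_re = relative_error(intra_mean, nominal[key])
                break
        if intra_mean is None:
            flags.append("missing_intra: no day with >= 2 replicates")
        pooled = [v for reps in by_day.values() for v in reps]
        inter_mean = inter_rsd = inter_re = None
        if len(by_day) >= 2 and len(pooled) >= 2:
            inter_mean = statistics.fmean(pooled)
            inter_rsd = rsd(pooled)
            inter_re = relative_error(inter_mean, nominal[key])
        else:
            flags.append("missing_inter: need >= 2 days")
        report.levels.append(LevelMetrics(
            compound=compound, tissue=tissue, level=level, nominal=nominal[key],
            intra_mean=intra_mean, intra_rsd=intra_rsd, intra_re=intra_re,
            inter_mean=inter_mean, inter_rsd=inter_rsd, inter_re=inter_re,
            n_days=len(by_day), flags=tuple(flags)))

    by_pair: dict[tuple[str, str], list[QCBatch]] = {}
    for batch in stability_batches:
        by_pair.setdefault((batch.compound, batch.tissue), []).append(batch)
    for (compound, tissue), group in by_pair.items():
        for (condition, level), re in stability_re(group).items():
            report.stability[(compound, tissue, level, condition)] = re

    if recovery_results:
        report.recovery.update(recovery_results)
    if matrix_results:
        report.matrix_effect.update(matrix_results)
    return report
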