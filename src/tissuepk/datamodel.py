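"""Domain types and file I/O for the tissue-distribution quantification pipeline.

Units are fixed throughout the package: concentrations in ng/mL of tissue
homogenate, time in minutes, peak areas in arbitrary detector units and AUC
in ng·min/mL.  The exchange format is a flat CSV with one row per injection
(:func:`read_peak_table` / :func:`write_peak_table`); the study design is a
small YAML document (:func:`load_design`), with a packaged default
describing a two-group destructive-sampling rat study over eight tissues
and seven time points.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import DesignError, RecordError, SchemaError

GROUPS = ("crude", "salt_processed")
SEXES = ("M", "F")
SAMPLE_KINDS = ("calibration", "qc", "study", "blank")
SEX_RULES = ("female_only", "male_only", "both")

#: Columns of the peak-table CSV, in writing order.
PEAK_COLUMNS = (
    "compound",
    "tissue",
    "sample_kind",
    "nominal_conc",
    "time_min",
    "animal_id",
    "sex",
    "group",
    "analyte_area",
    "is_area",
)


@dataclass(frozen=True)
class Compound:
    """An analyte with its ionization mode, internal standard and extract contents.

    ``content_crude`` / ``content_salt`` are the in-vitro amounts per gram of
    extract; both must be positive when content normalization of the
    salt-processed group's AUC is requested.
    """

    name: str
    ionization_mode: str = "negative"
    internal_standard: str = ""
    content_crude: float | None = None
    content_salt: float | None = None

    def __post_init__(self) -> None:
        if self.ionization_mode not in ("negative", "positive"):
            raise ValueError(f"unknown ionization mode {self.ionization_mode!r}")
        for label, value in (("content_crude", self.content_crude),
                             ("content_salt", self.content_salt)):
            if value is not None and value <= 0:
                raise ValueError(f"{label} must be > 0, got {value}")

    def content_ratio(self) -> float:
        """Salt/crude extract content ratio used for AUC normalization."""
        if self.content_crude is None or self.content_salt is None:
            raise ValueError(f"contents undefined for compound {self.name!r}")
        return self.content_salt / self.content_crude


@dataclass(frozen=True)
class StudyDesign:
    """Destructive-sampling two-group tissue study layout.

    ``animals_per_point_per_group`` is the number for shared organs; tissues
    marked ``female_only``/``male_only`` receive half that number (one sex).
    """

    tissues: tuple[str, ...]
    sex_specific: Mapping[str, str]
    time_points_min: tuple[float, ...]
    animals_per_point_per_group: int = 6
    groups: tuple[str, str] = GROUPS
    dose_volume_per_bw: float = 1.2  # mL per 200 g body weight
    homogenate_dilution_factor: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissues", tuple(self.tissues))
        object.__setattr__(self, "time_points_min", tuple(float(t) for t in self.time_points_min))
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "sex_specific", dict(self.sex_specific))
        tp = self.time_points_min
        if any(t <= 0 for t in tp):
            raise DesignError(f"time points must be positive, got {tp}")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise DesignError(f"time points must be strictly increasing, got {tp}")
        for tissue in self.tissues:
            rule = self.sex_specific.get(tissue)
            if rule is None:
                raise DesignError(f"no sex rule for tissue {tissue!r}")
            if rule not in SEX_RULES:
                raise DesignError(f"unknown sex rule {rule!r} for tissue {tissue!r}")
        if self.homogenate_dilution_factor < 1:
            raise DesignError("homogenate dilution factor must be >= 1")
        if self.animals_per_point_per_group < 1:
            raise DesignError("animals_per_point_per_group must be >= 1")

    def sexes_for(self, tissue: str) -> tuple[str, ...]:
        rule = self.sex_specific[tissue]
        if rule == "female_only":
            return ("F",)
        if rule == "male_only":
            return ("M",)
        return SEXES

    def animals_for(self, tissue: str) -> int:
        """Animals contributing this tissue per time point per group."""
        if self.sex_specific[tissue] == "both":
            return self.animals_per_point_per_group
        return self.animals_per_point_per_group // 2

    def expected_study_records(self, n_compounds: int) -> int:
        """Combinatorial record count of a complete study peak table."""
        per_time = sum(self.animals_for(t) for t in self.tissues)
        return n_compounds * per_time * len(self.time_points_min) * len(self.groups)


@dataclass(frozen=True)
class PeakRecord:
    """One injection: analyte and internal-standard integrated peak areas.

    ``nominal_conc`` is set for calibration/QC samples only; ``time_min``,
    ``animal_id``, ``sex`` and ``group`` are set for study samples.
    """

    compound: str
    tissue: str
    sample_kind: str
    analyte_area: float
    is_area: float
    nominal_conc: float | None = None
    time_min: float | None = None
    animal_id: str | None = None
    sex: str | None = None
    group: str | None = None

    def area_ratio(self) -> float:
        return self.analyte_area / self.is_area

    def check(self, design: StudyDesign | None = None) -> None:
        """Raise ``ValueError`` on the first violated invariant."""
        if self.sample_kind not in SAMPLE_KINDS:
            raise ValueError(f"unknown sample_kind {self.sample_kind!r}")
        if not self.is_area > 0:
            raise ValueError(f"is_area must be > 0, got {self.is_area}")
        if self.analyte_area < 0:
            raise ValueError(f"analyte_area must be >= 0, got {self.analyte_area}")
        if self.sample_kind in ("calibration", "qc"):
            if self.nominal_conc is None or not self.nominal_conc > 0:
                raise ValueError(
                    f"{self.sample_kind} record needs nominal_conc > 0, got {self.nominal_conc}")
        if self.sample_kind == "study":
            if self.time_min is None or self.time_min <= 0:
                raise ValueError(f"study record needs time_min > 0, got {self.time_min}")
            if self.animal_id in (None, ""):
                raise ValueError("study record needs animal_id")
            if self.sex not in SEXES:
                raise ValueError(f"study record needs sex M/F, got {self.sex!r}")
            if self.group in (None, ""):
                raise ValueError("study record needs group")
        if design is not None:
            if self.tissue not in design.tissues:
                raise ValueError(f"tissue {self.tissue!r} not in study design")
            if self.sample_kind == "study":
                if self.group not in design.groups:
                    raise ValueError(f"group {self.group!r} not in design groups {design.groups}")
                if self.sex not in design.sexes_for(self.tissue):
                    raise ValueError(
                        f"sex {self.sex!r} inconsistent with tissue {self.tissue!r} "
                        f"({design.sex_specific[self.tissue]})")


@dataclass(frozen=True)
class TimePointStats:
    """Per-animal concentrations and their summary at a single time point."""

    time_min: float
    values: tuple[float, ...]
    mean: float
    sd: float
    n: int
    flag: str = ""  # "", "gap", "above_range"


@dataclass(frozen=True)
class ConcentrationProfile:
    """Mean ± SD tissue concentration versus time for one compound/tissue/group."""

    compound: str
    tissue: str
    group: str
    points: tuple[TimePointStats, ...]

    def times(self) -> tuple[float, ...]:
        return tuple(p.time_min for p in self.points)

    def usable_points(self) -> tuple[TimePointStats, ...]:
        return tuple(p for p in self.points if p.n > 0)


# ---------------------------------------------------------------------------
# peak-table CSV

def _parse_float(text: str | None, column: str):
    if text is None or text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(f"column {column!r}: not a number: {text!r}") from exc


def read_peak_table(path, design: StudyDesign | None = None) -> list[PeakRecord]:
    """Read and validate a peak-table CSV.

    Every row must satisfy the :class:`PeakRecord` invariants (and match
    *design* when given); offending rows are reported together with their
    file line numbers via :class:`RecordError`.
    """
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        required = {"compound", "tissue", "sample_kind", "analyte_area", "is_area"}
        missing = required - set(header)
        if missing:
            raise SchemaError(f"peak table {path} missing column(s): {sorted(missing)}")
        records: list[PeakRecord] = []
        problems: list[tuple[int, str]] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                record = PeakRecord(
                    compound=row["compound"],
                    tissue=row["tissue"],
                    sample_kind=row["sample_kind"],
                    analyte_area=_parse_float(row["analyte_area"], "analyte_area") or 0.0,
                    is_area=_parse_float(row["is_area"], "is_area") or 0.0,
                    nominal_conc=_parse_float(row.get("nominal_conc"), "nominal_conc"),
                    time_min=_parse_float(row.get("time_min"), "time_min"),
                    animal_id=row.get("animal_id") or None,
                    sex=row.get("sex") or None,
                    group=row.get("group") or None,
                )
                record.check(design)
            except ValueError as exc:
                problems.append((lineno, str(exc)))
                continue
            records.append(record)
    if problems:
        if design is not None and all("not in study design" in m for _, m in problems):
            raise DesignError(
                "tissue(s) not in study design: "
                + "; ".join(f"row {r}: {m}" for r, m in problems))
        raise RecordError(problems)
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest lossless representation
    return str(value)


def write_peak_table(records: Iterable[PeakRecord], path) -> None:
    """Write records to CSV; lossless round-trip with :func:`read_peak_table`."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(PEAK_COLUMNS)
        for r in records:
            writer.writerow([
                r.compound, r.tissue, r.sample_kind,
                _fmt(r.nominal_conc), _fmt(r.time_min),
                _fmt(r.animal_id), _fmt(r.sex), _fmt(r.group),
                _fmt(r.analyte_area), _fmt(r.is_area),
            ])


# ---------------------------------------------------------------------------
# profiles CSV

PROFILE_COLUMNS = ("compound", "tissue", "group", "time_min",
                   "mean_ng_ml", "sd_ng_ml", "n", "flag")


def write_profiles(profiles: Sequence[ConcentrationProfile], path,
                   animals_path=None) -> None:
    """Write the summary profile table and, optionally, a long per-animal table."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(PROFILE_COLUMNS)
        for prof in profiles:
            for pt in prof.points:
                writer.writerow([prof.compound, prof.tissue, prof.group,
                                 _fmt(pt.time_min), _fmt(pt.mean), _fmt(pt.sd),
                                 pt.n, pt.flag])
    if animals_path is not None:
        with open(animals_path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(("compound", "tissue", "group", "time_min",
                             "replicate", "conc_ng_ml"))
            for prof in profiles:
                for pt in prof.points:
                    for i, value in enumerate(pt.values, start=1):
                        writer.writerow([prof.compound, prof.tissue, prof.group,
                                         _fmt(pt.time_min), i, _fmt(value)])


def read_profiles(path) -> list[ConcentrationProfile]:
    """Read a summary profile table (per-animal values are not reconstructed)."""
    rows: dict[tuple[str, str, str], list[TimePointStats]] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        missing = set(PROFILE_COLUMNS[:-1]) - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"profile table {path} missing column(s): {sorted(missing)}")
        for row in reader:
            key = (row["compound"], row["tissue"], row["group"])
            mean = _parse_float(row["mean_ng_ml"], "mean_ng_ml")
            sd = _parse_float(row["sd_ng_ml"], "sd_ng_ml")
            rows.setdefault(key, []).append(TimePointStats(
                time_min=float(row["time_min"]),
                values=(),
                mean=math.nan if mean is None else mean,
                sd=math.nan if sd is None else sd,
                n=int(row["n"]),
                flag=row.get("flag") or "",
            ))
    profiles = []
    for (compound, tissue, group), points in rows.items():
        points.sort(key=lambda p: p.time_min)
        profiles.append(ConcentrationProfile(compound, tissue, group, tuple(points)))
    profiles.sort(key=lambda p: (p.compound, p.tissue, p.group))
    return profiles


# ---------------------------------------------------------------------------
# study-design config

def default_design_path():
    return resources.files("tissuepk") / "data" / "default_design.yaml"


def load_design(path=None) -> StudyDesign:
    """Load a :class:`StudyDesign` from YAML; ``path=None`` loads the packaged default."""
    if path is None:
        text = default_design_path().read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as handle:
            text = handle.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise DesignError("design config must be a mapping")
    if "design" in doc and isinstance(doc["design"], dict):
        doc = doc["design"]
    try:
        tissues = tuple(doc["tissues"])
        sex_specific = dict(doc["sex_specific"])
        time_points = tuple(doc["time_points_min"])
    except KeyError as exc:
        raise DesignError(f"design config missing key {exc}") from exc
    kwargs = {}
    for key in ("animals_per_point_per_group", "groups", "dose_volume_per_bw",
                "homogenate_dilution_factor"):
        if key in doc:
            kwargs[key] = doc[key]
    return StudyDesign(tissues=tissues, sex_specific=sex_specific,
                       time_points_min=time_points, **kwargs)


def to_per_gram(conc_ng_ml: float, design: StudyDesign) -> float:
    """Convert homogenate ng/mL to ng per g of tissue via the dilution factor."""
    return conc_ng_ml * design.homogenate_dilution_factor
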