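"""Synthetic study generator with known ground truth.

Tissue concentration-time curves follow a one-compartment extravascular
shape C(t) = scale * (exp(-ke*t) - exp(-ka*t)), which rises and falls over
the 10-720 min window; it is a simulation device with an analytic AUC
(scale * (1/ke - 1/ka)), not a physiological claim.  Between-animal and
analytical variability are multiplicative lognormal factors with unit mean,
so simulated concentrations stay positive and the pipeline's mean profiles
are unbiased for the truth.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .calibration import CalibrationCurve, back_calculate
from .datamodel import GROUPS, PeakRecord, StudyDesign
from .validation import CONDITIONS, LEVELS, QCBatch

DEFAULT_IS_AREA = 1.0e5


@dataclass(frozen=True)
class Kinetics:
    """One-compartment extravascular concentration curve parameters."""

    ka: float  # absorption rate, 1/min
    ke: float  # elimination rate, 1/min
    scale: float  # ng/mL

    def __post_init__(self) -> None:
        if not (self.ka > self.ke > 0):
            raise ValueError(f"need ka > ke > 0, got ka={self.ka}, ke={self.ke}")
        if not self.scale >= 0:
            raise ValueError(f"scale must be >= 0, got {self.scale}")

    def conc(self, t: float) -> float:
        return self.scale * (math.exp(-self.ke * t) - math.exp(-self.ka * t))

    def auc_inf(self) -> float:
        """Closed-form AUC over [0, inf)."""
        return self.scale * (1.0 / self.ke - 1.0 / self.ka)

    def auc_discrete(self, times: Sequence[float]) -> float:
        """Trapezoid AUC of the noise-free curve on the design grid with C(0)=0."""
        t = [0.0] + [float(v) for v in times]
        c = [self.conc(v) for v in t]
        return float(np.trapezoid(c, t))


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated two-group tissue study."""

    kinetics: Mapping[tuple[str, str, str], Kinetics]  # (compound, tissue, group)
    between_animal_cv: float = 0.15
    analytical_cv: float = 0.05
    contents: Mapping[str, tuple[float, float]] = field(default_factory=dict)  # (crude, salt)
    seed: int = 0

    def __post_init__(self) -> None:
        for cv in (self.between_animal_cv, self.analytical_cv):
            if not 0 <= cv < 1:
                raise ValueError(f"CV must be in [0, 1), got {cv}")
        object.__setattr__(self, "kinetics", dict(self.kinetics))
        object.__setattr__(self, "contents", dict(self.contents))

    def compounds(self) -> list[str]:
        return sorted({key[0] for key in self.kinetics})


def _lognormal_multiplier(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal factor with the given coefficient of variation."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def generate_study(design: StudyDesign, truth: SimTruth,
                   curves: Mapping[tuple[str, str], CalibrationCurve],
                   seed: int | None = None) -> list[PeakRecord]:
    """Emit a complete study peak table for the design under the truth.

    Iteration order (compound, tissue, group, time, animal) and the single
    RNG stream make output byte-identical across runs for a fixed seed.
    Shared organs get half males then half females per point; sex-specific
    organs only the matching sex.  Warns once listing time points whose
    noise-free concentration exceeds the curve range.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    records: list[PeakRecord] = []
    saturated: list[tuple[str, str, str, float]] = []
    for compound in truth.compounds():
        for tissue in design.tissues:
            for group in design.groups:
                kin = truth.kinetics.get((compound, tissue, group))
                if kin is None:
                    raise KeyError(f"no kinetics for {(compound, tissue, group)}")
                curve = curves[(compound, tissue)]
                sexes = design.sexes_for(tissue)
                n = design.animals_for(tissue)
                for t in design.time_points_min:
                    if kin.conc(t) > curve.range_high:
                        saturated.append((compound, tissue, group, t))
                    for i in range(n):
                        sex = sexes[0] if (len(sexes) == 1 or i < n // 2) else sexes[1]
                        conc = (kin.conc(t)
                                * _lognormal_multiplier(rng, truth.between_animal_cv)
                                * _lognormal_multiplier(rng, truth.analytical_cv))
                        ratio = max(curve.forward(conc), 0.0)
                        records.append(PeakRecord(
                            compound=compound, tissue=tissue, sample_kind="study",
                            analyte_area=ratio * DEFAULT_IS_AREA,
                            is_area=DEFAULT_IS_AREA,
                            time_min=float(t),
                            animal_id=f"{group[:1]}-t{t:g}-{i + 1}",
                            sex=sex, group=group))
    if saturated:
        warnings.warn(f"{len(saturated)} design point(s) exceed the curve range, "
                      f"e.g. {saturated[:3]}", stacklevel=2)
    return records


def generate_calibration_records(curves: Mapping[tuple[str, str], CalibrationCurve],
                                 n_levels: int = 7, cv: float = 0.0,
                                 seed: int = 0) -> list[PeakRecord]:
    """Calibration-standard records at geometric levels spanning each curve's range."""
    rng = np.random.default_rng(seed)
    records = []
    for (compound, tissue) in sorted(curves):
        curve = curves[(compound, tissue)]
        levels = np.geomspace(curve.range_low, curve.range_high, n_levels)
        for level in levels:
            ratio = curve.forward(float(level)) * _lognormal_multiplier(rng, cv)
            records.append(PeakRecord(
                compound=compound, tissue=tissue, sample_kind="calibration",
                nominal_conc=float(level),
                analyte_area=max(ratio, 0.0) * DEFAULT_IS_AREA,
                is_area=DEFAULT_IS_AREA))
    return records


@dataclass(frozen=True)
class ValidationNoise:
    """Noise/bias specification for QC batch generation."""

    analytical_cv: float = 0.04
    condition_bias: Mapping[str, float] = field(default_factory=dict)  # fraction, e.g. -0.02
    days: int = 3
    replicates: int = 6

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition_bias", dict(self.condition_bias))
        for condition in self.condition_bias:
            if condition not in CONDITIONS or condition == "fresh":
                raise ValueError(f"unknown stability condition {condition!r}")


def qc_nominal_levels(curve: CalibrationCurve) -> dict[str, float]:
    """QC nominals derived from the curve: LLOQ, then low/mid/high in range."""
    return {
        "lloq": curve.lloq,
        "low": min(2.5 * curve.lloq, curve.range_high),
        "mid": 0.5 * curve.range_high,
        "high": 0.8 * curve.range_high,
    }


def generate_validation_records(curves: Mapping[tuple[str, str], CalibrationCurve],
                                noise: ValidationNoise | None = None,
                                seed: int = 0) -> list[PeakRecord]:
    """QC peak records: fresh replicates over days plus storage-condition sets.

    Day and condition are encoded in ``animal_id`` as ``day<d>.rep<r>`` and
    ``<condition>.rep<r>``; :func:`qc_batches_from_records` decodes them.
    """
    noise = noise or ValidationNoise()
    rng = np.random.default_rng(seed)
    records = []
    for (compound, tissue) in sorted(curves):
        curve = curves[(compound, tissue)]
        nominals = qc_nominal_levels(curve)
        for level in LEVELS:
            nominal = nominals[level]
            for day in range(1, noise.days + 1):
                for rep in range(1, noise.replicates + 1):
                    conc = nominal * _lognormal_multiplier(rng, noise.analytical_cv)
                    records.append(PeakRecord(
                        compound=compound, tissue=tissue, sample_kind="qc",
                        nominal_conc=nominal,
                        analyte_area=max(curve.forward(conc), 0.0) * DEFAULT_IS_AREA,
                        is_area=DEFAULT_IS_AREA,
                        animal_id=f"day{day}.rep{rep}"))
            if level == "lloq":
                continue  # stability assessed at low/mid/high only
            for condition, bias in noise.condition_bias.items():
                for rep in range(1, noise.replicates + 1):
                    conc = nominal * (1.0 + bias) \
                        * _lognormal_multiplier(rng, noise.analytical_cv)
                    records.append(PeakRecord(
                        compound=compound, tissue=tissue, sample_kind="qc",
                        nominal_conc=nominal,
                        analyte_area=max(curve.forward(conc), 0.0) * DEFAULT_IS_AREA,
                        is_area=DEFAULT_IS_AREA,
                        animal_id=f"{condition}.rep{rep}"))
    return records


def qc_batches_from_records(records: Iterable[PeakRecord],
                            curves: Mapping[tuple[str, str], CalibrationCurve],
                            ) -> list[QCBatch]:
    """Back-calculate QC records into :class:`QCBatch` groups.

    Level labels are assigned from the rank of the nominal within each
    compound/tissue (four nominals -> lloq/low/mid/high, three -> low/mid/high).
    """
    grouped: dict[tuple, list[float]] = {}
    for record in records:
        if record.sample_kind != "qc":
            continue
        tag = record.animal_id or "day1.rep1"
        head = tag.split(".", 1)[0]
        if head.startswith("day"):
            condition, day = "fresh", int(head[3:])
        else:
            condition, day = head, 1
        curve = curves[(record.compound, record.tissue)]
        value = back_calculate(curve, record.area_ratio()).value
        key = (record.compound, record.tissue, record.nominal_conc, condition, day)
        grouped.setdefault(key, []).append(value)

    nominal_rank: dict[tuple[str, str], dict[float, str]] = {}
    for (compound, tissue, nominal, _c, _d) in grouped:
        nominal_rank.setdefault((compound, tissue), {})[nominal] = ""
    for pair, nominals in nominal_rank.items():
        ordered = sorted(nominals)
        labels = LEVELS if len(ordered) == 4 else LEVELS[1:][:len(ordered)]
        for nominal, label in zip(ordered, labels):
            nominals[nominal] = label

    batches = []
    for (compound, tissue, nominal, condition, day), values in sorted(grouped.items()):
        batches.append(QCBatch(
            compound=compound, tissue=tissue,
            level=nominal_rank[(compound, tissue)][nominal],
            nominal=nominal, replicates=tuple(values),
            day=day, condition=condition))
    return batches


# ---------------------------------------------------------------------------
# demo builders used by the CLI and the test-suite

def demo_curves(design: StudyDesign, compounds: Sequence[str],
                seed: int = 0) -> dict[tuple[str, str], CalibrationCurve]:
    """Plausible per-compound-per-tissue curves (slopes 1e-3..5e-2, range 1-1000)."""
    rng = np.random.default_rng(seed)
    curves = {}
    for compound in compounds:
        for tissue in design.tissues:
            slope = float(10 ** rng.uniform(-3.0, -1.3))
            intercept = float(slope * rng.uniform(-5.0, 30.0))
            curves[(compound, tissue)] = CalibrationCurve(
                compound=compound, tissue=tissue, slope=slope,
                intercept=intercept, r=1.0, range_low=1.0, range_high=1000.0,
                lloq=1.0)
    return curves


def demo_truth(design: StudyDesign, compounds: Sequence[str],
               shifted_tissues: Sequence[str] = ("kidney", "uterus", "ovary", "testes"),
               shift: float = 1.8, content_ratio: float = 1.2,
               seed: int = 0) -> SimTruth:
    """Demo ground truth: salt group exposure shifted toward the given tissues.

    Scales are kept well inside the demo curve range so that censoring only
    triggers at late time points.
    """
    rng = np.random.default_rng(seed)
    kinetics = {}
    contents = {}
    for compound in compounds:
        contents[compound] = (1.0, content_ratio)
        for tissue in design.tissues:
            ka = float(rng.uniform(0.02, 0.06))
            ke = float(rng.uniform(0.003, 0.007))
            scale = float(rng.uniform(80.0, 400.0))
            kinetics[(compound, tissue, "crude")] = Kinetics(ka=ka, ke=ke, scale=scale)
            salt_scale = scale * content_ratio
            if tissue in shifted_tissues:
                salt_scale *= shift
            kinetics[(compound, tissue, "salt_processed")] = Kinetics(
                ka=ka, ke=ke, scale=salt_scale)
    return SimTruth(kinetics=kinetics, contents=contents, seed=seed)


def write_truth(truth: SimTruth, path) -> None:
    """YAML sidecar with the ground truth, for test assertions and audit."""
    doc = {
        "seed": truth.seed,
        "between_animal_cv": truth.between_animal_cv,
        "analytical_cv": truth.analytical_cv,
        "contents": {c: {"crude": v[0], "salt": v[1]}
                     for c, v in sorted(truth.contents.items())},
        "kinetics": [
            {"compound": c, "tissue": t, "group": g,
             "ka": k.ka, "ke": k.ke, "scale": k.scale,
             "auc_inf": k.auc_inf()}
            for (c, t, g), k in sorted(truth.kinetics.items())
        ],
    }
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False)


def read_truth(path) -> SimTruth:
    with open(path, encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    kinetics = {(e["compound"], e["tissue"], e["group"]):
                Kinetics(ka=e["ka"], ke=e["ke"], scale=e["scale"])
                for e in doc["kinetics"]}
    contents = {c: (v["crude"], v["salt"]) for c, v in doc.get("contents", {}).items()}
    return SimTruth(kinetics=kinetics,
                    between_animal_cv=doc["between_animal_cv"],
                    analytical_cv=doc["analytical_cv"],
                    contents=contents, seed=doc["seed"])
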