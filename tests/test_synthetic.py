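import math

import numpy as np
import pytest

from tissuepk.datamodel import write_peak_table
from tissuepk.nca import auc_trapezoid
from tissuepk.quantify import quantify_study
from tissuepk.synthetic import (Kinetics, SimTruth, ValidationNoise, demo_curves,
                                demo_truth, generate_calibration_records,
                                generate_study, generate_validation_records,
                                qc_batches_from_records, read_truth, write_truth)
from tissuepk.validation import assess, stability_re


class TestKinetics:
    def test_orders_required(self):
        with pytest.raises(ValueError):
            Kinetics(ka=0.001, ke=0.01, scale=1.0)

    def test_closed_form_auc(self):
        kin = Kinetics(ka=0.04, ke=0.005, scale=100.0)
        assert kin.auc_inf() == pytest.approx(100.0 * (1 / 0.005 - 1 / 0.04))

    def test_profile_rises_then_falls(self):
        kin = Kinetics(ka=0.04, ke=0.005, scale=100.0)
        concs = [kin.conc(t) for t in (10, 30, 90, 180, 360, 480, 720)]
        peak = concs.index(max(concs))
        assert 0 < peak < len(concs) - 1


def _single_tissue_setup(design, cv_animal=0.0, cv_assay=0.0, seed=0):
    compounds = ("cpd01",)
    curves = demo_curves(design, compounds, seed=seed)
    kinetics = {("cpd01", tissue, group): Kinetics(ka=0.03, ke=0.004, scale=200.0)
                for tissue in design.tissues for group in design.groups}
    truth = SimTruth(kinetics=kinetics, between_animal_cv=cv_animal,
                     analytical_cv=cv_assay, seed=seed)
    return truth, curves


class TestGenerateStudy:
    def test_record_count_matches_combinatorics(self, design):
        truth, curves = _single_tissue_setup(design)
        records = generate_study(design, truth, curves)
        assert len(records) == design.expected_study_records(1)

    def test_same_seed_byte_identical_csv(self, tmp_path, design):
        truth, curves = _single_tissue_setup(design, cv_animal=0.2, cv_assay=0.05)
        for name in ("a.csv", "b.csv"):
            write_peak_table(generate_study(design, truth, curves, seed=77),
                             tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_different_seed_differs(self, design):
        truth, curves = _single_tissue_setup(design, cv_animal=0.2)
        a = generate_study(design, truth, curves, seed=1)
        b = generate_study(design, truth, curves, seed=2)
        assert a != b

    def test_zero_cv_recovers_discretized_auc(self, design):
        truth, curves = _single_tissue_setup(design)
        records = generate_study(design, truth, curves)
        profiles = quantify_study(records, curves, design=design)
        kin = truth.kinetics[("cpd01", "kidney", "crude")]
        expected = kin.auc_discrete(design.time_points_min)
        for prof in profiles:
            result = auc_trapezoid(prof)
            assert result.auc == pytest.approx(expected, rel=1e-9)
            assert result.se == pytest.approx(0.0, abs=1e-9)

    def test_sex_specific_tissues_single_sex(self, design):
        truth, curves = _single_tissue_setup(design)
        records = generate_study(design, truth, curves)
        uterus = {r.sex for r in records if r.tissue == "uterus"}
        testes = {r.sex for r in records if r.tissue == "testes"}
        kidney = {r.sex for r in records if r.tissue == "kidney"}
        assert uterus == {"F"} and testes == {"M"} and kidney == {"M", "F"}

    def test_saturation_warning(self, design):
        compounds = ("cpd01",)
        curves = demo_curves(design, compounds, seed=0)
        kinetics = {("cpd01", t, g): Kinetics(ka=0.03, ke=0.004, scale=5000.0)
                    for t in design.tissues for g in design.groups}
        truth = SimTruth(kinetics=kinetics, seed=0)
        with pytest.warns(UserWarning, match="exceed the curve range"):
            generate_study(design, truth, curves)

    def test_pipeline_auc_unbiased(self, design):
        """Mean pipeline AUC over 200 simulations matches the discretized truth."""
        from tissuepk.datamodel import StudyDesign
        mini = StudyDesign(tissues=("kidney",), sex_specific={"kidney": "both"},
                           time_points_min=design.time_points_min,
                           groups=("crude",))
        curves = demo_curves(mini, ("cpd01",), seed=0)
        kin = Kinetics(ka=0.03, ke=0.004, scale=200.0)
        truth = SimTruth(kinetics={("cpd01", "kidney", "crude"): kin},
                         between_animal_cv=0.15, analytical_cv=0.05, seed=0)
        expected = kin.auc_discrete(mini.time_points_min)
        estimates = []
        key = ("cpd01", "kidney")
        for seed in range(200):
            records = generate_study(mini, truth, curves, seed=seed)
            (prof,) = quantify_study(records, {key: curves[key]})
            estimates.append(auc_trapezoid(prof).auc)
        mean = float(np.mean(estimates))
        mc_se = float(np.std(estimates, ddof=1) / math.sqrt(len(estimates)))
        assert abs(mean - expected) < 4 * mc_se + 1e-9


class TestCalibrationGenerator:
    def test_levels_span_range_and_refit(self, design):
        from tissuepk.calibration import fit_weighted_linear
        compounds = ("cpd01",)
        curves = demo_curves(design, compounds, seed=4)
        records = generate_calibration_records(curves, cv=0.0, seed=4)
        key = ("cpd01", "kidney")
        points = [(r.nominal_conc, r.area_ratio()) for r in records
                  if (r.compound, r.tissue) == key]
        assert len(points) == 7
        fitted = fit_weighted_linear(points)
        assert fitted.slope == pytest.approx(curves[key].slope, rel=1e-9)
        assert fitted.intercept == pytest.approx(curves[key].intercept, rel=1e-6)


class TestValidationGenerator:
    def _curves(self, design):
        return demo_curves(design, ("cpd01",), seed=6)

    def test_zero_noise_all_pass(self, design):
        curves = self._curves(design)
        records = generate_validation_records(
            curves, ValidationNoise(analytical_cv=0.0), seed=6)
        report = assess(qc_batches_from_records(records, curves))
        assert report.all_pass()
        assert all(m.intra_re == pytest.approx(0.0, abs=1e-9) for m in report.levels)

    def test_injected_bias_recovered(self, design):
        curves = self._curves(design)
        records = generate_validation_records(
            curves, ValidationNoise(analytical_cv=0.0,
                                    condition_bias={"freeze_thaw": -0.02}),
            seed=6)
        batches = [b for b in qc_batches_from_records(records, curves)
                   if b.condition != "fresh" and b.compound == "cpd01"
                   and b.tissue == "kidney"]
        res = stability_re(batches)
        for (condition, _level), re in res.items():
            assert condition == "freeze_thaw"
            assert re == pytest.approx(-2.0, abs=1e-9)

    def test_noise_targets_printed_rsd_scale(self, design):
        """Intra-day RSD at cv ~ 5.46 % lands within +/- 2 points over batches."""
        curves = {("cpd01", "kidney"): self._curves(design)[("cpd01", "kidney")]}
        rsds = []
        for seed in range(200):
            records = generate_validation_records(
                curves, ValidationNoise(analytical_cv=0.0546, days=1), seed=seed)
            report = assess(qc_batches_from_records(records, curves))
            low = [m for m in report.levels if m.level == "low"]
            rsds.append(low[0].intra_rsd)
        assert abs(float(np.mean(rsds)) - 5.46) < 2.0

    def test_batch_structure(self, design):
        curves = {("cpd01", "kidney"): self._curves(design)[("cpd01", "kidney")]}
        records = generate_validation_records(curves, ValidationNoise(), seed=1)
        batches = qc_batches_from_records(records, curves)
        fresh = [b for b in batches if b.condition == "fresh"]
        # 4 levels x 3 days
        assert len(fresh) == 12
        assert all(len(b.replicates) == 6 for b in fresh)
        assert {b.level for b in fresh} == {"lloq", "low", "mid", "high"}


class TestTruthSidecar:
    def test_yaml_round_trip(self, tmp_path, design):
        truth = demo_truth(design, ("cpd01", "cpd02"), seed=5)
        path = tmp_path / "truth.yaml"
        write_truth(truth, path)
        loaded = read_truth(path)
        assert loaded.kinetics == truth.kinetics
        assert loaded.contents == truth.contents
        assert loaded.seed == truth.seed
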