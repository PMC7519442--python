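# tissuepk

Quantification-through-targeting pipeline for LC-MS/MS tissue-distribution
studies of two-group (crude vs. salt-processed) herbal extracts:

- **calibration** — per-compound-per-tissue 1/x² weighted linear calibration
  curves on analyte/internal-standard peak-area ratios, with S/N-based
  LLOQ/LLOD estimation and flagged back-calculation
- **validation** — full bioanalytical method validation: intra-/inter-day
  precision and accuracy, extraction recovery, matrix effect, and
  four-condition storage stability, with |RE| ≤ 15 % / RSD ≤ 15 %
  (20 % at LLOQ) acceptance thresholds
- **quantify** — study peak records → per-animal concentrations →
  mean ± SD concentration-time profiles with selectable below-LLOQ
  censoring (`zero`, `lloq2`, `drop`)
- **nca** — sparse-sampling (destructive-design) noncompartmental AUC:
  linear trapezoid over [0, t_last] with C(0) = 0, Bailer standard error
  and z-test group comparison
- **targeting** — content-normalized relative targeting efficiency
  RTE = frac_salt / frac_crude − 1 per tissue (fractions of each group's
  total multi-tissue AUC), with ranked target classification
- **synthetic** — a deterministic study generator (one-compartment
  extravascular truth, lognormal animal/assay noise) so every stage is
  testable with known ground truth

The pipeline starts at integrated peak areas (flat CSV, one row per
injection); vendor raw files, peak picking and MRM management are out of
scope.  Units throughout: ng/mL homogenate, minutes, ng·min/mL.

## CLI

Each stage is a subcommand; `run-all` chains them and writes a
`MANIFEST.json` recording per-stage status (on failure the failing stage is
named and partial outputs are retained).

```sh
# full demo: simulate -> calibrate -> validate -> quantify -> nca -> rte
tissuepk run-all --out out/ --seed 1

# stage by stage
tissuepk simulate  --out sim/ --seed 1
tissuepk calibrate --peaks sim/peaks_calibration.csv --out curves.csv
tissuepk validate  --peaks sim/peaks_qc.csv --curves curves.csv --out val/
tissuepk quantify  --peaks sim/peaks_study.csv --curves curves.csv \
                   --censor zero --out q/
tissuepk nca       --profiles q/profiles.csv --out auc.csv
tissuepk rte       --auc auc.csv --out rte/
```

The default study design (8 tissues with sex-specific uterus/ovary/testes,
time points 10–720 min, 6 animals per point per group, 3 per sex) is
packaged; pass `--config my_design.yaml` to override.

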