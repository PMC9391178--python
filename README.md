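# qams

Single-marker multi-analyte quantification for nonlinear ELSD detectors.

Routine HPLC assays of multi-component materials (here the model system is
the eight fructooligosaccharides GF1–GF8 of *Morinda officinalis*, with
nystose GF3 as the marker) need one expensive reference standard per
analyte. The single-marker strategy — *quantitative analysis of
multi-components by a single marker* (QAMS) — replaces them with one
standard plus a **relative correction factor** (RCF) per analyte. On an
evaporative light scattering detector (ELSD) the response is a power law,

    A = 10^b · C^F    ⇔    lg A = F · lg C + b,

so the RCF has no single agreed definition. This package, aimed at
analytical chemists developing or validating QAMS assays, provides:

- **calibration** — per-analyte OLS fits of the log-log response, inverse
  prediction (area → concentration) with range flagging, and S/N-based
  LOD/LOQ;
- **rcf** — the six circulating RCF conventions (A: marker-curve readout
  `RCF = C_detected / C`; B: slope ratio `F_k / F_s`; C, D, E: per-level
  area/concentration ratios; F: no correction), assembled into comparable
  tables;
- **quantify** — external-standard (ESM) vs single-marker (QAMS,
  `C = C_detected / RCF`) contents in % w/w, the relative-error criterion
  `RE% = (QAMS − ESM)/ESM · 100`, and the ranking that selects the most
  accurate RCF convention;
- **validation** — RSD (n−1 convention), spike recovery, replicate
  summaries, cross-instrument RCF system suitability;
- **simulate** — a synthetic ELSD response generator with known ground
  truth, so every pipeline stage is testable without instrument data.

The core objects are sklearn-style estimators (`PowerLawCalibrator`,
`QAMSQuantifier` with `fit`/`predict`/`get_params`); module-level functions
wrap them for one-off use, and a `qams` command line wraps the pipeline.

## Worked example

```python
import qams

# detector models at published-scale parameters; noiseless here
models = qams.default_panel()
tops = qams.default_top_concentrations()
panel = {a: qams.make_calibration_series(m, tops[a]) for a, m in models.items()}

curve = qams.fit_loglog_calibration(panel["GF3"])
print(f"GF3: lgA = {curve.slope:.2f} lgC + {curve.intercept:.2f}, "
      f"R2 = {curve.r_squared:.4f}, range {curve.range_low:.2f}-{curve.range_high:.2f} ug/mL")

table = qams.build_rcf_table(panel, marker_id="GF3", method="B", rounding=2)
print("method-B RCFs:", table.values())

sample = qams.SampleMeasurement(
    sample_id="Raw_01", group="Raw", mass_g=0.25, volume_ml=25.0, dilution=1.0,
    areas={"GF3": qams.simulate_area(models["GF3"], 500.0)},
)
est = qams.QAMSQuantifier(marker="GF3", method="A").fit(panel)
print(est.predict([sample])[["analyte_id", "content_esm_pct",
                             "content_qams_pct", "re_pct"]].to_string(index=False))
```

prints

```
GF3: lgA = 1.82 lgC + -1.67, R2 = 1.0000, range 118.04-1180.40 ug/mL
method-B RCFs: {'GF1': 1.03, 'GF2': 1.07, 'GF3': 1.0, 'GF4': 0.99, 'GF5': 0.99, 'GF6': 0.99, 'GF7': 1.01, 'GF8': 1.02}
analyte_id  content_esm_pct  content_qams_pct       re_pct
       GF3              5.0               5.0 1.776357e-14
```

Reading this: the marker's fitted response recovers its generating
parameters exactly on noiseless data (F = 1.82, b = −1.67, R² = 1); the
slope-ratio RCFs of the other analytes fall within a few percent of unity;
and a 500 µg/mL extract of a 0.25 g sample in 25 mL is 5.0 % w/w content,
identical under ESM and QAMS for the marker itself (RE ≈ 0, as it must be —
same curve, RCF = 1).

From a shell the same pipeline is:

```sh
qams simulate --seed 3 --out demo/            # calibration.csv, samples.csv, truth.csv
qams rank --calibration demo/calibration.csv --samples demo/samples.csv \
     --marker GF3 --out demo/summary.csv      # ranks the six RCF methods by mean |RE|
```

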