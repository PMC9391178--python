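# Methods

## The problem

An evaporative light scattering detector (ELSD) responds to the mass of
nonvolatile analyte reaching it, not to absorbance, and its peak area is a
power law in concentration:

    A = 10^b · C^F        ⇔        lg A = F · lg C + b,

with `lg` the base-10 logarithm, exponent `F` typically 1.8–1.95 and log
intercept `b` around −1.9…−1.55 for oligosaccharides on HILIC-HPLC-ELSD.
Because the response is nonlinear, the single-marker strategy (QAMS:
quantify a whole panel from one physical reference standard) has no unique
definition of the *relative correction factor* (RCF) that links an
analyte's response to the marker's. This package implements the six
circulating conventions and the machinery to decide among them.

## Calibration model

Per analyte, ordinary least squares of `lg A` on `lg C` (unweighted; no
weighting scheme is standard for this detector class and log transformation
already stabilises the multiplicative variance). The fit is delegated to
`scipy.stats.linregress`; `r_squared` is the squared correlation of the
log-log pairs and is reported to 4 decimal places. A minimum of three
levels is enforced; the reference design uses five, the co-dilutions
1, 1.5, 2.2, 4 and 10× of a mixed stock.

Inverse prediction is the closed form `C = 10^((lg A − b)/F)`. Readouts
outside the calibrated concentration range are *flagged* through a
`CalibrationRangeWarning`, never refused: unknown extracts routinely land
slightly outside the standards' span and the analyst decides whether to
redilute.

LOD and LOQ use the signal-to-noise convention: the concentrations whose
predicted areas equal 3× and 10× a supplied baseline-noise SD. This is a
declared choice of this package (the common alternatives — calibration-SD
based limits, dilution to extinction — need data the peak table does not
carry).

## The six RCF conventions

With `s` the marker and `k` any analyte:

| method | definition | per-level? |
|---|---|---|
| A | read each analyte level off the *marker's* curve; RCF = C_detected / C | yes |
| B | F_k / F_s (slope ratio) | no |
| C | (C_s / lg A_s) / (C_k / lg A_k) | yes |
| D | (lg C_k / lg A_k) / (lg C_s / lg A_s) | yes |
| E | (A_s / C_s) / (A_k / C_k) — the linear-detector response-factor ratio | yes |
| F | 1.00 (no correction) | no |

Level-wise values are combined by the arithmetic mean (the plain reading of
"average"). Levels are paired by `level_index`, justified because the mixed
standard is co-diluted, so level *i* of every analyte shares one dilution
event; a separately prepared series (like the sucrose standard here) pairs
by ordinal position, which C/D/E accommodate since both concentrations
appear explicitly in their formulas. Reported RCFs round to 2 decimals at
serialization only; computation keeps full precision.

Algebraically, with equal slopes (F_k = F_s) the method-A level values are
all `10^((b_k − b_s)/F_s)` — constant across levels — while method B returns
exactly 1 regardless of intercepts. Method A is therefore the only
convention that tracks an intercept (sensitivity) shift between analytes,
which is the mechanism behind its selection by the relative-error criterion.

## Quantification and the selection criterion

- **ESM** (external standard method): each analyte off its own curve.
- **QAMS**: each analyte off the *marker's* curve, then `C = C_detected /
  RCF`. The same inversion is applied whichever method produced the RCF —
  the only reading under which all six conventions share one content
  pipeline and method F means "pretend everything is the marker".

Content (% w/w) = `C · V · dilution / (m · 10⁶) · 100` with `C` in µg/mL,
extraction volume `V` in mL and sample mass `m` in g; as-weighed basis, no
moisture correction. The accuracy criterion is the signed relative error
`RE% = (QAMS − ESM)/ESM · 100` per sample and analyte; methods are ranked
by the mean of |RE| pooled over analytes and samples (the distributional
"closest to zero" notion made into a scalar), and the smallest mean |RE|
wins. Out-of-range readouts are flagged, not dropped; sample exclusion is
manual only (an outlier replicate is a judgment call, not a threshold).

## Validation statistics

RSD uses the sample (n−1) standard deviation — the convention that
reproduces the published recovery table's printed 1.81 % from its own rows.
Spike recovery is `(detected − origin)/spiked · 100 %`, with the origin
content taken from a prior assay of the same lot. Repeatability across the
three-mass design is computed on content (%), not raw area, since the
weighed masses differ by design. Cross-instrument system suitability is the
per-analyte mean and RSD of RCFs over instruments, which must share marker
and method; it is exactly column-wise RSD.

## Synthetic data generator

`simulate` draws areas from `A = 10^(F·lg C + b) · exp(ε) + ε_add`, with
`ε ~ N(0, ln(1 + noise_cv))` (multiplicative, lognormal — ELSD noise scales
with signal) and optional additive baseline noise feeding LOD/LOQ work.
Defaults: `noise_cv = 0.01`, in the range that yields replicate RSDs of
1–2 %, the scale seen in routine precision tables; baseline noise 0.

The batch generator emulates a herb-processing study: `n_raw = 3` lots,
each processed three ways (steamed St, salt-steamed S, licorice-boiled L)
in triplicate → 30 samples; 0.25 g extracted into 25 mL. Lot-to-lot
contents get lognormal jitter (CV 10 %). Base contents put the marker near
5 % and the eight-analyte total near 45 %. Default group multipliers follow
the qualitative processing chemistry — long-chain fructans (GF7/GF8)
hydrolyse during steaming while short ones (GF1/GF2) accumulate; boiling is
milder — with magnitudes (e.g. GF2 ×1.5–1.7, GF8 ×0.45–0.6 for steamed
groups) chosen once as plausible effect sizes. The generator returns the
hidden truth table alongside the observable batch so recovery of configured
effects is testable.

What the generator does **not** emulate: chromatographic reality (retention
shifts, co-elution, integration error), drift within a sequence,
inter-laboratory effects, or matrix suppression. Passing tests therefore
demonstrate the *arithmetic and statistical* correctness of the pipeline
and the discriminating power of the RE criterion under the stated response
model — not that any particular instrument obeys that model.

## Numerical choices and edge cases

- Degenerate designs raise: < 3 levels, identical concentrations, zero
  marker slope, empty batches, unpaired level sets.
- Areas in (0, 1) make `lg A` negative; methods C/D compute as-is but emit
  `LogDomainWarning` (real areas are ≫ 1). An area of exactly 1 is an error
  where a formula divides by `lg A`.
- A concentration of exactly 1 makes `lg C` zero; method D warns and, where
  the marker side divides by it, raises.
- Determinism: every stochastic routine takes a `numpy` `Generator` or a
  seed; identical seed + design ⇒ bit-identical output.
- Problem sizes in the test-bench runs: 5-level calibrations, 30-sample
  batches, 10⁴-draw Monte-Carlo noise checks — the sizes of the reference
  design itself, and comfortably desk-scale.

## Known limitations

- The RCF inversion `C = C_detected / RCF` is exact for method A with equal
  slopes and approximate otherwise; with unequal slopes the error vanishes
  only near the level where `C_detected / C` equals the averaged RCF.
- Method-B values recomputed from 2-dp-rounded slopes can differ in the
  last digit from values computed on full-precision fits; the package never
  forces agreement.
- No multivariate chemometrics (HCA/PCA/OPLS-DA): the content-ratio matrix
  this package emits is the input those external analyses consume.
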