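# Methods

## Estimation equations

The package evaluates five published anthropometric BF% equations
exactly as printed, with no refitting and no clamping of outputs.
Values outside the physiologically plausible 0–60% band (possible for
extreme inputs) are returned as computed and logged, never truncated.
The equations differ in their sex dummy: CUN-BAE, ECORE-BF, RFM and
Palafolls code women = 1 / men = 0, Deurenberg the reverse. To keep the
reversed coding from leaking into user code, sex is carried everywhere
as an enumeration (`female`/`male`); the 0/1 dummies exist only inside
`sex_code`.

Unit conventions: age in years, weight in kg, height and waist
circumference (WC) in cm, BMI in kg/m². The RFM height/WC ratio is
dimensionless (both in cm). The Palafolls BMI/WC term uses WC in cm;
evaluating the formula at the published male means (BMI 26.7, WC 88.7)
reproduces the published male mean estimate of 29.7%, which fixes the
unit choice — metres would add an absurd ~270-point term. BMI is always
recomputed from weight and height at ingest; a supplied BMI column
deviating by more than 0.1 kg/m² triggers a logged warning and the
recomputed value wins (single source of truth). Ages outside the 18–65
occupational inclusion window are accepted but flagged
(`in_protocol = False`), not rejected.

## Classification

WHO BMI categories are taken as half-open bins: normal weight < 25,
overweight [25, 30), obesity ≥ 30. Underweight (BMI < 18.5) is folded
into normal weight so that three categories partition any cohort, which
is how the source cohort's three-row prevalence table behaves.

The sex-specific BF% cut-offs for Caucasian adults are published as
"<30 / 30.1–35 / >35.1" (women) and "<20 / 20.1–25 / >25.1" (men),
which leaves 0.1-wide gaps at the anchors. They are resolved as bins
closed on the right — women ≤30 / (30, 35] / >35, men ≤20 / (20, 25] /
>25 — the unique exhaustive partition using the printed anchors as
edges. Both classifications are monotone by construction.

Age groups are the sample quartiles: breaks are the 25th/50th/75th
percentiles rounded to whole years (half away from zero), labels
`<=b1`, `b1+1-b2`, `b2+1-b3`, `>=b3+1`. An age exactly at a break goes
to the lower group, and ages are floored to integer years for group
assignment only — consistent with printed labels like "<32" vs "33–40"
under integer ages. Whether the source study put boundary ages in the
lower or upper group is not documented; this convention is a documented
choice, not inferred intent. Samples whose quartiles are not distinct
raise an error rather than silently merging groups.

## Agreement statistics

Differences are always estimate − reference (candidate minus CUN-BAE);
this sign convention is fixed by the published mean differences (e.g.
RFM −1.57 ≈ 27.9 − 29.5 from the cohort means).

* **Pearson r** via `scipy.stats.pearsonr`; constant series are an
  error (the coefficient is undefined), as are series shorter than 3.
* **Lin's CCC** uses 1/n (biased) moment estimators, per the original
  definition. The convention matters in principle because the squared
  mean-shift term makes the 1/n and 1/(n−1) versions non-equivalent; at
  the cohort sizes this package targets the difference is far below
  reporting precision, so the choice is documented rather than
  consequential. The confidence interval applies the Fisher
  z-transform with Lin's asymptotic variance and back-transforms; when
  |CCC| is numerically 1 the variance degenerates and the interval
  collapses to the point estimate. The source tables report no CCC
  CIs, so `ccc_l95`/`ccc_u95` are an extension, flagged as such in the
  report provenance block.
* **Bland–Altman**: mean difference, SD of differences with the n−1
  denominator, limits of agreement at a fixed 1.96 multiplier (not a t
  quantile — reconstructions of the published limits from published
  MD/SD match at exactly 1.96; at n ≈ 200,000 the n−1 vs n choice is
  indistinguishable and is recorded as a convention).
* **Two-sample t-test** defaults to the pooled-variance form, with
  Welch selectable; p-values below 1e-300 are stored as 0 numerically
  and rendered `<1e-300` in text.

One published inconsistency is worth noting: the source's discussion
quotes the Palafolls lower limit as 0.66 while its table prints −0.66,
and reconstruction from the printed MD/SD gives ≈ −0.67. The table's
sign is treated as authoritative.

## Synthetic cohort generator

The raw cohort (196,844 workers) is not deposited, so analyses run on a
synthetic stand-in. Per sex, (age, height, BMI, WC) is drawn from a
truncated multivariate normal whose marginal means and SDs equal the
published per-sex descriptives (women: age 39.4 (10.5) y, height 161.7
(6.5) cm, BMI 25.2 (5.0), WC 75.9 (8.2); men: 40.4 (10.7), 174.4
(7.0), 26.7 (4.3), 88.7 (8.9); 41.7% women). Weight is derived as
BMI·(height/100)² rather than simulated, because BMI and WC are the
inputs that drive every equation — matching their printed moments is
what makes the downstream agreement statistics realistic.

The joint structure is not published; the default correlation matrix —
corr(BMI, WC) = 0.85, corr(age, WC) = 0.25, corr(age, BMI) = 0.20,
corr(height, WC) = 0.10, corr(height, BMI) = −0.05,
corr(age, height) = −0.10 — is a physiologically plausible choice,
fully overridable in the JSON config. Truncation bounds (age 18–65, the
occupational inclusion window; height 140–200 cm; BMI 15–50; WC 55–140
cm) are enforced by rejection, not clipping, so marginal shapes stay
smooth; they cut only far tails, and the induced mean bias is bounded
by the calibration tests (per-sex means of height/BMI/WC within 2% of
target at n = 100,000, age within 0.5 y). A run whose bounds reject
more than 99% of draws errors out rather than looping.

A single integer seed drives one `numpy` generator; sex assignment,
then the female block, then the male block consume from it in that
fixed order, so cohorts are bit-reproducible and the full pipeline is
byte-deterministic given (input, config, seed).

What the generator does **not** emulate: the real cohort's BMI
right-skew (truncated normals are symmetric apart from the truncation),
occupational covariates, measurement error, and any missing-data
mechanism. The published category prevalences are emergent, not
calibrated — the synthetic cohort reproduces the *direction* of the
headline patterns (BF%-based obesity prevalence far above BMI-based;
concordance ordering ECORE-BF > Deurenberg > Palafolls > RFM), not the
printed numbers, which belong to the unavailable data. Passing tests
on synthetic data therefore validate the machinery and the qualitative
structure, not population-level point estimates.

## Pipeline

Stratification for the agreement tables uses the BMI-based categories
(the source's stated choice), plus overall, sex, and the four
age-quartile groups — ten strata, each crossed with the four candidate
equations. Age groups are recomputed from the analysed cohort by
default; `--age-breaks 32,40,48` pins the published boundaries. The
reference method is a parameter defaulting to CUN-BAE. Strata with
n < 3 are emitted with statistics marked unavailable (NaN), never
dropped, so the 40-row table shape is invariant. The overall row is
always recomputed on the unstratified cohort, never aggregated from
strata.

Emitted tables round r/CCC to 3 decimals (as the source tables do) and
difference statistics to 4; the source mixes 2–4 decimals in its
difference table, and standardising on 4 is a deliberate deviation.

## Problem sizes

Default analysis cohorts in the tests use n = 50,000 (headline
qualitative checks, seed 1) and n = 100,000 (generator calibration),
with smaller seeded cohorts (300–2,000) for structural and CLI tests;
these sizes give Monte-Carlo error well inside the tolerances checked
while keeping the suite fast.
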