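# Methods

## Correction formulas

All computations use canonical units — QT in ms, RR in seconds, HR in
bpm — with explicit conversions from standard 25 mm/s ECG paper (1 small
square = 40 ms; HR = 1500 / RR-in-squares). Nothing is rounded inside a
computation; human-readable reports round to 2 decimals.

The four reference corrections use their standard literature forms:
Bazett QT/√RR, Fridericia QT/RR^(1/3), Framingham QT + 154(1 − RR),
Hodges QT + 1.75(HR − 60). The piecewise simple rule is
QT + 2(HR − 60), with a further −10 ms when HR > 90 bpm; the boundary
HR = 90 belongs to the no-subtraction branch. Because the rule and
Hodges are both linear in QT with the same coefficient, their difference
is a pure function of rate,

    d(HR) = 0.25 (HR − 60) − 10·[HR > 90],

which attains ±7.5 ms at the edges of a 40–130 bpm working band, reaches
10 ms at 140 bpm, and grows without bound beyond (14.47 ms at
1500/9.5 ≈ 157.9 bpm). The rule is therefore an approximation *to
Hodges*, not to the truth; whatever systematic error Hodges has, the
rule inherits.

When a record carries both RR and HR, they must agree within 1 bpm, and
RR wins (HR is recomputed from it): RR is the quantity actually measured
on paper. Degenerate inputs — QT not shorter than the cycle length,
rates outside 20–300 bpm, non-positive intervals — are rejected with a
validation error rather than silently corrected.

Prolonged QTc means strictly greater than 450 ms in men and 460 ms in
women; "normal up to the threshold" is read boundary-inclusive, so
exactly 450 ms in a man is normal.

## Agreement statistics

Bland–Altman: bias = mean(a − b), SD of the differences with the n−1
denominator (standard practice; the sources this package follows do not
state a denominator, and n−1 matches common method-comparison software),
95% limits of agreement = bias ± 1.96 SD. "A x B" in reports always
means A − B. Lin's concordance correlation coefficient uses the original
1/n moment estimators: CCC = 2 cov(a,b) / (var a + var b + (ā − b̄)²).

Rate dependence is the OLS slope of QTc on HR (ms/bpm) with its R².
Slope homogeneity across methods is tested as the method×HR interaction
F-test in a stacked linear model — one concrete reading of a
between-method "ANOVA" that is otherwise underspecified; the result
object carries a note saying so. Prolonged-QTc prevalences are compared
with a two-proportion chi-square test without continuity correction,
ignoring the pairing of the same ECGs across methods (a paired McNemar
analysis would need discordant-pair counts that comparison tables do not
report); this is documented as an approximation. p-values are reported
to 4 decimals; no multiple-testing correction is applied.

Serial analysis pairs each patient's two tracings by the explicit
`ecg_index` column (no timestamps exist in this data model) and defines
ΔQTc = QTc(ECG 2) − QTc(ECG 1) — a sign convention only, since
Bland–Altman agreement of deltas is symmetric under reversal. Patients
lacking a second tracing are excluded from serial analysis and counted
in the log. For the two linear methods the QT terms cancel:
Δsimple − ΔHodges = 0.25(HR₂ − HR₁) − 10([HR₂ > 90] − [HR₁ > 90]).

## Synthetic cohort generator

The generator emulates the bookkeeping of a single-centre acute
pulmonary oedema cohort: 150 admitted, 9 with unmeasurable tracings, 37
excluded for wide QRS or irregular rhythm (26 LBBB — one of whom also
had AF — 7 AF/atrial tachycardia, 4 RBBB), 104 included, 86 with a
second ECG ≥ 24 h later: 190 usable ECGs. The published exclusion
listing sums to 38 because the AF+LBBB patient appears under two
reasons; this package counts that patient once, inside the LBBB total,
which is the only reading consistent with the 104/190 totals.

Heart rate is drawn from a normal(92, 23) bpm truncated to the observed
44–150 bpm range, by exact rejection sampling. Note the configured
mean/SD parameterise the *parent* normal: truncation shifts the realised
mean to ≈ 92.7 and shrinks the SD to ≈ 21.3 (the exact truncated-normal
moments, which the tests check against scipy's `truncnorm`).

The truth model is a generator invention — no generative model is
published for this kind of data. It is deliberately Hodges-consistent:
each patient has a latent rate-free QTc₀ ~ N(420, 30) ms and each
measured QT is QTc₀ − 1.75(HR − 60) + ε with ε ~ N(0, 8) ms, quantised
to 20 ms (half a small square, emulating manual caliper reading; the
quantum is configurable because real reading precision is unknown). Any
draw violating 0 < QT < RR is redrawn. Consequences that the tests
verify: Hodges correction recovers a rate-flat QTc (|slope| < 0.05
ms/bpm on a 20,000-patient cohort, where the slope's standard error is
≈ 0.01), Bazett re-introduces a rate trend (slope ≥ 0.2 ms/bpm), and the
simple-vs-Hodges Bland–Altman bias falls in the −10…3 ms band. With the
default parameters the prolonged-QTc prevalence under non-Bazett methods
computes to roughly 11–16%, with Bazett about twice that.

The two ECGs of one patient draw independent heart rates by default; a
within-patient correlation knob (default 0, no published estimate
exists) draws a correlated latent pair instead. A single integer seed
fully determines the output, and each patient has an independent spawned
RNG stream, so enlarging the cohort never changes earlier patients'
draws.

What the generator does *not* emulate: waveform-level measurement (lead
choice, T-wave end ambiguity), inter-observer variability, clinical
drivers of QTc change between tracings, or any QT/rate relationship
other than the Hodges-linear one. Passing tests on this data therefore
show the statistics and plumbing are correct and that the comparison
machinery detects formula-dependent rate sensitivity; they do not certify
any formula's fidelity to real patients, and distribution-dependent
statistics (biases, SDs, prevalences, slopes) on synthetic cohorts
approximate — but cannot reproduce — values measured on real data.

## Numerical and design choices

- LOA multiplier fixed at 1.96 (95% limits).
- Sample SD (ddof = 1) for Bland–Altman; population moments (1/n) for
  CCC, following each statistic's canonical definition.
- A constant QTc series regresses to slope 0, R² 0 (nothing to explain);
  constant HR is an error (slope undefined).
- The slope-homogeneity F-statistic is set to 0 when both the
  interaction and residual sums of squares vanish (identical copies).
- Equal prevalence counts short-circuit to statistic 0, p = 1.
- CSV is the single interchange format. Machine-readable outputs keep
  full precision and round-trip exactly (`float_precision="round_trip"`
  on read); human tables round to 2 decimals. Report writers always emit
  computed values — arithmetic is never adjusted to match an external
  table, and external tables with internally inconsistent rows are
  treated as erratum candidates, not targets. Two such rows in the
  comparison literature this package was built around: a "Fridericia x
  Simple" row whose printed limits are inconsistent with its own
  bias ± 1.96 SD (apparently transposed), and a narrative SD of 4.96
  where the table's 3.36 is the only value consistent with the printed
  limits −9.94 to 3.23.

## Known limitations

- No corrections for wide QRS or irregular rhythm; such records are out
  of scope (the study design excludes those patients), and no
  repeated-measures adjustment is made for the two-ECGs-per-patient
  clustering in Bland–Altman analyses.
- The chi-square prevalence comparison treats methods as independent
  samples; with 190 shared ECGs it is conservative in an unquantified
  way.
- The simple rule is validated against Hodges only; at rates above
  ~140 bpm its divergence exceeds 10 ms and it should not be used.
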