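# Methods

## Scope and model

`dietrisk` implements the standard risk-characterisation chain for a
pesticide residue in fresh produce, instantiated for chlorpyrifos (CPF)
in tomato and cucumber consumed by the Armenian adult population:

    EDI  = C_content × C_food / BW          (mg/kg bw/day)
    MOE  = HBGV / EDI                       (chronic)
    HQ   = EDI / ARfD                       (acute)
    HI   = Σ HQ,  ΣMOE = HBGV / ΣEDI        (cumulative over commodities)

The EDI is linear in consumption, so the mean EDI of a consumer group
equals the EDI of the group's mean consumption; group-level and
individual-level computations are interchangeable for means. The EDI
carries no exposure-duration or frequency-of-exposure adjustment: it is
an average daily dose, not a lifetime dose.

Reference values (defaults in `ReferenceValues`): chronic HBGV = the
EFSA developmental-neurotoxicity LOAEL of 0.3 mg/kg bw/day; acute
ARfD = the artificially low 1 × 10⁻⁴ mg/kg bw/day adopted in 2020 as the
headline basis, with the pre-2020 ARfD of 0.005 mg/kg bw/day switchable
via `arfd_basis="2014"`; MOE concern thresholds 300 (concern) and 1000
(possible concern); body weight 71.5 kg, the mean for Armenian adults.
An HQ or HI exactly equal to 1 is classified as a concern: "below 1
means no concern" is read conservatively, so the boundary falls on the
concern side.

## Left-censored residue data

Samples below the LOD (0.0003 mg/kg here; LOQ 0.001 mg/kg) are handled
by substitution: 0 (lower bound), LOD/2 (middle bound) or LOD (upper
bound). The default summary rule is `detected_only` — statistics over
the detected concentrations alone — because the exposure estimates are
anchored to the detected mean residue level; LB/MB/UB remain available
as scenario flags, and for any survey mean(LB) ≤ mean(MB) ≤ mean(UB)
with the UB−LB gap equal to LOD × (censored fraction) under a single
LOD. Requesting `detected_only` on a survey with no detections is an
explicit error, never a silent zero. No distributional censoring model
(Kaplan–Meier, ROS, censored MLE) is attempted: substitution is the
method under study. Standard deviations use the sample (n−1)
convention by default; a measurement between LOD and LOQ is treated as
an ordinary detected value.

## FFQ intake modelling

Frequency categories are converted to events/day through a mapping
table shipped as data (`DEFAULT_FREQUENCY_MAP`), using the
midpoint-of-range convention ("2–4 times per week" → 3/7) and an
average month of 30.44 days. The survey instrument's conversion is not
published, so the table is explicit and overridable; the open-ended
"other" category has no default rate and must be supplied by the
caller. Chronic intake is events/day × portion/1000 (kg/day); acute
intake is the portion itself (kg/occasion). A consuming respondent
with no portion size is flagged and excluded rather than imputed.

Outlier handling is a one-sided upper trim (default 5% when invoked):
self-reported intake distributions are right-skewed and the published
consumer counts indicate an upper-tail exclusion. Whether the original
exclusion removed the top 5% or 5% in total is ambiguous; the package
documents and implements the top-5% reading, with two-sided trimming
left to the caller. The assessment pipeline applies no trim by default
because the synthetic generator emits the already-analysed population
(see below).

Consumers are binned into k = 5 ordered consumption groups. The
original analysis used a spreadsheet "visual binning" whose manual
cutpoints are not recoverable (its group fractions are unequal:
19.19/23.23/32.24/6.82/18.52% for tomato), so the package accepts
explicit cutpoints as configuration and defaults to equal-count
(quantile) binning otherwise. Intervals are lower-inclusive,
upper-exclusive except the last; ties at a boundary join the interval
whose lower bound they equal. Groups are formed on chronic intake and
the assignment is reused for the acute table, so each respondent sits
in one group across horizons. Demographics (gender, age, education,
employment, income) are carried through for reporting but never enter
any computation — the groups are defined by consumption level alone.

## Monte Carlo propagation

Each iteration draws consumption and residue values per commodity,
forms the EDI, and applies the metric; cumulative metrics sum EDIs (for
ΣMOE) or HQs (for HI) within-iteration before transforming. Draws are
independent across inputs by default — no correlation structure between
consumption and residue levels is assumed — with an Iman–Conover
rank-correlation hook (`rank_correlation=`) for scenario analysis.
Inputs are sampled at the population level from parametric fits;
passing an empirical vector instead of a spec switches that input to
bootstrap resampling of individuals.

Distribution families: triangular(a, m, b); Beta-PERT(a, m, b) with
shape λ = 4 (the standard default; mean (a + 4m + b)/6) sampled as
Beta(1 + λ(m−a)/(b−a), 1 + λ(b−m)/(b−a)) rescaled to [a, b];
beta-general(α₁, α₂, a, b); and a point mass as the degenerate limit —
with all-point inputs the simulation mean equals the deterministic
metric to floating-point precision, which is the principal correctness
check tying the two halves of the package together.

Fitting: triangular and PERT by maximum likelihood, initialised with
bounds just outside the data range and the mode at the half-sample
mode (scipy's triangular MLE recovers (0, 1, 2) to ±0.005 at n = 10⁵).
Beta-general uses method of moments on min/max-rescaled data only to
initialise a full four-parameter MLE: the sample extrema understate a
Beta support, and moments against that truncated support bias the
shape parameters 15% or more low, while the MLE recovers them to a few
percent. Degenerate (all-equal) data collapse to a point spec with a
warning. Family selection ranks candidates by the Kolmogorov–Smirnov
statistic (the original tool's criterion is unstated; AIC is available
by configuration), breaking ties by the caller's candidate order.

Besides direct propagation, `simulate_from_metric_fit` supports the
fit-to-metric mode — fitting a distribution to per-respondent metric
values and simulating from the fit — since spreadsheet risk tools
describe their output panels as fitted distributions (triangular for
single-commodity HQ/MOE, PERT for HI/ΣMOE) and it is not decidable
from the published material which mode produced them. The package
asserts neither; both are first-class.

Output summaries report mean, median, half-sample mode (robust for
continuous draws; the original tool's mode estimator is unstated), a
90% normal-approximation CI of the mean (mean ± z·sd/√n), type-7
(linear-interpolation) percentiles P50/P75/P90/P95, min, max and the
n−1 standard deviation. Sensitivity is the Spearman rank correlation
of each input stream with the output, ranked by absolute value;
constant inputs get 0. Note the distinction between the MOE *of the
mean EDI* (the deterministic table entry) and the *mean of the MOE
draws*: the MOE is convex in the EDI, so the simulated mean MOE sits
above the deterministic value — both are reported, neither is an error.

Reproducibility: one master seed feeds a `numpy.random.SeedSequence`
that spawns one substream per input stream in sorted-commodity order;
identical configuration and seed give bit-for-bit identical draws and
summaries.

For the Monte Carlo inputs built from assessed data, consumption uses a
beta-general fit to the individual intakes, while the residue input is
a mean-preserving triangular over the detected concentrations (mode
solved from mean = (a+m+b)/3, clipped into [min, max]; a point mass
when all detections are equal). A likelihood fit is not supportable on
3–4 detected values, and the mean-preserving triangular keeps the
simulated residue level centred on the detected mean with dispersion
bounded by the observed range — deliberately narrower than the
consumption input, which is the dominant source of variability.

## Synthetic data and calibration

The individual FFQ answers and per-sample residue measurements behind
the Armenian assessment are not public; `dietrisk.synthetic` generates
populations matching the published marginals so the pipeline is
testable end to end. Design choices:

* **Fixed counts, not binomial draws.** Detection counts, consumer
  counts, frequency-category counts and the gender quota (563/766) are
  allocated exactly (largest-remainder), so small-survey fractions like
  3/20 detected reproduce the published 15% exactly rather than on
  average.
* **Residues.** Tomato: 20 samples, 3 detected, all at 0.003 mg/kg.
  Cucumber: 14 samples, 4 detected; the published summary fixes the
  minimum (0.002), maximum (0.005), mean (0.003) and rounded SD
  (0.001) but not the two middle values, so the generator uses the
  synthetic stand-ins 0.002 and 0.003, which reproduce all four printed
  statistics. Generators can alternatively draw detected values
  uniformly in a range and rescale them to a target mean.
* **Consumption.** Portions are drawn from right-skewed bounded
  beta-general shapes (real FFQ portions are bounded and right-skewed)
  and rescaled so the sample mean portion equals the consumption
  implied by the published mean *acute* EDI (374.2 g tomato, 203.1 g
  cucumber at BW 71.5 kg and C_content 0.003 mg/kg). Frequency-category
  probabilities are then solved (two-anchor linear calibration in
  `calibrate_frequency_probs`) so the mean events/day brings the mean
  *chronic* intake to the level implied by the published mean chronic
  EDI (0.3003 and 0.1666 kg/day). Calibration targets the published
  mean EDIs — the reported statistic — not the unpublished full intake
  distribution; the generated population is the analysed (post-
  exclusion) consumer set, which is why the pipeline default applies no
  further trim.

With 1188/1194 consumers, the remaining sampling noise in the mean
chronic EDI is the rate-portion cross term, about 0.5% SD across seeds
— comfortably within the ±3% end-to-end calibration check, and
seed-to-seed movement stays under 2%.

What the generator does **not** emulate: the true portion-size and
frequency marginals of the Yerevan survey (unpublished — the shapes
here are stand-ins), any demographic structure of consumption, the
original manual group cutpoints, and the day-to-day within-person
variance structure a 24-h-recall design would give. Passing tests
therefore demonstrate the correctness and calibration of the pipeline,
not distributional fidelity to the original survey; simulated extreme
percentiles (e.g. P95 of ΣMOE) are not comparable to the original
probabilistic panels, which depended on the unpublished individual
data.

## Numerical conventions and degenerate inputs

* Quantiles and percentiles: type 7 (linear interpolation) throughout.
* MOE at zero exposure returns the string sentinel `"unbounded"`, never
  an IEEE infinity, so reports stay serialisable and explicit.
* Report rounding: scientific notation at 3 significant figures for
  EDI/MOE, 2 decimal places for HQ/HI; all internal computation is full
  precision and rounding happens only in the report layer. Machine
  outputs use `1.26e-05`; the human-readable report uses
  `1.26 × 10^-5`.
* Cumulative EDI ranges are the sums of the per-commodity range
  endpoints (co-monotone worst/best case), matching how the cumulative
  rows of the published tables behave.
* MOE ranges invert the EDI range (min MOE from max EDI). One published
  cumulative-MOE range is internally transposed relative to the text
  and to this identity; the package follows the identity.
* Empty surveys, all-censored surveys under `detected_only`, mixed
  commodity sets, non-monotone cutpoints, unknown frequency categories
  and non-positive body weights are explicit errors; empty consumer
  sets render reports with explicit "no consumers" rows.

## Problem sizes

The test suite runs the full calibrated scenario (1329 respondents,
both commodities) once as a shared fixture, Monte Carlo checks at
10⁴–10⁵ iterations, and parameter-recovery checks at n = 10⁵ — sizes
chosen so each statistical tolerance (3·SE closed-form checks, ±5%/±10%
recovery, ±3% calibration) is meaningful while the whole suite stays
interactive.

## Known limitations

* Single analyte, single-route (dietary) assessment; no cumulative
  multi-pesticide assessment with relative potency factors.
* No processing-factor modelling (washing, peeling, cooking).
* The adult population only; no vulnerable-subgroup assessment.
* Substitution-based censoring only, by design.
* The probabilistic panels of the original study are not reproducible
  from public information; the Monte Carlo module is validated by
  closed-form and degenerate-limit properties instead.
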