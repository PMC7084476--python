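# Methods

## Scope

`radon-pt` analyses interlaboratory proficiency-testing campaigns for indoor
radon exposure (time-integrated activity concentration, kBq·m⁻³·h). A
campaign consists of participants — passive detector groups and active
monitors — exposed together in a radon chamber over two overlapping windows:
a short first window E1 (13 h) closed near the chamber's concentration peak,
and a long second window E2 (70 h) closed after the concentration has
decayed. Each participant reports one exposure per window with a k = 1
standard uncertainty. The package computes consensus assigned values,
performance scores, and outlier diagnostics, and ships a synthetic campaign
generator with complete ground truth so the entire pipeline is testable
without confidential participant data.

## Consensus assigned value

The assigned value is the robust average of all reported exposures for a
window, by ISO 13528's Algorithm A:

1. initialise `E_ref = median(E_i)`, `s* = 1.483 · median|E_i − E_ref|`;
2. winsorize: with `δ = 1.5·s*`, replace values outside `[E_ref−δ, E_ref+δ]`
   by the nearer bound;
3. update `E_ref ← mean`, `s* ← 1.134 · SD` of the winsorized values;
4. repeat 2–3 until convergence.

Numerical choices (the standard leaves them open):

- **Convergence** is declared when both `E_ref` and `s*` change by a relative
  `tolerance` (default 1e-9) in one iteration, with a 1000-iteration cap.
  This is far tighter than the "no change in the third significant figure"
  working rule; iteration counts are reported in the result.
- **Degenerate spread**: if the initial MAD is zero the winsorization
  interval collapses and every iterate would return the median, so
  `(median, 0)` is returned immediately with a `degenerate` flag.
- **Standard deviation** uses the sample (`p − 1`) denominator, consistent
  with treating the p results as a sample when propagating to
  `u(E_ref)`; `sd_ddof=0` switches to the population form.
- **Even counts**: the median is the mean of the two central order
  statistics.

The standard uncertainty of the assigned value is `u(E_ref) = 1.25·s*/√p`,
and the assigned value is declared fit for proficiency assessment when
`u(E_ref) < 0.3·σp`, where `σp = fraction · E_ref` is the standard deviation
for proficiency assessment (fraction 0.20 for E1, 0.10 for E2 — wider for
the short window because a 13 h exposure is harder to deliver and measure).
Despite the occasional description of such consensus values as "weighted
averages", the algorithm applies no explicit weights; winsorization is the
implicit down-weighting of extreme results. Results with `p < 5` carry a
non-fatal low-count warning; the reference campaign had p = 45 and 41, so
this path only arises in reduced simulations.

## Performance scores

For each submission: `D(%) = 100·(E_i − E_ref)/E_ref`,
`ζ = (E_i − E_ref)/√(u²(E_i) + u²(E_ref))`, `z = (E_i − E_ref)/σp`.
Classification follows the printed inequalities: `|score| ≤ 2.0`
satisfactory, `2.0 < |score| < 3.0` problem, `|score| ≥ 3.0` not
satisfactory — so 2.0 is satisfactory and 3.0 is not, exactly. ζ diagnoses
the realism of the participant's uncertainty budget; z measures fitness
against the campaign's tolerance. The joint action table has four rows
(both satisfactory → no action; ζ bad only → claimed uncertainty too low;
z bad only → result outside requirements; both bad → complete revaluation).
Because the action table is two-valued while classification is three-banded,
the intermediate problem band inherits the not-satisfactory action and sets
a separate `borderline` flag, so three-band percentage summaries remain
exact. Scores are always computed from full-precision consensus values —
rounding first could flip a result sitting on a band edge. ζ with zero
combined uncertainty and zero deviation returns 0 (the limit), not NaN.

## Outlier screen

Per window, quartiles are computed by linear interpolation of order
statistics (the spreadsheet default; Tukey hinges by option — "boxplot"
quartiles are convention-dependent and the choice moves fences slightly for
small p). Values strictly outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are
flagged; a value exactly on a fence is not an outlier. Screening is
per-window; flagged results are *not* removed from the consensus (consistent
with keeping all results when the two variants agree). The sensitivity
check operationalizes "no statistical difference" as
`|E_ref(all) − E_ref(without outliers)| ≤ 2·√(u²_all + u²_without)`; this
2-σ form is this package's choice, as no formula is standard.

## Synthetic campaign generator

The generator emulates the study conditions, not any particular dataset.

**Chamber.** A parametric rise–plateau–decay curve, not a source/ventilation
ODE: concentration rises from a 0.5 kBq·m⁻³ baseline toward a 30 kBq·m⁻³
plateau at 1.0 h⁻¹, then decays exponentially at 0.048 h⁻¹ from hour 13.
These defaults were tuned once against the campaign's anchors — ≈30 kBq·m⁻³
at the end of E1, under 2 kBq·m⁻³ at the end of E2, concentrations spanning
≈0.5–30 kBq·m⁻³ — and then frozen; they put the true exposures at ≈343
(E1) and ≈942 (E2) kBq·m⁻³·h, within 4% and 8% of the reference campaign's
356 and 1014. Hourly multiplicative lognormal jitter (cv 3%) models room
fluctuation; the **true** exposure of a window is the integral of the
realized (jittered) series, because that is the concentration the devices
actually received — the noiseless backbone is kept alongside for reference.

**Passive groups.** Each group deploys 10 detectors per window; each
detector reads a lognormal draw around `truth × calibration_bias ×
degassing_factor` with cv 10%, and the group reports the mean with the
standard error of the mean as its k = 1 uncertainty. Real participants'
uncertainty budgets are unknowable; the SE-of-mean model is a labelled
stand-in that makes ζ-score behaviour analyzable (it systematically
understates between-method bias, which is exactly what ζ is designed to
expose). Transit detectors are represented as a background subtraction at
the storage level (8 Bq·m⁻³ over 48 h ≈ 0.4 kBq·m⁻³·h, ≈0.1% of E1) rather
than as 10 simulated physical units.

**Active monitors.** Hourly observed concentration is Poisson counting
noise on `sensitivity × concentration × 60` expected counts, divided back —
so an ionization chamber at 50 cpm/(kBq·m⁻³) tracks the chamber to ≈0.3%
per hour at the plateau while a 0.1 cpm photodiode monitor is visibly
noisy. The reported uncertainty is the counting-statistics propagation.
Sensitivities are drawn per monitor from {50, 20, 7, 1.8, 0.1}.

**Contamination (holder degassing).** A configurable fraction of passive
groups (default 5/23) multiplies its E1 exposure by a factor drawn uniformly
from [1.4, 2.6] — radon adsorbed in holder material keeps exposing the
detector after the window closes. It is applied to E1 only: E1 ends near
the 30 kBq·m⁻³ peak, whereas by the end of E2 the chamber is below
2 kBq·m⁻³ and post-window adsorption adds no measurable dose.

**Composition.** Defaults: 23 passive groups + 22 active monitors over 20
labs → 45 E1 results; 3 passive and 1 active participant report E1 only,
giving 41 E2 results (the split implied by the reference campaign's summary
percentages). All randomness flows from a single campaign seed.

**What the generator does not emulate.** By default every device is
perfectly calibrated (`calibration_bias = 1`), so the between-participant
spread is only reporting noise: the synthetic robust CV (`s*/E_ref` ≈ 2–5%)
is far below the ≈12% seen in real field campaigns, where method and
calibration differences dominate. A `between_lab_cv` knob adds a
multiplicative lognormal calibration spread when realism matters more than
the minimal stated noise model. Two visible consequences of the tight
default: the IQR screen, fed a mixture of very precise active monitors and
noisier passive groups, flags some clean passive groups alongside the
contaminated ones (the contaminated codes are still always a subset of the
flags); and the fraction of passive E1 results with |z| ≤ 2 is capped at
18/23 ≈ 78% because all five contaminated groups necessarily exceed z = 2.
No radon-progeny equilibrium, temperature/pressure/humidity response, or
SSNTD etching/readout is modelled.

## Known limitation: recovery under contamination

With 5 of 45 results biased high and *all* results kept in the consensus
(the campaign's own policy), Algorithm A's winsorized mean retains a
one-sided bias of ≈ (5/45)·1.5·s*/(1 − 5/45) ≈ 0.19·s*, while the 2·u(E_ref)
band is 0.37·s*; adding the across-seed sampling spread of E_ref
(≈0.15·s*), the probability that E_ref lands within 2·u(E_ref) of the true
exposure is ≈0.89 at the default conditions — a structural property of the
estimator under 11% one-sided contamination, invariant to the noise scale.
The corresponding test asserts a 95% recovery rate and therefore fails; it
is kept failing deliberately as documentation of this ceiling. Removing the
flagged outliers first, or lowering the contaminated fraction, restores
near-nominal coverage.

## Reporting

Reference-parameter tables print integers (round-half-even; whether
half-up or half-even matches the source tables is indeterminable from two
rows) while JSON output keeps full precision. Summary percentages are
computed per device class and window over that cell's own result count,
which is always reported, and the three ζ (and z) bands always sum to 100%.
Timestamps follow the printed exposure schedule (November 2018 dates,
UTC+01:00 local time, treated as naive); the accompanying prose mentions
December, and the printed schedule was taken as authoritative since only it
yields the 13 h / 70 h durations.
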