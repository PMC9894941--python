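# Methods

## Scope

`lhpulse` reproduces, as tested code, the computational layer of a serial
tail-tip LH sampling experiment in a letrozole-induced PCOS mouse model:
pulse-peak identification and pulsatility parameters, estrous-cyclicity
and qPCR endpoints, and the group statistics. Wet-lab stages (sampling,
assay chemistry, vaginal cytology reading, histology) are out of scope;
their outputs are emulated by seeded generators so every downstream stage
is testable without data.

## Pulse detection

The detector applies three criteria to candidate peaks (interior local
maxima; leftmost sample of a plateau, so flat-topped pulses are counted
once): a >20% rise over the previous one or two samples, a >10% fall in
the next one or two samples, and an amplitude of ≥0.320 ng/mL over the
preceding nadir (lowest of the three preceding samples, earliest index on
ties). Percent criteria use strict inequalities, the amplitude criterion
is non-strict, matching the published wording.

Two readings of "the previous one or two values" are possible: the rise
may need to hold against *either* neighbouring sample or against *both*.
We adopt the either-of reading (equivalently, against the window minimum)
because it admits two-sample ascents, which is how slow rises present at
5-min sampling; `DetectionParams(window_mode="all")` switches to the
stricter reading. The same choice applies to the fall window. Criterion 3
is read as peak-minus-nadir (the text's own amplitude definition), not a
sample-to-sample change.

Peaks at the first or last sample are ineligible (a preceding/subsequent
value is required). No refractory or merging rule is applied — candidacy
already forbids adjacent peaks, and the rule set states none. Frequency
uses elapsed sampled time (`times[-1] − times[0]`), not a nominal 120 min,
so truncated sessions are summarized correctly; a profile may carry 24 or
25 samples (t=0 inclusive or not) without special handling.

## Secretion simulator

The generator is a minimal identifiable model of episodic neuroendocrine
secretion, not a physiological GnRH/KNDy network:

- **Pulse times** — a *stationary* gamma renewal process: interpulse
  intervals are gamma(shape `ipi_shape`, mean `mean_ipi`); the wait from
  the start of simulation (−`burn_in`, default 60 min) to the first pulse
  is an equilibrium forward-recurrence time (drawn as U·L with L
  length-biased). Starting in equilibrium makes the expected pulse count
  in any window exactly `T / mean_ipi` — there is no start-up transient to
  bias rate estimates — and matches the steady-state premise of sampling
  an undisturbed animal. `burn_in` exists so pulses before t=0 contribute
  residual concentration to the first samples.
- **Boluses** — instantaneous log-normal masses (median `exp(bolus_mu)`
  ng/mL). At 5-min sampling a secretion event shorter than the sampling
  interval is indistinguishable from a delta, so finite-duration events
  would add parameters without identifiability.
- **Clearance** — first-order with half-life `half_life` (default 15 min,
  a realistic LH clearance scale in mouse): between pulses the noiseless
  log-excess log(C − basal) falls linearly at ln2/half_life (asserted as
  a property test on the dense signal).
- **Noise and floor** — multiplicative Gaussian, value × (1 + cv·z),
  because immunoassay CVs scale with concentration; reported values are
  clipped at `floor` (default 0; set 0.320 to mimic assay censoring).

Group presets encode only the qualitative ordering the study reports:
LET pulses faster (mean_ipi 20 vs 60 min), taller (bolus median 2.0 vs
1.0 ng/mL) and on a higher basal (0.8 vs 0.3 ng/mL) than CON; LET_TRF
equals CON. The study prints no concentrations in text or tables, so the
preset numbers are implementer choices sized to a plausible ultrasensitive-
ELISA range; nothing downstream depends on them beyond the ordering.
Cohorts derive per-animal streams as
`SeedSequence([master_seed, crc32(label), animal_index])`, so runs are
reproducible and insensitive to preset order.

What a green simulation-based test establishes: the detector recovers the
generative pulses (F1 ≥ 0.90 under low noise and well-separated pulses)
and preserves the preset ordering through the full pipeline. What it does
not establish: agreement with real LH profiles, which carry baseline
drift, irregular pulse shapes, assay censoring and occasional missed
draws that the model deliberately omits.

## Estrous and qPCR endpoints

Stage logs are first-order Markov chains over {P, E, M, D} (default: 75%
chance of advancing through the cycle each day); `arrest_bias` moves
probability onto the diestrus self-transition to emulate letrozole-induced
arrest. The analysis itself starts at coded logs and computes percent
diestrus (100·#D/#days) with group mean ± SEM; no arrest threshold (e.g.
N consecutive D days) is computed because none is defined in the source
procedure.

qPCR uses 2^−ΔΔCt with efficiency fixed at 2 and tissue-specific
references: L19 in ovary, Gapdh in adipose and pituitary. Gapdh is
*assumed* for hypothalamus/POA, where the procedure leaves the reference
unstated. ΔΔCt is centered on the control group's **mean** ΔCt rather
than a designated calibrator sample, matching "mean fold change compared
with control"; this forces the geometric mean of control-group folds to
exactly 1 (tested to 1e-9), while the control arithmetic mean fold is ≥1
by Jensen's inequality. Group summaries are means ± SEM on the linear
fold scale, the study's reporting convention; averaging on the log scale
is available to callers via the per-sample table
(`sample_fold_changes`).

## Group statistics

The pooled-variance (Student's, not Welch) two-tailed t-test is computed
from its closed form; with zero pooled variance the contract is t = 0,
p = 1 for equal means and t = ±∞, p = 0 otherwise (flagged by the
infinite statistic so pipelines keep running). Two-way ANOVA (group ×
diet, with interaction) delegates to statsmodels OLS with Type II sums of
squares — the SS type is immaterial on the balanced cohorts the simulator
produces; with zero residual variance, terms are resolved by whether
their sum of squares is numerically zero. α = 0.05 throughout, no
multiple-testing correction (none is applied in the source procedure);
the pipeline report records the number of tests run.

## Pipeline

`run_pipeline` chains the stages with CSV as the only interchange format:
profiles, ground-truth pulses, peak tables, pulsatility summaries,
estrous logs, Ct tables, endpoint and comparison tables, plus a JSON
report carrying per-group means ± SEM, a per-criterion peak-rejection
audit, and provenance (config hash, seed, version). Each stage can be
rerun standalone from the previous stage's CSVs with identical results,
and a rerun under the same config is byte-identical.

## Numerical notes and limitations

- Boundary cases are decided exactly as printed: a rise of exactly 20% or
  a fall of exactly 10% rejects; an amplitude of exactly 0.320 ng/mL
  accepts. The acceptance script recovers all three boundaries by
  bisection to 1e-6.
- Detected peaks lag their generating pulse by up to one sampling
  interval (boluses land between grid points); the F1 matcher therefore
  allows the detection to trail by half a grid step plus the ±1-sample
  window.
- Simulated type-I error of the t-test is checked at 10,000 replicates
  (5% ± 1%); this verifies calibration under normality, not robustness.
- The two-group t requires n ≥ 2 per group; animals with zero detected
  pulses have undefined mean amplitude (NaN) and are dropped from that
  endpoint's comparisons only.
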