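# Methods

## Decision problem and model structure

The model compares two strategies for selecting adjuvant systemic
therapy in women aged around 50 with early, operable, node-negative,
ER-positive breast cancer: risk classification by a genomic prognostic
test (a 70-gene-signature-like assay with a per-test price) versus a
clinical-pathological guideline (no test price).  Everyone receives
endocrine therapy; a high-risk call adds chemotherapy.

Outcomes are computed by a deterministic Markov cohort model with four
mutually exclusive states — *disease free*, *relapse* (loco-regional
recurrence, second primary or contralateral tumour), *distant
metastasis*, *dead* — annual cycles, and a 20-year horizon.  Death is
absorbing.  Costs are discounted at 4%/year and effects at 1.5%/year
(Dutch pharmacoeconomic guidance); costs are in 2005 euros.

Structural choices:

* **No half-cycle correction** by default; state payoffs are charged on
  cycle-start occupancy.  Annual-cycle spreadsheet models of this
  vintage typically omit the correction; a switch
  (`EconomicSettings(half_cycle_correction=True)`) enables start/end
  averaging for sensitivity analysis.
* **One relapse only.** Re-entering relapse as a new event has zero
  probability; remaining in the state is continued occupancy of the same
  episode.  The one-time relapse treatment cost is charged on *entry*
  (the trace keeps separate entry bookkeeping), the same for all
  patients regardless of their adjuvant treatment.
* **Cycle 0 is the year of diagnosis and testing.** Adjuvant treatment
  costs (endocrine, chemotherapy) and the chemotherapy quality-of-life
  decrement fall in cycle 0, undiscounted.
* **Time-homogeneous transitions** within a run; no tunnel states; age
  effects on background mortality are folded into a flat annual rate.
* Relapse → distant metastasis is allowed by default (configurable via
  `allow_relapse_to_metastasis`); the alternative routes that
  probability into continued relapse occupancy.

## Risk classification and the joint law

"Truth" is operationalised as *elevated distant-metastasis risk under
endocrine-only treatment*: truth-high patients carry a substantially
higher annual disease-free → metastasis transition probability.
A test with sensitivity *se* and specificity *sp* splits a cohort of
prevalence *p* into true-high = p·se, false-low = p·(1−se),
true-low = (1−p)·sp, false-high = (1−p)·(1−sp).

Non-compliance acts on *discordant* patients, so the two tests' calls
must be modelled jointly.  Default: conditional independence given
truth, with a single concordance-adjustment knob added to
P(both high | truth) in each truth stratum, bounded by the Fréchet
limits of the two margins (an infeasible value raises an error stating
the feasible interval).  `fit_concordance_adjustment` sets the knob from
a target total discordant mass; the packaged anchor for that target is
the observed 2005 feasibility-study discordance split (0.15
clinical-high/genomic-low + 0.20 clinical-low/genomic-high).  The
default parameter set keeps the knob at 0.

## Diffusion drivers and composition order

Per labelled year, three drivers apply (packaged trajectory in
parentheses for 2005/2010/2020):

| driver | meaning | values |
|---|---|---|
| technical failure *f* | assay yields no result; 10% of the test price is still incurred; treatment follows the guideline | 0.27 / 0.20 / 0.08 |
| non-compliance | fraction of each discordant cell treated per the guideline despite a delivered result | total 0.35 / 0.26 / 0.08 |
| uptake *u* | fraction of the eligible population actually tested | 0.03 / 0.50 / 0.92 |

Non-compliance totals are reported additively as the sum of the two
cell rates and are scaled across years proportionally to the 2005
split (0.15 : 0.20), since later years publish only totals.  An
alternative 2020 failure preset of 0.14 is exposed
(`default_trajectory(failure_2020=0.14)`); the packaged default is 0.08.

Canonical composition (regression-tested as non-commutative):

1. classify by each test; build the joint law;
2. **non-compliance** within delivered results (failed tests never reach
   a compliance decision — no result exists);
3. **failure** mixing: (1−f)·delivered + f·(guideline + 0.1·price);
4. **uptake** to the population level.

Two uptake readings are implemented.  The default **mixture** treats the
untested remainder as guideline-managed, making ΔE and ΔC exactly
linear through the origin in *u*.  The alternative **program** mode
(`uptake_mode="program"`) charges the expected testing cost for the
whole eligible population while only clinical consequences scale with
*u*; it reproduces the qualitative pattern of population incremental
costs *falling* as uptake rises (savings from better-targeted
chemotherapy grow with u against a fixed testing budget).  Neither is
asserted to be "the" historical mechanism; the mixture reading is the
default because it is the literal population interpretation of uptake.

## Synthetic parameters and defaults

The original model's clinical inputs are unpublished, so the packaged
parameter set is **synthetic**: structurally faithful, field-plausible,
and labelled `SYNTHETIC` in every serialized artefact so it cannot be
mistaken for clinical data.  Defaults (all overridable; annual
probabilities unless noted):

* disease-free → relapse 0.015; → metastasis 0.004 (truth-low) / 0.055
  (truth-high, endocrine only; 10-year cumulative ≈ 0.43 — "high risk"
  means strongly elevated, not certain); background death 0.006;
  relapse → metastasis 0.06; metastasis → death 0.30 (median survival
  ≈ 2–3 years).
* chemotherapy multiplies the metastasis transition by (1 − RRR),
  RRR = 0.45 by default.
* utilities 0.90 / 0.80 / 0.60 / 0 per state; chemotherapy disutility
  0.12 QALY in cycle 0.
* annual costs €250 / €1,000 / €9,000 per living state; relapse entry
  €12,000 once; chemotherapy €6,000 and endocrine therapy €1,500 once;
  signature price €2,675; guideline free.
* tests: signature sensitivity 0.95 / specificity 0.75; guideline 0.72 /
  0.40 (the guideline over-treats: low specificity); prevalence of
  truth-high 0.25; eligible incidence 2,400/year.

`generate_random` draws sets uniformly from feasibility-checked ranges
for property/fuzz testing; every draw passes full validation.

## Calibration

`calibrate` tunes free parameters (default: signature price, chemo RRR,
prevalence, chemo cost — each target responds monotonically to at least
one of them, see the emitted sensitivity table) by bounded Nelder–Mead
on a unit cube with seeded multi-start, minimising the sum of squared
relative residuals; it returns only if *every* target is inside its
relative tolerance, otherwise it raises with the best-achieved
residuals.  The default anchors are the published combined-2010
increments (ΔE = 0.0728 QALY, ΔC = €1,630 at drivers 0.20/0.26/0.50),
hit to numerical precision in a few hundred evaluations.

The published scenario rows are not mutually consistent under any fixed
composition of the above form: the per-tested effect gains implied by
the uptake and combined rows (0.1184 → 0.1456 → 0.1622 across the three
driver settings) require the non-compliance factor to *amplify* between
the first two settings and *dampen* between the last two, and the 2005
start row is a factor ≈ 3.5 below linear uptake scaling of the uptake
rows.  Calibration therefore anchors on the combined-2010 row only;
cross-year transfers are out-of-sample.  The calibrated set reproduces
the 2020 combined effect gain to within ≈ 17% (structurally
irreducible in this model family — verified by scanning the entire
exact-2010 solution manifold) and does not reproduce the published 2020
incremental-cost decline under the mixture reading, consistent with the
cost-side ambiguity noted above.

## Probabilistic sensitivity analysis

Families follow standard CEA practice (the source analysis assigns
distributions without naming families): **beta** for probabilities,
utilities and test accuracies, **gamma** for costs, both moment-matched
to the deterministic value as mean with a 10% relative standard error by
default (configurable); normal/log-normal available; drivers held
**fixed** by default, with `drivers.*` distribution targets available to
randomize them.  The same uncertainty specification is reused at every
year — uncertainty is treated as constant over the diffusion horizon.
1,000 iterations by default; all sampling flows from one
`numpy.random.Generator` seed, and identical (seed, config, inputs)
yield bit-identical draws.  Common random numbers across years (same
seed per year) support the acceptability frontier, defined at each λ as
the probability that the *expected*-iNMB-maximising strategy (the
comparator counting as zero) has the highest net benefit draw by draw;
ties go to the comparator.

Invalid draws (e.g. transition rows exceeding 1) are rejected and
redrawn; at the default 10% SE this is rare.

The published acceptance probabilities at €30,000/QALY (56% in 2010,
73% in 2020) depend on unpublished uncertainty magnitudes and are
treated as qualitative anchors only; with the synthetic defaults the
model produces the same ordering (rising acceptability along the
diffusion path, above 50% from 2010 on) but the levels are not expected
to match.

## Numerical choices and problem sizes

* Tolerances: transition rows sum to 1 within 1e-9 (validation) and
  traces conserve mass within 1e-10 (tested); share algebra within
  1e-12.
* ICER quadrants: ΔE > 0, ΔC < 0 → *dominant*; ΔE ≤ 0, ΔC > 0 →
  *dominated*; both ≤ 0 → ratio flagged *southwest* (not rankable by
  ratio).  Threshold decisions are strict: iNMB must exceed 0.
* Deterministic scenario evaluation is milliseconds; the test suite
  cross-validates the cohort engine against a 100,000-individual
  microsimulation (within 3 binomial standard errors) and exercises
  1,000 random matrices, sizes chosen to keep the full suite under a
  minute while leaving Monte-Carlo error negligible.

## What the synthetic generator does and does not show

The generator emulates the *structure* of the clinical inputs (state
transitions, misclassification, per-state economics) and, after
calibration, their published scenario-level consequences at the anchor
year.  It does not emulate: correlations between clinical parameters,
age-dependent mortality, time-varying recurrence hazards, or the true
joint behaviour of guideline and genomic calls beyond the one-knob
joint law.  Passing tests therefore demonstrate the correctness and
internal consistency of the *method* — classification algebra, cohort
arithmetic, diffusion composition, decision rules, uncertainty
propagation — not the clinical accuracy of any particular number; no
quantity computed from the synthetic defaults should be read as a
statement about the real test.

## Known limitations

* Single comparator; no multi-test market or >2-strategy frontier on
  the plane.
* Diffusion trajectories are exogenous inputs; no adoption-curve
  fitting.
* No value-of-information analysis.
* The published cost decline with rising uptake is reproduced only
  qualitatively, and only under the program-mode reading.
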