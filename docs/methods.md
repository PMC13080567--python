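# Methods

This note documents the model implemented by `dkdcea`, the assumptions
behind it, the choices made where the underlying evidence is silent, and
what the validation suite does and does not establish.

## Model structure

The cohort enters at age 65 distributed over early DKD stages G1/G2/G3a/G3b
(2.8% / 13.9% / 68.9% / 14.4%). A decision tree splits each stage by true
5-year PDKF status (prevalence `p` per stage) crossed with the arm's test
call (sensitivity `se`, specificity `sp`), yielding TP/FN/FP/TN cells.
Test-positive cells receive comprehensive care: an annual add-on of $2,655
(therapy escalation and extra visits) plus $143 (dietitian visit and
disease education), charged while the patient remains in G1–G3b. The
AI-assay arm additionally books a one-time $1,050 test fee at entry,
undiscounted. The comparator arm applies guideline-based stratification
(lower `se`/`sp`) at no assay cost.

Each cell then evolves through a 10-state annual-cycle Markov model for
5 years: G1→…→G5 → long-term dialysis → transient transplant →
post-transplant, with absorbing death and no regression to milder stages.
The transient transplant state lasts exactly one cycle and blends
perioperative-transplant and post-transplant cost/disutility with weights
0.25/0.75 (a 3-month perioperative period in a 1-year cycle; the weight is
configurable).

### Pathway-specific progression

The registry's stage exit rates are composite annual probabilities of
"progression to a more advanced stage or death" among patients *without*
prospective PDKF. Pathway rates derive from the base rate `r`:

| pathway | annual exit | interpretation |
|---|---|---|
| TN | `r` | no PDKF, conventional care |
| FN | `r·RR` | PDKF missed by the test (`RR ≥ 1` per stage) |
| TP | `r·RR·max(HR, 1/RR)` | PDKF treated; `HR ≤ 1` per stage |
| FP | `0.95·r` | nominal benefit of unnecessary comprehensive care |

The `max(HR, 1/RR)` cap encodes the assumption that correctly treated
high-risk patients can at best progress like true negatives, never more
slowly. All products are clamped to [0, 1]. From G4 onward renal-protective
care is standard management, so all four pathways share identical rows and
the care add-on ceases (both switchable).

### Destination allocation and the death split

The evidence base reports only composite exit rates, not their
destinations. The default allocation is the minimal structure consistent
with the state diagram: each G stage's exit mass goes to the next severity
state or directly to death, dialysis exits (0.222/y) go to transplant at
0.049/y with the remainder to death, the transplant cycle resolves to death
at 0.049 else post-transplant, and post-transplant exits (0.077/y) are
deaths. The whole allocation table is configurable and validated
(simplex rows, no regression).

The split of each composite exit between progression and death is not
published. `dkdcea` uses a single `death_share` setting, default **0.5**,
fixed a priori on clinical grounds: in this population annual mortality is
of the same order as stage progression (the non-monotone exit rates — G1
0.110/y exceeding G2 0.088/y — are themselves a sign of a large mortality
component), and an even split is the uninformative choice. This is the
model's single most consequential structural unknown: *levels* (arm costs
and QALYs) are fairly insensitive to it, while *increments* (ΔC, ΔQ and
hence every ICER) are acutely sensitive, because the assay's benefit is
mostly averted mortality. Reference values for the increment-derived
quantities should therefore be read with that caveat; the acceptance tests
encode the discrepancy honestly instead of fitting `death_share` to the
reference results.

### PDKF prevalence

The source input table this registry transcribes prints stage-level PDKF
point values (0.617/0.610/0.794/0.815) that contradict both their own
plausible ranges (≈0.11–0.37) and the downstream outputs of the original
analysis (an 18%/16% comprehensive-care share and a first-year budget
impact of ≈$1,112 per tested patient, both of which imply a cohort
prevalence near 0.25; a "50% prevalence" scenario described as *doubling*
the risk implies the same). The registry therefore uses the midpoints of
the printed ranges (0.210/0.205/0.260/0.270) as working bases — which
reproduce those downstream outputs exactly (the package computes
comprehensive-care shares of 18.1%/16.0%) — and preserves the printed point
values in the config notes. A settings switch substitutes the single
overall prevalence (0.766) for all stages instead.

## Rewards, discounting, aging

State utility at age `a` is `max(0, u₀ − δ·a − d_state)` with population
constant `u₀ = 0.944`, age decrement `δ = 0.0007` per year of age, and
state disutilities from 0.15 (G1/G2) to 0.53 (dialysis, perioperative
transplant); death scores 0. Age advances one year per cycle from 65.
Costs and QALYs accrue on start-of-cycle occupancy; cycle `t` (1…5) is
discounted by `1.03^−t`. Both conventions are switches
(`half_cycle_correction` averages start/end occupancy;
`discount_from_cycle_one=False` leaves the first cycle undiscounted).
QALY = Σ_cycles Σ_states occupancy × utility × cycle length.

## Uncertainty analysis

**Distributions.** Each non-fixed parameter's plausible range is read as a
95% interval: SD = (high − low)/3.92, mean = base, and Beta/Gamma/Normal
hyperparameters are fitted by the method of moments (uniform keeps its
endpoints). An infeasible Beta match (variance ≥ m(1−m)) falls back to
fixed with a warning. Normal draws are truncated to the parameter's domain
(hazard ratios to (0, 1], relative risks to [1, ∞)) by resampling, which
keeps every drawn transition matrix valid without material mean shift.
Three rows whose printed ranges do not bracket their base (transplant cost
and the transplant/post-transplant exit rates) carry substitute ±25% ranges,
with the printed ranges preserved in the notes.

**OWSA.** Two full pipeline runs per parameter (range endpoints, all else
base), ranked by ICER spread; dominance outcomes are kept as labels.
Degenerate ranges reproduce the base-case ICER exactly.

**PSA.** Default 1,000 joint draws (seeded, reproducible); the CEAC point
at threshold λ is the fraction of draws with positive incremental NMB. The
G3b stage share is set to the complement of the other drawn shares so the
initial distribution stays on the simplex.

**Scenarios.** `high_risk` sets PDKF prevalence to 0.50 at every initial
stage (in both arms). `liberal` reruns the tree with user-supplied
alternative sensitivity/specificity for a looser treatment threshold; no
defaults are shipped because the corresponding operating points are not
published, so requesting it without overrides is an error.

**Budget impact.** Undiscounted annual cost differences per patient scaled
by the tested population; year 1 carries the assay fee. The recurring
program tests the same number of new patients each year (default
42,000/y), each cohort's stream truncated at the 5-calendar-year window;
the budget share divides the cumulative impact by the reference budget
($70B/y) times the window length.

## Validation: what the microsimulation shows

`dkdcea.microsim` redraws the entire model patient by patient — initial
stage, pathway cell, then seeded categorical transitions — and accrues the
same rewards. It shares no code path with the cohort recursion beyond the
reward/transition definitions themselves, so agreement of its sample means
with the cohort totals (within 3 Monte-Carlo SEs at 200,000 patients,
checked for both arms and both scenarios) validates the matrix algebra,
aggregation and discounting of the deterministic engine. It does *not*
validate the inputs or the structural assumptions: both engines share the
same allocation, death split and reward conventions, so errors there would
cancel. Runs for both arms under one seed share common random numbers,
sharpening incremental comparisons.

## Problem sizes and numerical choices

Deterministic runs evolve 4 pathway vectors over 5 cycles (milliseconds);
the shipped analyses use 1,000 PSA draws and 200,000 microsimulation
patients, sizes at which Monte-Carlo error is well below the decision
tolerances. Row-stochasticity is enforced to 1e−12 and occupancy
conservation to 1e−10; utilities are floored at 0; ICERs are computed from
unrounded totals and rounded only at presentation. The default seed,
20260112, is an explicit argument everywhere.

## Known limitations

* The progression-vs-death split and the destination allocation are
  structural guesses (documented defaults, fully configurable); increments
  and ICERs depend on them strongly.
* No background mortality separate from the composite exits; no treatment
  switching or discontinuation; no patient-level covariates beyond stage.
* The transient transplant state approximates a 3-month episode inside a
  1-year cycle by blending rewards.
* Costs are not inflation-adjusted across currency years; the perspective
  is a single payer, and results do not transfer to populations with lower
  baseline risk.
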