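"""Annual-cycle Markov cohort engine over the ten DKD health states.

States: G1..G3b (early DKD, where risk stratification and comprehensive
care operate), G4, G5 (advanced DKD), long-term dialysis, a one-cycle
transient kidney-transplant (KT) state, post-KT, and absorbing death.
Regression to a less severe stage is not allowed.

Each pathway cell from the decision tree evolves under its own transition
matrix.  The published inputs give, per stage, a composite annual exit
probability ("progression to any advanced stage or death") for patients
without prospective PDKF; pathway-specific exits are derived from it:

* TN: the base exit rate ``r``;
* FN: ``r * RR`` where RR is the PDKF relative risk for that stage;
* TP: ``r * RR * max(HR, 1/RR)`` — comprehensive care's hazard ratio HR,
  capped so that correctly treated patients never progress more slowly than
  true negatives;
* FP: ``r * HR_fp`` with a nominal HR of 0.95 for comprehensive care in
  patients without prospective PDKF.

From G4 onward all pathways share identical rows: once DKD is advanced,
renal protective care is standard management and the PDKF label carries no
further meaning.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .params import EARLY_STAGES, ConfigError, InputSet
from .tree import COMPREHENSIVE_PATHWAYS, PATHWAYS, PathwayMix


class State(IntEnum):
    G1 = 0
    G2 = 1
    G3A = 2
    G3B = 3
    G4 = 4
    G5 = 5
    DIALYSIS = 6
    KT = 7          # transient: occupied for exactly one cycle
    POST_KT = 8
    DEATH = 9       # absorbing


N_STATES = len(State)

#: config-key suffix per state (DEATH has no rates/costs of its own).
_KEY = {
    State.G1: "g1", State.G2: "g2", State.G3A: "g3a", State.G3B: "g3b",
    State.G4: "g4", State.G5: "g5", State.DIALYSIS: "dialysis",
    State.KT: "kt", State.POST_KT: "post_kt",
}

EARLY_STATES = (State.G1, State.G2, State.G3A, State.G3B)
STAGE_TO_STATE = dict(zip(EARLY_STAGES, EARLY_STATES))


def effective_exit_probability(stage: str, pathway: str,
                               inputs: InputSet) -> float:
    """Annual composite exit probability for one early stage and pathway.

    Implements the cap rule: the benefit of correctly administered
    comprehensive care (TP) is limited by the inverse of the PDKF relative
    risk, so the TP exit never falls below the TN exit.
    """
    if stage not in EARLY_STAGES:
        raise ValueError(f"stage must be one of {EARLY_STAGES}, got {stage!r}")
    if pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}")
    r = inputs[f"exit_{stage}"]
    if pathway == "TN":
        return r
    if pathway == "FP":
        return min(r * inputs["hr_comp_fp"], 1.0)
    rr = inputs[f"rr_pdkf_{stage}"]
    if rr < 1.0:
        raise ConfigError(f"rr_pdkf_{stage} must be >= 1, got {rr}")
    if pathway == "FN":
        return min(r * rr, 1.0)
    hr = inputs[f"hr_comp_tp_{stage}"]
    return min(r * rr * max(hr, 1.0 / rr), 1.0)


# --------------------------------------------------------------------------
# destination allocation


def default_allocation(inputs: InputSet) -> dict[State, dict[State, float]]:
    """Default split of each state's exit mass among successor states.

    Each G-stage's composite exit is divided between the next severity state
    and death according to ``settings.death_share``; dialysis exits go to
    transient KT at the KT-entry rate (remainder to death); the transient KT
    cycle resolves to death at the listed KT exit rate, else post-KT; post-KT
    exits are deaths.
    """
    s = inputs.settings
    d = s.death_share
    exit_dial = inputs["exit_dialysis"]
    kt_share = min(s.kt_entry_rate / exit_dial, 1.0) if exit_dial > 0 else 0.0
    exit_kt = inputs["exit_kt"]
    nxt = {State.G1: State.G2, State.G2: State.G3A, State.G3A: State.G3B,
           State.G3B: State.G4, State.G4: State.G5, State.G5: State.DIALYSIS}
    alloc: dict[State, dict[State, float]] = {
        g: {n: 1.0 - d, State.DEATH: d} for g, n in nxt.items()
    }
    alloc[State.DIALYSIS] = {State.KT: kt_share, State.DEATH: 1.0 - kt_share}
    alloc[State.KT] = {State.DEATH: exit_kt, State.POST_KT: 1.0 - exit_kt}
    alloc[State.POST_KT] = {State.DEATH: 1.0}
    return alloc


def validate_allocation(alloc: dict[State, dict[State, float]]) -> None:
    """Check allocation rows: simplex weights, no regression to milder stages."""
    for state in State:
        if state is State.DEATH:
            continue
        if state not in alloc:
            raise ConfigError(f"allocation missing row for {state.name}")
        row = alloc[state]
        total = sum(row.values())
        if abs(total - 1.0) > 1e-12:
            raise ConfigError(
                f"allocation for {state.name} sums to {total}, expected 1"
            )
        for succ, w in row.items():
            if w < 0:
                raise ConfigError(
                    f"allocation {state.name}->{succ.name} is negative"
                )
            if succ <= state:
                raise ConfigError(
                    f"allocation {state.name}->{succ.name} moves to a state "
                    "that is not more severe (regression is not allowed)"
                )


# --------------------------------------------------------------------------
# transition model


@dataclass
class TransitionModel:
    """Per-pathway annual transition matrices plus the shared allocation."""

    matrices: dict[str, np.ndarray]
    allocation: dict[State, dict[State, float]]

    def matrix(self, pathway: str) -> np.ndarray:
        return self.matrices[pathway]


def _exit_probability(state: State, pathway: str, inputs: InputSet) -> float:
    if state in EARLY_STATES:
        return effective_exit_probability(_KEY[state], pathway, inputs)
    if state is State.KT:
        return 1.0  # transient: the whole mass leaves after one cycle
    if state is State.DEATH:
        return 0.0
    return inputs[f"exit_{_KEY[state]}"]


def build_transition_model(
    inputs: InputSet,
    allocation: dict[State, dict[State, float]] | None = None,
) -> TransitionModel:
    """Build the four pathway transition matrices (shared by both arms)."""
    alloc = default_allocation(inputs) if allocation is None else allocation
    validate_allocation(alloc)
    matrices = {}
    for pathway in PATHWAYS:
        P = np.zeros((N_STATES, N_STATES))
        for state in State:
            if state is State.DEATH:
                P[state, state] = 1.0
                continue
            e = _exit_probability(state, pathway, inputs)
            P[state, state] = 1.0 - e
            for succ, w in alloc[state].items():
                P[state, succ] += e * w
        rowsum = P.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-12):
            raise ConfigError(
                f"{pathway}: transition rows do not sum to 1: {rowsum}"
            )
        matrices[pathway] = P
    return TransitionModel(matrices=matrices, allocation=alloc)


# --------------------------------------------------------------------------
# per-state rewards


def state_disutility(state: State, inputs: InputSet) -> float:
    if state is State.DEATH:
        return 0.0
    if state is State.KT:
        w = inputs.settings.kt_cost_blend
        return w * inputs["disutility_kt"] + (1 - w) * inputs["disutility_post_kt"]
    return inputs[f"disutility_{_KEY[state]}"]


def state_utility(state: State, age: float, inputs: InputSet) -> float:
    """Utility of one state at a given age: baseline minus age decrement
    minus the state disutility, floored at zero; death scores zero."""
    if age <= 0:
        raise ValueError("age must be positive")
    if state is State.DEATH:
        return 0.0
    baseline = inputs["utility_constant"] - inputs["utility_age_decrement"] * age
    return max(baseline - state_disutility(state, inputs), 0.0)


def state_cost(state: State, pathway: str, inputs: InputSet) -> float:
    """Annual cost of occupying one state on one pathway.

    Comprehensive-care patients (TP/FP) accrue the care add-on (therapy
    escalation + education) while in the early stages; by default the add-on
    ceases at G4 and beyond, where renal protection is part of standard
    management and the state costs already cover it.  The transient KT cycle
    blends perioperative-transplant and post-transplant costs.
    """
    if state is State.DEATH:
        return 0.0
    if state is State.KT:
        w = inputs.settings.kt_cost_blend
        cost = w * inputs["cost_kt"] + (1 - w) * inputs["cost_post_kt"]
    else:
        cost = inputs[f"cost_{_KEY[state]}"]
    if pathway in COMPREHENSIVE_PATHWAYS:
        addon = inputs["cost_comprehensive_care"] + inputs["cost_education"]
        if state in EARLY_STATES or inputs.settings.comp_care_in_advanced:
            cost += addon
    return cost


# --------------------------------------------------------------------------
# cohort simulation


@dataclass
class ArmResult:
    """Aggregate outcome of one arm's 5-year cohort simulation.

    ``occupancy[t]`` is the cohort state distribution at the start of cycle
    ``t+1`` (``occupancy[0]`` is the initial distribution); ``cycle_cost`` /
    ``cycle_qaly`` are undiscounted per-cycle accruals excluding the one-time
    test cost, which is kept in ``test_cost``.
    """

    arm: str
    occupancy: np.ndarray          # (horizon + 1, N_STATES)
    cycle_cost: np.ndarray         # (horizon,) undiscounted USD
    cycle_qaly: np.ndarray         # (horizon,) undiscounted QALY
    disc_cost: float               # discounted USD incl. test cost
    disc_qaly: float
    test_cost: float

    @property
    def undisc_cost(self) -> float:
        return float(self.cycle_cost.sum() + self.test_cost)

    @property
    def undisc_qaly(self) -> float:
        return float(self.cycle_qaly.sum())


def run_cohort(mix: PathwayMix, inputs: InputSet,
               allocation: dict[State, dict[State, float]] | None = None,
               ) -> ArmResult:
    """Evolve every pathway cell over the horizon and aggregate the arm.

    Rewards are accrued on start-of-cycle occupancy; cycle ``t`` (1-based)
    is discounted by ``(1 + rate)^-t`` and uses age ``age0 + t - 1``.  The
    one-time test cost is booked undiscounted at entry.  Switches in
    :class:`~dkdcea.params.ModelSettings` select half-cycle reward averaging
    and first-cycle discounting conventions.
    """
    horizon = int(round(inputs["time_horizon"]))
    cycle_len = inputs["cycle_length"]
    rate = inputs["discount_rate"]
    age0 = inputs["age"]
    settings = inputs.settings

    model = build_transition_model(inputs, allocation)
    stage_w = np.array([inputs[f"stage_share_{s}"] for s in EARLY_STAGES])
    stage_w = stage_w / stage_w.sum()  # guard against drawn shares off by eps

    occupancy = np.zeros((horizon + 1, N_STATES))
    cycle_cost = np.zeros(horizon)
    cycle_qaly = np.zeros(horizon)
    disc_cost = 0.0
    disc_qaly = 0.0

    for pathway in PATHWAYS:
        occ = np.zeros(N_STATES)
        for stage, w in zip(EARLY_STAGES, stage_w):
            occ[STAGE_TO_STATE[stage]] = w * mix.fractions[stage][pathway]
        if occ.sum() == 0.0:
            continue
        P = model.matrix(pathway)
        cost_vec = np.array([state_cost(s, pathway, inputs) for s in State])
        occupancy[0] += occ
        for t in range(1, horizon + 1):
            age = age0 + (t - 1) * cycle_len
            util_vec = np.array(
                [state_utility(s, age, inputs) if s is not State.DEATH else 0.0
                 for s in State]
            )
            occ_next = occ @ P
            occ_accrual = 0.5 * (occ + occ_next) \
                if settings.half_cycle_correction else occ
            c = float(occ_accrual @ cost_vec) * cycle_len
            q = float(occ_accrual @ util_vec) * cycle_len
            if settings.test_cost_recurring and mix.test_cost_per_patient:
                alive = float(occ_accrual.sum() - occ_accrual[State.DEATH])
                c += alive * mix.test_cost_per_patient
            exponent = t if settings.discount_from_cycle_one else t - 1
            d = (1.0 + rate) ** (-exponent)
            cycle_cost[t - 1] += c
            cycle_qaly[t - 1] += q
            disc_cost += d * c
            disc_qaly += d * q
            occ = occ_next
            occupancy[t] += occ

    total = occupancy.sum(axis=1)
    if not np.allclose(total, 1.0, atol=1e-10):
        raise ConfigError(f"occupancy not conserved: sums {total}")

    test_cost = 0.0 if settings.test_cost_recurring else mix.test_cost_per_patient
    disc_cost += test_cost  # booked at entry, undiscounted
    return ArmResult(
        arm=mix.arm, occupancy=occupancy, cycle_cost=cycle_cost,
        cycle_qaly=cycle_qaly, disc_cost=disc_cost, disc_qaly=disc_qaly,
        test_cost=test_cost,
    )
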