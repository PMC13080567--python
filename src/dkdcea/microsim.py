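"""Individual-level microsimulation: a brute-force oracle for the cohort engine.

Patients are drawn one at a time through the same decision tree and
transition structure as the cohort model (initial stage from the stage
distribution, pathway cell from the test's confusion probabilities, then
seeded categorical state transitions each cycle) and accrue the same
discounted costs and QALYs.  By the law of large numbers the sample means
converge to the cohort model's expectations, which makes this module an
independent check on the deterministic engine.

All random numbers derive from the seed alone, not from the arm, so runs
for the two arms with the same seed share common random numbers; this
sharpens comparisons of arm differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import (N_STATES, STAGE_TO_STATE, State, build_transition_model,
                     state_cost, state_utility)
from .params import EARLY_STAGES, InputSet
from .tree import PATHWAYS, build_pathway_mix


@dataclass
class MicrosimResult:
    """Monte-Carlo estimates of one arm's per-patient discounted outcomes."""

    arm: str
    n: int
    seed: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float


def simulate_patients(inputs: InputSet, arm: str, n: int,
                      seed: int = 20260112) -> MicrosimResult:
    """Simulate ``n`` independent patients through one arm of the model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    settings = inputs.settings
    horizon = int(round(inputs["time_horizon"]))
    cycle_len = inputs["cycle_length"]
    rate = inputs["discount_rate"]
    age0 = inputs["age"]

    mix = build_pathway_mix(inputs, arm)
    model = build_transition_model(inputs)
    cum_p = np.stack(
        [np.cumsum(model.matrix(p), axis=1) for p in PATHWAYS]
    )  # (pathway, state, state)

    rng = np.random.default_rng(seed)
    u_stage = rng.random(n)
    u_path = rng.random(n)
    u_trans = rng.random((n, horizon))

    stage_w = np.array([inputs[f"stage_share_{s}"] for s in EARLY_STAGES])
    stage_w = stage_w / stage_w.sum()
    stage_idx = np.searchsorted(np.cumsum(stage_w), u_stage, side="right")
    stage_idx = np.minimum(stage_idx, len(EARLY_STAGES) - 1)

    # pathway assignment conditional on the patient's initial stage
    path_idx = np.empty(n, dtype=np.intp)
    for i, stage in enumerate(EARLY_STAGES):
        sel = stage_idx == i
        probs = np.array([mix.fractions[stage][p] for p in PATHWAYS])
        cuts = np.cumsum(probs)
        path_idx[sel] = np.minimum(
            np.searchsorted(cuts, u_path[sel], side="right"), len(PATHWAYS) - 1
        )

    cost_tab = np.array(
        [[state_cost(s, p, inputs) for s in State] for p in PATHWAYS]
    )  # (pathway, state)

    states = np.array(
        [STAGE_TO_STATE[EARLY_STAGES[i]] for i in stage_idx], dtype=np.intp
    )
    cost = np.full(n, float(mix.test_cost_per_patient)
                   if not settings.test_cost_recurring else 0.0)
    qaly = np.zeros(n)

    for t in range(1, horizon + 1):
        age = age0 + (t - 1) * cycle_len
        util_vec = np.array([state_utility(s, age, inputs) for s in State])
        nxt = (u_trans[:, t - 1][:, None] > cum_p[path_idx, states]).sum(axis=1)
        nxt = np.minimum(nxt, N_STATES - 1)
        if settings.half_cycle_correction:
            c = 0.5 * (cost_tab[path_idx, states] + cost_tab[path_idx, nxt])
            q = 0.5 * (util_vec[states] + util_vec[nxt])
            alive = 0.5 * ((states != State.DEATH) + (nxt != State.DEATH))
        else:
            c = cost_tab[path_idx, states]
            q = util_vec[states]
            alive = (states != State.DEATH).astype(float)
        if settings.test_cost_recurring and mix.test_cost_per_patient:
            c = c + alive * mix.test_cost_per_patient
        exponent = t if settings.discount_from_cycle_one else t - 1
        d = (1.0 + rate) ** (-exponent)
        cost += d * c * cycle_len
        qaly += d * q * cycle_len
        states = nxt

    return MicrosimResult(
        arm=arm, n=n, seed=seed,
        mean_cost=float(cost.mean()), mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)),
    )
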