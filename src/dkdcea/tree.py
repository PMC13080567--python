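"""Decision-tree stratification of the cohort into test-outcome pathways.

Each arm (AIKD assay vs KDIGO standard of care) classifies patients in the
early DKD stages G1-G3b as high risk or not for progressive decline in
kidney function (PDKF).  Crossing the true PDKF status with the test call
splits every initial stage into four pathway cells:

==========  ==================  =====================
pathway     true status         care received
==========  ==================  =====================
TP          PDKF, test +        comprehensive
FN          PDKF, test -        conventional
FP          no PDKF, test +     comprehensive
TN          no PDKF, test -     conventional
==========  ==================  =====================

The AIKD arm additionally books the one-time assay cost per patient.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import EARLY_STAGES, InputSet

ARMS = ("AIKD", "SoC")
PATHWAYS = ("TP", "FN", "FP", "TN")

#: Pathways routed to comprehensive care (test-positive calls).
COMPREHENSIVE_PATHWAYS = ("TP", "FP")


def stratify(prevalence: float, sensitivity: float,
             specificity: float) -> tuple[float, float, float, float]:
    """Split a population into (TP, FN, FP, TN) fractions.

    Standard confusion-matrix arithmetic: ``TP = p*se``, ``FN = p*(1-se)``,
    ``FP = (1-p)*(1-sp)``, ``TN = (1-p)*sp``; the four fractions sum to 1.
    """
    for label, v in (("prevalence", prevalence), ("sensitivity", sensitivity),
                     ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{label} must be in [0, 1], got {v}")
    tp = prevalence * sensitivity
    fn = prevalence * (1.0 - sensitivity)
    fp = (1.0 - prevalence) * (1.0 - specificity)
    tn = (1.0 - prevalence) * specificity
    return tp, fn, fp, tn


@dataclass
class PathwayMix:
    """Per-arm pathway composition of the cohort.

    ``fractions[stage][pathway]`` is conditional on the initial stage (the
    four pathways sum to 1 within each stage); combine with the initial stage
    distribution to obtain cohort-level cell weights.
    """

    arm: str
    fractions: dict[str, dict[str, float]]
    test_cost_per_patient: float

    def cell_weight(self, inputs: InputSet, stage: str, pathway: str) -> float:
        """Cohort-level weight of one (stage, pathway) cell."""
        return inputs[f"stage_share_{stage}"] * self.fractions[stage][pathway]

    def comprehensive_share(self, inputs: InputSet) -> float:
        """Fraction of the cohort routed to comprehensive care (TP + FP)."""
        return sum(
            self.cell_weight(inputs, s, p)
            for s in EARLY_STAGES for p in COMPREHENSIVE_PATHWAYS
        ) / sum(inputs[f"stage_share_{s}"] for s in EARLY_STAGES)


def build_pathway_mix(inputs: InputSet, arm: str) -> PathwayMix:
    """Apply the arm's test to every initial stage and return the mix.

    Stage-specific PDKF prevalence is used by default; the
    ``stage_specific_prevalence`` setting switches to the single overall
    value for all stages.  The assay cost is charged once, to the AIKD arm
    only.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if arm == "AIKD":
        se, sp = inputs["aikd_sensitivity"], inputs["aikd_specificity"]
        test_cost = inputs["cost_test"]
    else:
        se, sp = inputs["soc_sensitivity"], inputs["soc_specificity"]
        test_cost = 0.0
    fractions: dict[str, dict[str, float]] = {}
    for stage in EARLY_STAGES:
        if inputs.settings.stage_specific_prevalence:
            p = inputs[f"pdkf_prevalence_{stage}"]
        else:
            p = inputs["pdkf_prevalence_overall"]
        tp, fn, fp, tn = stratify(p, se, sp)
        fractions[stage] = {"TP": tp, "FN": fn, "FP": fp, "TN": tn}
    return PathwayMix(arm=arm, fractions=fractions,
                      test_cost_per_patient=test_cost)
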