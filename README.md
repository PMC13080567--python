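# dkdcea

Cost-effectiveness and budget-impact modelling of AI-driven risk
stratification in early diabetic kidney disease (DKD), from a payer
perspective.

## The problem

Adults with type 2 diabetes and early DKD (stages G1–G3b) differ widely in
their risk of *progressive decline in kidney function* (PDKF): an eGFR slope
worse than −5 mL/min/y, a sustained ≥40% eGFR drop, or kidney failure within
5 years. Patients flagged high-risk are switched to comprehensive management
(SGLT2-inhibitor-based therapy escalation, diet counselling, disease
education), which slows progression but costs more. An AI-driven in vitro
risk assay (blood biomarkers + EHR features; here "AIKD") classifies
patients more accurately than guideline-based (KDIGO) stratification — but
adds a $1,050 one-time fee. Is the trade worth it?

`dkdcea` answers this with a hybrid decision model for a health system
whose users are health-economics and outcomes researchers working in Python:

1. **Decision tree** — per initial stage, the cohort splits into
   true/false positives/negatives from the PDKF prevalence `p` and the
   test's sensitivity `se` / specificity `sp`:
   `TP = p·se`, `FN = p·(1−se)`, `FP = (1−p)·(1−sp)`, `TN = (1−p)·sp`.
   Test-positive patients (TP, FP) receive comprehensive care.
2. **Markov cohort model** — ten health states (G1…G3b, G4, G5, long-term
   dialysis, a one-cycle transient transplant state, post-transplant,
   death), annual cycles, 5-year horizon, no regression to milder stages.
   Pathway-specific exit probabilities from each early stage derive from the
   base rate `r`, the PDKF relative risk `RR ≥ 1` and the care hazard ratio
   `HR ≤ 1`:
   `TN: r`, `FN: r·RR`, `TP: r·RR·max(HR, 1/RR)` (capped so treated
   high-risk patients never do better than true negatives), `FP: 0.95·r`.
3. **Outcomes** — discounted (3%/y) costs and QALYs per arm;
   `ICER = ΔC/ΔE`; net monetary benefit `NMB = λ·E − C` at
   willingness-to-pay `λ`.
4. **Uncertainty** — one-way sensitivity analysis (tornado), probabilistic
   sensitivity analysis with moment-matched Beta/Gamma/Normal/Uniform
   distributions (mean = base, SD = range/3.92) and the acceptability curve,
   scenario analyses (50%-prevalence high-risk cohort; user-specified
   liberal classification), and undiscounted budget impact for a tested
   population.
5. **Validation** — a seeded individual-level microsimulation replays the
   identical structure patient by patient and must agree with the cohort
   engine within Monte-Carlo error.

All inputs ship in a YAML registry (`dkdcea/data/default_inputs.yaml`) with
base value, plausible range and distribution family, and everything is
configurable, including the structural switches (progression-vs-death split
of the composite exit rates, transplant-cycle blending, discount timing,
half-cycle correction). See `docs/methods.md` for the modelling choices and
their rationale.

## Worked example

```python
from dkdcea import default_inputs, run_base_case
print(run_base_case(default_inputs()).to_string(index=False))
```

prints

```
 scenario     cost_aikd  qaly_aikd      cost_soc  qaly_soc  delta_cost  delta_qaly          icer
base_case 145521.541787   2.870613 143967.015878  2.861589 1554.525909    0.009025 172254.924990
high_risk 146107.546942   2.847649 143483.504014  2.828781 2624.042928    0.018868 139071.392297
```

Read: under base-case inputs the AI-guided arm costs $145,522 and yields
2.8706 discounted QALYs per patient over 5 years, versus $143,967 and
2.8616 for standard of care — an extra $1,555 for 0.0090 QALYs, i.e. an
ICER of ≈ $172,000 per QALY gained. In the high-risk scenario (PDKF
prevalence 50% at every initial stage) the assay prevents more
misclassification harm and the ICER falls to ≈ $139,000 per QALY.

The `examples/` scripts walk through each capability (base case, tornado,
PSA/CEAC, budget impact, microsimulation check) and print annotated output.
A thin CLI wraps the same pipeline:

```bash
dkdcea run                 # scenario table
dkdcea owsa --top 10       # tornado
dkdcea psa --n-draws 1000  # acceptance probabilities
dkdcea bia --n 42000       # budget impact
dkdcea validate cfg.yaml   # config validation
dkdcea run-all --out-dir out/   # full artifact bundle + manifest
```

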