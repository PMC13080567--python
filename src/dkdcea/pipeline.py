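"""End-to-end orchestration: config -> tree -> Markov -> CEA metrics.

These are the library entry points the CLI, the sensitivity analyses and
the budget-impact module all share, so every analysis runs the identical
pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .markov import ArmResult, State, run_cohort
from .metrics import CEAOutput, compare_arms
from .params import InputSet, ScenarioError, dump_inputs, scenario
from .tree import ARMS, build_pathway_mix


def arm_results(inputs: InputSet) -> tuple[ArmResult, ArmResult]:
    """Run both arms of the model; returns (AIKD, SoC)."""
    aikd = run_cohort(build_pathway_mix(inputs, "AIKD"), inputs)
    soc = run_cohort(build_pathway_mix(inputs, "SoC"), inputs)
    return aikd, soc


def evaluate(inputs: InputSet,
             wtps: tuple[float, ...] = (150_000.0, 200_000.0)) -> CEAOutput:
    """Full deterministic pipeline: AIKD vs SoC cost-effectiveness."""
    aikd, soc = arm_results(inputs)
    return compare_arms(aikd, soc, wtps=wtps)


def occupancy_frame(result: ArmResult) -> pd.DataFrame:
    """Tidy per-cycle state occupancy trace for one arm."""
    rows = []
    for t, occ in enumerate(result.occupancy):
        for s in State:
            rows.append({"arm": result.arm, "cycle": t,
                         "state": s.name, "fraction": occ[s]})
    return pd.DataFrame(rows)


def run_base_case(inputs: InputSet,
                  liberal_overrides: Mapping[str, float] | None = None,
                  ) -> pd.DataFrame:
    """Headline results table: base case, high-risk, optional liberal row.

    The liberal-classification scenario needs user-supplied alternative
    sensitivity/specificity values; without them the row is omitted (the
    source does not print those operating points).
    """
    rows = []
    cases = [("base_case", scenario(inputs, "base_case"))]
    if liberal_overrides:
        cases.append(
            ("liberal", scenario(inputs, "liberal", liberal_overrides))
        )
    cases.append(("high_risk", scenario(inputs, "high_risk")))
    for tag, case_inputs in cases:
        cea = evaluate(case_inputs)
        rows.append({
            "scenario": tag,
            "cost_aikd": cea.cost_a, "qaly_aikd": cea.qaly_a,
            "cost_soc": cea.cost_b, "qaly_soc": cea.qaly_b,
            "delta_cost": cea.delta_cost, "delta_qaly": cea.delta_qaly,
            "icer": cea.icer,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# full artifact bundle


@dataclass
class RunManifest:
    config_sha256: str
    scenario: str
    seed: int
    n_draws: int
    package_version: str
    python_version: str
    outputs: dict[str, str]

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2),
                        encoding="utf-8")


def run_all(inputs: InputSet, out_dir: str | Path, seed: int = 20260112,
            n_draws: int = 1000, n_tested: int = 42_000,
            make_plots: bool = False) -> RunManifest:
    """Run every analysis and write the artifact bundle to ``out_dir``.

    Emits ``results.json`` (scenario table + base-case CEA), ``tornado.csv``,
    ``psa_draws.csv``, ``ceac.csv``, ``bia.csv`` and ``manifest.json``;
    optionally PNG plots of the tornado, CE plane and acceptability curve.
    """
    from .budget import bia_one_time, bia_recurring
    from .metrics import DEFAULT_WTP_GRID
    from .sensitivity import owsa, psa, tornado_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    table = run_base_case(inputs)
    base_cea = evaluate(inputs)
    results = {
        "scenarios": table.to_dict(orient="records"),
        "base_case": base_cea.as_dict(),
    }

    entries = owsa(inputs)
    tornado = tornado_frame(entries)
    tornado.to_csv(out / "tornado.csv", index=False)
    outputs["tornado"] = "tornado.csv"

    psa_res = psa(inputs, n=n_draws, seed=seed, wtp_grid=DEFAULT_WTP_GRID)
    pd.DataFrame({
        "draw": np.arange(psa_res.n),
        "delta_cost": psa_res.delta_cost,
        "delta_qaly": psa_res.delta_qaly,
    }).to_csv(out / "psa_draws.csv", index=False)
    outputs["psa_draws"] = "psa_draws.csv"
    pd.DataFrame({
        "wtp": psa_res.wtp_grid, "probability": psa_res.ceac,
    }).to_csv(out / "ceac.csv", index=False)
    outputs["ceac"] = "ceac.csv"
    results["psa"] = {
        "n": psa_res.n, "seed": psa_res.seed,
        "acceptance_150k": psa_res.acceptance(150_000.0),
        "acceptance_200k": psa_res.acceptance(200_000.0),
    }

    bia1 = bia_one_time(inputs, n_tested=n_tested)
    biar = bia_recurring(inputs, n_per_year=n_tested)
    pd.DataFrame({
        "year": np.arange(1, len(bia1.annual) + 1),
        "one_time_delta_usd": bia1.annual,
        "recurring_delta_usd": biar.annual,
    }).to_csv(out / "bia.csv", index=False)
    outputs["bia"] = "bia.csv"
    results["bia"] = {
        "one_time_total": bia1.cumulative, "one_time_share": bia1.budget_share,
        "recurring_total": biar.cumulative, "recurring_share": biar.budget_share,
    }

    (out / "results.json").write_text(
        json.dumps(results, indent=2, default=float), encoding="utf-8"
    )
    outputs["results"] = "results.json"

    if make_plots:
        from .plots import plot_ce_plane, plot_ceac, plot_tornado
        plot_tornado(entries, base_cea.icer, out / "tornado.png")
        plot_ce_plane(psa_res, out / "ce_plane.png")
        plot_ceac(psa_res, out / "ceac.png")
        outputs.update(tornado_plot="tornado.png", ce_plane="ce_plane.png",
                       ceac_plot="ceac.png")

    manifest = RunManifest(
        config_sha256=hashlib.sha256(dump_inputs(inputs).encode()).hexdigest(),
        scenario=inputs.scenario,
        seed=seed,
        n_draws=n_draws,
        package_version=__version__,
        python_version=platform.python_version(),
        outputs=outputs,
    )
    manifest.write(out / "manifest.json")
    return manifest
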