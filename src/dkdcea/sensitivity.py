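"""One-way (tornado) and probabilistic sensitivity analyses.

OWSA reruns the full pipeline twice per parameter (at its plausible-range
endpoints, everything else at base) and ranks parameters by the spread of
the resulting ICERs.  PSA draws every non-fixed parameter jointly from its
moment-matched distribution, reruns the pipeline per draw, and summarises
the draws as a cost-effectiveness plane and acceptability curve (CEAC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .metrics import DEFAULT_WTP_GRID
from .params import REGISTRY, InputSet, sample_psa
from .pipeline import evaluate


@dataclass
class TornadoEntry:
    """ICER excursion of one parameter over its plausible range."""

    name: str
    low_input: float
    high_input: float
    icer_low: float | str    # dominance runs keep their label
    icer_high: float | str
    spread: float            # |icer_high - icer_low|; NaN if either is a label

    @staticmethod
    def _numeric(x: float | str) -> bool:
        return not isinstance(x, str)


def owsa(inputs: InputSet,
         parameters: Iterable[str] | None = None) -> list[TornadoEntry]:
    """One-way sensitivity analysis over the given (default: all) parameters.

    Parameters with a degenerate range are skipped when scanning the whole
    registry but honoured (spread 0) when named explicitly.  Entries are
    sorted by descending spread; label-valued (dominance) entries sort last.
    """
    if parameters is None:
        names = [n for n, s in REGISTRY.items() if s.varies]
    else:
        names = list(parameters)
        unknown = set(names) - set(REGISTRY)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
    entries = []
    for name in names:
        spec = REGISTRY[name]
        icer_lo = evaluate(inputs.replace(**{name: spec.low})).icer
        icer_hi = evaluate(inputs.replace(**{name: spec.high})).icer
        if TornadoEntry._numeric(icer_lo) and TornadoEntry._numeric(icer_hi):
            spread = abs(icer_hi - icer_lo)
        else:
            spread = float("nan")
        entries.append(TornadoEntry(name, spec.low, spec.high,
                                    icer_lo, icer_hi, spread))
    entries.sort(key=lambda e: (np.isnan(e.spread), -0.0 if np.isnan(e.spread)
                                else -e.spread))
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.name, "low_input": e.low_input,
        "high_input": e.high_input, "icer_low": e.icer_low,
        "icer_high": e.icer_high, "spread": e.spread,
    } for e in entries])


@dataclass
class PSAResult:
    """Draw-level incremental outcomes plus the acceptability curve."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    wtp_grid: np.ndarray
    ceac: np.ndarray
    seed: int
    n: int

    def acceptance(self, wtp: float) -> float:
        """Fraction of draws with positive incremental NMB at ``wtp``."""
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0.0))


def psa(inputs: InputSet, n: int = 1000, seed: int = 20260112,
        wtp_grid: Sequence[float] = DEFAULT_WTP_GRID) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n`` Monte-Carlo draws."""
    draws = sample_psa(inputs, n, seed)
    dc = np.empty(n)
    de = np.empty(n)
    for i, draw in enumerate(draws):
        cea = evaluate(draw, wtps=())
        dc[i] = cea.delta_cost
        de[i] = cea.delta_qaly
    grid = np.asarray(wtp_grid, dtype=float)
    ceac = np.array([np.mean(w * de - dc > 0.0) for w in grid])
    return PSAResult(delta_cost=dc, delta_qaly=de, wtp_grid=grid,
                     ceac=ceac, seed=seed, n=n)
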