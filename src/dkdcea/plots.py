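"""Plot helpers: tornado diagram, cost-effectiveness plane, CEAC."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def plot_tornado(entries: Sequence, base_icer: float, path: str | Path,
                 top: int = 15) -> None:
    """Horizontal tornado of ICER excursions around the base-case ICER.

    Dominance (label-valued) runs are drawn at the plot boundary with their
    label.
    """
    numeric = [e for e in entries if not isinstance(e.icer_low, str)
               and not isinstance(e.icer_high, str)]
    shown = numeric[:top]
    shown = shown[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * max(len(shown), 4) + 1.2))
    for i, e in enumerate(shown):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878a8")
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.name for e in shown], fontsize=8)
    ax.set_xlabel("ICER (USD per QALY)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(psa_result, path: str | Path,
                  wtp: float = 150_000.0) -> None:
    """Scatter of incremental (QALY, cost) draws with a WTP reference line."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa_result.delta_qaly, psa_result.delta_cost, s=6, alpha=0.4)
    lim = max(abs(psa_result.delta_qaly).max(), 1e-6)
    xs = [-lim, lim]
    ax.plot(xs, [wtp * x for x in xs], "k--", lw=1,
            label=f"WTP ${wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (USD)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(psa_result, path: str | Path) -> None:
    """Cost-effectiveness acceptability curve over the WTP grid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(psa_result.wtp_grid, psa_result.ceac, marker="o", ms=3)
    ax.set_xlabel("Willingness to pay (USD per QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
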