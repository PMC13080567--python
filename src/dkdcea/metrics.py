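"""Cost-effectiveness metrics: incremental cost/QALY, ICER, NMB.

The incremental cost-effectiveness ratio is reported from unrounded arm
totals; dominance cases are returned as labels rather than numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .markov import ArmResult

DOMINANT = "dominant"
DOMINATED = "dominated"
INDETERMINATE = "indeterminate"


def icer(cost_a: float, qaly_a: float, cost_b: float,
         qaly_b: float) -> float | str:
    """ICER of strategy A versus B, or a dominance label.

    Returns ``delta_cost / delta_qaly`` when A gains QALYs at extra cost
    (and, by convention, in the south-west quadrant where A is cheaper and
    less effective); ``"dominant"`` when A is cheaper and more effective;
    ``"dominated"`` when A is costlier and less effective; and
    ``"indeterminate"`` when the QALY difference is exactly zero.
    """
    dc = cost_a - cost_b
    de = qaly_a - qaly_b
    if de == 0.0:
        return INDETERMINATE
    if de > 0.0 and dc < 0.0:
        return DOMINANT
    if de < 0.0 and dc > 0.0:
        return DOMINATED
    return dc / de


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * qaly - cost


#: Default willingness-to-pay grid, $0-$200,000 in $5,000 steps.
DEFAULT_WTP_GRID = tuple(range(0, 200_001, 5_000))


@dataclass
class CEAOutput:
    """Pairwise cost-effectiveness comparison of two arms (A vs B)."""

    arm_a: str
    arm_b: str
    cost_a: float
    qaly_a: float
    cost_b: float
    qaly_b: float
    wtps: tuple[float, ...] = (150_000.0, 200_000.0)
    delta_cost: float = field(init=False)
    delta_qaly: float = field(init=False)
    icer: float | str = field(init=False)
    inc_nmb: dict[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.delta_cost = self.cost_a - self.cost_b
        self.delta_qaly = self.qaly_a - self.qaly_b
        self.icer = icer(self.cost_a, self.qaly_a, self.cost_b, self.qaly_b)
        self.inc_nmb = {
            w: nmb(self.cost_a, self.qaly_a, w) - nmb(self.cost_b, self.qaly_b, w)
            for w in self.wtps
        }

    def as_dict(self) -> dict:
        return {
            "arm_a": self.arm_a, "arm_b": self.arm_b,
            "cost_a": self.cost_a, "qaly_a": self.qaly_a,
            "cost_b": self.cost_b, "qaly_b": self.qaly_b,
            "delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "inc_nmb": {str(int(w)): v for w, v in self.inc_nmb.items()},
        }


def compare_arms(result_a: ArmResult, result_b: ArmResult,
                 wtps: tuple[float, ...] = (150_000.0, 200_000.0)) -> CEAOutput:
    """Build a :class:`CEAOutput` from two simulated arms."""
    return CEAOutput(
        arm_a=result_a.arm, arm_b=result_b.arm,
        cost_a=result_a.disc_cost, qaly_a=result_a.disc_qaly,
        cost_b=result_b.disc_cost, qaly_b=result_b.disc_qaly,
        wtps=wtps,
    )
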