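"""Incremental cost-effectiveness arithmetic: ICER, iNMB, decision rules.

The comparison is always "new strategy minus comparator", summarised by
the incremental cost-effectiveness ratio ICER = dC / dE and the
incremental net monetary benefit iNMB = dE * lambda - dC at a
willingness-to-pay threshold lambda (EUR per QALY, 30,000 by default).
The new strategy is deemed cost-effective iff iNMB > 0 (strict: an ICER
exactly at the threshold does not qualify).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "WTPThreshold",
    "Icer",
    "CEResult",
    "icer",
    "inmb",
    "is_cost_effective",
]

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class WTPThreshold:
    """Willingness-to-pay ceiling ratio, EUR per QALY."""

    lambda_eur_per_qaly: float = 30_000.0

    def __post_init__(self) -> None:
        if self.lambda_eur_per_qaly < 0:
            raise ValueError("threshold must be >= 0")


@dataclass(frozen=True)
class Icer:
    """ICER as a ratio or a dominance code.

    ``ratio`` is dC/dE where defined; ``code`` is ``"dominant"`` (more
    effect, less cost), ``"dominated"`` (less or equal effect, more cost)
    or ``None``.  ``southwest`` flags the cost-saving/effect-losing
    quadrant, where a *smaller* ratio is not better and the ratio must
    not be naively ranked.
    """

    ratio: float | None
    code: str | None = None
    southwest: bool = False

    def display(self) -> str:
        if self.code is not None:
            return self.code
        if self.ratio is None or math.isnan(self.ratio):
            return "undefined"
        tag = " (SW)" if self.southwest else ""
        return f"{self.ratio:,.0f}{tag}"


def icer(delta_costs: float, delta_effects: float) -> Icer:
    """Classify the incremental pair on the cost-effectiveness plane.

    Northeast (dE > 0, dC >= 0): plain ratio.  Southeast (dE > 0,
    dC < 0): ``dominant``.  Northwest (dE <= 0, dC > 0): ``dominated``.
    Southwest (dE <= 0, dC <= 0): ratio reported with a flag, since less
    effect at lower cost cannot be ranked by the ratio alone.
    """
    de, dc = float(delta_effects), float(delta_costs)
    if de > 0:
        if dc < 0:
            return Icer(ratio=None, code=DOMINANT)
        return Icer(ratio=dc / de)
    if dc > 0:
        return Icer(ratio=None, code=DOMINATED)
    # southwest quadrant (incl. the 0/0 origin)
    ratio = math.nan if de == 0 else dc / de
    return Icer(ratio=ratio, southwest=True)


def inmb(delta_effects: float, delta_costs: float, threshold: WTPThreshold | float = WTPThreshold()) -> float:
    """Incremental net monetary benefit dE * lambda - dC."""
    lam = threshold.lambda_eur_per_qaly if isinstance(threshold, WTPThreshold) else float(threshold)
    return float(delta_effects) * lam - float(delta_costs)


@dataclass(frozen=True)
class CEResult:
    """Incremental outcome summary for one scenario evaluation."""

    delta_effects: float
    delta_costs: float
    icer: Icer
    inmb: float
    threshold: WTPThreshold = WTPThreshold()

    @classmethod
    def from_increments(
        cls,
        delta_effects: float,
        delta_costs: float,
        threshold: WTPThreshold = WTPThreshold(),
    ) -> "CEResult":
        return cls(
            delta_effects=float(delta_effects),
            delta_costs=float(delta_costs),
            icer=icer(delta_costs, delta_effects),
            inmb=inmb(delta_effects, delta_costs, threshold),
            threshold=threshold,
        )

    def to_record(self) -> dict:
        return {
            "delta_effects": self.delta_effects,
            "delta_costs": self.delta_costs,
            "icer": self.icer.display(),
            "inmb": self.inmb,
            "lambda": self.threshold.lambda_eur_per_qaly,
        }


def is_cost_effective(result: CEResult, threshold: WTPThreshold | None = None) -> bool:
    """Strict positive-iNMB decision rule.

    Agrees with the ICER-below-lambda comparison whenever dE > 0; at the
    boundary (iNMB = 0, i.e. ICER = lambda) the strategy is *not*
    cost-effective.
    """
    thr = threshold if threshold is not None else result.threshold
    return inmb(result.delta_effects, result.delta_costs, thr) > 0
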