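"""Risk classification by prognostic tests and strategy-level expected outcomes.

A prognostic test (the genomic 70-gene-signature-like assay, or the
clinical-pathological guideline used as comparator) labels each eligible
patient *high* or *low* risk of distant metastasis.  Against the latent
truth (elevated metastasis risk under endocrine-only treatment) this
yields four risk groups — true low/high, false low/high — whose cohort
shares follow directly from prevalence, sensitivity and specificity.
High-risk calls receive adjuvant chemotherapy on top of endocrine
therapy; low-risk calls receive endocrine therapy only.

For the interplay of two tests on the same patient (needed to model
non-compliance with discordant results) an eight-cell joint law over
(guideline call x genomic call x truth) is built, by default assuming the
two calls are conditionally independent given the truth, with a single
concordance-adjustment knob bounded by the Frechet limits of the two
margins.

This layer assumes full adherence: test results are always followed.
Technical failure, non-compliance and uptake live in :mod:`diffcea.diffusion`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .health_model import (
    INITIAL_DISEASE_FREE,
    EconomicSettings,
    ModelValidationError,
    accumulate,
    run_cohort,
)

__all__ = [
    "PrognosticTest",
    "PopulationProfile",
    "RiskGroupShares",
    "JointClassification",
    "TreatmentPolicy",
    "DEFAULT_POLICY",
    "classify",
    "joint_classification",
    "fit_concordance_adjustment",
    "RASTER_DISCORDANCE",
    "group_outcome",
    "strategy_expected_outcomes",
]

ENDOCRINE = "endocrine"
ENDOCRINE_CHEMO = "endocrine_chemo"


@dataclass(frozen=True)
class PrognosticTest:
    """A binary risk classifier with a per-test price (EUR)."""

    name: str
    sensitivity: float
    specificity: float
    unit_cost: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("sensitivity", "specificity"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ModelValidationError(f"{self.name}: {attr} must lie in [0, 1]")
        if self.unit_cost < 0:
            raise ModelValidationError(f"{self.name}: unit_cost must be >= 0")

    def p_high(self, truth_high: bool) -> float:
        """P(test calls high | truth)."""
        return self.sensitivity if truth_high else 1.0 - self.specificity


@dataclass(frozen=True)
class PopulationProfile:
    """Eligible population: node-negative, ER-positive early breast cancer.

    ``prevalence_true_high`` is the fraction of eligible patients at
    truly elevated distant-metastasis risk under endocrine-only
    treatment; ``annual_incidence`` the number of eligible patients per
    year in the jurisdiction.
    """

    prevalence_true_high: float
    annual_incidence: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence_true_high <= 1.0:
            raise ModelValidationError("prevalence must lie in [0, 1]")
        if self.annual_incidence < 0:
            raise ModelValidationError("annual incidence must be >= 0")


@dataclass(frozen=True)
class RiskGroupShares:
    """Cohort fractions over the four (truth x call) risk groups."""

    true_low: float
    true_high: float
    false_low: float
    false_high: float

    def __post_init__(self) -> None:
        vals = self.as_dict()
        for k, v in vals.items():
            if v < -1e-12 or v > 1 + 1e-12:
                raise ModelValidationError(f"share {k}={v} outside [0, 1]")
        if abs(sum(vals.values()) - 1.0) > 1e-12:
            raise ModelValidationError("risk-group shares must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "true_low": self.true_low,
            "true_high": self.true_high,
            "false_low": self.false_low,
            "false_high": self.false_high,
        }

    @property
    def prevalence(self) -> float:
        return self.true_high + self.false_low

    @property
    def sensitivity(self) -> float:
        p = self.prevalence
        return self.true_high / p if p > 0 else float("nan")

    @property
    def specificity(self) -> float:
        q = self.true_low + self.false_high
        return self.true_low / q if q > 0 else float("nan")


def classify(profile: PopulationProfile, test: PrognosticTest) -> RiskGroupShares:
    """Split the eligible cohort into the four risk groups.

    true_high = prevalence x sensitivity, false_low = prevalence x
    (1 - sensitivity), true_low = (1 - prevalence) x specificity,
    false_high = (1 - prevalence) x (1 - specificity).
    """
    p = profile.prevalence_true_high
    return RiskGroupShares(
        true_low=(1 - p) * test.specificity,
        true_high=p * test.sensitivity,
        false_low=p * (1 - test.sensitivity),
        false_high=(1 - p) * (1 - test.specificity),
    )


@dataclass(frozen=True)
class JointClassification:
    """Joint law over (guideline call, genomic call, truth).

    ``cells[g, s, t]`` with indices 0 = low/not-high-risk-truth and
    1 = high: the probability a patient draws guideline call ``g``,
    signature call ``s`` and truth ``t``.
    """

    cells: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cells, dtype=float)
        if c.shape != (2, 2, 2):
            raise ModelValidationError("joint classification must be 2x2x2")
        if np.any(c < -1e-12):
            raise ModelValidationError("joint cells must be non-negative")
        if abs(c.sum() - 1.0) > 1e-10:
            raise ModelValidationError("joint cells must sum to 1")
        object.__setattr__(self, "cells", np.clip(c, 0.0, 1.0))

    @property
    def concordant(self) -> float:
        return float(self.cells[0, 0].sum() + self.cells[1, 1].sum())

    @property
    def discordant_chgl(self) -> float:
        """Clinical high / genomic low mass."""
        return float(self.cells[1, 0].sum())

    @property
    def discordant_clgh(self) -> float:
        """Clinical low / genomic high mass."""
        return float(self.cells[0, 1].sum())

    def guideline_shares(self) -> RiskGroupShares:
        return self._margin(axis=1)

    def signature_shares(self) -> RiskGroupShares:
        return self._margin(axis=0)

    def _margin(self, axis: int) -> RiskGroupShares:
        m = self.cells.sum(axis=axis)  # (call, truth)
        return RiskGroupShares(
            true_low=float(m[0, 0]),
            true_high=float(m[1, 1]),
            false_low=float(m[0, 1]),
            false_high=float(m[1, 0]),
        )


def joint_classification(
    profile: PopulationProfile,
    guideline: PrognosticTest,
    signature: PrognosticTest,
    concordance_adjustment: float = 0.0,
) -> JointClassification:
    """Joint call distribution, conditionally independent given truth.

    ``concordance_adjustment`` shifts probability mass towards (positive)
    or away from (negative) concordant calls *within each truth stratum*:
    P(both high | truth) = P(g high | truth) P(s high | truth) + adj.
    It must lie within the Frechet bounds of both strata; an infeasible
    value raises an error stating the feasible interval.
    """
    adj = float(concordance_adjustment)
    lo, hi = -np.inf, np.inf
    for truth_high in (False, True):
        pg = guideline.p_high(truth_high)
        ps = signature.p_high(truth_high)
        lo = max(lo, max(0.0, pg + ps - 1.0) - pg * ps)
        hi = min(hi, min(pg, ps) - pg * ps)
    if not lo - 1e-12 <= adj <= hi + 1e-12:
        raise ModelValidationError(
            f"concordance adjustment {adj} infeasible; "
            f"feasible interval is [{lo:.6f}, {hi:.6f}]"
        )

    cells = np.zeros((2, 2, 2))
    weights = (1 - profile.prevalence_true_high, profile.prevalence_true_high)
    for t, w in enumerate(weights):
        pg = guideline.p_high(bool(t))
        ps = signature.p_high(bool(t))
        p11 = pg * ps + adj
        cells[1, 1, t] = p11
        cells[1, 0, t] = pg - p11
        cells[0, 1, t] = ps - p11
        cells[0, 0, t] = 1 - pg - ps + p11
        cells[:, :, t] *= w
    return JointClassification(cells=cells)


#: discordance fractions (clinical-high/genomic-low, clinical-low/genomic-high)
#: observed in the 2005 feasibility study; packaged fixture for setting the
#: concordance-adjustment knob.
RASTER_DISCORDANCE = (0.15, 0.20)


def fit_concordance_adjustment(
    profile: PopulationProfile,
    guideline: PrognosticTest,
    signature: PrognosticTest,
    target_total_discordance: float = sum(RASTER_DISCORDANCE),
) -> float:
    """Concordance adjustment that matches a target total discordant mass.

    A single knob cannot match both discordant cells separately; the
    total is matched instead (clipped to the feasible Frechet interval).
    """
    from scipy import optimize

    lo, hi = -np.inf, np.inf
    for truth_high in (False, True):
        pg, ps = guideline.p_high(truth_high), signature.p_high(truth_high)
        lo = max(lo, max(0.0, pg + ps - 1.0) - pg * ps)
        hi = min(hi, min(pg, ps) - pg * ps)

    def discordance(adj: float) -> float:
        j = joint_classification(profile, guideline, signature, adj)
        return j.discordant_chgl + j.discordant_clgh

    # total discordance is linear and decreasing in the adjustment
    d_lo, d_hi = discordance(lo), discordance(hi)
    if not d_hi <= target_total_discordance <= d_lo:
        return float(np.clip(lo if target_total_discordance > d_lo else hi, lo, hi))
    return float(optimize.brentq(lambda a: discordance(a) - target_total_discordance, lo, hi))


@dataclass(frozen=True)
class TreatmentPolicy:
    """Total mapping from a risk call to an adjuvant treatment."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        for call in ("low", "high"):
            if call not in self.mapping:
                raise ModelValidationError(f"policy lacks a treatment for call '{call}'")

    def treatment(self, call: str) -> str:
        return self.mapping[call]


#: high-risk call -> add chemotherapy; low-risk call -> endocrine only
DEFAULT_POLICY = TreatmentPolicy({"low": ENDOCRINE, "high": ENDOCRINE_CHEMO})


def group_outcome(params, settings: EconomicSettings, truth: str, treatment: str) -> tuple[float, float]:
    """Discounted per-patient (QALYs, costs) for one (truth, treatment) group.

    ``params`` must supply ``matrix(truth, treatment)`` and
    ``outcome_spec(truth, treatment)`` (see
    :class:`diffcea.synthetic_params.ParameterSet`).
    """
    try:
        matrix = params.matrix(truth, treatment)
        spec = params.outcome_spec(truth, treatment)
    except KeyError as exc:
        raise ModelValidationError(
            f"parameter set has no group truth={truth!r}, treatment={treatment!r}"
        ) from exc
    trace = run_cohort(matrix, INITIAL_DISEASE_FREE, settings)
    return accumulate(trace, spec, settings, received_chemo=(treatment == ENDOCRINE_CHEMO))


#: risk group -> (truth, call) used to pick matrices and treatment
GROUP_DEFINITIONS = {
    "true_low": ("low", "low"),
    "true_high": ("high", "high"),
    "false_low": ("high", "low"),
    "false_high": ("low", "high"),
}


def strategy_expected_outcomes(
    shares: RiskGroupShares,
    params,
    settings: EconomicSettings,
    test: PrognosticTest | None = None,
    policy: TreatmentPolicy = DEFAULT_POLICY,
) -> tuple[float, float]:
    """Share-weighted per-patient (QALYs, costs) of a fully followed strategy.

    When ``test`` is given, its unit cost is added for every patient
    (the comparator guideline carries no test price).
    """
    qalys = 0.0
    costs = 0.0
    for group, share in shares.as_dict().items():
        if share == 0.0:
            continue
        truth, call = GROUP_DEFINITIONS[group]
        q, c = group_outcome(params, settings, truth, policy.treatment(call))
        qalys += share * q
        costs += share * c
    if test is not None:
        costs += test.unit_cost
    return qalys, costs
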