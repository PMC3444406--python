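"""Diffusion drivers: technical failure, non-compliance and uptake.

The genomic test spreads through clinical practice gradually; three
scenario parameters capture that diffusion at each time point:

* **technical failure** — the assay yields no result (insufficient
  tissue quantity/quality).  A fraction of the test price (10% by
  default) is still incurred and treatment reverts to the clinical
  guideline.
* **non-compliance** — the result is available but, in discordant cases
  (clinical high / genomic low, or clinical low / genomic high), the
  clinician follows the guideline instead.  The test price is incurred
  either way.  Rates are per discordant cell, with the reported "total"
  being their sum (the additive convention of the source trajectories).
* **uptake** — the fraction of the eligible population actually tested.

Canonical composition order (regression-tested; the pipeline is not
commutative): classification -> non-compliance within the delivered
results -> failure mixing (failed tests never reach a compliance
decision: no result exists) -> uptake scaling to the population level.

Two uptake readings of the cost side are provided: the default pure
population *mixture* (both dE and dC exactly linear through the origin
in uptake) and a *program* mode in which the expected testing cost is
borne for the whole eligible population while only the clinical
consequences scale with uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .economics import CEResult, WTPThreshold
from .health_model import EconomicSettings, ModelValidationError
from .test_strategy import (
    DEFAULT_POLICY,
    JointClassification,
    PrognosticTest,
    TreatmentPolicy,
    classify,
    group_outcome,
    joint_classification,
    strategy_expected_outcomes,
)

__all__ = [
    "DiffusionDrivers",
    "ScenarioTrajectory",
    "default_trajectory",
    "apply_failure",
    "apply_noncompliance",
    "apply_uptake",
    "evaluate_scenario",
    "scenario_table",
    "UPTAKE_MIXTURE",
    "UPTAKE_PROGRAM",
]

UPTAKE_MIXTURE = "mixture"
UPTAKE_PROGRAM = "program"

#: observed split of non-compliance between the two discordant cell types
#: (clinical-high/genomic-low : clinical-low/genomic-high) in the 2005
#: feasibility-study anchor: 0.15 and 0.20, total 0.35.
NC_SPLIT_CHGL = 0.15
NC_SPLIT_CLGH = 0.20


@dataclass(frozen=True)
class DiffusionDrivers:
    """The three diffusion parameters at one labelled time point."""

    year: str
    failure: float
    noncompliance_chgl: float
    noncompliance_clgh: float
    uptake: float
    failed_test_cost_fraction: float = 0.10
    source: str = "custom"

    def __post_init__(self) -> None:
        for attr in (
            "failure",
            "noncompliance_chgl",
            "noncompliance_clgh",
            "uptake",
            "failed_test_cost_fraction",
        ):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ModelValidationError(f"{attr}={v} must lie in [0, 1]")

    @property
    def total_noncompliance(self) -> float:
        """Reported total: sum of the two discordant-cell rates."""
        return self.noncompliance_chgl + self.noncompliance_clgh

    @classmethod
    def from_total_noncompliance(
        cls,
        year: str,
        failure: float,
        total_noncompliance: float,
        uptake: float,
        **kwargs,
    ) -> "DiffusionDrivers":
        """Split a total non-compliance rate over the two discordant cells
        proportionally to the 0.15/0.20 anchor split."""
        total0 = NC_SPLIT_CHGL + NC_SPLIT_CLGH
        s = total_noncompliance / total0
        return cls(
            year=year,
            failure=failure,
            noncompliance_chgl=NC_SPLIT_CHGL * s,
            noncompliance_clgh=NC_SPLIT_CLGH * s,
            uptake=uptake,
            **kwargs,
        )


@dataclass(frozen=True)
class ScenarioTrajectory:
    """Ordered drivers per labelled year."""

    points: tuple[DiffusionDrivers, ...]

    def __post_init__(self) -> None:
        if not self.points:
            raise ModelValidationError("trajectory must contain at least one year")
        years = [p.year for p in self.points]
        if sorted(years) != years or len(set(years)) != len(years):
            raise ModelValidationError("trajectory years must be strictly increasing")

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def baseline(self) -> DiffusionDrivers:
        return self.points[0]


def default_trajectory(failure_2020: float = 0.08) -> ScenarioTrajectory:
    """The packaged 2005/2010/2020 trajectory.

    2005 values are observational (feasibility-study anchor); 2010 and
    2020 come from the expert scenario workshop: failure 0.27/0.20/0.08,
    total non-compliance 0.35/0.26/0.08, uptake 0.03/0.50/0.92.  An
    alternative 2020 failure preset of 0.14 circulates for the same
    trajectory; pass ``failure_2020=0.14`` to use it.
    """
    mk = DiffusionDrivers.from_total_noncompliance
    return ScenarioTrajectory(
        points=(
            mk("2005", 0.27, 0.35, 0.03, source="RASTER"),
            mk("2010", 0.20, 0.26, 0.50, source="scenario-workshop"),
            mk("2020", failure_2020, 0.08, 0.92, source="scenario-workshop"),
        )
    )


def apply_failure(
    signature_outcomes: tuple[float, float],
    guideline_outcomes: tuple[float, float],
    drivers: DiffusionDrivers,
    test: PrognosticTest,
) -> tuple[float, float]:
    """Mix the delivered-result pathway with the failed-test pathway.

    A failed test produces guideline effects exactly, plus the partial
    test cost ``failed_test_cost_fraction x unit_cost``.
    """
    f = drivers.failure
    frac = drivers.failed_test_cost_fraction
    e = (1 - f) * signature_outcomes[0] + f * guideline_outcomes[0]
    c = (1 - f) * signature_outcomes[1] + f * (guideline_outcomes[1] + frac * test.unit_cost)
    return e, c


def apply_noncompliance(
    joint: JointClassification,
    drivers: DiffusionDrivers,
    params,
    settings: EconomicSettings,
    policy: TreatmentPolicy = DEFAULT_POLICY,
) -> tuple[float, float]:
    """Expected (QALYs, costs) per successfully tested patient.

    Enumerates the eight (guideline call, genomic call, truth) cells.
    Concordant cells follow the (identical) advice; in each discordant
    cell the stated non-compliance fraction is treated according to the
    guideline call instead of the genomic call.  The signature's unit
    cost is charged for every tested patient regardless of compliance.
    """
    if not isinstance(joint, JointClassification):
        raise ModelValidationError(
            "non-compliance requires a joint (guideline x signature) classification"
        )
    calls = ("low", "high")
    qalys = 0.0
    costs = 0.0
    for g in (0, 1):
        for s in (0, 1):
            if g == 1 and s == 0:
                nc = drivers.noncompliance_chgl
            elif g == 0 and s == 1:
                nc = drivers.noncompliance_clgh
            else:
                nc = 0.0
            for t in (0, 1):
                w = float(joint.cells[g, s, t])
                if w == 0.0:
                    continue
                truth = "high" if t else "low"
                q_s, c_s = group_outcome(params, settings, truth, policy.treatment(calls[s]))
                if nc > 0.0:
                    q_g, c_g = group_outcome(params, settings, truth, policy.treatment(calls[g]))
                    q = (1 - nc) * q_s + nc * q_g
                    c = (1 - nc) * c_s + nc * c_g
                else:
                    q, c = q_s, c_s
                qalys += w * q
                costs += w * c
    costs += params.signature.unit_cost
    return qalys, costs


def apply_uptake(
    tested_outcomes: tuple[float, float],
    guideline_outcomes: tuple[float, float],
    drivers: DiffusionDrivers,
    mode: str = UPTAKE_MIXTURE,
    test_cost_component: float | None = None,
) -> tuple[float, float]:
    """Population-level (dE, dC) given the tested fraction ``u``.

    ``mixture`` (default): the untested remainder follows the guideline,
    so dE(u) = u (E_t - E_g) and dC(u) = u (C_t - C_g) — both exactly
    linear through the origin.  ``program``: the expected testing cost
    (``test_cost_component``, per tested patient) is borne for the whole
    eligible population while the clinical consequences scale with u.
    """
    u = drivers.uptake
    if not 0.0 <= u <= 1.0:
        raise ModelValidationError("uptake must lie in [0, 1]")
    de = u * (tested_outcomes[0] - guideline_outcomes[0])
    if mode == UPTAKE_MIXTURE:
        dc = u * (tested_outcomes[1] - guideline_outcomes[1])
    elif mode == UPTAKE_PROGRAM:
        if test_cost_component is None:
            raise ModelValidationError("program mode requires test_cost_component")
        dc = test_cost_component + u * (
            tested_outcomes[1] - guideline_outcomes[1] - test_cost_component
        )
    else:
        raise ModelValidationError(f"unknown uptake mode {mode!r}")
    return de, dc


def per_tested_increments(
    params,
    drivers: DiffusionDrivers,
    settings: EconomicSettings,
    policy: TreatmentPolicy = DEFAULT_POLICY,
) -> dict:
    """Per-tested-patient pipeline up to (but excluding) uptake scaling.

    Returns the guideline outcomes, the failure- and compliance-adjusted
    tested outcomes, their increments and the expected test-cost
    component per tested patient.
    """
    guideline_shares = classify(params.profile, params.guideline)
    e_g, c_g = strategy_expected_outcomes(
        guideline_shares, params, settings, test=None, policy=policy
    )
    joint = joint_classification(
        params.profile, params.guideline, params.signature, params.concordance_adjustment
    )
    delivered = apply_noncompliance(joint, drivers, params, settings, policy=policy)
    tested = apply_failure(delivered, (e_g, c_g), drivers, params.signature)
    test_cost_component = (
        (1 - drivers.failure) * params.signature.unit_cost
        + drivers.failure * drivers.failed_test_cost_fraction * params.signature.unit_cost
    )
    return {
        "guideline": (e_g, c_g),
        "tested": tested,
        "delta_effects": tested[0] - e_g,
        "delta_costs": tested[1] - c_g,
        "test_cost_component": test_cost_component,
    }


def evaluate_scenario(
    params,
    drivers: DiffusionDrivers,
    settings: EconomicSettings = EconomicSettings(),
    threshold: WTPThreshold = WTPThreshold(),
    uptake_mode: str = UPTAKE_MIXTURE,
    policy: TreatmentPolicy = DEFAULT_POLICY,
) -> CEResult:
    """Full deterministic pipeline for one driver setting.

    classification -> non-compliance -> failure -> uptake -> incremental
    cost-effectiveness versus the guideline strategy.
    """
    detail = per_tested_increments(params, drivers, settings, policy=policy)
    de, dc = apply_uptake(
        detail["tested"],
        detail["guideline"],
        drivers,
        mode=uptake_mode,
        test_cost_component=detail["test_cost_component"],
    )
    return CEResult.from_increments(de, dc, threshold)


def scenario_table(
    params,
    trajectory: ScenarioTrajectory,
    settings: EconomicSettings = EconomicSettings(),
    threshold: WTPThreshold = WTPThreshold(),
    uptake_mode: str = UPTAKE_MIXTURE,
) -> pd.DataFrame:
    """One-at-a-time and combined scenario results, one row per run.

    For a multi-year trajectory: a start row at the baseline year, then
    for each later year one row per driver varied alone (the other two
    held at baseline), then one combined row per year.  Columns: year,
    scenario, failure, noncompliance, uptake, delta_effects, delta_costs,
    icer, inmb.
    """
    if len(trajectory) == 0:
        raise ModelValidationError("empty trajectory")
    base = trajectory.baseline
    rows: list[tuple[str, DiffusionDrivers]] = []
    if len(trajectory) > 1:
        rows.append(("start", base))
        later = list(trajectory)[1:]
    else:
        later = list(trajectory)
    for point in later:
        rows.append(
            ("failure", replace(base, year=point.year, failure=point.failure))
        )
        rows.append(
            (
                "noncompliance",
                replace(
                    base,
                    year=point.year,
                    noncompliance_chgl=point.noncompliance_chgl,
                    noncompliance_clgh=point.noncompliance_clgh,
                ),
            )
        )
        rows.append(("uptake", replace(base, year=point.year, uptake=point.uptake)))
    for point in trajectory:
        rows.append(("combined", point))

    records = []
    for scenario, drv in rows:
        res = evaluate_scenario(
            params, drv, settings, threshold=threshold, uptake_mode=uptake_mode
        )
        records.append(
            {
                "year": drv.year,
                "scenario": scenario,
                "failure": drv.failure,
                "noncompliance": drv.total_noncompliance,
                "uptake": drv.uptake,
                "delta_effects": res.delta_effects,
                "delta_costs": res.delta_costs,
                "icer": res.icer.display(),
                "inmb": res.inmb,
            }
        )
    return pd.DataFrame.from_records(records)
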