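"""Synthetic parameter sets and calibration to published incremental outcomes.

The clinical and economic inputs behind the decision model (group-wise
transition probabilities, utilities, costs, test accuracy, test price)
are not published alongside the scenario analysis; they live in a prior
publication.  This module therefore generates complete, internally
consistent parameter sets with the *structure* the analysis assumes —
four health states, treatment-dependent metastasis risk, test
misclassification, per-state costs and utilities — and calibrates the
free parameters so the pipeline reproduces published scenario-level
incremental outcomes.  All generated values are synthetic and are
labelled as such in every serialized artefact.

A :class:`ParameterSet` is defined by a flat layer of scalar clinical
inputs from which the per-(truth, treatment) transition matrices and
outcome specifications are derived:

* disease-free patients face annual risks of relapse, distant
  metastasis (truth- and treatment-dependent) and background death;
* chemotherapy multiplies the metastasis risk by ``1 - chemo_rrr``
  (relative risk reduction);
* relapse patients may progress to distant metastasis (configurable)
  or die of background causes; metastatic patients face an elevated
  annual death risk;
* death is absorbing.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

from . import diffusion as _diffusion
from .health_model import (
    EconomicSettings,
    ModelValidationError,
    OutcomeSpec,
    TransitionMatrix,
)
from .test_strategy import ENDOCRINE, ENDOCRINE_CHEMO, PopulationProfile, PrognosticTest

__all__ = [
    "SCHEMA_VERSION",
    "ClinicalInputs",
    "ParameterSet",
    "generate_default",
    "generate_random",
    "get_path",
    "with_paths",
    "list_paths",
    "path_kind",
    "CalibrationTarget",
    "SearchSpec",
    "CalibrationReport",
    "CalibrationError",
    "calibrate",
]

SCHEMA_VERSION = 1
SYNTHETIC_LABEL = "SYNTHETIC"

TRUTHS = ("low", "high")
TREATMENTS = (ENDOCRINE, ENDOCRINE_CHEMO)


@dataclass(frozen=True)
class ClinicalInputs:
    """Scalar clinical/economic inputs from which group matrices derive."""

    # annual transition probabilities
    p_relapse: float = 0.015
    p_dm_low: float = 0.004
    p_dm_high: float = 0.055
    chemo_rrr: float = 0.45
    p_relapse_to_dm: float = 0.06
    p_dm_death: float = 0.30
    p_death_background: float = 0.006
    allow_relapse_to_metastasis: bool = True
    # utilities (QALY weights per year)
    utility_dfs: float = 0.90
    utility_relapse: float = 0.80
    utility_dm: float = 0.60
    # annual costs per state (EUR, 2005)
    cost_dfs: float = 250.0
    cost_relapse: float = 1_000.0
    cost_dm: float = 9_000.0
    # one-off costs and the chemotherapy quality-of-life decrement
    relapse_entry_cost: float = 12_000.0
    chemo_cost: float = 6_000.0
    endocrine_cost: float = 1_500.0
    chemo_disutility: float = 0.12


@dataclass(frozen=True)
class ParameterSet:
    """Everything the pipeline needs, labelled SYNTHETIC.

    Exposes one :class:`TransitionMatrix` and one :class:`OutcomeSpec`
    per (truth, treatment) group, derived from ``clinical``.
    """

    clinical: ClinicalInputs = ClinicalInputs()
    profile: PopulationProfile = PopulationProfile(
        prevalence_true_high=0.25, annual_incidence=2_400.0
    )
    guideline: PrognosticTest = PrognosticTest(
        "clinical-guideline", sensitivity=0.72, specificity=0.40, unit_cost=0.0
    )
    signature: PrognosticTest = PrognosticTest(
        "70-gene-signature", sensitivity=0.95, specificity=0.75, unit_cost=2_675.0
    )
    concordance_adjustment: float = 0.0
    label: str = SYNTHETIC_LABEL

    # -- derived model objects ------------------------------------------------

    def p_dm(self, truth: str, treatment: str) -> float:
        if truth not in TRUTHS:
            raise KeyError(truth)
        if treatment not in TREATMENTS:
            raise KeyError(treatment)
        p = self.clinical.p_dm_low if truth == "low" else self.clinical.p_dm_high
        if treatment == ENDOCRINE_CHEMO:
            p *= 1.0 - self.clinical.chemo_rrr
        return p

    def matrix(self, truth: str, treatment: str) -> TransitionMatrix:
        c = self.clinical
        p_dm = self.p_dm(truth, treatment)
        p_bg = c.p_death_background
        p_rel_dm = c.p_relapse_to_dm if c.allow_relapse_to_metastasis else 0.0
        return TransitionMatrix(
            np.array(
                [
                    [1 - c.p_relapse - p_dm - p_bg, c.p_relapse, p_dm, p_bg],
                    [0.0, 1 - p_rel_dm - p_bg, p_rel_dm, p_bg],
                    [0.0, 0.0, 1 - c.p_dm_death, c.p_dm_death],
                    [0.0, 0.0, 0.0, 1.0],
                ]
            )
        )

    def outcome_spec(self, truth: str, treatment: str) -> OutcomeSpec:
        if truth not in TRUTHS or treatment not in TREATMENTS:
            raise KeyError((truth, treatment))
        c = self.clinical
        return OutcomeSpec(
            utility_per_state=np.array(
                [c.utility_dfs, c.utility_relapse, c.utility_dm, 0.0]
            ),
            annual_cost_per_state=np.array([c.cost_dfs, c.cost_relapse, c.cost_dm, 0.0]),
            transition_cost=np.array([0.0, c.relapse_entry_cost, 0.0, 0.0]),
            chemo_cost=c.chemo_cost,
            endocrine_cost=c.endocrine_cost,
            chemo_disutility=c.chemo_disutility,
        )

    def validate(self) -> None:
        """Check all structural invariants; raises on violation."""
        c = self.clinical
        for truth in TRUTHS:
            for treatment in TREATMENTS:
                self.matrix(truth, treatment)  # row feasibility
                self.outcome_spec(truth, treatment)
        if not 0.0 < c.chemo_rrr < 1.0:
            raise ModelValidationError(
                "chemotherapy must strictly reduce metastasis risk (0 < chemo_rrr < 1)"
            )
        if self.p_dm("high", ENDOCRINE) <= self.p_dm("low", ENDOCRINE):
            raise ModelValidationError(
                "truth-high metastasis risk must exceed truth-low under like treatment"
            )

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "label": self.label,
            "clinical": dataclasses.asdict(self.clinical),
            "profile": dataclasses.asdict(self.profile),
            "guideline": dataclasses.asdict(self.guideline),
            "signature": dataclasses.asdict(self.signature),
            "concordance_adjustment": self.concordance_adjustment,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        version = d.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ModelValidationError(
                f"unsupported parameter-set schema version {version!r}"
            )
        return cls(
            clinical=ClinicalInputs(**d["clinical"]),
            profile=PopulationProfile(**d["profile"]),
            guideline=PrognosticTest(**d["guideline"]),
            signature=PrognosticTest(**d["signature"]),
            concordance_adjustment=float(d.get("concordance_adjustment", 0.0)),
            label=d.get("label", SYNTHETIC_LABEL),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ParameterSet":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(io.StringIO(str(source)))
        return cls.from_dict(data)


def generate_default() -> ParameterSet:
    """The documented, version-pinned default synthetic set."""
    ps = ParameterSet()
    ps.validate()
    return ps


# -- parameter paths -----------------------------------------------------------

_PROBABILITY_FIELDS = {
    "p_relapse",
    "p_dm_low",
    "p_dm_high",
    "chemo_rrr",
    "p_relapse_to_dm",
    "p_dm_death",
    "p_death_background",
    "utility_dfs",
    "utility_relapse",
    "utility_dm",
    "chemo_disutility",
    "prevalence_true_high",
    "sensitivity",
    "specificity",
}
_NONNEGATIVE_FIELDS = {
    "cost_dfs",
    "cost_relapse",
    "cost_dm",
    "relapse_entry_cost",
    "chemo_cost",
    "endocrine_cost",
    "unit_cost",
    "annual_incidence",
}


def list_paths(ps: ParameterSet) -> list[str]:
    """All dotted scalar paths addressable in a parameter set."""
    paths = []
    for f in fields(ClinicalInputs):
        if f.type in ("float", float):
            paths.append(f"clinical.{f.name}")
    paths += ["profile.prevalence_true_high", "profile.annual_incidence"]
    for test in ("guideline", "signature"):
        paths += [f"{test}.sensitivity", f"{test}.specificity", f"{test}.unit_cost"]
    paths.append("concordance_adjustment")
    return paths


def path_kind(path: str) -> str:
    """Feasible-domain kind of a path: probability, nonnegative or real."""
    leaf = path.rsplit(".", 1)[-1]
    if leaf in _PROBABILITY_FIELDS:
        return "probability"
    if leaf in _NONNEGATIVE_FIELDS:
        return "nonnegative"
    return "real"


def get_path(ps: ParameterSet, path: str) -> float:
    obj = ps
    try:
        for part in path.split("."):
            obj = getattr(obj, part)
    except AttributeError as exc:
        raise ModelValidationError(f"unknown parameter path {path!r}") from exc
    return float(obj)


def with_paths(ps: ParameterSet, updates: dict[str, float]) -> ParameterSet:
    """Return a copy of ``ps`` with the dotted paths replaced."""
    grouped: dict[str, dict[str, float]] = {}
    top: dict[str, float] = {}
    for path, value in updates.items():
        get_path(ps, path)  # validates existence
        if "." in path:
            head, leaf = path.split(".", 1)
            if "." in leaf:
                raise ModelValidationError(f"path {path!r} nests too deep")
            grouped.setdefault(head, {})[leaf] = float(value)
        else:
            top[path] = float(value)
    out = ps
    for head, kv in grouped.items():
        out = replace(out, **{head: replace(getattr(out, head), **kv)})
    if top:
        out = replace(out, **top)
    return out


def generate_random(
    seed: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    base: ParameterSet | None = None,
) -> ParameterSet:
    """Seed-deterministic random parameter set, uniform over ``ranges``.

    ``ranges`` maps dotted paths to (low, high) bounds; degenerate
    ranges (low == high) pin the value.  Defaults to moderate windows
    around the default set, constructed to keep every invariant
    satisfiable.
    """
    base = base if base is not None else generate_default()
    if ranges is None:
        ranges = {
            "clinical.p_dm_high": (0.03, 0.09),
            "clinical.p_dm_low": (0.001, 0.008),
            "clinical.chemo_rrr": (0.2, 0.7),
            "clinical.chemo_cost": (2_000.0, 12_000.0),
            "clinical.chemo_disutility": (0.03, 0.2),
            "profile.prevalence_true_high": (0.1, 0.4),
            "signature.unit_cost": (1_000.0, 5_000.0),
            "signature.sensitivity": (0.85, 0.98),
            "signature.specificity": (0.55, 0.85),
            "guideline.sensitivity": (0.6, 0.85),
            "guideline.specificity": (0.25, 0.5),
        }
    rng = np.random.default_rng(seed)
    updates = {}
    for path, (lo, hi) in ranges.items():
        if hi < lo:
            raise ModelValidationError(f"infeasible range for {path!r}: ({lo}, {hi})")
        kind = path_kind(path)
        if kind == "probability" and not (0 <= lo and hi <= 1):
            raise ModelValidationError(f"range for probability path {path!r} leaves [0, 1]")
        if kind == "nonnegative" and lo < 0:
            raise ModelValidationError(f"range for cost path {path!r} is negative")
        updates[path] = lo if hi == lo else rng.uniform(lo, hi)
    ps = with_paths(base, updates)
    ps.validate()
    return ps


# -- calibration ---------------------------------------------------------------

#: target quantities computable from the pipeline at stated drivers
_QUANTITIES = (
    "delta_effects",
    "delta_costs",
    "per_tested_delta_effects",
    "per_tested_delta_costs",
)


@dataclass(frozen=True)
class CalibrationTarget:
    """A published incremental outcome the calibrated set must reproduce."""

    quantity: str
    value: float
    drivers: _diffusion.DiffusionDrivers
    rel_tol: float = 0.02
    name: str = ""

    def __post_init__(self) -> None:
        if self.quantity not in _QUANTITIES:
            raise ModelValidationError(
                f"unknown target quantity {self.quantity!r}; one of {_QUANTITIES}"
            )
        if self.rel_tol <= 0:
            raise ModelValidationError("tolerance must be > 0")


DEFAULT_FREE_PARAMETERS: dict[str, tuple[float, float]] = {
    "signature.unit_cost": (500.0, 6_000.0),
    "clinical.chemo_rrr": (0.05, 0.80),
    "profile.prevalence_true_high": (0.05, 0.45),
    "clinical.chemo_cost": (500.0, 20_000.0),
}


@dataclass(frozen=True)
class SearchSpec:
    """Free parameters (with bounds) and optimizer settings for calibration."""

    free_parameters: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FREE_PARAMETERS)
    )
    max_evaluations: int = 4_000
    n_restarts: int = 4
    seed: int = 0


@dataclass
class CalibrationReport:
    converged: bool
    n_evaluations: int
    free_values: dict[str, float]
    residuals: dict[str, float]  # relative residual per target
    sensitivity: "object" = None  # DataFrame: d(target)/d(log param)

    def summary(self) -> str:
        lines = [f"calibration {'converged' if self.converged else 'FAILED'} "
                 f"after {self.n_evaluations} evaluations"]
        for k, v in self.free_values.items():
            lines.append(f"  {k} = {v:.6g}")
        for k, r in self.residuals.items():
            lines.append(f"  residual[{k}] = {r:+.4%}")
        return "\n".join(lines)


class CalibrationError(RuntimeError):
    """Calibration did not reach every target; carries the best report."""

    def __init__(self, report: CalibrationReport):
        self.report = report
        super().__init__("calibration failed\n" + report.summary())


def _target_value(ps: ParameterSet, target: CalibrationTarget, settings, uptake_mode) -> float:
    detail = _diffusion.per_tested_increments(ps, target.drivers, settings)
    if target.quantity == "per_tested_delta_effects":
        return detail["delta_effects"]
    if target.quantity == "per_tested_delta_costs":
        return detail["delta_costs"]
    de, dc = _diffusion.apply_uptake(
        detail["tested"],
        detail["guideline"],
        target.drivers,
        mode=uptake_mode,
        test_cost_component=detail["test_cost_component"],
    )
    return de if target.quantity == "delta_effects" else dc


def _target_key(t: CalibrationTarget) -> str:
    return t.name or f"{t.quantity}@{t.drivers.year}"


def calibrate(
    base: ParameterSet,
    targets: list[CalibrationTarget],
    search_spec: SearchSpec | None = None,
    settings: EconomicSettings = EconomicSettings(),
    uptake_mode: str = _diffusion.UPTAKE_MIXTURE,
) -> tuple[ParameterSet, CalibrationReport]:
    """Tune the free parameters until every target is met within tolerance.

    Derivative-free search (bounded Nelder-Mead on a unit cube with
    seeded multi-start) minimising the sum of squared relative
    residuals.  Deterministic for a fixed ``search_spec.seed``.  Raises
    :class:`CalibrationError` with the best-achieved residuals if any
    target stays outside its tolerance; never silently succeeds.
    """
    from scipy import optimize

    spec = search_spec if search_spec is not None else SearchSpec()
    paths = list(spec.free_parameters)
    bounds = [spec.free_parameters[p] for p in paths]
    for path, (lo, hi) in zip(paths, bounds):
        if hi <= lo:
            raise ModelValidationError(f"empty bounds for free parameter {path!r}")

    n_evals = 0

    def build(x: np.ndarray) -> ParameterSet:
        updates = {
            p: lo + float(np.clip(xi, 0, 1)) * (hi - lo)
            for p, (lo, hi), xi in zip(paths, bounds, x)
        }
        return with_paths(base, updates)

    def residuals(ps: ParameterSet) -> dict[str, float]:
        out = {}
        for t in targets:
            got = _target_value(ps, t, settings, uptake_mode)
            scale = abs(t.value) if t.value != 0 else 1.0
            out[_target_key(t)] = (got - t.value) / scale
        return out

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        try:
            ps = build(x)
            ps.validate()
        except ModelValidationError:
            return 1e6
        r = residuals(ps)
        return float(sum(v * v for v in r.values()))

    def within_tol(r: dict[str, float]) -> bool:
        return all(abs(r[_target_key(t)]) <= t.rel_tol for t in targets)

    def to_unit(ps: ParameterSet) -> np.ndarray:
        return np.array(
            [
                (get_path(ps, p) - lo) / (hi - lo)
                for p, (lo, hi) in zip(paths, bounds)
            ]
        )

    # fixed point: base already meets every target
    base_res = residuals(base)
    if within_tol(base_res):
        report = CalibrationReport(
            converged=True,
            n_evaluations=0,
            free_values={p: get_path(base, p) for p in paths},
            residuals=base_res,
        )
        return base, report

    rng = np.random.default_rng(spec.seed)
    starts = [np.clip(to_unit(base), 0.0, 1.0)]
    starts += [rng.random(len(paths)) for _ in range(spec.n_restarts)]
    best_x, best_f = None, np.inf
    per_start = max(spec.max_evaluations // len(starts), 50)
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=[(0.0, 1.0)] * len(paths),
            options={"maxfev": per_start, "xatol": 1e-6, "fatol": 1e-12},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
        if within_tol(residuals(build(best_x))):
            break

    ps_best = build(best_x)
    res_best = residuals(ps_best)
    report = CalibrationReport(
        converged=within_tol(res_best),
        n_evaluations=n_evals,
        free_values={p: get_path(ps_best, p) for p in paths},
        residuals=res_best,
        sensitivity=_sensitivity_table(ps_best, targets, paths, settings, uptake_mode),
    )
    if not report.converged:
        raise CalibrationError(report)
    ps_best.validate()
    return ps_best, report


def _sensitivity_table(ps, targets, paths, settings, uptake_mode, bump: float = 0.01):
    """Relative change of each target per +1% relative change of each free
    parameter, at the calibrated point."""
    import pandas as pd

    rows = {}
    base_vals = {
        _target_key(t): _target_value(ps, t, settings, uptake_mode) for t in targets
    }
    for p in paths:
        v = get_path(ps, p)
        step = abs(v) * bump if v != 0 else bump
        try:
            ps_up = with_paths(ps, {p: v + step})
            ps_up.validate()
        except ModelValidationError:
            rows[p] = {k: np.nan for k in base_vals}
            continue
        rows[p] = {
            k: (
                (_target_value(ps_up, t, settings, uptake_mode) - base_vals[k])
                / (abs(base_vals[k]) if base_vals[k] != 0 else 1.0)
                / bump
            )
            for k, t in zip(base_vals, targets)
        }
    return pd.DataFrame(rows).T
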