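"""Probabilistic sensitivity analysis and cost-effectiveness acceptability curves.

Parameter uncertainty is propagated by Monte Carlo simulation: each
iteration draws a full parameter set from per-parameter distributions,
runs the deterministic scenario pipeline and records the incremental
(QALY, cost) pair versus the guideline comparator.  Distribution
families follow standard cost-effectiveness practice: beta for
probabilities and utilities (moment-matched to a mean and standard
error), gamma for costs, with normal/log-normal and degenerate ``fixed``
available.  Driver values are held fixed by default, and the same
uncertainty specification is reused at every time point (uncertainty is
treated as constant over the diffusion horizon).

Decision uncertainty is summarised by cost-effectiveness acceptability
curves (probability that the tested strategy is cost-effective as a
function of the willingness-to-pay threshold) and by the acceptability
frontier, which tracks the curve of the expected-net-benefit-maximising
strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .diffusion import UPTAKE_MIXTURE, DiffusionDrivers, evaluate_scenario
from .economics import WTPThreshold
from .health_model import EconomicSettings, ModelValidationError
from .synthetic_params import ParameterSet, get_path, path_kind, with_paths

__all__ = [
    "ParameterDistribution",
    "PsaConfig",
    "PsaResult",
    "Ceac",
    "default_distributions",
    "sample_parameters",
    "run_psa",
    "ceac",
    "ceac_frontier",
]

_FAMILIES = ("beta", "gamma", "normal", "lognormal", "fixed")


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling distribution for one dotted parameter path.

    ``params`` is family-specific: ``mean``/``se`` for beta, gamma,
    normal and lognormal (moment-matched), optional ``value`` for fixed.
    """

    target: str
    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ModelValidationError(
                f"unknown family {self.family!r}; one of {_FAMILIES}"
            )

    def validate_against(self, base: ParameterSet) -> None:
        base_value = get_path(base, self.target)  # raises for unknown paths
        kind = path_kind(self.target)
        if self.family == "beta" and kind != "probability":
            raise ModelValidationError(
                f"beta is only feasible for [0,1]-bounded targets, not {self.target!r}"
            )
        if self.family in ("gamma", "lognormal") and kind == "real":
            raise ModelValidationError(
                f"{self.family} is only feasible for non-negative targets, "
                f"not {self.target!r}"
            )
        del base_value

    def _mean_se(self, base_value: float) -> tuple[float, float]:
        mean = float(self.params.get("mean", base_value))
        if "se" in self.params:
            se = float(self.params["se"])
        else:
            se = abs(mean) * float(self.params.get("rel_se", 0.10))
        return mean, se

    def draw(self, rng: np.random.Generator, base_value: float) -> float:
        """Sample one value; ``base_value`` supplies the mean when the
        distribution specification does not state one."""
        if self.family == "fixed":
            return float(self.params.get("value", base_value))
        mean, se = self._mean_se(base_value)
        if se == 0:
            return mean
        if self.family == "beta":
            if not 0 < mean < 1:
                return mean
            nu = mean * (1 - mean) / se**2 - 1.0
            if nu <= 0:
                raise ModelValidationError(
                    f"beta SE {se} too large for mean {mean} on {self.target!r}"
                )
            return float(rng.beta(mean * nu, (1 - mean) * nu))
        if self.family == "gamma":
            shape = (mean / se) ** 2
            scale = se**2 / mean if mean > 0 else 0.0
            return float(rng.gamma(shape, scale)) if mean > 0 else 0.0
        if self.family == "normal":
            return float(rng.normal(mean, se))
        # lognormal, moment-matched on the natural scale
        sigma2 = np.log1p((se / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return float(rng.lognormal(mu, np.sqrt(sigma2)))


def default_distributions(
    base: ParameterSet, rel_se: float = 0.10
) -> list[ParameterDistribution]:
    """Beta on probabilities/utilities, gamma on costs, at a common
    relative standard error (10% by default); test accuracies included,
    incidence and the concordance adjustment held fixed."""
    dists: list[ParameterDistribution] = []
    skip = {"profile.annual_incidence", "concordance_adjustment"}
    from .synthetic_params import list_paths

    for path in list_paths(base):
        if path in skip:
            continue
        value = get_path(base, path)
        kind = path_kind(path)
        if value == 0.0:
            dists.append(ParameterDistribution(path, "fixed"))
        elif kind == "probability":
            dists.append(
                ParameterDistribution(path, "beta", {"rel_se": rel_se})
            )
        else:
            dists.append(
                ParameterDistribution(path, "gamma", {"rel_se": rel_se})
            )
    return dists


def sample_parameters(
    distributions: Sequence[ParameterDistribution],
    base: ParameterSet,
    seed: int | np.random.Generator,
) -> Iterator[ParameterSet]:
    """Endless stream of valid parameter-set draws (seed-deterministic).

    Draws violating structural invariants (e.g. a sampled transition row
    exceeding probability 1) are rejected and redrawn.
    """
    for d in distributions:
        d.validate_against(base)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    while True:
        for _attempt in range(100):
            updates = {
                d.target: d.draw(rng, get_path(base, d.target)) for d in distributions
            }
            try:
                ps = with_paths(base, updates)
                ps.validate()
            except ModelValidationError:
                continue
            break
        else:
            raise ModelValidationError(
                "could not draw a valid parameter set in 100 attempts"
            )
        yield ps


@dataclass(frozen=True)
class PsaConfig:
    n_iterations: int = 1_000
    seed: int = 0
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 100_001.0, 1_000.0)
    )

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ModelValidationError("n_iterations must be >= 1")
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ModelValidationError("lambda grid must be strictly ascending")
        object.__setattr__(self, "lambda_grid", grid)


@dataclass(frozen=True)
class PsaResult:
    """Paired incremental draws (dE, dC) plus run metadata."""

    delta_effects: np.ndarray
    delta_costs: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        de = np.asarray(self.delta_effects, dtype=float)
        dc = np.asarray(self.delta_costs, dtype=float)
        if de.shape != dc.shape or de.ndim != 1:
            raise ModelValidationError("draws must be paired 1-d arrays")
        object.__setattr__(self, "delta_effects", de)
        object.__setattr__(self, "delta_costs", dc)

    @property
    def n(self) -> int:
        return self.delta_effects.size

    def inmb(self, lam: float) -> np.ndarray:
        return self.delta_effects * lam - self.delta_costs

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "draw": np.arange(self.n),
                "delta_effects": self.delta_effects,
                "delta_costs": self.delta_costs,
            }
        )


def run_psa(
    base: ParameterSet,
    drivers: DiffusionDrivers,
    distributions: Sequence[ParameterDistribution],
    config: PsaConfig,
    settings: EconomicSettings = EconomicSettings(),
    uptake_mode: str = UPTAKE_MIXTURE,
    threshold: WTPThreshold = WTPThreshold(),
) -> PsaResult:
    """Monte Carlo propagation of parameter uncertainty through the pipeline.

    Distributions targeting ``drivers.*`` paths randomize the diffusion
    drivers themselves (off unless explicitly supplied); everything else
    samples the clinical/economic parameter set.  Deterministic for a
    fixed ``config.seed``.
    """
    driver_dists = [d for d in distributions if d.target.startswith("drivers.")]
    param_dists = [d for d in distributions if not d.target.startswith("drivers.")]
    for d in driver_dists:
        leaf = d.target.split(".", 1)[1]
        if not hasattr(drivers, leaf):
            raise ModelValidationError(f"unknown driver path {d.target!r}")

    rng = np.random.default_rng(config.seed)
    stream = sample_parameters(param_dists, base, rng)
    de = np.empty(config.n_iterations)
    dc = np.empty(config.n_iterations)
    from dataclasses import replace as _replace

    for i in range(config.n_iterations):
        ps = next(stream)
        drv = drivers
        if driver_dists:
            updates = {}
            for d in driver_dists:
                leaf = d.target.split(".", 1)[1]
                value = d.draw(rng, getattr(drivers, leaf))
                updates[leaf] = min(max(value, 0.0), 1.0)
            drv = _replace(drivers, **updates)
        res = evaluate_scenario(
            ps, drv, settings, threshold=threshold, uptake_mode=uptake_mode
        )
        de[i], dc[i] = res.delta_effects, res.delta_costs
    return PsaResult(
        delta_effects=de,
        delta_costs=dc,
        metadata={
            "seed": config.seed,
            "n_iterations": config.n_iterations,
            "year": drivers.year,
            "drivers": {
                "failure": drivers.failure,
                "noncompliance_chgl": drivers.noncompliance_chgl,
                "noncompliance_clgh": drivers.noncompliance_clgh,
                "uptake": drivers.uptake,
            },
            "uptake_mode": uptake_mode,
        },
    )


@dataclass(frozen=True)
class Ceac:
    """Acceptability curve: P(cost-effective) over a lambda grid."""

    lambdas: np.ndarray
    probabilities: np.ndarray
    frontier: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if lam.shape != p.shape:
            raise ModelValidationError("lambda grid and probabilities differ in length")
        if np.any(p < 0) or np.any(p > 1):
            raise ModelValidationError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "lambdas", lam)
        object.__setattr__(self, "probabilities", p)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"lambda": self.lambdas, "probability": self.probabilities})

    def at(self, lam: float) -> float:
        idx = int(np.argmin(np.abs(self.lambdas - lam)))
        return float(self.probabilities[idx])


def ceac(result: PsaResult, grid: np.ndarray | None = None, label: str = "") -> Ceac:
    """Fraction of draws with positive iNMB at each threshold.

    At lambda = 0 this is the fraction of cost-saving draws; as lambda
    grows it tends to the fraction of effect-gaining draws.
    """
    if result.n == 0:
        raise ModelValidationError("empty PSA result")
    lam = np.asarray(
        grid if grid is not None else PsaConfig().lambda_grid, dtype=float
    )
    if lam.size == 0:
        raise ModelValidationError("empty lambda grid")
    nmb = np.outer(lam, result.delta_effects) - result.delta_costs[None, :]
    probs = (nmb > 0).mean(axis=1)
    return Ceac(lambdas=lam, probabilities=probs, label=label)


def ceac_frontier(
    results: Sequence[PsaResult], grid: np.ndarray | None = None
) -> Ceac:
    """Acceptability frontier over the comparator and the given strategies.

    Strategies must share the comparator and draw count (common random
    numbers).  At each threshold the strategy with the highest *expected*
    incremental NMB is selected (the comparator counts as iNMB = 0), and
    the frontier reports the probability that this selected strategy has
    the highest NMB draw-by-draw.
    """
    if not results:
        raise ModelValidationError("no strategies supplied")
    n = results[0].n
    if any(r.n != n for r in results):
        raise ModelValidationError("strategies have mismatched draw counts")
    lam = np.asarray(
        grid if grid is not None else PsaConfig().lambda_grid, dtype=float
    )
    if lam.size == 0:
        raise ModelValidationError("empty lambda grid")

    # iNMB per (strategy, lambda, draw); comparator is the zero row
    inmb = np.stack(
        [np.zeros((lam.size, n))]
        + [np.outer(lam, r.delta_effects) - r.delta_costs[None, :] for r in results]
    )
    expected = inmb.mean(axis=2)  # (strategy, lambda)
    best = expected.argmax(axis=0)  # comparator wins ties (index 0 first)
    is_max = inmb.argmax(axis=0) == best[None, :].T
    probs = is_max.mean(axis=1)
    return Ceac(lambdas=lam, probabilities=probs, frontier=True)
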