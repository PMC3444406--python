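"""Markov cohort engine for a four-state breast-cancer natural-history model.

A closed cohort is propagated through the mutually exclusive states
*disease-free*, *relapse* (loco-regional recurrence, second primary or
contralateral tumour), *distant metastasis* and *dead* in annual cycles.
Death is absorbing.  The engine accumulates discounted quality-adjusted
life years (QALYs) and costs; a per-individual microsimulation is provided
as an independent stochastic cross-check of the deterministic cohort
arithmetic.

Conventions
-----------
* Cycle length is one year; cycle index 0 is the year of diagnosis and
  testing.  State utilities and annual state costs are charged on the
  occupancy at the start of each cycle (no half-cycle correction by
  default; a switch exposes it).
* One-off costs attached to *entering* a state (the single funded relapse
  treatment) are charged in the year of arrival, via the entry bookkeeping
  of :class:`CohortTrace`.  Remaining in the relapse state is continued
  occupancy of the same episode, never a second chargeable relapse.
* Adjuvant treatment costs (endocrine therapy, chemotherapy) and the
  chemotherapy quality-of-life decrement fall in cycle 0, undiscounted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HealthState",
    "STATE_LABELS",
    "N_STATES",
    "ModelValidationError",
    "TransitionMatrix",
    "OutcomeSpec",
    "EconomicSettings",
    "CohortTrace",
    "run_cohort",
    "discount_factor",
    "accumulate",
    "microsim_oracle",
]


class HealthState(enum.IntEnum):
    """The four mutually exclusive health states."""

    DISEASE_FREE = 0
    RELAPSE = 1
    DISTANT_METASTASIS = 2
    DEAD = 3


STATE_LABELS = ("disease_free", "relapse", "distant_metastasis", "dead")
N_STATES = 4

#: cohort that starts entirely disease-free, the model's standard entry point
INITIAL_DISEASE_FREE = np.array([1.0, 0.0, 0.0, 0.0])

_ROW_TOL = 1e-12


class ModelValidationError(ValueError):
    """Raised when model inputs violate their structural invariants."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Annual transition probabilities between the four health states.

    ``probs[i, j]`` is the probability of moving from state ``i`` to state
    ``j`` within one cycle.  Rows must be probability vectors and the
    ``dead`` row must be the identity row (death is absorbing).
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_STATES, N_STATES):
            raise ModelValidationError(
                f"transition matrix must be {N_STATES}x{N_STATES}, got {p.shape}"
            )
        if np.any(p < -_ROW_TOL) or np.any(p > 1 + _ROW_TOL):
            raise ModelValidationError("transition probabilities must lie in [0, 1]")
        sums = p.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
        if bad.size:
            i = int(bad[0])
            raise ModelValidationError(
                f"row {i} ({STATE_LABELS[i]}) sums to {sums[i]:.12f}, not 1"
            )
        dead = int(HealthState.DEAD)
        if not np.allclose(p[dead], np.eye(N_STATES)[dead], atol=_ROW_TOL):
            raise ModelValidationError("dead must be absorbing (identity row)")
        object.__setattr__(self, "probs", p)

    def __array__(self, dtype=None, copy=None):  # numpy interop
        return np.array(self.probs, dtype=dtype)


@dataclass(frozen=True)
class OutcomeSpec:
    """Utilities and costs attached to states, entries and adjuvant treatment.

    Parameters
    ----------
    utility_per_state:
        QALY weight per state per year, each in [0, 1]; dead must be 0.
    annual_cost_per_state:
        EUR per state per year of occupancy.
    transition_cost:
        EUR charged once on *entering* each state.  The relapse slot holds
        the one-time cost of the single funded relapse treatment.
    chemo_cost, endocrine_cost:
        One-off adjuvant treatment costs (EUR), charged in cycle 0.
    chemo_disutility:
        QALY decrement applied in cycle 0 to chemotherapy recipients.
    """

    utility_per_state: np.ndarray
    annual_cost_per_state: np.ndarray
    transition_cost: np.ndarray
    chemo_cost: float = 0.0
    endocrine_cost: float = 0.0
    chemo_disutility: float = 0.0

    def __post_init__(self) -> None:
        u = np.asarray(self.utility_per_state, dtype=float)
        c = np.asarray(self.annual_cost_per_state, dtype=float)
        tc = np.asarray(self.transition_cost, dtype=float)
        for name, arr in (("utility", u), ("annual cost", c), ("transition cost", tc)):
            if arr.shape != (N_STATES,):
                raise ModelValidationError(f"{name} vector must have length {N_STATES}")
        if np.any(u < 0) or np.any(u > 1):
            raise ModelValidationError("utilities must lie in [0, 1]")
        if abs(u[HealthState.DEAD]) > 0:
            raise ModelValidationError("utility of dead must be 0")
        if np.any(c < 0) or np.any(tc < 0) or self.chemo_cost < 0 or self.endocrine_cost < 0:
            raise ModelValidationError("costs must be non-negative")
        object.__setattr__(self, "utility_per_state", u)
        object.__setattr__(self, "annual_cost_per_state", c)
        object.__setattr__(self, "transition_cost", tc)


@dataclass(frozen=True)
class EconomicSettings:
    """Horizon, cycle length and Dutch-guideline discount rates (2005 EUR)."""

    horizon_years: int = 20
    cycle_length: float = 1.0
    discount_rate_costs: float = 0.04
    discount_rate_effects: float = 0.015
    currency_year: str = "2005 EUR"
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ModelValidationError("horizon_years must be >= 1")
        if self.discount_rate_costs < 0 or self.discount_rate_effects < 0:
            raise ModelValidationError("discount rates must be >= 0")
        if self.cycle_length != 1.0:
            raise ModelValidationError("only annual cycles are supported")


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per cycle plus the new-entry bookkeeping.

    ``occupancy[t, s]`` is the cohort fraction in state ``s`` at the start
    of year ``t`` (t = 0..horizon).  ``entries[t, s]`` is the fraction
    newly arriving in ``s`` at time ``t`` (row 0 is the initial
    distribution); diagonal stays are never counted as entries, which is
    what makes one-off entry costs single-charged.
    """

    occupancy: np.ndarray
    entries: np.ndarray

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self):
        """Long-format table with columns cycle, state, occupancy."""
        import pandas as pd

        t, s = np.meshgrid(
            np.arange(self.occupancy.shape[0]), np.arange(N_STATES), indexing="ij"
        )
        return pd.DataFrame(
            {
                "cycle": t.ravel(),
                "state": [STATE_LABELS[i] for i in s.ravel()],
                "occupancy": self.occupancy.ravel(),
            }
        )


def run_cohort(
    matrix: TransitionMatrix,
    initial: np.ndarray,
    settings: EconomicSettings,
) -> CohortTrace:
    """Propagate a cohort distribution through annual cycles.

    Returns a trace with ``horizon + 1`` occupancy rows; row ``t + 1`` is
    row ``t`` multiplied by the transition matrix.  Entry bookkeeping
    records off-diagonal inflow only.
    """
    if isinstance(matrix, np.ndarray):
        matrix = TransitionMatrix(matrix)
    init = np.asarray(initial, dtype=float)
    if init.shape != (N_STATES,):
        raise ModelValidationError(f"initial distribution must have length {N_STATES}")
    if np.any(init < 0):
        raise ModelValidationError("initial distribution has negative mass")
    if abs(init.sum() - 1.0) > 1e-9:
        raise ModelValidationError(f"initial distribution sums to {init.sum():.12f}, not 1")

    p = matrix.probs
    horizon = settings.horizon_years
    occ = np.empty((horizon + 1, N_STATES))
    ent = np.empty((horizon + 1, N_STATES))
    occ[0] = init
    ent[0] = init
    off_diag = p - np.diag(np.diag(p))
    for t in range(horizon):
        occ[t + 1] = occ[t] @ p
        ent[t + 1] = occ[t] @ off_diag
    return CohortTrace(occupancy=occ, entries=ent)


def discount_factor(rate: float, year_index: int) -> float:
    """Present-value factor ``1 / (1 + rate)^year`` (year 0 -> 1.0)."""
    if rate < 0:
        raise ModelValidationError("discount rate must be >= 0")
    year = np.asarray(year_index)
    if np.any(year < 0):
        raise ModelValidationError("year index must be >= 0")
    out = (1.0 + rate) ** -np.asarray(year_index, dtype=float)
    return float(out) if np.isscalar(year_index) else out


def accumulate(
    trace: CohortTrace,
    spec: OutcomeSpec,
    settings: EconomicSettings,
    received_chemo: bool = False,
) -> tuple[float, float]:
    """Discounted lifetime (QALYs, costs) for one cohort trace.

    State payoffs are charged on cycle-start occupancy for each of the
    ``horizon`` cycles; entry costs are charged in the year of arrival;
    adjuvant-treatment costs and the chemotherapy disutility fall in
    year 0.  With ``settings.half_cycle_correction`` each cycle instead
    uses the mean of its start and end occupancy.
    """
    horizon = settings.horizon_years
    if trace.occupancy.shape != (horizon + 1, N_STATES):
        raise ModelValidationError(
            f"trace has {trace.occupancy.shape[0] - 1} cycles, settings expect {horizon}"
        )
    years = np.arange(horizon)
    df_e = discount_factor(settings.discount_rate_effects, years)
    df_c = discount_factor(settings.discount_rate_costs, years)

    if settings.half_cycle_correction:
        occ = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])
    else:
        occ = trace.occupancy[:-1]

    qalys = float(df_e @ (occ @ spec.utility_per_state))
    costs = float(df_c @ (occ @ spec.annual_cost_per_state))

    df_c_all = discount_factor(settings.discount_rate_costs, np.arange(horizon + 1))
    costs += float(df_c_all @ (trace.entries @ spec.transition_cost))

    alive0 = 1.0 - trace.occupancy[0, HealthState.DEAD]
    costs += spec.endocrine_cost * alive0
    if received_chemo:
        costs += spec.chemo_cost * alive0
        qalys -= spec.chemo_disutility * alive0
    return qalys, costs


def microsim_oracle(
    matrix: TransitionMatrix,
    initial: np.ndarray,
    settings: EconomicSettings,
    n_individuals: int,
    seed: int,
) -> CohortTrace:
    """Empirical trace from simulating individual patient trajectories.

    Serves as an independent stochastic oracle for :func:`run_cohort`;
    the empirical occupancy converges to the deterministic trace at the
    binomial Monte-Carlo rate.
    """
    if isinstance(matrix, np.ndarray):
        matrix = TransitionMatrix(matrix)
    if n_individuals < 1:
        raise ModelValidationError("n_individuals must be >= 1")
    init = np.asarray(initial, dtype=float)
    if abs(init.sum() - 1.0) > 1e-9 or np.any(init < 0):
        raise ModelValidationError("initial must be a probability distribution")

    rng = np.random.default_rng(seed)
    horizon = settings.horizon_years
    cum = np.cumsum(matrix.probs, axis=1)
    states = rng.choice(N_STATES, size=n_individuals, p=init)
    occ = np.zeros((horizon + 1, N_STATES))
    ent = np.zeros((horizon + 1, N_STATES))
    occ[0] = np.bincount(states, minlength=N_STATES) / n_individuals
    ent[0] = occ[0]
    for t in range(horizon):
        u = rng.random(n_individuals)
        nxt = (u[:, None] > cum[states]).sum(axis=1)
        moved = nxt != states
        occ[t + 1] = np.bincount(nxt, minlength=N_STATES) / n_individuals
        ent[t + 1] = np.bincount(nxt[moved], minlength=N_STATES) / n_individuals
        states = nxt
    return CohortTrace(occupancy=occ, entries=ent)
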