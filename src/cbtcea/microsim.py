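"""Individual-level Monte-Carlo validation of the cohort engine.

Simulates the identical decision process one student at a time — acceptance,
adherence, phase outcome, monthly state transitions, Bernoulli hospitalisation
events, death — so that large-sample averages converge to the cohort engine's
deterministic expectations.  Also provides a random-scenario generator used to
fuzz the model invariants.

Randomness layout: one uniform variate matrix of shape (n, columns) is drawn
in a single call from a seeded generator.  Because the array fills row-major,
individual ``i`` consumes exactly the same variates whatever ``n`` is, so
results for the first ``m`` individuals are reproducible as the sample grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import _programme_rates, initial_phase_split, stratum_split
from .economics import (
    CYCLES_PER_YEAR,
    StrategyOutcome,
    _course_payment_factor,
    _utility_vector,
    discount_factor,
)
from .parameters import (
    ConfigError,
    ParameterSet,
    StructuralConfig,
    course_cost,
    effective_uptake,
    employment_fraction,
    TABLE1,
)
from .transitions import N_STATES, State, build_monthly_matrix

OCCUPANCY_CHECK_CYCLES = (3, 12, 60)


@dataclass(frozen=True)
class MicrosimResult:
    """Sample means with standard errors from the individual-level simulator."""

    arm: str
    n: int
    seed: int
    mean_outcome: StrategyOutcome
    se_direct: float
    se_indirect: float
    se_total: float
    se_qaly: float
    occupancy: dict[int, np.ndarray]  # cycle -> 5-state occupancy estimate
    occupancy_se: dict[int, np.ndarray]
    records: pd.DataFrame | None = None


def simulate_individuals(
    params: ParameterSet,
    cfg: StructuralConfig | None = None,
    arm: str = "icbt",
    n: int = 10_000,
    seed: int = 0,
    check_cycles: tuple[int, ...] = OCCUPANCY_CHECK_CYCLES,
    return_records: bool = False,
) -> MicrosimResult:
    """Simulate ``n`` students through one strategy and summarise."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    cfg = cfg if cfg is not None else StructuralConfig()
    pt = params.point() if isinstance(params, ParameterSet) else params
    horizon = int(pt.horizon_cycles)
    phase = cfg.phase_cycles
    if phase > horizon:
        raise ConfigError("phase_cycles exceeds horizon_cycles")

    T = build_monthly_matrix(pt, cfg).entries
    cum_T = np.cumsum(T, axis=1)
    mort_mild = T[State.MILD, State.DEAD]
    p_acc, p_adh, _ = effective_uptake(pt, arm)
    rec_e, det_e = _programme_rates(pt, arm)
    split_eff = stratum_split(rec_e, det_e, pt, cfg)
    split_non = stratum_split(pt.recovery_none, pt.deterioration_none, pt, cfg)
    cum_eff = np.cumsum(split_eff)
    cum_non = np.cumsum(split_non)

    # uniform variates: accept, adhere, phase outcome, per-cycle transition,
    # per-cycle hospitalisation
    n_cols = 3 + horizon + horizon
    u = np.random.default_rng(seed).random((n, n_cols))
    u_accept, u_adhere, u_outcome = u[:, 0], u[:, 1], u[:, 2]
    u_move = u[:, 3 : 3 + horizon]
    u_hosp = u[:, 3 + horizon :]

    accepted = u_accept < p_acc
    adhered = accepted & (u_adhere < p_adh)

    state = np.full(n, int(State.MILD), dtype=np.int8)
    disc = np.array([discount_factor(c, pt.discount_annual) for c in range(horizon + 1)])
    utility = _utility_vector(pt)
    outp_idx = np.zeros(N_STATES, dtype=bool)
    for s in cfg.outpatient_states:
        outp_idx[State[s.upper()]] = True
    indirect_states = np.zeros(N_STATES, dtype=bool)
    indirect_states[[State.MODERATE, State.SEVERE]] = True
    wage_loss = employment_fraction(pt) * pt.student_wage * pt.hours_per_month

    course = course_cost(pt, "i_low" if arm == "icbt" else "f_low")
    course_high = course_cost(pt, "f_high")
    if cfg.course_cost_nonadherent == "full":
        pay_factor = np.ones(n)
    else:
        pay_factor = np.where(adhered, 1.0, 0.5)
    # course fee is prepaid on acceptance, booked in phase-cycle instalments
    instalment = accepted * pay_factor * course / phase

    direct = np.zeros(n)
    indirect = np.zeros(n)
    qaly = np.zeros(n)
    occupancy: dict[int, np.ndarray] = {}
    occupancy_se: dict[int, np.ndarray] = {}
    hosp_count = np.zeros(n, dtype=np.int32)

    for c in range(1, horizon + 1):
        alive = state != State.DEAD
        if c < phase:
            dies = alive & (u_move[:, c - 1] < mort_mild)
            state[dies] = State.DEAD
        elif c == phase:
            dies = alive & (u_move[:, c - 1] < mort_mild)
            state[dies] = State.DEAD
            survivors = state != State.DEAD
            cum = np.where(adhered[:, None], cum_eff[None, :], cum_non[None, :])
            outcome = (u_outcome[:, None] > cum).sum(axis=1)
            state[survivors] = outcome[survivors].astype(np.int8)
            if cfg.escalation_enabled:
                if cfg.escalation_recipients == "all_not_well":
                    escalated = survivors & (state != State.WELL)
                else:
                    escalated = accepted & survivors & (state != State.WELL)
                direct += escalated * course_high * disc[c]
        else:
            moved = state.copy()
            for s in range(N_STATES - 1):  # DEAD is absorbing
                mask = state == s
                if mask.any():
                    moved[mask] = np.searchsorted(
                        cum_T[s], u_move[mask, c - 1], side="right"
                    ).astype(np.int8)
            state = moved

        if c <= phase:
            direct += instalment * disc[c]
        severe = state == State.SEVERE
        hosp = severe & (u_hosp[:, c - 1] < pt.p_hosp_severe)
        hosp_count += hosp
        direct += (
            outp_idx[state] * pt.outpatient_monthly
            + hosp * pt.hosp_cost_episode
        ) * disc[c]
        indirect += indirect_states[state] * wage_loss * disc[c]
        qaly += utility[state] / CYCLES_PER_YEAR * disc[c]

        if c in check_cycles:
            counts = np.bincount(state, minlength=N_STATES) / n
            occupancy[c] = counts
            occupancy_se[c] = np.sqrt(counts * (1.0 - counts) / n)

    total = direct + indirect

    def se(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    mean_outcome = StrategyOutcome(
        arm=arm,
        direct_cost=float(direct.mean()),
        indirect_cost=float(indirect.mean()),
        qalys=float(qaly.mean()),
    )
    records = None
    if return_records:
        records = pd.DataFrame(
            {
                "id": np.arange(n),
                "arm": arm,
                "accepted": accepted,
                "adhered": adhered,
                "final_state": [State(s).name.lower() for s in state],
                "hospitalizations": hosp_count,
                "cost": total,
                "qaly": qaly,
            }
        )
    return MicrosimResult(
        arm=arm,
        n=n,
        seed=seed,
        mean_outcome=mean_outcome,
        se_direct=se(direct),
        se_indirect=se(indirect),
        se_total=se(total),
        se_qaly=se(qaly),
        occupancy=occupancy,
        occupancy_se=occupancy_se,
        records=records,
    )


def generate_random_scenario(
    seed: int,
) -> tuple[ParameterSet, StructuralConfig]:
    """Random valid inputs + structural switches for property-test fuzzing.

    Input values are drawn uniformly within their declared ranges (which keeps
    every transition row feasible); structural switches are drawn uniformly
    over their alternatives.
    """
    rng = np.random.default_rng(seed)
    specs = {}
    for key, spec in TABLE1.items():
        if spec.degenerate:
            specs[key] = spec
        else:
            value = float(rng.uniform(spec.low, spec.high))
            specs[key] = type(spec)(spec.family, value, spec.low, spec.high)
    params = ParameterSet(specs)

    choice = rng.integers
    states = ("mild", "moderate", "severe")
    outpatient = frozenset(s for s in states if choice(0, 2))
    cfg = StructuralConfig(
        phase_cycles=int(choice(1, 4)),
        deterioration_split_rule=("proportional", "all_moderate")[choice(0, 2)],
        outpatient_states=outpatient or frozenset({"moderate", "severe"}),
        escalation_enabled=bool(choice(0, 2)),
        escalation_recipients=("accepters_not_well", "all_not_well")[choice(0, 2)],
        course_cost_nonadherent=("full", "half")[choice(0, 2)],
        half_cycle_correction=bool(choice(0, 2)),
    )
    return params, cfg
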