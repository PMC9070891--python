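"""Valuation of a cohort trace: discounted costs, QALYs, and strategy comparison.

Costs are societal: direct medical items (CBT course instalments, the one-time
high-intensity escalation course, monthly psychiatric outpatient care in the
configured states, and expected hospitalisation among the severe) plus the
friction-cost productivity loss of employed students during months with
moderate or severe symptoms.  Health outcome is the quality-adjusted life-year
with age-adjusted state utilities (age-specific utility x state-specific
utility).  Everything is discounted to model entry at the annual rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np

from .cohort import CohortTrace, run_cohort
from .parameters import (
    ConfigError,
    ParameterSet,
    StructuralConfig,
    course_cost,
    effective_uptake,
    employment_fraction,
)
from .transitions import State

CYCLES_PER_YEAR = 12

DOMINANT_INTERVENTION = "intervention_dominant"
DOMINANT_COMPARATOR = "comparator_dominant"
TRADE_OFF = "trade_off"


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted per-person results of one strategy over the horizon."""

    arm: str
    direct_cost: float
    indirect_cost: float
    qalys: float

    @property
    def total_cost(self) -> float:
        return self.direct_cost + self.indirect_cost


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of intervention versus comparator."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str
    inmb: float
    wtp: float


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Present-value factor for a monthly cycle at an annual discount rate."""
    if cycle < 0:
        raise ConfigError("cycle must be >= 0")
    return float((1.0 + annual_rate) ** (-cycle / CYCLES_PER_YEAR))


def state_utility(params: ParameterSet | SimpleNamespace, state: State) -> float:
    """Age-adjusted utility weight of a state (0 for DEAD by definition)."""
    pt = params.point() if isinstance(params, ParameterSet) else params
    if state == State.DEAD:
        return 0.0
    specific = {
        State.WELL: pt.utility_well,
        State.MILD: pt.utility_mild,
        State.MODERATE: pt.utility_mod,
        State.SEVERE: pt.utility_sev,
    }[State(state)]
    return pt.utility_age * specific


def _utility_vector(pt: SimpleNamespace) -> np.ndarray:
    return np.array([state_utility(pt, s) for s in State])


def _course_payment_factor(pt: SimpleNamespace, cfg: StructuralConfig, arm: str) -> float:
    """Expected share of the course fee paid per accepter.

    Under ``full`` every accepter is charged the whole course (sessions are
    provisioned on acceptance); under ``half`` non-adherent accepters are
    charged half for dropout proration.
    """
    if cfg.course_cost_nonadherent == "full":
        return 1.0
    _, p_adh, _ = effective_uptake(pt, arm)
    return p_adh + 0.5 * (1.0 - p_adh)


def cycle_value(
    trace_row: np.ndarray,
    cycle: int,
    arm: str,
    params: ParameterSet | SimpleNamespace,
    cfg: StructuralConfig | None = None,
    escalation_fraction: float = 0.0,
) -> tuple[float, float, float]:
    """Discounted (direct, indirect, qaly) contribution of one cycle.

    Course instalments are spread evenly over the phase cycles; the escalation
    charge falls at the phase-end cycle.
    """
    pt = params.point() if isinstance(params, ParameterSet) else params
    cfg = cfg if cfg is not None else StructuralConfig()
    occ = np.asarray(trace_row, dtype=float)

    outp_idx = [State[s.upper()] for s in cfg.outpatient_states]
    direct = sum(occ[i] for i in outp_idx) * pt.outpatient_monthly
    direct += occ[State.SEVERE] * pt.p_hosp_severe * pt.hosp_cost_episode

    if 1 <= cycle <= cfg.phase_cycles:
        p_acc, _, _ = effective_uptake(pt, arm)
        course = course_cost(pt, "i_low" if arm == "icbt" else "f_low")
        direct += (
            p_acc * _course_payment_factor(pt, cfg, arm) * course / cfg.phase_cycles
        )
    if cycle == cfg.phase_cycles:
        direct += escalation_fraction * course_cost(pt, "f_high")

    indirect = (
        (occ[State.MODERATE] + occ[State.SEVERE])
        * employment_fraction(pt)
        * pt.student_wage
        * pt.hours_per_month
    )
    qaly = float(occ @ _utility_vector(pt)) / CYCLES_PER_YEAR

    d = discount_factor(cycle, pt.discount_annual)
    return direct * d, indirect * d, qaly * d


def summarize(
    trace: CohortTrace,
    params: ParameterSet | SimpleNamespace,
    cfg: StructuralConfig | None = None,
) -> StrategyOutcome:
    """Discounted per-person outcome of a cohort trace.

    With the half-cycle correction on, state-occupancy valuations use the mean
    of the cycle's start and end rows; the course and escalation charges are
    event costs and are not averaged.
    """
    pt = params.point() if isinstance(params, ParameterSet) else params
    cfg = cfg if cfg is not None else StructuralConfig()
    horizon = trace.occupancy.shape[0] - 1
    direct = indirect = qalys = 0.0
    for c in range(1, horizon + 1):
        row = trace.occupancy[c]
        if cfg.half_cycle_correction:
            row = 0.5 * (trace.occupancy[c - 1] + row)
        esc = trace.escalation_fraction if c == trace.phase_end_cycle else 0.0
        d, i, q = cycle_value(row, c, trace.arm, pt, cfg, escalation_fraction=esc)
        direct += d
        indirect += i
        qalys += q
    return StrategyOutcome(
        arm=trace.arm, direct_cost=direct, indirect_cost=indirect, qalys=qalys
    )


def evaluate_strategy(
    params: ParameterSet | SimpleNamespace,
    cfg: StructuralConfig | None = None,
    arm: str = "icbt",
    on_invalid_row: str = "raise",
) -> StrategyOutcome:
    """Run the cohort for one arm and value the trace."""
    cfg = cfg if cfg is not None else StructuralConfig()
    trace = run_cohort(params, cfg, arm, on_invalid_row=on_invalid_row)
    return summarize(trace, params, cfg)


def compare(
    intervention: StrategyOutcome,
    comparator: StrategyOutcome,
    wtp: float,
) -> CEResult:
    """Incremental cost, QALYs, ICER/dominance, and net monetary benefit.

    Deltas are intervention minus comparator.  The ICER is reported only in
    the trade-off quadrants (cost and QALY deltas of equal sign, QALY delta
    nonzero); with a zero QALY delta the classification follows the cost sign.
    """
    delta_cost = intervention.total_cost - comparator.total_cost
    delta_qaly = intervention.qalys - comparator.qalys
    icer: float | None = None
    if delta_qaly > 0 and delta_cost < 0:
        dominance = DOMINANT_INTERVENTION
    elif delta_qaly < 0 and delta_cost > 0:
        dominance = DOMINANT_COMPARATOR
    elif delta_qaly == 0:
        if delta_cost < 0:
            dominance = DOMINANT_INTERVENTION
        elif delta_cost > 0:
            dominance = DOMINANT_COMPARATOR
        else:
            dominance = TRADE_OFF
    else:
        dominance = TRADE_OFF
        icer = delta_cost / delta_qaly
    inmb = wtp * delta_qaly - delta_cost
    return CEResult(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer,
        dominance=dominance,
        inmb=inmb,
        wtp=wtp,
    )


def base_case(
    params: ParameterSet,
    cfg: StructuralConfig | None = None,
    wtp: float | None = None,
) -> tuple[StrategyOutcome, StrategyOutcome, CEResult]:
    """Deterministic evaluation of both arms plus their comparison."""
    cfg = cfg if cfg is not None else StructuralConfig()
    wtp = wtp if wtp is not None else params.wtp.base
    out_i = evaluate_strategy(params, cfg, "icbt")
    out_f = evaluate_strategy(params, cfg, "fcbt")
    return out_i, out_f, compare(out_i, out_f, wtp)
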