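"""Cohort simulation: treatment phase, phase-end outcome split, Markov cycles.

A cohort of students with mild anxiety enters the model, is offered a
low-intensity CBT course delivered either over the internet (``icbt``) or face
to face (``fcbt``), and is then followed over monthly cycles to the horizon.

During the programme phase the cohort is held in MILD apart from background
mortality: the programme-level recovery and deterioration probabilities already
summarise within-programme change, so applying monthly transitions concurrently
would double-count.  At the end of the phase the surviving cohort is split into
well / mild / moderate / severe according to a mixture of two strata:

* effective (accepted and adhered, weight p_accept x p_adhere): recovery and
  deterioration of the low-intensity course (internet arm scaled by its
  relative differences);
* non-effective (declined or dropped out, pooled): the no-intervention rates.

Deteriorating mass is divided between moderate and severe in proportion to the
background mild-to-moderate and mild-to-severe probabilities (or sent wholly to
moderate under the ``all_moderate`` rule).  Afterwards the monthly transition
matrix applies unchanged to the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .parameters import (
    ConfigError,
    ParameterSet,
    StructuralConfig,
    effective_uptake,
)
from .transitions import N_STATES, STATE_NAMES, State, build_monthly_matrix

ARMS = ("icbt", "fcbt")


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions per cycle for one strategy.

    ``occupancy`` has ``horizon_cycles + 1`` rows (row 0 = model entry, all
    MILD) and five columns in :class:`~cbtcea.transitions.State` order.
    ``escalation_fraction`` is the share of the entry cohort charged the
    high-intensity course at the end of the phase.
    """

    arm: str
    occupancy: np.ndarray
    phase_end_cycle: int
    escalation_fraction: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[f"p_{s}" for s in STATE_NAMES])
        df.insert(0, "cycle", np.arange(len(df)))
        return df


def stratum_split(
    recovery: float,
    deterioration: float,
    pt: SimpleNamespace,
    cfg: StructuralConfig,
) -> np.ndarray:
    """Distribution over (WELL, MILD, MODERATE, SEVERE) for one stratum."""
    if recovery + deterioration > 1.0:
        raise ConfigError(
            f"recovery ({recovery}) + deterioration ({deterioration}) > 1"
        )
    if cfg.deterioration_split_rule == "proportional":
        denom = pt.p_mild_mod + pt.p_mild_sev
        # degenerate background probabilities leave no split information
        to_mod = pt.p_mild_mod / denom if denom > 0 else 1.0
    else:  # all_moderate
        to_mod = 1.0
    return np.array(
        [
            recovery,
            1.0 - recovery - deterioration,
            deterioration * to_mod,
            deterioration * (1.0 - to_mod),
        ]
    )


def initial_phase_split(
    params: ParameterSet | SimpleNamespace,
    cfg: StructuralConfig,
    arm: str,
) -> np.ndarray:
    """Phase-end distribution over (WELL, MILD, MODERATE, SEVERE).

    Mixture of the effective and non-effective strata weighted by the arm's
    effective uptake.
    """
    pt = params.point() if isinstance(params, ParameterSet) else params
    _, _, p_eff = effective_uptake(pt, arm)
    rec_e, det_e = _programme_rates(pt, arm)
    eff = stratum_split(rec_e, det_e, pt, cfg)
    non = stratum_split(pt.recovery_none, pt.deterioration_none, pt, cfg)
    return p_eff * eff + (1.0 - p_eff) * non


def _programme_rates(pt: SimpleNamespace, arm: str) -> tuple[float, float]:
    """Recovery/deterioration of the low-intensity course for one arm."""
    if arm == "fcbt":
        return pt.recovery_licbt, pt.deterioration_licbt
    if arm == "icbt":
        return (
            min(1.0, pt.recovery_licbt * pt.rr_recovery_icbt),
            min(1.0, pt.deterioration_licbt * pt.rr_deterioration_icbt),
        )
    raise ConfigError(f"unknown arm {arm!r}")


def run_cohort(
    params: ParameterSet | SimpleNamespace,
    cfg: StructuralConfig | None = None,
    arm: str = "icbt",
    on_invalid_row: str = "raise",
) -> CohortTrace:
    """Propagate the cohort over the full horizon for one strategy."""
    pt = params.point() if isinstance(params, ParameterSet) else params
    cfg = cfg if cfg is not None else StructuralConfig()
    if arm not in ARMS:
        raise ConfigError(f"unknown arm {arm!r}")
    horizon = int(pt.horizon_cycles)
    phase = cfg.phase_cycles
    if phase > horizon:
        raise ConfigError("phase_cycles exceeds horizon_cycles")

    T = build_monthly_matrix(pt, cfg, on_invalid_row=on_invalid_row).entries
    mort_mild = T[State.MILD, State.DEAD]
    mix = initial_phase_split(pt, cfg, arm)

    occ = np.zeros((horizon + 1, N_STATES))
    occ[0, State.MILD] = 1.0
    escalation_fraction = 0.0

    for c in range(1, horizon + 1):
        prev = occ[c - 1]
        if c < phase:
            cur = prev.copy()
            cur[State.DEAD] += prev[State.MILD] * mort_mild
            cur[State.MILD] *= 1.0 - mort_mild
        elif c == phase:
            dead = prev[State.DEAD] + prev[State.MILD] * mort_mild
            alive = prev[State.MILD] * (1.0 - mort_mild)
            cur = np.zeros(N_STATES)
            cur[: State.DEAD] = alive * mix
            cur[State.DEAD] = dead
            escalation_fraction = _escalation_fraction(pt, cfg, arm, cur)
        else:
            cur = prev @ T
        occ[c] = cur

    return CohortTrace(
        arm=arm,
        occupancy=occ,
        phase_end_cycle=phase,
        escalation_fraction=escalation_fraction,
    )


def _escalation_fraction(
    pt: SimpleNamespace, cfg: StructuralConfig, arm: str, phase_end_row: np.ndarray
) -> float:
    """Share of the entry cohort advanced to the high-intensity course."""
    if not cfg.escalation_enabled:
        return 0.0
    alive = 1.0 - phase_end_row[State.DEAD]
    if cfg.escalation_recipients == "all_not_well":
        return alive - phase_end_row[State.WELL]
    # accepters_not_well: adherent accepters follow the programme recovery,
    # non-adherent accepters the no-intervention recovery
    p_acc, p_adh, _ = effective_uptake(pt, arm)
    rec_e, _ = _programme_rates(pt, arm)
    not_well = p_adh * (1.0 - rec_e) + (1.0 - p_adh) * (1.0 - pt.recovery_none)
    return p_acc * not_well * alive
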