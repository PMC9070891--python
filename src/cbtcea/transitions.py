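"""Monthly transition matrix of the five-state anxiety model.

States are WELL, MILD, MODERATE, SEVERE, DEAD (absorbing).  Morbidity entries
are the published monthly probabilities; all-cause mortality enters each alive
row directly, multiplied by the anxiety mortality rate ratio in the symptomatic
states, with the stay probability absorbing the remainder.

Also provides the eigendecomposition k-th root used to shorten transition
probabilities quoted over multi-month intervals to the monthly cycle.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import IntEnum
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .parameters import ConfigError, ParameterSet, StructuralConfig


class State(IntEnum):
    WELL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    DEAD = 4


STATE_NAMES = tuple(s.name.lower() for s in State)
N_STATES = len(State)

_ROW_TOL = 1e-12


class StochasticRootError(ValueError):
    """The requested matrix has no valid stochastic k-th root."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 5x5 monthly transition matrix (rows = origin state)."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.shape != (N_STATES, N_STATES):
            raise ConfigError(f"expected {N_STATES}x{N_STATES} matrix, got {m.shape}")
        if (m < 0).any() or (m > 1).any():
            raise ConfigError("transition probabilities must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=_ROW_TOL, rtol=0):
            raise ConfigError("every row must sum to 1")
        dead = np.zeros(N_STATES)
        dead[State.DEAD] = 1.0
        if not np.array_equal(m[State.DEAD], dead):
            raise ConfigError("DEAD must be absorbing")
        object.__setattr__(self, "entries", m)

    def to_csv(self) -> str:
        df = pd.DataFrame(self.entries, index=STATE_NAMES, columns=STATE_NAMES)
        return df.to_csv(index_label="state")

    @classmethod
    def from_csv(cls, text: str) -> "TransitionMatrix":
        df = pd.read_csv(io.StringIO(text), index_col="state")
        df = df.loc[list(STATE_NAMES), list(STATE_NAMES)]
        return cls(df.to_numpy(dtype=float))


def matrix_root(P: np.ndarray, k: int) -> np.ndarray:
    """Matrix M with ``M^k = P`` via eigendecomposition (principal roots).

    Small negative entries from numerical noise (> -1e-8) are clipped to zero
    and rows renormalised.  Raises :class:`StochasticRootError` when P is not
    diagonalizable or an eigenvalue admits no real principal k-th root.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ConfigError("matrix_root requires a square matrix")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9, rtol=0):
        raise ConfigError("matrix_root requires a row-stochastic matrix")
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ConfigError("k must be a positive integer")
    if k == 1:
        return P.copy()

    w, V = np.linalg.eig(P)
    # a defective eigenvector basis makes V numerically singular
    if np.linalg.cond(V) > 1e12:
        raise StochasticRootError("no valid stochastic root: P is not diagonalizable")
    neg_real = (w.real < 0) & (np.abs(w.imag) < 1e-12)
    if neg_real.any():
        raise StochasticRootError(
            "no valid stochastic root: negative real eigenvalue "
            f"{w[neg_real][0].real:.6g}"
        )
    root = np.power(w.astype(complex), 1.0 / k)
    M = V @ np.diag(root) @ np.linalg.inv(V)
    if np.abs(M.imag).max() > 1e-8:
        raise StochasticRootError(
            "no valid stochastic root: complex residue "
            f"{np.abs(M.imag).max():.3g} in the reconstructed root"
        )
    M = M.real
    if M.min() < -1e-8:
        raise StochasticRootError(
            f"no valid stochastic root: entry {M.min():.3g} < 0"
        )
    M = np.clip(M, 0.0, None)
    M /= M.sum(axis=1, keepdims=True)
    if np.abs(np.linalg.matrix_power(M, k) - P).max() > 1e-8:
        raise StochasticRootError(
            "no valid stochastic root: reconstruction M^k differs from P"
        )
    return M


def build_monthly_matrix(
    params: ParameterSet | SimpleNamespace,
    cfg: StructuralConfig | None = None,
    on_invalid_row: str = "raise",
) -> TransitionMatrix:
    """Assemble the monthly matrix from the published inputs.

    The death column is the monthly all-cause probability, multiplied by the
    anxiety mortality rate ratio in the states listed by
    ``cfg.mortality_rr_states``; the diagonal absorbs the remainder.  With
    ``on_invalid_row="rescale"`` an off-diagonal row sum >= 1 (possible only
    for extreme sampled inputs) is rescaled proportionally instead of raising.
    """
    pt = params.point() if isinstance(params, ParameterSet) else params
    cfg = cfg if cfg is not None else StructuralConfig()
    if on_invalid_row not in ("raise", "rescale"):
        raise ConfigError(f"on_invalid_row: {on_invalid_row!r}")

    def death(state_name: str) -> float:
        rr = pt.rr_mortality_anxiety if state_name in cfg.mortality_rr_states else 1.0
        return pt.mortality_monthly * rr

    S = State
    off = {
        S.WELL: {S.MILD: pt.p_well_mild, S.MODERATE: pt.p_well_mod,
                 S.SEVERE: pt.p_well_sev, S.DEAD: death("well")},
        S.MILD: {S.WELL: pt.p_mild_well, S.MODERATE: pt.p_mild_mod,
                 S.SEVERE: pt.p_mild_sev, S.DEAD: death("mild")},
        S.MODERATE: {S.WELL: pt.p_mod_well, S.MILD: pt.p_mod_mild,
                     S.SEVERE: pt.p_mod_sev, S.DEAD: death("moderate")},
        S.SEVERE: {S.WELL: pt.p_sev_well, S.MILD: pt.p_sev_mild,
                   S.MODERATE: pt.p_sev_mod, S.DEAD: death("severe")},
    }
    m = np.zeros((N_STATES, N_STATES))
    for origin, row in off.items():
        total = sum(row.values())
        if total >= 1.0:
            if on_invalid_row == "raise":
                raise ConfigError(
                    f"off-diagonal probabilities from {origin.name} sum to "
                    f"{total:.4f} >= 1"
                )
            scale = (1.0 - 1e-12) / total
            row = {dest: p * scale for dest, p in row.items()}
            total = sum(row.values())
        for dest, p in row.items():
            m[origin, dest] = p
        m[origin, origin] = 1.0 - total
    m[S.DEAD, S.DEAD] = 1.0
    return TransitionMatrix(m)
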