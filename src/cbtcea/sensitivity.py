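"""Sensitivity analyses: one-way with thresholds, two-way grids, and PSA.

One-way analysis sweeps a single input over its declared range and reports the
endpoint comparisons plus any value at which the incremental QALY changes sign
(found by bisection).  The two-way analysis classifies the cost-effective
strategy over a grid of two inputs at a willingness-to-pay threshold and
extracts the decision frontier.  The probabilistic analysis redraws every input
from its distribution (beta by method of moments on the mean and range,
triangular with mode at the base value) and re-evaluates both arms per draw,
yielding mean incremental results with normal-approximation confidence
intervals and cost-effectiveness acceptability curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np
from scipy import stats

from .economics import CEResult, StrategyOutcome, compare, evaluate_strategy
from .parameters import ConfigError, ParameterSet, StructuralConfig, TABLE1

logger = logging.getLogger(__name__)

#: WTP grid for acceptability curves: 0 to 3x GDP per capita in 2,000 steps,
#: plus the exact 1x / 2x / 3x anchors.
DEFAULT_WTP_GRID = np.unique(
    np.concatenate([np.arange(0, 138_211, 2000), [46_070, 92_140, 138_210]])
).astype(float)

_QALY_OBJECTIVE = "delta_qaly_zero"
_INMB_OBJECTIVE = "inmb_zero"


# --------------------------------------------------------------------------- #
# result containers
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class OWSAResult:
    """Endpoint comparisons and threshold for one swept parameter."""

    param_key: str
    low: float
    high: float
    low_result: CEResult
    high_result: CEResult
    threshold: float | None
    degenerate: bool = False


@dataclass(frozen=True)
class TwoWayResult:
    """Cost-effective-strategy classification over a two-parameter grid."""

    key1: str
    key2: str
    values1: np.ndarray  # grid_n values of key1 (x)
    values2: np.ndarray  # grid_n values of key2 (y)
    icbt_preferred: np.ndarray  # (grid_n, grid_n) bool, rows = key2
    frontier: np.ndarray  # per key2 value: key1 threshold (NaN if none)
    wtp: float


@dataclass(frozen=True)
class PSAResult:
    """Per-draw incremental pairs, summary statistics, and CEAC points."""

    n_draws: int
    seed: int
    cost_icbt: np.ndarray
    qaly_icbt: np.ndarray
    cost_fcbt: np.ndarray
    qaly_fcbt: np.ndarray
    wtp_grid: np.ndarray
    ceac_icbt: np.ndarray
    n_rescaled_rows: int = 0

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_icbt - self.cost_fcbt

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qaly_icbt - self.qaly_fcbt

    def mean_ci(self, values: np.ndarray, level: float = 0.95):
        """Mean with normal-approximation CI of the mean (SE = sd / sqrt(n))."""
        m = float(np.mean(values))
        se = float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
        z = stats.norm.ppf(0.5 + level / 2)
        return m, m - z * se, m + z * se

    def ceac_at(self, wtp: float) -> float:
        """Probability the internet arm has the higher net benefit at ``wtp``."""
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0))


# --------------------------------------------------------------------------- #
# threshold search and one-/two-way analysis
# --------------------------------------------------------------------------- #


def _objective(
    params: ParameterSet,
    cfg: StructuralConfig,
    key: str,
    value: float,
    objective: str,
    wtp: float,
) -> float:
    p = params.with_base(key, value)
    out_i = evaluate_strategy(p, cfg, "icbt")
    out_f = evaluate_strategy(p, cfg, "fcbt")
    if objective == _QALY_OBJECTIVE:
        return out_i.qalys - out_f.qalys
    if objective == _INMB_OBJECTIVE:
        return wtp * (out_i.qalys - out_f.qalys) - (
            out_i.total_cost - out_f.total_cost
        )
    raise ConfigError(f"unknown objective {objective!r}")


def find_threshold(
    params: ParameterSet,
    cfg: StructuralConfig,
    param_key: str,
    objective: str = _QALY_OBJECTIVE,
    lo: float | None = None,
    hi: float | None = None,
    wtp: float | None = None,
    xtol: float = 1e-6,
) -> float | None:
    """Bisection root of the chosen objective in ``param_key`` over [lo, hi].

    Returns None when the objective does not change sign over the interval.
    """
    spec = params.specs[param_key]
    lo = lo if lo is not None else spec.low
    hi = hi if hi is not None else spec.high
    wtp = wtp if wtp is not None else params.wtp.base
    f_lo = _objective(params, cfg, param_key, lo, objective, wtp)
    f_hi = _objective(params, cfg, param_key, hi, objective, wtp)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        return None
    a, b, f_a = lo, hi, f_lo
    while b - a > xtol:
        m = 0.5 * (a + b)
        f_m = _objective(params, cfg, param_key, m, objective, wtp)
        if f_m == 0.0:
            return m
        if np.sign(f_a) == np.sign(f_m):
            a, f_a = m, f_m
        else:
            b = m
    return 0.5 * (a + b)


def one_way(
    params: ParameterSet,
    cfg: StructuralConfig,
    param_key: str,
    n_points: int = 2,
    wtp: float | None = None,
) -> OWSAResult:
    """Sweep one parameter over its declared range.

    ``n_points > 2`` additionally scans interior points for an incremental-QALY
    sign change before the bisection (guarding against non-monotone responses).
    """
    if param_key not in params.specs:
        raise ConfigError(f"unknown parameter key: {param_key!r}")
    spec = params.specs[param_key]
    wtp = wtp if wtp is not None else params.wtp.base

    def result_at(value: float) -> CEResult:
        p = params.with_base(param_key, value)
        return compare(
            evaluate_strategy(p, cfg, "icbt"),
            evaluate_strategy(p, cfg, "fcbt"),
            wtp,
        )

    if spec.degenerate:
        res = result_at(spec.base)
        return OWSAResult(param_key, spec.low, spec.high, res, res, None, True)

    grid = np.linspace(spec.low, spec.high, max(2, n_points))
    results = [result_at(v) for v in grid]
    threshold = None
    dq = np.array([r.delta_qaly for r in results])
    sign_change = np.nonzero(np.diff(np.sign(dq)) != 0)[0]
    if sign_change.size:
        i = sign_change[0]
        threshold = find_threshold(
            params, cfg, param_key, _QALY_OBJECTIVE, grid[i], grid[i + 1], wtp
        )
    return OWSAResult(
        param_key, spec.low, spec.high, results[0], results[-1], threshold
    )


def tornado(
    params: ParameterSet,
    cfg: StructuralConfig,
    keys: list[str] | None = None,
    wtp: float | None = None,
) -> list[OWSAResult]:
    """One-way results for every (non-degenerate) input, for tornado output."""
    keys = keys if keys is not None else list(TABLE1)
    return [one_way(params, cfg, k, wtp=wtp) for k in keys]


def two_way(
    params: ParameterSet,
    cfg: StructuralConfig,
    key1: str,
    range1: tuple[float, float] | None = None,
    key2: str | None = None,
    range2: tuple[float, float] | None = None,
    grid_n: int = 50,
    wtp: float | None = None,
) -> TwoWayResult:
    """Classify the cost-effective strategy over a grid of two inputs.

    The internet arm is preferred in a cell when its incremental net monetary
    benefit at ``wtp`` is positive (dominance and the ICER-versus-WTP rule
    collapse to this for two strategies).  The frontier column holds, for each
    key2 value, the key1 value where the preference flips (bisection; NaN when
    one strategy is preferred over the whole key1 range).
    """
    if key2 is None:
        raise ConfigError("two_way requires two parameter keys")
    wtp = wtp if wtp is not None else params.wtp.base
    s1, s2 = params.specs[key1], params.specs[key2]
    lo1, hi1 = range1 if range1 is not None else (s1.low, s1.high)
    lo2, hi2 = range2 if range2 is not None else (s2.low, s2.high)
    v1 = np.linspace(lo1, hi1, grid_n)
    v2 = np.linspace(lo2, hi2, grid_n)

    preferred = np.zeros((grid_n, grid_n), dtype=bool)
    frontier = np.full(grid_n, np.nan)
    for j, y in enumerate(v2):
        p_row = params.with_base(key2, y)
        for i, x in enumerate(v1):
            preferred[j, i] = (
                _objective(p_row, cfg, key1, x, _INMB_OBJECTIVE, wtp) > 0
            )
        frontier[j] = (
            find_threshold(p_row, cfg, key1, _INMB_OBJECTIVE, lo1, hi1, wtp)
            or np.nan
        )
    return TwoWayResult(key1, key2, v1, v2, preferred, frontier, wtp)


# --------------------------------------------------------------------------- #
# probabilistic sensitivity analysis
# --------------------------------------------------------------------------- #


def fit_beta(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """Method-of-moments beta parameters from a mean and a 95% range.

    The range is read as mean +/- 1.96 sd, i.e. sd = (hi - lo) / 3.92.  Raises
    :class:`ConfigError` when the implied shape parameters are not positive
    (variance too large for the mean); callers fall back to triangular.
    """
    if not 0.0 < mean < 1.0:
        raise ConfigError(f"beta mean {mean} outside (0, 1)")
    if not lo < hi:
        raise ConfigError(f"beta range ({lo}, {hi}) is empty")
    sd = (hi - lo) / 3.92
    var = sd * sd
    common = mean * (1.0 - mean) / var - 1.0
    alpha = mean * common
    beta = (1.0 - mean) * common
    if alpha <= 0 or beta <= 0:
        raise ConfigError(
            f"beta fit failed for mean={mean}, range=({lo}, {hi}): "
            f"alpha={alpha:.4g}, beta={beta:.4g}"
        )
    return alpha, beta


def _sample_spec(spec, rng: np.random.Generator, size=None):
    """Draw from one input's distribution (scalar or vector)."""
    if spec.family == "fixed" or spec.degenerate:
        return spec.base if size is None else np.full(size, spec.base)
    if spec.family == "triangular":
        return rng.triangular(spec.low, spec.base, spec.high, size)
    try:
        alpha, beta = fit_beta(spec.base, spec.low, spec.high)
    except ConfigError as exc:
        logger.warning("%s; falling back to triangular", exc)
        return rng.triangular(spec.low, spec.base, spec.high, size)
    return rng.beta(alpha, beta, size)


def sample_parameters(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One random point drawn from every input's distribution.

    Returns a new :class:`ParameterSet` whose base values are the draws (the
    declared families and ranges are preserved for reference).  Keys are drawn
    independently in registry order, so a fixed generator state reproduces the
    draw exactly.
    """
    new = {}
    for key, spec in params.specs.items():
        value = float(_sample_spec(spec, rng))
        lo, hi = min(spec.low, value), max(spec.high, value)
        new[key] = type(spec)(spec.family, value, lo, hi)
    return ParameterSet(new)


def run_psa(
    params: ParameterSet,
    cfg: StructuralConfig | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Monte-Carlo re-evaluation of both arms under input uncertainty.

    Each draw shares one sampled input set across the two arms.  Sampled
    transition rows whose off-diagonal sum reaches 1 are rescaled
    proportionally (counted in ``n_rescaled_rows``).
    """
    cfg = cfg if cfg is not None else StructuralConfig()
    if n_draws < 1:
        raise ConfigError("n_draws must be >= 1")
    wtp_grid = (
        np.asarray(wtp_grid, dtype=float) if wtp_grid is not None else DEFAULT_WTP_GRID
    )
    rng = np.random.default_rng(seed)
    # vectorised draw: one array of n_draws values per input, registry order
    draws = {k: _sample_spec(s, rng, n_draws) for k, s in params.specs.items()}

    cost_i = np.empty(n_draws)
    qaly_i = np.empty(n_draws)
    cost_f = np.empty(n_draws)
    qaly_f = np.empty(n_draws)
    n_rescaled = 0
    keys = list(draws)
    for j in range(n_draws):
        pt = SimpleNamespace(**{k: float(draws[k][j]) for k in keys})
        morbidity = (
            pt.p_well_mild + pt.p_well_mod + pt.p_well_sev,
            pt.p_mild_well + pt.p_mild_mod + pt.p_mild_sev,
            pt.p_mod_well + pt.p_mod_mild + pt.p_mod_sev,
            pt.p_sev_well + pt.p_sev_mild + pt.p_sev_mod,
        )
        if max(morbidity) + pt.mortality_monthly * pt.rr_mortality_anxiety >= 1.0:
            n_rescaled += 1
        out_i = evaluate_strategy(pt, cfg, "icbt", on_invalid_row="rescale")
        out_f = evaluate_strategy(pt, cfg, "fcbt", on_invalid_row="rescale")
        cost_i[j], qaly_i[j] = out_i.total_cost, out_i.qalys
        cost_f[j], qaly_f[j] = out_f.total_cost, out_f.qalys

    delta_c = cost_i - cost_f
    delta_q = qaly_i - qaly_f
    ceac = np.array(
        [float(np.mean(w * delta_q - delta_c > 0)) for w in wtp_grid]
    )
    if n_rescaled:
        logger.warning("rescaled transition rows in %d draw(s)", n_rescaled)
    return PSAResult(
        n_draws=n_draws,
        seed=seed,
        cost_icbt=cost_i,
        qaly_icbt=qaly_i,
        cost_fcbt=cost_f,
        qaly_fcbt=qaly_f,
        wtp_grid=wtp_grid,
        ceac_icbt=ceac,
        n_rescaled_rows=n_rescaled,
    )
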