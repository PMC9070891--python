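"""Presentation-only plots: PSA scatter, acceptability curves, tornado, grid.

Matplotlib is imported lazily; no analysis logic lives here.
"""

from __future__ import annotations

import numpy as np

from .sensitivity import OWSAResult, PSAResult, TwoWayResult


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_psa_scatter(psa: PSAResult, ax=None):
    """Incremental cost against incremental QALYs, one point per draw."""
    ax = _axes(ax)
    ax.scatter(psa.delta_qaly, psa.delta_cost, s=2, alpha=0.3)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("incremental QALYs (i-CBT vs f-CBT)")
    ax.set_ylabel("incremental cost (US$)")
    return ax


def plot_ceac(psa: PSAResult, ax=None):
    """Probability each strategy is cost-effective against willingness-to-pay."""
    ax = _axes(ax)
    ax.plot(psa.wtp_grid, psa.ceac_icbt, label="i-CBT")
    ax.plot(psa.wtp_grid, 1.0 - psa.ceac_icbt, label="f-CBT")
    ax.set_xlabel("willingness-to-pay (US$/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax


def plot_tornado(results: list[OWSAResult], ax=None, top: int = 15):
    """Horizontal bars of incremental-QALY swings per input."""
    ax = _axes(ax)
    swept = [r for r in results if not r.degenerate]
    swept.sort(
        key=lambda r: abs(r.high_result.delta_qaly - r.low_result.delta_qaly),
        reverse=True,
    )
    swept = swept[:top][::-1]
    y = np.arange(len(swept))
    lows = [r.low_result.delta_qaly for r in swept]
    highs = [r.high_result.delta_qaly for r in swept]
    ax.barh(y, np.subtract(highs, lows), left=lows, height=0.6)
    ax.set_yticks(y, [r.param_key for r in swept])
    ax.set_xlabel("incremental QALYs (i-CBT vs f-CBT)")
    return ax


def plot_two_way(result: TwoWayResult, ax=None):
    """Cost-effective-strategy map over the two swept inputs."""
    ax = _axes(ax)
    ax.pcolormesh(
        result.values1,
        result.values2,
        result.icbt_preferred.astype(float),
        cmap="Greys_r",
        shading="nearest",
        vmin=0,
        vmax=1,
    )
    ok = ~np.isnan(result.frontier)
    ax.plot(result.frontier[ok], result.values2[ok], "r-", lw=1.5)
    ax.set_xlabel(result.key1)
    ax.set_ylabel(result.key2)
    return ax
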