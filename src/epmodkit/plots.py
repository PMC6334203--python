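"""Figure helpers for posterior and readout diagnostics.

All functions return matplotlib Figure objects; saving is left to the
caller (or to :func:`epmodkit.cli_io.write_report`).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def plot_posterior_kde(pop, pair: Sequence[str], grid_size: int = 64):
    """2D kernel density estimate of a posterior parameter pair, with the
    per-generation constraining visible as overlaid particle scatters."""
    from .abc_smc import posterior_kde

    xg, yg, dens = posterior_kde(pop, pair, grid_size=grid_size)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.contourf(xg, yg, dens.T, levels=20, cmap="viridis")
    i, j = (pop.names.index(p) for p in pair)
    for k, gen in enumerate(pop.generations):
        ax.scatter(gen.particles[:, i], gen.particles[:, j], s=2,
                   alpha=0.15 + 0.5 * k / max(1, len(pop.generations) - 1),
                   color="white", linewidths=0)
    ax.set_xlabel(pair[0])
    ax.set_ylabel(pair[1])
    ax.set_title(f"posterior density: {pair[0]} vs {pair[1]}")
    fig.tight_layout()
    return fig


def plot_fit_envelope(envelopes: Mapping[str, dict],
                      observed: Mapping[str, np.ndarray] | None = None,
                      x_grids: Mapping[str, np.ndarray] | None = None):
    """Posterior-predictive median and central interval per summary curve,
    with observed points overlaid as crosses."""
    keys = list(envelopes)
    fig, axes = plt.subplots(1, len(keys), figsize=(4 * len(keys), 3.2),
                             squeeze=False)
    for ax, key in zip(axes[0], keys):
        e = envelopes[key]
        x = (x_grids or {}).get(key, np.arange(len(e["median"])))
        ax.fill_between(x, e["lo"], e["hi"], alpha=0.3, label="95% interval")
        ax.plot(x, e["median"], lw=1.5, label="median")
        if observed is not None and key in observed:
            ax.plot(x, observed[key], "kx", ms=4, label="observed")
        ax.set_title(key)
        ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_readout_scatter(table):
    """Truth-vs-prediction scatter for the six latent parameters
    (expects the frame produced by ``param_readout.prediction_table``)."""
    from .param_readout import TARGET_NAMES

    fig, axes = plt.subplots(2, 3, figsize=(10, 6))
    for ax, name in zip(axes.ravel(), TARGET_NAMES):
        t = table[f"{name}_true"]
        p = table[f"{name}_pred"]
        ax.scatter(t, p, s=6, alpha=0.6)
        lo, hi = min(t.min(), p.min()), max(t.max(), p.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
        ax.set_title(name)
        ax.set_xlabel("target")
        ax.set_ylabel("predicted")
    fig.tight_layout()
    return fig


def plot_training_curve(train_log):
    """Per-epoch training and validation loss of a surrogate fit."""
    ep = [r["epoch"] for r in train_log]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.semilogy(ep, [r["train_mse"] for r in train_log], label="train")
    ax.semilogy(ep, [r["val_mse"] for r in train_log], label="validation")
    ax.set_xlabel("epoch")
    ax.set_ylabel("MSE")
    ax.legend()
    fig.tight_layout()
    return fig
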