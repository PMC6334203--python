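"""Regressing the latent physical parameters from the surrogate's memory.

The recurrent hidden state of a trained forecasting network, captured at
every rollout step and stacked along the channel axis, is fed to a small
readout network (two convolutions + one fully connected layer) trained to
predict the six scenario parameters: the four regional diffusivities
(d0, d1, d0_scar, d1_scar) and the partition-line orientation ``theta`` and
offset ``beta``. theta is axial (period pi), so it is regressed internally
as (sin 2θ, cos 2θ) and mapped back before scoring; the remaining targets
are standardised to zero mean / unit variance on the training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .nn.layers import Conv2d, Linear, collect_params, relu, relu_backward
from .nn.optim import Adam
from .scenario_gen import DiffusionScenario
from .surrogate import SurrogateModel

TARGET_NAMES = ("d0", "d1", "d0_scar", "d1_scar", "theta", "beta")
_LINEAR_TARGETS = ("d0", "d1", "d0_scar", "d1_scar", "beta")


@dataclass
class LatentStack:
    """Recurrent hidden activity for all rollout steps, channels stacked:
    shape (n, k_out * lstm_channels, latent, latent)."""

    activity: np.ndarray
    scenario_ids: Sequence[int] | None = None


def extract_latents(model: SurrogateModel, inputs: np.ndarray,
                    scenario_ids: Sequence[int] | None = None) -> LatentStack:
    """Capture the LSTM hidden state at each of the ``k_out`` rollout steps.

    ``inputs`` is (n, kb, H, W) (or a single (kb, H, W) sequence) of observed
    frames; deterministic given model + input.
    """
    x = np.asarray(inputs, dtype=float)
    if x.ndim == 3:
        x = x[None]
    _, hidden = model.predict_rollout(x, return_hidden=True)
    return LatentStack(activity=hidden, scenario_ids=scenario_ids)


@dataclass(frozen=True)
class ReadoutConfig:
    """Two convolutional layers + one fully connected layer.

    Defaults (128, 64) channels with 6x6 filters and stride 2 suit the
    8x8 latent grid of 64x64 inputs; smaller filters/strides suit the
    smaller latents of scaled-down experiments.
    """

    conv_channels: tuple = (128, 64)
    conv_filter: int = 6
    conv_stride: int = 2
    epochs: int = 300
    lr: float = 1e-3
    batch: int = 32
    weight_decay: float = 1e-5
    seed: int = 0


class ReadoutModel:
    """Weights + target standardisation of the parameter-readout network."""

    def __init__(self, n_in_channels: int, latent_hw: int,
                 config: ReadoutConfig, rng: np.random.Generator):
        self.config = config
        c = config
        pad = (c.conv_filter - 1) // 2
        chans = (n_in_channels,) + c.conv_channels
        self.convs = [Conv2d(ci, co, c.conv_filter, stride=c.conv_stride,
                             pad=pad, rng=rng)
                      for ci, co in zip(chans, c.conv_channels)]
        hw = latent_hw
        for _ in c.conv_channels:
            hw = (hw + 2 * pad - c.conv_filter) // c.conv_stride + 1
            if hw < 1:
                raise ValueError(
                    "latent grid too small for the configured conv stack; "
                    "reduce conv_filter/conv_stride")
        self.flat = c.conv_channels[-1] * hw * hw
        # 7 outputs: (sin 2theta, cos 2theta) + five standardised scalars
        self.fc = Linear(self.flat, 2 + len(_LINEAR_TARGETS), rng=rng)
        self.target_names = TARGET_NAMES
        self.t_mean = np.zeros(len(_LINEAR_TARGETS))
        self.t_std = np.ones(len(_LINEAR_TARGETS))

    def params(self):
        return collect_params(*self.convs, self.fc)

    def _forward(self, x):
        caches = []
        for conv in self.convs:
            x, cc = conv.forward(x)
            x, cr = relu(x)
            caches.append((cc, cr))
        shp = x.shape
        y, cf = self.fc.forward(x.reshape(shp[0], -1))
        return y, (caches, shp, cf)

    def _backward(self, dy, cache):
        caches, shp, cf = cache
        dx = self.fc.backward(dy, cf).reshape(shp)
        for conv, (cc, cr) in zip(reversed(self.convs), reversed(caches)):
            dx = relu_backward(dx, cr)
            dx = conv.backward(dx, cc)
        return dx

    def predict(self, latents: LatentStack | np.ndarray) -> Dict[str, np.ndarray]:
        """Predicted parameters in physical units, per sample."""
        x = latents.activity if isinstance(latents, LatentStack) else latents
        y, _ = self._forward(np.asarray(x, dtype=float))
        theta = np.mod(0.5 * np.arctan2(y[:, 0], y[:, 1]), np.pi)
        out = {"theta": theta}
        for k, name in enumerate(_LINEAR_TARGETS):
            out[name] = y[:, 2 + k] * self.t_std[k] + self.t_mean[k]
        return out


def _targets_matrix(truths: Sequence[DiffusionScenario]) -> Dict[str, np.ndarray]:
    return {name: np.array([getattr(s, name) for s in truths])
            for name in TARGET_NAMES}


def train_readout(latents: LatentStack, truths: Sequence[DiffusionScenario],
                  rng: np.random.Generator | int | None = None,
                  config: ReadoutConfig | None = None,
                  verbose: bool = False) -> ReadoutModel:
    """Fit the readout by MSE on standardised targets (Adam, seeded)."""
    config = config or ReadoutConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    x = np.asarray(latents.activity, dtype=float)
    if x.shape[0] != len(truths):
        raise ValueError(f"{x.shape[0]} latent stacks but {len(truths)} truths")
    t = _targets_matrix(truths)

    model = ReadoutModel(x.shape[1], x.shape[2], config, rng)
    lin = np.stack([t[name] for name in _LINEAR_TARGETS], axis=1)
    model.t_mean = lin.mean(axis=0)
    model.t_std = np.where(lin.std(axis=0) > 0, lin.std(axis=0), 1.0)
    y = np.concatenate([
        np.sin(2 * t["theta"])[:, None], np.cos(2 * t["theta"])[:, None],
        (lin - model.t_mean) / model.t_std], axis=1)

    opt = Adam(model.params(), lr=config.lr, weight_decay=config.weight_decay)
    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep = 0.0
        for s in range(0, n, config.batch):
            idx = order[s:s + config.batch]
            pred, cache = model._forward(x[idx])
            diff = pred - y[idx]
            opt.zero_grad()
            model._backward(2.0 * diff / diff.size, cache)
            opt.step()
            ep += float(np.sum(diff**2))
        if verbose and epoch % 50 == 0:
            print(f"readout epoch {epoch}: mse {ep / y.size:.3e}", flush=True)
    return model


def _unwrap_axial(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Shift each predicted angle by a multiple of pi to the branch nearest
    the truth (theta is defined modulo pi)."""
    cands = pred[:, None] + np.array([-np.pi, 0.0, np.pi])[None, :]
    k = np.argmin(np.abs(cands - truth[:, None]), axis=1)
    return cands[np.arange(len(pred)), k]


def evaluate_readout(model: ReadoutModel, latents: LatentStack,
                     truths: Sequence[DiffusionScenario]) -> Dict[str, float]:
    """Pearson correlation between truth and prediction, per parameter.

    A degenerate (zero-variance) target or prediction yields NaN for that
    parameter rather than an error.
    """
    preds = model.predict(latents)
    t = _targets_matrix(truths)
    out = {}
    for name in TARGET_NAMES:
        p, y = preds[name], t[name]
        if name == "theta":
            p = _unwrap_axial(p, y)
        if np.std(p) == 0 or np.std(y) == 0:
            out[name] = float("nan")
        else:
            out[name] = float(np.corrcoef(p, y)[0, 1])
    return out


def prediction_table(model: ReadoutModel, latents: LatentStack,
                     truths: Sequence[DiffusionScenario]):
    """Per-scenario truth/prediction pairs for scatter plots or CSV export."""
    import pandas as pd

    preds = model.predict(latents)
    t = _targets_matrix(truths)
    data = {"scenario_id": (latents.scenario_ids
                            if latents.scenario_ids is not None
                            else np.arange(len(truths)))}
    for name in TARGET_NAMES:
        data[f"{name}_true"] = t[name]
        data[f"{name}_pred"] = preds[name]
    return pd.DataFrame(data)
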