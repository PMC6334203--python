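"""Encoder / convolutional-LSTM / decoder surrogate for frame forecasting.

The network consumes ``Kb`` observed frames of the diffusing field, encodes
each through a three-stage convolutional encoder (conv + batch-norm + ReLU +
2x2 max-pool, so the latent grid is 1/8 of the input per side), warms up a
convolutional LSTM with the encoded sequence, then free-runs the recurrent
cell for ``K_out`` steps; each step's hidden state is decoded back to a full
frame by three stride-2 transposed convolutions. Training minimises the MSE
of the first ``Kt`` predicted frames only; the model is always asked to
extrapolate beyond the training horizon at evaluation time.

Evaluation compares against the last-input baseline (repeat the final
observed frame) with a paired Wilcoxon signed-rank test over held-out
simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List, Sequence, Tuple

import numpy as np
from scipy.stats import wilcoxon

from .nn.layers import (BatchNorm2d, Conv2d, ConvLSTMCell, ConvTranspose2d,
                        collect_params, get_state, max_pool2,
                        max_pool2_backward, relu, relu_backward, set_state)
from .nn.optim import Adam


@dataclass(frozen=True)
class SurrogateConfig:
    """Architecture and training hyper-parameters.

    Defaults follow the reference architecture: encoder channels (64, 32, 32)
    with 5x5 filters and 2x2 max pooling, a 32-channel ConvLSTM with 5x5
    filters, and a decoder of stride-2 transposed 4x4 convolutions (32, 64)
    finishing in a linear single-channel frame head applied at every rollout
    step. Reduced channel counts / frame sizes are supported for scaled-down
    experiments.
    """

    kb: int = 3
    kt: int = 4
    k_out: int = 11
    frame_size: int = 64
    encoder_channels: Tuple[int, int, int] = (64, 32, 32)
    encoder_filter: int = 5
    lstm_channels: int = 32
    lstm_filter: int = 5
    decoder_channels: Tuple[int, int, int] = (32, 64, 1)
    decoder_filter: int = 4
    decoder_stride: int = 2
    lr0: float = 5e-4
    lr_drop_epoch: int = 700
    lr_drop_factor: float = 10.0
    epochs: int = 1000
    batch: int = 64
    weight_decay: float = 1e-5
    folds: int = 5
    val_frac: float = 0.2
    teacher_forcing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kb not in (2, 3):
            raise ValueError("kb must be 2 or 3")
        if not 1 <= self.kt <= 7:
            raise ValueError("kt must lie in [1, 7]")
        if self.kt > self.k_out:
            raise ValueError("kt cannot exceed k_out")
        if self.frame_size % 8 != 0:
            raise ValueError("frame_size must be divisible by 8 (three 2x2 pools)")
        if self.decoder_channels[-1] != 1:
            raise ValueError("the frame head decodes one frame per rollout step")

    @property
    def latent_size(self) -> int:
        return self.frame_size // 8


@dataclass
class EvalMetrics:
    """Held-out forecasting metrics against the last-input baseline."""

    mse_per_sim: np.ndarray
    baseline_mse_per_sim: np.ndarray
    nmse_per_step: np.ndarray
    wilcoxon_p: float

    @property
    def mse(self) -> float:
        return float(np.mean(self.mse_per_sim))

    @property
    def baseline_mse(self) -> float:
        return float(np.mean(self.baseline_mse_per_sim))


class SurrogateModel:
    """Weights + architecture; exposes rollout prediction and LSTM activity."""

    def __init__(self, config: SurrogateConfig, rng: np.random.Generator):
        self.config = config
        c = config
        enc_in = (1,) + c.encoder_channels[:-1]
        self.enc_convs = [Conv2d(ci, co, c.encoder_filter, rng=rng)
                          for ci, co in zip(enc_in, c.encoder_channels)]
        self.enc_bns = [BatchNorm2d(co) for co in c.encoder_channels]
        self.lstm = ConvLSTMCell(c.encoder_channels[-1], c.lstm_channels,
                                 c.lstm_filter, rng=rng)
        dec_in = (c.lstm_channels,) + c.decoder_channels[:-1]
        self.dec_convs = [ConvTranspose2d(ci, co, c.decoder_filter,
                                          c.decoder_stride, 1, rng=rng)
                          for ci, co in zip(dec_in, c.decoder_channels)]
        self.dec_bns = [BatchNorm2d(co) for co in c.decoder_channels[:-1]]
        self.norm_scale = 1.0
        self.train_log: List[dict] = []

    # ------------------------------------------------------------ plumbing
    def params(self):
        return collect_params(*self.enc_convs, *self.enc_bns, self.lstm,
                              *self.dec_convs, *self.dec_bns)

    def state_dict(self):
        return {
            "params": get_state(self.params()),
            "bn_stats": [(bn.running_mean.copy(), bn.running_var.copy())
                         for bn in self.enc_bns + self.dec_bns],
            "norm_scale": self.norm_scale,
        }

    def load_state_dict(self, state) -> None:
        set_state(self.params(), state["params"])
        for bn, (m, v) in zip(self.enc_bns + self.dec_bns, state["bn_stats"]):
            bn.running_mean[...] = m
            bn.running_var[...] = v
        self.norm_scale = float(state["norm_scale"])

    # ------------------------------------------------------------- encoder
    def _encode(self, x, train):
        caches = []
        for conv, bn in zip(self.enc_convs, self.enc_bns):
            x, cc = conv.forward(x)
            x, cb = bn.forward(x, train)
            x, cr = relu(x)
            x, cp = max_pool2(x)
            caches.append((cc, cb, cr, cp))
        return x, caches

    def _encode_backward(self, dx, caches):
        for conv, bn, (cc, cb, cr, cp) in zip(reversed(self.enc_convs),
                                              reversed(self.enc_bns),
                                              reversed(caches)):
            dx = max_pool2_backward(dx, cp)
            dx = relu_backward(dx, cr)
            dx = bn.backward(dx, cb)
            dx = conv.backward(dx, cc)
        return dx

    # ------------------------------------------------------------- decoder
    def _decode(self, h, train):
        caches = []
        x = h
        for k, conv in enumerate(self.dec_convs):
            x, cc = conv.forward(x)
            if k < len(self.dec_bns):
                x, cb = self.dec_bns[k].forward(x, train)
                x, cr = relu(x)
                caches.append((cc, cb, cr))
            else:
                caches.append((cc, None, None))  # linear frame head
        return x, caches

    def _decode_backward(self, dy, caches):
        for k in range(len(self.dec_convs) - 1, -1, -1):
            cc, cb, cr = caches[k]
            if cb is not None:
                dy = relu_backward(dy, cr)
                dy = self.dec_bns[k].backward(dy, cb)
            dy = self.dec_convs[k].backward(dy, cc)
        return dy

    # ------------------------------------------------------------- rollout
    def _forward(self, inputs, *, n_decode, train, tf_frames=None,
                 collect_hidden=False):
        """inputs (N, Kb, H, W) already standardised; returns predictions
        (N, n_decode, H, W), the rollout cache, and optionally the hidden
        stack for all k_out steps."""
        c = self.config
        n, kb, hgt, wid = inputs.shape
        hc = self.lstm.init_state(n, c.latent_size, c.latent_size)
        warm = []
        for t in range(kb):
            z, enc_cache = self._encode(inputs[:, t:t + 1], train)
            hc, lstm_cache = self.lstm.forward(z, hc)
            warm.append((enc_cache, lstm_cache))
        free = []
        hidden = []
        preds = np.empty((n, n_decode, hgt, wid))
        # steps beyond n_decode carry no gradient, so skip them unless the
        # hidden stack for the full rollout was requested
        n_steps = c.k_out if collect_hidden else n_decode
        for t in range(n_steps):
            if tf_frames is not None and t >= 1:
                z, enc_cache = self._encode(tf_frames[:, t - 1:t], train)
            else:
                z, enc_cache = None, None
            hc, lstm_cache = self.lstm.forward(z, hc)
            if collect_hidden:
                hidden.append(hc[0])
            if t < n_decode:
                y, dec_cache = self._decode(hc[0], train)
                preds[:, t] = y[:, 0]
            else:
                dec_cache = None
            free.append((enc_cache, lstm_cache, dec_cache))
        cache = (warm, free)
        hidden_stack = np.concatenate(hidden, axis=1) if collect_hidden else None
        return preds, cache, hidden_stack

    def _backward(self, dpreds, cache):
        warm, free = cache
        dh = dc = None
        for t in range(len(free) - 1, -1, -1):
            enc_cache, lstm_cache, dec_cache = free[t]
            if dec_cache is not None and t < dpreds.shape[1]:
                dhid = self._decode_backward(dpreds[:, t:t + 1], dec_cache)
            else:
                dhid = None
            if dh is None:
                ref = dhid if dhid is not None else None
                if ref is None:
                    # undecoded trailing step: no gradient flows from it
                    continue
                dh = np.zeros_like(ref)
                dc = np.zeros_like(ref)
            dh_total = dh + dhid if dhid is not None else dh
            dz, dh, dc = self.lstm.backward(dh_total, dc, lstm_cache)
            if dz is not None and enc_cache is not None:
                self._encode_backward(dz, enc_cache)
        for t in range(len(warm) - 1, -1, -1):
            enc_cache, lstm_cache = warm[t]
            dz, dh, dc = self.lstm.backward(dh, dc, lstm_cache)
            self._encode_backward(dz, enc_cache)

    # -------------------------------------------------------------- public
    def predict_rollout(self, inputs: np.ndarray, *, raw_scale: bool = True,
                        return_hidden: bool = False):
        """Forecast ``k_out`` frames from ``kb`` observed frames.

        ``inputs`` is (kb, H, W) or (N, kb, H, W) in physical units; outputs
        match. Uses batch-norm running statistics (inference mode).
        """
        c = self.config
        x = np.asarray(inputs, dtype=float)
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.shape[1] != c.kb or x.shape[2] != c.frame_size:
            raise ValueError(
                f"expected (N, {c.kb}, {c.frame_size}, {c.frame_size}) inputs, "
                f"got {x.shape}")
        xs = x / self.norm_scale
        preds, _, hidden = self._forward(xs, n_decode=c.k_out, train=False,
                                         collect_hidden=return_hidden)
        if raw_scale:
            preds = preds * self.norm_scale
        if single:
            preds = preds[0]
            hidden = hidden[0] if hidden is not None else None
        return (preds, hidden) if return_hidden else preds


def build(config: SurrogateConfig, rng: np.random.Generator | int | None = None) -> SurrogateModel:
    """Construct the surrogate with freshly initialised weights."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    return SurrogateModel(config, rng)


def _stack_sims(sims) -> np.ndarray:
    arr = [s.frames if hasattr(s, "frames") else np.asarray(s) for s in sims]
    return np.stack(arr)


def train(model: SurrogateModel, sims, config: SurrogateConfig | None = None,
          *, rng: np.random.Generator | int | None = None,
          verbose: bool = False) -> SurrogateModel:
    """Train on a collection of frame sequences (each >= kb + k_out frames).

    Back-propagates the MSE of the first ``kt`` predicted frames only; Adam
    with weight decay, learning rate dropped by ``lr_drop_factor`` at
    ``lr_drop_epoch``; 20% of the training simulations are set aside for
    validation and the best-validation weights are restored at the end.
    """
    config = config or model.config
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    data = _stack_sims(sims)
    c = config
    if data.shape[1] < c.kb + c.k_out:
        raise ValueError(
            f"need at least kb + k_out = {c.kb + c.k_out} frames per "
            f"simulation, got {data.shape[1]}")

    n = data.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(c.val_frac * n))) if n > 1 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = perm, perm

    model.norm_scale = float(np.std(data[tr_idx])) or 1.0
    xs = data / model.norm_scale
    inputs = xs[:, :c.kb]
    targets = xs[:, c.kb:c.kb + c.k_out]

    opt = Adam(model.params(), lr=c.lr0, weight_decay=c.weight_decay)
    best = (np.inf, None)
    model.train_log = []
    for epoch in range(c.epochs):
        opt.lr = c.lr0 / (c.lr_drop_factor if epoch >= c.lr_drop_epoch else 1.0)
        order = rng.permutation(tr_idx)
        ep_loss = 0.0
        for start in range(0, len(order), c.batch):
            idx = order[start:start + c.batch]
            xb, tb = inputs[idx], targets[idx]
            tf = tb if c.teacher_forcing else None
            preds, cache, _ = model._forward(xb, n_decode=c.kt, train=True,
                                             tf_frames=tf)
            diff = preds - tb[:, :c.kt]
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss}")
            opt.zero_grad()
            model._backward(2.0 * diff / diff.size, cache)
            opt.step()
            ep_loss += loss * len(idx)
        ep_loss /= len(tr_idx)

        vp, _, _ = model._forward(inputs[val_idx], n_decode=c.kt, train=False)
        val_loss = float(np.mean((vp - targets[val_idx][:, :c.kt])**2))
        model.train_log.append({"epoch": epoch, "train_mse": ep_loss,
                                "val_mse": val_loss})
        if val_loss < best[0]:
            best = (val_loss, model.state_dict())
        if verbose and (epoch % 10 == 0 or epoch == c.epochs - 1):
            print(f"epoch {epoch}: train {ep_loss:.3e} val {val_loss:.3e}",
                  flush=True)
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model


def evaluate(model: SurrogateModel, sims) -> EvalMetrics:
    """Forecast metrics on held-out simulations vs the last-input baseline.

    MSE is averaged over all ``k_out`` predicted frames; NMSE per step is
    the MSE of that step divided by the mean square of its target frame;
    the Wilcoxon signed-rank test is two-sided on the paired per-simulation
    (model, baseline) MSEs.
    """
    if len(sims) == 0:
        raise ValueError("empty test set")
    data = _stack_sims(sims)
    c = model.config
    inputs = data[:, :c.kb]
    targets = data[:, c.kb:c.kb + c.k_out]
    preds = model.predict_rollout(inputs)
    err2 = (preds - targets) ** 2
    mse_per_sim = err2.mean(axis=(1, 2, 3))
    base = np.repeat(inputs[:, -1:], c.k_out, axis=1)
    base_per_sim = ((base - targets) ** 2).mean(axis=(1, 2, 3))
    denom = (targets ** 2).mean(axis=(0, 2, 3))
    nmse_per_step = np.where(denom > 0, err2.mean(axis=(0, 2, 3)) / denom, np.inf)
    diff = mse_per_sim - base_per_sim
    if np.allclose(diff, 0):
        p = 1.0
    else:
        p = float(wilcoxon(mse_per_sim, base_per_sim,
                           alternative="two-sided").pvalue)
    return EvalMetrics(mse_per_sim=mse_per_sim,
                       baseline_mse_per_sim=base_per_sim,
                       nmse_per_step=nmse_per_step, wilcoxon_p=p)


def crossvalidate(sims, config: SurrogateConfig,
                  rng: np.random.Generator | int | None = None):
    """K-fold cross-validation: train on k-1 folds (with the usual internal
    validation split), evaluate on the held-out fold. Returns the per-fold
    metrics and the fold assignment."""
    data = _stack_sims(sims)
    n = data.shape[0]
    if n < config.folds:
        raise ValueError(f"{n} simulations cannot fill {config.folds} folds")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    perm = rng.permutation(n)
    folds = np.array_split(perm, config.folds)
    results = []
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        model = build(config, np.random.default_rng([config.seed, k]))
        train(model, data[train_idx], config,
              rng=np.random.default_rng([config.seed, k, 1]))
        results.append(evaluate(model, data[test_idx]))
    return results, folds


def aggregate_mse(results: Sequence[EvalMetrics], folds) -> float:
    """Fold-size-weighted mean of fold MSEs."""
    total = sum(m.mse * len(f) for m, f in zip(results, folds))
    return total / sum(len(f) for f in folds)


def save_checkpoint(model: SurrogateModel, path: str) -> None:
    """Single-file checkpoint: weights, batch-norm stats, config, log."""
    state = model.state_dict()
    arrays = {f"p{i}": a for i, a in enumerate(state["params"])}
    for i, (m, v) in enumerate(state["bn_stats"]):
        arrays[f"bnm{i}"], arrays[f"bnv{i}"] = m, v
    np.savez(path,
             config=json.dumps(asdict(model.config)),
             norm_scale=model.norm_scale,
             n_params=len(state["params"]),
             n_bn=len(state["bn_stats"]),
             train_log=json.dumps(model.train_log),
             **arrays)


def load_checkpoint(path: str) -> SurrogateModel:
    z = np.load(path, allow_pickle=False)
    cfg_d = json.loads(str(z["config"]))
    cfg_d["encoder_channels"] = tuple(cfg_d["encoder_channels"])
    cfg_d["decoder_channels"] = tuple(cfg_d["decoder_channels"])
    config = SurrogateConfig(**cfg_d)
    model = build(config, np.random.default_rng(0))
    state = {
        "params": [z[f"p{i}"] for i in range(int(z["n_params"]))],
        "bn_stats": [(z[f"bnm{i}"], z[f"bnv{i}"]) for i in range(int(z["n_bn"]))],
        "norm_scale": float(z["norm_scale"]),
    }
    model.load_state_dict(state)
    model.train_log = json.loads(str(z["train_log"]))
    return model
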