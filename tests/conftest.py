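"""Shared fixtures.

The expensive fixtures (the scaled-down forecasting study) are
session-scoped so the surrogate is trained once and shared between the
baseline-comparison and parameter-readout checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from epmodkit.diffusion_sim import simulate_scenario_seed
from epmodkit.param_readout import (LatentStack, ReadoutConfig,
                                    evaluate_readout, extract_latents,
                                    train_readout)
from epmodkit.surrogate import SurrogateConfig, build, evaluate, train

# Scaled-down study conditions: 400 simulations observed on a 16x16 grid
# (solver 32x32), spectrum cut-offs reduced with the grid so the shortest
# retained wavelength spans >= 4 cells as in the full-scale conditions, and
# a frame cadence at which the field decays substantially over the 11-frame
# forecast horizon.
STUDY_SEED = 123
N_SIMS = 400
N_TRAIN = 300
SIM_KW = dict(solver_n=32, n_frames=14, frame_interval=3.2e-2, n_obs=16,
              gen_resolution=32, f0_choices=(2, 3, 4))
SURROGATE_CFG = SurrogateConfig(
    kb=3, kt=4, k_out=11, frame_size=16,
    encoder_channels=(16, 16, 16), lstm_channels=16,
    decoder_channels=(16, 16, 1), epochs=100, batch=16,
    lr0=2e-3, lr_drop_epoch=75, seed=STUDY_SEED)
READOUT_CFG = ReadoutConfig(conv_channels=(32, 32), conv_filter=3,
                            conv_stride=1, epochs=300, lr=1e-3, batch=32,
                            seed=7)


@pytest.fixture(scope="session")
def study_data():
    """Frames + scenarios of the scaled-down forecasting study."""
    sims, scens = [], []
    for k in range(N_SIMS):
        seq = simulate_scenario_seed([STUDY_SEED, k], **SIM_KW)
        sims.append(seq.frames)
        scens.append(seq.scenario)
    return np.array(sims), scens


@pytest.fixture(scope="session")
def trained_study(study_data):
    """Surrogate trained on the study's training split, with held-out
    forecast metrics."""
    sims, scens = study_data
    model = build(SURROGATE_CFG, STUDY_SEED)
    train(model, sims[:N_TRAIN], SURROGATE_CFG, rng=STUDY_SEED)
    metrics = evaluate(model, sims[N_TRAIN:])
    return model, metrics


@pytest.fixture(scope="session")
def readout_correlations(study_data, trained_study):
    """Held-out per-parameter correlations of the latent readout."""
    sims, scens = study_data
    model, _ = trained_study
    lat = extract_latents(model, sims[:, :SURROGATE_CFG.kb])
    readout = train_readout(LatentStack(lat.activity[:N_TRAIN]),
                            scens[:N_TRAIN], rng=READOUT_CFG.seed,
                            config=READOUT_CFG)
    return evaluate_readout(readout, LatentStack(lat.activity[N_TRAIN:]),
                            scens[N_TRAIN:])


@pytest.fixture()
def tiny_surrogate_config():
    return SurrogateConfig(kb=3, kt=2, k_out=5, frame_size=16,
                           encoder_channels=(4, 4, 4), lstm_channels=4,
                           decoder_channels=(4, 4, 1), epochs=10, batch=4,
                           lr0=2e-3, lr_drop_epoch=1000, seed=0)


@pytest.fixture()
def toy_sims(tiny_surrogate_config):
    """Smooth decaying toy sequences for fast surrogate unit tests."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(42)
    cfg = tiny_surrogate_config
    T = cfg.kb + cfg.k_out
    sims = []
    for _ in range(12):
        base = gaussian_filter(rng.standard_normal((16, 16)), 2.0)
        sims.append(np.stack([base * np.exp(-0.2 * t) for t in range(T)]))
    return np.array(sims)
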