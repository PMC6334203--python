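"""Finite-difference solver for heterogeneous anisotropic 2D diffusion.

Solves ``dv/dt = div(D grad v)`` on the square domain [-2, 2]^2 with zero
Dirichlet boundary data, where ``D = diag(d0(x, y), d1(x, y))`` is a
per-cell diagonal diffusion tensor. Space is discretised with second-order
flux-conservative finite differences on a cell-centred grid (face
diffusivities are arithmetic means of the adjacent cells; the boundary
condition enters through ghost cells mirrored with a sign flip), and time
with explicit Euler under the usual parabolic stability bound. Frame
sequences are restricted to a regular 64x64 observation grid by cell
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .scenario_gen import (DiffusionScenario, InitialField, SpectrumConfig,
                           generate_initial_field, interpolate_to_mesh,
                           rasterise_field, sample_scenario,
                           sample_spectrum_config)

DOMAIN_WIDTH = 4.0


@dataclass(frozen=True)
class GridSpec:
    """A regular cell-centred grid over [-2, 2]^2 with nx x ny cells."""

    nx: int = 128
    ny: int = 128

    def __post_init__(self) -> None:
        if self.nx < 16 or self.ny < 16:
            raise ValueError("grid must have at least 16 cells per side")

    @property
    def dx(self) -> float:
        return DOMAIN_WIDTH / self.nx

    @property
    def dy(self) -> float:
        return DOMAIN_WIDTH / self.ny


@dataclass
class FrameSequence:
    """Time-ordered snapshots of the diffusing field on the observation grid."""

    frames: np.ndarray  # (n_frames, n_obs, n_obs)
    frame_interval: float
    t0: float = 0.0
    scenario_id: int | None = None
    scenario: DiffusionScenario | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, nx, ny)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def stable_dt(grid: GridSpec, d_field: np.ndarray) -> float:
    """Admissible explicit time step: min(dx, dy)^2 / (4 * max diffusivity)."""
    d_max = float(np.max(d_field))
    return min(grid.dx, grid.dy) ** 2 / (4.0 * d_max)


def step(v: np.ndarray, d_field: np.ndarray, dt: float,
         grid: GridSpec | None = None) -> np.ndarray:
    """One explicit Euler update of the flux-conservative discretisation.

    ``v`` is the cell-centred field (nx, ny) with axis 0 horizontal;
    ``d_field`` holds per-cell (d_horizontal, d_vertical) pairs, shape
    (nx, ny, 2). Zero Dirichlet data on the domain boundary is imposed via
    ghost cells ``v_ghost = -v_edge`` so the wall value vanishes.

    Raises ``ValueError`` when ``dt`` exceeds the stability bound.
    """
    if grid is None:
        grid = GridSpec(nx=v.shape[0], ny=v.shape[1])
    dt_max = stable_dt(grid, d_field)
    if dt > dt_max * (1.0 + 1e-12):
        raise ValueError(
            f"dt={dt:g} violates the explicit stability bound; "
            f"use dt <= {dt_max:g}"
        )
    dx2, dy2 = grid.dx**2, grid.dy**2
    d0 = d_field[..., 0]
    d1 = d_field[..., 1]

    # interior face fluxes (times face diffusivity), divided differences
    fx = 0.5 * (d0[1:, :] + d0[:-1, :]) * (v[1:, :] - v[:-1, :])  # (nx-1, ny)
    fy = 0.5 * (d1[:, 1:] + d1[:, :-1]) * (v[:, 1:] - v[:, :-1])  # (nx, ny-1)

    lap = np.zeros_like(v)
    lap[:-1, :] += fx / dx2
    lap[1:, :] -= fx / dx2
    lap[:, :-1] += fy / dy2
    lap[:, 1:] -= fy / dy2
    # boundary faces: ghost value -v gives flux d * (-2 v)
    lap[0, :] += d0[0, :] * (-2.0 * v[0, :]) / dx2
    lap[-1, :] += d0[-1, :] * (-2.0 * v[-1, :]) / dx2
    lap[:, 0] += d1[:, 0] * (-2.0 * v[:, 0]) / dy2
    lap[:, -1] += d1[:, -1] * (-2.0 * v[:, -1]) / dy2

    out = v + dt * lap
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("diffusion step produced non-finite values")
    return out


def restrict(v: np.ndarray, n_obs: int) -> np.ndarray:
    """Area-weighted restriction of a solver field onto n_obs x n_obs by
    block averaging; requires the solver side to be a multiple of n_obs."""
    n = v.shape[0]
    if n % n_obs != 0:
        raise ValueError(f"solver grid {n} is not a multiple of {n_obs}")
    k = n // n_obs
    return v.reshape(n_obs, k, n_obs, k).mean(axis=(1, 3))


def simulate(scenario: DiffusionScenario, v0: np.ndarray, n_frames: int = 20,
             frame_interval: float = 1e-3, *, n_obs: int = 64,
             grid: GridSpec | None = None, cfl_safety: float = 0.9,
             scenario_id: int | None = None) -> FrameSequence:
    """Run the diffusion model and store ``n_frames`` snapshots.

    The first stored frame is the initial condition itself (restricted to the
    observation grid); each subsequent frame advances ``frame_interval`` time
    units with automatic sub-stepping under the stability bound.
    """
    if n_frames < 14:
        raise ValueError("need at least 14 frames per simulation")
    v = np.array(v0, dtype=float)
    if grid is None:
        grid = GridSpec(nx=v.shape[0], ny=v.shape[1])
    d_field = scenario.d_field
    if d_field is None or d_field.shape[:2] != v.shape:
        d_field = rasterise_field(scenario, v.shape)

    dt_max = cfl_safety * stable_dt(grid, d_field)
    n_sub = max(1, int(np.ceil(frame_interval / dt_max)))
    dt = frame_interval / n_sub

    frames = np.empty((n_frames, n_obs, n_obs))
    frames[0] = restrict(v, n_obs)
    for k in range(1, n_frames):
        for _ in range(n_sub):
            v = step(v, d_field, dt, grid)
        frames[k] = restrict(v, n_obs)
    return FrameSequence(frames=frames, frame_interval=frame_interval,
                         scenario_id=scenario_id, scenario=scenario)


def simulate_scenario_seed(sim_seed: Sequence[int] | int, *, solver_n: int = 128,
                           n_frames: int = 20, frame_interval: float = 1e-3,
                           n_obs: int = 64, gen_resolution: int = 128,
                           f0_choices=None,
                           scenario_id: int | None = None) -> FrameSequence:
    """Generate one scenario + initial field from a seed and simulate it.

    ``f0_choices`` overrides the spectrum cut-off set for scaled-down
    observation grids (see :func:`epmodkit.scenario_gen.sample_spectrum_config`).
    """
    rng = np.random.default_rng(sim_seed)
    kw = {} if f0_choices is None else {"f0_choices": tuple(f0_choices)}
    cfg = sample_spectrum_config(rng, gen_resolution=gen_resolution, **kw)
    fld = generate_initial_field(cfg, rng)
    scen = sample_scenario(rng, (solver_n, solver_n))
    v0 = interpolate_to_mesh(fld, (solver_n, solver_n))
    return simulate(scen, v0, n_frames, frame_interval, n_obs=n_obs,
                    scenario_id=scenario_id)


SCENARIO_KEYS = ("theta", "beta", "d0", "d1", "d0_scar", "d1_scar",
                 "gamma", "lam")


def _write_sim(h5, k: int, seq: FrameSequence, sim_seed: int) -> None:
    g = h5.create_group(f"sim/{k}")
    g.create_dataset("frames", data=seq.frames)
    sg = g.create_group("scenario")
    scen = seq.scenario
    for key in SCENARIO_KEYS:
        sg.attrs[key] = getattr(scen, key)
    sg.attrs["fast_axis"] = scen.fast_axis
    sg.attrs["seed"] = sim_seed
    g.attrs["frame_interval"] = seq.frame_interval


def batch_simulate(n: int, seed: int, out: str, *, solver_n: int = 128,
                   n_frames: int = 20, frame_interval: float = 1e-3,
                   n_obs: int = 64, gen_resolution: int = 128,
                   resume: bool = False, progress: bool = False) -> str:
    """Simulate ``n`` independent scenarios into an HDF5 archive.

    Per-simulation seeds are derived deterministically from the master seed,
    so an interrupted run resumed with ``resume=True`` produces an archive
    bit-identical to an uninterrupted one.
    """
    import h5py

    import os
    mode = "a" if (resume and os.path.exists(out)) else "w-"
    if not resume and os.path.exists(out):
        raise FileExistsError(
            f"{out} exists; pass resume=True to continue a partial archive")
    with h5py.File(out, mode) as h5:
        h5.attrs["master_seed"] = seed
        h5.attrs["solver_n"] = solver_n
        h5.attrs["n_obs"] = n_obs
        h5.attrs["frame_interval"] = frame_interval
        for k in range(n):
            if f"sim/{k}" in h5:
                continue
            sim_seed = [seed, k]
            seq = simulate_scenario_seed(
                sim_seed, solver_n=solver_n, n_frames=n_frames,
                frame_interval=frame_interval, n_obs=n_obs,
                gen_resolution=gen_resolution, scenario_id=k)
            _write_sim(h5, k, seq, k)
            if progress:
                print(f"simulated {k + 1}/{n}", flush=True)
    return out


def load_archive(path: str) -> List[FrameSequence]:
    """Read every frame sequence (with its scenario) from an archive."""
    import h5py

    from .scenario_gen import DiffusionScenario

    out: List[FrameSequence] = []
    with h5py.File(path, "r") as h5:
        keys = sorted((int(k) for k in h5["sim"]))
        for k in keys:
            g = h5[f"sim/{k}"]
            sa = g["scenario"].attrs
            scen = DiffusionScenario(
                theta=float(sa["theta"]), beta=float(sa["beta"]),
                d0=float(sa["d0"]), d1=float(sa["d1"]),
                d0_scar=float(sa["d0_scar"]), d1_scar=float(sa["d1_scar"]),
                gamma=float(sa["gamma"]), lam=float(sa["lam"]),
                fast_axis=str(sa["fast_axis"]))
            out.append(FrameSequence(frames=g["frames"][()],
                                     frame_interval=float(g.attrs["frame_interval"]),
                                     scenario_id=k, scenario=scen))
    return out


def write_scenario_archive(n: int, seed: int, out: str, *,
                           grid_shape=(128, 128), gen_resolution: int = 128) -> str:
    """Generate ``n`` scenarios + initial fields (no simulation) to HDF5."""
    import h5py

    with h5py.File(out, "w") as h5:
        h5.attrs["master_seed"] = seed
        h5.attrs["gen_resolution"] = gen_resolution
        h5.attrs["grid_nx"], h5.attrs["grid_ny"] = grid_shape
        for k in range(n):
            rng = np.random.default_rng([seed, k])
            cfg = sample_spectrum_config(rng, gen_resolution=gen_resolution)
            fld = generate_initial_field(cfg, rng, seed=k)
            scen = sample_scenario(rng, tuple(grid_shape), seed=k)
            g = h5.create_group(f"scenario/{k}")
            for key in SCENARIO_KEYS:
                g.attrs[key] = getattr(scen, key)
            g.attrs["fast_axis"] = scen.fast_axis
            g.attrs["seed"] = k
            g.attrs["alpha"] = cfg.alpha
            g.attrs["f_0"] = cfg.f_0
            g.create_dataset("initial/values", data=fld.values)
    return out
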