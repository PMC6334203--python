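"""Stochastic scenario generation for the 2D diffusion problem.

Each simulation scenario consists of (a) a spatially smoothed random initial
field built from a power-law Fourier spectrum with a hard frequency cut-off,
and (b) a two-region anisotropic diffusion field: a straight line with random
orientation and offset partitions the square domain into a "healthy" and a
"scarred" region, with diffusivities tied together by an anisotropy ratio
``gamma`` (larger/smaller diagonal diffusivity within a region) and a
heterogeneity ratio ``lam`` (healthy/scar diffusivity, equal on both axes).

All randomness flows through a caller-supplied :class:`numpy.random.Generator`
so scenarios are exactly reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator

DOMAIN_HALF_WIDTH = 2.0  # domain is [-2, 2]^2

ALPHA_CHOICES = (-1.0, -2.0)
F0_CHOICES = (8.0, 12.0, 16.0)
F_C_DEFAULT = 3.0

GAMMA_RANGE = (1.0, 3.0)
LAM_RANGE = (2.0, 7.0)
D_MAX_RANGE = (3.2, 3.8)


@dataclass(frozen=True)
class SpectrumConfig:
    """Spectral shape of the random initial condition.

    The amplitude envelope is ``(fx^2 + fy^2 + f_c)^(alpha/2)`` with a hard
    cut-off (zero amplitude) wherever ``fx^2 + fy^2 >= f_0^2``. Frequencies
    are measured in cycles per domain length.
    """

    alpha: float = -1.0
    f_c: float = F_C_DEFAULT
    f_0: float = 8.0
    gen_resolution: int = 128
    contrast: float = 1.0
    margin_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.f_0 <= 0:
            raise ValueError("f_0 must be positive")
        if self.gen_resolution < 2 * self.f_0:
            raise ValueError(
                f"gen_resolution={self.gen_resolution} violates the Nyquist "
                f"bound 2*f_0={2 * self.f_0}: the cut-off frequency would alias"
            )
        if not 0 < self.margin_frac < 1:
            raise ValueError("margin_frac must lie in (0, 1)")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")


@dataclass(frozen=True)
class DiffusionScenario:
    """Latent parameters of one heterogeneous anisotropic diffusion field.

    ``theta`` (radians, axial in [0, pi)) and ``beta`` (signed perpendicular
    distance from the domain centre, domain units) define the partition line.
    ``(d0, d1)`` are the healthy horizontal/vertical diffusivities and
    ``(d0_scar, d1_scar)`` the scar values; they satisfy exactly

    * ``max(d0, d1) / min(d0, d1) = max(d0_scar, d1_scar) / min(d0_scar, d1_scar) = gamma``
    * ``d0 / d0_scar = d1 / d1_scar = lam``
    """

    theta: float
    beta: float
    d0: float
    d1: float
    d0_scar: float
    d1_scar: float
    gamma: float
    lam: float
    fast_axis: str  # "horizontal" or "vertical"
    scar_positive_side: bool = True
    seed: int | None = None
    d_field: np.ndarray | None = field(default=None, compare=False)

    def with_field(self, d_field: np.ndarray) -> "DiffusionScenario":
        return replace(self, d_field=d_field)


@dataclass(frozen=True)
class InitialField:
    """A smoothed-noise initial condition on the generation grid."""

    values: np.ndarray
    config: SpectrumConfig
    seed: int | None = None


def sample_spectrum_config(rng: np.random.Generator, *, contrast: float = 1.0,
                           gen_resolution: int = 128,
                           f0_choices: Tuple[float, ...] = F0_CHOICES) -> SpectrumConfig:
    """Draw a spectrum configuration: alpha uniform on {-1, -2}, f_0 uniform
    on {8, 12, 16}, corner frequency fixed at f_c = 3.

    ``f0_choices`` exists for scaled-down experiments on coarser observation
    grids, where the cut-off set is reduced proportionally so the shortest
    retained wavelength keeps the same extent in grid cells (>= 4) as the
    default conditions have on the 64x64 grid.
    """
    alpha = float(rng.choice(ALPHA_CHOICES))
    f_0 = float(rng.choice(f0_choices))
    return SpectrumConfig(alpha=alpha, f_c=F_C_DEFAULT, f_0=f_0,
                          gen_resolution=gen_resolution, contrast=contrast)


def _boundary_window(n: int, margin_frac: float) -> np.ndarray:
    """Separable raised-cosine taper, exactly zero on the outermost ring.

    The taper acts over the outer ``margin_frac`` of each half-width.
    """
    x = np.linspace(-1.0, 1.0, n)
    w = np.ones(n)
    edge = 1.0 - margin_frac
    outer = np.abs(x) > edge
    # cosine ramp from 1 at |x| = edge to 0 at |x| = 1
    w[outer] = 0.5 * (1.0 + np.cos(np.pi * (np.abs(x[outer]) - edge) / margin_frac))
    w[0] = w[-1] = 0.0
    return np.outer(w, w)


def generate_initial_field(config: SpectrumConfig, rng: np.random.Generator,
                           *, apply_window: bool = True,
                           seed: int | None = None) -> InitialField:
    """Generate a smoothed-noise field from a random Fourier spectrum.

    A complex spectrum is built as ``envelope * g * exp(i phi)`` with
    ``g ~ N(0, 1)`` amplitude noise and phases uniform on [0, 2pi), then
    conjugate-symmetrised (a bin averaged with the conjugate of its mirror) so
    the inverse transform is real. The field is tapered to zero at the domain
    boundary and scaled so ``max |v0| = contrast``.

    Set ``apply_window=False`` to obtain the raw (pre-taper, pre-normalise)
    field, e.g. for spectral diagnostics.
    """
    n = config.gen_resolution
    f = np.fft.fftfreq(n, d=1.0 / n)  # integer cycles per domain length
    fx, fy = np.meshgrid(f, f, indexing="ij")
    f2 = fx**2 + fy**2

    envelope = (f2 + config.f_c) ** (config.alpha / 2.0)
    envelope[f2 >= config.f_0**2] = 0.0

    amp = rng.standard_normal((n, n))
    phase = rng.uniform(0.0, 2.0 * np.pi, size=(n, n))
    spectrum = envelope * amp * np.exp(1j * phase)

    # conjugate symmetrisation: average each bin with the conjugate of its
    # mirror bin S[-k]; the result satisfies S[k] = conj(S[-k]) exactly.
    mirror = spectrum[np.ix_(-np.arange(n) % n, -np.arange(n) % n)]
    spectrum = 0.5 * (spectrum + np.conj(mirror))

    fld = np.fft.ifft2(spectrum)
    peak = np.max(np.abs(fld)) or 1.0
    if np.max(np.abs(fld.imag)) > 1e-10 * peak:
        raise AssertionError("conjugate symmetrisation failed to yield a real field")
    values = fld.real

    if apply_window:
        values = values * _boundary_window(n, config.margin_frac)
        m = np.max(np.abs(values))
        if m > 0:
            values = values * (config.contrast / m)
    return InitialField(values=values, config=config, seed=seed)


def sample_scenario(rng: np.random.Generator,
                    grid_shape: Tuple[int, int] | None = None,
                    *, seed: int | None = None) -> DiffusionScenario:
    """Draw one diffusion scenario.

    theta ~ U[0, pi); beta ~ U[-1, 1]; gamma ~ U[1, 3]; lam ~ U[2, 7];
    the fast axis is chosen uniformly and given a diffusivity from
    U[3.2, 3.8]; the slow axis gets that value divided by gamma; scar
    diffusivities are the healthy ones divided by lam. Which side of the
    partition line is scarred is itself a fair coin flip.
    """
    theta = float(rng.uniform(0.0, np.pi))
    beta = float(rng.uniform(-1.0, 1.0))
    gamma = float(rng.uniform(*GAMMA_RANGE))
    lam = float(rng.uniform(*LAM_RANGE))
    fast_axis = "horizontal" if rng.random() < 0.5 else "vertical"
    d_max = float(rng.uniform(*D_MAX_RANGE))
    scenario = make_scenario(theta=theta, beta=beta, gamma=gamma, lam=lam,
                             fast_axis=fast_axis, d_max=d_max,
                             scar_positive_side=bool(rng.random() < 0.5),
                             seed=seed)
    if grid_shape is not None:
        scenario = scenario.with_field(rasterise_field(scenario, grid_shape))
    return scenario


def make_scenario(*, theta: float, beta: float, gamma: float, lam: float,
                  fast_axis: str, d_max: float,
                  scar_positive_side: bool = True,
                  seed: int | None = None) -> DiffusionScenario:
    """Construct a scenario with the diffusivity ratio constraints applied
    exactly (useful for deterministic fixtures)."""
    if fast_axis not in ("horizontal", "vertical"):
        raise ValueError("fast_axis must be 'horizontal' or 'vertical'")
    d_slow = d_max / gamma
    if fast_axis == "horizontal":
        d0, d1 = d_max, d_slow
    else:
        d0, d1 = d_slow, d_max
    return DiffusionScenario(
        theta=theta, beta=beta, d0=d0, d1=d1,
        d0_scar=d0 / lam, d1_scar=d1 / lam,
        gamma=gamma, lam=lam, fast_axis=fast_axis,
        scar_positive_side=scar_positive_side, seed=seed,
    )


def cell_centres(grid_shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    """Cell-centre coordinates of an (nx, ny) grid covering [-2, 2]^2.

    Index convention: axis 0 is x (horizontal), axis 1 is y (vertical)."""
    nx, ny = grid_shape
    L = DOMAIN_HALF_WIDTH
    xc = -L + (np.arange(nx) + 0.5) * (2 * L / nx)
    yc = -L + (np.arange(ny) + 0.5) * (2 * L / ny)
    return xc, yc


def scar_mask(scenario: DiffusionScenario, grid_shape: Tuple[int, int]) -> np.ndarray:
    """Boolean mask of scar cells: cells whose centre lies on the scar side
    of the line with direction (cos theta, sin theta) offset beta along the
    normal (-sin theta, cos theta)."""
    xc, yc = cell_centres(grid_shape)
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    nx_, ny_ = -np.sin(scenario.theta), np.cos(scenario.theta)
    signed = X * nx_ + Y * ny_ - scenario.beta
    return (signed > 0) if scenario.scar_positive_side else (signed <= 0)


def rasterise_field(scenario: DiffusionScenario,
                    grid_shape: Tuple[int, int]) -> np.ndarray:
    """Per-cell (d_horizontal, d_vertical) pairs, shape (nx, ny, 2).

    Every cell takes exactly one of the two diffusivity pairs according to
    which side of the partition line its centre falls on.
    """
    mask = scar_mask(scenario, grid_shape)
    d = np.empty(grid_shape + (2,), dtype=float)
    d[..., 0] = np.where(mask, scenario.d0_scar, scenario.d0)
    d[..., 1] = np.where(mask, scenario.d1_scar, scenario.d1)
    return d


def interpolate_to_mesh(fld: InitialField | np.ndarray,
                        grid_shape: Tuple[int, int]) -> np.ndarray:
    """Bilinear interpolation of a generation-grid field onto solver cell
    centres. Source samples are taken as nodes spanning [-2, 2]."""
    values = fld.values if isinstance(fld, InitialField) else np.asarray(fld)
    n = values.shape[0]
    L = DOMAIN_HALF_WIDTH
    src = np.linspace(-L, L, n)
    interp = RegularGridInterpolator((src, src), values, method="linear",
                                     bounds_error=True)
    xc, yc = cell_centres(grid_shape)
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    return interp(np.stack([X.ravel(), Y.ravel()], axis=-1)).reshape(grid_shape)


def interpolate_to_nodes(fld: InitialField | np.ndarray, n_target: int) -> np.ndarray:
    """Bilinear interpolation onto an n_target x n_target node grid spanning
    [-2, 2]; values at shared nodes are preserved."""
    values = fld.values if isinstance(fld, InitialField) else np.asarray(fld)
    n = values.shape[0]
    L = DOMAIN_HALF_WIDTH
    src = np.linspace(-L, L, n)
    tgt = np.linspace(-L, L, n_target)
    interp = RegularGridInterpolator((src, src), values, method="linear",
                                     bounds_error=True)
    X, Y = np.meshgrid(tgt, tgt, indexing="ij")
    return interp(np.stack([X.ravel(), Y.ravel()], axis=-1)).reshape(n_target, n_target)
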