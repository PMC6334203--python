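"""Fast sodium channel model and simulated patch-clamp protocols.

The channel carries the current ``I_Na = G_Na * m^3 * h * j * (V - E_Na)``
with an activation gate ``m``, a fast inactivation gate ``h`` and a slow
inactivation gate ``j``. Steady states are Boltzmann sigmoids,

    m_inf(V) = 1 / (1 + exp((p1 + V) / p2))          (p2 < 0: rises with V)
    h_inf(V) = j_inf(V) = 1 / (1 + exp((q1 + V) / q2))   (q2 > 0: falls)

and the activation time constant is the inverse of a sum of two rate terms,

    tau_m(V) = { p3 (V + p4) / [1 - exp(p5 (V + p4))] + p6 exp(-V / p7) }^-1,

with a removable singularity at V = -p4 where the first term tends to
-p3/p5. The inactivation time constants are held fixed (they are not probed
by the steady-state-dominated protocols and are excluded from inference).

Units are mV and ms throughout; the conductance is normalised (G_Na = 1)
because every protocol summary is normalised to unit peak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Sequence

import numpy as np

# Published parameter values of the rat-ventricle fast sodium channel, and
# the uniform prior bounds (roughly an order of magnitude wide) used when
# the nine kinetic parameters are inferred.
ORIG_PARAMS: Dict[str, float] = {
    "p1": 45.0, "p2": -6.5, "p3": 0.235, "p4": 47.1, "p5": -0.1,
    "p6": 0.0588, "p7": 11.0, "q1": 76.1, "q2": 6.07,
}
PRIOR_BOUNDS: Dict[str, tuple] = {
    "p1": (0.0, 100.0), "p2": (-50.0, 0.0), "p3": (0.0, 1.0),
    "p4": (0.0, 100.0), "p5": (-50.0, 0.0), "p6": (0.0, 1.0),
    "p7": (0.0, 1000.0), "q1": (0.0, 100.0), "q2": (0.0, 50.0),
}
INFERABLE = tuple(ORIG_PARAMS)

PROTOCOL_IDS = ("activation_iv", "activation_gv", "inactivation",
                "pulse_train", "recovery")


@dataclass(frozen=True)
class ChannelParams:
    """Kinetic parameters plus fixed conductance / reversal / inactivation
    time-constant settings (the latter are not inferred)."""

    p1: float = ORIG_PARAMS["p1"]
    p2: float = ORIG_PARAMS["p2"]
    p3: float = ORIG_PARAMS["p3"]
    p4: float = ORIG_PARAMS["p4"]
    p5: float = ORIG_PARAMS["p5"]
    p6: float = ORIG_PARAMS["p6"]
    p7: float = ORIG_PARAMS["p7"]
    q1: float = ORIG_PARAMS["q1"]
    q2: float = ORIG_PARAMS["q2"]
    g_na: float = 1.0
    e_na: float = 65.0  # mV
    tau_h: float = 5.0  # ms, fixed
    tau_j: float = 50.0  # ms, fixed

    @classmethod
    def from_dict(cls, d: Dict[str, float], **fixed) -> "ChannelParams":
        return cls(**{**d, **fixed})

    def to_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in INFERABLE}

    def replace(self, **kw) -> "ChannelParams":
        return replace(self, **kw)


@dataclass
class GateState:
    """Gate occupancies and clamp voltage at one instant."""

    m: float
    h: float
    j: float
    v: float
    t: float = 0.0


def _sigmoid(z):
    # 1/(1+exp(z)) with overflow saturated to 0/1
    z = np.clip(z, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


def m_inf(v, params: ChannelParams):
    """Steady-state activation."""
    return _sigmoid((params.p1 + np.asarray(v, dtype=float)) / params.p2)


def h_inf(v, params: ChannelParams):
    """Steady-state (fast and slow) inactivation; j_inf is identical."""
    return _sigmoid((params.q1 + np.asarray(v, dtype=float)) / params.q2)


j_inf = h_inf


def tau_m(v, params: ChannelParams):
    """Activation time constant in ms; the removable singularity at
    V = -p4 is evaluated by its analytic limit -p3/p5."""
    v = np.asarray(v, dtype=float)
    u = v + params.p4
    with np.errstate(over="ignore"):
        expo = np.exp(np.clip(params.p5 * u, -700.0, 700.0))
    denom = 1.0 - expo
    near = np.abs(u) < 1e-7
    safe = np.where(near, 1.0, denom)
    a = np.where(near, -params.p3 / params.p5, params.p3 * u / safe)
    b = params.p6 * np.exp(np.clip(-v / params.p7, -700.0, 700.0))
    out = 1.0 / (a + b)
    return out if out.ndim else float(out)


def i_na(state: GateState, params: ChannelParams) -> float:
    """Normalised sodium current G_Na m^3 h j (V - E_Na) (negative = inward)."""
    return params.g_na * state.m**3 * state.h * state.j * (state.v - params.e_na)


def gate_step(state: GateState, v_clamp: float, dt: float,
              params: ChannelParams) -> GateState:
    """Exact exponential relaxation of each gate at a fixed clamp voltage:
    ``g(t+dt) = g_inf + (g - g_inf) exp(-dt / tau_g)``. The update is a
    convex combination, so gates cannot leave [0, 1]."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return GateState(m=state.m, h=state.h, j=state.j, v=v_clamp, t=state.t)
    em = np.exp(-dt / tau_m(v_clamp, params))
    eh = np.exp(-dt / params.tau_h)
    ej = np.exp(-dt / params.tau_j)
    mi = float(m_inf(v_clamp, params))
    hi = float(h_inf(v_clamp, params))
    return GateState(
        m=mi + (state.m - mi) * em,
        h=hi + (state.h - hi) * eh,
        j=hi + (state.j - hi) * ej,
        v=v_clamp, t=state.t + dt,
    )


@dataclass(frozen=True)
class SummaryCurve:
    """A normalised protocol summary: y vs voltage / interval / pulse index."""

    protocol_id: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")


@dataclass(frozen=True)
class ProtocolConfig:
    """Voltage-step protocol settings (holding potentials in mV, durations
    in ms). Defaults are explicit, configurable stand-ins for standard
    activation / inactivation / recovery protocols."""

    v_hold: float = -80.0
    act_v: tuple = (-60.0, 30.0, 5.0)  # start, stop, step (mV)
    act_dur: float = 20.0
    inact_prepulse_v: tuple = (-120.0, -20.0, 5.0)
    inact_prepulse_dur: float = 500.0
    inact_test_v: float = -20.0
    inact_test_dur: float = 20.0
    train_n: int = 20
    train_v: float = -20.0
    train_dur: float = 20.0
    train_gap: float = 50.0
    rec_v: float = -20.0
    rec_pulse_dur: float = 20.0
    rec_intervals: tuple = tuple(np.round(np.logspace(0, np.log10(500.0), 12), 3))
    dt: float = 0.01  # ms, current sampling resolution for peak detection


def _rest_state(params: ChannelParams, cfg: ProtocolConfig) -> GateState:
    return GateState(m=float(m_inf(cfg.v_hold, params)),
                     h=float(h_inf(cfg.v_hold, params)),
                     j=float(h_inf(cfg.v_hold, params)), v=cfg.v_hold)


def _peak_current(state: GateState, v: float, dur: float,
                  params: ChannelParams, dt: float) -> tuple:
    """Advance ``state`` through a clamp step, returning (peak |I| signed
    value at the peak, state at end of step)."""
    n = max(1, int(round(dur / dt)))
    # gate trajectories are analytic at fixed v: evaluate on the time grid
    t = dt * np.arange(1, n + 1)
    mi = float(m_inf(v, params))
    hi = float(h_inf(v, params))
    tm = float(tau_m(v, params))
    m = mi + (state.m - mi) * np.exp(-t / tm)
    h = hi + (state.h - hi) * np.exp(-t / params.tau_h)
    j = hi + (state.j - hi) * np.exp(-t / params.tau_j)
    cur = params.g_na * m**3 * h * j * (v - params.e_na)
    k = int(np.argmax(np.abs(cur)))
    end = GateState(m=float(m[-1]), h=float(h[-1]), j=float(j[-1]), v=v,
                    t=state.t + dur)
    return float(cur[k]), end


def _normalise(y: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(y))
    return y / peak if peak > 0 else y


def run_protocol(protocol_id: str, params: ChannelParams,
                 cfg: ProtocolConfig | None = None) -> SummaryCurve:
    """Simulate one of the five patch-clamp protocols and return its
    normalised summary curve. Deterministic."""
    cfg = cfg or ProtocolConfig()
    if protocol_id in ("activation_iv", "activation_gv"):
        lo, hi, dv = cfg.act_v
        volts = np.arange(lo, hi + dv / 2, dv)
        peaks = []
        for v in volts:
            pk, _ = _peak_current(_rest_state(params, cfg), v, cfg.act_dur,
                                  params, cfg.dt)
            peaks.append(pk)
        peaks = np.asarray(peaks)
        if protocol_id == "activation_iv":
            return SummaryCurve(protocol_id, volts, _normalise(peaks))
        g = peaks / (volts - params.e_na)
        return SummaryCurve(protocol_id, volts, _normalise(g))

    if protocol_id == "inactivation":
        lo, hi, dv = cfg.inact_prepulse_v
        volts = np.arange(lo, hi + dv / 2, dv)
        peaks = []
        for vp in volts:
            st = _rest_state(params, cfg)
            st = gate_step(st, vp, cfg.inact_prepulse_dur, params)
            pk, _ = _peak_current(st, cfg.inact_test_v, cfg.inact_test_dur,
                                  params, cfg.dt)
            peaks.append(abs(pk))
        return SummaryCurve(protocol_id, volts, _normalise(np.asarray(peaks)))

    if protocol_id == "pulse_train":
        st = _rest_state(params, cfg)
        peaks = []
        for _ in range(cfg.train_n):
            pk, st = _peak_current(st, cfg.train_v, cfg.train_dur,
                                   params, cfg.dt)
            peaks.append(abs(pk))
            st = gate_step(st, cfg.v_hold, cfg.train_gap, params)
        idx = np.arange(1, cfg.train_n + 1, dtype=float)
        return SummaryCurve(protocol_id, idx, _normalise(np.asarray(peaks)))

    if protocol_id == "recovery":
        fracs = []
        for gap in cfg.rec_intervals:
            st = _rest_state(params, cfg)
            p1_, st = _peak_current(st, cfg.rec_v, cfg.rec_pulse_dur,
                                    params, cfg.dt)
            st = gate_step(st, cfg.v_hold, float(gap), params)
            p2_, _ = _peak_current(st, cfg.rec_v, cfg.rec_pulse_dur,
                                   params, cfg.dt)
            fracs.append(abs(p2_) / abs(p1_) if p1_ != 0 else 0.0)
        return SummaryCurve(protocol_id, np.asarray(cfg.rec_intervals, float),
                            _normalise(np.asarray(fracs)))

    raise ValueError(f"unknown protocol_id {protocol_id!r}; "
                     f"expected one of {PROTOCOL_IDS}")


def steady_state_curves(params: ChannelParams,
                        v_grid: Sequence[float]) -> Dict[str, SummaryCurve]:
    """Analytic steady-state activation and inactivation curves on a voltage
    grid — the fast deterministic summaries used as ABC observations in the
    recovery experiments."""
    v = np.asarray(v_grid, dtype=float)
    if np.any(np.diff(v) <= 0):
        raise ValueError("v_grid must be strictly increasing")
    return {
        "ss_activation": SummaryCurve("ss_activation", v, m_inf(v, params)),
        "ss_inactivation": SummaryCurve("ss_inactivation", v, h_inf(v, params)),
    }
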