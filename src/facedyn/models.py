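"""Recurrent linear dynamical network models of the IT hierarchy.

Every model is a cascade of leaky-integrator rate stages driven by a
sigmoidally ramped step input.  The two-stage networks have two inputs u
feeding two hidden units x that converge onto one output unit y
(A = aI, B = b[1,1]); the three-stage networks have four inputs u feeding
four hidden units w, converging pairwise onto two units x
(B = b[[1,1,0,0],[0,0,1,1]]) and then onto one output y (C = c[1,1]).

Architectures:

* ``feedforward`` -- pure cascade, leak only.
* ``lateral_inhibition`` -- mutual inhibition (weight k_l) within hidden
  stages.
* ``normalization_linear`` -- subtractive pooled-activity suppression
  (k_s * sum(stage) * unit) at every stage.
* ``normalization_nonlinear`` -- pooled activity nonlinearly scales the
  shunting leak, 1/(tau (1 - k_s sum)); simulated with the fourth-order
  Taylor expansion of the shunt factor around zero.
* ``feedback_linear_reconstruction`` -- gradient descent on the quadratic
  reconstruction cost C = 1/2|u - A^T x|^2 + 1/2|x - B^T y|^2 (per adjacent
  stage pair), giving symmetric feedforward/feedback weights; k_td weights
  the top-down term.
* ``feedback_nonlinear_reconstruction`` -- reconstruction through a
  monotonic nonlinearity f(v) = tanh(v - th) + bi.
* ``feedback_linear_construction`` -- discriminative variant descending
  C = 1/2|Au - x|^2 + 1/2|Bx - y|^2.

Feedback architectures expose the between-stage reconstruction errors
(e0 = u - A^T x, e1 = x - B^T y, ...).  The top-stage error uses an
auxiliary downstream predictor z that relaxes toward the top state
(dz/dt = (y - z)/tau), with a gain parameter (c for two-stage, d for
three-stage models) scaling the error's magnitude: e_top = gain * (y - z).
Readouts square each unit (rectified rates) and sum: sc * sum(units^2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.special import ndtr

ARCHITECTURES = (
    "feedforward",
    "lateral_inhibition",
    "normalization_linear",
    "normalization_nonlinear",
    "feedback_linear_reconstruction",
    "feedback_nonlinear_reconstruction",
    "feedback_linear_construction",
)
FEEDBACK_ARCHITECTURES = ARCHITECTURES[4:]
_ARCH_CODE = {name: i for i, name in enumerate(ARCHITECTURES)}

#: fitting bounds for each parameter (lower, upper)
BOUNDS = {
    "t0": (50.0, 70.0),
    "sigma": (0.5, 25.0),
    "tau": (0.5, 1000.0),
    "a": (0.0, 2.0),
    "b": (0.0, 2.0),
    "c": (0.0, 2.0),
    "d": (0.0, 2.0),
    "k_l": (0.0, 1.0),
    "k_s": (0.0, 1.0),
    "k_td": (0.0, 1.0),
    "h": (0.0, 20.0),
    "sc": (0.0, 100.0),
    "th": (-20.0, 20.0),
    "bi": (-1.0, 1.0),
}

N_CONDITIONS = 2  # typical, atypical


class SimulationError(RuntimeError):
    """The integrated state became non-finite (unstable parameters)."""


@dataclass(frozen=True)
class ModelSpec:
    architecture: str
    n_stages: int = 3
    readout: str = "state"

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.n_stages not in (2, 3):
            raise ValueError("n_stages must be 2 or 3")
        if self.readout not in ("state", "state_and_error"):
            raise ValueError(f"unknown readout {self.readout!r}")
        if self.readout == "state_and_error" and self.architecture not in FEEDBACK_ARCHITECTURES:
            raise ValueError("state_and_error readout requires a feedback architecture")

    @property
    def n_inputs(self) -> int:
        return 2 if self.n_stages == 2 else 4

    @property
    def stage_sizes(self) -> tuple:
        """input -> ... -> top unit counts."""
        return (2, 2, 1) if self.n_stages == 2 else (4, 4, 2, 1)

    @property
    def gain_name(self) -> str | None:
        """The parameter scaling the top-level error (two-stage: c,
        three-stage: d); None for state-only readouts."""
        if self.readout != "state_and_error":
            return None
        return "c" if self.n_stages == 2 else "d"

    def param_names(self) -> list:
        """Free-parameter enumeration for this spec (defines the fit vector).

        The base feedforward enumeration has 10 entries for two-stage models
        (t0, sigma, tau, a, b, four h values, sc) and 15 for three-stage
        (extra weight c and eight h values); recurrent families append their
        coupling constants.
        """
        names = ["t0", "sigma", "tau", "a", "b"]
        if self.n_stages == 3:
            names.append("c")
        names += [f"h{cond + 1}{i + 1}" for cond in range(N_CONDITIONS)
                  for i in range(self.n_inputs)]
        names.append("sc")
        if self.architecture == "lateral_inhibition":
            names.append("k_l")
        elif self.architecture.startswith("normalization"):
            names.append("k_s")
        elif self.architecture in FEEDBACK_ARCHITECTURES:
            names.append("k_td")
            if self.architecture == "feedback_nonlinear_reconstruction":
                names += ["th", "bi"]
            if self.readout == "state_and_error" and self.gain_name not in names:
                names.append(self.gain_name)
        return names

    def bounds(self) -> list:
        return [BOUNDS["h"] if n.startswith("h") else BOUNDS[n] for n in self.param_names()]

    def to_json(self) -> str:
        return json.dumps(self.__dict__ | {})


@dataclass
class ModelParams:
    """Parameter container; ``h`` is (n_conditions, n_inputs)."""

    t0: float = 60.0
    sigma: float = 5.0
    tau: float = 20.0
    a: float = 1.0
    b: float = 1.0
    c: float = 1.0
    d: float = 1.0
    k_l: float = 0.0
    k_s: float = 0.0
    k_td: float = 0.0
    h: np.ndarray = field(default_factory=lambda: np.ones((N_CONDITIONS, 2)))
    sc: float = 1.0
    th: float = 0.0
    bi: float = 0.0

    def __post_init__(self):
        self.h = np.atleast_2d(np.asarray(self.h, dtype=float))
        if np.any(self.h < 0):
            raise ValueError("h amplitudes must be nonnegative")

    def to_vector(self, spec: ModelSpec) -> np.ndarray:
        vec = []
        for name in spec.param_names():
            if name.startswith("h"):
                cond, i = int(name[1]) - 1, int(name[2]) - 1
                vec.append(self.h[cond, i])
            else:
                vec.append(getattr(self, name))
        return np.array(vec, dtype=float)

    @classmethod
    def from_vector(cls, spec: ModelSpec, vec) -> "ModelParams":
        vec = np.asarray(vec, dtype=float)
        names = spec.param_names()
        if vec.size != len(names):
            raise ValueError(f"expected {len(names)} parameters, got {vec.size}")
        kwargs: dict = {"h": np.zeros((N_CONDITIONS, spec.n_inputs))}
        for name, value in zip(names, vec):
            if name.startswith("h"):
                kwargs["h"][int(name[1]) - 1, int(name[2]) - 1] = value
            else:
                kwargs[name] = float(value)
        return cls(**kwargs)


@dataclass
class SimulatedTrace:
    """Per-stage state (and error) time series for each condition."""

    time: np.ndarray                    # (nt,) ms
    states: dict                        # name -> (n_cond, nt, n_units)
    errors: dict                        # name -> (n_cond, nt, n_units)
    spec: ModelSpec
    params: ModelParams


# ---------------------------------------------------------------------------
# input ramp
# ---------------------------------------------------------------------------

def ramp_input(h, t0: float, sigma: float, time_grid) -> np.ndarray:
    """Gaussian-smoothed step input: u(t) = h * Phi((t - t0) / sigma).

    The latency to half height is t0 and the rise time is set by sigma; the
    asymptote is h.  ``h`` may be scalar or an array broadcast against the
    trailing axis of the result.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = np.asarray(time_grid, dtype=float)
    phi = ndtr((t - t0) / sigma)
    h = np.asarray(h, dtype=float)
    if h.ndim == 0:
        return h * phi
    # (..., n_inputs) amplitudes against a (nt,) grid -> (..., nt, n_inputs)
    return h[..., None, :] * phi[:, None]


# ---------------------------------------------------------------------------
# numba integrator core
# ---------------------------------------------------------------------------

@njit(cache=True)
def _phi(v):
    return 0.5 * (1.0 + math.erf(v / math.sqrt(2.0)))


@njit(cache=True)
def _taylor_shunt(v):
    """Fourth-order Taylor expansion of the shunt factor 1/(1 - v) around
    zero.  The exact shunting leak diverges as v -> 1 (an impenetrable
    barrier of the true dynamics), so the expansion is only trusted for
    v < 1; beyond it the state is marked invalid (NaN) rather than letting
    the polynomial wander into a regime the model does not define."""
    if v >= 1.0:
        return np.nan
    return 1.0 + v + v * v + v ** 3 + v ** 4


@njit(cache=True)
def _deriv(arch, nst, s, u, a, b, c, kl, ks, ktd, tau, th, bi, gain):
    """Time derivative of the packed state vector.

    Layout: two-stage [x0, x1, y, z]; three-stage [w0..w3, x0, x1, y, z].
    """
    ds = np.zeros(s.size)
    if nst == 2:
        x0, x1, y, z = s[0], s[1], s[2], s[3]
        sum_x = x0 + x1
        if arch == 0:  # feedforward
            ds[0] = a * u[0] - x0 / tau
            ds[1] = a * u[1] - x1 / tau
            ds[2] = b * sum_x - y / tau
        elif arch == 1:  # lateral inhibition (hidden stage only)
            ds[0] = a * u[0] - kl * x1 - x0 / tau
            ds[1] = a * u[1] - kl * x0 - x1 / tau
            ds[2] = b * sum_x - y / tau
        elif arch == 2:  # normalization, subtractive pooled suppression
            ds[0] = a * u[0] - ks * sum_x * x0 - x0 / tau
            ds[1] = a * u[1] - ks * sum_x * x1 - x1 / tau
            ds[2] = b * sum_x - ks * y * y - y / tau
        elif arch == 3:  # normalization, nonlinear shunt (Taylor-4)
            tx = _taylor_shunt(ks * sum_x)
            ty = _taylor_shunt(ks * y)
            ds[0] = a * u[0] - x0 / tau * tx
            ds[1] = a * u[1] - x1 / tau * tx
            ds[2] = b * sum_x - y / tau * ty
        elif arch == 4:  # feedback, linear reconstruction
            e0_0 = u[0] - a * x0
            e0_1 = u[1] - a * x1
            e1_0 = x0 - b * y
            e1_1 = x1 - b * y
            ds[0] = a * e0_0 - ktd * e1_0 - x0 / tau
            ds[1] = a * e0_1 - ktd * e1_1 - x1 / tau
            ds[2] = b * (e1_0 + e1_1) - y / tau
            ds[3] = (y - z) / tau
        elif arch == 5:  # feedback, nonlinear reconstruction
            p0 = math.tanh(a * x0 - th) + bi
            p1 = math.tanh(a * x1 - th) + bi
            fp0 = 1.0 - math.tanh(a * x0 - th) ** 2
            fp1 = 1.0 - math.tanh(a * x1 - th) ** 2
            py = math.tanh(b * y - th) + bi
            fpy = 1.0 - math.tanh(b * y - th) ** 2
            e1_0 = x0 - py
            e1_1 = x1 - py
            ds[0] = a * fp0 * (u[0] - p0) - ktd * e1_0 - x0 / tau
            ds[1] = a * fp1 * (u[1] - p1) - ktd * e1_1 - x1 / tau
            ds[2] = b * fpy * (e1_0 + e1_1) - y / tau
            ds[3] = (y - z) / tau
        else:  # arch == 6: feedback, linear construction
            g2 = b * sum_x - y
            ds[0] = (a * u[0] - x0) - ktd * b * g2 - x0 / tau
            ds[1] = (a * u[1] - x1) - ktd * b * g2 - x1 / tau
            ds[2] = g2 - y / tau
    else:
        w0, w1, w2, w3 = s[0], s[1], s[2], s[3]
        x0, x1, y, z = s[4], s[5], s[6], s[7]
        sum_w = w0 + w1 + w2 + w3
        bw0 = b * (w0 + w1)
        bw1 = b * (w2 + w3)
        sum_x = x0 + x1
        cx = c * sum_x
        if arch == 0:
            for i in range(4):
                ds[i] = a * u[i] - s[i] / tau
            ds[4] = bw0 - x0 / tau
            ds[5] = bw1 - x1 / tau
            ds[6] = cx - y / tau
        elif arch == 1:
            for i in range(4):
                ds[i] = a * u[i] - kl * (sum_w - s[i]) - s[i] / tau
            ds[4] = bw0 - kl * x1 - x0 / tau
            ds[5] = bw1 - kl * x0 - x1 / tau
            ds[6] = cx - y / tau
        elif arch == 2:
            for i in range(4):
                ds[i] = a * u[i] - ks * sum_w * s[i] - s[i] / tau
            ds[4] = bw0 - ks * sum_x * x0 - x0 / tau
            ds[5] = bw1 - ks * sum_x * x1 - x1 / tau
            ds[6] = cx - ks * y * y - y / tau
        elif arch == 3:
            tw = _taylor_shunt(ks * sum_w)
            tx = _taylor_shunt(ks * sum_x)
            ty = _taylor_shunt(ks * y)
            for i in range(4):
                ds[i] = a * u[i] - s[i] / tau * tw
            ds[4] = bw0 - x0 / tau * tx
            ds[5] = bw1 - x1 / tau * tx
            ds[6] = cx - y / tau * ty
        elif arch == 4:
            e1_0 = w0 - b * x0
            e1_1 = w1 - b * x0
            e1_2 = w2 - b * x1
            e1_3 = w3 - b * x1
            e2_0 = x0 - c * y
            e2_1 = x1 - c * y
            ds[0] = a * (u[0] - a * w0) - ktd * e1_0 - w0 / tau
            ds[1] = a * (u[1] - a * w1) - ktd * e1_1 - w1 / tau
            ds[2] = a * (u[2] - a * w2) - ktd * e1_2 - w2 / tau
            ds[3] = a * (u[3] - a * w3) - ktd * e1_3 - w3 / tau
            ds[4] = b * (e1_0 + e1_1) - ktd * e2_0 - x0 / tau
            ds[5] = b * (e1_2 + e1_3) - ktd * e2_1 - x1 / tau
            ds[6] = c * (e2_0 + e2_1) - y / tau
            ds[7] = (y - z) / tau
        elif arch == 5:
            btx0 = b * x0
            btx1 = b * x1
            cty = c * y
            fpx0 = 1.0 - math.tanh(btx0 - th) ** 2
            fpx1 = 1.0 - math.tanh(btx1 - th) ** 2
            fpy = 1.0 - math.tanh(cty - th) ** 2
            px0 = math.tanh(btx0 - th) + bi
            px1 = math.tanh(btx1 - th) + bi
            py = math.tanh(cty - th) + bi
            e1_0 = w0 - px0
            e1_1 = w1 - px0
            e1_2 = w2 - px1
            e1_3 = w3 - px1
            e2_0 = x0 - py
            e2_1 = x1 - py
            for i in range(4):
                pw = math.tanh(a * s[i] - th) + bi
                fpw = 1.0 - math.tanh(a * s[i] - th) ** 2
                ds[i] = a * fpw * (u[i] - pw) - s[i] / tau
            ds[0] -= ktd * e1_0
            ds[1] -= ktd * e1_1
            ds[2] -= ktd * e1_2
            ds[3] -= ktd * e1_3
            ds[4] = b * (fpx0 * (e1_0 + e1_1)) - ktd * e2_0 - x0 / tau
            ds[5] = b * (fpx1 * (e1_2 + e1_3)) - ktd * e2_1 - x1 / tau
            ds[6] = c * fpy * (e2_0 + e2_1) - y / tau
            ds[7] = (y - z) / tau
        else:  # arch == 6
            g2_0 = bw0 - x0
            g2_1 = bw1 - x1
            g3 = cx - y
            ds[0] = (a * u[0] - w0) - ktd * b * g2_0 - w0 / tau
            ds[1] = (a * u[1] - w1) - ktd * b * g2_0 - w1 / tau
            ds[2] = (a * u[2] - w2) - ktd * b * g2_1 - w2 / tau
            ds[3] = (a * u[3] - w3) - ktd * b * g2_1 - w3 / tau
            ds[4] = g2_0 - ktd * c * g3 - x0 / tau
            ds[5] = g2_1 - ktd * c * g3 - x1 / tau
            ds[6] = g3 - y / tau
    return ds


@njit(cache=True)
def _rk4(arch, nst, n_in, dim, h, t0, sigma, a, b, c, kl, ks, ktd, tau, th, bi,
         gain, t_start, dt, nt):
    n_cond = h.shape[0]
    out = np.zeros((n_cond, nt, dim))
    u = np.zeros(n_in)
    for cond in range(n_cond):
        s = np.zeros(dim)
        for k in range(nt - 1):
            t = t_start + k * dt
            ramp0 = _phi((t - t0) / sigma)
            ramp_h = _phi((t + 0.5 * dt - t0) / sigma)
            ramp1 = _phi((t + dt - t0) / sigma)
            for i in range(n_in):
                u[i] = h[cond, i] * ramp0
            k1 = _deriv(arch, nst, s, u, a, b, c, kl, ks, ktd, tau, th, bi, gain)
            for i in range(n_in):
                u[i] = h[cond, i] * ramp_h
            k2 = _deriv(arch, nst, s + 0.5 * dt * k1, u, a, b, c, kl, ks, ktd, tau, th, bi, gain)
            k3 = _deriv(arch, nst, s + 0.5 * dt * k2, u, a, b, c, kl, ks, ktd, tau, th, bi, gain)
            for i in range(n_in):
                u[i] = h[cond, i] * ramp1
            k4 = _deriv(arch, nst, s + dt * k3, u, a, b, c, kl, ks, ktd, tau, th, bi, gain)
            s = s + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            out[cond, k + 1] = s
    return out


def state_derivative(spec: ModelSpec, params: ModelParams, u, state) -> np.ndarray:
    """Python-level access to the packed-state time derivative (used for
    gradient checks and closed-form comparisons)."""
    gain = getattr(params, spec.gain_name) if spec.gain_name else 0.0
    return _deriv(
        _ARCH_CODE[spec.architecture], spec.n_stages,
        np.asarray(state, dtype=float), np.asarray(u, dtype=float),
        params.a, params.b, params.c, params.k_l, params.k_s, params.k_td,
        params.tau, params.th, params.bi, gain,
    )


# ---------------------------------------------------------------------------
# simulation and readout
# ---------------------------------------------------------------------------

def _unpack(spec: ModelSpec, out: np.ndarray) -> dict:
    if spec.n_stages == 2:
        return {"x": out[:, :, 0:2], "y": out[:, :, 2:3], "z": out[:, :, 3:4]}
    return {"w": out[:, :, 0:4], "x": out[:, :, 4:6], "y": out[:, :, 6:7],
            "z": out[:, :, 7:8]}


def _compute_errors(spec: ModelSpec, params: ModelParams, states: dict,
                    u_traces: np.ndarray) -> dict:
    """Between-stage error time series (feedback architectures only)."""
    if spec.architecture not in FEEDBACK_ARCHITECTURES:
        return {}
    a, b, c = params.a, params.b, params.c
    gain = getattr(params, spec.gain_name) if spec.gain_name else (
        params.c if spec.n_stages == 2 else params.d)
    y = states["y"]
    z = states["z"]
    x = states["x"]

    def f(v):
        return np.tanh(v - params.th) + params.bi

    nonlin = spec.architecture == "feedback_nonlinear_reconstruction"
    pred = (lambda v: f(v)) if nonlin else (lambda v: v)

    if spec.architecture == "feedback_linear_construction":
        if spec.n_stages == 2:
            e0 = a * u_traces - x
            e1 = b * x.sum(axis=2, keepdims=True) - y
            return {"e0": e0, "e1": gain * e1}
        w = states["w"]
        e1 = a * u_traces - w
        bw = np.stack([b * (w[:, :, 0] + w[:, :, 1]), b * (w[:, :, 2] + w[:, :, 3])], axis=2)
        e2 = bw - x
        e3 = c * x.sum(axis=2, keepdims=True) - y
        return {"e1": e1, "e2": e2, "e3": gain * e3}

    if spec.n_stages == 2:
        e0 = u_traces - pred(a * x)
        e1 = x - pred(b * y)
        e2 = gain * (y - z)
        return {"e0": e0, "e1": e1, "e2": e2}
    w = states["w"]
    e0 = u_traces - pred(a * w)
    btx = np.concatenate([b * x[:, :, 0:1], b * x[:, :, 0:1],
                          b * x[:, :, 1:2], b * x[:, :, 1:2]], axis=2)
    e1 = w - pred(btx)
    e2 = x - pred(c * y)
    e3 = gain * (y - z)
    return {"e0": e0, "e1": e1, "e2": e2, "e3": e3}


def simulate(
    spec: ModelSpec,
    params: ModelParams,
    dt: float = 0.5,
    horizon=(0.0, 250.0),
) -> SimulatedTrace:
    """Integrate the architecture's ODEs (explicit RK4, fixed step) from zero
    initial state for every stimulus condition in ``params.h``."""
    if dt > 1.0 or dt <= 0:
        raise ValueError("dt must be in (0, 1] ms")
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    if params.h.shape[1] != spec.n_inputs:
        raise ValueError(
            f"h has {params.h.shape[1]} inputs; spec needs {spec.n_inputs}")
    t_start, t_end = horizon
    nt = int(round((t_end - t_start) / dt)) + 1
    time = t_start + dt * np.arange(nt)
    dim = 4 if spec.n_stages == 2 else 8
    gain = getattr(params, spec.gain_name) if spec.gain_name else (
        params.c if spec.n_stages == 2 else params.d)
    out = _rk4(
        _ARCH_CODE[spec.architecture], spec.n_stages, spec.n_inputs, dim,
        np.ascontiguousarray(params.h, dtype=float), params.t0, params.sigma,
        params.a, params.b, params.c, params.k_l, params.k_s, params.k_td,
        params.tau, params.th, params.bi, gain, float(t_start), float(dt), nt,
    )
    bad = ~np.isfinite(out)
    if bad.any():
        cond, t_idx, s_idx = np.argwhere(bad)[0]
        raise SimulationError(
            f"non-finite state (condition {cond}, state index {s_idx}) "
            f"at t = {time[t_idx]:.1f} ms"
        )
    states = _unpack(spec, out)
    u_traces = params.h[:, None, :] * ndtr((time[None, :, None] - params.t0) / params.sigma)
    errors = _compute_errors(spec, params, states, u_traces)
    return SimulatedTrace(time=time, states=states, errors=errors, spec=spec,
                          params=params)


#: readout source per region: (kind, key) where kind is "state" or "error"
def _readout_map(spec: ModelSpec) -> dict:
    if spec.readout == "state":
        if spec.n_stages == 2:
            return {"pIT": ("state", "x"), "aIT": ("state", "y")}
        return {"pIT": ("state", "w"), "cIT": ("state", "x"), "aIT": ("state", "y")}
    if spec.architecture == "feedback_linear_construction":
        if spec.n_stages == 2:
            return {"pIT": ("error", "e0"), "aIT": ("error", "e1")}
        return {"pIT": ("error", "e1"), "cIT": ("error", "e2"), "aIT": ("error", "e3")}
    if spec.n_stages == 2:
        return {"pIT": ("error", "e1"), "aIT": ("error", "e2")}
    return {"pIT": ("error", "e1"), "cIT": ("error", "e2"), "aIT": ("error", "e3")}


def readout(trace: SimulatedTrace, spec: ModelSpec | None = None,
            params: ModelParams | None = None) -> dict:
    """Map a simulated trace onto per-region model signals.

    Each unit of the region's source (a stage's states, or its
    reconstruction errors for state-and-error models) is squared — the
    smooth stand-in for rectification, since a neuron's firing rate is
    non-negative — and the population signal is the sum of the squared
    units scaled by ``sc``: signal = sc * sum(units^2), shape (n_cond, nt)
    per region.  Squaring per unit (not after summing) matters: it keeps
    the imbalance between channels visible in the population signal, which
    is what lets error populations lose their preference for balanced
    (typical) inputs once feedback cancels the predicted component.
    """
    spec = spec or trace.spec
    params = params or trace.params
    mapping = _readout_map(spec)
    signals = {}
    for region, (kind, key) in mapping.items():
        source = trace.states if kind == "state" else trace.errors
        if key not in source:
            raise ValueError(
                f"trace lacks {kind} {key!r} required by the {spec.readout} readout")
        signals[region] = params.sc * (source[key] ** 2).sum(axis=2)
    return signals


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------

def compute_cost(spec: ModelSpec, params: ModelParams, u, states: dict) -> float:
    """The architecture's cost evaluated at one state snapshot.

    ``states`` holds per-stage vectors ('x', 'y' for two-stage; 'w', 'x',
    'y' for three-stage); ``u`` is the input vector.  Only defined for
    feedback architectures.
    """
    if spec.architecture not in FEEDBACK_ARCHITECTURES:
        raise ValueError(f"{spec.architecture} has no associated cost function")
    a, b, c = params.a, params.b, params.c
    u = np.asarray(u, dtype=float)
    x = np.asarray(states["x"], dtype=float)
    y = np.atleast_1d(np.asarray(states["y"], dtype=float))

    def f(v):
        return np.tanh(v - params.th) + params.bi

    if spec.architecture == "feedback_linear_construction":
        if spec.n_stages == 2:
            return float(0.5 * np.sum((a * u - x) ** 2)
                         + 0.5 * np.sum((b * x.sum() - y) ** 2))
        w = np.asarray(states["w"], dtype=float)
        bw = np.array([b * (w[0] + w[1]), b * (w[2] + w[3])])
        return float(0.5 * np.sum((a * u - w) ** 2)
                     + 0.5 * np.sum((bw - x) ** 2)
                     + 0.5 * np.sum((c * x.sum() - y) ** 2))

    pred = f if spec.architecture == "feedback_nonlinear_reconstruction" else (lambda v: v)
    if spec.n_stages == 2:
        return float(0.5 * np.sum((u - pred(a * x)) ** 2)
                     + 0.5 * np.sum((x - pred(b * y)) ** 2))
    w = np.asarray(states["w"], dtype=float)
    btx = np.array([b * x[0], b * x[0], b * x[1], b * x[1]])
    return float(0.5 * np.sum((u - pred(a * w)) ** 2)
                 + 0.5 * np.sum((w - pred(btx)) ** 2)
                 + 0.5 * np.sum((x - pred(c * y)) ** 2))


def trace_to_frame(trace: SimulatedTrace):
    """Flatten a simulated trace to a long-format table (time, condition,
    one column per state/error unit), e.g. for CSV export."""
    import pandas as pd

    frames = []
    n_cond = next(iter(trace.states.values())).shape[0]
    for cond in range(n_cond):
        data = {"time_ms": trace.time, "condition": cond}
        for source in (trace.states, trace.errors):
            for name, arr in source.items():
                for unit in range(arr.shape[2]):
                    data[f"{name}{unit}"] = arr[cond, :, unit]
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def params_to_json(spec: ModelSpec, params: ModelParams) -> str:
    return json.dumps(
        {
            "spec": {"architecture": spec.architecture, "n_stages": spec.n_stages,
                     "readout": spec.readout},
            "params": {n: v for n, v in zip(spec.param_names(),
                                            params.to_vector(spec).tolist())},
        },
        indent=1,
    )


def params_from_json(text: str) -> tuple[ModelSpec, ModelParams]:
    payload = json.loads(text)
    spec = ModelSpec(**payload["spec"])
    vec = [payload["params"][n] for n in spec.param_names()]
    return spec, ModelParams.from_vector(spec, vec)
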