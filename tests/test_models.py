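"""Dynamical network models: integrator correctness against closed-form
linear-systems oracles, gradient structure of the feedback costs, and the
model family's qualitative invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad_vec
from scipy.linalg import expm
from scipy.special import ndtr

from facedyn.models import (
    ModelParams,
    ModelSpec,
    SimulationError,
    compute_cost,
    ramp_input,
    readout,
    simulate,
    state_derivative,
)


def params_2stage(**kw):
    defaults = dict(t0=60.0, sigma=5.0, tau=40.0, a=0.6, b=0.4, c=0.5,
                    k_l=0.3, k_s=0.02, k_td=0.5,
                    h=np.array([[3.0, 1.0], [1.5, 2.5]]), sc=1.0)
    defaults.update(kw)
    return ModelParams(**defaults)


def params_3stage(**kw):
    defaults = dict(t0=60.0, sigma=5.0, tau=40.0, a=0.5, b=0.4, c=0.6, d=0.7,
                    k_l=0.2, k_s=0.02, k_td=0.4,
                    h=np.array([[3.0, 1.0, 2.0, 0.5], [1.5, 2.5, 0.5, 2.0]]),
                    sc=1.0)
    defaults.update(kw)
    return ModelParams(**defaults)


class TestRampInput:
    def test_asymptotes_and_half_height(self):
        t = np.arange(0.0, 400.0)
        u = ramp_input(4.0, t0=60.0, sigma=5.0, time_grid=t)
        assert u[0] == pytest.approx(0.0, abs=1e-12)
        assert u[-1] == pytest.approx(4.0, rel=1e-9)
        assert ramp_input(4.0, 60.0, 5.0, [60.0]) == pytest.approx(2.0)

    def test_vector_amplitudes_broadcast(self):
        t = np.arange(0.0, 200.0)
        u = ramp_input(np.array([1.0, 3.0]), 60.0, 5.0, t)
        assert u.shape == (t.size, 2)
        np.testing.assert_allclose(u[-1], [1.0, 3.0], rtol=1e-9)

    def test_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            ramp_input(1.0, 60.0, 0.0, [0.0])


class TestFeedforwardSteadyState:
    def test_two_stage_equilibrium(self):
        p = params_2stage(tau=15.0)
        spec = ModelSpec("feedforward", n_stages=2)
        tr = simulate(spec, p, dt=0.5, horizon=(0, 600))
        x_end = tr.states["x"][:, -1]
        y_end = tr.states["y"][:, -1, 0]
        np.testing.assert_allclose(x_end, p.tau * p.a * p.h, rtol=1e-6)
        np.testing.assert_allclose(
            y_end, p.tau ** 2 * p.a * p.b * p.h.sum(axis=1), rtol=1e-6)
        # readout: squared rectified units summed, scaled by sc
        sig = readout(tr)
        np.testing.assert_allclose(
            sig["pIT"][:, -1], p.sc * (p.tau * p.a * p.h) ** 2 @ np.ones(2),
            rtol=1e-6)

    def test_three_stage_equilibrium(self):
        p = params_3stage(tau=12.0)
        spec = ModelSpec("feedforward", n_stages=3)
        tr = simulate(spec, p, dt=0.5, horizon=(0, 600))
        w_end = tr.states["w"][:, -1]
        np.testing.assert_allclose(w_end, p.tau * p.a * p.h, rtol=1e-6)
        x_exp = p.tau ** 2 * p.a * p.b * np.stack(
            [p.h[:, 0] + p.h[:, 1], p.h[:, 2] + p.h[:, 3]], axis=1)
        np.testing.assert_allclose(tr.states["x"][:, -1], x_exp, rtol=1e-6)
        np.testing.assert_allclose(
            tr.states["y"][:, -1, 0], p.tau * p.c * x_exp.sum(axis=1), rtol=1e-6)


def _linear_system(arch, n_stages, p):
    """Independent construction of the equivalent linear system (M, N) for
    the state-coding linear architectures, built directly from the printed
    stage equations (not from the simulator)."""
    tau, a, b, c = p.tau, p.a, p.b, p.c
    if n_stages == 2:
        A = a * np.eye(2)
        B = b * np.ones((1, 2))
        dim, n_in = 4, 2                       # x0 x1 y z
        M = np.zeros((dim, dim))
        N = np.zeros((dim, n_in))
        x, y, z = slice(0, 2), 2, 3
        M[x, x] = -np.eye(2) / tau
        M[y, y] = -1 / tau
        N[x] = A
        if arch == "feedforward":
            M[y, x] = B
        elif arch == "lateral_inhibition":
            M[x, x] += -p.k_l * (np.ones((2, 2)) - np.eye(2))
            M[y, x] = B
        elif arch == "feedback_linear_reconstruction":
            M[x, x] += -(A @ A.T) - p.k_td * np.eye(2)
            M[x, y] = (p.k_td * B.T).ravel()
            M[y, x] = B
            M[y, y] += -float((B @ B.T)[0, 0])
            M[z, y] = 1 / tau
            M[z, z] = -1 / tau
        elif arch == "feedback_linear_construction":
            M[x, x] += -np.eye(2) - p.k_td * (B.T @ B)
            M[x, y] = (p.k_td * B.T).ravel()
            M[y, x] = B
            M[y, y] += -1.0
        return M, N
    A = a * np.eye(4)
    B = b * np.array([[1.0, 1, 0, 0], [0, 0, 1, 1]])
    C = c * np.ones((1, 2))
    dim, n_in = 8, 4                           # w(4) x(2) y z
    M = np.zeros((dim, dim))
    N = np.zeros((dim, n_in))
    w, x, y, z = slice(0, 4), slice(4, 6), 6, 7
    M[w, w] = -np.eye(4) / tau
    M[x, x] = -np.eye(2) / tau
    M[y, y] = -1 / tau
    N[w] = A
    if arch == "feedforward":
        M[x, w] = B
        M[y, x] = C
    elif arch == "feedback_linear_reconstruction":
        M[w, w] += -(A @ A.T) - p.k_td * np.eye(4)
        M[w, x] = p.k_td * B.T
        M[x, w] = B
        M[x, x] += -(B @ B.T) - p.k_td * np.eye(2)
        M[x, y] = (p.k_td * C.T).ravel()
        M[y, x] = C
        M[y, y] += -float((C @ C.T)[0, 0])
        M[z, y] = 1 / tau
        M[z, z] = -1 / tau
    return M, N


LINEAR_CASES = [
    ("feedforward", 2), ("lateral_inhibition", 2),
    ("feedback_linear_reconstruction", 2), ("feedback_linear_construction", 2),
    ("feedforward", 3), ("feedback_linear_reconstruction", 3),
]


@pytest.mark.parametrize("arch,n_stages", LINEAR_CASES)
def test_simulator_matches_matrix_exponential_oracle(arch, n_stages):
    """Every linear architecture's trajectory agrees with the closed-form
    x(T) = int_0^T exp(M (T-s)) N u(s) ds to better than 1e-6 relative."""
    maker = params_2stage if n_stages == 2 else params_3stage
    # lateral inhibition destabilizes the difference mode unless k_l < 1/tau
    p = maker(tau=10.0, k_l=0.05) if arch == "lateral_inhibition" else maker()
    spec = ModelSpec(arch, n_stages=n_stages)
    M, N = _linear_system(arch, n_stages, p)
    T = 180.0
    tr = simulate(spec, p, dt=0.25, horizon=(0.0, T))
    packed = np.concatenate(
        [tr.states[k][:, -1] for k in (("x", "y", "z") if n_stages == 2
                                       else ("w", "x", "y", "z"))], axis=1)

    for cond in range(2):
        def integrand(s):
            u = p.h[cond] * ndtr((s - p.t0) / p.sigma)
            return expm(M * (T - s)) @ N @ u
        exact, _ = quad_vec(integrand, 0.0, T, epsabs=1e-12, epsrel=1e-12)
        scale = np.abs(exact).max()
        np.testing.assert_allclose(packed[cond], exact, atol=1e-6 * scale)


GRAD_CASES = [
    ("feedback_linear_reconstruction", 2), ("feedback_linear_reconstruction", 3),
    ("feedback_nonlinear_reconstruction", 2), ("feedback_nonlinear_reconstruction", 3),
    ("feedback_linear_construction", 2), ("feedback_linear_construction", 3),
]


@pytest.mark.parametrize("arch,n_stages", GRAD_CASES)
def test_drift_is_negative_cost_gradient(arch, n_stages, rng):
    """With unit top-down weighting and the leak removed, each feedback
    architecture's state drift equals minus the finite-difference gradient
    of its cost."""
    p = (params_2stage if n_stages == 2 else params_3stage)(
        k_td=1.0, tau=1e9, th=0.2, bi=0.1)
    spec = ModelSpec(arch, n_stages=n_stages)
    dim = 4 if n_stages == 2 else 8
    state = rng.normal(0.5, 0.4, size=dim)
    u = rng.uniform(0.5, 2.0, size=spec.n_inputs)

    def unpack(s):
        if n_stages == 2:
            return {"x": s[0:2], "y": s[2:3]}
        return {"w": s[0:4], "x": s[4:6], "y": s[6:7]}

    drift = state_derivative(spec, p, u, state)
    n_state = dim - 1   # exclude the auxiliary z
    grad = np.zeros(n_state)
    eps = 1e-6
    for i in range(n_state):
        up, down = state.copy(), state.copy()
        up[i] += eps
        down[i] -= eps
        grad[i] = (compute_cost(spec, p, u, unpack(up))
                   - compute_cost(spec, p, u, unpack(down))) / (2 * eps)
    np.testing.assert_allclose(drift[:n_state], -grad, rtol=1e-4, atol=1e-6)


class TestCosts:
    def test_zero_at_exact_reconstruction(self):
        p = params_2stage(a=0.8, b=0.5)
        spec = ModelSpec("feedback_linear_reconstruction", n_stages=2)
        y = 1.3
        x = np.array([p.b * y, p.b * y])       # e1 = 0
        u = p.a * x                            # e0 = 0
        assert compute_cost(spec, p, u, {"x": x, "y": y}) == pytest.approx(0.0)

    def test_nonnegative_everywhere(self, rng):
        for arch in ("feedback_linear_reconstruction",
                     "feedback_nonlinear_reconstruction",
                     "feedback_linear_construction"):
            spec = ModelSpec(arch, n_stages=2)
            p = params_2stage(th=0.3, bi=-0.2)
            for _ in range(10):
                states = {"x": rng.normal(size=2), "y": rng.normal(size=1)}
                u = rng.normal(size=2)
                assert compute_cost(spec, p, u, states) >= 0.0

    def test_state_models_have_no_cost(self):
        with pytest.raises(ValueError):
            compute_cost(ModelSpec("feedforward", n_stages=2), params_2stage(),
                         np.ones(2), {"x": np.ones(2), "y": 1.0})

    def test_energy_descent_without_leak(self):
        """Gradient-descent dynamics with constant input and no leak make
        the reconstruction cost non-increasing along trajectories."""
        p = params_2stage(k_td=1.0, tau=1e9, t0=-30.0, sigma=0.5)
        spec = ModelSpec("feedback_linear_reconstruction", n_stages=2)
        tr = simulate(spec, p, dt=0.5, horizon=(0, 200))
        for cond in range(2):
            costs = [
                compute_cost(spec, p, p.h[cond],
                             {"x": tr.states["x"][cond, k],
                              "y": tr.states["y"][cond, k]})
                for k in range(0, tr.time.size, 20)
            ]
            diffs = np.diff(costs)
            assert (diffs <= 1e-9).all()


h_pair = st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=2, max_size=2)


@given(h1=h_pair, h2=h_pair)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_feedforward_sign_preservation(h1, h2):
    """The hidden-stage differential of the feedforward model never changes
    sign: it is a positive-kernel convolution of the input differential."""
    if abs(sum(h1) - sum(h2)) < 1e-3:
        return
    p = params_2stage(h=np.array([h1, h2]))
    tr = simulate(ModelSpec("feedforward", n_stages=2), p, dt=1.0)
    diff = tr.states["x"][0].sum(axis=1) - tr.states["x"][1].sum(axis=1)
    expected = np.sign(sum(h1) - sum(h2))
    assert ((np.sign(diff) == expected) | (np.abs(diff) < 1e-9)).all()


def test_linearity_of_state_traces():
    p = params_2stage()
    doubled = params_2stage(h=2.0 * p.h)
    spec = ModelSpec("lateral_inhibition", n_stages=2)
    t1 = simulate(spec, p, dt=0.5)
    t2 = simulate(spec, doubled, dt=0.5)
    np.testing.assert_allclose(t2.states["x"], 2.0 * t1.states["x"], atol=1e-9)
    np.testing.assert_allclose(t2.states["y"], 2.0 * t1.states["y"], atol=1e-9)


def test_integrator_convergence_under_dt_halving():
    p = params_3stage()
    spec = ModelSpec("feedback_linear_reconstruction", n_stages=3,
                     readout="state_and_error")
    sig_a = readout(simulate(spec, p, dt=0.5))
    sig_b = readout(simulate(spec, p, dt=0.25))
    for region in sig_a:
        a = sig_a[region][:, ::2][:, 120:400].mean()
        b = sig_b[region][:, ::4][:, 120:400].mean()
        assert abs(a - b) < 1e-3 * max(abs(b), 1e-12)


def test_taylor_shunt_matches_series_remainder():
    """The hard-coded fourth-order coefficients reproduce the geometric
    series: 1/(1-v) - sum_0^4 v^n = v^5/(1-v) exactly."""
    from facedyn.models import _taylor_shunt

    for v in np.linspace(-0.9, 0.9, 19):
        approx = _taylor_shunt(v)
        exact = 1.0 / (1.0 - v)
        assert approx == pytest.approx(exact - v ** 5 / (1.0 - v), rel=1e-12)
    assert np.isnan(_taylor_shunt(1.2))


def test_shunt_blowup_raises_simulation_error():
    p = params_2stage(k_s=1.0, h=np.full((2, 2), 20.0), tau=1000.0)
    with pytest.raises(SimulationError, match="non-finite"):
        simulate(ModelSpec("normalization_nonlinear", n_stages=2), p)


class TestSpecAndParams:
    def test_parameter_vector_lengths(self):
        assert len(ModelSpec("feedforward", n_stages=2).param_names()) == 10
        assert len(ModelSpec("feedforward", n_stages=3).param_names()) == 15

    @pytest.mark.parametrize("arch,extra", [
        ("lateral_inhibition", ["k_l"]),
        ("normalization_linear", ["k_s"]),
        ("normalization_nonlinear", ["k_s"]),
        ("feedback_linear_reconstruction", ["k_td"]),
        ("feedback_nonlinear_reconstruction", ["k_td", "th", "bi"]),
        ("feedback_linear_construction", ["k_td"]),
    ])
    def test_family_specific_parameters(self, arch, extra):
        base = ModelSpec("feedforward", n_stages=3).param_names()
        names = ModelSpec(arch, n_stages=3).param_names()
        assert names == base + extra

    def test_error_readout_adds_gain(self):
        spec2 = ModelSpec("feedback_linear_reconstruction", n_stages=2,
                          readout="state_and_error")
        spec3 = ModelSpec("feedback_linear_reconstruction", n_stages=3,
                          readout="state_and_error")
        assert spec2.param_names()[-1] == "c"
        assert spec3.param_names()[-1] == "d"

    def test_vector_roundtrip(self):
        spec = ModelSpec("feedback_nonlinear_reconstruction", n_stages=3,
                         readout="state_and_error")
        p = params_3stage(th=1.5, bi=-0.3)
        vec = p.to_vector(spec)
        back = ModelParams.from_vector(spec, vec)
        np.testing.assert_allclose(back.to_vector(spec), vec)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            ModelSpec("deep_resnet")
        with pytest.raises(ValueError):
            ModelSpec("feedforward", n_stages=4)
        with pytest.raises(ValueError):
            ModelSpec("feedforward", readout="state_and_error")

    def test_wrong_input_count_rejected(self):
        spec = ModelSpec("feedforward", n_stages=3)
        with pytest.raises(ValueError, match="inputs"):
            simulate(spec, params_2stage())

    def test_readout_requires_matching_trace(self):
        spec_state = ModelSpec("feedforward", n_stages=2)
        tr = simulate(spec_state, params_2stage())
        err_spec = ModelSpec("feedback_linear_reconstruction", n_stages=2,
                             readout="state_and_error")
        with pytest.raises(ValueError):
            readout(tr, err_spec, params_2stage())


def test_trace_csv_roundtrip(tmp_path):
    from facedyn.models import params_from_json, params_to_json, trace_to_frame

    spec = ModelSpec("feedback_linear_reconstruction", n_stages=2,
                     readout="state_and_error")
    p = params_2stage(k_td=0.3)
    tr = simulate(spec, p, dt=1.0, horizon=(0, 100))
    frame = trace_to_frame(tr)
    path = tmp_path / "trace.csv"
    frame.to_csv(path, index=False)
    assert {"time_ms", "condition", "x0", "y0", "e10"} <= set(frame.columns)
    assert len(frame) == 2 * tr.time.size

    spec2, p2 = params_from_json(params_to_json(spec, p))
    assert spec2 == spec
    np.testing.assert_allclose(p2.to_vector(spec2), p.to_vector(spec))
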