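"""Gaussian time-to-spike error assignment, surrogate gradient, and the
reverse-time accumulation, checked against independent loop oracles."""

import math

import numpy as np
import pytest

from fscode import (
    BackpropConfig,
    DenseLayer,
    MaxPoolLayer,
    NeuronParams,
    assign_time_error_to_spikes,
    backward,
    build_network,
    forward,
    gaussian_weight,
    surrogate_derivative,
    window_size,
)
from fscode.backprop import assign_time_errors_batch
from oracles import naive_backward, naive_forward, naive_time_assignment


class TestWindowSize:
    @pytest.mark.parametrize(
        "T,D,expected",
        [
            (100, 8, (12, 73)),
            (100, 16, (6, 37)),
            (100, 32, (3, 19)),
            (120, 8, (15, 91)),
            (120, 12, (10, 61)),
            (100, 100, (1, 7)),
            (100, 1, (100, 100)),  # W capped at T
        ],
    )
    def test_sigma_and_width(self, T, D, expected):
        assert window_size(T, D) == expected

    def test_delta_limit(self):
        assert window_size(10, 11) == (0, 1)
        assert window_size(10, 1000) == (0, 1)

    def test_invalid(self):
        with pytest.raises(ValueError):
            window_size(0, 4)
        with pytest.raises(ValueError):
            window_size(10, 0)


class TestGaussianWeight:
    def test_symmetric_negative_peaked_at_zero(self):
        xs = np.arange(-10, 11)
        g = gaussian_weight(xs, sigma=4, A=100.0)
        np.testing.assert_allclose(g, g[::-1])
        assert np.all(g < 0)
        assert np.argmax(np.abs(g)) == 10

    def test_peak_magnitude(self):
        assert abs(gaussian_weight(0, sigma=3, A=60.0)) == pytest.approx(
            60.0 / (math.sqrt(2 * math.pi) * 3)
        )

    def test_reference_value(self):
        # A=200, sigma=6, x=3 against a direct high-precision evaluation
        expected = -(200 / (math.sqrt(2 * math.pi) * 6)) * math.exp(-9 / 72)
        assert gaussian_weight(3, sigma=6, A=200.0) == pytest.approx(
            expected, rel=1e-14
        )

    def test_sigma_zero_rejected(self):
        with pytest.raises(ValueError):
            gaussian_weight(0, sigma=0, A=10.0)


class TestSurrogate:
    def test_at_threshold(self):
        assert surrogate_derivative(1.0, theta=1.0, rho=5.0) == 1.0

    def test_unit_offset(self):
        assert surrogate_derivative(2.0, 1.0, 5.0) == pytest.approx(1 / 36)
        assert surrogate_derivative(0.0, 1.0, 5.0) == pytest.approx(1 / 36)

    def test_monotone_decreasing_in_distance(self):
        d = np.array([0.0, 0.1, 0.5, 1.0, 3.0])
        v = surrogate_derivative(1.0 + d, 1.0, 5.0)
        assert np.all(np.diff(v) < 0)
        assert np.all((v > 0) & (v <= 1))


class TestTimeAssignment:
    CFG = BackpropConfig(A=100.0, D=8)

    def test_active_center_gets_g0(self):
        T = 40
        sigma, _ = self.CFG.sigma_W(T)
        out = assign_time_error_to_spikes(2.0, 5, T, self.CFG)
        assert out[4] == pytest.approx(2.0 * gaussian_weight(0, sigma, 100.0))

    def test_active_truncated_at_three_sigma(self):
        T = 40
        sigma, _ = self.CFG.sigma_W(T)
        out = assign_time_error_to_spikes(1.0, 20, T, self.CFG)
        n = np.arange(1, T + 1)
        assert np.all(out[np.abs(n - 20) > 3 * sigma] == 0)
        assert np.all(out[np.abs(n - 20) <= 3 * sigma] != 0)

    def test_delta_limit_single_step(self):
        """D > T: the whole error lands on the one step with weight
        -A/sqrt(2*pi)."""
        cfg = BackpropConfig(A=50.0, D=100)
        out = assign_time_error_to_spikes(1.0, 4, 10, cfg)
        expected = -50.0 / math.sqrt(2 * math.pi)
        assert out[3] == pytest.approx(expected)
        assert np.count_nonzero(out) == 1

    def test_sign_opposite_to_time_error(self, rng):
        """Positive time error (decrease the time) pushes spikes up."""
        T = 30
        for _ in range(20):
            dl = rng.normal()
            step = int(rng.integers(1, T + 1)) if rng.uniform() < 0.5 else None
            out = assign_time_error_to_spikes(dl, step, T, self.CFG)
            nz = out[out != 0]
            assert np.all(np.sign(nz) == -np.sign(dl))

    @pytest.mark.parametrize("first_step", [None, 1, 7, 16])
    def test_matches_naive_transcription(self, first_step):
        T = 16
        cfg = BackpropConfig(A=32.0, D=5)
        out = assign_time_error_to_spikes(0.7, first_step, T, cfg)
        ref = naive_time_assignment(0.7, first_step, T, A=32.0, D=5)
        np.testing.assert_allclose(out, ref[1:], rtol=1e-12)

    def test_wide_window_plateau(self):
        """D=1 (W=T): the inactive-neuron profile is nearly flat away from
        the edges, approaching the uniform per-step assignment of rate
        training."""
        T = 50
        out = assign_time_error_to_spikes(1.0, None, T, BackpropConfig(A=100.0, D=1))
        interior = out[T // 4 : -T // 4]
        assert interior.std() / abs(interior.mean()) < 0.05

    def test_batch_assignment_matches_scalar(self, rng):
        T = 25
        cfg = BackpropConfig(A=50.0, D=6)
        B, C = 3, 4
        dl = rng.normal(size=(B, C))
        first = rng.integers(0, T + 1, size=(B, C))  # 0 = silent
        out = assign_time_errors_batch(dl, first, T, cfg)
        for b in range(B):
            for c in range(C):
                step = int(first[b, c]) or None
                ref = assign_time_error_to_spikes(dl[b, c], step, T, cfg)
                np.testing.assert_allclose(out[1:, b, c], ref, atol=1e-12)


def random_dense_net(rng):
    n_layers = int(rng.integers(1, 3))
    widths = [int(rng.integers(2, 7))]
    for _ in range(n_layers):
        widths.append(int(rng.integers(2, 17)))
    layers = []
    for i in range(n_layers):
        params = NeuronParams(
            tau=float(rng.uniform(0.01, 0.2)),
            theta=float(rng.uniform(0.2, 1.0)),
            dt=0.01,
        )
        Q, J = widths[i + 1], widths[i]
        W = rng.normal(scale=0.5, size=(Q, J))
        V = rng.normal(scale=0.3, size=(Q, Q)) if rng.uniform() < 0.5 else None
        layers.append(DenseLayer(W, params, V=V))
    return layers, widths


class TestBackward:
    def test_zero_output_error_gives_zero_gradients(self, rng):
        layers, widths = random_dense_net(rng)
        T = 12
        x = rng.poisson(1, size=(1, widths[0], T)).astype(float)
        trajs = forward(layers, x)
        tape = backward(layers, trajs, x, np.zeros((T + 1, 1, widths[-1])))
        for g in tape.dL_dW:
            assert np.all(g == 0)

    def test_single_layer_single_step(self):
        """T=1 degenerate chain: dL/dW = dL/dI^1 * s^{0,1} with
        dL/dI^1 = 0 (no n=2 terms), hence zero; dL/dU^1 is the surrogate-
        scaled output error."""
        layer = DenseLayer(np.array([[2.0]]), NeuronParams(0.05, 0.5, 0.01))
        x = np.array([[[3.0]]])
        trajs = forward([layer], x)
        dl = np.zeros((2, 1, 1))
        dl[1, 0, 0] = 1.5
        tape = backward([layer], trajs, x, dl, rho=5.0)
        assert tape.dL_dW[0][0, 0] == 0.0
        expected_dU = 1.5 * surrogate_derivative(trajs[0].U[1, 0, 0], 0.5, 5.0)
        assert tape.dL_dU[0][1, 0, 0] == pytest.approx(expected_dU)

    def test_oracle_equivalence_on_random_nets(self):
        """The central check: vectorized backward == independent per-neuron
        reverse accumulation, 50 random instances, <1e-6 relative error."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            layers, widths = random_dense_net(rng)
            T = int(rng.integers(4, 33))
            x = rng.poisson(1.2, size=(widths[0], T)).astype(float)
            trajs = forward(layers, x[None])
            states = naive_forward(layers, x)
            dl = rng.normal(size=(widths[-1], T + 1))
            dl[:, 0] = 0
            dl_prod = np.zeros((T + 1, 1, widths[-1]))
            dl_prod[1:] = dl[:, 1:].T[:, None, :]
            tape = backward(layers, trajs, x[None], dl_prod, rho=5.0)
            grads, signals = naive_backward(layers, states, x, dl, rho=5.0)
            for l, (dW_ref, dV_ref) in enumerate(grads):
                scale = max(np.max(np.abs(dW_ref)), 1e-12)
                assert np.max(np.abs(tape.dL_dW[l] - dW_ref)) / scale < 1e-6
                if dV_ref is not None:
                    scale = max(np.max(np.abs(dV_ref)), 1e-12)
                    assert np.max(np.abs(tape.dL_dV[l] - dV_ref)) / scale < 1e-6
                ds_ref = signals[l]["ds"]
                np.testing.assert_allclose(
                    np.moveaxis(tape.dL_ds[l][:, 0], 0, -1), ds_ref, atol=1e-9
                )

    def test_batch_is_sum_of_trials(self, rng):
        """Weight gradients over a batch equal the sum of per-trial ones."""
        layers, widths = random_dense_net(rng)
        T = 10
        x = rng.poisson(1, size=(3, widths[0], T)).astype(float)
        dl = rng.normal(size=(T + 1, 3, widths[-1]))
        dl[0] = 0
        tape = backward(layers, forward(layers, x), x, dl, rho=5.0)
        summed = np.zeros_like(layers[0].W)
        for b in range(3):
            xb = x[b : b + 1]
            tb = backward(layers, forward(layers, xb), xb, dl[:, b : b + 1], rho=5.0)
            summed += tb.dL_dW[0]
        np.testing.assert_allclose(tape.dL_dW[0], summed, rtol=1e-9, atol=1e-12)

    def test_maxpool_routes_to_first_argmax(self):
        """Pool backward sends error only to the first spiking unit of each
        block (first-index tie-break)."""
        pool = MaxPoolLayer(2)
        s_in = np.zeros((1, 1, 2, 2))
        s_in[0, 0, 0, 1] = 1.0
        s_in[0, 0, 1, 0] = 1.0  # two active units -> first in flat order wins
        from fscode.backprop import _pool_route

        routed = _pool_route(pool, s_in, np.full((1, 1, 1, 1), 2.5))
        assert routed[0, 0, 0, 1] == 2.5
        assert routed.sum() == 2.5
        # silent block: error goes to the (first) zero entry, none is lost
        routed0 = _pool_route(pool, np.zeros((1, 1, 2, 2)), np.full((1, 1, 1, 1), 1.0))
        assert routed0[0, 0, 0, 0] == 1.0

    def test_conv_adjoint_identities(self, rng):
        """Conv input-error and weight-gradient paths are the exact adjoints
        of the (linear) forward drive: <conv_W(x), y> = <x, conv_W^T(y)> and
        <conv_W(x), y> = <W, dW(x, y)>."""
        params = NeuronParams(0.05, 0.5, 0.01)
        from fscode import ConvLayer

        layer = ConvLayer(rng.normal(size=(3, 2, 3, 3)), params, stride=2)
        x = rng.normal(size=(2, 2, 9, 9))
        out = layer.drive(x, None)
        y = rng.normal(size=out.shape)
        Cout = 3
        Wm = layer.W.reshape(Cout, -1)
        y_flat = y.reshape(2, Cout, -1)
        dcols = np.einsum("oc,bop->bcp", Wm, y_flat)
        x_grad = layer.col2im(dcols, x.shape[1:])
        assert np.sum(out * y) == pytest.approx(np.sum(x * x_grad), rel=1e-10)
        cols = layer.im2col(x)
        dW = np.einsum("bop,bcp->oc", y_flat, cols).reshape(layer.W.shape)
        assert np.sum(out * y) == pytest.approx(np.sum(layer.W * dW), rel=1e-10)

    def test_conv_pool_chain_backward_runs(self, rng):
        """End-to-end gradient shapes for a conv-pool-dense chain."""
        layers = build_network(
            "[1,8,8]-2C3-P2-FC5-2", dt=0.01, tau1=0.03, theta1=0.2,
            tau2=0.1, theta2=0.4, rng=rng,
        )
        x = rng.poisson(1, size=(2, 1, 8, 8, 6)).astype(float)
        trajs = forward(layers, x)
        dl = rng.normal(size=(7, 2, 2))
        dl = np.concatenate([np.zeros((1, 2, 2)), dl[1:]], axis=0)
        tape = backward(layers, trajs, x, dl, rho=5.0)
        assert tape.dL_dW[0].shape == layers[0].W.shape
        assert tape.dL_dW[2].shape == layers[2].W.shape
        assert np.isfinite(tape.dL_dW[0]).all()
        assert tape.dL_dx.shape == (7, 2, 1, 8, 8)
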