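"""The recurrent cell, bidirectional composition and densely linked stack
are checked against literal, independently written transcriptions of their
defining gate equations."""

import numpy as np
import pytest

from pdeeg.cells import (BiLSTMParams, DenseLinkSpec, LSTMParams, LSTMState,
                         StructuralError, bilstm_forward, dense_link_forward,
                         init_bilstm_params, init_lstm_params, lstm_cell_step,
                         lstm_forward, zero_state)

# --- literal equation-by-equation oracles (kept deliberately naive) --------


def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


def oracle_cell(x, h_prev, c_prev, p: LSTMParams):
    z = np.concatenate([h_prev, x])
    i = _sig(p.W_i @ z + p.b_i)
    f = _sig(p.W_f @ z + p.b_f)
    o = _sig(p.W_o @ z + p.b_o)
    c_hat = np.tanh(p.W_c @ z + p.b_c)
    c = f * c_prev + i * c_hat
    h = o * np.tanh(c)
    return h, c, (i, f, o)


def oracle_lstm(X, p: LSTMParams):
    h, c = np.zeros(p.units), np.zeros(p.units)
    out = []
    for t in range(len(X)):
        h, c, _ = oracle_cell(X[t], h, c, p)
        out.append(h)
    return np.array(out)


def oracle_bilstm(X, p: BiLSTMParams):
    hf = oracle_lstm(X, p.forward)
    hb = oracle_lstm(X[::-1], p.backward)[::-1]
    return np.concatenate([hf, hb], axis=1)


def oracle_dense_link(X, spec: DenseLinkSpec, params):
    d = [X]
    for layer_params in params:
        inp = np.concatenate(d, axis=1)
        h = (oracle_bilstm(inp, layer_params) if spec.bidirectional
             else oracle_lstm(inp, layer_params))
        d.append(np.concatenate([h, X], axis=1))
    return d[-1]


def random_params(rng, input_dim, units):
    def w():
        return rng.standard_normal((units, input_dim + units))

    return LSTMParams(W_i=w(), W_f=w(), W_o=w(), W_c=w(),
                      b_i=rng.standard_normal(units),
                      b_f=rng.standard_normal(units),
                      b_o=rng.standard_normal(units),
                      b_c=rng.standard_normal(units))


# --- analytic special cases ------------------------------------------------


def test_zero_params_give_half_gates_and_zero_output():
    p = LSTMParams(*(np.zeros((3, 5)) for _ in range(4)),
                   *(np.zeros(3) for _ in range(4)))
    s = lstm_cell_step(np.array([1.0, -2.0]), zero_state(3), p)
    assert np.allclose(s.c, 0.0) and np.allclose(s.h, 0.0)


def test_zero_params_halve_previous_cell_state():
    p = LSTMParams(*(np.zeros((3, 5)) for _ in range(4)),
                   *(np.zeros(3) for _ in range(4)))
    s = lstm_cell_step(np.zeros(2), LSTMState(h=np.zeros(3), c=np.ones(3)), p)
    assert np.allclose(s.c, 0.5)
    assert np.allclose(s.h, 0.5 * np.tanh(0.5))


def test_saturated_gates_carry_memory_unchanged():
    # forget gate ~1, input gate ~0: the cell state rides through
    units = 4
    p = LSTMParams(*(np.zeros((units, units + 2)) for _ in range(4)),
                   b_i=np.full(units, -20.0), b_f=np.full(units, 20.0),
                   b_o=np.zeros(units), b_c=np.zeros(units))
    state = LSTMState(h=np.zeros(units), c=np.linspace(-1, 1, units))
    c0 = state.c.copy()
    for _ in range(10):
        state = lstm_cell_step(np.zeros(2), state, p)
    assert np.allclose(state.c, c0, atol=1e-8)


def test_nonfinite_input_raises():
    p = random_params(np.random.default_rng(0), 2, 3)
    with pytest.raises(FloatingPointError):
        lstm_cell_step(np.array([np.nan, 0.0]), zero_state(3), p)


# --- oracle equivalence on random instances --------------------------------


def test_cell_matches_literal_oracle_on_random_instances(rng):
    for _ in range(100):
        units = int(rng.integers(1, 9))
        dim = int(rng.integers(1, 9))
        p = random_params(rng, dim, units)
        x = rng.standard_normal(dim)
        h0, c0 = rng.standard_normal(units), rng.standard_normal(units)
        s = lstm_cell_step(x, LSTMState(h=h0, c=c0), p)
        h, c, gates = oracle_cell(x, h0, c0, p)
        assert np.max(np.abs(s.h - h)) <= 1e-12
        assert np.max(np.abs(s.c - c)) <= 1e-12
        for g in gates:  # gate boundedness
            assert np.all((g > 0) & (g < 1))
        assert np.all(np.abs(s.h) < 1)


def test_lstm_forward_matches_stepwise_oracle(rng):
    for _ in range(25):
        T = int(rng.integers(1, 11))
        p = random_params(rng, 3, 4)
        X = rng.standard_normal((T, 3))
        assert np.max(np.abs(lstm_forward(X, p) - oracle_lstm(X, p))) <= 1e-12


def test_lstm_forward_single_step_equals_cell():
    rng = np.random.default_rng(5)
    p = random_params(rng, 2, 3)
    x = rng.standard_normal((1, 2))
    s = lstm_cell_step(x[0], zero_state(3), p)
    assert np.allclose(lstm_forward(x, p, return_sequence=False), s.h)


def test_bilstm_backward_half_is_reversed_forward(rng):
    for _ in range(25):
        T = int(rng.integers(2, 11))
        p = BiLSTMParams(random_params(rng, 3, 4), random_params(rng, 3, 4))
        X = rng.standard_normal((T, 3))
        out = bilstm_forward(X, p)
        hb = lstm_forward(X[::-1], p.backward)[::-1]
        assert np.max(np.abs(out[:, 4:] - hb)) <= 1e-12
        assert out.shape == (T, 8)
        final = bilstm_forward(X, p, return_sequence=False)
        assert np.allclose(final, np.concatenate([out[-1, :4], out[0, 4:]]))


def test_bilstm_palindrome_symmetry(rng):
    # identical directions on a palindromic sequence mirror in time
    p0 = random_params(rng, 2, 3)
    p = BiLSTMParams(p0, p0)
    half = rng.standard_normal((4, 2))
    X = np.vstack([half, half[::-1]])
    out = bilstm_forward(X, p)
    hf, hb = out[:, :3], out[:, 3:]
    T = len(X)
    for t in range(T):
        assert np.allclose(hf[t], hb[T - 1 - t], atol=1e-12)


def test_dense_link_matches_bruteforce_oracle(rng):
    for bidirectional in (False, True):
        spec = DenseLinkSpec(units=[3, 3], bidirectional=bidirectional)
        X = rng.standard_normal((6, 2))
        params = []
        for layer in range(spec.n_layers):
            w = spec.input_width(layer, 2)
            params.append(
                BiLSTMParams(random_params(rng, w, 3), random_params(rng, w, 3))
                if bidirectional else random_params(rng, w, 3))
        out = dense_link_forward(X, spec, params)
        assert np.max(np.abs(out - oracle_dense_link(X, spec, params))) <= 1e-12


def test_dense_link_width_bookkeeping():
    spec = DenseLinkSpec(units=[4, 4, 4], bidirectional=False)
    assert [spec.input_width(l, 2) for l in range(3)] == [2, 8, 14]
    assert [spec.output_width(l, 2) for l in range(3)] == [6, 6, 6]


def test_dense_link_single_layer_reduces_to_plain_lstm(rng):
    spec = DenseLinkSpec(units=[5], bidirectional=False)
    p = random_params(rng, 3, 5)
    X = rng.standard_normal((7, 3))
    out = dense_link_forward(X, spec, [p])
    h = lstm_forward(X, p)
    assert np.allclose(out, np.concatenate([h, X], axis=1))


def test_dense_link_width_mismatch_names_layer(rng):
    spec = DenseLinkSpec(units=[3, 3], bidirectional=False)
    good0 = random_params(rng, spec.input_width(0, 2), 3)
    bad1 = random_params(rng, 5, 3)  # layer 1 expects width 8
    with pytest.raises(StructuralError, match="layer 1"):
        dense_link_forward(np.zeros((4, 2)), spec, [good0, bad1])


def test_initializer_contract(rng):
    p = init_lstm_params(4, 6, rng)
    assert p.units == 6 and p.input_dim == 4
    assert np.allclose(p.b_f, 1.0) and np.allclose(p.b_i, 0.0)
    bp = init_bilstm_params(4, 6, rng)
    assert not np.allclose(bp.forward.W_i, bp.backward.W_i)
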