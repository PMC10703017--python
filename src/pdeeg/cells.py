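"""LSTM primitives as pure-NumPy functions.

These implement the recurrent cell a gate at a time: input, forget and
output gates are sigmoids of an affine map of the concatenation
[h_{t-1}, x_t]; the candidate cell state is a tanh of the same form; the
cell state is the forget-gated previous cell plus the input-gated
candidate; the hidden state is the output gate times tanh of the cell.
The bidirectional composition runs one cell forward in time and an
independent cell backward, concatenating the two hidden states per step.
The densely linked stack feeds every layer the concatenation of all
preceding layers' per-step outputs, and each layer's output is its hidden
state concatenated with the raw input at that step.

These functions are the reference semantics; the trainable network in
:mod:`pdeeg.network` is held to agree with them in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class StructuralError(ValueError):
    """Raised when parameter shapes do not match the declared wiring."""


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LSTMParams:
    """Gate weights, each (units, input_dim + units), acting on [h_{t-1}, x_t]."""

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.W_i.shape, self.W_f.shape, self.W_o.shape, self.W_c.shape}
        if len(shapes) != 1:
            raise StructuralError("all four gate weight matrices must share a shape")
        units = self.W_i.shape[0]
        for b in (self.b_i, self.b_f, self.b_o, self.b_c):
            if b.shape != (units,):
                raise StructuralError("bias length must equal units")
        if self.W_i.shape[1] <= units:
            raise StructuralError("weight columns must cover units + input_dim")
        for a in (self.W_i, self.W_f, self.W_o, self.W_c,
                  self.b_i, self.b_f, self.b_o, self.b_c):
            if not np.all(np.isfinite(a)):
                raise FloatingPointError("non-finite LSTM parameter")

    @property
    def units(self) -> int:
        return self.W_i.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_i.shape[1] - self.units


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray


@dataclass
class BiLSTMParams:
    forward: LSTMParams
    backward: LSTMParams

    def __post_init__(self) -> None:
        if self.forward.input_dim != self.backward.input_dim:
            raise StructuralError("forward and backward cells must share input_dim")


@dataclass
class DenseLinkSpec:
    """Densely linked stack: layer l consumes [d^0, ..., d^{l-1}]."""

    units: list[int]
    bidirectional: bool = False

    @property
    def n_layers(self) -> int:
        return len(self.units)

    def output_width(self, layer: int, input_dim: int) -> int:
        h = self.units[layer] * (2 if self.bidirectional else 1)
        return h + input_dim

    def input_width(self, layer: int, input_dim: int) -> int:
        return input_dim + sum(self.output_width(m, input_dim)
                               for m in range(layer))


def zero_state(units: int) -> LSTMState:
    return LSTMState(h=np.zeros(units), c=np.zeros(units))


def init_lstm_params(input_dim: int, units: int,
                     rng: np.random.Generator) -> LSTMParams:
    """Glorot-uniform gate weights, zero biases except forget bias = 1."""
    fan_in, fan_out = input_dim + units, units
    limit = np.sqrt(6.0 / (fan_in + fan_out))

    def w() -> np.ndarray:
        return rng.uniform(-limit, limit, size=(units, input_dim + units))

    return LSTMParams(W_i=w(), W_f=w(), W_o=w(), W_c=w(),
                      b_i=np.zeros(units), b_f=np.ones(units),
                      b_o=np.zeros(units), b_c=np.zeros(units))


def init_bilstm_params(input_dim: int, units: int,
                       rng: np.random.Generator) -> BiLSTMParams:
    return BiLSTMParams(forward=init_lstm_params(input_dim, units, rng),
                        backward=init_lstm_params(input_dim, units, rng))


def lstm_cell_step(x_t: np.ndarray, state: LSTMState,
                   params: LSTMParams) -> LSTMState:
    """One gate update: returns the new (h, c)."""
    x_t = np.asarray(x_t, dtype=float)
    if not np.all(np.isfinite(x_t)) or not np.all(np.isfinite(state.h)) \
            or not np.all(np.isfinite(state.c)):
        raise FloatingPointError("non-finite input or state in lstm_cell_step")
    if x_t.shape != (params.input_dim,):
        raise StructuralError(
            f"x_t has shape {x_t.shape}, expected ({params.input_dim},)")
    z = np.concatenate([state.h, x_t])
    i = sigmoid(params.W_i @ z + params.b_i)
    f = sigmoid(params.W_f @ z + params.b_f)
    o = sigmoid(params.W_o @ z + params.b_o)
    c_hat = np.tanh(params.W_c @ z + params.b_c)
    c = f * state.c + i * c_hat
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c)


def lstm_forward(X: np.ndarray, params: LSTMParams,
                 return_sequence: bool = True) -> np.ndarray:
    """Iterate the cell over a T x input_dim sequence from a zero state."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty T x input_dim sequence")
    state = zero_state(params.units)
    hs = np.empty((X.shape[0], params.units))
    for t in range(X.shape[0]):
        state = lstm_cell_step(X[t], state, params)
        hs[t] = state.h
    return hs if return_sequence else hs[-1]


def bilstm_forward(X: np.ndarray, params: BiLSTMParams,
                   return_sequence: bool = True) -> np.ndarray:
    """Forward and backward passes concatenated per step, [h_f(t), h_b(t)].

    When ``return_sequence`` is false the output is [h_f(T), h_b(1)] — the
    final step of each direction.
    """
    X = np.asarray(X, dtype=float)
    hf = lstm_forward(X, params.forward, return_sequence=True)
    hb_rev = lstm_forward(X[::-1], params.backward, return_sequence=True)
    hb = hb_rev[::-1]
    if return_sequence:
        return np.concatenate([hf, hb], axis=1)
    return np.concatenate([hf[-1], hb[0]])


def dense_link_forward(X: np.ndarray, spec: DenseLinkSpec,
                       all_params: list) -> np.ndarray:
    """Densely linked (bi)LSTM stack.

    Layer l receives [d^0, ..., d^{l-1}] per step (d^0 = x), produces its
    hidden sequence h^l, and emits d^l = [h^l, x].  Returns the last
    layer's d sequence, T x (h_width + input_dim).
    """
    X = np.asarray(X, dtype=float)
    if len(all_params) != spec.n_layers:
        raise StructuralError(
            f"expected {spec.n_layers} parameter sets, got {len(all_params)}")
    input_dim = X.shape[1]
    d_list = [X]
    for layer, params in enumerate(all_params):
        inp = np.concatenate(d_list, axis=1)
        expected = spec.input_width(layer, input_dim)
        if inp.shape[1] != expected:
            raise StructuralError(
                f"layer {layer}: assembled input width {inp.shape[1]} != {expected}")
        if spec.bidirectional:
            if not isinstance(params, BiLSTMParams):
                raise StructuralError(f"layer {layer}: expected BiLSTMParams")
            if params.forward.input_dim != inp.shape[1]:
                raise StructuralError(
                    f"layer {layer}: params expect input_dim "
                    f"{params.forward.input_dim}, got {inp.shape[1]}")
            h = bilstm_forward(inp, params, return_sequence=True)
        else:
            if not isinstance(params, LSTMParams):
                raise StructuralError(f"layer {layer}: expected LSTMParams")
            if params.input_dim != inp.shape[1]:
                raise StructuralError(
                    f"layer {layer}: params expect input_dim "
                    f"{params.input_dim}, got {inp.shape[1]}")
            h = lstm_forward(inp, params, return_sequence=True)
        d_list.append(np.concatenate([h, X], axis=1))
    return d_list[-1]
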