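"""Directed-edge message passing encoder.

Each directed edge x->y carries a hidden message vector.  The initial
message is a learned transform of the merged node-edge feature f_x || f_xy;
subsequent depths add, through a second learned transform, the sum of
messages arriving at x from every neighbour except y (the reverse edge is
excluded so information never bounces straight back).  The merged input
term is re-injected at every depth — a skip connection that keeps gradients
alive over long paths:

    M^1_{xy}     = act(W_inp (f_x || f_xy))
    M^d_{xy}     = act(W_inp (f_x || f_xy) + W_h  sum_{z in N(x)\\y} M^{d-1}_{zx})
    h_y          = act(W_o (W_ah f_y + sum_{z in N(y)} M^d_{zy}))

All depths update synchronously; after depth d a node's hidden vector h_y
summarizes its radius-d neighbourhood.  The per-atom hidden matrix
G = {h_1 ... h_n} is the graph representation handed to the readout.

No bias terms are used (the products above are pure matrix products).  The
vectorized implementation aggregates incoming messages with a scatter-add
over the edge index lists; the identity
sum_{z in N(x)\\y} M_{zx} = (sum of all messages into x) - M_{yx} avoids
building per-edge neighbour lists.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np

from .chemgraph import ATOM_FDIM, EDGE_FDIM, BatchedGraph, MolGraph

# ---------------------------------------------------------------------------
# activations: name -> (f, df) with df(pre, out) the elementwise derivative

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _relu(x):
    return np.maximum(x, 0.0)


ACTIVATIONS = {
    "relu": (_relu, lambda pre, out: (pre > 0).astype(pre.dtype)),
    "tanh": (np.tanh, lambda pre, out: 1.0 - out * out),
    "elu": (
        lambda x: np.where(x > 0, x, np.expm1(np.minimum(x, 0.0))),
        lambda pre, out: np.where(pre > 0, 1.0, out + 1.0),
    ),
    "leakyrelu": (
        lambda x: np.where(x > 0, x, 0.01 * x),
        lambda pre, out: np.where(pre > 0, 1.0, 0.01),
    ),
    # fixed-slope variant of the parametric rectifier (slope not learned)
    "prelu": (
        lambda x: np.where(x > 0, x, 0.25 * x),
        lambda pre, out: np.where(pre > 0, 1.0, 0.25),
    ),
    "selu": (
        lambda x: _SELU_SCALE * np.where(x > 0, x, _SELU_ALPHA * np.expm1(np.minimum(x, 0.0))),
        lambda pre, out: _SELU_SCALE * np.where(pre > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(pre, 0.0))),
    ),
}


def get_activation(name: str):
    try:
        return ACTIVATIONS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}") from None


def param_rng(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible stream for one named parameter.

    Streams are keyed by (seed, name) so adding or resizing one parameter
    never shifts the draws of another.
    """
    return np.random.default_rng([int(seed), zlib.crc32(name.encode()) & 0x7FFFFFFF])


def _init_matrix(rng: np.random.Generator, shape, dtype):
    # uniform(-1/sqrt(fan_in), +1/sqrt(fan_in)); depends on fan-in only so
    # widening the output dimension leaves earlier rows' draws unchanged
    bound = 1.0 / np.sqrt(shape[-1])
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


# ---------------------------------------------------------------------------
# parameter / tensor containers


@dataclasses.dataclass
class EncoderParams:
    """Learned weights of the message passing encoder."""

    W_inp: np.ndarray   # (H, 150) merged node-edge feature -> hidden
    W_h: np.ndarray     # (H, H)   message update
    W_o: np.ndarray     # (H, H)   output transform
    W_ah: np.ndarray    # (H, 139) atom self-feature transform
    hidden_size: int
    depth: int
    activation: str = "relu"

    def __post_init__(self):
        H = self.hidden_size
        if H < 1 or self.depth < 1:
            raise ValueError("hidden_size and depth must be >= 1")
        expect = {"W_inp": (H, EDGE_FDIM), "W_h": (H, H), "W_o": (H, H), "W_ah": (H, ATOM_FDIM)}
        for name, shape in expect.items():
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, expected {shape}")
        get_activation(self.activation)


def init_encoder_params(
    hidden_size: int,
    depth: int,
    seed: int = 0,
    activation: str = "relu",
    dtype=np.float32,
) -> EncoderParams:
    return EncoderParams(
        W_inp=_init_matrix(param_rng(seed, "enc.W_inp"), (hidden_size, EDGE_FDIM), dtype),
        W_h=_init_matrix(param_rng(seed, "enc.W_h"), (hidden_size, hidden_size), dtype),
        W_o=_init_matrix(param_rng(seed, "enc.W_o"), (hidden_size, hidden_size), dtype),
        W_ah=_init_matrix(param_rng(seed, "enc.W_ah"), (hidden_size, ATOM_FDIM), dtype),
        hidden_size=hidden_size,
        depth=depth,
        activation=activation,
    )


@dataclasses.dataclass
class MessageTensor:
    """Per-directed-edge hidden vectors at one message passing depth."""

    messages: np.ndarray  # (n_edges, H)
    depth: int


@dataclasses.dataclass
class GraphRepresentation:
    """Per-atom hidden matrix G; row y is h_y."""

    G: np.ndarray  # (n_atoms, H)


# ---------------------------------------------------------------------------
# forward ops


def merged_edge_input(graph: MolGraph | BatchedGraph) -> np.ndarray:
    """Per-edge input f_x || f_xy (source-atom features, then bond features)."""
    return np.concatenate(
        [graph.atom_features[graph.edge_source], graph.edge_features], axis=1
    )


def init_messages(graph, params: EncoderParams, _X: np.ndarray | None = None) -> MessageTensor:
    act, _ = get_activation(params.activation)
    X = merged_edge_input(graph) if _X is None else _X
    return MessageTensor(act(X @ params.W_inp.T), depth=1)


def _incoming_sum(messages: np.ndarray, graph, n_atoms: int) -> np.ndarray:
    A = np.zeros((n_atoms, messages.shape[1]), dtype=messages.dtype)
    np.add.at(A, graph.edge_target, messages)
    return A


def update_messages(prev: MessageTensor, graph, params: EncoderParams, _X=None) -> MessageTensor:
    """One synchronous depth step over every directed edge.

    The neighbour sum for edge x->y excludes the reverse message M_{yx},
    matching the rule that x forwards to y only what arrived from the other
    neighbours.
    """
    if prev.depth < 1:
        raise ValueError("previous depth must be >= 1")
    act, _ = get_activation(params.activation)
    X = merged_edge_input(graph) if _X is None else _X
    n_atoms = graph.atom_features.shape[0]
    A = _incoming_sum(prev.messages, graph, n_atoms)
    S = A[graph.edge_source] - prev.messages[graph.edge2revedge]
    return MessageTensor(act(X @ params.W_inp.T + S @ params.W_h.T), depth=prev.depth + 1)


def node_hidden(graph, final: MessageTensor, params: EncoderParams) -> GraphRepresentation:
    """Aggregate final incoming messages with atom self-features (h_y)."""
    act, _ = get_activation(params.activation)
    n_atoms = graph.atom_features.shape[0]
    B = _incoming_sum(final.messages, graph, n_atoms)
    C = graph.atom_features.astype(final.messages.dtype) @ params.W_ah.T + B
    return GraphRepresentation(act(C @ params.W_o.T))


def encode(graph, params: EncoderParams) -> GraphRepresentation:
    """Full encoder: init -> (depth-1) updates -> node aggregation."""
    X = merged_edge_input(graph)
    m = init_messages(graph, params, _X=X)
    for _ in range(params.depth - 1):
        m = update_messages(m, graph, params, _X=X)
    return node_hidden(graph, m, params)


# ---------------------------------------------------------------------------
# forward with cache + backward (training path)


@dataclasses.dataclass
class EncoderCache:
    X: np.ndarray                   # (E, 150)
    steps: list                     # per depth>=2: (S, dact, dropmask)
    dact1: np.ndarray
    dropmask1: np.ndarray | None
    C: np.ndarray                   # (N, H) pre-W_o aggregate
    dactG: np.ndarray


def encode_with_cache(
    graph,
    params: EncoderParams,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Forward pass retaining the intermediates the backward pass needs.

    Dropout (inverted scaling) is applied to the messages after each
    activation; pass ``dropout=0`` at evaluation time.
    """
    act, dact = get_activation(params.activation)
    dtype = params.W_inp.dtype
    X = merged_edge_input(graph).astype(dtype)
    n_atoms = graph.atom_features.shape[0]
    Z = X @ params.W_inp.T

    def drop(m):
        if dropout <= 0.0:
            return m, None
        keep = (rng.random(m.shape) >= dropout).astype(dtype) / (1.0 - dropout)
        return m * keep, keep

    pre = Z
    M = act(pre)
    g1 = dact(pre, M)
    M, mask1 = drop(M)
    steps = []
    for _ in range(params.depth - 1):
        A = _incoming_sum(M, graph, n_atoms)
        S = A[graph.edge_source] - M[graph.edge2revedge]
        pre = Z + S @ params.W_h.T
        Mn = act(pre)
        g = dact(pre, Mn)
        Mn, mask = drop(Mn)
        steps.append((S, g, mask))
        M = Mn
    B = _incoming_sum(M, graph, n_atoms)
    C = graph.atom_features.astype(dtype) @ params.W_ah.T + B
    preG = C @ params.W_o.T
    G = act(preG)
    return G, EncoderCache(X=X, steps=steps, dact1=g1, dropmask1=mask1, C=C, dactG=dact(preG, G))


def encode_backward(dG: np.ndarray, graph, params: EncoderParams, cache: EncoderCache) -> dict:
    """Gradients of the loss w.r.t. the four encoder weight matrices."""
    dQ = dG * cache.dactG
    dW_o = dQ.T @ cache.C
    dC = dQ @ params.W_o
    dW_ah = dC.T @ graph.atom_features.astype(dC.dtype)
    # B = scatter-add of final messages by edge target
    dM = dC[graph.edge_target]
    dZ = np.zeros((cache.X.shape[0], params.hidden_size), dtype=dM.dtype)
    dW_h = np.zeros_like(params.W_h)
    for S, g, mask in reversed(cache.steps):
        if mask is not None:
            dM = dM * mask
        dP = dM * g
        dZ += dP
        dW_h += dP.T @ S
        dS = dP @ params.W_h
        dA = np.zeros((graph.atom_features.shape[0], params.hidden_size), dtype=dS.dtype)
        np.add.at(dA, graph.edge_source, dS)
        dM = dA[graph.edge_target] - dS[graph.edge2revedge]
    if cache.dropmask1 is not None:
        dM = dM * cache.dropmask1
    dZ += dM * cache.dact1
    dW_inp = dZ.T @ cache.X
    return {"W_inp": dW_inp, "W_h": dW_h, "W_o": dW_o, "W_ah": dW_ah}


# ---------------------------------------------------------------------------
# serialization


def encoder_state(params: EncoderParams) -> dict:
    return {
        "W_inp": params.W_inp,
        "W_h": params.W_h,
        "W_o": params.W_o,
        "W_ah": params.W_ah,
        "hidden_size": params.hidden_size,
        "depth": params.depth,
        "activation": params.activation,
    }
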