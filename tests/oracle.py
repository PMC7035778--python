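"""Explicit-loop reference implementation of the message passing equations.

Deliberately naive: python loops and dict lookups over (source, target)
pairs, float64 throughout, no scatter-adds — an independent check of the
vectorized encoder.
"""

import numpy as np


def _act(name):
    if name == "relu":
        return lambda v: np.maximum(v, 0.0)
    if name == "tanh":
        return np.tanh
    raise ValueError(name)


def reference_encode(graph, params) -> np.ndarray:
    """Per-atom hidden matrix computed edge by edge with explicit sums."""
    act = _act(params.activation)
    W_inp = params.W_inp.astype(np.float64)
    W_h = params.W_h.astype(np.float64)
    W_o = params.W_o.astype(np.float64)
    W_ah = params.W_ah.astype(np.float64)

    n_edges = 2 * graph.n_bonds
    pair_to_edge = {}
    for e in range(n_edges):
        pair_to_edge[(int(graph.edge_source[e]), int(graph.edge_target[e]))] = e

    inputs = []
    for e in range(n_edges):
        f_x = graph.atom_features[int(graph.edge_source[e])].astype(np.float64)
        f_xy = graph.edge_features[e].astype(np.float64)
        inputs.append(np.concatenate([f_x, f_xy]))

    msgs = [act(W_inp @ inputs[e]) for e in range(n_edges)]
    for _ in range(params.depth - 1):
        new = []
        for e in range(n_edges):
            x = int(graph.edge_source[e])
            y = int(graph.edge_target[e])
            total = np.zeros(params.hidden_size)
            for z in graph.node2neinode[x]:
                if z == y:
                    continue
                total = total + msgs[pair_to_edge[(z, x)]]
            new.append(act(W_inp @ inputs[e] + W_h @ total))
        msgs = new

    H = np.zeros((graph.n_atoms, params.hidden_size))
    for y in range(graph.n_atoms):
        f_y = graph.atom_features[y].astype(np.float64)
        total = np.zeros(params.hidden_size)
        for z in graph.node2neinode[y]:
            total = total + msgs[pair_to_edge[(z, y)]]
        H[y] = act(W_o @ (W_ah @ f_y + total))
    return H
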