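"""Dot-product self-attention readout over atom hidden vectors.

Given the graph representation G (one row per atom), the attention matrix
is the row-wise softmax of the raw Gram matrix,

    W_att = softmax(G G^T),        E_G = W_att G,

deliberately *unscaled* (no 1/sqrt(H) factor, unlike the transformer
convention) and with no learned query/key/value projections: G attends to
itself directly.  The molecule latent vector is the global average pool of
G + E_G over atoms.

For interpretation, each atom's weight score is an aggregate of W_att —
by default the mean of its *column* (attention received); the attention
coefficient is that score minus the molecular mean score, so coefficients
always sum to zero and positive values mark atoms drawing more than
average attention.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .encoder import GraphRepresentation


@dataclasses.dataclass
class AttentionResult:
    """Attention matrix, attentive embedding, pooled latent and per-atom coefficients."""

    W_att: np.ndarray        # (n, n) row-stochastic
    E_G: np.ndarray          # (n, H)
    latent: np.ndarray       # (H,)
    coefficients: np.ndarray  # (n,), sums to 0


def _as_matrix(G) -> np.ndarray:
    return G.G if isinstance(G, GraphRepresentation) else np.asarray(G)


def attention_weights(G) -> np.ndarray:
    """Row-wise softmax of G G^T (numerically stabilized)."""
    G = _as_matrix(G)
    if G.shape[0] < 1:
        raise ValueError("need at least one atom")
    L = G @ G.T
    L = L - L.max(axis=1, keepdims=True)
    W = np.exp(L)
    return W / W.sum(axis=1, keepdims=True)


def attentive_embedding(W_att: np.ndarray, G) -> np.ndarray:
    """E_G = W_att · G."""
    G = _as_matrix(G)
    if W_att.shape != (G.shape[0], G.shape[0]):
        raise ValueError(f"W_att shape {W_att.shape} does not match {G.shape[0]} atoms")
    return W_att @ G


def molecule_latent(G, E_G: np.ndarray) -> np.ndarray:
    """Global average pooling over atoms of G + E_G."""
    G = _as_matrix(G)
    if G.shape != E_G.shape:
        raise ValueError("G and E_G shapes differ")
    return (G + E_G).mean(axis=0)


def attention_coefficients(W_att: np.ndarray, score: str = "column") -> np.ndarray:
    """Per-atom deviation of the attention weight score from the molecular mean.

    ``score='column'`` (default) averages attention *received* by each atom;
    ``'row'`` averages attention paid.
    """
    if score == "column":
        s = W_att.mean(axis=0)
    elif score == "row":
        s = W_att.mean(axis=1)
    else:
        raise ValueError("score must be 'column' or 'row'")
    return s - s.mean()


def self_attention(G, score: str = "column") -> AttentionResult:
    """Run the full readout for one molecule."""
    G = _as_matrix(G)
    W = attention_weights(G)
    E = attentive_embedding(W, G)
    return AttentionResult(W, E, molecule_latent(G, E), attention_coefficients(W, score))


# ---------------------------------------------------------------------------
# batched pooling (used by the trainer); molecules never attend across
# molecule boundaries — the batch attention matrix is block-diagonal by
# construction because each block is computed from its own scope.


def pool_batch(G: np.ndarray, atom_scope, attention: bool = True):
    """Pool per-atom hidden vectors into per-molecule latents.

    With ``attention=False`` this is plain average pooling of G (the
    ablation encoder-only model).  Returns (latents, caches).
    """
    latents = np.empty((len(atom_scope), G.shape[1]), dtype=G.dtype)
    caches = []
    for i, (start, n) in enumerate(atom_scope):
        Gi = G[start : start + n]
        if attention:
            W = attention_weights(Gi)
            E = W @ Gi
            latents[i] = (Gi + E).mean(axis=0)
            caches.append(W)
        else:
            latents[i] = Gi.mean(axis=0)
            caches.append(None)
    return latents, caches


def pool_batch_backward(dlatents: np.ndarray, G: np.ndarray, atom_scope, caches, attention: bool = True) -> np.ndarray:
    """Gradient of the pooled latents w.r.t. G."""
    dG = np.zeros_like(G)
    for i, (start, n) in enumerate(atom_scope):
        Gi = G[start : start + n]
        d = dlatents[i] / n
        if not attention:
            dG[start : start + n] += d
            continue
        W = caches[i]
        dGi = np.tile(d, (n, 1))          # direct G path of mean(G + E)
        dE = np.tile(d, (n, 1))
        dGi += W.T @ dE                   # E = W G
        dW = dE @ Gi.T
        dL = W * (dW - (dW * W).sum(axis=1, keepdims=True))  # softmax rows
        dGi += (dL + dL.T) @ Gi           # L = G G^T
        dG[start : start + n] += dGi
    return dG
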