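"""Independent brute-force reference implementations.

Every function here recomputes a pipeline quantity with explicit scalar
loops (or closed forms), sharing no code with the package internals, so the
vectorised implementations can be checked against them on small instances.
"""

import numpy as np


def squash_ref(s: np.ndarray) -> np.ndarray:
    """v = (1 - e^{-||s||}) s / ||s||, zero vector fixed."""
    n = np.linalg.norm(s)
    if n == 0:
        return np.zeros_like(s)
    return (1.0 - np.exp(-n)) * s / n


def votes_ref(u: np.ndarray, W: np.ndarray) -> np.ndarray:
    b, n_in, d_in = u.shape
    n_out, d_out = W.shape[1], W.shape[3]
    out = np.zeros((b, n_in, n_out, d_out))
    for bb in range(b):
        for i in range(n_in):
            for j in range(n_out):
                for e in range(d_out):
                    out[bb, i, j, e] = sum(u[bb, i, d] * W[i, j, d, e]
                                           for d in range(d_in))
    return out


def self_attention_routing_ref(u_hat: np.ndarray, B: np.ndarray,
                               D: float) -> tuple[np.ndarray, np.ndarray]:
    """Transcription of the routing equations with explicit loops.

    Returns (output capsules v, coupling coefficients C).
    """
    b, n_in, n_out, d_out = u_hat.shape
    v = np.zeros((b, n_out, d_out))
    C_all = np.zeros((b, n_in, n_out))
    for bb in range(b):
        rowsum = np.zeros((n_in, n_out))
        for j in range(n_out):
            A = np.zeros((n_in, n_in))
            for i in range(n_in):
                for k in range(n_in):
                    A[i, k] = np.dot(u_hat[bb, i, j], u_hat[bb, k, j]) / D
            for i in range(n_in):
                rowsum[i, j] = A[i].sum()
        for i in range(n_in):
            e = np.exp(rowsum[i] - rowsum[i].max())
            C_all[bb, i] = e / e.sum()
        for j in range(n_out):
            s = np.zeros(d_out)
            for i in range(n_in):
                s += (C_all[bb, i, j] + B[i, j]) * u_hat[bb, i, j]
            v[bb, j] = squash_ref(s)
    return v, C_all


def margin_loss_ref(v_norms: np.ndarray, onehot: np.ndarray,
                    m_plus=0.9, m_minus=0.1, lam=0.5) -> float:
    total = 0.0
    for b in range(v_norms.shape[0]):
        for k in range(v_norms.shape[1]):
            T = onehot[b, k]
            total += (T * max(0.0, m_plus - v_norms[b, k]) ** 2
                      + lam * (1 - T) * max(0.0, v_norms[b, k] - m_minus) ** 2)
    return total / v_norms.shape[0]


def gat_layer_ref(H: np.ndarray, edges: list[tuple[int, int]],
                  W: np.ndarray, a_dst: np.ndarray, a_src: np.ndarray,
                  slope: float = 0.2) -> np.ndarray:
    """One GAT layer, single head, explicit loops; ``edges`` as (src, dst)
    pairs including self-loops. Returns pre-activation aggregation."""
    n, d_out = H.shape[0], W.shape[1]
    z = H @ W
    nbrs = {i: [] for i in range(n)}
    for s, d in edges:
        nbrs[d].append(s)
    out = np.zeros((n, d_out))
    for i in range(n):
        js = nbrs[i]
        e = []
        for j in js:
            x = float(a_dst @ z[i] + a_src @ z[j])
            e.append(x if x > 0 else slope * x)
        e = np.array(e)
        alpha = np.exp(e - e.max())
        alpha /= alpha.sum()
        for k, j in enumerate(js):
            out[i] += alpha[k] * z[j]
    return out


def variance_kept_ref(values: np.ndarray, threshold: float) -> list[int]:
    kept = []
    for j in range(values.shape[1]):
        col = values[:, j]
        var = np.mean(col ** 2) - np.mean(col) ** 2
        if var >= threshold:
            kept.append(j)
    return kept


def correlation_kept_ref(values: np.ndarray, threshold: float,
                         use_absolute: bool = True) -> list[int]:
    """Greedy left-to-right pass with per-pair Pearson recomputation."""
    kept: list[int] = []
    for j in range(values.shape[1]):
        drop = False
        for k in kept:
            x, y = values[:, k], values[:, j]
            rho = (np.mean(x * y) - np.mean(x) * np.mean(y)) / (
                np.sqrt(np.mean(x ** 2) - np.mean(x) ** 2)
                * np.sqrt(np.mean(y ** 2) - np.mean(y) ** 2))
            if (abs(rho) if use_absolute else rho) > threshold:
                drop = True
                break
        if not drop:
            kept.append(j)
    return kept


def auc_ref(labels: np.ndarray, scores: np.ndarray) -> float:
    """All-pairs AUC: P(score_pos > score_neg) with ties counting 1/2."""
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
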