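"""Skip-gram with negative sampling (SGNS) over walk corpora.

A compact, single-threaded word2vec-style trainer operating on integer token
matrices (rows = walks). It follows the classic C implementation's conventions:
dynamic (randomly shrunk) context window, unigram^0.75 negative-sampling table,
sigmoid lookup table clipped at ±6, and linear learning-rate decay. Being
sequential and seeded, training is bit-reproducible — a contract the rest of
the pipeline relies on.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EXP_TABLE_SIZE = 1000
_MAX_EXP = 6.0


def _build_exp_table() -> np.ndarray:
    x = (np.arange(_EXP_TABLE_SIZE) / _EXP_TABLE_SIZE * 2 - 1) * _MAX_EXP
    return (1.0 / (1.0 + np.exp(-x))).astype(np.float32)


def build_negative_table(counts: np.ndarray, size: int = 1_000_000) -> np.ndarray:
    """Unigram^0.75 sampling table mapping uniform draws to vocabulary ids."""
    p = counts.astype(np.float64) ** 0.75
    p /= p.sum()
    bounds = np.cumsum(p) * size
    table = np.zeros(size, dtype=np.int32)
    j = 0
    for i in range(size):
        while j < len(bounds) - 1 and i >= bounds[j]:
            j += 1
        table[i] = j
    return table


@njit(cache=True, fastmath=True)
def _train_epochs(
    walks,  # (n_walks, L) int32
    syn0,  # (V, dim) float32, in/out
    syn1,  # (V, dim) float32, in/out
    neg_table,  # int32
    window: int,
    negative: int,
    epochs: int,
    alpha0: float,
    min_alpha: float,
    seed: int,
):
    np.random.seed(seed)
    n_walks, L = walks.shape
    dim = syn0.shape[1]
    table_size = neg_table.shape[0]
    total = epochs * n_walks * L
    processed = 0
    work = np.zeros(dim, dtype=np.float32)
    for ep in range(epochs):
        for wi in range(n_walks):
            for pos in range(L):
                center = walks[wi, pos]
                if center < 0:
                    processed += 1
                    continue
                alpha = alpha0 * (1.0 - processed / (total + 1))
                if alpha < min_alpha:
                    alpha = min_alpha
                b = np.random.randint(0, window)
                lo = pos - window + b
                if lo < 0:
                    lo = 0
                hi = pos + window - b + 1
                if hi > L:
                    hi = L
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    ctx = walks[wi, cpos]
                    if ctx < 0:
                        continue
                    # predict center's vector from context word (skip-gram)
                    for d in range(dim):
                        work[d] = 0.0
                    v = syn0[ctx]
                    for k in range(negative + 1):
                        if k == 0:
                            target = center
                            label = 1.0
                        else:
                            target = neg_table[np.random.randint(0, table_size)]
                            if target == center:
                                continue
                            label = 0.0
                        u = syn1[target]
                        f = np.float32(0.0)
                        for d in range(dim):
                            f += v[d] * u[d]
                        if f > _MAX_EXP:
                            g = (label - 1.0) * alpha
                        elif f < -_MAX_EXP:
                            g = label * alpha
                        else:
                            idx = int((f + _MAX_EXP) * (_EXP_TABLE_SIZE / (2 * _MAX_EXP)))
                            sig = _EXP[idx]
                            g = (label - sig) * alpha
                        for d in range(dim):
                            work[d] += g * u[d]
                            u[d] += g * v[d]
                    for d in range(dim):
                        v[d] += work[d]
                processed += 1
    return syn0


# module-level sigmoid table captured by the jitted function
_EXP = _build_exp_table()


def train_sgns(
    walks: np.ndarray,
    vocab_size: int,
    dim: int = 128,
    window: int = 5,
    negative: int = 5,
    epochs: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    seed: int = 0,
) -> np.ndarray:
    """Train SGNS vectors on an int32 walk matrix (−1 = padding).

    Returns the (vocab_size, dim) float32 input-embedding matrix.
    """
    walks = np.ascontiguousarray(walks, dtype=np.int32)
    if vocab_size < 2:
        raise ValueError("vocabulary must contain at least 2 nodes")
    rng = np.random.default_rng(seed)
    syn0 = ((rng.random((vocab_size, dim), dtype=np.float32) - 0.5) / dim).astype(
        np.float32
    )
    syn1 = np.zeros((vocab_size, dim), dtype=np.float32)
    counts = np.bincount(walks[walks >= 0].ravel(), minlength=vocab_size)
    if (counts == 0).all():
        raise ValueError("empty corpus")
    neg_table = build_negative_table(np.maximum(counts, 1))
    _train_epochs(
        walks,
        syn0,
        syn1,
        neg_table,
        int(window),
        int(negative),
        int(epochs),
        float(alpha),
        float(min_alpha),
        int(seed) & 0x7FFFFFFF,
    )
    return syn0
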