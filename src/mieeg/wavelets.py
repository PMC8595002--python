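"""Orthogonal Daubechies filter banks and periodized (I)DWT / wavelet-packet
transforms.

Implemented from first principles because the pipeline's invariants (perfect
reconstruction and Parseval energy conservation to 1e-8) require a square
orthogonal transform.  Signals are extended periodically; odd-length blocks
are padded by replicating the final sample, and the pad is removed again on
synthesis, so round trips are exact for any length.
"""

from __future__ import annotations

import functools

import numpy as np
from scipy.special import comb

__all__ = [
    "daubechies_filters",
    "dwt_single",
    "idwt_single",
    "wavedec",
    "waverec",
    "wp_decompose",
    "wp_reconstruct",
]


@functools.lru_cache(maxsize=None)
def daubechies_filters(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Return the (lowpass, highpass) analysis pair for dbN, length 2N.

    Built by spectral factorization of the Daubechies half-band polynomial:
    the minimum-phase root of |m0|^2 = cos^{2N}(w/2) * P(sin^2(w/2)) is kept
    for every root of P.  Normalized so that sum(lo) = sqrt(2).
    """
    if order < 1:
        raise ValueError("Daubechies order must be >= 1")
    if order == 1:  # Haar, closed form
        lo = np.array([1.0, 1.0]) / np.sqrt(2.0)
    else:
        n = order
        # P(y) = sum_k C(N-1+k, k) y^k, k = 0..N-1  (highest degree first)
        p = np.array([comb(n - 1 + k, k, exact=True) for k in range(n)][::-1],
                     dtype=float)
        roots_y = np.roots(p)
        # map each root y -> z via z^2 - (2 - 4y) z + 1 = 0, keep |z| < 1
        z_roots = []
        for y in roots_y:
            c = 2.0 - 4.0 * y
            zs = np.roots([1.0, -c, 1.0])
            z_roots.append(zs[np.argmin(np.abs(zs))])
        # h(z) ~ (1 + z)^N * prod (z - z_k); conjugate pairing keeps it real
        h = np.array([1.0], dtype=complex)
        for _ in range(n):
            h = np.convolve(h, [1.0, 1.0])
        for zk in z_roots:
            h = np.convolve(h, [1.0, -zk])
        lo = np.real(h)
        lo *= np.sqrt(2.0) / lo.sum()
    hi = lo[::-1].copy()
    hi[1::2] *= -1.0  # quadrature mirror: g[k] = (-1)^k h[L-1-k]
    lo.setflags(write=False)
    hi.setflags(write=False)
    return lo, hi


def _pad_even(x: np.ndarray) -> np.ndarray:
    if len(x) % 2:
        return np.concatenate([x, x[-1:]])
    return x


def dwt_single(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """One periodized analysis step: x -> (approx, detail).

    Odd-length inputs are padded by one replicated sample first, so the
    output blocks both have ceil(len(x)/2) coefficients.
    """
    x = _pad_even(np.asarray(x, dtype=float))
    n = len(x)
    half = n // 2
    a = np.zeros(half)
    d = np.zeros(half)
    k2 = 2 * np.arange(half)
    for t in range(len(lo)):
        idx = (k2 + t) % n
        a += lo[t] * x[idx]
        d += hi[t] * x[idx]
    return a, d


def idwt_single(a: np.ndarray, d: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                out_len: int) -> np.ndarray:
    """Inverse of :func:`dwt_single`, trimmed to ``out_len`` samples."""
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    if len(a) != len(d):
        raise ValueError("approximation/detail length mismatch")
    n = 2 * len(a)
    y = np.zeros(n)
    k2 = 2 * np.arange(len(a))
    for t in range(len(lo)):
        idx = (k2 + t) % n
        np.add.at(y, idx, lo[t] * a + hi[t] * d)
    return y[:out_len]


def wavedec(x: np.ndarray, lo: np.ndarray, hi: np.ndarray, level: int):
    """Multilevel DWT: returns ([D1, D2, ..., Dlevel, A_level], lengths).

    ``lengths`` records the input length of every analysis step so that
    :func:`waverec` can undo the odd-length padding exactly.
    """
    x = np.asarray(x, dtype=float)
    if level < 1:
        raise ValueError("level must be >= 1")
    if len(x) < 2 ** level:
        raise ValueError(
            f"signal of {len(x)} samples too short for level {level}")
    details = []
    lengths = []
    cur = x
    for _ in range(level):
        lengths.append(len(cur))
        a, d = dwt_single(cur, lo, hi)
        details.append(d)
        cur = a
    return details + [cur], lengths


def waverec(bands, lengths, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Inverse of :func:`wavedec`."""
    *details, approx = bands
    cur = np.asarray(approx, dtype=float)
    for d, n in zip(reversed(details), reversed(lengths)):
        cur = idwt_single(cur, d, lo, hi, n)
    return cur


def _wp_lengths(n: int, level: int) -> list[list[int]]:
    """Block length at every tree level; lens[l][i] for node i at depth l."""
    lens = [[n]]
    for _ in range(level):
        nxt = []
        for m in lens[-1]:
            c = (m + 1) // 2
            nxt.extend([c, c])
        lens.append(nxt)
    return lens


def wp_decompose(x: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                 level: int) -> list[np.ndarray]:
    """Complete wavelet-packet tree of the given depth.

    Returns the 2**level terminal blocks in natural filter-bank order:
    each node splits into [lowpass child, highpass child], recursively.
    level 0 returns the input as a single block.
    """
    x = np.asarray(x, dtype=float)
    if level < 0:
        raise ValueError("level must be >= 0")
    if len(x) < 2 ** max(level, 1) and level > 0:
        raise ValueError(
            f"signal of {len(x)} samples too short for level {level}")
    nodes = [x]
    for _ in range(level):
        nxt = []
        for node in nodes:
            a, d = dwt_single(node, lo, hi)
            nxt.extend([a, d])
        nodes = nxt
    return nodes


def wp_reconstruct(blocks, lo: np.ndarray, hi: np.ndarray,
                   source_length: int) -> np.ndarray:
    """Invert :func:`wp_decompose` given the original signal length."""
    n_blocks = len(blocks)
    level = int(np.log2(n_blocks))
    if 2 ** level != n_blocks:
        raise ValueError("block count must be a power of two")
    lens = _wp_lengths(source_length, level)
    nodes = [np.asarray(b, dtype=float) for b in blocks]
    for depth in range(level, 0, -1):
        parent_lens = lens[depth - 1]
        nxt = []
        for i in range(0, len(nodes), 2):
            out_len = parent_lens[i // 2]
            nxt.append(idwt_single(nodes[i], nodes[i + 1], lo, hi, out_len))
        nodes = nxt
    return nodes[0]
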