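"""Per-position element frequencies and the position-specific score matrix.

For a population of N equal-length secondary structure strings the
frequency matrix is ``f[k, j] = (1/N) * sum_i I(X_ij = k)`` over the
7-letter element alphabet.  Scoring a foreground population against a
random-sequence background combines a frequency-weighted log-odds with an
information-content normalization:

    mu[k, j]    = (c_bg[k, j] + alpha) / (N_bg + 7 * alpha)
    theta[k, j] = (7 * alpha * mu[k, j] + c[k, j]) / (7 * alpha + N)
    W[k, j]     = f[k, j] * log2(theta[k, j] / mu[k, j])
    H[j]        = max(0, log2(7) - sum_k f[k, j] * log2(1 / mu[k, j]))
    S[k, j]     = H[j] * W[k, j]

``mu`` is the additively smoothed background position frequency matrix,
``theta`` the normalized position probability matrix, ``alpha`` the
smoothing pseudo-count (default 1).  ``S`` is zero for an element absent
from the foreground; the signed display score
``Dsp[k, j] = H[j] * log2(theta/mu)`` goes negative there instead, which
is what plots use to show depletion below the axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sse_annotation import SSE_ALPHABET, SSE_INDEX

__all__ = [
    "PositionFrequencyMatrix",
    "DeltaSSEMatrix",
    "PSSM",
    "strings_to_counts",
    "compute_frequencies",
    "delta_sse",
    "compute_pssm",
    "score_string",
    "best_match",
    "matrix_frame",
]

K = len(SSE_ALPHABET)


def _check_strings(ss_strings: Sequence[str]) -> int:
    if not ss_strings:
        raise ValueError("empty string set")
    l = len(ss_strings[0])
    for s in ss_strings:
        if len(s) != l:
            raise ValueError(
                f"ragged lengths: expected {l}, got {len(s)} for {s[:10]!r}..."
            )
        bad = set(s) - set(SSE_ALPHABET)
        if bad:
            raise ValueError(f"letters outside element alphabet: {sorted(bad)}")
    return l


def strings_to_counts(ss_strings: Sequence[str]) -> np.ndarray:
    """7 x l matrix of letter counts per position."""
    l = _check_strings(ss_strings)
    arr = np.frombuffer(
        "".join(ss_strings).encode("ascii"), dtype=np.uint8
    ).reshape(len(ss_strings), l)
    counts = np.zeros((K, l), dtype=np.int64)
    for k, letter in enumerate(SSE_ALPHABET):
        counts[k] = (arr == ord(letter)).sum(axis=0)
    return counts


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    freq: np.ndarray  # 7 x l, columns sum to 1
    n_strings: int
    l: int


@dataclass(frozen=True)
class DeltaSSEMatrix:
    delta: np.ndarray  # 7 x l percentage points; columns sum to 0


@dataclass(frozen=True)
class PSSM:
    alpha: float
    counts: np.ndarray  # foreground counts c
    freq: np.ndarray  # foreground frequencies f
    mu: np.ndarray  # smoothed background position frequencies
    theta: np.ndarray  # normalized position probabilities
    W: np.ndarray  # position weight matrix
    H: np.ndarray  # information-content normalization per column
    S: np.ndarray  # score matrix, bits
    Dsp: np.ndarray  # signed display score H * log2(theta/mu)
    n_foreground: int
    n_background: int

    @property
    def l(self) -> int:
        return self.S.shape[1]


def compute_frequencies(ss_strings: Sequence[str]) -> PositionFrequencyMatrix:
    strings = list(ss_strings)
    counts = strings_to_counts(strings)
    n = len(strings)
    return PositionFrequencyMatrix(
        freq=counts / n, n_strings=n, l=counts.shape[1]
    )


def delta_sse(
    pfm_dom: PositionFrequencyMatrix, pfm_domsub: PositionFrequencyMatrix
) -> DeltaSSEMatrix:
    """Percentage-point shift: dominant-only minus dominant+suboptimal."""
    if pfm_dom.l != pfm_domsub.l:
        raise ValueError(
            f"length mismatch: {pfm_dom.l} vs {pfm_domsub.l}"
        )
    return DeltaSSEMatrix(delta=100.0 * (pfm_dom.freq - pfm_domsub.freq))


def compute_pssm(
    foreground: Sequence[str],
    background: Sequence[str],
    alpha: float = 1.0,
) -> PSSM:
    if alpha <= 0:
        raise ValueError("alpha must be > 0 (background smoothing)")
    fg = list(foreground)
    bg = list(background)
    if not bg:
        raise ValueError("background must be non-empty")
    c = strings_to_counts(fg)
    c_bg = strings_to_counts(bg)
    if c.shape != c_bg.shape:
        raise ValueError(
            f"foreground/background length mismatch: {c.shape[1]} vs {c_bg.shape[1]}"
        )
    n, n_bg = len(fg), len(bg)
    f = c / n
    mu = (c_bg + alpha) / (n_bg + K * alpha)
    theta = (K * alpha * mu + c) / (K * alpha + n)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_odds = np.log2(theta / mu)
    W = f * log_odds
    H = np.maximum(0.0, math.log2(K) + (f * np.log2(mu)).sum(axis=0))
    S = H * W
    Dsp = H * log_odds
    return PSSM(
        alpha=alpha, counts=c, freq=f, mu=mu, theta=theta,
        W=W, H=H, S=S, Dsp=Dsp, n_foreground=n, n_background=n_bg,
    )


def score_string(pssm: PSSM, ss_string: str) -> float:
    """Total score in bits: sum over positions of S[letter_j, j]."""
    if len(ss_string) != pssm.l:
        raise ValueError(f"string length {len(ss_string)} != matrix length {pssm.l}")
    try:
        rows = [SSE_INDEX[ch] for ch in ss_string]
    except KeyError as exc:
        raise ValueError(f"letter outside element alphabet: {exc}") from exc
    return float(pssm.S[rows, np.arange(pssm.l)].sum())


def best_match(
    pssm: PSSM, ss_strings: Mapping[str, str] | Iterable[tuple[str, str]]
) -> tuple[str, float]:
    """Label of the highest-scoring string (ties: lexicographically
    smallest label), with its score."""
    items = (
        list(ss_strings.items())
        if isinstance(ss_strings, Mapping)
        else list(ss_strings)
    )
    if not items:
        raise ValueError("empty population")
    scored = sorted(
        ((label, score_string(pssm, s)) for label, s in items),
        key=lambda t: (-t[1], t[0]),
    )
    return scored[0]


def matrix_frame(matrix: np.ndarray) -> pd.DataFrame:
    """7 x l matrix as a DataFrame with element-letter index and 1-based
    base-position columns (the TSV export layout)."""
    return pd.DataFrame(
        matrix,
        index=list(SSE_ALPHABET),
        columns=range(1, matrix.shape[1] + 1),
    )
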