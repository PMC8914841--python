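"""Sample entropy (SampEn) of single-channel signals.

SampEn(m, r) = -ln(A / B), where B counts pairs of length-m templates whose
Chebyshev distance is <= r, A counts the same for length m+1, and
self-matches are excluded. r is expressed as a fraction of the signal's
standard deviation, which makes the statistic amplitude-invariant. Low SampEn
means a regular signal: a channel swamped by a slow eye-blink transient is
*more* regular than ongoing EEG, which is what the SETET screen exploits.

Both template lengths use the same T - m - 1 + 1 = T - m starting offsets so
the two counts are comparable (the standard convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .types import Trial


@dataclass(frozen=True)
class SampEnParams:
    """Template length ``m_embed`` and SD-relative tolerance ``r_frac``.

    The defaults (m=2, r=0.2*SD) are the standard choice for short
    physiological signals.
    """

    m_embed: int = 2
    r_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.m_embed < 1:
            raise ValueError("m_embed must be >= 1")
        if self.r_frac <= 0:
            raise ValueError("r_frac must be positive")


def _match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """(B, A): template-pair match counts at lengths m and m+1.

    Vectorized over all pairs; O(T^2) memory on T <= a few thousand signals,
    which covers the 200-sample trials this package targets.
    """
    n = x.size - m  # number of usable template start offsets
    # pairwise Chebyshev distances built up coordinate by coordinate
    d_m = np.zeros((n, n))
    for k in range(m):
        seg = x[k:k + n]
        np.maximum(d_m, np.abs(seg[:, None] - seg[None, :]), out=d_m)
    iu = np.triu_indices(n, k=1)
    b = int(np.count_nonzero(d_m[iu] <= r))
    seg = x[m:m + n]
    d_m1 = np.maximum(d_m, np.abs(seg[:, None] - seg[None, :]))
    a = int(np.count_nonzero(d_m1[iu] <= r))
    return b, a


def sample_entropy(x: Sequence[float] | np.ndarray, params: SampEnParams = SampEnParams()) -> float:
    """SampEn of a 1-D signal; 0 for constant signals, +inf when no (m+1)-matches exist."""
    x = np.asarray(x, dtype=float).ravel()
    m = params.m_embed
    if x.size <= m + 1:
        raise ValueError(f"signal of {x.size} samples too short for m_embed={m}")
    sd = float(np.std(x))
    if sd == 0.0:
        # a constant signal is maximally regular
        return 0.0
    r = params.r_frac * sd
    b, a = _match_counts(x, m, r)
    if a == 0:
        return math.inf
    if a == b:
        return 0.0
    return -math.log(a / b)


def max_entropy(n_samples: int, params: SampEnParams = SampEnParams()) -> float:
    """Finite cap used when aggregating +inf SampEn values.

    ln(n*(n-1)) with n the template count: the largest value a single
    observed (m+1)-match could have produced.
    """
    n = n_samples - params.m_embed
    return math.log(n * (n - 1))


def channel_entropies(trial: Trial, params: SampEnParams = SampEnParams()) -> np.ndarray:
    """SampEn of every channel of a trial (vector of length C, may contain +inf)."""
    return np.array([sample_entropy(ch, params) for ch in trial.data])


def mean_channel_entropy(
    trials: Iterable[Trial],
    channels: Sequence[str],
    params: SampEnParams = SampEnParams(),
) -> float:
    """Mean SampEn over every (trial, selected channel) pair.

    +inf contributions are clamped to :func:`max_entropy` so the mean stays
    finite; the per-channel raw values are available via
    :func:`channel_entropies`.
    """
    trials = list(trials)
    if not trials or not channels:
        raise ValueError("need at least one trial and one channel")
    vals: list[float] = []
    for trial in trials:
        idx = [trial.channel_index(c) for c in channels]
        cap = max_entropy(trial.n_samples, params)
        for i in idx:
            se = sample_entropy(trial.data[i], params)
            vals.append(min(se, cap))
    return float(np.mean(vals))
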