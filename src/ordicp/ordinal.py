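"""Bandt–Pompe ordinal symbolization, permutation entropy and missing patterns.

The Bandt–Pompe construction maps each length-``m`` embedded vector
``(x_t, x_{t+tau}, ..., x_{t+(m-1)tau})`` of a scalar time series onto the
permutation describing the ordering of its values.  The Shannon entropy of
the resulting pattern distribution, normalized by ``ln(m!)``, is the
permutation entropy (PE), a complexity measure bounded in ``[0, 1]``.
Patterns that never occur in a window are *missing* (forbidden) patterns;
their count, normalized by ``m!``, is the normalized number of missing
patterns (nNMP).

Conventions
-----------
* A pattern is the tuple of 1-based *original indices* of the values sorted
  ascending (so ``(8, 9, 5)`` maps to ``(3, 1, 2)``: the smallest value sat
  at position 3, the next at position 1, the largest at position 2).
* Ties are broken stably, earlier index first.
* Patterns are ranked 1..m! in strict lexicographic order of their digit
  tuples, so the fully ascending pattern has rank 1 and the fully
  descending pattern has rank m!.
* Natural logarithms throughout; ``0 * ln 0 := 0``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MAX_EMBEDDING_DIM",
    "EmbeddingConfig",
    "OrdinalPattern",
    "PatternDistribution",
    "pattern_of",
    "rank_of",
    "unrank",
    "symbolize",
    "distribution",
    "permutation_entropy",
    "missing_patterns",
]

logger = logging.getLogger(__name__)

#: m! must stay tractable; 10! = 3,628,800 is the supported ceiling.
MAX_EMBEDDING_DIM = 10


@dataclass(frozen=True)
class EmbeddingConfig:
    """Embedding dimension ``m`` and delay ``tau`` (in samples).

    Defaults follow the ICP-monitoring protocol: ``m=6`` (720 patterns,
    a compromise between resolution and per-window cost) and ``tau=1``.
    """

    m: int = 6
    tau: int = 1

    def __post_init__(self) -> None:
        if not isinstance(self.m, (int, np.integer)) or not 2 <= self.m <= MAX_EMBEDDING_DIM:
            raise ValueError(
                f"embedding dimension m must be an integer in [2, {MAX_EMBEDDING_DIM}], got {self.m!r}"
            )
        if not isinstance(self.tau, (int, np.integer)) or self.tau < 1:
            raise ValueError(f"delay tau must be a positive integer, got {self.tau!r}")

    @property
    def n_patterns(self) -> int:
        """Cardinality of the pattern alphabet, ``m!``."""
        return math.factorial(self.m)

    @property
    def span(self) -> int:
        """Number of samples covered by one embedded vector, ``(m-1)*tau + 1``."""
        return (self.m - 1) * self.tau + 1


def _validate_permutation(digits: Sequence[int]) -> tuple[int, ...]:
    digits = tuple(int(d) for d in digits)
    m = len(digits)
    if m < 1 or sorted(digits) != list(range(1, m + 1)):
        raise ValueError(f"not a permutation of 1..{m}: {digits!r}")
    return digits


@dataclass(frozen=True)
class OrdinalPattern:
    """A Bandt–Pompe ordinal pattern: a permutation of ``(1..m)`` plus its rank.

    ``digits[k]`` is the 1-based original position of the ``k``-th smallest
    value of the embedded vector.  ``rank`` is the 1-based lexicographic rank
    of ``digits``; the ascending pattern ``(1, 2, ..., m)`` has rank 1 and the
    descending pattern ``(m, ..., 2, 1)`` has rank ``m!``.
    """

    digits: tuple[int, ...]
    rank: int = field(init=False)

    def __post_init__(self) -> None:
        digits = _validate_permutation(self.digits)
        object.__setattr__(self, "digits", digits)
        object.__setattr__(self, "rank", _lehmer_rank(digits))

    @property
    def m(self) -> int:
        return len(self.digits)

    def __str__(self) -> str:  # e.g. "312"
        return "".join(str(d) for d in self.digits)


def _lehmer_rank(digits: tuple[int, ...]) -> int:
    """1-based lexicographic rank of a permutation via its Lehmer code."""
    m = len(digits)
    rank = 0
    for i in range(m):
        smaller_right = sum(1 for j in range(i + 1, m) if digits[j] < digits[i])
        rank += smaller_right * math.factorial(m - 1 - i)
    return rank + 1


def pattern_of(window: Sequence[float]) -> OrdinalPattern:
    """Map one embedded vector to its ordinal pattern.

    Parameters
    ----------
    window
        Exactly ``m`` real values.

    Returns
    -------
    OrdinalPattern
        The permutation listing, in ascending value order, the 1-based
        original indices.  Equal values are ordered earlier-index-first.

    Examples
    --------
    >>> pattern_of([8, 9, 5]).digits
    (3, 1, 2)
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 1:
        raise ValueError("window must be a non-empty 1-D sequence")
    order = np.argsort(w, kind="stable") + 1
    return OrdinalPattern(tuple(int(i) for i in order))


def rank_of(pattern: OrdinalPattern | Sequence[int]) -> int:
    """Lexicographic rank (1..m!) of an ordinal pattern or raw digit tuple."""
    if isinstance(pattern, OrdinalPattern):
        return pattern.rank
    return _lehmer_rank(_validate_permutation(pattern))


def unrank(rank: int, m: int) -> OrdinalPattern:
    """Inverse of :func:`rank_of`: the pattern at lexicographic position ``rank``.

    ``unrank(1, m)`` is the ascending pattern, ``unrank(m!, m)`` the
    descending one.
    """
    n = math.factorial(m)
    if not 1 <= rank <= n:
        raise ValueError(f"rank must be in 1..{n}, got {rank}")
    r = rank - 1
    pool = list(range(1, m + 1))
    digits = []
    for i in range(m):
        f = math.factorial(m - 1 - i)
        q, r = divmod(r, f)
        digits.append(pool.pop(q))
    return OrdinalPattern(tuple(digits))


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """All overlapping embedded vectors as rows of an ``(n_vec, m)`` array."""
    n_vec = x.size - (m - 1) * tau
    idx = np.arange(n_vec)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _ranks_of_rows(emb: np.ndarray) -> np.ndarray:
    """Vectorized stable-argsort + Lehmer ranking of each row."""
    m = emb.shape[1]
    order = np.argsort(emb, axis=1, kind="stable")  # 0-based digits
    rank = np.zeros(emb.shape[0], dtype=np.int64)
    for i in range(m):
        smaller_right = np.zeros(emb.shape[0], dtype=np.int64)
        for j in range(i + 1, m):
            smaller_right += order[:, j] < order[:, i]
        rank += smaller_right * math.factorial(m - 1 - i)
    return rank + 1


def symbolize(
    series: Sequence[float],
    cfg: EmbeddingConfig = EmbeddingConfig(),
    *,
    strict: bool = True,
) -> np.ndarray:
    """Bandt–Pompe symbolization of a time series.

    Maps every overlapping embedded vector of ``series`` to the lexicographic
    rank of its ordinal pattern.

    Parameters
    ----------
    series
        Real-valued 1-D time series of length ``T``.
    cfg
        Embedding dimension and delay.
    strict
        If the series is too short for a single embedded vector
        (``T < (m-1)*tau + 1``), raise (default) or warn and return an
        empty array.

    Returns
    -------
    numpy.ndarray
        Integer ranks in ``1..m!``, length ``T - (m-1)*tau``.

    Examples
    --------
    >>> symbolize([3, 6, 8, 9, 5, 10, 2], EmbeddingConfig(m=3, tau=1))
    array([1, 1, 5, 3, 5])
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    n_vec = x.size - (cfg.m - 1) * cfg.tau
    if n_vec < 1:
        msg = (
            f"series of length {x.size} too short for m={cfg.m}, tau={cfg.tau} "
            f"(needs at least {cfg.span} samples)"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
        return np.empty(0, dtype=np.int64)
    return _ranks_of_rows(_embed(x, cfg.m, cfg.tau))


@dataclass(frozen=True)
class PatternDistribution:
    """Empirical probability distribution over all ``m!`` ordinal patterns."""

    m: int
    counts: np.ndarray  # length m!, counts[i] = occurrences of rank i+1
    n_vectors: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (math.factorial(self.m),):
            raise ValueError(f"counts must have length {self.m}! = {math.factorial(self.m)}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() != self.n_vectors:
            raise ValueError("counts must sum to n_vectors")
        if self.n_vectors < 1:
            raise ValueError("distribution requires at least one embedded vector")
        object.__setattr__(self, "counts", counts)

    @property
    def n_patterns(self) -> int:
        return self.counts.size

    @property
    def probs(self) -> np.ndarray:
        """Relative frequencies ``p_i = counts_i / n_vectors`` (sum to 1)."""
        return self.counts / self.n_vectors

    def prob_of_rank(self, rank: int) -> float:
        return float(self.counts[rank - 1]) / self.n_vectors


def distribution(ranks: Iterable[int], m: int) -> PatternDistribution:
    """Tabulate pattern-rank occurrences into a :class:`PatternDistribution`.

    Raises on an empty rank sequence — there is no empirical distribution to
    speak of — and on ranks outside ``1..m!``.
    """
    r = np.asarray(list(ranks) if not isinstance(ranks, np.ndarray) else ranks, dtype=np.int64)
    if r.size == 0:
        raise ValueError("cannot form a pattern distribution from zero embedded vectors")
    n = math.factorial(m)
    if (r < 1).any() or (r > n).any():
        raise ValueError(f"pattern ranks must lie in 1..{n}")
    counts = np.bincount(r, minlength=n + 1)[1:]
    return PatternDistribution(m=m, counts=counts, n_vectors=int(r.size))


def entropy_from_counts(counts: np.ndarray, n_vectors: int) -> float:
    """Normalized Shannon entropy from raw pattern counts (internal fast path)."""
    c = counts[counts > 0]
    p = c / n_vectors
    h = float(-(p * np.log(p)).sum()) / math.log(counts.size)
    # guard the float boundary; H is mathematically in [0, 1]
    return min(max(h, 0.0), 1.0)


def permutation_entropy(dist: PatternDistribution) -> float:
    """Normalized permutation entropy ``H[P] = S(P) / ln(m!)`` in ``[0, 1]``.

    ``S`` is the Shannon entropy in nats; zero-probability patterns
    contribute nothing.  ``H`` is 1 exactly for the uniform distribution and
    0 when a single pattern has probability 1.
    """
    return entropy_from_counts(dist.counts, dist.n_vectors)


def missing_patterns(dist: PatternDistribution) -> tuple[int, float]:
    """Missing (forbidden) patterns of a distribution.

    Returns
    -------
    count : int
        Number of patterns with zero occurrences.
    normalized : float
        ``count / m!`` in ``[0, 1]``.
    """
    count = int((dist.counts == 0).sum())
    return count, count / dist.n_patterns
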