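"""Type-frequency distributions and distribution-based productivity measures.

A morphological rule (here, a plural suffix) applies to a set of word *types*;
each type is observed some number of times (*tokens*). This module provides
the core containers for such data — a rank-ordered :class:`FrequencyDistribution`
and its derived :class:`FrequencySpectrum` — together with the measures of a
rule's generalisability that operate on them:

* Shannon entropy of the type distribution (in bits), a summary of skew;
* the Tolerance Principle threshold ``theta = N / ln N`` and its
  productive/unproductive verdict;
* potential productivity ``P`` (hapax legomena over tokens), the growth rate
  of the vocabulary;
* a low-frequency-tail comparison that walks two frequency spectra upward
  from frequency 1 and prefers the distribution with more rare types;
* vocabulary growth curves (expected distinct types seen after ``n`` tokens).

Three canonical training distributions are built in, each dividing 24 tokens
per block between its types:

* ``Skew4``: 24 tokens over 4 types, skewed, per-block counts ``[14, 6, 3, 1]``;
* ``Unif4``: 24 tokens over 4 types, uniform, ``[6, 6, 6, 6]``;
* ``Unif8``: 24 tokens over 8 types, uniform, ``[3] * 8``.

The Skew4 vector is pinned down uniquely by three published properties of the
distribution — a rank-1 frequency of 14, a rarest type of frequency 1, and an
entropy of 1.52 bits — and the uniqueness of ``[14, 6, 3, 1]`` among all
descending 4-part compositions of 24 is verified by enumeration in the test
suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_BLOCK_COUNTS",
    "CANONICAL_NAMES",
    "FrequencyDistribution",
    "FrequencySpectrum",
    "ToleranceResult",
    "VocabularyGrowthCurve",
    "canonical_distribution",
    "frequency_spectrum",
    "shannon_entropy",
    "entropy_bits",
    "rank1_frequency",
    "tolerance_evaluate",
    "tolerance_threshold",
    "potential_productivity",
    "low_freq_tail_winner",
    "compare_low_freq_tails",
    "vocabulary_growth",
    "read_frequency_table",
]

#: Per-block token counts of the three canonical training distributions.
CANONICAL_BLOCK_COUNTS: dict[str, tuple[int, ...]] = {
    "Skew4": (14, 6, 3, 1),
    "Unif4": (6, 6, 6, 6),
    "Unif8": (3, 3, 3, 3, 3, 3, 3, 3),
}

CANONICAL_NAMES = tuple(CANONICAL_BLOCK_COUNTS)

#: Tokens per distribution per training block.
TOKENS_PER_BLOCK = 24


@dataclass(frozen=True)
class FrequencyDistribution:
    """Rank-ordered token counts of the types a rule applies to.

    Parameters
    ----------
    label : str
        Identifier for the distribution (e.g. ``"Skew4"``).
    counts : tuple of int
        Per-type token counts in non-increasing order (rank 1 first).
        All counts must be positive.
    type_ids : tuple of str, optional
        Stable identifiers aligned with ``counts``.
    """

    label: str
    counts: tuple[int, ...]
    type_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) == 0:
            raise ValueError("a frequency distribution must contain at least one type")
        if any(c <= 0 for c in counts):
            raise ValueError(f"all counts must be positive integers, got {counts}")
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"counts must be non-increasing (rank order), got {counts}")
        object.__setattr__(self, "counts", counts)
        if self.type_ids is not None:
            ids = tuple(str(t) for t in self.type_ids)
            if len(ids) != len(counts):
                raise ValueError("type_ids must align one-to-one with counts")
            if len(set(ids)) != len(ids):
                raise ValueError("type_ids must be unique")
            object.__setattr__(self, "type_ids", ids)

    @property
    def token_total(self) -> int:
        """Total number of tokens (sum of counts)."""
        return sum(self.counts)

    @property
    def type_count(self) -> int:
        """Number of distinct types."""
        return len(self.counts)

    def probabilities(self) -> np.ndarray:
        """Relative frequencies ``counts / token_total``."""
        counts = np.asarray(self.counts, dtype=float)
        return counts / counts.sum()

    def scale(self, factor: int) -> "FrequencyDistribution":
        """Multiply every count by a positive integer ``factor``.

        Models observing ``factor`` identical blocks of input; rank order
        and all scale-invariant measures (entropy, spectrum shape) are
        preserved.
        """
        if int(factor) != factor or factor < 1:
            raise ValueError("scale factor must be a positive integer")
        return FrequencyDistribution(
            label=self.label,
            counts=tuple(c * int(factor) for c in self.counts),
            type_ids=self.type_ids,
        )


@dataclass(frozen=True)
class FrequencySpectrum:
    """Map from a frequency value to the number of types with that frequency.

    Where a frequency distribution plots rank against frequency, the spectrum
    plots each frequency value against *its* count: how many hapax legomena
    (frequency 1), dis legomena (frequency 2), and so on, does the sample
    contain. Conservation laws tie it back to the source distribution:
    ``sum(freq * count)`` equals the token total and ``sum(count)`` the type
    count.
    """

    spectrum: dict[int, int]

    def __post_init__(self) -> None:
        clean = {int(f): int(c) for f, c in self.spectrum.items()}
        if not clean:
            raise ValueError("a frequency spectrum cannot be empty")
        if any(f <= 0 or c <= 0 for f, c in clean.items()):
            raise ValueError("frequencies and counts must be positive")
        object.__setattr__(self, "spectrum", clean)

    @property
    def token_total(self) -> int:
        return sum(f * c for f, c in self.spectrum.items())

    @property
    def type_count(self) -> int:
        return sum(self.spectrum.values())

    def count_at(self, frequency: int) -> int:
        """Number of types with exactly ``frequency`` tokens (0 if absent)."""
        return self.spectrum.get(frequency, 0)

    @property
    def max_frequency(self) -> int:
        return max(self.spectrum)


@dataclass(frozen=True)
class ToleranceResult:
    """Verdict of the Tolerance Principle for a rule over ``N`` types.

    The rule tolerates at most ``theta = N / ln(N)`` exceptions; it is
    productive iff the exception count ``e`` satisfies ``e <= theta``.
    """

    N: int
    e: int
    theta: float
    productive: bool


@dataclass(frozen=True)
class VocabularyGrowthCurve:
    """Mean distinct-type count after 1..n tokens, with a 95% band.

    ``mean_types[i]`` is the mean number of distinct types observed after
    ``i + 1`` tokens, averaged over ``n_randomisations`` shuffled orderings of
    one block's tokens. ``completion_tokens`` holds, per randomisation, the
    token count at which the last type was first encountered.
    """

    label: str
    mean_types: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_randomisations: int
    completion_tokens: np.ndarray = field(repr=False)

    @property
    def mean_completion(self) -> float:
        """Mean number of tokens needed to encounter every type."""
        return float(self.completion_tokens.mean())


def canonical_distribution(name: str, n_blocks: int = 1) -> FrequencyDistribution:
    """Return one of the canonical distributions scaled to ``n_blocks`` blocks.

    Parameters
    ----------
    name : {"Skew4", "Unif4", "Unif8"}
    n_blocks : int
        Number of 24-token training blocks observed (>= 1). Counts scale
        linearly: three blocks of Skew4 give ``[42, 18, 9, 3]``.
    """
    if name not in CANONICAL_BLOCK_COUNTS:
        raise ValueError(f"unknown distribution {name!r}; expected one of {CANONICAL_NAMES}")
    if int(n_blocks) != n_blocks or n_blocks < 1:
        raise ValueError("n_blocks must be a positive integer")
    base = FrequencyDistribution(name, CANONICAL_BLOCK_COUNTS[name])
    return base if n_blocks == 1 else base.scale(int(n_blocks))


def frequency_spectrum(dist: FrequencyDistribution) -> FrequencySpectrum:
    """Tally how many types occur with each frequency value."""
    spec: dict[int, int] = {}
    for c in dist.counts:
        spec[c] = spec.get(c, 0) + 1
    return FrequencySpectrum(spec)


def entropy_bits(counts: Sequence[int]) -> float:
    """Shannon entropy in bits of the relative-frequency distribution of ``counts``.

    Uses the convention ``0 * log2(0) == 0``; zero counts contribute nothing.
    """
    total = float(sum(counts))
    if total <= 0:
        raise ValueError("total count must be positive")
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def shannon_entropy(dist: FrequencyDistribution) -> float:
    """Shannon entropy (bits) of a frequency distribution.

    Maximal (``log2(type_count)``) for a uniform distribution and lower the
    more skewed the distribution is; invariant under scaling all counts by a
    common factor.
    """
    return entropy_bits(dist.counts)


def rank1_frequency(dist: FrequencyDistribution) -> int:
    """Token count of the single most frequent (rank 1) type."""
    return dist.counts[0]


def tolerance_threshold(N: int) -> float:
    """Tolerance Principle threshold ``theta_N = N / ln(N)`` for ``N >= 2``."""
    if int(N) != N or N < 2:
        raise ValueError("the tolerance threshold is defined for integer N >= 2")
    return N / math.log(N)


def tolerance_evaluate(N: int, e: int) -> ToleranceResult:
    """Apply the Tolerance Principle to a rule over ``N`` types with ``e`` exceptions.

    Parameters
    ----------
    N : int
        Number of types the rule could potentially apply to (>= 2).
    e : int
        Number of those types that are exceptions to the rule (0 <= e <= N).

    Returns
    -------
    ToleranceResult
        With ``theta = N / ln(N)`` and ``productive = (e <= theta)``.
    """
    theta = tolerance_threshold(N)
    if int(e) != e or e < 0 or e > N:
        raise ValueError("exception count e must satisfy 0 <= e <= N")
    return ToleranceResult(N=int(N), e=int(e), theta=theta, productive=e <= theta)


def potential_productivity(dist: FrequencyDistribution) -> float:
    """Potential productivity ``P``: hapax legomena over total tokens.

    ``P`` estimates the probability of encountering a type exactly once in a
    sample of this size — equivalently, the slope of the vocabulary growth
    curve at the observed token count. ``P`` is zero whenever the sample
    contains no hapax legomena.
    """
    hapaxes = sum(1 for c in dist.counts if c == 1)
    return hapaxes / dist.token_total


def compare_low_freq_tails(counts_a: Sequence[int], counts_b: Sequence[int]) -> int:
    """Compare two count vectors by their low-frequency spectrum tails.

    Walks frequencies 1, 2, 3, ... up to the larger maximum frequency; at the
    first frequency where the number of types differs, the vector with more
    types at that frequency wins. Returns +1 if ``counts_a`` wins, -1 if
    ``counts_b`` wins, 0 if the spectra are identical.
    """
    spec_a: dict[int, int] = {}
    for c in counts_a:
        spec_a[c] = spec_a.get(c, 0) + 1
    spec_b: dict[int, int] = {}
    for c in counts_b:
        spec_b[c] = spec_b.get(c, 0) + 1
    top = max(max(spec_a), max(spec_b))
    for f in range(1, top + 1):
        na, nb = spec_a.get(f, 0), spec_b.get(f, 0)
        if na != nb:
            return 1 if na > nb else -1
    return 0


def low_freq_tail_winner(
    a: FrequencyDistribution, b: FrequencyDistribution
) -> Literal["a", "b", "tie"]:
    """Which of two distributions has the heavier low-frequency tail.

    Compares the frequency spectra of ``a`` and ``b`` starting from frequency
    1 (hapax legomena): whichever distribution has more types at the first
    discriminating frequency wins. Returns ``"tie"`` when the spectra are
    identical.
    """
    cmp = compare_low_freq_tails(a.counts, b.counts)
    return "a" if cmp > 0 else "b" if cmp < 0 else "tie"


def vocabulary_growth(
    dist: FrequencyDistribution,
    n_randomisations: int = 100,
    seed: int | np.random.Generator | None = None,
) -> VocabularyGrowthCurve:
    """Vocabulary growth curve over shuffled orderings of one block's tokens.

    For each of ``n_randomisations`` random orderings of the distribution's
    tokens, counts the number of distinct types observed after each prefix of
    1..token_total tokens, then reports the mean and a normal-approximation
    95% confidence band for the mean across randomisations.

    Parameters
    ----------
    dist : FrequencyDistribution
        Typically a single-block canonical distribution (24 tokens).
    n_randomisations : int
        Number of shuffled orderings to average over (default 100).
    seed : int, Generator, or None
        Source of randomness.
    """
    if int(n_randomisations) != n_randomisations or n_randomisations < 1:
        raise ValueError("n_randomisations must be a positive integer")
    rng = np.random.default_rng(seed)
    n = dist.token_total
    tokens = np.repeat(np.arange(dist.type_count), dist.counts)
    curves = np.empty((n_randomisations, n), dtype=float)
    completion = np.empty(n_randomisations, dtype=int)
    for r in range(n_randomisations):
        perm = rng.permutation(tokens)
        _, first_idx = np.unique(perm, return_index=True)
        increments = np.zeros(n, dtype=float)
        increments[first_idx] = 1.0
        curves[r] = np.cumsum(increments)
        completion[r] = first_idx.max() + 1
    mean = curves.mean(axis=0)
    if n_randomisations > 1:
        half = 1.96 * curves.std(axis=0, ddof=1) / math.sqrt(n_randomisations)
    else:
        half = np.zeros_like(mean)
    lo, hi = mean - half, mean + half
    return VocabularyGrowthCurve(
        label=dist.label,
        mean_types=mean,
        ci_low=lo,
        ci_high=hi,
        n_randomisations=int(n_randomisations),
        completion_tokens=completion,
    )


def read_frequency_table(
    path: str | Path, label: str | None = None
) -> FrequencyDistribution:
    """Read a two-column (type_id, count) delimited text file.

    Accepts comma- or tab-separated UTF-8 text; a header row is detected and
    skipped when the second field of the first row is not an integer. Rows are
    re-sorted into rank order (descending count).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (type_id, count)")
    first = str(df.iloc[0, 1]).strip()
    try:
        int(first)
    except ValueError:
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    type_ids = df.iloc[:, 0].astype(str).str.strip().tolist()
    counts = df.iloc[:, 1].astype(int).tolist()
    order = sorted(range(len(counts)), key=lambda i: (-counts[i], type_ids[i]))
    return FrequencyDistribution(
        label=label or path.stem,
        counts=tuple(counts[i] for i in order),
        type_ids=tuple(type_ids[i] for i in order),
    )
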