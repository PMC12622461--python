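"""Urn model of rule generalisation: two urns, six strategies, one choice rule.

A learner is represented by two urns, one per suffix, each accumulating every
token observed with that suffix. Generalising to a novel stem means choosing
which urn the stem is added to. The choice is stochastic: the learner starts
from probability matching over urn token counts, augments the *preferred*
urn's count by a per-learner preference strength ``k ~ Poisson(lambda)``, and
samples an urn from the normalised counts::

    u_pref    = n_pref + k
    u_dispref = n_dispref
    U         = (u_pref, u_dispref) / (u_pref + u_dispref)

Which urn is preferred depends on the learner's generalisation strategy:

==================== =======================================================
probability_matching no preference; k is forced to 0
type_count           the urn with more distinct types
tolerance            the urn the Tolerance Principle deems productive, with
                     N = all types across both urns and the other urn's
                     types as exceptions
rank1_skew           the urn whose rank-1 type has the higher frequency
low_entropy          the urn with lower Shannon entropy (more skew)
low_freq_tail        the urn with more low-frequency types, comparing
                     frequency spectra upward from frequency 1
==================== =======================================================

Ties are resolved by a fair coin before augmentation. Familiar test stems are
answered correctly (perfect learners) and their token added to the correct
urn; novel stems are added to the chosen urn, so choices feed back into later
preferences ("rich get richer", as in a two-table Chinese restaurant process).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .experiment import LanguageSpec, TestSchedule, build_language, test_schedule
from .freqdist import (
    CANONICAL_BLOCK_COUNTS,
    FrequencyDistribution,
    compare_low_freq_tails,
    entropy_bits,
    tolerance_evaluate,
)

__all__ = [
    "Strategy",
    "Urn",
    "LearnerState",
    "GridConfig",
    "train_urns",
    "sample_preference_strength",
    "preferred_urn",
    "choose_urn",
    "simulate_test_phase",
    "simulate_learner",
    "run_grid",
    "grid_cell_means",
    "DEFAULT_LAMBDA_GRID",
]

N_TRAINING_BLOCKS = 3
DEFAULT_LAMBDA_GRID = (1, 5, 10, 20, 50, 100)


class Strategy(str, Enum):
    """Closed enumeration of the six generalisation strategies."""

    PROBABILITY_MATCHING = "probability_matching"
    TYPE_COUNT = "type_count"
    TOLERANCE = "tolerance"
    RANK1_SKEW = "rank1_skew"
    LOW_ENTROPY = "low_entropy"
    LOW_FREQ_TAIL = "low_freq_tail"


@dataclass
class Urn:
    """Token multiset for one suffix: per-type counts, mutated during test."""

    label: str
    counts: dict[str, int]

    @property
    def n(self) -> int:
        """Total token count."""
        return sum(self.counts.values())

    @property
    def type_count(self) -> int:
        return len(self.counts)

    def add(self, stem: str) -> None:
        self.counts[stem] = self.counts.get(stem, 0) + 1

    def count_vector(self) -> list[int]:
        """Counts in rank order (descending)."""
        return sorted(self.counts.values(), reverse=True)

    def distribution(self) -> FrequencyDistribution:
        items = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return FrequencyDistribution(
            label=self.label,
            counts=tuple(c for _, c in items),
            type_ids=tuple(s for s, _ in items),
        )


@dataclass
class LearnerState:
    """A trained learner: two urns, a strategy, and a preference strength."""

    group: int
    urns: tuple[Urn, Urn]
    strategy: Strategy
    preference_strength: int
    non_baseline_label: str

    def urn(self, label: str) -> Urn:
        for u in self.urns:
            if u.label == label:
                return u
        raise KeyError(label)


def train_urns(
    lang: LanguageSpec,
    strategy: Strategy | str = Strategy.PROBABILITY_MATCHING,
    preference_strength: int = 0,
) -> LearnerState:
    """Fill both urns with the full three-block training input (72 tokens each)."""
    strategy = Strategy(strategy)
    if preference_strength < 0:
        raise ValueError("preference strength must be non-negative")
    urns = []
    for suffix in lang.suffixes:
        per_block = CANONICAL_BLOCK_COUNTS[lang.suffix_to_distribution[suffix]]
        counts = {
            stem: per_block[rank] * N_TRAINING_BLOCKS
            for rank, stem in enumerate(lang.stems_for(suffix))
        }
        urns.append(Urn(label=suffix, counts=counts))
    return LearnerState(
        group=lang.group,
        urns=(urns[0], urns[1]),
        strategy=strategy,
        preference_strength=int(preference_strength),
        non_baseline_label=lang.non_baseline_suffix,
    )


def sample_preference_strength(lam: float, rng: np.random.Generator) -> int:
    """Draw a learner's preference strength ``k ~ Poisson(lambda)``."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return int(rng.poisson(lam))


def _tolerance_preference(a: Urn, b: Urn) -> str | None:
    # N = distinct types currently in either urn; the other urn's types are
    # the exceptions to this urn's rule.
    n_total = a.type_count + b.type_count
    prod_a = tolerance_evaluate(n_total, b.type_count).productive
    prod_b = tolerance_evaluate(n_total, a.type_count).productive
    if prod_a == prod_b:
        return None
    return a.label if prod_a else b.label


def preferred_urn(state: LearnerState) -> str | None:
    """Which urn the learner's strategy prefers on its current contents.

    Returns the preferred urn's label, or None for a tie.
    """
    a, b = state.urns
    s = state.strategy
    if s is Strategy.PROBABILITY_MATCHING:
        return None
    if s is Strategy.TYPE_COUNT:
        if a.type_count == b.type_count:
            return None
        return a.label if a.type_count > b.type_count else b.label
    if s is Strategy.TOLERANCE:
        return _tolerance_preference(a, b)
    va, vb = a.count_vector(), b.count_vector()
    if s is Strategy.RANK1_SKEW:
        if va[0] == vb[0]:
            return None
        return a.label if va[0] > vb[0] else b.label
    if s is Strategy.LOW_ENTROPY:
        ha, hb = entropy_bits(va), entropy_bits(vb)
        if ha == hb:
            return None
        return a.label if ha < hb else b.label
    if s is Strategy.LOW_FREQ_TAIL:
        cmp = compare_low_freq_tails(va, vb)
        return None if cmp == 0 else (a.label if cmp > 0 else b.label)
    raise ValueError(f"unknown strategy {s!r}")  # pragma: no cover


def choose_urn(
    state: LearnerState,
    preferred: str | None,
    rng: np.random.Generator,
) -> tuple[tuple[float, float], str]:
    """Sample an urn from the augmented-count choice distribution.

    A tie is resolved first by a fair coin; the resulting preferred urn's
    token count is augmented by the learner's preference strength ``k``
    (forced to 0 for probability matching), counts are normalised, and the
    chosen urn is sampled. Returns the probability pair ``U = (p_preferred,
    p_dispreferred)`` — invariant to the ordering of the state's urns — and
    the chosen urn's label.
    """
    a, b = state.urns
    if a.n == 0 or b.n == 0:
        raise ValueError("urns must be non-empty")
    k = 0 if state.strategy is Strategy.PROBABILITY_MATCHING else state.preference_strength
    if preferred is None:
        preferred = a.label if rng.random() < 0.5 else b.label
    pref_urn = state.urn(preferred)
    dispref_urn = b if pref_urn is a else a
    u_pref = pref_urn.n + k
    u_dispref = dispref_urn.n
    total = u_pref + u_dispref
    probs = (u_pref / total, u_dispref / total)
    chosen = pref_urn.label if rng.random() < probs[0] else dispref_urn.label
    return probs, chosen


@dataclass(frozen=True)
class TestPhaseResult:
    """Per-trial record of one simulated test phase."""

    trials: pd.DataFrame  # stem, is_novel, chosen, chose_non_baseline
    state: LearnerState

    @property
    def non_baseline_proportion(self) -> float:
        novel = self.trials[self.trials["is_novel"]]
        return float(novel["chose_non_baseline"].mean())


def simulate_test_phase(
    state: LearnerState,
    schedule: TestSchedule,
    rng: np.random.Generator,
    dynamic: bool = True,
) -> TestPhaseResult:
    """Run one learner through a 16-trial test phase, mutating its urns.

    Familiar stems are answered with the correct urn and a token of the stem
    added to it. Novel stems trigger the strategy: the preferred urn is
    (by default) recomputed on the urns' current contents before every novel
    trial, the choice sampled from the augmented counts, and the novel type
    added to the chosen urn at frequency 1. ``dynamic=False`` freezes the
    preference at its pre-test value (sensitivity variant).
    """
    labels = {u.label for u in state.urns}
    static_pref = preferred_urn(state) if not dynamic else None
    records = []
    for trial in schedule.trials:
        if trial.is_novel:
            pref = preferred_urn(state) if dynamic else static_pref
            _, chosen = choose_urn(state, pref, rng)
            state.urn(chosen).add(trial.stem)
            records.append((trial.stem, True, chosen, chosen == state.non_baseline_label))
        else:
            if trial.correct_suffix not in labels:
                raise ValueError(
                    f"schedule/language mismatch: no urn labelled {trial.correct_suffix!r}"
                )
            if trial.stem not in state.urn(trial.correct_suffix).counts:
                raise ValueError(f"schedule/language mismatch: unknown stem {trial.stem!r}")
            state.urn(trial.correct_suffix).add(trial.stem)
            records.append((trial.stem, False, trial.correct_suffix, None))
    frame = pd.DataFrame(
        records, columns=["stem", "is_novel", "chosen", "chose_non_baseline"]
    )
    return TestPhaseResult(trials=frame, state=state)


def simulate_learner(
    group: int,
    strategy: Strategy | str,
    lam: float | None,
    rng: np.random.Generator,
    dynamic: bool = True,
    preference_strength: int | None = None,
) -> float:
    """One learner end-to-end; returns their novel-trial non-baseline proportion.

    ``k`` is drawn once per learner from Poisson(``lam``) unless
    ``preference_strength`` overrides it.
    """
    strategy = Strategy(strategy)
    lang = build_language(group, rng)
    if preference_strength is None:
        if strategy is Strategy.PROBABILITY_MATCHING:
            k = 0  # never swayed; equivalent in distribution and exact
        else:
            k = sample_preference_strength(lam, rng)
    else:
        k = int(preference_strength)
    state = train_urns(lang, strategy, k)
    sched = test_schedule(lang, rng)
    return simulate_test_phase(state, sched, rng, dynamic=dynamic).non_baseline_proportion


@dataclass(frozen=True)
class GridConfig:
    """Configuration of the strategy x lambda grid simulation."""

    strategies: tuple[Strategy, ...] = tuple(Strategy)
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    n_learners: int = 1000
    groups: tuple[int, ...] = (1, 2)
    seed: int = 0
    dynamic: bool = True

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("all lambda values must be positive")
        if self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")
        object.__setattr__(
            self, "strategies", tuple(Strategy(s) for s in self.strategies)
        )


def run_grid(config: GridConfig) -> pd.DataFrame:
    """Simulate every (strategy, lambda, group) cell of the grid.

    Each cell runs ``n_learners`` independent learners, each with a fresh
    random language, its own Poisson preference strength, and its own RNG
    substream derived from the master seed by spawn-key splitting (cells are
    reproducible independently of execution order). Returns a tidy frame with
    one row per learner.
    """
    rows = []
    for si, strategy in enumerate(config.strategies):
        for li, lam in enumerate(config.lambda_grid):
            for group in config.groups:
                for learner in range(config.n_learners):
                    ss = np.random.SeedSequence(
                        entropy=config.seed, spawn_key=(si, li, group, learner)
                    )
                    rng = np.random.default_rng(ss)
                    prop = simulate_learner(
                        group, strategy, lam, rng, dynamic=config.dynamic
                    )
                    rows.append(
                        (strategy.value, float(lam), group, learner, prop)
                    )
    return pd.DataFrame(
        rows, columns=["strategy", "lambda", "group", "learner", "prop_non_baseline"]
    )


def grid_cell_means(grid: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean non-baseline proportion of a tidy grid result."""
    return (
        grid.groupby(["strategy", "lambda", "group"], as_index=False)[
            "prop_non_baseline"
        ]
        .mean()
        .rename(columns={"prop_non_baseline": "mean_non_baseline"})
    )
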