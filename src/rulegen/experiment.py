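"""Synthetic generator for the artificial-language plural-learning experiment.

The experiment teaches adults a miniature language with two plural suffixes
(``-mo``, ``-ni``), each applying to its own set of nonce stems. One suffix's
stems always follow the uniform baseline distribution ``Unif4``; the other
suffix's stems follow ``Skew4`` (Group 1) or ``Unif8`` (Group 2). Training
runs for three blocks of 48 trials (24 per suffix); at test, participants
choose a suffix for 8 familiar and 8 novel stems.

This module generates the experiment's structure (per-participant language,
training schedule, test schedule) and simulates participant choice data with
known ground truth: perfect-learner accuracy on familiar stems plus a
configurable Bernoulli bias toward the non-baseline suffix on novel stems.
The simulated response tables stand in for raw participant data and support
recovery tests of the analysis pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .freqdist import CANONICAL_BLOCK_COUNTS

__all__ = [
    "PRINTED_STEMS",
    "SUFFIXES",
    "BASELINE_DISTRIBUTION",
    "NON_BASELINE_DISTRIBUTION",
    "PRACTICE_PHASE_TRIALS",
    "DEFAULT_GENERALISATION_BIAS",
    "LanguageSpec",
    "TrainingTrial",
    "TrainingSchedule",
    "TestTrial",
    "TestSchedule",
    "ParticipantBehaviour",
    "build_language",
    "training_schedule",
    "test_schedule",
    "simulate_participants",
    "summarise_generalisation",
]

#: The 20 nonce stems participants' languages are built from.
PRINTED_STEMS: tuple[str, ...] = (
    "bas", "chul", "cral", "duk", "fup", "gloot", "harg", "jes", "kuz", "loor",
    "puth", "ruz", "shoof", "sleb", "thap", "tob", "veb", "wak", "yeth", "zoof",
)

SUFFIXES: tuple[str, str] = ("mo", "ni")

BASELINE_DISTRIBUTION = "Unif4"
#: The group-specific comparison distribution.
NON_BASELINE_DISTRIBUTION = {1: "Skew4", 2: "Unif8"}

#: Length of the (not behaviourally modelled) practice phase, for documentation:
#: every trained stem appears once as a word-selection and once as an
#: image-selection target, so 2 x 8 trials for Group 1 and 2 x 12 for Group 2.
PRACTICE_PHASE_TRIALS = {1: 16, 2: 24}

N_BLOCKS = 3
TRIALS_PER_BLOCK = 48
N_FAMILIAR_TEST = 8
N_NOVEL_TEST = 8
FAMILIAR_PER_SUFFIX = 4

#: Default probability of choosing the non-baseline suffix on a novel trial:
#: the inverse-logit of the 0.26 log-odds grand-mean preference estimated for
#: perfect learners.
DEFAULT_GENERALISATION_BIAS = 1.0 / (1.0 + math.exp(-0.26))

_ONSETS = ("b", "ch", "d", "f", "g", "h", "j", "k", "l", "m", "n", "p", "r",
           "s", "t", "v", "w", "y", "z", "bl", "br", "cr", "dr", "fl", "gl",
           "pr", "sk", "sl", "tr")
_VOWELS = ("a", "e", "i", "o", "u", "oo", "ee")
_CODAS = ("b", "d", "f", "g", "k", "l", "m", "n", "p", "r", "s", "t", "th", "z")


@dataclass(frozen=True)
class LanguageSpec:
    """One participant's randomly assembled language.

    Maps each suffix to a training distribution (one is always the Unif4
    baseline) and each trained stem to a (suffix, frequency rank) slot.
    Group 1 languages train 8 stems (4 + 4); Group 2 languages train 12
    (4 + 8).
    """

    group: int
    suffixes: tuple[str, str]
    suffix_to_distribution: dict[str, str]
    stem_to_rank: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        if self.group not in (1, 2):
            raise ValueError("group must be 1 or 2")

    @property
    def baseline_suffix(self) -> str:
        return next(
            s for s, d in self.suffix_to_distribution.items() if d == BASELINE_DISTRIBUTION
        )

    @property
    def non_baseline_suffix(self) -> str:
        return next(
            s for s, d in self.suffix_to_distribution.items() if d != BASELINE_DISTRIBUTION
        )

    def stems_for(self, suffix: str) -> list[str]:
        """Trained stems of ``suffix``, ordered by frequency rank."""
        pairs = [(r, stem) for stem, (s, r) in self.stem_to_rank.items() if s == suffix]
        return [stem for _, stem in sorted(pairs)]

    @property
    def trained_stems(self) -> list[str]:
        return list(self.stem_to_rank)


@dataclass(frozen=True)
class TrainingTrial:
    block: int
    stem: str
    suffix: str


@dataclass(frozen=True)
class TrainingSchedule:
    """Ordered training tokens: 3 blocks x 48 trials, 24 per suffix per block."""

    trials: tuple[TrainingTrial, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.block, t.stem, t.suffix) for t in self.trials],
            columns=["block", "stem", "suffix"],
        )


@dataclass(frozen=True)
class TestTrial:
    stem: str
    is_novel: bool
    correct_suffix: str | None  # None for novel stems


@dataclass(frozen=True)
class TestSchedule:
    """16 shuffled test trials: 8 familiar (4 per distribution) + 8 novel."""

    trials: tuple[TestTrial, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.stem, t.is_novel, t.correct_suffix) for t in self.trials],
            columns=["stem", "is_novel", "correct_suffix"],
        )


@dataclass(frozen=True)
class ParticipantBehaviour:
    """Ground-truth response probabilities of a simulated participant.

    ``p_correct_familiar`` is the probability of choosing the trained suffix
    on a familiar trial; ``p_nonbaseline_novel`` the probability of choosing
    the non-baseline suffix on a novel trial (0.5 = pure probability
    matching).
    """

    p_correct_familiar: float = 1.0
    p_nonbaseline_novel: float = DEFAULT_GENERALISATION_BIAS

    def __post_init__(self) -> None:
        for name in ("p_correct_familiar", "p_nonbaseline_novel"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


def build_language(
    group: int, seed: int | np.random.Generator | None = None
) -> LanguageSpec:
    """Randomly assemble one participant's language.

    One suffix is assigned (uniformly at random) to the baseline Unif4
    distribution, the other to the group's non-baseline distribution; stems
    are drawn without replacement from the 20 printed stems and mapped
    bijectively onto frequency ranks.
    """
    if group not in (1, 2):
        raise ValueError("group must be 1 or 2")
    rng = np.random.default_rng(seed)
    nb_dist = NON_BASELINE_DISTRIBUTION[group]
    order = rng.permutation(2)
    suffix_to_distribution = {
        SUFFIXES[order[0]]: BASELINE_DISTRIBUTION,
        SUFFIXES[order[1]]: nb_dist,
    }
    n_stems = {1: 8, 2: 12}[group]
    stems = list(rng.choice(PRINTED_STEMS, size=n_stems, replace=False))
    stem_to_rank: dict[str, tuple[str, int]] = {}
    i = 0
    for suffix in SUFFIXES:
        dist_name = suffix_to_distribution[suffix]
        for rank in range(1, len(CANONICAL_BLOCK_COUNTS[dist_name]) + 1):
            stem_to_rank[stems[i]] = (suffix, rank)
            i += 1
    return LanguageSpec(
        group=group,
        suffixes=SUFFIXES,
        suffix_to_distribution=suffix_to_distribution,
        stem_to_rank=stem_to_rank,
    )


def training_schedule(
    lang: LanguageSpec, seed: int | np.random.Generator | None = None
) -> TrainingSchedule:
    """Build the 144-trial training schedule (3 blocks, shuffled within block).

    Within each block every stem appears exactly its per-block frequency (its
    rank's count in the suffix's canonical distribution), giving 24 tokens per
    suffix per block.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrainingTrial] = []
    for block in range(1, N_BLOCKS + 1):
        block_trials: list[TrainingTrial] = []
        for suffix in lang.suffixes:
            counts = CANONICAL_BLOCK_COUNTS[lang.suffix_to_distribution[suffix]]
            for stem, count in zip(lang.stems_for(suffix), counts):
                block_trials.extend(TrainingTrial(block, stem, suffix) for _ in range(count))
        order = rng.permutation(len(block_trials))
        trials.extend(block_trials[i] for i in order)
    return TrainingSchedule(trials=tuple(trials))


def _novel_stem(rng: np.random.Generator, exclude: set[str]) -> str:
    """Generate a CVC/CCVC filler stem disjoint from ``exclude``."""
    while True:
        stem = (
            _ONSETS[rng.integers(len(_ONSETS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            + _CODAS[rng.integers(len(_CODAS))]
        )
        if stem not in exclude:
            return stem


def test_schedule(
    lang: LanguageSpec, seed: int | np.random.Generator | None = None
) -> TestSchedule:
    """Build the 16-trial test schedule: 8 familiar + 8 distinct novel stems.

    Familiar trials cover 4 stems per trained distribution (for Unif8, 4 of
    its 8 stems sampled uniformly without replacement). Novel stems are drawn
    first from the printed stems left untrained, then from generated CVC/CCVC
    fillers; trial order is fully randomised.
    """
    rng = np.random.default_rng(seed)
    trials: list[TestTrial] = []
    for suffix in lang.suffixes:
        stems = lang.stems_for(suffix)
        if len(stems) > FAMILIAR_PER_SUFFIX:
            chosen = list(rng.choice(stems, size=FAMILIAR_PER_SUFFIX, replace=False))
        else:
            chosen = stems
        trials.extend(TestTrial(s, False, suffix) for s in chosen)

    trained = set(lang.trained_stems)
    unused = [s for s in PRINTED_STEMS if s not in trained]
    novel = list(rng.permutation(unused))[:N_NOVEL_TEST]
    exclude = set(PRINTED_STEMS) | set(novel)
    while len(novel) < N_NOVEL_TEST:
        stem = _novel_stem(rng, exclude)
        novel.append(stem)
        exclude.add(stem)
    trials.extend(TestTrial(s, True, None) for s in novel)

    order = rng.permutation(len(trials))
    return TestSchedule(trials=tuple(trials[i] for i in order))


def simulate_participants(
    n: int,
    group: int,
    behaviour: ParticipantBehaviour | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate test-phase responses for ``n`` participants of one group.

    Each participant gets a fresh random language and test schedule. Familiar
    trials are answered correctly with probability ``p_correct_familiar``;
    novel trials choose the non-baseline suffix with probability
    ``p_nonbaseline_novel``. Returns a tidy response table with one row per
    test trial.
    """
    if int(n) != n or n < 1:
        raise ValueError("n must be a positive integer")
    behaviour = behaviour or ParticipantBehaviour()
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for pid in range(1, int(n) + 1):
        lang = build_language(group, rng)
        sched = test_schedule(lang, rng)
        nb_suffix = lang.non_baseline_suffix
        for idx, trial in enumerate(sched.trials, start=1):
            if trial.is_novel:
                chose_nb = bool(rng.random() < behaviour.p_nonbaseline_novel)
                chosen = nb_suffix if chose_nb else lang.baseline_suffix
                correct = None
            else:
                correct = bool(rng.random() < behaviour.p_correct_familiar)
                other = next(s for s in lang.suffixes if s != trial.correct_suffix)
                chosen = trial.correct_suffix if correct else other
                chose_nb = None
            rows.append(
                {
                    "participant": pid,
                    "group": group,
                    "trial": idx,
                    "stem": trial.stem,
                    "is_novel": trial.is_novel,
                    "chosen_suffix": chosen,
                    "correct": correct,
                    "chose_non_baseline": chose_nb,
                }
            )
    return pd.DataFrame(rows)


def summarise_generalisation(
    responses: pd.DataFrame,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-group mean non-baseline proportion with a bootstrap 95% interval.

    Aggregates to one non-baseline proportion per participant (novel trials
    only), then reports the group mean and a percentile bootstrap interval
    over participants. This participant-level bootstrap is the package's
    summary of generalisation behaviour, in place of a hierarchical
    regression.
    """
    if responses.empty:
        raise ValueError("response table is empty")
    novel = responses[responses["is_novel"]]
    if novel.empty:
        raise ValueError("response table contains no novel trials")
    rng = np.random.default_rng(seed)
    out = []
    for group, gdf in novel.groupby("group"):
        props = (
            gdf.groupby("participant")["chose_non_baseline"].mean().to_numpy(dtype=float)
        )
        if props.size == 0:
            raise ValueError(f"group {group} has no participants")
        idx = rng.integers(0, props.size, size=(int(n_boot), props.size))
        boot_means = props[idx].mean(axis=1)
        lo, hi = np.percentile(boot_means, [2.5, 97.5])
        out.append(
            {
                "group": group,
                "n_participants": props.size,
                "mean_non_baseline": float(props.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_boot": int(n_boot),
            }
        )
    return pd.DataFrame(out)
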