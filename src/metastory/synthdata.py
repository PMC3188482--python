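"""Synthetic expert cohorts: story populations, comment tables, popularity law.

Real expert elicitations of the metastatic cascade are scarce, so this
module generates cohorts whose statistical structure mirrors an interview
study: 20-30 experts, each contributing one or two alternative stories of
3-15 stages over a ~26-symbol vocabulary, plus a comment corpus of a few
hundred (expert, topic, idea, stance) records.

Story cohorts come in three agreement regimes:

``complete``
    every expert repeats the canonical story verbatim;
``moderate``
    each expert perturbs the canonical story independently with adjacent
    swaps, stage deletions and insertions of unused vocabulary stages —
    stories stay recognizably close to the canonical order;
``random``
    each story is a uniform permutation of a uniform random subset of the
    vocabulary, sharing nothing but the symbol set.

All generators are pure functions of their spec: the same spec (including
seed) yields byte-identical serialized output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from metastory.cascades import (
    DEFAULT_VOCABULARY,
    ExpertScenarioSet,
    StageVocabulary,
    Story,
    canonical_story,
)
from metastory.topics import STANCES, CommentRecord, CommentTable

REGIMES = ("complete", "moderate", "random")

#: Background-attribute category sets used for round-robin labelling.
ATTRIBUTE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "degree": ("PhD", "MD", "MD/PhD"),
    "gender": ("male", "female"),
    "degree_era": ("before_1986", "1986_1995", "after_1995"),
    "site": ("local", "elsewhere"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for a synthetic story cohort under one agreement regime."""

    regime: str = "moderate"
    n_experts: int = 28
    canonical: Story = field(default_factory=canonical_story)
    swap_rate: float = 0.1
    deletion_rate: float = 0.1
    insertion_rate: float = 0.05
    alt_story_prob: float = 0.15
    seed: int = 0
    vocabulary: StageVocabulary = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime {self.regime!r} not in {REGIMES}")
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        if len(self.canonical.stages) < 2:
            raise ValueError("canonical story must have at least 2 stages")
        for name in ("swap_rate", "deletion_rate", "insertion_rate", "alt_story_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class CommentSpec:
    """Recipe for a synthetic comment corpus.

    ``topic_ideas`` maps each topic to its number of distinct ideas;
    ``mention_prob`` is the Bernoulli probability that a given expert
    raises a given idea; ``stance_probs`` the (agree, maybe, disagree)
    multinomial for each mention.  Defaults approximate a 28-expert corpus
    of roughly 776 comments with the observed stance mix (715 agree,
    43 maybe, 18 disagree).
    """

    n_experts: int = 28
    topic_ideas: dict[str, int] = field(
        default_factory=lambda: {
            "definition": 10,
            "when_acquired": 13,
            "depends_on": 19,
            "tropism": 13,
            "development": 12,
            "evolution": 4,
        }
    )
    mention_prob: float = 0.39
    stance_probs: tuple[float, float, float] = (715 / 776, 43 / 776, 18 / 776)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.stance_probs) - 1.0) > 1e-9:
            raise ValueError("stance probabilities must sum to 1")
        if not 0.0 <= self.mention_prob <= 1.0:
            raise ValueError("mention_prob must lie in [0, 1]")


def _perturb_moderate(rng: np.random.Generator, spec: ScenarioSpec) -> tuple[str, ...]:
    """One moderate-regime story: swaps, deletions, insertions off canonical."""
    stages = list(spec.canonical.stages)
    # independent adjacent-swap events decided on the original positions;
    # overlapping swaps are dropped so each stage moves at most one slot
    pos = 0
    while pos < len(stages) - 1:
        if rng.random() < spec.swap_rate:
            stages[pos], stages[pos + 1] = stages[pos + 1], stages[pos]
            pos += 2
        else:
            pos += 1
    # deletions; a stage survives if dropping it would leave < 2 stages
    kept: list[str] = []
    for idx, s in enumerate(stages):
        rest = len(stages) - idx - 1
        if rng.random() < spec.deletion_rate and len(kept) + rest >= 2:
            continue
        kept.append(s)
    stages = kept
    # insertions of unused vocabulary stages, one draw per interior gap
    # (moderate experts narrate the whole process, adding detail inside it);
    # stages deleted above stay deleted — only symbols foreign to the
    # canonical story qualify as insertions
    unused = [
        s for s in spec.vocabulary.stages
        if s not in spec.canonical.stages and s not in stages
    ]
    rng.shuffle(unused)
    out = [stages[0]]
    for s in stages[1:]:
        if unused and rng.random() < spec.insertion_rate:
            out.append(unused.pop())
        out.append(s)
    # adjacent swaps can create no duplicates (canonical has none), but
    # deletions of an intervening stage could if the canonical repeated a
    # symbol; collapse defensively
    deduped = [out[0]]
    for s in out[1:]:
        if s != deduped[-1]:
            deduped.append(s)
    return tuple(deduped)


def _random_story(rng: np.random.Generator, spec: ScenarioSpec) -> tuple[str, ...]:
    """One random-regime story: permuted random subset of the vocabulary."""
    vocab = spec.vocabulary.stages
    size = int(rng.integers(2, len(vocab) + 1))
    subset = rng.choice(len(vocab), size=size, replace=False)
    rng.shuffle(subset)
    return tuple(vocab[i] for i in subset)


def generate_scenarios(spec: ScenarioSpec) -> list[ExpertScenarioSet]:
    """Generate one synthetic cohort of expert scenario sets."""
    rng = np.random.default_rng(spec.seed)
    experts = []
    for idx in range(spec.n_experts):
        expert_id = f"E{idx + 1}"
        stories = [_one_story(rng, spec, expert_id)]
        if rng.random() < spec.alt_story_prob:
            stories.append(_one_story(rng, spec, expert_id))
        attributes = {
            key: cats[idx % len(cats)]
            for key, cats in ATTRIBUTE_CATEGORIES.items()
        }
        experts.append(
            ExpertScenarioSet(
                expert_id=expert_id, stories=stories, attributes=attributes
            )
        )
    return experts


def _one_story(
    rng: np.random.Generator, spec: ScenarioSpec, expert_id: str
) -> Story:
    if spec.regime == "complete":
        stages = spec.canonical.stages
    elif spec.regime == "moderate":
        stages = _perturb_moderate(rng, spec)
    else:
        stages = _random_story(rng, spec)
    return Story(expert_id=expert_id, stages=stages)


def generate_comment_table(spec: CommentSpec) -> CommentTable:
    """Generate a synthetic comment corpus.

    Each (expert, idea) cell is an independent Bernoulli mention; each
    mention draws its stance from the spec's multinomial.  Background
    attributes are assigned round-robin from the standard category sets.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    expert_ids = [f"E{i + 1}" for i in range(spec.n_experts)]
    stances = np.array(STANCES)
    for eid in expert_ids:
        for topic, n_ideas in spec.topic_ideas.items():
            for idea_idx in range(n_ideas):
                if rng.random() < spec.mention_prob:
                    stance = str(rng.choice(stances, p=spec.stance_probs))
                    records.append(
                        CommentRecord(
                            expert_id=eid,
                            topic=topic,
                            idea=f"{topic}_idea_{idea_idx + 1}",
                            stance=stance,
                        )
                    )
    attrs = {
        eid: {
            key: cats[i % len(cats)]
            for key, cats in ATTRIBUTE_CATEGORIES.items()
        }
        for i, eid in enumerate(expert_ids)
    }
    return CommentTable(records=records, expert_attributes=attrs)


def sample_assumption_popularity(
    gamma: float, n_assumptions: int, k_max: int, seed: int = 0
) -> list[int]:
    """Draw assumption share-counts from a truncated power (zeta) law.

    The probability that an assumption is shared by k experts is taken
    proportional to k^-gamma, truncated at the cohort size k_max:
    P(k) = k^-gamma / sum_{j=1..k_max} j^-gamma.
    """
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if n_assumptions < 0:
        raise ValueError("n_assumptions must be >= 0")
    ks = np.arange(1, k_max + 1)
    weights = ks.astype(float) ** -gamma
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    draws = rng.choice(ks, size=n_assumptions, p=probs)
    return [int(k) for k in draws]


def truncated_zeta_pmf(gamma: float, k_max: int) -> np.ndarray:
    """Exact pmf of the truncated zeta law over k = 1..k_max."""
    ks = np.arange(1, k_max + 1, dtype=float)
    w = ks**-gamma
    return w / w.sum()
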