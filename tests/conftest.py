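import pytest

from metastory.agreement import PairSet
from metastory.cascades import (
    ExpertScenarioSet,
    StageVocabulary,
    Story,
    to_pair_set,
)


@pytest.fixture
def letter_vocab() -> StageVocabulary:
    """Small abstract vocabulary for metric-level examples."""
    return StageVocabulary(stages=("a", "b", "c", "d", "f"))


def make_expert(expert_id: str, *sequences: str) -> ExpertScenarioSet:
    """Build an expert from single-letter stage strings, e.g. 'abc'."""
    stories = [
        Story(expert_id=expert_id, stages=tuple(seq)) for seq in sequences
    ]
    return ExpertScenarioSet(expert_id=expert_id, stories=stories)


@pytest.fixture
def worked_example_pairsets() -> tuple[PairSet, PairSet]:
    """The two-expert worked example: {ABC, AFDC} versus {ACBD}."""
    e1 = make_expert("E1", "abc", "afdc")
    e2 = make_expert("E2", "acbd")
    return to_pair_set(e1), to_pair_set(e2)
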