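"""Domain model and I/O for stage vocabularies and expert stage-cascade stories.

A *story* is one expert's ordered account of metastatic progression, written
over a controlled vocabulary of stage symbols (``primary_tumor``,
``detachment``, ``intravasation``, ...).  An expert may offer several
alternative stories, and may anchor a partial story to a canonical sequence
with ellipsis markers ("... -> extravasation -> colonization" means the
expert accepted the canonical stages leading up to extravasation).

The on-disk dialect is line oriented and diff friendly::

    # comment
    E1<TAB>primary_tumor -> detachment -> intravasation
    E1<TAB>... -> extravasation -> colonization

One story per line, ``expert_id`` separated from the stage chain by a tab,
stages joined with ``->``, a literal ``...`` allowed at either end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import yaml

ELLIPSIS_TOKEN = "..."

#: The 13 textbook stages of the metastatic cascade, in canonical order:
#: growth of the primary tumor, detachment of a cell, local invasion,
#: breaching of the extracellular matrix, entry into the vasculature
#: (intravasation), motility and migration through the circulation, exit
#: from the vasculature (extravasation), colonization of the distant site,
#: proliferation, recruitment of blood supply (angiogenesis), and growth
#: from micro- to macrometastasis.
TEXTBOOK_SEQUENCE: tuple[str, ...] = (
    "primary_tumor",
    "detachment",
    "invasion",
    "breach_ecm",
    "intravasation",
    "motility",
    "migration",
    "extravasation",
    "colonization",
    "proliferation",
    "angiogenesis",
    "micrometastasis",
    "macrometastasis",
)

#: Additional stages suggested by individual experts, extending the
#: textbook cascade to 26 substantive stages.
EXPERT_EXTENSION_STAGES: tuple[str, ...] = (
    "emt",                  # epithelial-mesenchymal transition
    "ecm_remodeling",
    "adhesion",
    "stroma_interaction",
    "immune_evasion",
    "circulation_transport",
    "arrest_in_capillary",
    "met",                  # mesenchymal-epithelial transition
    "dormancy",
    "niche_preparation",
    "seeding",
    "apoptosis_resistance",
    "genetic_instability",
)

#: Synonym table mapping free-text stage names to canonical symbols.  Experts
#: name the same step in many ways ("breach of the ECM", "entering the
#: bloodstream"); parsing normalizes through this table.
DEFAULT_ALIASES: dict[str, str] = {
    "primary_tumour": "primary_tumor",
    "breach_of_the_ecm": "breach_ecm",
    "breach_of_ecm": "breach_ecm",
    "ecm_breach": "breach_ecm",
    "entering_the_bloodstream": "intravasation",
    "entering_bloodstream": "intravasation",
    "leaving_the_bloodstream": "extravasation",
    "exiting_bloodstream": "extravasation",
    "epithelial_mesenchymal_transition": "emt",
    "mesenchymal_epithelial_transition": "met",
    "colonisation": "colonization",
    "angiogenic_switch": "angiogenesis",
    "micro_metastasis": "micrometastasis",
    "macro_metastasis": "macrometastasis",
}


def _normalize_symbol(raw: str) -> str:
    """Case-fold and whitespace/hyphen-normalize a stage name to snake_case."""
    s = raw.strip().casefold()
    s = re.sub(r"[\s\-]+", "_", s)
    return s


@dataclass(frozen=True)
class StageVocabulary:
    """Ordered controlled list of substantive stage symbols.

    ``start_symbol`` and ``end_symbol`` are reserved bookkeeping states used
    by the Markov model; they never appear inside stories.
    """

    stages: tuple[str, ...]
    start_symbol: str = "start"
    end_symbol: str = "end"
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized = tuple(_normalize_symbol(s) for s in self.stages)
        if any(not s for s in normalized):
            raise ValueError("empty stage symbol in vocabulary")
        if len(set(normalized)) != len(normalized):
            raise ValueError("duplicate stage symbols in vocabulary")
        if self.start_symbol in normalized or self.end_symbol in normalized:
            raise ValueError("start/end symbols must not be substantive stages")
        object.__setattr__(self, "stages", normalized)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.stages

    def __len__(self) -> int:
        return len(self.stages)

    def index(self, symbol: str) -> int:
        return self.stages.index(symbol)

    def canonicalize(self, raw: str) -> str:
        """Normalize a raw stage name and resolve aliases.

        Raises ``KeyError`` if the result is not a vocabulary symbol.
        """
        s = _normalize_symbol(raw)
        s = self.aliases.get(s, s)
        if s not in self.stages:
            raise KeyError(s)
        return s

    @property
    def states(self) -> tuple[str, ...]:
        """All Markov states: start symbol, substantive stages, end symbol."""
        return (self.start_symbol, *self.stages, self.end_symbol)

    def to_yaml(self) -> str:
        doc = {
            "stages": list(self.stages),
            "start_symbol": self.start_symbol,
            "end_symbol": self.end_symbol,
            "aliases": dict(self.aliases),
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "StageVocabulary":
        doc = yaml.safe_load(text)
        return cls(
            stages=tuple(doc["stages"]),
            start_symbol=doc.get("start_symbol", "start"),
            end_symbol=doc.get("end_symbol", "end"),
            aliases=dict(doc.get("aliases", {})),
        )


#: Default vocabulary: 13 textbook stages plus 13 expert-suggested
#: extensions (26 substantive stages), with the shipped alias table.
DEFAULT_VOCABULARY = StageVocabulary(
    stages=TEXTBOOK_SEQUENCE + EXPERT_EXTENSION_STAGES,
    aliases=dict(DEFAULT_ALIASES),
)


@dataclass(frozen=True)
class Story:
    """One ordered stage sequence told by one expert.

    Ellipsis flags record that the expert deferred to a canonical sequence
    before the first / after the last explicit stage.
    """

    expert_id: str
    stages: tuple[str, ...]
    has_leading_ellipsis: bool = False
    has_trailing_ellipsis: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        if len(self.stages) < 1:
            raise ValueError(f"empty story for expert {self.expert_id!r}")
        for a, b in zip(self.stages, self.stages[1:]):
            if a == b:
                raise ValueError(
                    f"story for expert {self.expert_id!r} repeats stage "
                    f"{a!r} in adjacent positions"
                )

    def validate(self, vocab: StageVocabulary) -> None:
        for s in self.stages:
            if s not in vocab:
                raise ValueError(
                    f"story for expert {self.expert_id!r} uses unknown "
                    f"stage {s!r}"
                )


#: Attribute schema for expert background labels.
ATTRIBUTE_SCHEMA: tuple[str, ...] = ("degree", "gender", "degree_era", "site")


@dataclass
class ExpertScenarioSet:
    """All alternative stories provided by one expert, plus background labels."""

    expert_id: str
    stories: list[Story]
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stories:
            raise ValueError(f"expert {self.expert_id!r} has no stories")
        for st in self.stories:
            if st.expert_id != self.expert_id:
                raise ValueError(
                    f"story expert_id {st.expert_id!r} does not match "
                    f"scenario set {self.expert_id!r}"
                )
        unknown = set(self.attributes) - set(ATTRIBUTE_SCHEMA)
        if unknown:
            raise ValueError(f"unknown attribute keys {sorted(unknown)}")


def parse_cascade_file(
    text: str, vocab: StageVocabulary = DEFAULT_VOCABULARY
) -> list[ExpertScenarioSet]:
    """Parse a cascade-dialect document into per-expert scenario sets.

    Stories are grouped by expert in order of first appearance.  Unknown
    stage symbols, empty stories and adjacent duplicate stages are rejected
    with the offending line number in the message.
    """
    by_expert: dict[str, list[Story]] = {}
    for lineno, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if "\t" not in line:
            raise ValueError(
                f"line {lineno}: expected '<expert_id><TAB><stages>'"
            )
        expert_id, chain = line.split("\t", 1)
        expert_id = expert_id.strip()
        if not expert_id:
            raise ValueError(f"line {lineno}: empty expert_id")
        tokens = [t.strip() for t in chain.split("->")]
        if any(not t for t in tokens):
            raise ValueError(f"line {lineno}: empty stage token")
        leading = tokens[0] == ELLIPSIS_TOKEN
        trailing = tokens[-1] == ELLIPSIS_TOKEN
        core = tokens[1 if leading else 0 : len(tokens) - 1 if trailing else None]
        if ELLIPSIS_TOKEN in core:
            raise ValueError(
                f"line {lineno}: '{ELLIPSIS_TOKEN}' only allowed at the ends"
            )
        if not core:
            raise ValueError(f"line {lineno}: story has no stages")
        stages = []
        for tok in core:
            try:
                stages.append(vocab.canonicalize(tok))
            except KeyError as exc:
                raise ValueError(
                    f"line {lineno}: unknown stage symbol {exc.args[0]!r}"
                ) from None
        try:
            story = Story(
                expert_id=expert_id,
                stages=tuple(stages),
                has_leading_ellipsis=leading,
                has_trailing_ellipsis=trailing,
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        by_expert.setdefault(expert_id, []).append(story)
    return [
        ExpertScenarioSet(expert_id=eid, stories=stories)
        for eid, stories in by_expert.items()
    ]


def write_cascade_file(experts: list[ExpertScenarioSet]) -> str:
    """Serialize scenario sets back to the cascade dialect (no comments)."""
    lines = []
    for exp in experts:
        for story in exp.stories:
            tokens = list(story.stages)
            if story.has_leading_ellipsis:
                tokens.insert(0, ELLIPSIS_TOKEN)
            if story.has_trailing_ellipsis:
                tokens.append(ELLIPSIS_TOKEN)
            lines.append(f"{exp.expert_id}\t{' -> '.join(tokens)}")
    return "\n".join(lines) + ("\n" if lines else "")


def expand_ellipsis(story: Story, canonical: Story) -> Story:
    """Splice a partially stated story against a canonical sequence.

    A leading ellipsis is replaced by the canonical prefix up to (excluding)
    the story's first explicit stage; a trailing ellipsis by the canonical
    suffix after its last explicit stage.  Stories without ellipses are
    returned unchanged.
    """
    if not (story.has_leading_ellipsis or story.has_trailing_ellipsis):
        return story
    stages = list(story.stages)
    if story.has_leading_ellipsis:
        anchor = stages[0]
        if anchor not in canonical.stages:
            raise ValueError(
                f"anchor stage {anchor!r} absent from canonical sequence"
            )
        idx = canonical.stages.index(anchor)
        stages = list(canonical.stages[:idx]) + stages
    if story.has_trailing_ellipsis:
        anchor = stages[-1]
        if anchor not in canonical.stages:
            raise ValueError(
                f"anchor stage {anchor!r} absent from canonical sequence"
            )
        idx = canonical.stages.index(anchor)
        stages = stages + list(canonical.stages[idx + 1 :])
    return Story(expert_id=story.expert_id, stages=tuple(stages))


def to_pair_set(expert: ExpertScenarioSet):
    """Reduce an expert's stories to their set of unique ordered stage pairs.

    Every positionally ordered pair (adjacent and non-adjacent) from every
    alternative story is collected and deduplicated.  This pair set is the
    unit on which the agreement metric operates.
    """
    from metastory.agreement import PairSet

    pairs: set[tuple[str, str]] = set()
    for story in expert.stories:
        seq = story.stages
        for i in range(len(seq)):
            for j in range(i + 1, len(seq)):
                if seq[i] != seq[j]:
                    pairs.add((seq[i], seq[j]))
    return PairSet(expert_id=expert.expert_id, pairs=frozenset(pairs))


def count_stage_votes(
    experts: list[ExpertScenarioSet], vocab: StageVocabulary
) -> dict[str, int]:
    """Number of distinct experts whose stories include each stage."""
    votes = {s: 0 for s in vocab.stages}
    for exp in experts:
        seen = {s for story in exp.stories for s in story.stages}
        for s in seen:
            if s in votes:
                votes[s] += 1
    return votes


def canonical_story(expert_id: str = "canonical") -> Story:
    """The 13-stage textbook cascade as a Story."""
    return Story(expert_id=expert_id, stages=TEXTBOOK_SEQUENCE)
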