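"""Comment-corpus analytics: stance tallies, non-uniformity tests, coverage.

The interview corpus is a table of (expert, topic, idea, stance) records:
each expert discussed some of the ideas grouped under a handful of topics
and took a stance (agree / maybe / disagree) on each idea mentioned.

Non-uniformity of attention across topics is tested one topic at a time by
collapsing the corpus into two bins — comments on the topic versus all
others — and comparing observed against uniform-null expected counts with
a one-degree-of-freedom chi-squared statistic, Bonferroni-corrected over
the topic family.  Coverage of a topic is the percentage of filled cells
in the expert-by-idea incidence matrix ("how much of what anyone said did
everyone say").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
from scipy import stats

STANCES = ("agree", "maybe", "disagree")


def _round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (printed-percentage convention)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class CommentRecord:
    expert_id: str
    topic: str
    idea: str
    stance: str

    def __post_init__(self) -> None:
        if self.stance not in STANCES:
            raise ValueError(
                f"stance {self.stance!r} not in {STANCES}"
            )


@dataclass
class CommentTable:
    """Comment records plus per-expert background attributes."""

    records: list[CommentRecord]
    expert_attributes: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            key = (r.expert_id, r.topic, r.idea)
            if key in seen:
                raise ValueError(f"duplicate comment record {key}")
            seen.add(key)
            if self.expert_attributes and r.expert_id not in self.expert_attributes:
                raise ValueError(
                    f"expert {r.expert_id!r} missing from attribute table"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def topics(self) -> list[str]:
        return sorted({r.topic for r in self.records})

    @property
    def experts(self) -> list[str]:
        if self.expert_attributes:
            return sorted(self.expert_attributes)
        return sorted({r.expert_id for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            attrs = self.expert_attributes.get(r.expert_id, {})
            rows.append(
                {
                    "expert_id": r.expert_id,
                    "degree": attrs.get("degree", ""),
                    "gender": attrs.get("gender", ""),
                    "degree_era": attrs.get("degree_era", ""),
                    "site": attrs.get("site", ""),
                    "topic": r.topic,
                    "idea": r.idea,
                    "stance": r.stance,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "expert_id", "degree", "gender", "degree_era", "site",
                "topic", "idea", "stance",
            ],
        )

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)

    @classmethod
    def from_tsv(cls, text: str) -> "CommentTable":
        from io import StringIO

        df = pd.read_csv(StringIO(text), sep="\t", dtype=str).fillna("")
        records = [
            CommentRecord(
                expert_id=row.expert_id, topic=row.topic,
                idea=row.idea, stance=row.stance,
            )
            for row in df.itertuples()
        ]
        attrs = {}
        for row in df.itertuples():
            attrs[row.expert_id] = {
                "degree": row.degree, "gender": row.gender,
                "degree_era": row.degree_era, "site": row.site,
            }
        return cls(records=records, expert_attributes=attrs)


@dataclass
class ChiSqResult:
    topic: str
    observed_t: int
    expected_t: float
    chi2: float
    p: float
    significant_bonferroni: bool = False


@dataclass
class StanceSummary:
    counts: dict[str, int]
    total: int
    mean_per_expert: float


def stance_summary(table: CommentTable) -> StanceSummary:
    """Counts by stance, grand total, and mean comments per expert.

    The mean is reported to one decimal, rounded half away from zero.
    """
    counts = {s: 0 for s in STANCES}
    for r in table.records:
        counts[r.stance] += 1
    total = len(table.records)
    n_experts = len(table.experts)
    mean = _round_half_away(total / n_experts, 1) if n_experts else 0.0
    return StanceSummary(counts=counts, total=total, mean_per_expert=mean)


def topic_chisq(table: CommentTable, topic: str) -> ChiSqResult:
    """One-df chi-squared test of a topic's share of comments against uniformity.

    The corpus is split into two bins — comments on ``topic`` (t) versus all
    the rest (T - t) — and compared with the expected split under a uniform
    distribution of the T comments over the topics present.
    """
    topics = table.topics
    if topic not in topics:
        raise ValueError(f"topic {topic!r} absent from table")
    if len(topics) < 2:
        raise ValueError("need at least two topics for a non-uniformity test")
    T = len(table.records)
    o_t = sum(1 for r in table.records if r.topic == topic)
    e_t = T / len(topics)
    e_rest = T - e_t
    o_rest = T - o_t
    chi2 = (o_t - e_t) ** 2 / e_t + (o_rest - e_rest) ** 2 / e_rest
    p = float(stats.chi2.sf(chi2, df=1))
    return ChiSqResult(topic=topic, observed_t=o_t, expected_t=e_t, chi2=chi2, p=p)


def bonferroni_adjust(
    results: list[ChiSqResult], family_alpha: float = 0.05
) -> list[ChiSqResult]:
    """Flag results significant at the Bonferroni-corrected family level."""
    if not results:
        raise ValueError("no results to adjust")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    threshold = family_alpha / len(results)
    return [
        replace(r, significant_bonferroni=r.p < threshold) for r in results
    ]


def coverage_percent(
    table: CommentTable, topic: str, experts: list[str] | None = None
) -> tuple[int, int, int]:
    """(filled, possible, percent) coverage of a topic's expert-by-idea matrix.

    ``possible`` = (number of experts) x (distinct ideas raised under the
    topic by anyone); ``filled`` = (expert, idea) incidences actually
    observed; ``percent`` rounded to the nearest integer, half away from
    zero.
    """
    if experts is None:
        experts = table.experts
    topic_records = [r for r in table.records if r.topic == topic]
    if not topic_records:
        raise ValueError(f"topic {topic!r} absent from table")
    ideas = {r.idea for r in topic_records}
    possible = len(experts) * len(ideas)
    if possible == 0:
        raise ValueError("zero possible cells")
    expert_set = set(experts)
    filled = len(
        {(r.expert_id, r.idea) for r in topic_records if r.expert_id in expert_set}
    )
    percent = int(_round_half_away(100.0 * filled / possible))
    return filled, possible, percent


def group_compare(
    table: CommentTable,
    idea: str,
    grouping_attribute: str,
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Chi-squared test of independence between expert group and idea uptake.

    Builds the (group level) x (discussed / not discussed) contingency
    table for one idea and tests independence with df = levels - 1.  No
    continuity correction by default.
    """
    discussed = {r.expert_id for r in table.records if r.idea == idea}
    if not discussed:
        raise ValueError(f"idea {idea!r} absent from table")
    levels: dict[str, list[int]] = {}
    for eid in table.experts:
        attrs = table.expert_attributes.get(eid, {})
        level = attrs.get(grouping_attribute)
        if level is None or level == "":
            raise ValueError(
                f"expert {eid!r} lacks attribute {grouping_attribute!r}"
            )
        yes = 1 if eid in discussed else 0
        levels.setdefault(level, [0, 0])
        levels[level][0] += yes
        levels[level][1] += 1 - yes
    if len(levels) < 2:
        raise ValueError(
            f"grouping attribute {grouping_attribute!r} has fewer than two levels"
        )
    contingency = pd.DataFrame(levels).T.to_numpy()
    if (contingency.sum(axis=0) == 0).any() or (contingency.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table (zero margin)")
    chi2, p, _, _ = stats.chi2_contingency(
        contingency, correction=continuity_correction
    )
    return float(chi2), float(p)


def results_to_tsv(results: list[ChiSqResult]) -> str:
    rows = ["topic\tobserved_t\texpected_t\tchi2\tp\tsignificant_bonferroni"]
    for r in results:
        rows.append(
            f"{r.topic}\t{r.observed_t}\t{r.expected_t:.6g}\t{r.chi2:.6g}"
            f"\t{r.p:.6g}\t{str(r.significant_bonferroni).lower()}"
        )
    return "\n".join(rows) + "\n"
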