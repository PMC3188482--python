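"""Pairwise expert agreement metric, cumulative curves, deadlock detection.

Each expert's stories are reduced to a set of ordered stage pairs
(:func:`metastory.cascades.to_pair_set`).  Agreement between two experts is
twice the number of pairs their sets share,

    S_ij = 2 |P_i ∩ P_j|,

and disagreement, under the default ``unmatched_count`` convention, is the
number of pairs present in exactly one of the two sets,

    D_ij = |P_i| + |P_j| - 2 |P_i ∩ P_j|,

which is the symmetric-difference cardinality and hence a pseudometric.
The alternative ``net_score`` convention, D = S minus the unmatched count,
can go negative and is kept only for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

UNMATCHED_COUNT = "unmatched_count"
NET_SCORE = "net_score"
_CONVENTIONS = (UNMATCHED_COUNT, NET_SCORE)


@dataclass(frozen=True)
class PairSet:
    """An expert's deduplicated set of ordered stage pairs."""

    expert_id: str
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"degenerate pair ({a!r}, {b!r})")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AgreementMatrix:
    """Symmetric similarity (S) and dissimilarity (D) matrices over experts."""

    expert_ids: list[str]
    S: np.ndarray
    D: np.ndarray
    convention: str = UNMATCHED_COUNT

    def n_experts(self) -> int:
        return len(self.expert_ids)

    def upper_triangle(self, which: str = "S") -> np.ndarray:
        """Off-diagonal values, one per unordered expert pair."""
        m = self.S if which == "S" else self.D
        iu = np.triu_indices(len(self.expert_ids), k=1)
        return m[iu]

    def to_tsv(self, which: str = "S") -> str:
        m = self.S if which == "S" else self.D
        header = "expert_id\t" + "\t".join(self.expert_ids)
        rows = [header]
        for i, eid in enumerate(self.expert_ids):
            rows.append(eid + "\t" + "\t".join(str(int(v)) for v in m[i]))
        return "\n".join(rows) + "\n"


@dataclass
class AgreementCurve:
    """Cumulative agreement / disagreement probabilities over level k."""

    k: np.ndarray
    p_agree_ge_k: np.ndarray
    p_disagree_le_k: np.ndarray

    def to_tsv(self) -> str:
        rows = ["k\tp_agree_ge_k\tp_disagree_le_k"]
        for k, pa, pd in zip(self.k, self.p_agree_ge_k, self.p_disagree_le_k):
            rows.append(f"{int(k)}\t{pa:.6g}\t{pd:.6g}")
        return "\n".join(rows) + "\n"


def similarity(a: PairSet, b: PairSet) -> int:
    """Twice the number of ordered pairs common to the two experts' sets."""
    return 2 * len(a.pairs & b.pairs)


def dissimilarity(a: PairSet, b: PairSet, convention: str = UNMATCHED_COUNT) -> int:
    """Disagreement between two experts' pair sets.

    ``unmatched_count`` (default) counts pairs claimed by exactly one of the
    two experts; ``net_score`` subtracts that count from the similarity and
    may be negative.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(
            f"unknown convention {convention!r}; expected one of {_CONVENTIONS}"
        )
    common = len(a.pairs & b.pairs)
    unmatched = len(a.pairs) + len(b.pairs) - 2 * common
    if convention == UNMATCHED_COUNT:
        return unmatched
    return 2 * common - unmatched


def pairwise_matrix(
    pairsets: list[PairSet], convention: str = UNMATCHED_COUNT
) -> AgreementMatrix:
    """Evaluate S and D for every unordered pair of experts.

    Diagonal convention: S_ii = 2|P_i| (an expert fully agrees with
    themself), D_ii = 0.
    """
    if len(pairsets) < 2:
        raise ValueError("need at least two experts")
    ids = [p.expert_id for p in pairsets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate expert_id in pair sets")
    n = len(pairsets)
    S = np.zeros((n, n), dtype=int)
    D = np.zeros((n, n), dtype=int)
    for i in range(n):
        S[i, i] = 2 * len(pairsets[i])
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = similarity(pairsets[i], pairsets[j])
            D[i, j] = D[j, i] = dissimilarity(pairsets[i], pairsets[j], convention)
    return AgreementMatrix(expert_ids=ids, S=S, D=D, convention=convention)


def agreement_curves(m: AgreementMatrix) -> AgreementCurve:
    """Cumulative probabilities over unordered expert pairs.

    ``p_agree_ge_k`` is the fraction of pairs with S >= k and
    ``p_disagree_le_k`` the fraction with D <= k, for k = 0 .. max
    observed value of either statistic.
    """
    if m.n_experts() < 2:
        raise ValueError("need at least two experts")
    s_vals = m.upper_triangle("S")
    d_vals = m.upper_triangle("D")
    k_max = int(max(s_vals.max(), d_vals.max(), 0))
    k = np.arange(k_max + 1)
    n_pairs = len(s_vals)
    p_agree = np.array([(s_vals >= kk).sum() / n_pairs for kk in k])
    p_disagree = np.array([(d_vals <= kk).sum() / n_pairs for kk in k])
    return AgreementCurve(k=k, p_agree_ge_k=p_agree, p_disagree_le_k=p_disagree)


def detect_deadlock(m: AgreementMatrix, d_threshold: int) -> list[str]:
    """Experts whose disagreement with *every* other expert exceeds the threshold.

    A non-empty result flags a "regulatory deadlock" candidate: an expert
    who, if their view were held exclusively, would dispute every
    colleague's account.
    """
    out = []
    n = m.n_experts()
    for i in range(n):
        others = [m.D[i, j] for j in range(n) if j != i]
        if others and all(d > d_threshold for d in others):
            out.append(m.expert_ids[i])
    return out
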