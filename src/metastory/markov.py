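"""Bayesian discrete-time Markov model integrating all expert stories.

Every expert story is mapped onto a first-order, homogeneous Markov chain
over the states (Start, 26 substantive stages, End): the chain always
begins at the artificial Start state, steps through the story's stages in
order, and is absorbed at the artificial End state.  Transition counts
c_ij pooled across all stories follow, row by row, a multinomial
likelihood with cell probabilities rho_ij.  With a conjugate Dirichlet
prior (per-row weight vector a_i over the allowed targets) the posterior
is again Dirichlet, giving closed-form estimators:

    posterior mean:  rho_ij = (c_ij + a_ij) / (m_i + sum_j a_ij)
    posterior mode:  rho_ij = (c_ij + a_ij - 1) / (m_i + sum_j a_ij - K_i)

where m_i = sum_j c_ij and K_i is the number of allowed targets in row i.

Structural zeros are imposed a priori: no self-transitions (the model
describes the *sequence* of stages, not their timing), no transitions into
Start, none out of End.  End is absorbing (rho_EE = 1) so that matrix
powers and occupancy trajectories are well defined.

The consensus story is the Start-to-End path maximizing the product of
fitted transition probabilities, found exactly as a shortest path under
edge weights -log rho (all positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from metastory.cascades import ExpertScenarioSet, StageVocabulary, Story

POSTERIOR_MEAN = "posterior_mean"
MAP = "map"
MLE = "mle"


def _allowed_mask(states: tuple[str, ...]) -> np.ndarray:
    """Boolean mask of structurally allowed transitions.

    Row i allows target j iff i is not End, j is not Start and j != i.
    The End row is handled separately (absorbing).
    """
    n = len(states)
    mask = np.ones((n, n), dtype=bool)
    np.fill_diagonal(mask, False)
    mask[:, 0] = False       # nothing enters Start
    mask[n - 1, :] = False   # nothing leaves End (absorption added later)
    return mask


@dataclass
class TransitionCounts:
    """Observed i->j transition counts pooled across all expert stories."""

    states: tuple[str, ...]
    c: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.states)
        self.c = np.asarray(self.c)
        if self.c.shape != (n, n):
            raise ValueError("count matrix shape does not match states")
        if (self.c < 0).any():
            raise ValueError("negative transition count")
        if np.diagonal(self.c).any():
            raise ValueError("self-transition counts are not allowed")
        if self.c[:, 0].any():
            raise ValueError("transitions into Start are not allowed")
        if self.c[-1, :].any():
            raise ValueError("transitions out of End are not allowed")

    @property
    def m(self) -> np.ndarray:
        """Row totals m_i."""
        return self.c.sum(axis=1)

    def to_tsv(self) -> str:
        header = "state\t" + "\t".join(self.states)
        rows = [header]
        for i, s in enumerate(self.states):
            rows.append(s + "\t" + "\t".join(f"{v:g}" for v in self.c[i]))
        return "\n".join(rows) + "\n"


@dataclass(frozen=True)
class PriorSpec:
    """Dirichlet prior over each row's allowed transition targets.

    ``total_alpha`` is the total prior weight per row, spread uniformly
    over the row's K_i allowed cells (a_ij = total_alpha / K_i);
    ``per_cell_alpha`` fixes a_ij directly instead.  With neither given,
    the default is 1.1 pseudo-counts per allowed cell (total 1.1 * K_i),
    the analogue of the customary row concentration slightly above the
    number of categories.
    """

    total_alpha: float | None = None
    allocation: str = "uniform_over_allowed"
    per_cell_alpha: float | None = None

    def __post_init__(self) -> None:
        if self.allocation != "uniform_over_allowed":
            raise ValueError(f"unknown allocation {self.allocation!r}")
        if self.total_alpha is not None and self.per_cell_alpha is not None:
            raise ValueError("give total_alpha or per_cell_alpha, not both")
        for v in (self.total_alpha, self.per_cell_alpha):
            if v is not None and v <= 0:
                raise ValueError("prior weights must be positive")

    def row_weights(self, allowed_row: np.ndarray) -> np.ndarray:
        """Per-cell prior weights a_ij for one row's allowed mask."""
        k = int(allowed_row.sum())
        if k == 0:
            raise ValueError("row has no allowed targets")
        if self.per_cell_alpha is not None:
            per_cell = self.per_cell_alpha
        elif self.total_alpha is not None:
            per_cell = self.total_alpha / k
        else:
            per_cell = 1.1
        a = np.zeros(len(allowed_row))
        a[allowed_row] = per_cell
        return a


@dataclass
class TransitionMatrix:
    """Row-stochastic transition probabilities with structural zeros."""

    states: tuple[str, ...]
    rho: np.ndarray
    estimator_tag: str = POSTERIOR_MEAN

    def __post_init__(self) -> None:
        n = len(self.states)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.shape != (n, n):
            raise ValueError("matrix shape does not match states")
        if (self.rho < -1e-15).any() or (self.rho > 1 + 1e-12).any():
            raise ValueError("transition probabilities outside [0, 1]")
        sums = self.rho.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("rows must sum to 1")
        if self.rho[:, 0].any():
            raise ValueError("transitions into Start are not allowed")
        end = n - 1
        if self.rho[end, end] != 1.0 or self.rho[end, :end].any():
            raise ValueError("End must be absorbing")

    def assert_structural_zeros(self) -> None:
        """Zero diagonal on Start and all substantive stages (not End)."""
        if np.diagonal(self.rho)[:-1].any():
            raise ValueError("non-zero self-transition probability")

    def state_index(self, state: str) -> int:
        return self.states.index(state)

    def to_tsv(self) -> str:
        header = "state\t" + "\t".join(self.states)
        rows = [header]
        for i, s in enumerate(self.states):
            rows.append(s + "\t" + "\t".join(f"{v:.10g}" for v in self.rho[i]))
        return "\n".join(rows) + "\n"


@dataclass
class OccupancyTrajectory:
    """State-occupancy distributions lambda_n for n = 0 .. n_max."""

    states: tuple[str, ...]
    distributions: np.ndarray  # shape (n_max + 1, n_states); row 0 = lambda_0

    @property
    def lambda0(self) -> np.ndarray:
        return self.distributions[0]

    @property
    def n_max(self) -> int:
        return self.distributions.shape[0] - 1

    def end_absorption(self) -> np.ndarray:
        """lambda_n(End) for n = 0 .. n_max (monotone non-decreasing)."""
        return self.distributions[:, -1]

    def to_tsv(self) -> str:
        rows = ["n\tstate\tprobability"]
        for n_step in range(self.distributions.shape[0]):
            for s, p in zip(self.states, self.distributions[n_step]):
                rows.append(f"{n_step}\t{s}\t{p:.10g}")
        return "\n".join(rows) + "\n"


@dataclass(frozen=True)
class ConsensusPath:
    """Most probable Start-to-End trajectory through the fitted chain."""

    stages: tuple[str, ...]   # substantive stages only, Start/End implicit
    log_probability: float
    tied: bool                # another path attains the same probability

    @property
    def probability(self) -> float:
        return math.exp(self.log_probability)

    def to_story(self, expert_id: str = "consensus") -> Story:
        return Story(expert_id=expert_id, stages=self.stages)


def count_transitions(
    experts: list[ExpertScenarioSet],
    vocab: StageVocabulary,
    weight_alternatives: bool = False,
    dedup_within_expert: bool = False,
) -> TransitionCounts:
    """Pool Start->first, consecutive, and last->End transitions over stories.

    By default each alternative story contributes with weight 1.  With
    ``weight_alternatives`` an expert's k alternatives each carry weight
    1/k; with ``dedup_within_expert`` a transition repeated across one
    expert's stories is counted once.
    """
    states = vocab.states
    n = len(states)
    index = {s: i for i, s in enumerate(states)}
    c = np.zeros((n, n), dtype=float)
    for exp in experts:
        w = 1.0 / len(exp.stories) if weight_alternatives else 1.0
        seen: set[tuple[int, int]] = set()
        for story in exp.stories:
            for s in story.stages:
                if s in (vocab.start_symbol, vocab.end_symbol):
                    raise ValueError(
                        f"story for expert {exp.expert_id!r} contains the "
                        f"reserved state {s!r}"
                    )
            path = [vocab.start_symbol, *story.stages, vocab.end_symbol]
            for a, b in zip(path, path[1:]):
                edge = (index[a], index[b])
                if dedup_within_expert:
                    if edge in seen:
                        continue
                    seen.add(edge)
                c[edge] += w
    if float(c.sum()) == float(c.astype(int).sum()):
        c = c.astype(int)
    return TransitionCounts(states=states, c=c)


def _estimate(
    counts: TransitionCounts, prior: PriorSpec, tag: str
) -> TransitionMatrix:
    states = counts.states
    n = len(states)
    allowed = _allowed_mask(states)
    rho = np.zeros((n, n))
    for i in range(n - 1):  # End row handled below
        a = prior.row_weights(allowed[i])
        k_i = int(allowed[i].sum())
        c_row = counts.c[i].astype(float)
        m_i = c_row.sum()
        if tag == POSTERIOR_MEAN:
            rho[i, allowed[i]] = (c_row[allowed[i]] + a[allowed[i]]) / (
                m_i + a.sum()
            )
        elif tag == MAP:
            if (a[allowed[i]] < 1.0).any():
                raise ValueError(
                    "MAP requires per-cell prior weight >= 1 on every "
                    "allowed cell (the Dirichlet mode is otherwise on the "
                    "boundary); increase total_alpha"
                )
            rho[i, allowed[i]] = (c_row[allowed[i]] + a[allowed[i]] - 1.0) / (
                m_i + a.sum() - k_i
            )
        elif tag == MLE:
            if m_i == 0:
                raise ValueError(
                    f"MLE undefined for row {states[i]!r} with no observed "
                    "transitions"
                )
            rho[i, allowed[i]] = c_row[allowed[i]] / m_i
        else:  # pragma: no cover
            raise ValueError(f"unknown estimator {tag!r}")
    rho[n - 1, n - 1] = 1.0  # End absorbing
    tm = TransitionMatrix(states=states, rho=rho, estimator_tag=tag)
    tm.assert_structural_zeros()
    return tm


def posterior_mean(counts: TransitionCounts, prior: PriorSpec = PriorSpec()) -> TransitionMatrix:
    """Posterior-expectation estimate of the transition matrix."""
    return _estimate(counts, prior, POSTERIOR_MEAN)


def posterior_map(counts: TransitionCounts, prior: PriorSpec = PriorSpec()) -> TransitionMatrix:
    """Maximum-a-posteriori estimate; refuses priors whose mode lies on the boundary."""
    return _estimate(counts, prior, MAP)


def mle(counts: TransitionCounts) -> TransitionMatrix:
    """Maximum-likelihood estimate c_ij / m_i; requires data in every row."""
    return _estimate(counts, PriorSpec(), MLE)


def chain_power(P: TransitionMatrix, n: int) -> TransitionMatrix:
    """Entrywise n-step transition matrix P^n (row-stochastic preserved).

    Note that P^n generally has positive diagonal entries for n >= 2
    (multi-step returns through other stages), so only the Start-column and
    End-row structural zeros survive powering.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rho_n = np.linalg.matrix_power(P.rho, n)
    # numerical cleanup: row sums drift at the 1e-16 level
    rho_n = np.clip(rho_n, 0.0, None)
    rho_n /= rho_n.sum(axis=1, keepdims=True)
    return TransitionMatrix(states=P.states, rho=rho_n, estimator_tag=P.estimator_tag)


def occupancy(P: TransitionMatrix, n_max: int) -> OccupancyTrajectory:
    """Distribution over states after n transitions from Start, n = 1..n_max."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    n_states = len(P.states)
    lam = np.zeros(n_states)
    lam[0] = 1.0  # unit mass on Start
    dists = [lam]
    for _ in range(n_max):
        lam = lam @ P.rho
        dists.append(lam)
    return OccupancyTrajectory(states=P.states, distributions=np.array(dists))


def consensus_path(
    P: TransitionMatrix, support: TransitionCounts | None = None
) -> ConsensusPath:
    """Most probable Start-to-End path under the fitted chain.

    Maximizing the product of transition probabilities equals minimizing
    the sum of -log rho over a path; all weights are positive, so Dijkstra
    shortest-path search is exact and never uses a cycle.  Ties are broken
    by shorter path first, then lexicographic stage order, and reported via
    ``tied``.

    With ``support`` given, the search is restricted to transitions at
    least one expert actually proposed (c_ij > 0).  Without it, any cell
    that carries residual prior mass is a legal hop, and on a smoothed
    matrix the product-maximal trajectory degenerates to a near-direct
    Start-to-End skip that no expert ever told — an artifact of the prior,
    not a consensus.  Pipelines fitting smoothed estimators should
    therefore pass the counts they fitted from.
    """
    n = len(P.states)
    start, end = 0, n - 1
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if support is not None and support.c[i, j] <= 0:
                continue
            if P.rho[i, j] > 0:
                G.add_edge(i, j, weight=-math.log(P.rho[i, j]))
    try:
        best_cost = nx.dijkstra_path_length(G, start, end)
    except nx.NetworkXNoPath:
        raise ValueError(
            "End unreachable from Start through positive-probability edges"
        ) from None
    candidates = [
        tuple(p) for p in nx.all_shortest_paths(G, start, end, weight="weight")
    ]
    chosen = min(
        candidates, key=lambda p: (len(p), tuple(P.states[i] for i in p))
    )
    stages = tuple(P.states[i] for i in chosen[1:-1])
    return ConsensusPath(
        stages=stages, log_probability=-best_cost, tied=len(candidates) > 1
    )


def row_entropy(P: TransitionMatrix) -> dict[str, float]:
    """Shannon entropy (bits) of each non-End row's transition distribution.

    High entropy marks stages about whose successor the experts disagree
    most; a deterministic consensus row has entropy 0.
    """
    out = {}
    for i, s in enumerate(P.states[:-1]):
        row = P.rho[i]
        nz = row[row > 0]
        out[s] = float(-(nz * np.log2(nz)).sum())
    return out
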