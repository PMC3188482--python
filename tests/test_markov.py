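"""Transition counting, Dirichlet estimators, chain powers, consensus path."""

import itertools
import math

import numpy as np
import pytest

from metastory.cascades import (
    DEFAULT_VOCABULARY,
    TEXTBOOK_SEQUENCE,
    StageVocabulary,
    Story,
    canonical_story,
)
from metastory.markov import (
    PriorSpec,
    TransitionCounts,
    TransitionMatrix,
    chain_power,
    consensus_path,
    count_transitions,
    mle,
    occupancy,
    posterior_map,
    posterior_mean,
    row_entropy,
)

from .conftest import make_expert

ABC_VOCAB = StageVocabulary(stages=("a", "b", "c"))


def idx(vocab: StageVocabulary, state: str) -> int:
    return vocab.states.index(state)


def matrix_from_edges(vocab: StageVocabulary, edges: dict) -> TransitionMatrix:
    """Build a row-stochastic matrix from {(from, to): prob} with End absorbing."""
    n = len(vocab.states)
    rho = np.zeros((n, n))
    for (a, b), p in edges.items():
        rho[idx(vocab, a), idx(vocab, b)] = p
    rho[n - 1, n - 1] = 1.0
    # states with no outgoing mass jump straight to End so rows stay stochastic
    for i in range(n - 1):
        if rho[i].sum() == 0:
            rho[i, n - 1] = 1.0
    return TransitionMatrix(states=vocab.states, rho=rho)


def brute_force_power(rho: np.ndarray, n: int) -> np.ndarray:
    """Sum path probabilities over all length-n index paths."""
    size = rho.shape[0]
    out = np.zeros_like(rho)
    for path in itertools.product(range(size), repeat=n + 1):
        p = 1.0
        for a, b in zip(path, path[1:]):
            p *= rho[a, b]
        out[path[0], path[-1]] += p
    return out


def brute_force_best_path(P: TransitionMatrix, support=None):
    """Enumerate all simple Start-to-End paths; return max product."""
    n = len(P.states)
    best, best_lp = None, -math.inf
    interior = range(1, n - 1)
    for r in range(n - 1):
        for combo in itertools.permutations(interior, r):
            path = (0, *combo, n - 1)
            lp = 0.0
            ok = True
            for a, b in zip(path, path[1:]):
                if P.rho[a, b] <= 0 or (
                    support is not None and support.c[a, b] <= 0
                ):
                    ok = False
                    break
                lp += math.log(P.rho[a, b])
            if ok and lp > best_lp:
                best, best_lp = path, lp
    return best, best_lp


class TestCountTransitions:
    def test_single_story_counts_start_and_end_hops(self):
        counts = count_transitions([make_expert("E1", "ab")], ABC_VOCAB)
        c = counts.c
        v = ABC_VOCAB
        assert c[idx(v, "start"), idx(v, "a")] == 1
        assert c[idx(v, "a"), idx(v, "b")] == 1
        assert c[idx(v, "b"), idx(v, "end")] == 1
        assert counts.m[idx(v, "start")] == 1
        assert c.sum() == 3

    def test_alternative_stories_contribute_independently(self):
        counts = count_transitions([make_expert("E1", "abc", "acb")], ABC_VOCAB)
        c, v = counts.c, ABC_VOCAB
        assert c[idx(v, "start"), idx(v, "a")] == 2
        assert c[idx(v, "a"), idx(v, "b")] == 1
        assert c[idx(v, "a"), idx(v, "c")] == 1
        assert c[idx(v, "b"), idx(v, "c")] == 1
        assert c[idx(v, "c"), idx(v, "b")] == 1
        assert c[idx(v, "b"), idx(v, "end")] == 1
        assert c[idx(v, "c"), idx(v, "end")] == 1

    def test_empty_cohort_gives_zero_counts(self):
        counts = count_transitions([], ABC_VOCAB)
        assert counts.c.sum() == 0

    def test_reserved_state_in_story_rejected(self):
        from metastory.cascades import ExpertScenarioSet

        vocab = StageVocabulary(stages=("a", "b"), start_symbol="s0", end_symbol="e0")
        bad = ExpertScenarioSet("E1", [Story("E1", ("s0", "a"))])
        with pytest.raises(ValueError, match="reserved"):
            count_transitions([bad], vocab)

    def test_weighting_splits_alternatives(self):
        counts = count_transitions(
            [make_expert("E1", "abc", "acb")], ABC_VOCAB, weight_alternatives=True
        )
        v = ABC_VOCAB
        assert counts.c[idx(v, "start"), idx(v, "a")] == pytest.approx(1.0)

    def test_dedup_within_expert(self):
        counts = count_transitions(
            [make_expert("E1", "abc", "abc")], ABC_VOCAB, dedup_within_expert=True
        )
        assert counts.c[idx(ABC_VOCAB, "a"), idx(ABC_VOCAB, "b")] == 1


class TestPosteriorMean:
    def test_prior_only_posterior_is_uniform_over_allowed(self):
        counts = count_transitions([], ABC_VOCAB)
        P = posterior_mean(counts)
        # row 'a' allows b, c, end -> 1/3 each
        row = P.rho[idx(ABC_VOCAB, "a")]
        assert row[idx(ABC_VOCAB, "b")] == pytest.approx(1 / 3)
        assert row[idx(ABC_VOCAB, "end")] == pytest.approx(1 / 3)

    def test_conjugate_mean_hand_value(self):
        # counts row a -> (b:2, c:1, end:1), per-cell prior weight 0.5
        counts = count_transitions(
            [make_expert("E1", "ab"), make_expert("E2", "ab"),
             make_expert("E3", "ac"), make_expert("E4", "a")],
            ABC_VOCAB,
        )
        v = ABC_VOCAB
        assert counts.c[idx(v, "a"), idx(v, "b")] == 2
        assert counts.c[idx(v, "a"), idx(v, "c")] == 1
        assert counts.c[idx(v, "a"), idx(v, "end")] == 1
        P = posterior_mean(counts, PriorSpec(per_cell_alpha=0.5))
        row = P.rho[idx(v, "a")]
        assert row[idx(v, "b")] == pytest.approx(2.5 / 5.5)
        assert row[idx(v, "c")] == pytest.approx(1.5 / 5.5)
        assert row[idx(v, "end")] == pytest.approx(1.5 / 5.5)

    def test_small_alpha_approaches_mle(self):
        counts = count_transitions(
            [make_expert("E1", "abc"), make_expert("E2", "abc")], ABC_VOCAB
        )
        P = posterior_mean(counts, PriorSpec(total_alpha=1e-9))
        Q = mle(counts)
        i = idx(ABC_VOCAB, "a")
        assert P.rho[i] == pytest.approx(Q.rho[i], abs=1e-9)

    def test_rows_stochastic_with_structural_zeros(self):
        counts = count_transitions([make_expert("E1", "abc")], ABC_VOCAB)
        P = posterior_mean(counts)
        assert np.allclose(P.rho.sum(axis=1), 1.0, atol=1e-12)
        assert (np.diagonal(P.rho)[:-1] == 0).all()
        assert (P.rho[:, 0] == 0).all()
        assert P.rho[-1, -1] == 1.0


class TestPosteriorMap:
    def test_flat_prior_recovers_mle(self):
        counts = count_transitions(
            [make_expert("E1", "ab"), make_expert("E2", "ac")], ABC_VOCAB
        )
        P = posterior_map(counts, PriorSpec(per_cell_alpha=1.0))
        i = idx(ABC_VOCAB, "a")
        assert P.rho[i, idx(ABC_VOCAB, "b")] == pytest.approx(0.5)

    def test_symmetric_mode_with_no_data(self):
        counts = count_transitions([], ABC_VOCAB)
        P = posterior_map(counts, PriorSpec(per_cell_alpha=2.0))  # K = 3
        row = P.rho[idx(ABC_VOCAB, "a")]
        assert row[idx(ABC_VOCAB, "b")] == pytest.approx(1 / 3)

    def test_mode_hand_value(self):
        # counts row (2,1,1), a_ij = 2, K = 3 -> (3/7, 2/7, 2/7)
        counts = count_transitions(
            [make_expert("E1", "ab"), make_expert("E2", "ab"),
             make_expert("E3", "ac"), make_expert("E4", "a")],
            ABC_VOCAB,
        )
        P = posterior_map(counts, PriorSpec(per_cell_alpha=2.0))
        v = ABC_VOCAB
        row = P.rho[idx(v, "a")]
        assert row[idx(v, "b")] == pytest.approx(3 / 7)
        assert row[idx(v, "c")] == pytest.approx(2 / 7)
        assert row[idx(v, "end")] == pytest.approx(2 / 7)

    def test_boundary_mode_refused(self):
        counts = count_transitions([make_expert("E1", "ab")], ABC_VOCAB)
        with pytest.raises(ValueError, match="boundary"):
            posterior_map(counts, PriorSpec(per_cell_alpha=0.3))


class TestChainPower:
    def test_deterministic_path_composes(self):
        vocab = StageVocabulary(stages=("a", "b", "c"))
        P = matrix_from_edges(vocab, {
            ("start", "a"): 1, ("a", "b"): 1, ("b", "c"): 1, ("c", "end"): 1,
        })
        P2 = chain_power(P, 2)
        assert P2.rho[idx(vocab, "start"), idx(vocab, "b")] == pytest.approx(1.0)

    def test_power_one_is_identity_of_exponent(self):
        counts = count_transitions([make_expert("E1", "abc")], ABC_VOCAB)
        P = posterior_mean(counts)
        assert np.allclose(chain_power(P, 1).rho, P.rho)

    def test_power_zero_rejected(self):
        counts = count_transitions([make_expert("E1", "abc")], ABC_VOCAB)
        with pytest.raises(ValueError):
            chain_power(posterior_mean(counts), 0)

    def test_matches_path_enumeration_oracle(self):
        vocab = StageVocabulary(stages=("a", "b"))
        counts = count_transitions(
            [make_expert("E1", "ab"), make_expert("E2", "ba"),
             make_expert("E3", "a")],
            vocab,
        )
        P = posterior_mean(counts)
        P3 = chain_power(P, 3)
        assert np.allclose(P3.rho, brute_force_power(P.rho, 3), atol=1e-12)

    def test_powers_preserve_start_column_and_end_row(self):
        counts = count_transitions(
            [make_expert("E1", "abc"), make_expert("E2", "cab")], ABC_VOCAB
        )
        P10 = chain_power(posterior_mean(counts), 10)
        assert (P10.rho[:, 0] == 0).all()
        assert P10.rho[-1, -1] == pytest.approx(1.0)


class TestOccupancy:
    def test_deterministic_textbook_chain_absorbs_at_14(self):
        from metastory.cascades import ExpertScenarioSet

        experts = [ExpertScenarioSet("E1", [canonical_story("E1")])]
        counts = count_transitions(experts, DEFAULT_VOCABULARY)
        P = mle_on_support(counts)
        traj = occupancy(P, 20)
        # Start + 13 stages + End: absorption completes at transition 14
        assert traj.end_absorption()[13] == pytest.approx(0.0, abs=1e-6)
        assert traj.end_absorption()[14] == pytest.approx(1.0)

    def test_distributions_conserve_mass(self):
        counts = count_transitions([make_expert("E1", "abc")], ABC_VOCAB)
        traj = occupancy(posterior_mean(counts), 50)
        assert np.allclose(traj.distributions.sum(axis=1), 1.0, atol=1e-9)

    def test_absorption_monotone_and_complete(self):
        counts = count_transitions(
            [make_expert("E1", "abc"), make_expert("E2", "bca")], ABC_VOCAB
        )
        traj = occupancy(posterior_mean(counts), 50)
        end = traj.end_absorption()
        assert (np.diff(end) >= -1e-15).all()
        assert end[-1] > 0.999

    def test_start_to_end_shortcut_mass(self):
        vocab = StageVocabulary(stages=("a",))
        P = matrix_from_edges(vocab, {
            ("start", "end"): 0.5, ("start", "a"): 0.5, ("a", "end"): 1.0,
        })
        traj = occupancy(P, 2)
        assert traj.end_absorption()[1] == pytest.approx(0.5)

    def test_bad_horizon_rejected(self):
        counts = count_transitions([make_expert("E1", "ab")], ABC_VOCAB)
        with pytest.raises(ValueError):
            occupancy(posterior_mean(counts), 0)


def mle_on_support(counts: TransitionCounts) -> TransitionMatrix:
    """Near-MLE matrix defined even when some rows carry no data."""
    return posterior_mean(counts, PriorSpec(total_alpha=1e-9))


class TestConsensusPath:
    def test_deterministic_chain_returns_only_path(self):
        vocab = StageVocabulary(stages=("a", "b", "c"))
        P = matrix_from_edges(vocab, {
            ("start", "a"): 1, ("a", "b"): 1, ("b", "c"): 1, ("c", "end"): 1,
        })
        path = consensus_path(P)
        assert path.stages == ("a", "b", "c")
        assert not path.tied

    def test_equal_parallel_routes_tie_flagged_lexicographic(self):
        vocab = StageVocabulary(stages=("x", "y"))
        P = matrix_from_edges(vocab, {
            ("start", "x"): 0.5, ("start", "y"): 0.5,
            ("x", "end"): 1.0, ("y", "end"): 1.0,
        })
        path = consensus_path(P)
        assert path.stages == ("x",)
        assert path.tied

    def test_unreachable_end_rejected(self):
        vocab = StageVocabulary(stages=("a", "b"))
        n = len(vocab.states)
        rho = np.zeros((n, n))
        rho[0, 1] = 1.0   # start -> a
        rho[1, 2] = 1.0   # a -> b
        rho[2, 1] = 1.0   # b -> a: End never reached
        rho[n - 1, n - 1] = 1.0
        P = TransitionMatrix(states=vocab.states, rho=rho)
        with pytest.raises(ValueError, match="unreachable"):
            consensus_path(P)

    def test_matches_exhaustive_enumeration_on_random_chains(self):
        rng = np.random.default_rng(2024)
        for trial in range(30):
            n_stages = int(rng.integers(2, 6))  # <= 7 states incl. Start/End
            vocab = StageVocabulary(
                stages=tuple(f"s{i}" for i in range(n_stages))
            )
            n = len(vocab.states)
            rho = np.zeros((n, n))
            for i in range(n - 1):
                allowed = [j for j in range(1, n) if j != i]
                w = rng.random(len(allowed)) * (rng.random(len(allowed)) < 0.7)
                if w.sum() == 0:
                    w[-1] = 1.0
                rho[i, allowed] = w / w.sum()
            rho[n - 1, n - 1] = 1.0
            P = TransitionMatrix(states=vocab.states, rho=rho)
            expected_path, expected_lp = brute_force_best_path(P)
            if expected_path is None:
                with pytest.raises(ValueError, match="unreachable"):
                    consensus_path(P)
                continue
            got = consensus_path(P)
            assert got.log_probability == pytest.approx(expected_lp)

    def test_support_restriction_excludes_prior_only_edges(self):
        counts = count_transitions(
            [make_expert("E1", "abc"), make_expert("E2", "abc")], ABC_VOCAB
        )
        P = posterior_mean(counts)
        free = consensus_path(P)
        supported = consensus_path(P, support=counts)
        # smoothing alone makes the direct Start->End hop the product winner
        assert free.stages == ()
        assert supported.stages == ("a", "b", "c")


class TestRowEntropy:
    def test_deterministic_row_zero_bits(self):
        vocab = StageVocabulary(stages=("a",))
        P = matrix_from_edges(vocab, {("start", "a"): 1.0, ("a", "end"): 1.0})
        assert row_entropy(P)["a"] == 0.0

    def test_uniform_row_log2_of_support(self):
        counts = count_transitions([], StageVocabulary(stages=("a", "b", "c", "d")))
        P = posterior_mean(counts)
        # row 'a' allows b, c, d, end: uniform over 4 -> 2 bits
        assert row_entropy(P)["a"] == pytest.approx(2.0)

    def test_half_quarter_quarter_row(self):
        vocab = StageVocabulary(stages=("a", "b", "c"))
        P = matrix_from_edges(vocab, {
            ("start", "a"): 1.0,
            ("a", "b"): 0.5, ("a", "c"): 0.25, ("a", "end"): 0.25,
            ("b", "end"): 1.0, ("c", "end"): 1.0,
        })
        assert row_entropy(P)["a"] == pytest.approx(1.5)
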