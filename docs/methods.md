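# Methods

## Stage vocabulary and story model

Stories are ordered sequences over a controlled vocabulary of 26
substantive metastasis stages: the 13 textbook stages (primary_tumor,
detachment, invasion, breach_ecm, intravasation, motility, migration,
extravasation, colonization, proliferation, angiogenesis, micrometastasis,
macrometastasis) plus 13 expert-suggested extensions (emt, ecm_remodeling,
adhesion, stroma_interaction, immune_evasion, circulation_transport,
arrest_in_capillary, met, dormancy, niche_preparation, seeding,
apoptosis_resistance, genetic_instability). Two reserved states — Start
and End — bracket every story in the Markov model but never appear inside
stories. Stage names are case-folded and whitespace-normalized at parse
time and routed through an editable alias table ("breach of the ECM" →
`breach_ecm`), because experts name the same step in many ways.

Immediate repetition of a stage is rejected at parse time rather than
merged: the Markov model forbids self-transitions (it describes the
*order* of stages, not their duration), and silently collapsing repeats
would make the text and the counts disagree.

A story may carry an ellipsis at either end ("... -> extravasation ->
colonization"), meaning the expert accepted the canonical sequence before
(or after) the stated stages. Expansion against the 13-stage textbook
sequence is the pipeline default and can be disabled; it splices the
canonical prefix strictly before the story's first stage (and the suffix
strictly after its last), so the explicit stages always remain a
contiguous block of the output.

## Agreement metric

An expert's pair set is the union, over their alternative stories, of all
positionally ordered stage pairs — adjacent and non-adjacent. Similarity
is twice the shared-pair count, S = 2|P_i ∩ P_j|. For disagreement the
package's default is the **unmatched-pair count**
D = |P_i| + |P_j| − 2|P_i ∩ P_j|: the symmetric-difference cardinality,
hence non-negative, symmetric, and a pseudometric (property-tested). The
alternative `net_score` convention, D = S − (unmatched count), is kept
selectable; it turns negative whenever the two experts share fewer pairs
than they dispute (on the classic two-expert example {ABC, AFDC} vs
{ACBD} it gives 6 − 8 = −2), which makes it unusable as a dispute count
but occasionally useful as a signed balance. No importance weighting of
pairs is applied: the elicitation provides no defensible weights.

Cumulative curves are computed over unordered expert pairs (self-pairs
excluded): the fraction of pairs with S ≥ k, and with D ≤ k, on the grid
k = 0 … max observed value. Deadlock detection returns the experts whose
D exceeds a threshold against *every* colleague.

## Dirichlet–multinomial transition model

Each story contributes Start→first stage, every consecutive pair, and
last stage→End, with weight 1 (a flag switches to weight 1/k for an
expert with k alternative stories; another deduplicates repeated
transitions within one expert — both off by default, so every told
transition counts once). Structural zeros — the diagonal (except End),
the Start column, the End row — are imposed a priori: Start and End are
definitional bookkeeping states, not learnable biology.

Row i has K_i allowed targets (every state except itself and Start; for
substantive stages K_i = 26, for Start K = 27 including a direct hop to
End). The prior is a symmetric Dirichlet over the allowed cells with
per-cell weight a_ij = 1.1 by default — the customary "slightly more than
one pseudo-count per category" concentration, configurable either
per cell or as a row total. Estimators:

- posterior mean ρ_ij = (c_ij + a_ij)/(m_i + Σ a_ij);
- posterior mode (MAP) ρ_ij = (c_ij + a_ij − 1)/(m_i + Σ a_ij − K_i),
  refused (not clipped) when any a_ij < 1, since the mode then sits on the
  simplex boundary and the closed form misreports it;
- MLE c_ij/m_i, defined only when every row has data.

End is made absorbing (ρ_EE = 1) so that matrix powers and occupancy are
well defined. Note that powering destroys the diagonal zeros — P² has
positive diagonal wherever a two-step return exists — so only the Start
column and End row zeros are invariant under Pⁿ; this is a property of
the mathematics, not a defect of the fit.

Occupancy starts from unit mass on Start: λ_n = λ_0 Pⁿ, reported for
n = 1…50 by default (the horizon at which a well-connected cohort chain
has ≥ 0.9 absorption). λ_n(End) is monotone non-decreasing because End is
absorbing.

## Consensus-path extraction

The consensus path maximizes the product of transition probabilities from
Start to End, computed exactly as a Dijkstra shortest path under weights
−log ρ (all positive, so no cycle can improve a path). Ties are broken by
shorter path, then lexicographically smaller state sequence, and flagged.

Two deliberate choices here:

1. **Support restriction.** The pipeline restricts the search to
   transitions at least one expert actually told (c_ij > 0). Without
   this, the residual prior mass on never-observed cells (≈ a/(m+Σa) ≈
   0.02 per cell under the default prior) makes the *direct Start→End
   hop* the product-winner — 0.02 beats the ~10⁻³ product of a 14-hop
   trajectory — which is an artifact of smoothing, not a consensus any
   expert voiced. The unrestricted search remains available.
2. **MAP matrix for path reading.** The posterior mean under the default
   prior adds ≈ 30 pseudo-counts to rows holding ~30 observations,
   flattening every row toward uniform; on a flattened matrix a path that
   skips a stage pays roughly the same as one that does not, and the
   most probable path systematically drops weakly attested stages. The
   MAP estimate, (c + 0.1)/(m + 2.7) under the default prior, tracks the
   data, so the CLI reads the consensus path off the MAP matrix whenever
   the prior admits an interior mode (falling back to the fitted matrix
   otherwise). Probability statements (occupancy, entropies, exported
   matrices) still use the requested estimator.

Row entropy is the base-2 Shannon entropy of each non-End row; high
entropy marks the stages whose successor the cohort disputes most.

## Synthetic cohorts

The generator emulates an interview study of 20–30 experts, each telling
one or two alternative stories of 3–15 stages. Defaults: 28 experts, a
second alternative story with probability 0.15, and three regimes:

- **complete** — every expert repeats the canonical 13-stage story
  verbatim;
- **moderate** — per expert, the canonical story passes through
  independent adjacent-swap events (probability 0.1 per boundary,
  non-overlapping so each stage moves at most one slot), per-stage
  deletion (0.1, never below 2 surviving stages), and insertion of
  vocabulary stages foreign to the canonical story into interior gaps
  (0.05 per gap). Interior-only insertion reflects what "moderate"
  means here: the expert narrates the whole process and adds detail
  inside it. Deleted stages stay deleted — allowing them to re-enter at
  arbitrary positions would manufacture long-range reorderings that
  belong to the random regime;
- **random** — a uniform permutation of a uniform random subset (≥ 2) of
  the vocabulary.

All generators are pure functions of their spec including the seed;
serialized output is byte-identical across calls.

The comment-table generator draws an independent Bernoulli mention per
(expert, idea) cell (default 0.39 over 71 ideas across six topics ≈ 776
expected comments for 28 experts) and a stance per mention from the
(agree, maybe, disagree) multinomial (defaults 715/776, 43/776, 18/776).
Background attributes (degree, gender, degree era, site) are assigned
round-robin from the standard category sets. Assumption popularity is
sampled from a truncated zeta law P(k) ∝ k^−γ on k = 1…k_max (experts are
finite, so the support is truncated at the cohort size).

What the generator does *not* emulate: correlated perturbations between
experts (schools of thought), stage-specific disagreement hot-spots
(real disagreement concentrates at vessel entry/exit), granularity
differences (real stories ranged from 3 to 15 stages; moderate synthetic
stories stay near 13), or free-text idea semantics. Passing tests
therefore demonstrate correctness of the machinery and recoverability
under homogeneous noise, not fidelity to any particular expert corpus.

## Parameter recovery and its limits

With 28 experts at swap/deletion rates 0.1, each consecutive-stage
boundary sees skip evidence from three sources that all create the same
i→i+2 adjacency: deletion of the middle stage and a swap at either
flanking boundary — a combined intensity near 0.3. The fitted skip
probability (~0.2) then sits close to the two-step product (~0.33), so a
single cohort recovers the full 13-stage sequence with probability only
≈ 0.4; the alternative outcomes are scattered one-stage omissions, each
individually rare. Recovery is therefore asserted *modally*: across 20
replicate cohorts the most frequent consensus path is the textbook
sequence, every recovered path preserves canonical relative order, and at
most two stages are dropped. The same analysis explains why the
acceptance script reports a recovery rate alongside the modal result.

## Topic statistics

The per-topic non-uniformity test collapses the corpus into two bins —
comments on the focal topic, t, versus all others, T − t — and compares
them with the uniform-null expectation (e = T / number of topics) via
χ² = (t−e)²/e + ((T−t)−(T−e))²/(T−e) with 1 degree of freedom, matching
an independent two-bin goodness-of-fit computation (tested against
`scipy.stats.chisquare` on randomized fixtures). Bonferroni correction
flags p < family_alpha / number of tests (family alpha 0.05 by default).

Coverage of a topic is filled/(experts × ideas) as a percentage, where
the idea set is *what anyone raised under that topic* — not a global idea
universe — and rounding is to the nearest integer, half away from zero;
the per-expert comment mean is likewise reported to one decimal, half
away from zero. These conventions reproduce all the documented worked
ratios (72/280 → 26%, 61/364 → 17%, 76/532 → 14%, 121/336 → 36%,
84/364 → 23%, 30/171 → 18%, 25/209 → 12%, 776/28 → 27.7). Group
comparisons build a (group level × discussed/not) contingency table per
idea and test independence without continuity correction by default.

## Numerical choices

- Row-stochasticity is enforced to 1e-12 at construction; matrix powers
  are renormalized after clipping at the 1e-16 drift level.
- 0·log 0 := 0 in entropies.
- Shortest-path ties are detected by exact float equality of path costs;
  genuinely tied products (equal probabilities along parallel routes)
  compare equal, and the reported tie-break is deterministic.
- Problem sizes in tests and the acceptance script — 28-expert cohorts,
  20 recovery replicates, 50-step occupancy horizons, 100-case property
  sweeps, 10⁵ popularity draws — were chosen as the smallest sizes at
  which the respective statistics are stable.

## Known limitations

- The consensus path is a modal summary; it carries no uncertainty
  interval. Posterior path uncertainty would need sampling over Dirichlet
  rows.
- The agreement metric treats all ordered pairs equally; transitive pairs
  implied by long stories dominate the counts, so long-winded experts
  weigh more in the curves.
- Comment analytics assume one record per (expert, topic, idea); repeated
  mentions by the same expert are not modelled.
- The truncated zeta sampler fixes γ; fitting γ to observed popularity
  data is out of scope.
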