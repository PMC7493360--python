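# Methods

## Problem and model

Positional TF–TF interaction predictors (ChIP-seq co-binding tools such as
TICA) flag pairs of transcription factors whose binding sites co-locate,
but cannot tell co-operation from competition: both put the two factors at
the same spots. This package classifies each candidate pair using two
extra facts from a physical PPI network — whether the pair has a direct
edge, and how many interactors it shares (*N₁₂*). The biological model is
that co-operating TFs belong to the same (large) transcriptional
complexes, hence share many partners and often interact directly, whereas
competitors bind a spot or partner mutually exclusively, hence rarely
interact directly and share few partners; non-interacting pairs share
almost none. *N₁₂* alone cannot separate the classes (well-studied
competitor pairs can share many partners purely through network density,
and true co-operators can share none through network incompleteness),
which is why the boolean positional label and the direct-edge flag gate
the thresholds rather than being folded into one score.

"Transcription factor" is used in a lax sense: proteins that bind TFs'
binding pockets (co-factors, chromatin modifiers) are included, since they
take part in the same transcription machineries and their interactions
are of the same three kinds.

## Network handling

Edges are undirected, self-loop-free and deduplicated. The BioGRID-style
reader keeps only rows whose experimental system type is `physical`
(optionally restricted to one organism's taxon id); multi-validated
filtering is supported through a provenance-tag filter because
multi-validated status is a distribution artefact of the source database,
not a computable property — pre-filtered files are accepted as-is.
Symbols are uppercased and stripped; no alias or identifier mapping is
attempted (that is a separate concern, and curated inputs use official
symbols).

A TF is *eligible* for classification when its degree in the full network
(before any TF restriction) is at least 3 (configurable). This removes
TFs isolated by network incompleteness and 2-node islands, and reflects
that a TF with fewer than 3 edges cannot have a meaningful
shared-interactor count. Ineligible TFs and non-TF proteins remain in the
graph and still count as shared partners of other pairs.

*N₁₂* counts common neighbours of the two pair members, excluding the
members themselves: a direct edge contributes to the direct-edge feature,
never to *N₁₂*. *N₁₂* values are summarised into eleven bins (0–9, 10+);
the tail is collapsed at 10 because the empirical distribution drops
sharply there.

## Decision tree

The tree is table-driven (`nautica.classify.TREE_RULES`); each branch is
keyed by the (predictor, direct-edge) boolean pair and holds the
threshold it applies and the labels below/at-or-above it. Conventions:

- Thresholds are **inclusive on the high-N₁₂ side** (*N₁₂* ≥ τ yields the
  high-N₁₂ label), matching the baseline tree's explicit
  "L inclusive, H exclusive" band convention.
- Branch (predictor=1, edge=1) applies no *N₁₂* test.
- Branch (predictor=1, edge=0) orients high *N₁₂* → COOP, low → COMP:
  a pair flagged by the positional predictor but with few shared partners
  is most plausibly competing at the spot level (subclass COMP+), while
  many shared partners indicate a shared complex missed by the network's
  direct edges.
- Branch (0,0) emits COMP− above *τ_H*: pairs with no direct evidence of
  interaction but an unusually high shared-partner count are interpreted
  as members of rival complexes competing indirectly.

COMP subclasses are annotations; the three-way label is what fitting and
evaluation use.

## Threshold fitting

The training interface takes curated (pair, label) examples and evaluates
per-class recall at every grid point (defaults τ_L, τ_H ∈ {1..12};
baseline L ∈ {1..8}, H ∈ {2..12} with L < H). The fitting objective is
deliberately a choice: increasing one class's recall necessarily costs
another's, and no single scalarisation is canonical. The default is
macro-averaged recall, with minimum class recall as an alternative; the
full per-point sensitivity table is always returned so the trade-off
stays inspectable. Ties break to the smallest (τ_H, τ_L)
lexicographically, so degenerate training sets yield the least aggressive
thresholds deterministically. Curated pairs carrying conflicting labels
are ambiguous and are dropped before fitting.

## Recall calibration

Curated test sets are sampled roughly uniformly across *N₁₂* bins, but
the real candidate population is heavily skewed to low *N₁₂*. Calibration
reweights each test pair by its bin's relative population size in a null
distribution: the smallest non-empty bin is the base (weight 1; ties go
to the smallest bin index, so a single base is always defined) and every
other bin gets `floor(count / base count)`. Pairs curated NINT or COMP
take weights from the NINT null (built over all candidate pairs, which
are predominantly non-interacting; curated competitions are too few to
form their own null, and competitors' *N₁₂* distribution is expected to
resemble non-interactors'). Pairs curated COOP take weights from a COOP
null built over curated co-operations. A weighted prediction counts as
*m* (its weight) predictions in the confusion matrix; recall is then read
off weighted rows. Bins empty in a null fall back to weight 1 with a
warning. Specificity is not calibrated — that would require additional
cross-class assumptions the weights do not carry.

## Precision estimation

Class-specific weights say nothing about relative class sizes inside a
bin, so precision cannot be read off the calibrated matrix. Instead, for
an assumed population split (y, x_coop, x_comp) of NINT:COOP:COMP and
per-class recalls R, precision of "interaction" (COOP or COMP) is

    P_INT = (x_coop·R_COOP + x_comp·R_COMP)
            / (x_coop·R_COOP + x_comp·R_COMP + y·(1 − R_NINT))

under the approximation that every missed NINT surfaces as a false
positive interaction (worst case for the numeratorless class). The total
candidate count cancels and is kept only to report absolute expected
counts. For a symmetric split y:x:x, `fold_over_random(x)` divides P_INT
by the random-guessing precision 2x; with the default tree recalls the
fold exceeds 2 for all x ≤ 0.14 and grows as x shrinks. The split is an
assumption, not data — there is no compiled resource giving real
COOP:COMP:NINT proportions — so both split and recalls are explicit
parameters of `PrecisionModel`.

## Per-bin association statistics

For two classes, each bin's 2×2 table (class × in-bin/out-of-bin) yields
relative risk, odds ratio and a Pearson chi-squared p-value. Yates
continuity correction is off by default (a flag enables it); tables with
a zero margin report NaN rather than raising. No multiple-testing
correction is applied; the table is descriptive.

## Complex enrichment

For each predicted pair the database is scanned for at least one complex
containing both members; a pair in several complexes counts once. The
percentage denominator is all predictions of the class, not just pairs
covered by the database (an optional restricted mode exists for
sensitivity analysis of symbol coverage). Fold-increase is the ratio of
two class percentages; zero-denominator folds are NaN. No statistical
test is attached — the ratios are descriptive validation.

## Synthetic generator

`nautica.simulate` produces everything the pipeline reads, seeded and
bit-reproducible (numpy `default_rng` with per-stage streams derived from
the seed):

- **Network**: Barabási–Albert preferential attachment (default 2000
  proteins, 4 edges per arrival), matching the heavy-tailed degree
  distribution of real PPI networks; TF status on a uniform random subset
  (default 120).
- **Planted pairs** (default 45, on disjoint TF sets so plantings cannot
  interfere): class drawn from a COOP-heavy mix (0.65 COOP / 0.15 COMP /
  0.20 NINT, approximating the composition of literature-curated training
  sets, where co-operations dominate because competition evidence is hard
  to document); shared-partner targets Poisson around class means (12
  COOP / 1 COMP / 0.5 NINT — chosen to straddle the default thresholds
  the way the biological model assumes, Poisson as the simplest
  non-negative count model); direct edges Bernoulli (0.8 COOP / 0.05
  COMP / 0 NINT); predictor labels with true-positive rate 0.9 and
  false-positive rate 0.05. Planting only adds shared partners (augment,
  not rewire); the truth record stores features recomputed from the final
  graph, never the requested targets.
- **Separable training sets** (`plant_separable_training`): pairs planted
  on both sides of target thresholds in every tree branch, making the
  recall optimum exactly the planted (τ_L, τ_H). This is the fixture for
  threshold-recovery experiments; the Poisson generator above is the
  fixture for end-to-end realism.
- **Complexes**: each COOP pair forms its own complex with probability
  `coverage` (default 0.3 — curated complex databases are incomplete);
  COMP/NINT pairs leak in at rate 0.02.

What the generator does **not** emulate: real BioGRID topology beyond
degree-tail heaviness (no clustering structure, no study bias towards
well-characterised proteins), ChIP-seq signal or the positional
predictor's internal statistics (labels are Bernoulli noise on the planted
truth), and symbol-mapping noise between resources. Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical assumptions, not performance on real data.

## Problem sizes and numerical choices

Tests and the acceptance self-check run the pipeline at a few hundred
proteins and tens of pairs, sizes at which every property being checked
(oracle agreement, recovery, calibration identities) is already fully
exercised; the defaults (2000 proteins) complete an end-to-end run in
seconds. Reported percentages round half-away-from-zero (the convention
of printed reports; Python's built-in `round` is banker's rounding).
Undefined quantities (empty-class percentages, zero-denominator folds and
precisions) are NaN, never exceptions. Grid fits are exhaustive, so there
are no initialisation or convergence concerns.

## Known limitations

- Alias/ID mapping between resources is out of scope; mismatched symbol
  conventions silently reduce overlap.
- The precision estimator's population split is an assumption; reported
  precisions move with it.
- The fitted thresholds depend on the curated training set's coverage of
  the boundary region; the sensitivity grid should always be inspected.
- COMP recall is structurally the weakest: competitions are rare in
  curation and their *N₁₂* distribution overlaps NINT's by design of the
  biological model.
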