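# Methods note

This note records the model definitions, parameter conventions, numerical
choices, and limitations of the `signedcircles` package. Every quantitative
statement here is one the test suite actually computes; no empirical claims
about real cohorts are made.

## 1. Data model and weight resolution

A survey consists of a roster (student id, group, gender, participation
flags per wave) and nomination records. Six questions map to signed
intensities: positive questions 1–3 are best friend / friend /
acquaintance-liked, negative questions 4–6 are worst enemy / enemy /
disliked. Intensity 1 denotes the inner (stronger) layer with magnitude 2;
intensity 2 the outer layer with magnitude 1.

Multiple records for the same ordered pair resolve in three steps:

1. within each sign, keep the most intense nomination (largest magnitude);
2. across signs, sum the surviving positive and negative weights;
3. remove links whose sum is zero.

The result is a signed, directed network with weights in {−2, −1, +1, +2}.
Records naming students missing from the roster, self-nominations, and
malformed rows are rejected and reported, never silently dropped.

## 2. Circle parameters μ and ρ

For ego *i*, C1 is the number of out-neighbors with weight +2 (inner
circle) and C2 the number with any positive weight (cumulative second
circle). The scaling parameter is

    mu_i = ln((C2 − C1) / C1)        (natural logarithm)

μ is undefined when C1 = 0 or C2 = C1; such egos are excluded from means
and counted in an `n_excluded` column, never imputed. C2 < C1 is
impossible by construction and raises an error. ρ is the identical
statistic computed on in-ties. Scopes: all positive ties, or restricted to
the ego's own group. Canonical reference point: circles with ratio 3
(C2 = 3·C1) give μ = ln 2 ≈ 0.693.

Wave-to-wave increments Δμ are computed per ego over egos with defined μ
in both waves. Tests on increments: Shapiro–Wilk normality, one-sample
t against zero (with explicit zero-variance conventions: t = 0, p = 1 when
all increments are zero), one-way ANOVA across groups, and Tukey HSD
pairwise comparisons; groups with fewer than 3 defined values are skipped
and reported as such.

## 3. Signed directed modularity

For a partition C, with w⁺ the total positive weight and w⁻ the total
absolute negative weight,

    Q = w⁺/(w⁺+|w⁻|) · Q⁺ − |w⁻|/(w⁺+|w⁻|) · Q⁻
    Q± = 1/(2w±) · Σ_{i,j} ( w±_ij − s±_i,out · s±_j,in / (2w±) ) · δ(C_i, C_j)

where the sum runs over **all ordered pairs including i = j** (the diagonal
null terms are partition-independent but affect the printed value). The
2w± normalization is the package default (`as_printed`); part of the
directed-modularity literature uses w± instead, exposed as
`directed_normalization="w_plus"`. The arg-max partition is identical
under both conventions.

### Optimization

`optimize_partition` is a multi-restart heuristic with a free number of
communities:

- greedy single-node moves with exact incremental ΔQ (candidate targets:
  every non-empty community plus one empty community — moves to
  non-adjacent communities can pay off through the null term);
- a best-improving pairwise community merge pass, alternated with local
  moves until stable;
- per restart, three iterated-local-search kicks (re-assign ⌈n/5⌉ random
  nodes, re-converge, keep only if Q improves);
- a final refinement alternating (a) extraction of each node into a fresh
  singleton followed by re-convergence and (b) a Kernighan–Lin-style
  escape pass: a sequence of best single moves with each moved node
  locked, negative gains allowed, keeping the prefix with the highest
  cumulative gain. The KL pass crosses barriers that need several
  coordinated moves (e.g. optima that isolate two nodes simultaneously),
  which single-move dynamics cannot reach.

Everything is deterministic given `seed`. Ties in ΔQ break toward the
lowest community id; a 1e-13 epsilon guards against floating-point churn.

`brute_force_partition` enumerates all set partitions (Bell-number growth,
refused above 10 nodes) and is used as the exact oracle in tests: the
heuristic attains the enumerated optimum on 50/50 random signed instances
with 4–8 nodes, and the evaluation itself matches an independently coded
literal double-loop to 1e-12 on 100 random networks.

### Positive-only comparison

`positive_only_comparison` partitions the signed network and its
positive-only subnetwork and reports which signed communities merge when
negative links are dropped (a positive-only community "absorbs" a signed
community when it contains ≥ 80% of its members). The unit-test fixture
for this phenomenon was verified by exhaustive enumeration: its signed
optimum has two communities while its positive-only optimum is a single
community.

## 4. Reciprocity and the rewiring null

Observed reciprocity is the fraction of directed links (u, v) such that
(v, u) exists with the same sign. The null model redraws each node's
out-neighbors uniformly at random without replacement, preserving every
out-degree (mode `outdegree`); for a uniform out-degree d on n nodes the
null expectation is d/(n−1), which the sampled null brackets (calibration
test: d = 10, n = 200, expectation 10/199). A `double_edge_swap` mode that
also preserves in-degrees is available. Confidence intervals are
percentile-based over the sampled null; the upper-tail p-value uses the
add-one rule (k+1)/(m+1).

## 5. Structural balance

The directed signed network is projected to an undirected signed graph
under criterion (a) — negative only if both directions are negative — or
criterion (b) — negative if either direction is negative. Triangles are
classified by their number of negative edges; balanced = 0 or 2 negatives.
An edge's *embedding* is the number of triangles it lies in. The null
permutes edge signs uniformly **within classes of equal embedding**,
holding topology fixed, and recounts unbalanced triangles (vectorized over
the precomputed triangle → edge-index triples). Reported: the observed
census, the null distribution, and the fraction of realizations with
strictly fewer unbalanced triangles than observed. A perfectly balanced
two-faction network is a lower bound: no permutation goes below zero, and
the test asserts the fraction is exactly 0 over 10⁴ realizations.
Degenerate nulls (all signs in one class equal) are flagged rather than
silently reported.

## 6. Synthetic generator

`generate_wave` builds one survey wave from a `GeneratorConfig`:

- **Roster.** Groups of given sizes and girl fractions; deterministic ids.
- **Communities.** `n_communities_per_group` planted communities per
  group, filled with gender bias `community_gender_bias` (alternating
  majority gender); wave 2 re-assigns each student with probability given
  by the churn component of `wave2_drift`.
- **Circle sizes.** Per ego, C1 ~ Poisson(`mean_C1`) and
  C2 − C1 ~ Poisson(`mean_C1`·(`circle_ratio`−1)), truncated to the group
  size. Feasibility (`mean_C1`·`circle_ratio` ≤ min group size − 1, both
  waves) is validated up front.
- **Positive ties.** Intra-group only. Inner slots get weight +2, outer
  +1. Reciprocity is realized by first constructing M = round(r·Σd/2)
  mutual dyads — each consuming one out-slot at both endpoints — and then
  filling remaining out-slots with one-way ties that avoid accidental
  reciprocation. This preserves each ego's drawn (C1, C2) *exactly*, which
  is what makes μ recovery testable. The alternative of adding reverse
  edges post hoc with probability r inflates out-circles (about
  `density`·C2 extra outer ties per ego) and biases mean μ upward by ~0.4
  under typical settings, so it was rejected by design. Partner choice
  mixes community preference (`p_intra_community`) and gender homophily
  (`gender_homophily`).
- **Negative ties.** Per ego ~ Poisson(`neg_rate`), targets biased across
  community boundaries by `neg_cross_community_bias`, intensity split by
  `neg_inner_fraction`.
- **Seeding.** All randomness flows through per-purpose child seeds of the
  config seed; the same seed reproduces the wave bit for bit.

Under this design the expected mean of defined μ converges to
ln(`circle_ratio` − 1) with a small upward Jensen bias of order
1/(4·`mean_C1`); the recovery tests therefore use `mean_C1` = 10 with
ratio 3 and require the 10-seed mean within 0.05 of ln 2.

Two auxiliary generators serve the balance and community tests:
`generate_balanced` (two factions, reciprocated positive ties within and
negative ties between — every triangle balanced by construction) and
`planted_partition_signed` (stochastic block model with separate positive
and negative within/between probabilities; recovery test: blocks
(10,10,10), p⁺_in = 0.6, p⁺_out = 0.05, p⁻_out = 0.1, ARI ≥ 0.9 in ≥ 95
of 100 seeds).

### Realism and limitations

The generator reproduces the structural features the estimators target
(circle-size distributions, reciprocity level, group-confined positive
ties, community-aligned negative ties, gender-biased communities, wave
drift). It does **not** model: inter-group friendships, degree–attribute
correlations beyond gender homophily, transitivity/triadic closure in
positive ties (clustering arises only through communities), intensity
heterogeneity beyond the two layers, or non-response. Detected communities
at default mixing recover school groups; resolving the planted
sub-communities requires stronger separation (higher
`p_intra_community` / `neg_cross_community_bias`) — signed modularity, like
its unsigned counterpart, has a resolution limit.

## 7. Pipeline

`signedcircles run` executes simulate → circles → communities →
reciprocity → balance. Stage seeds are SHA-256 hashes of
`"{seed}:{stage}"` reduced mod 2³¹, so stages are independently
reproducible and disabling one never shifts another's random stream.
Outputs: GraphML intermediates, per-stage CSV/JSON tables, `report.json`,
and `manifest.json` with the config hash and stage seeds. Reports are
byte-identical across reruns of the same config.

## 8. Numerical conventions

- Natural logarithms throughout; no base-10 anywhere.
- Undefined statistics are `None`/NaN plus an exclusion count — never 0.
- Floating-point comparisons in optimizers use a 1e-13 epsilon; oracle
  agreement is asserted at 1e-12 (evaluation) and 1e-10 (optimum).
- ANOVA degrees of freedom are reported as (k−1, N−k); Tukey HSD comes
  from statsmodels.
- All Monte Carlo machinery (nulls, permutations, generators) takes
  explicit seeds and is deterministic given them.
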