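# Methods

## The measurement problem

A facility assessment yields a binary matrix: facility × item, 1 when the
item was directly observed present (and functional where applicable), 0 when
it was absent **or could not be assessed** — notably when the relevant
service is not offered, a deliberate coding rule that treats undemonstrated
capacity as absent. Items belong to substantive domains (amenities,
equipment, infection prevention, diagnostics, medication, management).

The readiness score is a two-stage average: items are averaged within domain
and the domain means averaged, giving a score in [0, 1] in which every domain
carries equal weight regardless of its item count. This is the standard
construction for service-readiness indices; it differs from the flat item
mean whenever domain means differ, and `readix` treats it as the defining
primitive (`compute_index`). Two conventions matter at the edges:

- **Missing items** (an item not extractable for a survey wave) are handled
  by renormalizing the within-domain denominator over the items actually
  available (`IndexDefinition.restrict_to`); nominal domain sizes are never
  used as denominators.
- **Empty domains** (no selected item) drop out of the outer average. This
  choice keeps the index defined along every greedy selection path down to a
  single item; the alternative (scoring an empty domain 0) would make any
  1-item index nearly degenerate.

## Quantile classification and agreement

Facilities are ranked by descending score and cut into q contiguous groups
with rank boundaries at ⌈kn/q⌉, k = 1..q. This convention yields group sizes
1848/1848/1847/1848/1847 for n = 9238, q = 5 — matching the published
quintile Ns that the agreement tests reconstruct — and group sizes never
differ by more than one when scores are distinct. Ties are broken by the
stable input order, making classification deterministic; when *every* score
is identical a `DegenerateClassificationError` is raised rather than
returning an arbitrary split.

Agreement between two classifications uses the unweighted Cohen's kappa,
κ = (p₀ − pₑ)/(1 − pₑ), with pₑ from the marginal products. Unweighted (not
linearly/quadratically weighted) kappa is the right reading here: only the
unweighted form reproduces the kappa values printed alongside the published
cross-tabulations that `readix.published` transcribes (0.35 / 0.75 / 0.84 /
0.79). Those panels are given as row percentages at 0.1% resolution, so
reconstructed cell counts are kept real-valued (rounding twice would bias
kappa) and carry up to 0.05 percentage points of drift in the diagonal
share — which is why one printed agreement of "83.0%" reconstructs as 82.94%.

## Greedy abbreviation

Sequential backward selection starts from the full item set; at each step
every removable item's exclusion is scored by recomputing the index,
reclassifying, and computing kappa against a **fixed** reference
classification (full-item quantiles, never recomputed during selection), and
the item with the highest post-removal kappa is dropped. Forward selection
mirrors this from the locked set upward. Design choices:

- **Ties** between candidates are broken by the smallest item column index —
  deterministic and order-stable. Ties are common early in backward selection
  (many removals leave the classification untouched), and different
  tie-breaking can produce different item lists without changing the kappa
  path; item-list instability under near-ties is a real feature of this
  method, not an implementation artifact.
- **Locked items** (an expert-defined core) are never candidates for removal
  and seed the forward path, producing "enriched" indices.
- **Degenerate candidates** (a subset whose scores are identical across all
  facilities, e.g. a single constant item at the start of a forward path) are
  skipped; if every candidate is degenerate the selection aborts with an
  error rather than choosing arbitrarily.
- **Incremental evaluation.** The engine caches per-facility, per-domain
  integer item sums; a candidate's domain-mean matrix is rebuilt from these
  exact integer sums, so candidate kappas equal from-scratch recomputation
  (verified to 1e-12 against an independently coded naive pipeline, and
  per-step choices are verified against exhaustive enumeration on small
  fixtures). One backward pass over the 800 × 60 benchmark takes ~0.25 s.

Greedy paths are nested, so `index_at(trace, M)` reads any index length off
one path, and selection-order reports number the non-locked items with 1 for
the item discarded last (the most informative item conditional on the locked
core).

## Cross-validated evaluation

The expected out-of-sample performance of an M-item index is estimated by
k-fold CV (k = 10 by default): within each training set the reference
classification is recomputed (training facilities only — the held-out fold
never influences selection) and one greedy path is run; held-out facilities
are scored at every M by replaying the path incrementally. The pooled
out-of-fold scores of all n facilities are then classified into q groups and
compared against the full-data full-item reference. Items may differ between
folds at the same M; only the length is fixed.

Pooling is a genuine design choice: classifying all n out-of-fold scores at
once (default) uses the same group sizes as the reference and is less noisy
than quantiling each ~n/k-facility fold separately; the per-fold variant is
available via `pool="per_fold"` for comparison. Fold assignment is the only
randomness in the pipeline and is governed by a single seed.

Two empirical regularities are asserted as seeded regression tests on the
benchmark: resubstitution kappa at M = 20 exceeds the CV kappa at M = 20
(selection optimism), and the CV curve rises steeply while informative items
remain (κ at M = 12 > κ at M = 4; κ ≥ 0.95 at M = 59).

### Backward versus forward selection

On the packaged benchmark the two greedy directions do **not** order
uniformly: backward selection wins near full length, but forward selection
attains higher CV kappa over a mid-range of index lengths (around M ≈ 8–30,
by up to ~0.2). The mechanism is visible in the traces: backward selection,
being one-step myopic, never abandons a domain — removing the last item of a
large noise-dominated domain is locally expensive even when shedding the
whole domain would help — so near the floor it carries noisy single-item
domain representatives, while forward selection composes small item sets
freely (and can complete a small domain exactly). In very large item pools
with heavy item redundancy, backward selection has been observed to dominate
at every length; that behaviour does not transfer to this 60-item benchmark,
and the test suite records the discrepancy rather than hiding it. Both
directions' per-step argmax behaviour is verified against exhaustive
enumeration, so the crossing reflects the estimand, not a defect.

## The synthetic generator

No public microdata exist for the target surveys, so the generator produces
SPA-like matrices from a latent-trait model: facility readiness
θᵢ = country offset + hospital bonus + N(0, 1), and item presence
P(xᵢⱼ = 1) = logistic(aⱼ(θᵢ − bⱼ)). Discrimination aⱼ ≥ 0 controls how
strongly an item tracks readiness (aⱼ = 0 is pure noise with prevalence ½);
difficulty bⱼ is the readiness level at which prevalence crosses ½. Items in
a service block are forced to 0 when the facility's (Bernoulli) service
indicator is off, reproducing the structural zeros of the "could not be
assessed" coding. Sampling weights are stratum-scaled uniforms; an optional
redundancy hook clones an item with independent flips to create the
near-duplicate items that drive item-list instability.

**Benchmark** (`benchmark_config`, fixed seed, 800 facilities × 60 items,
four country strata, 20% hospitals with +1 readiness bonus): twelve
high-discrimination items (a = 2.5, difficulties spread over ±1.2 and
interleaved across domains so each covers a distinct readiness slice) sit in
four compact core domains (3/3/4/6 items); the two large catch-all domains
(21 and 23 items) hold six service-gated items (a = 1.0, offered by 70% of
facilities) and 42 zero-discrimination noise items. The uneven layout mirrors
real assessments — compact expert domains against broad medication- and
management-style item batteries — and is what makes the signal recoverable:
the two-stage average upweights items in small domains, so the full index is
strongly readiness-driven (Spearman r ≈ 0.94 with θ) and backward selection
retains 9–11 of the 12 signal items in its 20-item index across seeds. With
even 10-item domains the same pipeline retains only ~6: every noise item is
then the sole carrier of a non-trivial share of the reference ranking, and
reproducing the reference — the method's actual objective — genuinely favours
keeping them. That contrast is itself informative about what
reference-agreement selection optimizes.

What the generator does **not** emulate: real prevalence patterns and country
means, item-specific missingness across survey waves, non-latent-trait
dependence between items (beyond gates and explicit redundancy), and
within-country sampling designs richer than a weight scale. Passing tests
therefore demonstrate the pipeline's correctness and its qualitative
behaviour on latent-trait data, not quantitative findings about any real
health system.

## Scale and problem sizes

All packaged analyses run on the 800 × 60 benchmark: a full backward path
costs ~1,800 subset evaluations (~0.25 s), a 10-fold CV curve ~2 s, and the
full study driver (both modes and directions plus sensitivity analyses)
under a minute. The same code paths handle larger matrices; cost grows as
O(k · P²) subset evaluations for a CV curve, each O(n) after the cached-sum
update, so a 9,238 × 649 analysis is supported but takes hours, as expected
for this method.

## Known limitations

- Greedy selection is locally optimal per step only; no look-ahead, no
  stochastic search. Divergent item lists under near-ties are expected.
- No confidence intervals on kappa and no weighted-kappa variants; the
  quantile classification itself ignores sampling weights (weights enter the
  descriptives only), matching the unweighted classification convention of
  the reference analysis.
- The CV curve carries no standard errors; fold-to-fold variability is not
  reported.
- `matrix_from_row_percentages` cannot beat the resolution of its inputs;
  statistics derived from printed percentages inherit ±0.05-point drift.
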