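# Methods

This note documents the statistical model, the numerical choices, and the
synthetic-data design behind `ethnophylo`, including what the tests do and
do not demonstrate about real data.

## Model and assumptions

The unit of analysis is a *community*: the subset of a reference pool of
tree tips recorded as treating one disease category. The analysis assumes:

1. a rooted phylogeny with nonnegative branch lengths whose patristic
   distances are meaningful on a common scale (any consistent unit; the
   standardization makes NRI/NTI unit-free);
2. binary, species-level trait data — a species either is or is not
   recorded for a category; record intensity and abundance are ignored;
3. exchangeability of tips under the null: any `k`-subset of the pool is an
   equally likely community.

Assumption 3 is where pool choice matters, and it is deliberately a caller
decision (see "Pool policy" below).

### Indices

For a community of size `k` with pool distance matrix `d`:

- MPD = mean of `d(i, j)` over unordered pairs of members;
- MNTD = mean over members of `min_j d(i, j)` for other members `j`;
- NRI = −(MPD_obs − mean(MPD_null)) / sd(MPD_null), NTI likewise from MNTD.

The null is the *taxa-label shuffle*: permute the tip labels of the pool's
distance matrix, keep the same `k` slots occupied. Because the permutation
only relabels, this is implemented as drawing `k` pool indices uniformly
without replacement per run (999 runs by default). The null sd uses the
`n−1` denominator, matching the convention of the standard R
implementation of these indices (one suite test cross-checks observed
values and effect sizes against picante through `Rscript`).

### p-values and ties

The one-tailed lower p-value is `rank / (runs + 1)`, where rank is the
position of the observed value among {observed} ∪ null with ties resolved
by midrank. Small p means unusually *small* distances, i.e. clustering;
overdispersed categories show p near 1. Midranks matter on trees with few
distinct distances: on a unit-branch balanced 8-tip tree a 2-member cherry
attains p ≈ 0.07 even though its MPD is the minimum possible, because 1/7
of random pairs tie it. With continuous branch lengths ties are measure
zero and the floor is 1/(runs+1).

A null sd of zero (community = pool, or a perfectly symmetric degenerate
case) yields a `degenerate` result with NA indices, never an error or a
division by zero; sds below 1e−12 of the null mean are treated as zero
because an exactly-constant null accumulates ~1e−16 of float summation
noise.

### Determinism

All randomness flows through `numpy.random.Generator`. The pipeline
derives one independent seed stream per (scope, category, metric) from the
run seed via `SeedSequence` with CRC-hashed scope/category names, so
adding or removing a category does not shift any other category's null.
Identical inputs and seed reproduce every output table bitwise; the run
manifest records seed, runs, package versions and SHA-256 digests of the
inputs.

## Pool policy

Which tips are eligible for the null draw is a scientific choice, not a
technicality:

- `all_tree_tips` (default): the pruned scope subtree, including
  non-medicinal species. This asks "are the species treating category X
  clustered relative to the whole flora of this clade?" — the natural
  question for bioprospecting.
- `medicinal_only`: only species present in the efficacy matrix. This asks
  "are they clustered relative to the medicinal species?"

The two can legitimately disagree. If the medicinal species are themselves
phylogenetically concentrated, every category will lean clustered against
the all-tips pool — a true signal of where medicinal knowledge sits, not a
calibration artifact. For exactly this reason the type-I calibration tests
use `medicinal_only`, matching the frame the synthetic generator draws
null communities from; against the all-tips pool the generator's
family-weighted medicinal subset is correctly detected as clustered.
Family-level scopes default to the family's matched species (both policies
then coincide); a caller holding the family's complete tip list may pass
it in an `AnalysisScope` to widen the pool.

No multiple-testing correction is applied across the 15 categories; the
significance flag is a per-test p < 0.05 and tables should be read
accordingly.

## Tree handling

Newick I/O, pruning and tip retention are delegated to dendropy; pruning
suppresses unary nodes and sums their branch lengths, so patristic
distances among surviving tips are unchanged (property-tested on random
tree/subset pairs). Patristic distances are computed by a single postorder
pass that fills cross-child blocks with numpy outer sums — O(n²) total —
because the analysis recomputes distance matrices for hundreds of
simulated trees. Missing branch lengths are a declared state: distance
computation raises unless a unit-branch-length fallback is explicitly
requested. Zero-length edges are allowed (they occur in large supertrees).
Tip labels are stored with underscores; spaces and underscores are
interchangeable on input.

## Name matching

`normalize_name` capitalises the genus, lower-cases epithets, preserves
`var.`/`subsp.`/`f.` rank tokens with their epithet, and strips trailing
authority strings (idempotent; fuzz-tested). Unmatched species are dropped
with a per-run report by default; the optional fallback maps an
infraspecific name onto its parent binomial with an OR-merge of the trait
rows. Dropping is the conservative default because it can never
double-count a tip. Duplicate species rows in input tables are OR-merged
(commutative and associative, so row order never changes the result).

## Synthetic data

The generator emulates the structure of a compiled ethnomedicinal study of
one plant order:

- **Tree**: pure-birth (Yule) simulation, birth rate 1.0/lineage/time,
  default 500 tips (the scale of an order-level subtree); ultrametric by
  construction, tips `t0001…`. Family analogues are the clades obtained by
  splitting the shallowest nodes until 5 groups exist.
- **Medicinal subset**: 551/1519 ≈ 36% of tips, allocated across the
  family clades with weights (0.544, 0.229, 0.125, 0.076, 0.025) — the
  five-family composition of the motivating compilation, largest clade
  paired with largest weight.
- **Categories**: 15, with default prevalences equal to the compilation's
  per-category species shares (13.2%…78.9% of medicinal species).
- **Community modes** per category: `null` (uniform draw), `clustered`
  (members drawn inside one random internal clade large enough to hold
  them; `strength` interpolates toward uniform), `overdispersed` (greedy
  max–min patristic spread, interpolated likewise). If no non-root clade
  is large enough, the largest is used and topped up uniformly, with a
  warning. Medicinal species left with all-zero rows are given one
  positive in a random null-mode category, since a recorded medicinal
  species must treat something.

A truth table (mode, strength, target and realised community size per
category) accompanies every simulated study for recovery scoring.

What the generator does *not* emulate: trait evolution (no
Brownian/OU model — clustering is planted by clade membership, which gives
an unambiguous truth label); name-matching noise (synthetic names always
match); correlated categories (each is drawn independently, whereas real
multi-use species induce correlated columns beyond the all-zero-row fix);
non-ultrametric supertree branch-length heterogeneity. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under its own assumptions, not that any particular real dataset satisfies
those assumptions.

## Problem sizes and tolerances in the test suite

Chosen as the package's own test design:

- metric correctness: 200 random (tree, subset) instances against naive
  enumeration, agreement to 1e−9;
- null calibration: pool 64, k = 8, 999 runs, 200 replicates; mean NRI
  within ±0.15 (≈2 standard errors) and Kolmogorov–Smirnov p > 0.01 for
  p-value uniformity;
- power: 300-tip trees, k = 30, strength 1, 999 runs, 100 seeds, ≥ 90%
  detection; overdispersed sign checked on 30 seeds;
- type-I: 100 all-null 15-category studies at 199 runs each (199 runs keep
  the check fast; the rank p-value's resolution of 1/200 is ample for a
  5% threshold), count of p < 0.05 within the 99% binomial band;
- exact-null consistency: an 8-tip pool where all C(8,3) communities are
  enumerated, sampled null mean/sd within 3 Monte-Carlo standard errors;
- picante cross-check: observed MPD/MNTD to 1e−8; NRI/NTI within 0.5,
  the combined Monte-Carlo spread of two independent 999-run nulls.

`scripts/acceptance.py` re-runs these quantities from scratch at the same
sizes and writes them as JSON.

## Known limitations

- The taxa-label shuffle is the only null model (by design); richness- and
  frequency-based nulls, abundance weighting, and Faith's PD are out of
  scope.
- Family scopes inherit the matrix's family column; the tree's internal
  node labels are never trusted for taxonomy.
- The iTOL export uses fixed named colors for the five reference families
  and a fallback cycle for others; exact published figure hues are not
  knowable from the figure itself.
- Greedy max–min overdispersion is a deterministic-ish heuristic, not the
  maximum-spread subset; at strength 1 its NRI is strongly negative, which
  is all the truth label requires.
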