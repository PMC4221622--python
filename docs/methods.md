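# Methods

## The inference problem

Two binary trait systems scored over the same set of groups can differ in
what shaped them even when both look superficially "shared culture."  The
pipeline separates two hypotheses:

* **Neutral, geographically mediated transmission.**  If traits spread by
  intergroup contact and are lost by drift, between-group similarity should
  decay with geographic separation — the cultural analogue of
  isolation-by-distance in population genetics.  The observable signature is
  a significant Mantel correlation between the cultural distance matrix and
  geographic distance (or border share), and nothing left over once
  geography is accounted for.
* **Lineage-linked (purifying) selection.**  If inherited ideological biases
  filter which variants are retained, groups sharing deep ancestry — proxied
  by language classification when language and geography are uncorrelated —
  stay similar regardless of location, and overall between-group diversity
  is suppressed relative to a neutrally transmitted system.  Signatures: a
  language association that survives a partial Mantel controlling geography,
  plus significantly lower paired distances than the neutral comparator.

All inference is permutational; no tree of group relationships is assumed.

## Distances and polarity

Jaccard similarity `S = a/(a+b+c)` ignores joint absences deliberately:
ethnographic "absent" very often means "not recorded."  Questionable cells
are excluded pairwise (the default) because recoding them either way invents
data; the `RECODE_PRESENT` policy exists to rerun everything as a
sensitivity check, and the two policies agree exactly on tables without
questionable cells.

Every matrix carries an explicit polarity (DISTANCE or SIMILARITY).  The
Mantel machinery is polarity-agnostic — r just flips sign — but mixed
polarities make signs easy to misread, so the report logs both polarities on
every comparison and the selection battery refuses anything but two DISTANCE
matrices.  Expected signs: distance × distance associations are positive
when the hypothesis fits; distance × similarity associations are negative.

Pair vectorization is fixed to upper-triangle row-major (i < j) order so the
paired selection tests always align the same group pairs.  Diagonals are
stored (0 for distances, 1 or 100 for similarities) but never enter any
statistic.

## Model matrices

* **Geography**: haversine great-circle distance between territory center
  points on a sphere of radius 6371.0088 km (IUGG mean).  At regional scale
  (hundreds to ~1500 km) the spherical approximation deviates from an
  ellipsoidal geodesic by well under 0.5%, and the Mantel r is insensitive
  to such near-linear rescalings.
* **Border share**: 0 for a shared territorial boundary, 1 otherwise — a
  coarse distance with the same orientation as geographic distance.
* **Language**: a tiered percent-similarity scheme applied to a
  family/subgroup classification — by default 5% between families, 50%
  within a family across subgroups, 80% within a subgroup, with optional
  per-pair overrides (e.g. raising especially close subgroup pairs to 95%)
  and tier variants (e.g. 30% within family) to check robustness of
  conclusions to the arbitrary percentages.  Groups without a named
  subgroup never match at the subgroup tier, so the scheme stays strictly
  three-tiered.
* **Scalar controls**: |v_i − v_j| for any per-group scalar, typically
  collection sample sizes, to rule out effort artifacts.

## Permutation tests

The Mantel statistic is the Pearson r of the two off-diagonal vectors; its
null distribution comes from simultaneous row+column permutations of the
*first* matrix (the second, and any control, stay fixed).  Sampled p-values
use the add-one convention `p = (1 + #extreme) / (n_perm + 1)`, which keeps
p strictly positive and is the standard finite-sample-valid choice; the
default tail is two-sided on |r| with one-sided tails available.  Ties are
counted as extreme (≥ with a 1e-12 float tolerance), matching the exact
enumeration.  `mantel_exact` enumerates all n! relabelings (identity
included, so min p = 1/n!) and is the oracle the sampler is validated
against for n ≤ 6.

The partial statistic is the first-order partial correlation
`r_AB·C = (r_AB − r_AC r_BC) / sqrt((1 − r_AC²)(1 − r_BC²))`, recomputed per
permutation of A with r_BC constant.  Permuting the first argument and
recomputing the full statistic (rather than permuting residual matrices) is
the simplest construction that is exactly reproducible; a permutation that
drives |r_AC| to 1 (possible only in pathological integer-valued matrices)
counts as extreme rather than aborting the run.

Defaults: 10,000 Mantel permutations, α = 0.05.  With 9 groups the sampled
null is effectively continuous (9! ≈ 3.6 × 10⁵ distinct relabelings).

## Selection battery

Three conservative nonparametric tests on the paired off-diagonal vectors:

* **Wilcoxon signed ranks, Monte Carlo**: W = sum of midranks of |d| over
  positive differences, zero differences dropped; the null flips each
  difference's sign independently (99,999 draws by default); the two-sided
  p compares |W − S/2| with S the total rank sum.
* **Sign test, exact**: count of positive differences among untied pairs;
  p doubles the smaller Binomial(m, ½) tail, capped at 1.
* **Mann-Whitney U, Monte Carlo**: U = min(U_x, U_y) from midranks, null by
  random reassignment of the pooled values (10,000 draws); small U is
  extreme in either direction, so the reassignment p is inherently
  two-sided.

The statistics (W, sign count, U) are seed-invariant; only Monte Carlo
p-values vary, within binomial error.  A direction is called only when all
three tests are significant at α (configurable to majority/any): PURIFYING
when the focal mean distance is below the reference mean, DIVERSIFYING when
above.  The paired distances share groups and are not independent, so every
run logs the caveat that this battery is a heuristic screen — corroborating
Mantel structure, not standalone proof of selection.

## Simulators

Both generators emit equilibrium presence/absence directly rather than
simulating a time-stepped contagion: the downstream statistics use only the
stationary pattern, and independent per-trait adoption is the simplest
process with the required covariance structure.

* **Neutral IBD**: each trait originates in a uniformly drawn group and is
  adopted by every other group independently with probability
  `exp(−d / decay_length)` — the canonical exponential distance kernel.
  Limits: decay → ∞ gives identical inventories (all distances 0);
  decay → 0 gives fully private inventories (all distances 1).
* **Lineage bias**: a `core_fraction` of traits is present everywhere; each
  remaining trait is favored by a random nonempty subset of language
  families (drawn with probability ½ per family), retained with certainty
  in favoring families and with probability `lineage_retention` elsewhere.
  Because favored subsets are drawn independently of the map, the language
  signal is geography-free in expectation.

Both apply independent per-cell noise flips last and are fully reproducible
from `SimulationParams.seed`.

Defaults — 200 traits, decay_length 500 km, core_fraction 0.6,
lineage_retention 0.1, noise_flip 0.02 — are the package's standard study
conditions: 500 km makes adjacent Plains-scale neighbours (300–600 km
apart) likely adopters and distant pairs (>1200 km) unlikely ones; a 60%
universal core mirrors trait lists dominated by region-wide elements with a
variable remainder; 2% flips approximate recording error.  At these
settings the acceptance benchmarks recover the geographic signal in
effectively all neutral replicates and a purifying verdict in effectively
all matched lineage replicates; the realized rates are recomputed, not
asserted, by `scripts/acceptance.py`.

What the simulators do *not* emulate: historical migration (group positions
are static), trait correlations (traits are exchangeable and independent),
borrowing asymmetries, population size effects, and any fitting of generator
parameters to real matrices.  Passing recovery benchmarks therefore shows
the pipeline detects the idealized signatures at realistic sizes — not that
real datasets of this size always yield unambiguous answers.

## Fixture layout

`make_plains_fixture()` ships a nine-group layout spanning four language
families (Algonquian with an Arapahoan subgroup, Siouan with a Dakotan
subgroup, Kiowa-Tanoan, Athabaskan).  Its coordinates and border pairs are
synthetic placeholder territory centers, plausible for the mid-late 19th
century High Plains and adequate for simulation and benchmarking; any
real-data analysis must load an authoritative coordinate table instead.
The placeholder status is deliberate and flagged in the docstring so
simulated benchmarks can never be mistaken for ethnographic results.

## Numerical and convention choices

* Add-one p-values everywhere a null is sampled; exact tests report exact p.
* Midranks for all tied ranks; zero differences dropped (no Pratt
  correction); ties excluded from the sign test.
* Extremeness comparisons use a 1e-12 absolute tolerance so float jitter
  cannot split tied statistics between "extreme" and "not."
* Unseeded public calls draw a seed from the OS and log it at INFO, so any
  run can be replayed.
* Label order is data order, never alphabetical; matrices are aligned by
  explicit reordering and any group-set mismatch aborts with the offending
  matrix named.
* Degenerate inputs (all-tied pairs, constant off-diagonals, pairs with no
  scorable presences) raise or warn explicitly rather than returning NaN.

## Known limitations

* Mantel-family tests have known power and error-rate caveats when the
  control structure is itself strongly autocorrelated; the pipeline reports
  the language × geography correlation precisely so users can judge whether
  the partial test is trustworthy for their layout.
* The selection screen compares two trait *systems*; it cannot attribute
  the contrast to selection on one of them without the Mantel context, and
  it ignores the non-independence of matrix entries (documented, not
  corrected).
* With nine groups there are only 36 pairs; p-values near α should be read
  with the granularity of permutation distributions in mind.
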