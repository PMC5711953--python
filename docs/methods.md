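# Methods

## Model and tests

A retrotransposon marker is a presence/absence character at an orthologous
locus, treated under Dollo logic: one insertion event, no precise excision.
The taxa carrying an insertion therefore delimit the clade descending from
the branch on which it inserted, except when hemiplasy (incomplete lineage
sorting, ILS, or introgression) lets a polymorphic insertion sort against
the species tree.  Precise excision is not modeled — empirically it is very
rare (below half a percent in comparable genome-scale surveys) — so every
conflicting pattern is explained as hemiplasy, never as reversal.

With markers ascertained in a single reference genome, one resolution of
every trichotomy (the one excluding the reference) is unobservable: the
"blind" tree.  The package's four tests are exact cumulative binomial tests
sharing one kernel, `P(X ≥ k)` for `X ~ Binomial(n, p)`:

| test | n | k | p | tail |
|---|---|---|---|---|
| multi-directional support (P) | a+b+c | a | 1/3 | upper |
| one-directional support (P_B) | a+b | a | 1/2 | upper |
| ILS symmetry (P_ILS) | a+b | max(a,b) | 1/2 | doubled, capped at 1 |
| insertion ratio (P_Rγ) | d+e | d | γ | upper |

The ILS test addresses H_ILS (blind tree true; the observable markers are
ILS hemiplasy, which is distributed symmetrically over the two observable
trees); it is independent of the unobservable count.  The ratio test
addresses H_Introgression (blind tree true; the sharing was donated by gene
flow).  Writing β and α for donor-stem insertions before/after the event and
γ for the genome fraction shared, the expected donated markers are n = βγ
and the donor-exclusive ones m = α + β(1−γ); since α, β are unobservable,
n is bounded by N = γ(d+e), attained at α = 0.  Using γ in the binomial in
place of the (unknown) true ratio makes the test conservative for the given
γ.  The blind tree is rejected only when both hypotheses are rejected; a
significant P_B alone never resolves a trichotomy in this regime.

All tails are computed with `fractions.Fraction` (exact rational
arithmetic); the printed reference values are exact rationals (e.g. 37/256 =
0.1445), so float summation error would otherwise surface in 4-decimal
comparisons.  Display rounding is half-up to 4 decimals; values below
0.00005 print as `<0.0001`.  Internal comparisons always use unrounded
values.  Probabilities given as floats are interpreted through their decimal
literal (0.2 means exactly 1/5).

## Tunable parameters

* `alpha` (default 0.05): rejection level for all tests.
* `trigger` (default 0.1): the hemiplasy tests run only when P_B ≤ trigger;
  below that binary preference they cannot be informative.  `--force`
  overrides.
* `gammas` (default 0.5 and 0.2): genome fractions for the ratio test;
  0.5 is the extreme F1-hybrid scenario, 0.2 a moderate-introgression one.
* `decisive_gamma` (default 0.5): the γ whose ratio test must reject before
  the blind tree falls.  Rejection only at a smaller γ is annotated
  ("rejected under the moderate-introgression assumption") but leaves the
  verdict at "no" — the conservative reading.
* `stringency` (default 2): a marker is CLEAN only if its absence is
  verified on at least this many lineages branching below its clade, or on
  all such lineages when the tree offers fewer (a marker on the branch
  adjacent to the root can have only one outgroup lineage).  A lineage whose
  members are all MISSING for the locus verifies nothing.  `strict_successive`
  additionally demands that the *nearest* lineages do the verifying.
* `bonferroni` (default off): optional α/n across scanned nodes; no
  cross-node correction is applied by default.

## Polarization and trichotomy counting

A locus is UNINFORMATIVE when present in none, one, or all sampled taxa;
CLEAN when its presence set equals the sampled membership of one tree clade
(MISSING cells are compatible with either state) and the stringency rule
holds; INSUFFICIENT_OUTGROUP when the pattern fits a clade but deeper
absence cannot be verified; otherwise AMBIGUOUS, with the minimal
conflicting taxa recorded.  Statuses are deterministic and independent of
row/column order.  Loci whose status rests on MISSING cells are flagged.
Polymorphic calls are coded PRESENT (the insertion demonstrably exists in
the lineage) with a warning.

Counting at a trichotomy is pattern-based rather than status-based, because
a marker can conflict with the overall species tree yet fit one of the three
local resolutions exactly (for example a pattern uniting the two non-sister
subgenera: globally hemiplasic, locally an unambiguous vote).  A marker
counts for a resolution when every taxon of that clade pair is present (or
missing), everything else is absent (or missing, or explicitly ignored), the
presence touches both clades of the pair, and the stringency rule holds
below the pair.  Markers violating this but touching exactly two of the
three clades are *resolvable-ambiguous*; they are tallied separately and
merged only on explicit request, never silently.

Two node types exist.  A standard node is three disjoint clades plus the
reference taxon, from which the blind pairing is derived.  A composite node
expresses questions like "where does taxon X attach, regardless of taxon Y":
each observable slot is a list of (required, optional) taxon sets, where
optional taxa are "don't care".  This is needed because cumulative counts
span successive branches — e.g. support for a nested placement aggregates
the markers of two consecutive stem branches — while a pattern that fails a
*required* absence (a marker absent in a lineage the hypothesis needs)
must still be excluded; plain taxon masking cannot do both.

The ratio pattern takes d from the tested slot's tally and e from markers
confined exactly to the reference-containing clade.  Because the shallower
exclusive branch is a branch of the accepted species tree, only globally
CLEAN markers are eligible for e (and for both counts of the stand-alone
`ratio_count_for_clade`); this keeps conflicting loci from masquerading as
exclusive-branch markers under "regardless of" masking.

## The packaged example and the synthetic-data generator

The kangaroo fixture (16 taxa, 29 informative loci, reference *M. eugenii*)
is a synthetic matrix constructed to realize the published per-node counts,
conflict set and ratio patterns of the macropodine solo-LTR survey; locus
identifiers are synthetic, and untested cells (MISSING) reproduce the
documented gaps.  One locus (K136) fits a deep clade but has only one
verifiable outgroup absence; it polarizes INSUFFICIENT_OUTGROUP and is
excluded from testing, matching its published treatment.  The fixture
encodes only the marker table — no sequences, dates or wet-lab results.

The simulator emulates the generative process on a rooted four-taxon
scaffold ((R,B),C,O): per-branch Poisson insertion counts (a fixed-count
mode exists for exact-expectation tests); markers on the internal branch of
the true tree resolve to the species pattern with probability
1 − (2/3)e^(−T) and to each discordant pair pattern with probability
(1/3)e^(−T), the standard three-lineage coalescent probabilities for an
internal branch of T coalescent units — the simplest model with the
symmetry property the ILS test assumes; introgression shares each pre-event
donor insertion with probability γ; finally the ascertainment filter drops
every marker absent in the reference.  Defaults (internal intensity 10,
T = 1 coalescent unit, β = 8, α = 0) are chosen to match the scale of the
empirical nodes, where individual branches carry roughly one to nine
markers.  For ratio-test calibration the reference lineage must be an
internal branch (a single-leaf marker is an uninformative autapomorphy), so
the scaffold splits R into a cherry (R1,R2); gene flow into the reference
lineage, the one direction whose calibration depends on rate equality, is
available with a donor-rate multiplier to reproduce the documented
overconfidence regime (donor inserting more than about twice as fast).

What the simulator does **not** emulate: finite-locus screening noise,
marker-family heterogeneity, insertion-site preferences, polymorphic
(unfixed) insertions, multilevel hemiplasy spanning several internal
branches, and real missing-data structure.  Passing calibration therefore
shows the tests hold their nominal level under the stated generative model,
not under every real-data pathology; the empirical fixture tests complement
this by pinning the full pipeline to published values.

## Numerical and design notes

* Binomial tails are summed exactly over `math.comb`; equality against a
  weighted enumeration of all 2^n outcome sequences is asserted for n ≤ 12,
  and against the scipy survival function in floats.
* Two-tailed convention: double the upper tail at max(a,b), capped at 1;
  ties give exactly 1.
* The caller designates the tested topology; counts are never silently
  reordered (a `canonicalized()` helper reports the swap).
* Calibration replicates with no testable markers count as non-rejections:
  an exact test cannot reject on empty data, and dropping them would bias
  the rate upward.
* Simulation problem sizes in the shipped tests: 1000 replicates per
  calibration null, 10^4 replicates for expectation checks, 10^5–3·10^5
  markers for the closed-form and exchangeability checks — ample for the
  3-standard-error and α-level assertions made.
* Reports are bit-stable for identical inputs; every test invocation is
  logged with its unrounded p-value.
* The CLI surfaces the library one-to-one; configs (node specs, simulation
  scenarios) are YAML and round-trip losslessly.

## Known limitations

* The framework covers three-way resolutions; four-branch generalizations
  and polytomy tests are out of scope.
* The ratio test's conservatism claim is numerical (simulated), not a
  closed-form proof, and fails by design when gene flow runs into the
  reference lineage from a much faster-inserting donor.
* Marker calling from reads/alignments, target-site-duplication validation
  and element subfamily classification are upstream of this package.
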