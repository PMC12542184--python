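# Methods

This note records the models, conventions and design choices behind
each module, in the order data flows through the pipeline.

## Trees and bipartitions

Trees are stored rooted (polytomies are first-class; no arbitrary
binarization), but all between-tree comparisons are made on unrooted
nontrivial bipartitions, so the stored rooting never affects a result.
A bipartition is canonicalized so that it equals its mirror; two splits
conflict iff all four pairwise side intersections are nonempty, and a
split restricted to a taxon subset is *degenerate* (uninformative) when
either side drops below two taxa. A binary unrooted tree on *n* tips
has exactly *n*−3 nontrivial splits; this invariant is enforced in the
tests over hundreds of random trees.

Newick parsing and serialization are delegated to dendropy. Branch
supports are accepted both as internal node labels and as bracketed
comments, and are interpreted on the 0–100 percent scale; a tree whose
supports all lie in [0, 1] is assumed to use the proportion convention
and is rescaled with a warning (bootstrap and coalescent-support
conventions coexist in the wild). Tip labels are normalized by
collapsing whitespace/underscore runs to a single underscore so that
tree tips join reliably against label tables. Output always uses the
internal-node-label form.

`collapse_low_support(t)` contracts internal branches with support
strictly below the threshold into polytomies; branches lacking a
support value are retained. The operation is idempotent at a fixed
threshold and monotone in it (the split set at a higher threshold is a
subset of the split set at a lower one). Thresholds of 10 and 30 are
the conventional settings for suppressing gene-tree estimation error
before coalescent summaries.

`root_on_outgroup` roots on the edge best separating the outgroup:
among all edge sides the one maximizing (outgroup coverage, then
fewest ingroup contaminants, then canonical order) is chosen. For a
monophyletic outgroup this is its stem branch. The coverage-first rule
is this package's decision for the non-monophyletic case — purity alone
cannot distinguish a lone outgroup tip's pendant edge from the full
outgroup clade, since both are perfectly pure. Rooting never changes
the unrooted split set.

## Tree concordance factors

For each reference branch, every input tree is classified
concordant / conflicting / uninformative after restricting both the
reference split and the input tree's splits to their shared taxa
(collections routinely have unequal taxon sets). Uninformative covers
two situations — missing-taxon degeneracy and polytomy-compatible
absence — distinguished in the per-tree verdicts but pooled in the
reported fraction, since they are one grey category in the usual pie
rendering. Uninformative trees stay in the denominator: fractions are
over the full collection, which is what makes 10/13 print as 77% with
the 3 dissenters printing as 23%.

A conflicting tree may contain several splits incompatible with the
reference branch; exactly one is attributed per tree — the incompatible
split with the largest overlap with the reference branch's clade side,
ties broken canonically — because the report format carries a single
best alternative per branch. The best alternative is the most frequent
attributed split; remaining conflicts are pooled as "other". Display
percentages are integers rounded half away from zero (12/13 → 92,
8/13 → 62, 5/13 → 38).

The engine is verified against a brute-force classifier (edge-deletion
split enumeration after pruning, with the textbook incompatibility
test) on all small-tree cases, and against planted truth: collections
built with exact per-branch concordance counts are recovered exactly.

## Barcode QC by species bins

Reported names are parsed into three statuses: proper binomials;
genus-only names (bare genus, or epithets in sp./spp./n.sp., plus
cf./aff. qualifiers, which are additionally flagged); and above-genus
placeholders (names matching a family in the registry or carrying a
rank suffix such as -iformes/-idae/-inae). Only binomials can pass QC.

Bin assignment makes the manual practice — inspecting a guide tree for
clusters of same-named sequences supported by two or more individuals —
operational. For each binomial name, the defining clade is the node
containing the most tips of that name subject to a purity constraint,
where purity ignores (a) nonspecific-labeled tips ("*Stomias* sp."
inside a *Stomias* bin is uninformative, not conflicting) and (b)
foreign binomial names represented by fewer than `min_members` tips
inside the clade — a lone foreign-named tip inside a tight cluster is
precisely the misidentification signature, not a genuine conflicting
cluster. On ties in own-tip count the larger clade wins, so those
suspects are absorbed into the defining clade. Defaults:
`min_members = 2`, `purity = 1.0`, both configurable; singleton species
cannot form bins unless `--allow-singletons` is given.

Verdicts follow the precedence nonspecific > mismatch > no_bin. A tip
inside a foreign defining clade is a mismatch when it either falls
within the clade's member core or its own name is supported by a bin
elsewhere; a lone, otherwise-unsupported name merely adjacent to a
cluster cannot be told apart from a genuine rarity and is conservatively
no_bin. A correctly named singleton nested in no foreign bin is no_bin,
not pass (the two-individual support rule). The module contains no
randomness: identical inputs always give identical bins and verdicts.

Per-family summaries resolve each record's genus through the registry
(above-genus names resolve to their family when it is one, else to an
"unplaced" row) and report percentages to one decimal, rounded half
away from zero (130/350 → 37.1). Because published rounded cells are
not always mutually consistent, reports carry the exact counts next to
every rounded value.

What the generator does and does not emulate: planted misidentification
is a pure relabeling (the sequence stays at its true position), planted
rogues are regrafted onto deep backbone branches, and species clusters
are simulated clean. Real barcode data add within-species paraphyly,
incomplete lineage sorting and alignment error, so passing the planted
recovery tests demonstrates the classifier logic, not robustness to
every failure mode of real COI data. Contaminated species can lose bin
support (fewer than two correctly named members remain), in which case
their correctly named sequences conservatively fail as no_bin — a real
property of the protocol, visible in the simulations as a small excess
of no_bin over the planted rogue count.

## Taxonomy registry and monophyly

The registry maps each genus to exactly one family per classification
scheme and carries per-genus valid-species counts, so family diversity
lines are recomputable sums. A bundled registry covers the eight-family
Stomiiformes arrangement (52 genera); tips resolve to genera by their
first underscore token unless an explicit tip table overrides.

Group monophyly on a tree is rooting-invariant: a group with ≥2 tips
present is monophyletic iff the group-versus-rest split exists in the
unrooted tree (trivially true when fewer than two tips remain outside).
Groups reduced to one tip are *monotypic* — rendered as a checkmark but
kept distinct internally, since monophyly by monotypy is a caveat worth
preserving; absent groups render as a dash. The test suite checks
agreement with an exhaustive-rooting oracle on hundreds of random
(tree, group) pairs.

## Supermatrix

Missing characters are `-`, `?` and `N`; other IUPAC ambiguity codes
count as present (the conventional reading; published "missing sites"
figures rarely define the set). A parsimony-informative site has ≥2
non-missing states each in ≥2 sequences. Locus filters are strict as
printed conventions dictate: retain loci with ≥4 sequences, length
strictly greater than the length threshold, strictly more than the
taxon threshold; the filters commute and the exclusion log names the
first failed rule.

Concatenation fills absent taxon-by-locus blocks with gaps and reports
two missingness figures — the total missing fraction over panel ×
length, and the absent-block-only fraction — because it is genuinely
ambiguous which convention a given published percentage uses. Partition
coordinates are 1-based inclusive; mean species per locus is the
arithmetic mean of per-locus taxon counts rounded to the nearest
integer.

The partitioner sorts non-anchor loci by (PI sites desc, length desc,
id) and deals them in snake order to *k* subsets. Snake dealing, unlike
greedy min-load balancing, guarantees subset cardinalities differing by
at most one — 927 non-anchors at k=3 give exactly 309 each — while
keeping PI and length sums balanced to within one locus. Anchors
(full-coverage loci) and extras (e.g. a barcode locus) are replicated
into every subset. The procedure is deterministic; the seed parameter
is accepted for interface stability only.

## Parsimony character mapping

Characters are unordered multistate (no ordering is asserted for
morphological traits); `?` contributes the full state set at its leaf.
The minimum step count is computed by unit-cost dynamic programming
over the rooted tree — the generalized Fitch intersection/union
recursion expressed as a cost table — which is exact on polytomies as
well as binary trees (collapsed trees must still be mappable without
inflating step counts).

ACCTRAN and DELTRAN are top-down resolutions over the DP table: at each
node, among the states that keep the subtree globally optimal given the
parent's state, ACCTRAN prefers a state different from the parent
(changes as early, i.e. root-ward, as possible — favoring early gains
with reversals) and DELTRAN prefers the parent's state (changes as
late, i.e. tip-ward, as possible — favoring parallelisms). Remaining
ties, including the root state, are broken by the smallest state in a
fixed ordering, so both maps are deterministic and both always realize
exactly the Fitch length. The stem-synapomorphy report lists, per
monophyletic group, the characters whose reconstruction places a change
on the group's stem branch under each resolution.

## Synthetic data

All generators draw from one RNG stream per operation, keyed by
(seed, operation name), so adding a generator never shifts existing
fixtures; integer-only tree construction keeps draws platform-stable.

Reference topologies are uniform over labeled unrooted binary trees
(sequential attachment to a uniformly chosen edge). Discordance is
planted by targeted nearest-neighbor interchanges rather than
coalescent simulation: an NNI across an internal edge replaces exactly
that edge's bipartition and no other, so planted per-branch concordance
counts are hit exactly — which is what the concordance acceptance
checks require; a coalescent mode is deliberately out of scope. With
the shared-alternative option all disrupted trees perform the same
subtree exchange and therefore agree on a single alternative split.

Barcode datasets expand a species backbone into per-species clades
(3–8 sequences by default — repository coverage of mesopelagic fishes
is thin and uneven, and a handful of sequences per species is typical)
and assign per-sequence fates by independent draws at the configured
rates, recording every planted fate in a truth table. Locus sets draw
lengths (251–420 bp by default, matching exon-capture markers that
survive a 250 bp filter), per-locus taxon subsets (6–34 taxa, centered
on ~20 species per locus), optional cell-level missingness and
full-coverage anchors, and can force an exact number of under-sampled
loci for filter tests.

## Problem sizes and runtime

The bundled tests and the acceptance script run at the study's own
scales where that is cheap (936 loci × 64 taxa for filtering and
partitioning; 13-tree collections for tCFs; the full 314,607 + 1,746
column concatenation) and at reduced scales for combinatorial oracles
(exhaustive parsimony enumeration on ≤8 tips; exhaustive rooting on
≤10 tips; tCF brute force on ≤7 tips), which is where those oracles
are tractable by construction. Barcode simulations use 20–40 species
with 3–14 sequences each — large enough for rate recovery within
binomial error, small enough to keep the suite fast.

## Known limitations

- tCF conflict attribution picks one split per tree; a tree conflicting
  with a branch in several distinct ways contributes only its
  largest-overlap conflict to the alternative tally.
- The QC surrogate is deliberately conservative: names lacking two
  supported individuals never pass, and heavily contaminated species
  can drag their correctly named sequences into no_bin.
- Polytomy handling in parsimony treats multifurcations as soft; hard
  polytomies (simultaneous radiation) would require counting changes
  differently.
- The barcode generator does not simulate sequence evolution; guide
  trees are topologically clean, so QC results on synthetic data bound
  the classifier's behavior from the favorable side.
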