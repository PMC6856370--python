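# Methods

## Coordinate model

All stages share a single promoter coordinate convention: positions are
1-based, TSS-relative and signed, with no position 0 — index 1..U of a
record maps to −U..−1 and index U+1..U+D to +1..+D, and bounds are
inclusive. This is the only convention under which a −1635..+86 fragment
has length 1,721 bases (1635 upstream + 86 downstream, nothing at 0), so it
is fixed package-wide rather than configurable. Promoters are stored
sense-oriented; any genomic-strand bookkeeping happens before data enter
the package and survives only as the `assembly` metadata label.

## Motif scanning

The WRE pattern `WWCAAAG` is expanded into its four literal 7-mers; a scan
tests every 7-window of the sense sequence against that set and, through
the window's reverse complement, against the same set for minus-strand
hits. The expansion sets for the two strands are disjoint for this motif,
so "four per strand" sums to eight distinct strings with no double
counting. Two deliberate conventions:

* **Hit anchor.** A hit's position is the TSS-relative coordinate of the
  *leftmost sense-strand base* of the 7-mer on both strands. Published
  site positions such as −1587 or −1413 do not state their anchor; the
  leftmost-base choice is the single unambiguous one and is used
  everywhere (scanner, conservation caller, reporter designer), so any
  systematic offset cancels within the package.
* **Literal semantics.** Overlapping and nested matches are all reported;
  `N` is legal input but matches nothing. Scans default to the full
  record; the canonical analysis window is U = 5000, D = 0.

## Conservation calling

There is no field-standard definition of a "conserved" motif occurrence,
so the package operationalizes it: per-species hits are projected into the
columns of a supplied promoter alignment (gap-aware, so a 7-mer can span
more than 7 columns), and hits whose column intervals overlap are merged
by single linkage into clusters. Within a cluster each species contributes
at most one hit — when several compete, the one sharing the most columns
with the other species' intervals wins, ties going to the more upstream
position. Strand is deliberately ignored for the call (a functional site
can sit on either strand in different lineages) and recorded per member.
A cluster is *conserved* when at least `m` species are present; `m`
defaults to all-but-one, the weakest threshold under which a five-species
site lost in a single lineage (the rat scenario) still calls as
conserved. Alignment construction itself is out of scope — alignments are
consumed, not computed — and when none is available a positional fallback
clusters hits whose TSS-relative positions agree within a tolerance
(default 50 bases; promoter alignments rarely shift orthologous sites
further at these evolutionary distances).

## Distances and trees

Distances are computed after **complete deletion**: every column
containing a gap or an N is removed and the retained-column count is
reported with the matrix. Four estimators are provided:

* `p` — raw mismatch proportion;
* `jc` — Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4
  (such pairs are flagged saturated and reported as +inf; tree building
  refuses non-finite input rather than guessing);
* `tn93` — the Tamura–Nei 1993 closed form with empirical (pair-averaged
  or user-supplied) base frequencies;
* `mcl-tn93` — the default: a composite-likelihood TN93 in which the two
  transition/transversion rate ratios and pooled base frequencies are
  shared across *all* pairs, and the summed pairwise multinomial
  log-likelihood is maximized jointly over those ratios and the pairwise
  distances (L-BFGS-B in log-parameter space, tolerance 1e−8; rate matrix
  normalized to one expected substitution per unit time; transition
  probabilities via the matrix exponential). Sharing parameters across
  pairs is what distinguishes "maximum composite likelihood" distances
  from independent per-pair ML and stabilizes estimates on short
  alignments. Because JC is nested in TN93, data whose pattern counts sit
  at a JC point recover the JC distance exactly — the closed forms serve
  as independent cross-checks of the optimizer.

Trees are built with the Saitou–Nei Neighbor-Joining agglomeration:
Q-criterion selection with a deterministic tie-break (first (i, j) pair in
current taxon order), standard branch-length formulas, and exact
resolution of the final three-taxon star. Negative branch-length
estimates are clamped to zero with the raw value kept in a log (the common
convention; the alternative of propagating negatives breaks downstream
path-length arithmetic). A two-taxon input becomes one edge split evenly
between the leaves, preserving the path length. On additive matrices NJ
recovers the generating tree exactly (tested to 1e−9 up to 12 taxa);
`scikit-bio`'s independent NJ implementation is used as a cross-check in
the test suite, never as the implementation. Newick serialization keeps at
least 10 significant digits.

Branch-length uncertainty is estimated by a **site bootstrap**
(`nj_leaf_branch_bootstrap`): alignment columns are resampled with
replacement, distances and the NJ tree recomputed per replicate, and the
spread of each pendant branch taken as its SE. This respects the
correlation between distances that share sites, which a per-pair binomial
variance would ignore.

Two published-scale quantities — a five-species exon tree with
branch-length sum 0.645 from 1,052 complete-deletion positions — depend on
genome downloads and an alignment step that is not specified anywhere
reproducible; the package computes and reports both numbers on
user-supplied exon alignments (`wre-conserve tree` prints the usable-site
count and branch-length sum) but asserts neither.

## Reporter design

`design_reporter` extracts the WT insert with the window machinery above
and substitutes a replacement 7-mer at a stated site position (leftmost
base anchor, consistent with the scanner). It refuses to "mutate" a
position carrying no motif match on either strand and refuses a no-op
replacement; a replacement that itself matches the motif is allowed with a
warning (the construct would not abolish binding). Both inserts are
re-scanned and `validate_construct` reports the hit difference and the
in-site Hamming distance — for the canonical TTCAAAG → CCGCGGT edit all 7
positions differ. The luminescence side of reporter assays is wet-lab and
out of scope.

## Synthetic data

The generator emulates the statistical structure the conservation analysis
assumes: an iid-uniform root promoter evolved site-independently along a
known species tree, with orthologous WRE sites whose retention/loss per
species is the ground truth. Default study conditions, chosen once to
mirror the five-vertebrate design: species human, mouse, rat, chicken,
zebrafish on the fixed topology
`(((human:0.08,(mouse:0.06,rat:0.06):0.04):0.12,chicken:0.35):0.15,zebrafish:0.50)`
(pendant distances in substitutions/site, roughly mammal-close /
chicken-intermediate / fish-distant at non-coding divergence scales);
promoter length 5000 with D = 0 (the canonical scan window); JC model;
one TTCAAAG site planted at −1413 retained in all species except rat,
where it is overwritten with the non-binding CCGCGGT. Exon simulations
default to shorter (2,000–10,000 nt) alignments without planting.

Design choices that matter for interpretation:

* **Indel-free simulation.** The true alignment is the identity alignment,
  emitted with the records, so conservation recovery is tested against an
  exact truth. Real-alignment uncertainty (misalignment moving a site
  across columns) is explicitly *not* modeled; passing tests demonstrate
  correctness of the calling machinery, not robustness to alignment error.
* **Frozen planted sites.** Planting overwrites the evolved bases *after*
  substitution, so recovery is deterministic; a decaying mode instead
  plants the site in the root and lets it erode along the branches, for
  power exploration.
* **Background scrubbing.** Chance WRE matches arise in random sequence at
  rate 8/4^7 ≈ 4.9 × 10⁻⁴ per position over both strands (~2.4 expected
  per 5-kb window), and a chance root site on a short-branch subtree can
  even look conserved. By default these background matches are removed
  (one invariant core base is randomized until no non-planted match
  remains) so the planted registry is the complete truth; with
  `scrub_background=False` the background is kept for false-cluster-rate
  studies.
* **Isoform duplicates** are identical copies with distinct isoform ids —
  enough to exercise the per-species deduplication contract; alternative
  TSSs with shifted windows are not modeled.
* One `numpy` Generator seeded from the user's seed drives everything;
  identical inputs and seed give byte-identical outputs.

## Problem sizes in the test suite

The scanner is verified against a naive all-offsets/all-variants oracle on
1,000 random sequences (length ≤ 200, N-bearing); conservation recovery
runs 20 independent seeds of the full five-species, 5-kb scenario; NJ
exactness uses random additive matrices up to 12 taxa; branch-length
recovery simulates 10-kb alignments with 100 bootstrap replicates. These
sizes give stable statistics while keeping the whole suite in the
seconds range.

## Known limitations

* Conservation is defined by interval overlap in a *given* alignment;
  with a poor alignment the caller faithfully reports what the alignment
  implies.
* The composite-likelihood TN93 shares rate ratios globally; lineage-
  specific rate variation and among-site rate heterogeneity (gamma) are
  not modeled.
* No bootstrap support values on tree topology, no rooting, no
  position-weight-matrix scoring — degenerate-pattern matching is binary
  by design, matching the eight-string search definition of the WRE.
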