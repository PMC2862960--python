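# Methods

## Motif model and scanning

The bHLH predictive consensus is compiled into an ordered element list: 19
constrained positions (a residue class or a literal residue, length exactly
1) and 11 wildcard runs, two of variable length — the basic-region spacer
X(3–6) and the loop X(5–22).  Span bounds follow by summation: 44–64
residues.  The class written `σ` in the consensus is taken to be {I,V,T}:
the same class is defined as `δ` in some presentations and the two symbols
are treated as synonyms, the only reading consistent with both notations.

`best_match_at` scores one anchored window with a dynamic programme over
(element, residues consumed).  Among all spacer-length assignments it
minimises the mismatch count; ties are broken by smallest total spacer
length, then by lexicographically smallest spacer vector, making output
deterministic.  This is exactly equivalent to enumerating the 72 concrete
templates (the test suite enforces the equivalence against an independent
enumeration oracle), but runs in one pass.  Non-standard characters
('U', 'O', 'B', 'Z', 'X', 'J', …) mismatch at constrained positions and are
consumed silently by wildcards; input is uppercased.

`scan` slides over all offsets, keeps matches with at most a configurable
mismatch budget (default 9 — the permissive end of the published range,
since a domain with 9 mismatches can still be genuine), greedily retains
non-overlapping matches in increasing (mismatch, start) order, and reports
at most one domain per protein by default (bHLH proteins carry a single
domain; the cap is configurable).  A candidate requires ≥ 10 of 19 conserved
sites matching; both thresholds are exposed as parameters because published
practice varies between "fewer than 8 mismatches" and "more than 10
conserved sites".

`anchor_align` produces a motif-anchored alignment: conserved sites form 19
exact columns and each wildcard run is right-padded with gaps to its
observed maximum — a deterministic stand-in for a general-purpose aligner
that is exact for motif-anchored domains.

## Trees and family assignment

The in-package tree route is p-distance (gap-excluded proportion of
differing columns) → neighbor joining → nonparametric bootstrap.  NJ is
implemented directly so its determinism contract can be stated precisely:
exact Q-criterion ties resolve to the lexicographically smallest pair of
cluster representatives, and negative branch-length estimates are clamped to
zero.  Bootstrap replicate *r* resamples columns with the independent RNG
stream `default_rng([seed, r])`, so supports are reproducible and
independent of replicate order; each internal clade of the full-data tree is
annotated with the percentage of replicates containing its bipartition.
Pairs with no comparable columns inside a replicate are assigned the maximal
distance 1.0 rather than aborting the replicate.

External trees are first-class inputs: Newick with supports as internal node
labels (Bayesian posterior probabilities × 100 work identically).  Unlabeled
internal clades default to support 100, the single-tree convention.

Family assignment needs a root to delimit clades.  A tree read with a
bifurcating root keeps that rooting; unrooted (trifurcating) trees are
midpoint-rooted (missing branch lengths count as 1); an explicit outgroup
overrides both.  Walking rootward from the query, the smallest clade
containing a reference decides the family provided its references are all of
one family; the walk continues through every nested clade that stays
family-pure and the **best-supported clade of that chain** backs the
assignment.  This matters in practice: with several close reference members,
the exact sister pairing inside a family is unstable under resampling (low
support) while the family clade itself is near-certain; using only the
smallest clade's support would mislabel confident assignments as weak.
Statuses follow catalog conventions: `assigned` (single-reference pairing,
support strictly > threshold, default 50), `n/m` (grouping only with a
multi-member family clade), `n/m*` (no clade of the chain exceeds the
threshold), `orphan` (mixed-family smallest clade, or no
reference-containing clade below the root).  Degenerate all-zero-length
trees skip midpoint rooting and keep their current rooting rather than
failing.

## Catalog statistics

The packaged chicken catalog (104 entries) and the 45-family × 7-species
count matrix use one family-naming scheme (the canonical 45-family scheme);
the SREBP1/SREBP2 labels are normalised to a single SREBP family so the
42-of-45 arithmetic closes.  `species_totals` computes column sums; the
printed totals for two invertebrate columns disagree with their own column
sums in the source table, so only internally consistent totals are asserted
in tests.  Clusters are ≥ 2 same-family entries sharing a contig (default)
or chromosome; Orphan entries are excluded (orphan is the absence of a
family, not a family), and entries with unknown keys are skipped.  Cluster
output is sorted and invariant to row order.  Chromosome labels are filled
only for the nine genes with text-documented locations; contigs are the
reliable clustering key.

## GO enrichment

The upper tail P(X ≥ k) is delegated to `scipy.stats.hypergeom.sf`
(log-space internally, stable in the far tail); bounds are validated
strictly and k = 0 short-circuits to 1.  The population is the full gene
universe of the annotation map and the study set must be contained in it.
Benjamini–Hochberg adjustment is applied within the tested namespace —
conventional for GO toolkits — and raw p-values are reported alongside for
comparability.  Ancestor (true-path) propagation is available as an optional
pass over a user-supplied term→parent table, off by default.  Ambiguous
catch-all terms are excluded via a user-supplied stop list, not hard-coded.

Because the hypergeometric test is discrete, its attained type-I rate at a
nominal cut-off is conservative: with the default synthetic GO world
(population 400, study 20, ~50 terms) the exact attainable rate at p < 0.05
is ≈ 0.033, and the null simulation in the acceptance suite checks both that
the empirical rate is approximately nominal (0.015–0.075) and that it agrees
with the exact analytic rate within Monte-Carlo error.

## Synthetic data

Generators derive RNGs from `default_rng([seed, component])` with fixed
per-generator component ids, so one seed reproduces every output
byte-for-byte and the generators do not perturb one another.

*Planted domains.*  Spacer lengths are uniform within bounds; conserved
sites are filled from their classes; exactly *m* sites are substituted with
**neutral residues** — the nine standard residues ({C,D,G,H,M,P,Q,S,W})
belonging to no conserved-site class — and wildcard fillers are neutral too.
This guarantees no alternative spacer assignment can score better than the
planted one, so manifests are exactly verifiable; a rejection re-score
guards the (vanishingly rare) residual cases.  At m = 19 every spacer
assignment ties, so the re-scored spacer vector is the tie-break-minimal
one rather than the planted draw; the mismatch count is still exact.

*Proteomes.*  Default 50 sequences, 40% carriers, planted mismatch counts
uniform on 0–9, flanks of 80–120 i.i.d. residues per side (uniform
composition by default, a frequency table optional).  Background sequences
match carrier lengths.  Because flanks are unconstrained, a flank residue
can occasionally extend a planted hit by one position with a spacer re-sync;
carrier/non-carrier truth and mismatch counts remain exact.

*Reference panels.*  A shared root domain is diverged per family at 30% per
position, members and queries at 5% from their family ancestor (defaults).
Mutations at conserved sites stay **within the site's residue class**
(single-residue sites are immutable) and wildcard positions mutate within
the neutral set — real bHLH families diverge around, not at, the conserved
sites, and this keeps every panel domain a zero-mismatch motif instance so
the scanning and tree stages compose exactly.  Consequences: panel
divergence underestimates real sequence divergence at conserved sites, and
the generator makes no attempt at indels, rate heterogeneity or realistic
substitution matrices — passing tests demonstrate the decision rule and its
plumbing, not phylogenetic accuracy on real data.

*GO worlds.*  Population 400 genes, 50 background terms at 4 per gene,
planted term at background frequency 0.05 and enrichment factor 10 in a
20-gene study (defaults); truth records the realised contingency counts.

## Problem sizes in the test suite

The acceptance suite runs NJ consistency up to 20 taxa, the scanner-oracle
sweep on 500 random sequences of 44–200 residues, family recovery on the
8-family × 3-member panel with 10 queries and 100 bootstrap replicates
(observed recovery 10/10 at threshold 50), the exact tail-probability grid
for all populations N ≤ 25, a 200-replicate null enrichment simulation, and
the full synth → scan → assign → summarize chain at the defaults above.

## Known limitations

- NJ + p-distance + bootstrap is a deliberate stand-in for Bayesian/ML
  inference; for publication-grade trees, build them externally and ingest
  the Newick.
- Midpoint rooting is a convention; when a reliable outgroup exists, prefer
  `--outgroup`.
- The scanner permits only the consensus's own spacer flexibility (no gaps
  within helices); true domains with indels at conserved sites are missed.
- One domain per protein by default; multi-domain proteins need
  `--per-seq 0`.
- GO results depend entirely on the supplied annotation tables; no ontology
  release is packaged.
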