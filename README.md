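# bhlhkit

Toolkit for genome-wide surveys of **basic helix-loop-helix (bHLH)
transcription factors**: scan a proteome for the degenerate bHLH predictive
motif, assign the candidate domains to orthologous families on
support-annotated phylogenetic trees, summarise the resulting gene catalog
(higher-order groups A–F, families, orphans, chromosomal clusters), and run
hypergeometric GO-term enrichment.  It is aimed at comparative genomicists
cataloguing a transcription-factor family in a newly sequenced genome, and
ships a seeded synthetic-data layer so every stage can be exercised
end-to-end against exact ground truth.

## The model

The bHLH domain (~60 aa: basic region, helix 1, loop, helix 2) is recognised
with the classic predictive consensus carrying **19 conserved sites**
interleaved with wildcard runs, two of variable length:

```
+ + X(3-6) E + X R X(3) α N X(2) Φ X(2) L + X(5-22) + X(2) K X(2) σ L X(2) A σ X Y α X(2) L
```

with residue classes `+` = {K,R}, `α` = {I,L,V}, `Φ` = {F,I,L},
`σ` = {I,V,T}.  Any 44–64-residue window is scored by the spacer-length
assignment minimising the number of conserved-site mismatches (dynamic
programme over the 4 × 18 = 72 concrete templates); a window with at least
10 of 19 sites matching (≤ 9 mismatches) is a candidate bHLH domain.

Candidates are placed into named orthologous families (MyoD, Atonal,
H/E(spl), …) by the monophyly rule: a query belongs to family *F* when, in a
tree containing reference domains of known family, the clade grouping the
query with only *F* references has support > 50%.  Trees are built in-package
(p-distance + neighbor joining + nonparametric bootstrap) or ingested as
Newick with supports from any external Bayesian/ML program — the rule
consumes only topology and supports.  Enrichment of a study set of *n* genes
against a population of *N* uses the upper-tail hypergeometric probability
P(X ≥ k), X ~ HG(N, K, n), with Benjamini–Hochberg adjustment.

## Worked example

```
$ bhlh synth proteome --seed 7 --n-seqs 20 --out data
wrote 20 sequences to data
$ bhlh scan --fasta data/proteome.fasta --out report.tsv
8 matches (8 candidates)
$ head -5 report.tsv | cut -f1-6
seq_id   start  end  n_mismatch  n_conserved  is_candidate
seq0000  112    161  8           11           True
seq0001  118    177  7           12           True
seq0002  106    166  8           11           True
seq0003  113    159  1           18           True
```

The generator planted one domain in 8 of 20 sequences (mismatch counts drawn
from 0–9); the scan recovers exactly those 8 carriers as candidates —
`n_mismatch` is the planted mismatch count, and `n_conserved =
19 − n_mismatch` stays at or above the ≥ 10 candidate threshold.
`data/manifest.tsv` holds the ground truth for comparison.  Downstream,
`bhlh assign` places each candidate domain into a family with a bootstrap
support percentage and a status (`assigned`, `n/m` for grouping with a
multi-member family clade, `n/m*` for support ≤ 50, `orphan`), and
`bhlh summarize` writes catalog statistics as JSON.

The packaged chicken catalog reproduces the published survey exactly:

```python
>>> from bhlhkit import load_packaged_catalog, group_counts
>>> group_counts(load_packaged_catalog())
{'A': 50, 'B': 21, 'C': 15, 'D': 4, 'E': 8, 'F': 3, 'orphan': 3}
```

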