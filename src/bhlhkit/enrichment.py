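"""Hypergeometric GO-term enrichment and term-frequency reports.

Given a study gene set drawn from an annotated population, each GO term
annotated to at least one study gene is scored with the upper-tail
hypergeometric probability

    P(X >= k),   X ~ Hypergeometric(N, K, n)

where ``N`` is the population size, ``K`` the population genes carrying the
term, ``n`` the study size, and ``k`` the study genes carrying the term.
Raw p-values are adjusted with Benjamini-Hochberg within the tested
namespace; both raw and adjusted values are reported.  Hypergeometric
p-values are discrete, so the achieved type-I rate at a nominal cut-off is
conservative (at or below the nominal level).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
_GAF_ASPECT = {"P": "biological_process", "F": "molecular_function",
               "C": "cellular_component"}


@dataclass
class AnnotationMap:
    """gene -> GO-term-set mapping plus a term -> namespace table."""

    gene_terms: Dict[str, frozenset]
    term_namespace: Dict[str, str]

    def __post_init__(self):
        missing = {
            t for terms in self.gene_terms.values() for t in terms
        } - set(self.term_namespace)
        if missing:
            raise ValueError(
                f"terms without a namespace: {sorted(missing)[:5]}..."
                if len(missing) > 5 else
                f"terms without a namespace: {sorted(missing)}"
            )

    @property
    def genes(self) -> Set[str]:
        return set(self.gene_terms)

    def terms_in(self, namespace: Optional[str]) -> Set[str]:
        if namespace is None:
            return set(self.term_namespace)
        return {t for t, ns in self.term_namespace.items() if ns == namespace}


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    namespace: str
    k: int  # study genes with term
    n: int  # study size
    K: int  # population genes with term
    N: int  # population size
    p_raw: float
    p_adj: float


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    The survival function is evaluated by scipy in log space, which keeps the
    extreme tail stable.  Bounds are validated strictly.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    study: Iterable[str],
    annot: AnnotationMap,
    namespace: Optional[str] = None,
    stoplist: Optional[Iterable[str]] = None,
) -> List[EnrichmentResult]:
    """Score every term annotated to at least one study gene.

    The population is the full gene universe of ``annot``; the study set
    must be a subset of it.  ``stoplist`` drops ambiguous catch-all terms
    before testing.  Results are BH-adjusted over the tested terms and
    sorted by raw p-value (ties by term id).
    """
    study_set = set(study)
    if not study_set:
        raise ValueError("study set is empty")
    absent = sorted(study_set - annot.genes)
    if absent:
        raise ValueError(f"study genes absent from population: {absent}")
    stop = set(stoplist or ())
    ns_terms = annot.terms_in(namespace) - stop

    N = len(annot.genes)
    n = len(study_set)
    k_counts: Dict[str, int] = {}
    K_counts: Dict[str, int] = {}
    for gene, terms in annot.gene_terms.items():
        in_study = gene in study_set
        for t in terms:
            if t not in ns_terms:
                continue
            K_counts[t] = K_counts.get(t, 0) + 1
            if in_study:
                k_counts[t] = k_counts.get(t, 0) + 1

    tested = sorted(k_counts)
    if not tested:
        return []
    p_raw = [
        hypergeom_upper(k_counts[t], K_counts[t], n, N) for t in tested
    ]
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            term=t,
            namespace=annot.term_namespace[t],
            k=k_counts[t],
            n=n,
            K=K_counts[t],
            N=N,
            p_raw=pr,
            p_adj=min(float(pa), 1.0),
        )
        for t, pr, pa in zip(tested, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term))
    return results


def term_frequencies(
    study: Iterable[str],
    annot: AnnotationMap,
    namespace: Optional[str] = None,
    min_count: int = 1,
) -> List[Tuple[str, int]]:
    """Per-term study-gene counts, filtered at ``count >= min_count``.

    Ordered by descending count, ties by term id — the layout of a
    term-frequency bar report.
    """
    study_set = set(study)
    absent = sorted(study_set - annot.genes)
    if absent:
        raise ValueError(f"study genes absent from population: {absent}")
    ns_terms = annot.terms_in(namespace)
    counts: Dict[str, int] = {}
    for gene in study_set:
        for t in annot.gene_terms[gene]:
            if t in ns_terms:
                counts[t] = counts.get(t, 0) + 1
    return sorted(
        ((t, c) for t, c in counts.items() if c >= min_count),
        key=lambda tc: (-tc[1], tc[0]),
    )


# ---------------------------------------------------------------------------
# readers


def read_annotations(
    gene_term_path,
    namespace_path=None,
    default_namespace: str = "biological_process",
) -> AnnotationMap:
    """Read a 2-column (gene, term) TSV plus an optional term-namespace TSV.

    Terms absent from the namespace table fall back to
    ``default_namespace``.
    """
    gene_terms: Dict[str, set] = {}
    with open(gene_term_path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"bad annotation row: {row!r}")
            gene_terms.setdefault(row[0].strip(), set()).add(row[1].strip())
    term_namespace: Dict[str, str] = {}
    if namespace_path is not None:
        with open(namespace_path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                term, ns = row[0].strip(), row[1].strip()
                if ns not in NAMESPACES:
                    raise ValueError(f"unknown namespace {ns!r} for {term!r}")
                term_namespace[term] = ns
    for terms in gene_terms.values():
        for t in terms:
            term_namespace.setdefault(t, default_namespace)
    return AnnotationMap(
        gene_terms={g: frozenset(ts) for g, ts in gene_terms.items()},
        term_namespace=term_namespace,
    )


def read_gaf(path) -> AnnotationMap:
    """Minimal GAF 2.x reader using only columns 2 (gene), 5 (term) and
    9 (aspect)."""
    gene_terms: Dict[str, set] = {}
    term_namespace: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"GAF line with fewer than 9 columns: {line!r}")
            gene, term, aspect = cols[1], cols[4], cols[8]
            if aspect not in _GAF_ASPECT:
                raise ValueError(f"unknown GAF aspect {aspect!r}")
            gene_terms.setdefault(gene, set()).add(term)
            term_namespace[term] = _GAF_ASPECT[aspect]
    return AnnotationMap(
        gene_terms={g: frozenset(ts) for g, ts in gene_terms.items()},
        term_namespace=term_namespace,
    )


def propagate(
    annot: AnnotationMap, term_parents: Dict[str, Set[str]]
) -> AnnotationMap:
    """Optional true-path propagation over a supplied term->parents table.

    Each gene inherits every ancestor of its annotated terms; ancestor
    namespaces default to the child's namespace when not already known.
    """
    # transitive closure per term, memoised
    closure: Dict[str, Set[str]] = {}

    def ancestors(t: str) -> Set[str]:
        if t in closure:
            return closure[t]
        out: Set[str] = set()
        for p in term_parents.get(t, ()):  # noqa: B023
            out.add(p)
            out |= ancestors(p)
        closure[t] = out
        return out

    ns = dict(annot.term_namespace)
    new_terms = {}
    for gene, terms in annot.gene_terms.items():
        full = set(terms)
        for t in terms:
            for a in ancestors(t):
                full.add(a)
                ns.setdefault(a, annot.term_namespace[t])
        new_terms[gene] = frozenset(full)
    return AnnotationMap(gene_terms=new_terms, term_namespace=ns)
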