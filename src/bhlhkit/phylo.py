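"""Tree building and monophyly-based orthologous-family assignment.

A query bHLH domain is assigned to a named family when, in a support-annotated
phylogenetic tree that also contains reference domains of known family, the
smallest clade containing the query whose reference leaves all belong to one
family has support above a threshold (conventionally 50%).  The decision rule
consumes only the tree topology and per-clade support values, so trees may be
built in-package (p-distance + neighbor-joining + nonparametric bootstrap) or
ingested from any external program as Newick with supports on internal node
labels (Bayesian posterior probabilities expressed as percentages work the
same way).

Statuses mirror the conventions of published bHLH catalogs:

* ``assigned`` — query is sister to a single reference with support above the
  threshold;
* ``n/m`` — query groups with a clade of two or more references of one family
  (no single-reference pairing), support above the threshold;
* ``n/m*`` — a family clade exists but its support does not exceed the
  threshold;
* ``orphan`` — no family-pure clade below the root contains the query.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

GAP = "-"


# ---------------------------------------------------------------------------
# distances


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Proportion of differing residues over gap-free columns.

    Columns where either string has a gap are excluded from the denominator.
    Raises ``ValueError`` on unequal lengths or when no column is comparable.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal lengths")
    a = np.frombuffer(aligned_a.upper().encode(), dtype="S1")
    b = np.frombuffer(aligned_b.upper().encode(), dtype="S1")
    mask = (a != GAP.encode()) & (b != GAP.encode())
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no gap-free comparable columns")
    return float((a[mask] != b[mask]).sum()) / n


def alignment_distance_matrix(
    rows: Sequence[Tuple[str, str]], on_empty: str = "error"
) -> Tuple[np.ndarray, List[str]]:
    """All-pairs p-distance matrix of a rectangular alignment.

    ``on_empty`` controls pairs with zero comparable columns: ``"error"``
    raises, ``"max"`` records distance 1.0 (used inside bootstrap replicates
    where a resample may drop all shared columns of a gappy pair).
    """
    labels = [sid for sid, _ in rows]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in alignment")
    arr = np.array([list(s.upper()) for _, s in rows])
    nongap = arr != GAP
    n = len(rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = nongap[i] & nongap[j]
            ncomp = int(mask.sum())
            if ncomp == 0:
                if on_empty == "error":
                    raise ValueError(
                        f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                    )
                d = 1.0
            else:
                d = float((arr[i, mask] != arr[j, mask]).sum()) / ncomp
            D[i, j] = D[j, i] = d
    return D, labels


# ---------------------------------------------------------------------------
# support trees


@dataclass
class SupportTree:
    """A leaf-labeled tree with per-clade support percentages.

    ``support`` maps a clade's leaf-label frozenset to a value in [0, 100].
    ``ref_family``/``ref_group`` tag reference leaves; untagged leaves are
    queries.
    """

    tree: dendropy.Tree
    support: Dict[frozenset, float] = field(default_factory=dict)
    ref_family: Dict[str, str] = field(default_factory=dict)
    ref_group: Dict[str, str] = field(default_factory=dict)

    @property
    def leaf_labels(self) -> List[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def query_labels(self) -> List[str]:
        return [l for l in self.leaf_labels if l not in self.ref_family]

    def clade_support(self, leafset: frozenset) -> Optional[float]:
        if leafset in self.support:
            return self.support[leafset]
        other = frozenset(self.leaf_labels) - leafset
        return self.support.get(other)

    def with_references(self, ref_family: Dict[str, str],
                        ref_group: Optional[Dict[str, str]] = None) -> "SupportTree":
        self.ref_family = dict(ref_family)
        self.ref_group = dict(ref_group or {})
        return self


@dataclass(frozen=True)
class FamilyAssignment:
    query_id: str
    family: str
    status: str  # assigned | n/m | n/m* | orphan
    support: Optional[float]


def _leafset(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _internal_splits(tree: dendropy.Tree) -> List[frozenset]:
    """Leaf sets of all non-trivial clades (one side of each internal edge)."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(all_leaves)
    out = []
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        side = _leafset(nd)
        if 1 < len(side) < n - 1:
            out.append(side)
    return out


def _canonical(side: frozenset, all_leaves: frozenset, anchor: str) -> frozenset:
    return side if anchor not in side else all_leaves - side


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dist: np.ndarray, labels: Sequence[str]) -> SupportTree:
    """Neighbor-joining tree from a distance matrix.

    Deterministic: exact ties in the Q criterion are resolved in favour of
    the lexicographically smallest pair of cluster representatives (a
    cluster's representative is its smallest leaf label).  All internal
    clades carry support 100 (single-tree input).  Negative branch-length
    estimates are clamped to zero.
    """
    D0 = np.asarray(dist, dtype=float)
    labels = list(labels)
    n = len(labels)
    if len(set(labels)) != n:
        raise ValueError("duplicate taxon labels")
    if D0.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D0, D0.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D0) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    off = D0[~np.eye(n, dtype=bool)]
    if np.any(off < 0):
        raise ValueError("negative off-diagonal distances")

    ns = dendropy.TaxonNamespace(labels)
    # growing working arrays: up to 2n-2 cluster slots
    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = D0
    nodes = {i: dendropy.Node(taxon=ns.get_taxon(labels[i])) for i in range(n)}
    reps = {i: labels[i] for i in range(n)}
    active = list(range(n))
    nxt = n

    while len(active) > 3:
        r = len(active)
        order = sorted(active, key=lambda k: reps[k])
        R = {k: sum(D[k, m] for m in active if m != k) for k in active}
        best = None
        best_pair = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                a, b = order[ii], order[jj]
                q = (r - 2) * D[a, b] - R[a] - R[b]
                if best is None or q < best:
                    best = q
                    best_pair = (a, b)
        a, b = best_pair
        la = D[a, b] / 2 + (R[a] - R[b]) / (2 * (r - 2))
        lb = D[a, b] - la
        u = dendropy.Node()
        u.add_child(nodes[a])
        u.add_child(nodes[b])
        nodes[a].edge.length = max(la, 0.0)
        nodes[b].edge.length = max(lb, 0.0)
        for k in active:
            if k in (a, b):
                continue
            D[nxt, k] = D[k, nxt] = (D[a, k] + D[b, k] - D[a, b]) / 2
        nodes[nxt] = u
        reps[nxt] = min(reps[a], reps[b])
        active = [k for k in active if k not in (a, b)] + [nxt]
        nxt += 1

    # final three-way join with the three-point formulas
    a, b, c = sorted(active, key=lambda k: reps[k])
    center = dendropy.Node()
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        lx = (D[x, y] + D[x, z] - D[y, z]) / 2
        center.add_child(nodes[x])
        nodes[x].edge.length = max(lx, 0.0)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=center)
    tree.is_rooted = False
    support = {}
    for side in _internal_splits(tree):
        support[side] = 100.0
        support[frozenset(labels) - side] = 100.0
    return SupportTree(tree=tree, support=support)


def nj_from_alignment(rows: Sequence[Tuple[str, str]],
                      on_empty: str = "error") -> SupportTree:
    D, labels = alignment_distance_matrix(rows, on_empty=on_empty)
    return nj_tree(D, labels)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    alignment: Sequence[Tuple[str, str]], n_reps: int = 100, seed: int = 0
) -> SupportTree:
    """NJ tree of the full alignment with bootstrap support percentages.

    Columns are resampled with replacement per replicate; each internal clade
    of the full-data tree is annotated with the percentage of replicate trees
    containing the same bipartition.  Replicate ``r`` draws from the
    independent RNG stream ``default_rng([seed, r])``, so results are
    reproducible and replicate-order independent.
    """
    rows = list(alignment)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(rows) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    ncol = len(rows[0][1])
    if ncol < 2:
        raise ValueError("alignment must have at least 2 columns")
    if any(len(s) != ncol for _, s in rows):
        raise ValueError("alignment is not rectangular")

    full = nj_from_alignment(rows, on_empty="max")
    all_leaves = frozenset(full.leaf_labels)
    anchor = min(all_leaves)

    arr = np.array([list(s.upper()) for _, s in rows])
    labels = [sid for sid, _ in rows]
    counts: Dict[frozenset, int] = {}
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = [
            (labels[i], "".join(arr[i, cols])) for i in range(len(rows))
        ]
        rep_tree = nj_from_alignment(rep_rows, on_empty="max")
        seen = set()
        for side in _internal_splits(rep_tree.tree):
            seen.add(_canonical(side, all_leaves, anchor))
        for split in seen:
            counts[split] = counts.get(split, 0) + 1

    support: Dict[frozenset, float] = {}
    for side in _internal_splits(full.tree):
        pct = 100.0 * counts.get(_canonical(side, all_leaves, anchor), 0) / n_reps
        support[side] = pct
        support[all_leaves - side] = pct
    full.support = support
    return full


# ---------------------------------------------------------------------------
# newick I/O


def read_newick(text: str, default_support: float = 100.0) -> SupportTree:
    """Parse a Newick string; internal node labels become clade supports.

    Unlabeled internal clades receive ``default_support`` (the single-tree
    convention).  Supports must lie in [0, 100].
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in newick input")
    n = len(labels)
    support: Dict[frozenset, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd is tree.seed_node:
            continue
        side = _leafset(nd)
        if len(side) < 2 or len(side) > n - 1:
            continue
        if nd.label is not None and str(nd.label).strip():
            try:
                val = float(nd.label)
            except ValueError as exc:
                raise ValueError(
                    f"internal node label {nd.label!r} is not a support value"
                ) from exc
        else:
            val = default_support
        if not 0.0 <= val <= 100.0:
            raise ValueError(f"support {val} outside [0, 100]")
        support[side] = val
    return SupportTree(tree=tree, support=support)


def write_newick(stree: SupportTree) -> str:
    """Serialise a SupportTree as Newick with supports on internal labels."""
    tree = stree.tree.clone(depth=1)
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd is tree.seed_node:
            continue
        val = stree.clade_support(_leafset(nd))
        nd.label = None if val is None else f"{val:g}"
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    ).strip()


# ---------------------------------------------------------------------------
# family assignment


def _rooted_working_tree(
    stree: SupportTree, outgroup: Optional[str] = None
) -> dendropy.Tree:
    """Clone and root the tree for clade enumeration.

    An input that is already rooted (bifurcating seed node) keeps its
    rooting; unrooted (trifurcating) trees are midpoint-rooted, with missing
    branch lengths counted as 1.  ``outgroup`` always reroots above the
    named leaf.  Degenerate trees with all-zero path lengths keep their
    current rooting.
    """
    tree = stree.tree.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.length is None and edge.head_node is not tree.seed_node:
            edge.length = 1.0
    if outgroup is not None:
        node = None
        for lf in tree.leaf_node_iter():
            if lf.taxon.label == outgroup:
                node = lf
                break
        if node is None:
            raise ValueError(f"outgroup {outgroup!r} not found in tree")
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
    elif len(tree.seed_node.child_nodes()) != 2:
        try:
            tree.reroot_at_midpoint(update_bipartitions=False)
        except Exception:
            pass  # zero-length degenerate tree: keep current rooting
    return tree


def assign_family(
    stree: SupportTree,
    query_id: str,
    threshold: float = 50.0,
    outgroup: Optional[str] = None,
) -> FamilyAssignment:
    """Assign one query leaf to a reference family by the monophyly rule.

    Walking rootward from the query in the rooted tree, the smallest clade
    containing at least one reference decides the family, provided its
    references all belong to one family.  The walk then continues through
    every nested clade that stays family-pure, and the best-supported clade
    of that chain backs the assignment: status ``assigned`` when the
    smallest clade pairs the query with a single reference and the support
    strictly exceeds ``threshold``; ``n/m`` when the query groups only with
    a multi-member family clade (no single-reference pairing), support
    above threshold; ``n/m*`` when no clade of the chain exceeds the
    threshold.  A mixed-family smallest clade, or no reference-containing
    clade below the root, yields ``orphan``.
    """
    if not stree.ref_family:
        raise ValueError("tree has no reference leaves with family tags")
    if query_id not in stree.leaf_labels:
        raise ValueError(f"query {query_id!r} not found in tree")

    tree = _rooted_working_tree(stree, outgroup=outgroup)
    qnode = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == query_id:
            qnode = lf
            break
    refs = set(stree.ref_family)

    chain = []  # nested family-pure clades: (refs_in_clade, support)
    fam = None
    node = qnode.parent_node
    while node is not None and node.parent_node is not None:
        clade = _leafset(node)
        refs_in = clade & refs
        if refs_in:
            families = {stree.ref_family[x] for x in refs_in}
            if len(families) > 1:
                break
            fam = families.pop()
            sup = stree.clade_support(clade)
            if sup is None:
                sup = 100.0  # unannotated clade: single-tree convention
            chain.append((refs_in, sup))
        node = node.parent_node
    if not chain:
        return FamilyAssignment(query_id, "orphan", "orphan", None)
    best_support = max(sup for _, sup in chain)
    single_pairing = len(chain[0][0]) == 1
    if best_support > threshold:
        status = "assigned" if single_pairing else "n/m"
    else:
        status = "n/m*"
    return FamilyAssignment(query_id, fam, status, best_support)


def assign_all(
    stree: SupportTree,
    threshold: float = 50.0,
    outgroup: Optional[str] = None,
) -> List[FamilyAssignment]:
    """Assign every query (non-reference) leaf; ordered by label."""
    return [
        assign_family(stree, q, threshold=threshold, outgroup=outgroup)
        for q in sorted(stree.query_labels())
    ]
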