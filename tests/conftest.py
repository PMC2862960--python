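import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec():
    from bhlhkit.motif import bhlh_motif

    return bhlh_motif()


# ---------------------------------------------------------------------------
# independent brute-force oracles (enumeration, no shared code with the
# implementations they check)


def oracle_template_scan(seq, spec):
    """Per-offset best match by exhaustive enumeration of every concrete
    spacer-length template (72 for the bHLH motif).

    Returns a list over start offsets: ``(n_mismatch, total_spacer,
    spacer_vector)`` or ``None`` where no template fits.
    """
    seq = seq.upper()
    L = len(seq)
    constrained = [e for e in spec.elements if e.kind == "constrained"]
    prof = np.array(
        [[c in e.allowed for e in constrained] for c in seq], dtype=bool
    ).reshape(L, len(constrained))
    ranges = [
        range(e.min_len, e.max_len + 1)
        for e in spec.elements
        if e.kind == "wildcard"
    ]
    combos = sorted(itertools.product(*ranges), key=lambda c: (sum(c), c))
    best = [None] * L
    for combo in combos:
        offs = []
        off = 0
        w = 0
        for e in spec.elements:
            if e.kind == "constrained":
                offs.append(off)
                off += 1
            else:
                off += combo[w]
                w += 1
        span = off
        npos = L - span + 1
        if npos <= 0:
            continue
        mm = np.zeros(npos, dtype=int)
        for j, o in enumerate(offs):
            mm += ~prof[o:o + npos, j]
        tot = sum(combo)
        for p in range(npos):
            key = (int(mm[p]), tot, combo)
            if best[p] is None or key < best[p]:
                best[p] = key
    return best


def oracle_hypergeom_upper(k, K, n, N):
    """P(X >= k) as an exact rational sum of binomial counts."""
    from math import comb

    num = sum(comb(K, i) * comb(N - K, n - i)
              for i in range(k, min(n, K) + 1))
    return num / comb(N, n)


def random_additive_tree(n_taxa, rng):
    """Random binary topology with random branch lengths; returns
    (newick string without supports, labels, additive distance matrix)."""
    labels = [f"T{i:02d}" for i in range(n_taxa)]
    D = np.zeros((n_taxa, n_taxa))
    idx = {l: i for i, l in enumerate(labels)}
    frag = {i: labels[i] for i in range(n_taxa)}
    # pend[c]: leaf -> distance from leaf up to cluster c's root
    pend = {i: {labels[i]: 0.0} for i in range(n_taxa)}
    alive = list(range(n_taxa))
    while len(alive) > 1:
        i, j = sorted(rng.choice(len(alive), size=2, replace=False))
        a, b = alive[i], alive[j]
        la = float(rng.uniform(0.1, 1.0))
        lb = float(rng.uniform(0.1, 1.0))
        for x, dx in pend[a].items():
            for y, dy in pend[b].items():
                d = dx + la + lb + dy
                D[idx[x], idx[y]] = D[idx[y], idx[x]] = d
        new_pend = {}
        for x, dx in pend[a].items():
            new_pend[x] = dx + la
        for y, dy in pend[b].items():
            new_pend[y] = dy + lb
        newid = max(pend) + 1
        pend[newid] = new_pend
        frag[newid] = f"({frag[a]}:{la},{frag[b]}:{lb})"
        alive = [z for z in alive if z not in (a, b)] + [newid]
    newick = frag[alive[0]] + ";"
    return newick, labels, D


def newick_splits(newick, labels):
    """Nontrivial bipartitions of a newick string, as canonical frozensets
    (side not containing the first label)."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick",
                          suppress_internal_node_taxa=True)
    allset = frozenset(labels)
    anchor = sorted(labels)[0]
    out = set()
    for nd in t.preorder_node_iter():
        if nd is t.seed_node or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if 1 < len(side) < len(labels) - 1:
            out.add(side if anchor not in side else allset - side)
    return out


def support_tree_splits(stree):
    """Canonical nontrivial bipartition set of a SupportTree."""
    from bhlhkit.phylo import _internal_splits

    labels = stree.leaf_labels
    allset = frozenset(labels)
    anchor = sorted(labels)[0]
    return {
        s if anchor not in s else allset - s
        for s in _internal_splits(stree.tree)
    }
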