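"""Seeded generators for every input the pipeline consumes.

Three worlds are generated, each with an exact ground-truth manifest:

* proteomes with planted bHLH domains at controlled mismatch counts and
  spacer lengths inside i.i.d. background flanks;
* family-structured reference domain panels (per-family ancestors diverged
  from a shared root, members and queries mutated within the family) for the
  tree-based assignment stage;
* gene -> GO-term annotation maps with one term planted at a controlled
  enrichment factor in a study set.

Residue choices are constructed so that ground truth is *exactly*
recoverable: wildcard (spacer) positions and mismatch substitutions are
drawn from the "neutral" residues that belong to no conserved-site class,
so no alternative spacer assignment can score better than the planted one;
within the reference panel, mutations at conserved sites stay inside the
site's residue class (real bHLH families diverge around, not at, the
conserved sites), so every planted domain remains a zero-mismatch motif
instance.

All generators derive their RNG from ``numpy.random.default_rng([seed, c])``
where ``c`` is a fixed per-generator component id, so the same seed gives
byte-identical outputs and the generators do not perturb each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .motif import (
    MotifSpec,
    STANDARD_AA,
    best_match_at,
    bhlh_motif,
)

# per-generator RNG component ids (stream separation under one seed)
_STREAM_DOMAIN = 0
_STREAM_PROTEOME = 1
_STREAM_PANEL = 2
_STREAM_GO = 3


def neutral_residues(spec: MotifSpec) -> Tuple[str, ...]:
    """Standard residues outside every conserved-site class of ``spec``."""
    used = set()
    for e in spec.elements:
        if e.kind == "constrained":
            used |= set(e.allowed)
    return tuple(sorted(STANDARD_AA - used))


# ---------------------------------------------------------------------------
# planted domains


@dataclass(frozen=True)
class DomainPlant:
    domain: str
    spacer_lengths: Tuple[int, ...]
    n_mismatch: int
    mismatch_positions: Tuple[int, ...]  # indices among the 19 conserved sites


def sample_domain(
    spec: Optional[MotifSpec] = None,
    n_mismatch: int = 0,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> DomainPlant:
    """Draw one motif instance with exactly ``n_mismatch`` mismatches.

    Spacer lengths are uniform within their bounds; conserved sites are
    filled uniformly from their allowed sets, then ``n_mismatch`` distinct
    sites are substituted with neutral residues (outside every class).
    The draw is rejected and repeated if re-scoring with
    :func:`~bhlhkit.motif.best_match_at` does not report exactly
    ``n_mismatch`` (an alternative spacer assignment scored better) —
    extremely rare by construction, but checked so the manifest is exact.
    """
    spec = spec or bhlh_motif()
    if not 0 <= n_mismatch <= spec.n_constrained:
        raise ValueError(
            f"n_mismatch must be in [0, {spec.n_constrained}], got {n_mismatch}"
        )
    rng = rng if rng is not None else np.random.default_rng([seed, _STREAM_DOMAIN])
    neutral = neutral_residues(spec)
    for _ in range(50):
        parts: List[str] = []
        spacers: List[int] = []
        site_pos: List[int] = []  # index into domain string per conserved site
        off = 0
        for e in spec.elements:
            if e.kind == "constrained":
                parts.append(rng.choice(sorted(e.allowed)))
                site_pos.append(off)
                off += 1
            else:
                run = int(rng.integers(e.min_len, e.max_len + 1))
                spacers.append(run)
                parts.append("".join(rng.choice(neutral, size=run)))
                off += run
        chars = list("".join(parts))
        mm_sites = tuple(
            sorted(rng.choice(spec.n_constrained, size=n_mismatch, replace=False))
        )
        for s in mm_sites:
            chars[site_pos[s]] = rng.choice(neutral)
        domain = "".join(chars)
        check = best_match_at(domain, 0, spec)
        if check is not None and check.n_mismatch == n_mismatch:
            return DomainPlant(domain, tuple(spacers), n_mismatch, mm_sites)
    raise RuntimeError("could not realise the requested mismatch count")


# ---------------------------------------------------------------------------
# proteomes


def make_proteome(
    n_seqs: int = 50,
    carrier_fraction: float = 0.4,
    mismatch_counts: Sequence[int] = tuple(range(10)),
    flank_len: Tuple[int, int] = (80, 120),
    background_freqs: Optional[Dict[str, float]] = None,
    seed: int = 0,
    spec: Optional[MotifSpec] = None,
    planted_domains: Optional[Dict[str, str]] = None,
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Synthesise a proteome with planted domains and a ground-truth manifest.

    Carriers hold one planted domain at a recorded offset inside i.i.d.
    background flanks; non-carriers are pure background of comparable
    length.  ``planted_domains`` (id -> domain string) overrides random
    planting: those ids become the carriers and ``n_seqs`` counts the
    additional background sequences.

    Returns ``(seqs, manifest)``; the manifest has one row per sequence with
    columns seq_id, carrier, start, end, n_mismatch, spacer_lengths.
    """
    if not 0.0 <= carrier_fraction <= 1.0:
        raise ValueError("carrier_fraction must be in [0, 1]")
    spec = spec or bhlh_motif()
    rng = np.random.default_rng([seed, _STREAM_PROTEOME])
    alphabet = sorted(STANDARD_AA)
    if background_freqs is None:
        probs = np.full(len(alphabet), 1.0 / len(alphabet))
    else:
        probs = np.array([background_freqs.get(a, 0.0) for a in alphabet])
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("background_freqs must sum to 1")

    def background(length: int) -> str:
        return "".join(rng.choice(alphabet, size=length, p=probs))

    lo, hi = flank_len
    rows = []
    seqs: Dict[str, str] = {}

    if planted_domains is not None:
        carriers = list(planted_domains.items())
        n_background = n_seqs
    else:
        n_carriers = int(round(carrier_fraction * n_seqs))
        mm = rng.choice(list(mismatch_counts), size=n_carriers)
        carriers = []
        for i in range(n_carriers):
            plant = sample_domain(spec, int(mm[i]), rng=rng)
            carriers.append((f"seq{i:04d}", plant.domain))
        n_background = n_seqs - n_carriers

    for sid, domain in carriers:
        left = background(int(rng.integers(lo, hi + 1)))
        right = background(int(rng.integers(lo, hi + 1)))
        seqs[sid] = left + domain + right
        check = best_match_at(seqs[sid], len(left), spec)
        rows.append(
            {
                "seq_id": sid,
                "carrier": True,
                "start": len(left),
                "end": len(left) + len(domain),
                "n_mismatch": check.n_mismatch,
                "spacer_lengths": ",".join(map(str, check.spacer_lengths)),
            }
        )
    offset = len(carriers) if planted_domains is None else 0
    for i in range(n_background):
        sid = f"seq{offset + i:04d}" if planted_domains is None else f"bg{i:04d}"
        length = int(rng.integers(lo, hi + 1)) + int(rng.integers(lo, hi + 1)) + (
            (spec.min_span + spec.max_span) // 2
        )
        seqs[sid] = background(length)
        rows.append(
            {
                "seq_id": sid,
                "carrier": False,
                "start": -1,
                "end": -1,
                "n_mismatch": -1,
                "spacer_lengths": "",
            }
        )
    manifest = pd.DataFrame(rows)
    return seqs, manifest


# ---------------------------------------------------------------------------
# reference panels


@dataclass
class FamilyTruth:
    ancestors: Dict[str, str]  # family -> ancestral domain
    member_family: Dict[str, str]  # reference leaf -> family
    query_family: Dict[str, str]  # query leaf -> true family
    mutation_counts: Dict[str, int]  # leaf -> substitutions from its ancestor
    spacer_lengths: Tuple[int, ...]


def _domain_layout(spec: MotifSpec, spacers: Sequence[int]):
    """Per-position annotation of a domain with the given spacer vector:
    list of (kind, allowed-or-None) per residue."""
    layout = []
    w = 0
    for e in spec.elements:
        if e.kind == "constrained":
            layout.append(("constrained", e.allowed))
        else:
            layout.extend([("wildcard", None)] * spacers[w])
            w += 1
    return layout


def _mutate(
    domain: str,
    layout,
    rate: float,
    rng: np.random.Generator,
    neutral: Tuple[str, ...],
) -> Tuple[str, int]:
    """Substitute each position with probability ``rate``.

    Conserved sites mutate within their residue class (single-residue sites
    are immutable); wildcard positions mutate within the neutral residue
    set.  Returns (mutated string, substitution count).
    """
    chars = list(domain)
    n_sub = 0
    for i, (kind, allowed) in enumerate(layout):
        if rng.random() >= rate:
            continue
        if kind == "constrained":
            options = sorted(set(allowed) - {chars[i]})
        else:
            options = sorted(set(neutral) - {chars[i]})
        if not options:
            continue
        chars[i] = rng.choice(options)
        n_sub += 1
    return "".join(chars), n_sub


def make_reference_panel(
    n_families: int = 8,
    members_per_family: int = 3,
    within_divergence: float = 0.05,
    between_divergence: float = 0.30,
    n_queries: int = 10,
    seed: int = 0,
    spec: Optional[MotifSpec] = None,
) -> Tuple[List[Tuple[str, str]], FamilyTruth]:
    """Family-structured reference domains plus queries of known family.

    One shared root domain (a clean motif instance with a single spacer
    vector) is diverged per family at ``between_divergence`` per position;
    members and queries then mutate their family ancestor at
    ``within_divergence`` per position.  All domains share the spacer
    vector, so the returned rows are already a rectangular motif-anchored
    alignment.  Recovery guarantees assume
    ``within_divergence < between_divergence``.
    """
    for name, val in (("within_divergence", within_divergence),
                      ("between_divergence", between_divergence)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    spec = spec or bhlh_motif()
    rng = np.random.default_rng([seed, _STREAM_PANEL])
    neutral = neutral_residues(spec)
    root = sample_domain(spec, 0, rng=rng)
    layout = _domain_layout(spec, root.spacer_lengths)

    ancestors: Dict[str, str] = {}
    member_family: Dict[str, str] = {}
    query_family: Dict[str, str] = {}
    mut_counts: Dict[str, int] = {}
    rows: List[Tuple[str, str]] = []

    fams = [f"FAM{i + 1}" for i in range(n_families)]
    for fam in fams:
        anc, _ = _mutate(root.domain, layout, between_divergence, rng, neutral)
        ancestors[fam] = anc
        for j in range(members_per_family):
            label = f"{fam}_M{j + 1}"
            dom, nsub = _mutate(anc, layout, within_divergence, rng, neutral)
            member_family[label] = fam
            mut_counts[label] = nsub
            rows.append((label, dom))
    for k in range(n_queries):
        fam = fams[int(rng.integers(0, n_families))]
        label = f"QUERY{k + 1}"
        dom, nsub = _mutate(ancestors[fam], layout, within_divergence, rng, neutral)
        query_family[label] = fam
        mut_counts[label] = nsub
        rows.append((label, dom))

    truth = FamilyTruth(
        ancestors=ancestors,
        member_family=member_family,
        query_family=query_family,
        mutation_counts=mut_counts,
        spacer_lengths=root.spacer_lengths,
    )
    return rows, truth


# ---------------------------------------------------------------------------
# GO worlds


@dataclass
class GoTruth:
    planted_term: str
    k: int
    K: int
    n: int
    N: int
    enrichment_factor: float


def make_go_world(
    n_genes: int = 400,
    n_terms: int = 50,
    terms_per_gene: int = 4,
    planted_term: str = "GO:9999999",
    study_size: int = 20,
    enrichment_factor: float = 10.0,
    background_frequency: float = 0.05,
    seed: int = 0,
):
    """Annotation map with one term planted at a controlled enrichment.

    Background terms are assigned uniformly (``terms_per_gene`` distinct
    draws per gene); the planted term is carried with probability
    ``background_frequency`` outside the study set and
    ``enrichment_factor x background_frequency`` (capped at 1) inside it.
    Returns ``(AnnotationMap, study gene list, GoTruth)`` with the realised
    contingency counts.
    """
    from .enrichment import AnnotationMap

    if study_size > n_genes:
        raise ValueError("study_size cannot exceed n_genes")
    if not 0.0 <= background_frequency <= 1.0:
        raise ValueError("background_frequency must be in [0, 1]")
    if enrichment_factor < 0:
        raise ValueError("enrichment_factor must be nonnegative")
    rng = np.random.default_rng([seed, _STREAM_GO])
    genes = [f"g{i:05d}" for i in range(n_genes)]
    pool = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    if planted_term in pool:
        raise ValueError("planted_term collides with the background term pool")
    study = sorted(rng.choice(genes, size=study_size, replace=False))
    study_set = set(study)
    p_in = min(1.0, enrichment_factor * background_frequency)

    gene_terms: Dict[str, frozenset] = {}
    k = K = 0
    for g in genes:
        terms = set(rng.choice(pool, size=min(terms_per_gene, n_terms),
                               replace=False))
        p = p_in if g in study_set else background_frequency
        if rng.random() < p:
            terms.add(planted_term)
            K += 1
            if g in study_set:
                k += 1
        gene_terms[g] = frozenset(terms)

    annot = AnnotationMap(
        gene_terms=gene_terms,
        term_namespace={t: "biological_process" for t in pool + [planted_term]},
    )
    truth = GoTruth(
        planted_term=planted_term,
        k=k,
        K=K,
        n=study_size,
        N=n_genes,
        enrichment_factor=enrichment_factor,
    )
    return annot, study, truth


# ---------------------------------------------------------------------------
# coupled end-to-end dataset


def make_pipeline_dataset(
    seed: int = 0,
    n_families: int = 8,
    members_per_family: int = 3,
    n_queries: int = 10,
    within_divergence: float = 0.0,
    between_divergence: float = 0.30,
    n_background: int = 20,
    flank_len: Tuple[int, int] = (80, 120),
    spec: Optional[MotifSpec] = None,
):
    """Reference panel plus a proteome whose carriers embed the panel's
    query domains — the full survey exercise on one synthetic world.

    Returns a dict with keys ``seqs``, ``manifest``, ``ref_alignment``,
    ``ref_family``, ``ref_group``, ``truth``, ``scheme`` (family -> group
    tags cycling A-F, so catalog summaries have well-formed groups).
    """
    spec = spec or bhlh_motif()
    rows, truth = make_reference_panel(
        n_families=n_families,
        members_per_family=members_per_family,
        within_divergence=within_divergence,
        between_divergence=between_divergence,
        n_queries=n_queries,
        seed=seed,
        spec=spec,
    )
    ref_rows = [(l, s) for l, s in rows if l in truth.member_family]
    query_domains = {l: s for l, s in rows if l in truth.query_family}
    seqs, manifest = make_proteome(
        n_seqs=n_background,
        seed=seed,
        spec=spec,
        planted_domains=query_domains,
        flank_len=flank_len,
    )
    groups = "ABCDEF"
    scheme = {
        fam: groups[i % len(groups)] for i, fam in enumerate(truth.ancestors)
    }
    return {
        "seqs": seqs,
        "manifest": manifest,
        "ref_alignment": ref_rows,
        "ref_family": dict(truth.member_family),
        "ref_group": {m: scheme[f] for m, f in truth.member_family.items()},
        "truth": truth,
        "scheme": scheme,
    }
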