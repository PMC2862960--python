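"""Degenerate bHLH motif compilation and proteome scanning.

The basic helix-loop-helix (bHLH) domain is recognised here with the classic
predictive consensus derived from large alignments of known bHLH proteins: 19
conserved sites (each constrained to a small residue class or a single
residue) interleaved with wildcard runs, two of which have variable length
(the basic-region spacer, 3-6 residues, and the loop, 5-22 residues).  A
candidate domain is a window whose best assignment of spacer lengths leaves at
least 10 of the 19 conserved sites matching (equivalently at most 9
mismatches).

Residue-class symbols follow the standard notation:

    ``+`` = {K, R}; ``α`` = {I, L, V}; ``Φ`` = {F, I, L}; ``σ`` = {I, V, T};
    uppercase letters are literal residues; ``X``/``X(i)``/``X(i-j)`` are
    wildcard runs.

``σ`` and ``δ`` are treated as synonyms for {I, V, T} (the class is commonly
written either way).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: residue classes of the predictive motif
RESIDUE_CLASSES = {
    "+": frozenset("KR"),
    "α": frozenset("ILV"),
    "Φ": frozenset("FIL"),
    "σ": frozenset("IVT"),
    "δ": frozenset("IVT"),
}

#: the built-in 19-site bHLH predictive motif (44-64 residue span)
BHLH_MOTIF = "++X(3-6)E+XRX(3)αNX(2)ΦX(2)L+X(5-22)+X(2)KX(2)σLX(2)AσXYαX(2)L"

#: default candidate rule: at least 10 of the 19 conserved sites must match
DEFAULT_MIN_CONSERVED = 10
#: default reporting cut-off (9 mismatches can still be a genuine bHLH)
DEFAULT_MAX_MISMATCH = 9


class MotifParseError(ValueError):
    """Raised when a motif formula string cannot be compiled."""


@dataclass(frozen=True)
class MotifElement:
    """One element of a compiled motif.

    ``kind`` is ``"constrained"`` (length exactly 1, residue drawn from
    ``allowed``) or ``"wildcard"`` (``min_len``..``max_len`` arbitrary
    residues, ``allowed`` is ``None``).
    """

    kind: str
    allowed: Optional[frozenset] = None
    min_len: int = 1
    max_len: int = 1
    symbol: str = field(default="", compare=False)  # cosmetic only

    def __post_init__(self):
        if self.kind == "constrained":
            if not self.allowed or not set(self.allowed) <= STANDARD_AA:
                raise MotifParseError(
                    f"constrained element {self.symbol!r} must draw from the "
                    "20 standard amino acids"
                )
            if (self.min_len, self.max_len) != (1, 1):
                raise MotifParseError("constrained elements have length 1")
        elif self.kind == "wildcard":
            if not (1 <= self.min_len <= self.max_len):
                raise MotifParseError(
                    f"wildcard element {self.symbol!r}: need "
                    f"1 <= min_len <= max_len, got ({self.min_len}, {self.max_len})"
                )
        else:
            raise MotifParseError(f"unknown element kind {self.kind!r}")


@dataclass(frozen=True)
class MotifSpec:
    """A compiled motif: ordered elements plus derived size bounds."""

    elements: tuple
    n_constrained: int
    min_span: int
    max_span: int

    @classmethod
    def from_elements(cls, elements: Sequence[MotifElement]) -> "MotifSpec":
        elements = tuple(elements)
        n_constrained = sum(1 for e in elements if e.kind == "constrained")
        min_span = sum(e.min_len for e in elements)
        max_span = sum(e.max_len for e in elements)
        return cls(elements, n_constrained, min_span, max_span)

    @property
    def wildcard_elements(self) -> tuple:
        return tuple(e for e in self.elements if e.kind == "wildcard")

    @property
    def n_wildcards(self) -> int:
        return len(self.wildcard_elements)


@dataclass(frozen=True)
class MotifMatch:
    """A located domain hit.

    Coordinates are 0-based half-open on the protein sequence.
    ``spacer_lengths`` gives the chosen length of each wildcard run in motif
    order; ``constrained_calls`` holds, per conserved site, the observed
    residue and whether it matched its allowed set.
    """

    seq_id: str
    start: int
    end: int
    spacer_lengths: tuple
    constrained_calls: tuple  # of (residue, matched: bool)
    n_mismatch: int
    n_conserved: int
    is_candidate: bool
    domain_seq: str


_WILDCARD_RE = re.compile(r"X(?:\((\d+)(?:\s*[-–]\s*(\d+))?\))?")


def parse_motif(spec_text: str) -> MotifSpec:
    """Compile a motif formula string into a :class:`MotifSpec`.

    The grammar accepts residue-class symbols (``+``, ``α``, ``Φ``, ``σ``,
    ``δ``), literal uppercase residues, and wildcard runs ``X``, ``X(i)`` and
    ``X(i-j)`` (hyphen or en-dash).  Whitespace is ignored.
    """
    text = "".join(spec_text.split())
    elements = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "X":
            m = _WILDCARD_RE.match(text, i)
            lo_s, hi_s = m.group(1), m.group(2)
            if lo_s is None:
                lo = hi = 1
            elif hi_s is None:
                lo = hi = int(lo_s)
            else:
                lo, hi = int(lo_s), int(hi_s)
            if lo > hi or lo < 1:
                raise MotifParseError(
                    f"bad wildcard range in token {m.group(0)!r}: "
                    f"need 1 <= i <= j"
                )
            elements.append(
                MotifElement("wildcard", None, lo, hi, symbol=m.group(0))
            )
            i = m.end()
        elif ch in RESIDUE_CLASSES:
            elements.append(
                MotifElement("constrained", RESIDUE_CLASSES[ch], symbol=ch)
            )
            i += 1
        elif ch in STANDARD_AA:
            elements.append(
                MotifElement("constrained", frozenset(ch), symbol=ch)
            )
            i += 1
        else:
            raise MotifParseError(f"unrecognised motif token {ch!r} at column {i}")
    if not elements:
        raise MotifParseError("empty motif formula")
    return MotifSpec.from_elements(elements)


def bhlh_motif() -> MotifSpec:
    """The built-in compiled bHLH predictive motif (19 conserved sites)."""
    return parse_motif(BHLH_MOTIF)


def match_profile(seq: str, spec: MotifSpec) -> np.ndarray:
    """Boolean table ``profile[i, j]``: does residue ``seq[i]`` satisfy the
    j-th constrained element?  Non-standard characters never match."""
    constrained = [e for e in spec.elements if e.kind == "constrained"]
    seq = seq.upper()
    prof = np.zeros((len(seq), len(constrained)), dtype=bool)
    for j, elem in enumerate(constrained):
        allowed = elem.allowed
        for i, ch in enumerate(seq):
            if ch in allowed:
                prof[i, j] = True
    return prof


def best_match_at(
    seq: str,
    pos: int,
    spec: MotifSpec,
    seq_id: str = "",
    min_conserved: int = DEFAULT_MIN_CONSERVED,
    _profile: Optional[np.ndarray] = None,
) -> Optional[MotifMatch]:
    """Best-scoring match of ``spec`` anchored at offset ``pos``.

    Dynamic programme over (element, consumed residues): among all
    assignments of wildcard spacer lengths, minimise the mismatch count; ties
    are broken by smallest total spacer length, then by lexicographically
    smallest spacer-length vector.  Returns ``None`` when not even the
    shortest realisation fits in the sequence.
    """
    seq = seq.upper()
    L = len(seq)
    if pos < 0 or pos + spec.min_span > L:
        return None
    prof = _profile if _profile is not None else match_profile(seq, spec)
    budget = L - pos  # residues available

    # state: consumed -> (n_mismatch, spacer_vector); DP keeps the best state
    # per consumed count (comparison of (m, vec) is a valid dominance order
    # because total spacer length is a function of `consumed`).
    states = {0: (0, ())}
    j = 0  # constrained-element index
    for elem in spec.elements:
        new: dict = {}
        if elem.kind == "constrained":
            for c, (m, vec) in states.items():
                if c + 1 > budget:
                    continue
                miss = 0 if prof[pos + c, j] else 1
                cand = (m + miss, vec)
                if c + 1 not in new or cand < new[c + 1]:
                    new[c + 1] = cand
            j += 1
        else:
            for c, (m, vec) in states.items():
                for run in range(elem.min_len, elem.max_len + 1):
                    if c + run > budget:
                        break
                    cand = (m, vec + (run,))
                    if c + run not in new or cand < new[c + run]:
                        new[c + run] = cand
        states = new
        if not states:
            return None

    # pick best final state: (n_mismatch, total spacer == consumed, vector)
    consumed, (n_mismatch, vec) = min(
        states.items(), key=lambda kv: (kv[1][0], kv[0], kv[1][1])
    )
    return _build_match(seq, pos, pos + consumed, vec, spec, seq_id, min_conserved)


def _build_match(
    seq: str,
    start: int,
    end: int,
    spacers: tuple,
    spec: MotifSpec,
    seq_id: str,
    min_conserved: int,
) -> MotifMatch:
    """Materialise a MotifMatch from a chosen spacer-length vector."""
    calls = []
    n_mismatch = 0
    off = start
    w = 0
    for elem in spec.elements:
        if elem.kind == "constrained":
            ch = seq[off]
            ok = ch in elem.allowed
            calls.append((ch, ok))
            n_mismatch += not ok
            off += 1
        else:
            off += spacers[w]
            w += 1
    assert off == end
    n_conserved = spec.n_constrained - n_mismatch
    return MotifMatch(
        seq_id=seq_id,
        start=start,
        end=end,
        spacer_lengths=spacers,
        constrained_calls=tuple(calls),
        n_mismatch=n_mismatch,
        n_conserved=n_conserved,
        is_candidate=n_conserved >= min_conserved,
        domain_seq=seq[start:end],
    )


def scan(
    seq: str,
    spec: MotifSpec,
    max_reported_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_conserved: int = DEFAULT_MIN_CONSERVED,
    max_per_seq: Optional[int] = 1,
    seq_id: str = "",
) -> list:
    """Scan one protein for motif matches.

    Every start offset is scored with :func:`best_match_at`; matches with at
    most ``max_reported_mismatch`` mismatches are then greedily retained
    without overlap in increasing (mismatch count, start) order.  By default
    at most one domain is reported per protein (``max_per_seq=None`` lifts
    the cap).  ``is_candidate`` is true when at least ``min_conserved`` of
    the conserved sites match.
    """
    if max_reported_mismatch > spec.n_constrained:
        raise ValueError("max_reported_mismatch exceeds the number of conserved sites")
    seq = seq.upper()
    if len(seq) < spec.min_span:
        return []
    prof = match_profile(seq, spec)
    hits = []
    for pos in range(len(seq) - spec.min_span + 1):
        m = best_match_at(seq, pos, spec, seq_id, min_conserved, _profile=prof)
        if m is not None and m.n_mismatch <= max_reported_mismatch:
            hits.append(m)
    hits.sort(key=lambda m: (m.n_mismatch, m.start))
    kept: list = []
    for m in hits:
        if max_per_seq is not None and len(kept) >= max_per_seq:
            break
        if all(m.end <= k.start or m.start >= k.end for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: m.start)
    return kept


def scan_proteome(
    seqs: dict,
    spec: MotifSpec,
    max_reported_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_conserved: int = DEFAULT_MIN_CONSERVED,
    max_per_seq: Optional[int] = 1,
) -> list:
    """Scan an id->sequence mapping; returns all matches, in input order."""
    out = []
    for sid, s in seqs.items():
        out.extend(
            scan(s, spec, max_reported_mismatch, min_conserved, max_per_seq, sid)
        )
    return out


def anchor_align(matches: Sequence[MotifMatch], spec: MotifSpec) -> list:
    """Motif-anchored multiple alignment of matched domains.

    The 19 constrained positions form aligned columns; each wildcard run is
    right-padded with ``-`` to the run's observed maximum length across the
    input matches.  Returns a list of ``(seq_id, aligned_string)`` pairs in
    input order; the strings are rectangular.
    """
    matches = list(matches)
    if not matches:
        return []
    n_w = spec.n_wildcards
    for m in matches:
        if len(m.spacer_lengths) != n_w:
            raise ValueError(
                f"match on {m.seq_id!r} has {len(m.spacer_lengths)} wildcard "
                f"runs, motif has {n_w}: different motif shapes"
            )
    run_max = [
        max(m.spacer_lengths[w] for m in matches) for w in range(n_w)
    ]
    rows = []
    for m in matches:
        parts = []
        off = 0
        w = 0
        for elem in spec.elements:
            if elem.kind == "constrained":
                parts.append(m.domain_seq[off])
                off += 1
            else:
                run = m.spacer_lengths[w]
                parts.append(m.domain_seq[off:off + run].ljust(run_max[w], "-"))
                off += run
                w += 1
        rows.append((m.seq_id, "".join(parts)))
    return rows
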