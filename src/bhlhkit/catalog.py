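"""Gene-family catalog representation and summary statistics.

A catalog row describes one bHLH gene: its higher-order group (A-F, or
``orphan``), orthologous family, protein accession, closest human homologue,
tree supports from Bayesian-inference and maximum-likelihood analyses (a
percentage, or the markers ``n/m`` / ``n/m*``), and genomic placement (contig
accession and, where known, chromosome).  Two fixtures ship with the package:
the 104-entry chicken catalog and a 45-family x 7-species count matrix used
as the canonical family reference scheme.

Support markers: ``n/m`` — the gene grouped with a multi-member family clade
rather than pairing with a single reference; ``n/m*`` — the clade's support
was below 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

GROUPS = ("A", "B", "C", "D", "E", "F", "orphan")
ORPHAN_FAMILY = "Orphan"
SUPPORT_MARKERS = ("n/m", "n/m*")
_UNKNOWN_KEYS = ("", "none", "unknown", "na", "no clear")

REQUIRED_COLUMNS = (
    "gene_name",
    "group",
    "family",
    "protein_id",
    "human_homologue",
    "bi_support",
    "ml_support",
    "contig",
)


@dataclass(frozen=True)
class CatalogEntry:
    gene_name: str
    group: str
    family: str
    protein_id: str
    human_homologue: Optional[str]
    bi_support: Union[float, str]
    ml_support: Union[float, str]
    contig: str
    chromosome: str = "unknown"

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for {self.gene_name!r}")
        if (self.group == "orphan") != (self.family == ORPHAN_FAMILY):
            raise ValueError(
                f"{self.gene_name!r}: group 'orphan' and family {ORPHAN_FAMILY!r} "
                "must co-occur"
            )
        for val in (self.bi_support, self.ml_support):
            if isinstance(val, str):
                if val not in SUPPORT_MARKERS:
                    raise ValueError(
                        f"{self.gene_name!r}: bad support marker {val!r}"
                    )
            elif not 0 <= val <= 100:
                raise ValueError(f"{self.gene_name!r}: support {val} outside [0, 100]")


def _parse_support(raw: str) -> Union[float, str]:
    raw = str(raw).strip()
    if raw in SUPPORT_MARKERS:
        return raw
    return float(raw)


def load_catalog(path) -> List[CatalogEntry]:
    """Load a catalog TSV; validates groups, supports and unique gene names."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog is missing mandatory columns: {missing}")
    entries: List[CatalogEntry] = []
    seen = set()
    for idx, row in df.iterrows():
        name = row["gene_name"].strip()
        if name in seen:
            raise ValueError(f"duplicate gene_name {name!r} at row {idx + 2}")
        seen.add(name)
        try:
            entries.append(
                CatalogEntry(
                    gene_name=name,
                    group=row["group"].strip(),
                    family=row["family"].strip(),
                    protein_id=row["protein_id"].strip(),
                    human_homologue=row["human_homologue"].strip() or None,
                    bi_support=_parse_support(row["bi_support"]),
                    ml_support=_parse_support(row["ml_support"]),
                    contig=row["contig"].strip(),
                    chromosome=(row.get("chromosome", "unknown") or "unknown").strip(),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {idx + 2}: {exc}") from exc
    return entries


def write_catalog(path, entries: Sequence[CatalogEntry]) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_name": e.gene_name,
                "group": e.group,
                "family": e.family,
                "protein_id": e.protein_id,
                "human_homologue": e.human_homologue or "",
                "bi_support": e.bi_support,
                "ml_support": e.ml_support,
                "contig": e.contig,
                "chromosome": e.chromosome,
            }
            for e in entries
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def group_counts(catalog: Sequence[CatalogEntry]) -> Dict[str, int]:
    """Entries per higher-order group; values sum to the catalog size."""
    counts = {g: 0 for g in GROUPS}
    for e in catalog:
        counts[e.group] += 1
    return counts


def family_summary(
    catalog: Sequence[CatalogEntry], reference_families: Sequence[str]
) -> Tuple[int, List[str], int]:
    """(families present, missing reference families, orphan count).

    A reference family is present when at least one catalog entry carries it;
    the Orphan pseudo-family is excluded from both tallies and counted
    separately.
    """
    present = {e.family for e in catalog if e.family != ORPHAN_FAMILY}
    ref = [f for f in reference_families if f != ORPHAN_FAMILY]
    n_present = sum(1 for f in ref if f in present)
    missing = [f for f in ref if f not in present]
    orphan_count = sum(1 for e in catalog if e.family == ORPHAN_FAMILY)
    return n_present, missing, orphan_count


@dataclass(frozen=True)
class Cluster:
    family: str
    key_value: str
    members: Tuple[str, ...]


def detect_clusters(
    catalog: Sequence[CatalogEntry], key: str = "contig"
) -> List[Cluster]:
    """Same-family genes sharing a contig or chromosome.

    A cluster is two or more entries of one named family with the same key
    value; entries with an unknown key value, and Orphan entries (not a
    family), are skipped.  Output is sorted by (family, key value) and is
    invariant to catalog row order.
    """
    if key not in ("contig", "chromosome"):
        raise ValueError("key must be 'contig' or 'chromosome'")
    buckets: Dict[Tuple[str, str], List[str]] = {}
    for e in catalog:
        if e.family == ORPHAN_FAMILY:
            continue
        val = getattr(e, key)
        if val.strip().lower() in _UNKNOWN_KEYS:
            continue
        buckets.setdefault((e.family, val), []).append(e.gene_name)
    return [
        Cluster(fam, val, tuple(sorted(members)))
        for (fam, val), members in sorted(buckets.items())
        if len(members) >= 2
    ]


# ---------------------------------------------------------------------------
# cross-species count matrix


@dataclass
class FamilyCountMatrix:
    """Per-family, per-species member counts with group tags."""

    counts: pd.DataFrame  # index: family, columns: species, int values
    groups: Dict[str, str]  # family -> group tag

    @property
    def families(self) -> List[str]:
        return list(self.counts.index)

    @property
    def species(self) -> List[str]:
        return list(self.counts.columns)


def load_family_counts(path) -> FamilyCountMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "family" or df.columns[1] != "group":
        raise ValueError("count matrix must start with 'family' and 'group' columns")
    if df["family"].duplicated().any():
        raise ValueError("duplicate family rows in count matrix")
    groups = dict(zip(df["family"], df["group"]))
    counts = df.drop(columns=["group"]).set_index("family").astype(int)
    if (counts < 0).any().any():
        raise ValueError("negative counts in matrix")
    return FamilyCountMatrix(counts=counts, groups=groups)


def species_totals(matrix: FamilyCountMatrix) -> Dict[str, int]:
    """Column sums: total catalog size per species."""
    return {sp: int(matrix.counts[sp].sum()) for sp in matrix.species}


def single_member_families(
    matrix: FamilyCountMatrix, species_subset: Iterable[str]
) -> List[str]:
    """Families (Orphan excluded) with exactly one member in every listed
    species.  An empty subset vacuously returns all families."""
    subset = list(species_subset)
    unknown = [s for s in subset if s not in matrix.species]
    if unknown:
        raise ValueError(f"unknown species: {unknown}")
    out = []
    for fam in matrix.families:
        if fam == ORPHAN_FAMILY:
            continue
        if all(matrix.counts.loc[fam, sp] == 1 for sp in subset):
            out.append(fam)
    return out


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_path(name: str):
    return resources.files("bhlhkit").joinpath("data", name)


def load_packaged_catalog() -> List[CatalogEntry]:
    """The packaged 104-entry chicken bHLH catalog."""
    with resources.as_file(_data_path("table1_catalog.tsv")) as p:
        return load_catalog(p)


def load_packaged_counts() -> FamilyCountMatrix:
    """The packaged 45-family x 7-species count matrix (plus the Orphan row)."""
    with resources.as_file(_data_path("table2_counts.tsv")) as p:
        return load_family_counts(p)


def reference_families() -> List[Tuple[str, str]]:
    """The canonical 45-family reference scheme as (family, group) pairs."""
    m = load_packaged_counts()
    return [(f, m.groups[f]) for f in m.families if f != ORPHAN_FAMILY]


def load_reference_scheme(path) -> List[Tuple[str, str]]:
    """Read a (family, group) reference-scheme TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "family" not in df.columns or "group" not in df.columns:
        raise ValueError("reference scheme needs 'family' and 'group' columns")
    return list(zip(df["family"], df["group"]))


def catalog_from_assignments(
    assignments,
    family_groups: Dict[str, str],
) -> List[CatalogEntry]:
    """Build catalog entries from tree-based family assignments.

    ``family_groups`` maps family name to higher-order group; queries with
    family ``orphan`` become Orphan entries.  Supports are recorded in the
    bi_support column (``n/m``/``n/m*`` statuses keep their marker in the
    support field, mirroring published catalogs).
    """
    entries = []
    for a in assignments:
        if a.status == "orphan":
            group, family, support = "orphan", ORPHAN_FAMILY, "n/m"
        else:
            family = a.family
            if family not in family_groups:
                raise KeyError(f"family {family!r} has no group tag")
            group = family_groups[family]
            if a.status == "assigned":
                support = a.support
            elif a.status == "n/m":
                support = "n/m"
            else:
                support = "n/m*"
        entries.append(
            CatalogEntry(
                gene_name=a.query_id,
                group=group,
                family=family,
                protein_id="synthetic",
                human_homologue=None,
                bi_support=support,
                ml_support=support,
                contig="none",
            )
        )
    return entries
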