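"""Gene-cluster annotation I/O and functional role classification.

A biosynthetic gene cluster is represented as an ordered collection of
:class:`GeneRecord` (one per ORF).  Roles are assigned from the free-text
"proposed function" column through an ordered, first-match-wins keyword rule
table (packaged default in ``data/role_rules.yaml``, user-overridable), since
for a manually curated cluster table that free text is the only ground truth.

The packaged ossamycin fixture transcribes the 27-ORF cluster table of the
*Streptomyces hygroscopicus* var. *ossamyceticus* ossamycin (*oss*) cluster
(127 kbp, accession MH763624).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

__all__ = [
    "GeneRecord",
    "ClusterAnnotation",
    "RoleAssignment",
    "ClusterParseError",
    "ROLE_VOCABULARY",
    "SUGAR_ROLES",
    "load_cluster_table",
    "write_cluster_table",
    "load_role_rules",
    "classify_roles",
    "role_census",
    "roles_report",
    "ossamycin_cluster",
]

#: Closed role vocabulary.
ROLE_VOCABULARY = frozenset(
    {
        "modular-PKS",
        "thioesterase-II",
        "regulator",
        "CCR",
        "FabH-like",
        "cytochrome-P450",
        "spirocyclase-like",
        "sugar-2,3-dehydratase",
        "sugar-3-ketoreductase",
        "sugar-3,4-dehydratase",
        "sugar-epimerase",
        "sugar-transaminase",
        "sugar-N-methyltransferase",
        "glycosyltransferase",
        "transporter",
        "hypothetical",
        "other",
    }
)

#: Roles that constitute the cluster-encoded deoxyaminosugar pathway.
SUGAR_ROLES = (
    "sugar-2,3-dehydratase",
    "sugar-3-ketoreductase",
    "sugar-3,4-dehydratase",
    "sugar-epimerase",
    "sugar-transaminase",
    "sugar-N-methyltransferase",
)


class ClusterParseError(ValueError):
    """Raised when a cluster annotation file cannot be parsed."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated ORF of a gene cluster."""

    gene_id: str  # stable internal id, unique within the cluster
    name: str  # display name, kept verbatim (may be duplicated)
    length_aa: int
    proposed_function: str
    ncbi_hit: Optional[str] = None
    accession: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length_aa <= 0:
            raise ValueError(f"{self.name}: length_aa must be positive, got {self.length_aa}")


@dataclass(frozen=True)
class ClusterAnnotation:
    """Ordered gene-cluster annotation; iteration order == input order."""

    genes: tuple[GeneRecord, ...]
    span_kbp: Optional[float] = None
    source: str = "fixture"

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene_id values must be unique within a cluster")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class RoleAssignment:
    gene_id: str
    role: str
    evidence: str  # rule id that fired, or "fallback:other"

    def __post_init__(self) -> None:
        if self.role not in ROLE_VOCABULARY:
            raise ValueError(f"role {self.role!r} not in the closed vocabulary")


def _snake(name: str) -> str:
    s = re.sub(r"(?<=[a-z0-9])(?=[A-Z])", "_", name)
    s = re.sub(r"[^A-Za-z0-9]+", "_", s)
    return s.strip("_").lower()


def _disambiguation_tag(function: str) -> Optional[str]:
    f = function.lower()
    if "transport" in f:
        return "transport"
    if any(k in f for k in ("hexose", "sugar", "ketoreductase", "epimerase", "dtdp")):
        return "sugar"
    return None


def _assign_ids(rows: Iterable[GeneRecord]) -> tuple[GeneRecord, ...]:
    """Give duplicated display names stable, function-derived internal ids.

    A cluster table may legitimately print the same protein name twice (the
    ossamycin table has two "OssT" entries, a sugar 3-ketoreductase and an ABC
    transporter); display names stay verbatim while ids get a tag such as
    ``oss_t_sugar`` / ``oss_t_transport``.
    """
    rows = list(rows)
    by_name: dict[str, list[int]] = {}
    for i, r in enumerate(rows):
        by_name.setdefault(r.name, []).append(i)
    out = list(rows)
    for name, idxs in by_name.items():
        if len(idxs) == 1:
            continue
        seen: set[str] = set()
        for ordinal, i in enumerate(idxs, start=1):
            tag = _disambiguation_tag(rows[i].proposed_function)
            if tag is None or f"{_snake(name)}_{tag}" in seen:
                tag = str(ordinal)
            gid = f"{_snake(name)}_{tag}"
            seen.add(gid)
            out[i] = replace(rows[i], gene_id=gid)
    return tuple(out)


_TSV_COLUMNS = ["name", "length_aa", "proposed_function", "ncbi_hit", "accession"]


def _load_tsv(path: Path) -> ClusterAnnotation:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ClusterParseError(f"{path}: empty cluster table") from exc
    missing = [c for c in ("name", "length_aa", "proposed_function") if c not in df.columns]
    if missing:
        raise ClusterParseError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ClusterParseError(f"{path}: cluster table has no rows")
    records = []
    for i, row in df.iterrows():
        try:
            length = int(row["length_aa"])
        except (TypeError, ValueError) as exc:
            raise ClusterParseError(
                f"{path}: row {i + 2}: length_aa {row['length_aa']!r} is not an integer"
            ) from exc
        if pd.isna(row["name"]) or pd.isna(row["proposed_function"]):
            raise ClusterParseError(f"{path}: row {i + 2}: name/proposed_function missing")
        records.append(
            GeneRecord(
                gene_id=_snake(str(row["name"])),
                name=str(row["name"]),
                length_aa=length,
                proposed_function=str(row["proposed_function"]),
                ncbi_hit=None if pd.isna(row.get("ncbi_hit")) else str(row["ncbi_hit"]),
                accession=None if pd.isna(row.get("accession")) else str(row["accession"]),
            )
        )
    return ClusterAnnotation(genes=_assign_ids(records), source="tsv")


def _feature_name(feature, index: int) -> str:
    for key in ("gene", "locus_tag", "protein_id", "label"):
        if key in feature.qualifiers:
            return str(feature.qualifiers[key][0])
    return f"cds_{index}"


def _load_genbank(path: Path) -> ClusterAnnotation:
    from Bio import SeqIO

    records = []
    index = 0
    parsed_any = False
    for rec in SeqIO.parse(str(path), "genbank"):
        parsed_any = True
        for feature in rec.features:
            if feature.type != "CDS":
                continue
            index += 1
            quals = feature.qualifiers
            if "translation" in quals:
                length = len(quals["translation"][0])
            else:
                # GenBank locations are 1-based inclusive; len() of the
                # location is already the nucleotide span.
                length = max(1, len(feature.location) // 3 - 1)
            records.append(
                GeneRecord(
                    gene_id=_snake(_feature_name(feature, index)),
                    name=_feature_name(feature, index),
                    length_aa=length,
                    proposed_function=str(quals.get("product", ["unknown"])[0]),
                    ncbi_hit=None,
                    accession=str(quals["protein_id"][0]) if "protein_id" in quals else None,
                )
            )
    if not parsed_any:
        raise ClusterParseError(f"{path}: no GenBank records found")
    if not records:
        raise ClusterParseError(f"{path}: GenBank file contains no CDS features")
    return ClusterAnnotation(genes=_assign_ids(records), source="genbank")


def _load_gff(path: Path) -> ClusterAnnotation:
    import gffutils

    try:
        db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True)
    except Exception as exc:  # gffutils raises assorted types on malformed input
        raise ClusterParseError(f"{path}: cannot parse GFF3 ({exc})") from exc
    records = []
    for i, feat in enumerate(db.features_of_type("CDS", order_by="start"), start=1):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [f"cds_{i}"]))[0]
        product = feat.attributes.get("product", ["unknown"])[0]
        # GFF3 coordinates are 1-based inclusive.
        length = max(1, (feat.end - feat.start + 1) // 3 - 1)
        records.append(
            GeneRecord(
                gene_id=_snake(name),
                name=name,
                length_aa=length,
                proposed_function=product,
                accession=feat.attributes.get("protein_id", [None])[0],
            )
        )
    if not records:
        raise ClusterParseError(f"{path}: GFF3 file contains no CDS features")
    return ClusterAnnotation(genes=_assign_ids(records), source="gff")


def load_cluster_table(path: str | Path, format: str = "tsv") -> ClusterAnnotation:
    """Read a cluster annotation from TSV, GenBank or GFF3.

    Order of genes is preserved from the input (file order for TSV/GenBank,
    coordinate order for GFF3).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    loaders = {"tsv": _load_tsv, "genbank": _load_genbank, "gff": _load_gff}
    if format not in loaders:
        raise ValueError(f"format must be one of {sorted(loaders)}, got {format!r}")
    return loaders[format](path)


def write_cluster_table(cluster: ClusterAnnotation, path: str | Path) -> None:
    """Write TSV that round-trips through :func:`load_cluster_table`."""
    df = pd.DataFrame(
        [
            {
                "name": g.name,
                "length_aa": g.length_aa,
                "proposed_function": g.proposed_function,
                "ncbi_hit": g.ncbi_hit,
                "accession": g.accession,
            }
            for g in cluster.genes
        ],
        columns=_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class _Rule:
    rule_id: str
    role: str
    pattern: re.Pattern


def load_role_rules(path: Optional[str | Path] = None) -> tuple[_Rule, ...]:
    """Load the ordered keyword-rule table (packaged default if no path)."""
    if path is None:
        text = resources.files("pksdecode.data").joinpath("role_rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    rules = []
    for entry in raw["rules"]:
        role = entry["role"]
        if role not in ROLE_VOCABULARY:
            raise ValueError(f"rule {entry['id']!r}: unknown role {role!r}")
        rules.append(_Rule(entry["id"], role, re.compile(entry["pattern"], re.IGNORECASE)))
    return tuple(rules)


def classify_roles(
    cluster: ClusterAnnotation, rules: Optional[tuple[_Rule, ...]] = None
) -> tuple[RoleAssignment, ...]:
    """Assign exactly one role per gene; unmatched functions become "other".

    Total and deterministic: depends only on each gene's proposed_function and
    the rule order, never on gene order.
    """
    if rules is None:
        rules = load_role_rules()
    out = []
    for gene in cluster.genes:
        assigned = None
        for rule in rules:
            if rule.pattern.search(gene.proposed_function):
                assigned = RoleAssignment(gene.gene_id, rule.role, rule.rule_id)
                break
        if assigned is None:
            assigned = RoleAssignment(gene.gene_id, "other", "fallback:other")
        out.append(assigned)
    return tuple(out)


def role_census(assignments: Iterable[RoleAssignment]) -> dict[str, int]:
    census: dict[str, int] = {}
    for a in assignments:
        census[a.role] = census.get(a.role, 0) + 1
    return census


def roles_report(
    cluster: ClusterAnnotation,
    assignments: Iterable[RoleAssignment],
    tsv_path: Optional[str | Path] = None,
    json_path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Tabulate role assignments; optionally write TSV and/or JSON."""
    amap = {a.gene_id: a for a in assignments}
    df = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "name": g.name,
                "length_aa": g.length_aa,
                "proposed_function": g.proposed_function,
                "role": amap[g.gene_id].role,
                "evidence": amap[g.gene_id].evidence,
            }
            for g in cluster.genes
        ]
    )
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(df.to_dict(orient="records"), indent=2))
    return df


def ossamycin_cluster() -> ClusterAnnotation:
    """The packaged 27-ORF ossamycin cluster table fixture."""
    with resources.as_file(
        resources.files("pksdecode.data").joinpath("ossamycin_table1.tsv")
    ) as p:
        cluster = load_cluster_table(p, "tsv")
    return replace(cluster, span_kbp=127.0, source="fixture")
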