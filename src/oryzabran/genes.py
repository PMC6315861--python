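"""Join discriminating metabolites to rice biosynthetic genes.

The gene map is a curated metabolite → gene table in the style of a
PlantCyc/OryzaCyc export: each metabolite carries a *direct* gene count
(genes specifically annotated to its biosynthesis, enumerated as rows with
internal IDs and MSU ``LOC_Os...`` locus names) and a *common* gene count
(genes shared by the generic class pathway, e.g. the ~150 genes common to
standard amino-acid biosynthesis).  Headline totals sum direct genes only;
common counts overlap heavily between metabolites and are carried as
metadata.

For some metabolites the table enumerates only the most-studied genes
(e.g. 5 of glutamate's 91), so the stored ``direct_count`` is authoritative
and the gene rows may be a partial list.  Taurine has no biosynthetic genes
in rice; its records are transporters and carry ``role="transport"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._normalize import resolve_name
from .io import ValidationError
from .scaling import DiscriminatorSet

_COLUMNS = [
    "metabolite",
    "gene_internal_id",
    "locus_name",
    "precursor",
    "pathway",
    "direct_count",
    "common_count",
]


@dataclass(frozen=True)
class GeneLinkRecord:
    """One enumerated metabolite–gene row."""

    metabolite_id: str
    gene_internal_id: str
    locus_name: str
    precursor: str
    biosynthesis_pathway: str
    is_direct: bool = True
    role: str = "biosynthesis"


@dataclass
class GeneMap:
    """Metabolite → biosynthetic-gene map with per-metabolite counts."""

    records: list[GeneLinkRecord] = field(repr=False)
    direct_gene_count: dict[str, int] = field(repr=False)
    common_gene_count: dict[str, int] = field(repr=False)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.direct_gene_count)

    def __len__(self) -> int:
        return len(self.direct_gene_count)

    def __contains__(self, metabolite_id: str) -> bool:
        return resolve_name(metabolite_id) in self.direct_gene_count

    def genes_of(self, metabolite_id: str) -> list[GeneLinkRecord]:
        mid = resolve_name(metabolite_id)
        return [r for r in self.records if r.metabolite_id == mid]


@dataclass
class LinkageReport:
    """Result of joining a discriminator set to a gene map."""

    matched_metabolites: list[str]
    unmatched_metabolites: list[str]
    total_direct_genes: int
    per_class_matched: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_matched": len(self.matched_metabolites),
            "n_unmatched": len(self.unmatched_metabolites),
            "total_direct_genes": self.total_direct_genes,
            "matched_metabolites": self.matched_metabolites,
            "unmatched_metabolites": self.unmatched_metabolites,
            "per_class_matched": self.per_class_matched,
        }


def load_gene_map(path: str | Path, delimiter: str = "\t") -> GeneMap:
    """Read a gene-map TSV.

    Required columns: metabolite, gene_internal_id, locus_name, precursor,
    pathway, direct_count, common_count; optional column ``role``
    (defaults to "biosynthesis").  A metabolite with direct_count = 0 may
    have a single row with empty gene fields (it still counts as mapped).
    Malformed counts raise with the offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"gene map {path} missing columns: {sorted(missing)}")
    if "role" not in df.columns:
        df["role"] = "biosynthesis"

    records: list[GeneLinkRecord] = []
    direct: dict[str, int] = {}
    common: dict[str, int] = {}
    for pos, row in enumerate(df.to_dict(orient="records")):
        line_no = pos + 2  # header is line 1
        mid = resolve_name(row["metabolite"])
        try:
            d = int(row["direct_count"])
            c = int(row["common_count"])
        except ValueError as exc:
            raise ValidationError(f"malformed gene count at line {line_no} of {path}: {exc}")
        if d < 0 or c < 0:
            raise ValidationError(f"negative gene count at line {line_no} of {path}")
        for counts, value, label in ((direct, d, "direct"), (common, c, "common")):
            if mid in counts and counts[mid] != value:
                raise ValidationError(
                    f"inconsistent {label}_count for {mid!r} at line {line_no} of {path}"
                )
            counts[mid] = value
        gid = row["gene_internal_id"].strip()
        locus = row["locus_name"].strip()
        if d > 0 and not gid and locus:
            raise ValidationError(f"direct gene row without internal ID at line {line_no}")
        if gid:
            records.append(
                GeneLinkRecord(
                    metabolite_id=mid,
                    gene_internal_id=gid,
                    locus_name=locus,
                    precursor=row["precursor"],
                    biosynthesis_pathway=row["pathway"],
                    is_direct=True,
                    role=row["role"] or "biosynthesis",
                )
            )
    return GeneMap(records=records, direct_gene_count=direct, common_gene_count=common)


def link(d: DiscriminatorSet, g: GeneMap, cat=None) -> LinkageReport:
    """Match distinct discriminating metabolites against the gene map.

    Matching is by normalized name through the shared synonym table.
    ``total_direct_genes`` sums the authoritative direct counts over matched
    metabolites; bracketed common-gene counts are never included.  Unmatched
    metabolites are reported, not an error.  Passing an
    :class:`~oryzabran.io.AnnotationCatalog` adds a per-class breakdown.
    """
    matched: list[str] = []
    unmatched: list[str] = []
    for mid in sorted(resolve_name(m) for m in d.metabolites):
        (matched if mid in g else unmatched).append(mid)
    total = sum(g.direct_gene_count[m] for m in matched)
    per_class: dict[str, int] = {}
    if cat is not None:
        for m in matched:
            cls = cat.class_of(m)
            per_class[cls] = per_class.get(cls, 0) + 1
    return LinkageReport(
        matched_metabolites=matched,
        unmatched_metabolites=unmatched,
        total_direct_genes=total,
        per_class_matched=per_class,
    )
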