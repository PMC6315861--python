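"""Data model, validation and readers/writers for metabolomics feature tables.

The central objects are:

* :class:`AbundanceMatrix` — a cultivar × metabolite table of relative
  abundances (unitless, ion-intensity derived).  Missing cells mean the
  metabolite was *not detected* in that cultivar; a stored zero is a legal
  detected value and is distinct from missing.
* :class:`AnnotationCatalog` — metabolite → chemical class + a single
  metabolic pathway, with optional KEGG/HMDB/PubChem identifiers.

Files are plain UTF-8 TSV (default) or CSV with a header row.  In abundance
files the first column is the metabolite ID and the remaining columns are
cultivars; empty cells or ``NA`` encode missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._normalize import normalize_name, resolve_name

#: The chemical-class vocabulary used for bran metabolite annotation.
CHEMICAL_CLASSES: frozenset[str] = frozenset(
    {
        "amino acids",
        "carbohydrates",
        "cofactors & vitamins",
        "lipids",
        "nucleotides",
        "peptides",
        "secondary metabolites",
    }
)


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetaboliteAnnotation:
    """One metabolite's catalog entry: class, pathway, external IDs."""

    metabolite_id: str
    chemical_class: str
    pathway: str
    kegg_id: str | None = None
    hmdb_id: str | None = None
    pubchem_id: str | None = None


class AnnotationCatalog:
    """Indexed collection of :class:`MetaboliteAnnotation` records.

    Invariants enforced at construction:

    * metabolite IDs are unique (after name normalization);
    * each metabolite has exactly one non-empty pathway;
    * a pathway label maps to exactly one chemical class;
    * chemical classes come from :data:`CHEMICAL_CLASSES` unless extra
      labels are explicitly allowed.
    """

    def __init__(
        self,
        records: list[MetaboliteAnnotation],
        extra_classes: tuple[str, ...] = (),
    ):
        allowed = CHEMICAL_CLASSES | {c.casefold() for c in extra_classes}
        index: dict[str, MetaboliteAnnotation] = {}
        pathway_class: dict[str, str] = {}
        for rec in records:
            mid = resolve_name(rec.metabolite_id)
            if mid in index:
                raise ValidationError(f"duplicate metabolite in catalog: {rec.metabolite_id!r}")
            cls = normalize_name(rec.chemical_class)
            if cls not in allowed:
                raise ValidationError(
                    f"unknown chemical class {rec.chemical_class!r} for {mid!r}; "
                    f"allowed: {sorted(allowed)}"
                )
            pw = rec.pathway.strip()
            if not pw:
                raise ValidationError(f"empty pathway for metabolite {mid!r}")
            if pw in pathway_class and pathway_class[pw] != cls:
                raise ValidationError(
                    f"pathway {pw!r} assigned to two chemical classes "
                    f"({pathway_class[pw]!r} and {cls!r})"
                )
            pathway_class[pw] = cls
            index[mid] = MetaboliteAnnotation(
                mid, cls, pw, rec.kegg_id, rec.hmdb_id, rec.pubchem_id
            )
        self._index = index

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, metabolite_id: str) -> bool:
        return resolve_name(metabolite_id) in self._index

    def __getitem__(self, metabolite_id: str) -> MetaboliteAnnotation:
        return self._index[resolve_name(metabolite_id)]

    def __iter__(self):
        return iter(self._index.values())

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self._index)

    @property
    def pathways(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self:
            seen.setdefault(rec.pathway)
        return list(seen)

    def class_of(self, metabolite_id: str) -> str:
        return self[metabolite_id].chemical_class

    def pathway_of(self, metabolite_id: str) -> str:
        return self[metabolite_id].pathway

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metabolite_id": r.metabolite_id,
                    "chemical_class": r.chemical_class,
                    "pathway": r.pathway,
                    "kegg_id": r.kegg_id,
                    "hmdb_id": r.hmdb_id,
                    "pubchem_id": r.pubchem_id,
                }
                for r in self
            ]
        )

    def to_json(self, path: str | Path) -> None:
        """Export the catalog as JSON for provenance records."""
        payload = self.to_frame().to_dict(orient="records")
        Path(path).write_text(json.dumps(payload, ensure_ascii=False, indent=1), "utf-8")


def read_catalog(
    path: str | Path,
    delimiter: str | None = None,
    extra_classes: tuple[str, ...] = (),
) -> AnnotationCatalog:
    """Read an annotation catalog from TSV/CSV.

    Required columns: ``metabolite_id``, ``chemical_class``, ``pathway``;
    optional: ``kegg_id``, ``hmdb_id``, ``pubchem_id``.  A metabolite listed
    under two pathways, or a class label outside the seven-class vocabulary
    (unless allowed via ``extra_classes``), raises :class:`ValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str)
    required = {"metabolite_id", "chemical_class", "pathway"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"catalog {path} missing columns: {sorted(missing)}")
    records = [
        MetaboliteAnnotation(
            metabolite_id=row["metabolite_id"],
            chemical_class=row["chemical_class"],
            pathway=row["pathway"],
            kegg_id=row.get("kegg_id") or None,
            hmdb_id=row.get("hmdb_id") or None,
            pubchem_id=row.get("pubchem_id") or None,
        )
        for row in df.fillna("").to_dict(orient="records")
    ]
    return AnnotationCatalog(records, extra_classes=extra_classes)


# ---------------------------------------------------------------------------
# Abundance matrix
# ---------------------------------------------------------------------------


@dataclass
class AbundanceMatrix:
    """Cultivar × metabolite relative abundances with missingness.

    ``values`` is a float DataFrame with metabolites as rows and cultivars
    as columns (the on-disk layout); ``NaN`` encodes "not detected".
    """

    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.values
        df.index.name = "metabolite_id"
        df.columns.name = "cultivar_id"
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate metabolite ID: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate cultivar ID: {dup!r}")
        arr = df.to_numpy(dtype=float)
        neg = np.argwhere(arr < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative abundance at metabolite {df.index[i]!r}, cultivar {df.columns[j]!r}"
            )
        empty = np.isnan(arr).all(axis=1)
        if empty.any():
            mid = df.index[int(np.argmax(empty))]
            raise ValidationError(f"metabolite {mid!r} not detected in any cultivar")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cultivar_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


def read_abundance(path: str | Path, delimiter: str | None = None) -> AbundanceMatrix:
    """Read a cultivar × metabolite abundance table.

    First column = metabolite ID, remaining columns = cultivars, empty cells
    or ``NA`` = not detected.  Input row/column order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_delimiter_for(path, delimiter),
        index_col=0,
        na_values=["", "NA"],
        keep_default_na=False,
        float_precision="round_trip",
    )
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric abundance value in {path}: {exc}") from exc
    return AbundanceMatrix(df)


def write_abundance(
    matrix: AbundanceMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write an abundance table; missing cells become empty fields.

    Values are serialized with ``repr`` so that read→write→read is the
    identity on every representable float.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = matrix.values
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["metabolite_id", *map(str, df.columns)]) + "\n")
        arr = df.to_numpy(dtype=float)
        for mid, row in zip(df.index, arr):
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(sep.join([str(mid), *cells]) + "\n")


def presence_matrix(ab: AbundanceMatrix) -> pd.DataFrame:
    """Binary detection matrix (cultivar × metabolite).

    An entry is True iff the metabolite was detected (value present,
    including zero) in that cultivar.  Column sums over metabolites give the
    per-cultivar detected-metabolite counts used in class-count summaries.
    """
    return ab.values.notna().T
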