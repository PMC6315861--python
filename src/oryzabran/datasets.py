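"""Loaders for the curated data bundled with the package.

Three text fixtures ship with ``oryzabran``:

* ``table1_class_counts.tsv`` — detected-metabolite counts per chemical
  class for the 17-cultivar bran panel;
* ``discriminator_catalog.tsv`` / ``discriminator_entries.tsv`` — the 71
  cultivar-discriminating metabolites (class + pathway) and their 74
  (metabolite, cultivar, direction) calls.  Published Z magnitudes are not
  reproduced, so ``z_value`` is NaN in this set;
* ``gene_map.tsv`` — the curated metabolite → rice biosynthetic gene table
  (34 metabolites; MSU ``LOC_Os...`` loci preserved verbatim).

The raw feature table behind these summaries is not distributed, so the
fixtures carry curated results, not raw data; the synthetic generator in
:mod:`oryzabran.simulate` stands in wherever a full table is needed.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .genes import GeneMap, load_gene_map
from .io import AnnotationCatalog, read_catalog
from .reporting import ClassCountTable
from .scaling import DiscriminatorSet


def _data_path(name: str):
    return resources.files("oryzabran.data").joinpath(name)


def load_class_counts() -> ClassCountTable:
    """The 17-cultivar class-count table, with totals and max/min flags."""
    with resources.as_file(_data_path("table1_class_counts.tsv")) as p:
        counts = pd.read_csv(p, sep="\t", index_col=0)
    return ClassCountTable.from_class_counts(counts)


def class_counts_as_presence() -> tuple[pd.DataFrame, AnnotationCatalog]:
    """Expand the class-count table into an equivalent presence matrix.

    Builds one placeholder metabolite per (class, slot) and marks it
    detected in a cultivar iff that cultivar's class count covers the slot.
    Recomputing class counts from this matrix reproduces the fixture
    exactly, which lets count-based summaries run through the same code
    path as real detection matrices.
    """
    from .io import MetaboliteAnnotation

    with resources.as_file(_data_path("table1_class_counts.tsv")) as p:
        counts = pd.read_csv(p, sep="\t", index_col=0)
    records = []
    cols: dict[str, np.ndarray] = {}
    for cls, row in counts.iterrows():
        for slot in range(int(row.max())):
            mid = f"{cls} placeholder {slot + 1:03d}"
            records.append(MetaboliteAnnotation(mid, str(cls), f"{cls} (pooled)"))
            cols[mid] = (row.to_numpy(dtype=int) > slot)
    presence = pd.DataFrame(cols, index=counts.columns)
    return presence, AnnotationCatalog(records)


def load_discriminator_catalog() -> AnnotationCatalog:
    """Class + pathway annotation for the 71 discriminating metabolites."""
    with resources.as_file(_data_path("discriminator_catalog.tsv")) as p:
        return read_catalog(p)


def load_discriminators() -> DiscriminatorSet:
    """The curated discriminator calls (direction only; Z not published)."""
    with resources.as_file(_data_path("discriminator_entries.tsv")) as p:
        entries = pd.read_csv(p, sep="\t")
    return DiscriminatorSet.from_entries(entries)


def load_gene_map_fixture() -> GeneMap:
    """The curated metabolite → biosynthetic-gene map."""
    with resources.as_file(_data_path("gene_map.tsv")) as p:
        return load_gene_map(p)
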