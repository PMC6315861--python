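"""Summary tables and ordination for cultivar panels.

Covers the standard reporting around the discriminator analysis: per
cultivar × chemical class detection counts (with max/min flags), the mean
lipid share of the metabolome, per-class discriminator breakdowns, and a
PCA-style ordination of the median-scaled table as plumbing for variance
summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from ._normalize import resolve_name
from .io import AnnotationCatalog, ValidationError
from .scaling import DiscriminatorSet, ScaledMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClassCountTable:
    """Detected-metabolite counts per cultivar × chemical class.

    ``counts``: chemical class × cultivar DataFrame.  ``totals``: per
    cultivar.  ``max_cultivars``/``min_cultivars`` flag the argmax/argmin of
    the totals (all tied cultivars flagged).
    """

    counts: pd.DataFrame = field(repr=False)
    totals: pd.Series = field(repr=False)
    max_cultivars: list[str] = field(default_factory=list)
    min_cultivars: list[str] = field(default_factory=list)

    @classmethod
    def from_class_counts(cls, counts: pd.DataFrame) -> "ClassCountTable":
        totals = counts.sum(axis=0)
        return cls(
            counts=counts,
            totals=totals,
            max_cultivars=list(totals.index[totals == totals.max()]),
            min_cultivars=list(totals.index[totals == totals.min()]),
        )


@dataclass
class ClassBreakdown:
    """Distinct discriminating metabolites per chemical class."""

    counts: dict[str, int]
    total: int


@dataclass
class LipidFraction:
    """Mean share of the detected metabolome that is lipids."""

    percent: float  # mean over cultivars of 100 * lipids/total
    headline: int  # percent rounded half-up to an integer
    pooled_percent: float  # 100 * (Σ lipids) / (Σ totals), for reference


@dataclass
class OrdinationSummary:
    """Percent variance per component and scores for the first two."""

    percent_variance: np.ndarray = field(repr=False)
    scores: pd.DataFrame = field(repr=False)  # cultivar × first two components


def class_count_table(presence: pd.DataFrame, cat: AnnotationCatalog) -> ClassCountTable:
    """Count detected annotated metabolites per cultivar and chemical class.

    ``presence`` is the cultivar × metabolite detection matrix.  A detected
    metabolite missing from the catalog is an error naming it.
    """
    classes = []
    for m in presence.columns:
        mid = resolve_name(str(m))
        if mid not in cat:
            raise ValidationError(f"detected metabolite {m!r} has no catalog annotation")
        classes.append(cat.class_of(mid))
    class_index = pd.Index(classes, name="chemical_class")
    counts = (
        presence.T.astype(int).groupby(class_index).sum()
    )  # class × cultivar
    return ClassCountTable.from_class_counts(counts)


def lipid_fraction(table: ClassCountTable) -> LipidFraction:
    """Mean per-cultivar lipid share of the metabolome, as a percent.

    The headline figure is the mean of per-cultivar ratios rounded half-up;
    the pooled ratio (summing counts first) is reported alongside.
    Cultivars with a zero total are excluded with a warning.
    """
    if "lipids" not in table.counts.index:
        raise ValidationError("class-count table has no 'lipids' row")
    lipids = table.counts.loc["lipids"]
    totals = table.totals
    ok = totals > 0
    if not ok.all():
        logger.warning(
            "excluding %d cultivar(s) with zero detected metabolites", int((~ok).sum())
        )
    ratios = 100.0 * lipids[ok] / totals[ok]
    mean_pct = float(ratios.mean())
    pooled = 100.0 * float(lipids[ok].sum()) / float(totals[ok].sum())
    return LipidFraction(
        percent=mean_pct,
        headline=int(math.floor(mean_pct + 0.5)),
        pooled_percent=pooled,
    )


def discriminator_breakdown(d: DiscriminatorSet, cat: AnnotationCatalog) -> ClassBreakdown:
    """Distinct discriminating metabolites per chemical class, plus total."""
    counts: dict[str, int] = {}
    for mid in d.metabolites:
        rid = resolve_name(mid)
        if rid not in cat:
            raise ValidationError(f"discriminator {mid!r} has no catalog annotation")
        cls = cat.class_of(rid)
        counts[cls] = counts.get(cls, 0) + 1
    return ClassBreakdown(counts=counts, total=sum(counts.values()))


def ordination_summary(
    s: ScaledMatrix, n_components: int = 2, unit_variance: bool = False
) -> OrdinationSummary:
    """Principal-component decomposition of the scaled table.

    Cultivars are observations and metabolites variables; columns are
    mean-centered (and optionally scaled to unit variance) before a
    singular value decomposition.  Percent variance per component is the
    squared singular value over the total.  Missing values must be imputed
    first.
    """
    df = s.values
    if df.isna().to_numpy().any():
        raise ValidationError(
            "scaled matrix contains missing values; impute first "
            "(e.g. impute_missing(s, 'min_impute'))"
        )
    X = df.to_numpy(dtype=float).T  # cultivar × metabolite
    if X.shape[0] < 2:
        raise ValidationError("ordination needs at least 2 cultivars")
    if unit_variance:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    scores = pd.DataFrame(
        coords[:, : min(2, n_components)],
        index=df.columns,
        columns=[f"PC{i + 1}" for i in range(min(2, n_components))],
    )
    return OrdinationSummary(
        percent_variance=100.0 * pca.explained_variance_ratio_,
        scores=scores,
    )
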