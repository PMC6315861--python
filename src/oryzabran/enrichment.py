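"""Pathway enrichment score (PES) for discriminating metabolites.

For a pathway within a scope unit (one cultivar, or the whole panel) the
score is the fold enrichment

    PES = (k / m) / (n / N)

where k = discriminating metabolites in the pathway, m = metabolites
identified in the pathway, n = discriminating metabolites in scope, and
N = metabolites identified in scope.  PES > 1 means the pathway holds more
than its share of the discriminating metabolites; PES is a descriptive fold
change with no significance test attached.  A hypergeometric tail
probability is available for context but is never used for selection.

All counts are over *distinct* metabolites; a metabolite flagged in several
cultivars still counts once inside each scope unit.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd
from scipy.stats import hypergeom

from .io import AnnotationCatalog, ValidationError
from .scaling import DiscriminatorSet

GLOBAL_SCOPE = "global"


@dataclass(frozen=True)
class EnrichmentCounts:
    """The 2×2-style counts behind one PES value."""

    k: int
    m: int
    n: int
    N: int

    def __post_init__(self) -> None:
        for name in ("k", "m", "n", "N"):
            v = getattr(self, name)
            if not isinstance(v, numbers.Integral) or isinstance(v, bool):
                raise ValidationError(f"count {name} must be an integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if not (0 <= self.k <= min(self.m, self.n)):
            raise ValidationError(f"require 0 <= k <= min(m, n); got {self}")
        if not (1 <= self.m <= self.N):
            raise ValidationError(f"require 1 <= m <= N; got {self}")
        if not (0 <= self.n <= self.N):
            raise ValidationError(f"require 0 <= n <= N; got {self}")


@dataclass(frozen=True)
class PESRecord:
    """PES for one (scope unit, pathway) pair."""

    cultivar_id: str  # a cultivar name, or "global"
    pathway: str
    counts: EnrichmentCounts
    score: float


def pes_score(counts: EnrichmentCounts) -> float:
    """Fold enrichment (k/m)/(n/N), computed in exact rational arithmetic.

    k = m and n = N gives exactly 1.0; k = 0 gives 0.0.  n = 0 (no
    discriminators in scope) leaves the score undefined and raises.
    """
    if counts.n == 0:
        raise ValidationError("PES undefined: no discriminating metabolites in scope (n = 0)")
    if counts.m == 0:
        raise ValidationError("PES undefined: empty pathway (m = 0)")
    return float(Fraction(counts.k, counts.m) / Fraction(counts.n, counts.N))


def hypergeom_pvalue(counts: EnrichmentCounts) -> float:
    """P(X >= k) for X ~ Hypergeom(N, m, n): an optional context check.

    Provided for modern readers; selection of enriched pathways never uses
    it.
    """
    return float(hypergeom.sf(counts.k - 1, counts.N, counts.m, counts.n))


def _counts_for_unit(
    unit: str,
    disc_metabolites: list[str],
    detected: list[str],
    cat: AnnotationCatalog,
) -> list[PESRecord]:
    for mid in disc_metabolites:
        if mid not in cat:
            raise ValidationError(f"discriminator metabolite {mid!r} absent from catalog")
    annotated = [m for m in detected if m in cat]
    N = len(annotated)
    n = len(disc_metabolites)
    if n == 0 or N == 0:
        return []
    by_pathway: dict[str, list[str]] = {}
    for m in annotated:
        by_pathway.setdefault(cat.pathway_of(m), []).append(m)
    disc_set = set(disc_metabolites)
    records = []
    for pw, members in by_pathway.items():
        k = sum(1 for m in members if m in disc_set)
        if k == 0:
            continue
        counts = EnrichmentCounts(k=k, m=len(members), n=n, N=N)
        records.append(PESRecord(unit, pw, counts, pes_score(counts)))
    return records


def enrich(
    d: DiscriminatorSet,
    cat: AnnotationCatalog,
    presence: pd.DataFrame,
    scope: str = "per_cultivar",
) -> list[PESRecord]:
    """PES records for every (scope unit, pathway) with k >= 1.

    ``presence`` is the cultivar × metabolite detection matrix.  With
    ``scope="per_cultivar"`` each cultivar is its own universe: k and n
    count that cultivar's discriminators, m and N its detected (and
    annotated) metabolites.  With ``scope="global"`` discriminators are
    pooled over cultivars (distinct metabolites) and m, N come from the
    union of detected metabolites.  Pathways with k = 0 are omitted.
    """
    from ._normalize import resolve_name

    pres = presence.copy()
    pres.columns = [resolve_name(str(c)) for c in pres.columns]

    if scope == GLOBAL_SCOPE:
        disc = [resolve_name(m) for m in d.metabolites]
        detected = list(pres.columns[pres.any(axis=0)])
        return _counts_for_unit(GLOBAL_SCOPE, disc, detected, cat)
    if scope == "per_cultivar":
        records = []
        for cv in pres.index:
            disc = [resolve_name(m) for m in d.metabolites_of(cv)]
            if not disc:
                continue
            detected = list(pres.columns[pres.loc[cv].to_numpy(dtype=bool)])
            records.extend(_counts_for_unit(str(cv), disc, detected, cat))
        return records
    raise ValueError(f"unknown scope: {scope!r}")


def select_enriched(records: list[PESRecord], tol: float = 1e-12) -> list[PESRecord]:
    """Records whose score differs from 1 (and k >= 1), sorted descending.

    A PES of exactly 1 means the pathway holds precisely its expected share
    of discriminators and is uninformative either way.
    """
    kept = [r for r in records if r.counts.k >= 1 and abs(r.score - 1.0) > tol]
    return sorted(kept, key=lambda r: (-r.score, r.cultivar_id, r.pathway))


def pes_matrix(records: list[PESRecord]) -> pd.DataFrame:
    """Wide pathway × cultivar PES table (NaN where no record)."""
    if not records:
        return pd.DataFrame()
    long = pes_long(records)
    return long.pivot(index="pathway", columns="cultivar_id", values="score")


def pes_long(records: list[PESRecord]) -> pd.DataFrame:
    """Long-format PES table with the k/m/n/N bookkeeping columns."""
    return pd.DataFrame(
        [
            {
                "cultivar_id": r.cultivar_id,
                "pathway": r.pathway,
                "k": r.counts.k,
                "m": r.counts.m,
                "n": r.counts.n,
                "N": r.counts.N,
                "score": r.score,
            }
            for r in records
        ]
    )
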