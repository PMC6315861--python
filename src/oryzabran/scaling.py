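"""Median scaling, cross-cultivar Z-scores, and discriminator detection.

The comparison procedure is deliberately simple and mirrors common practice
for small-n cultivar panels profiled on a Metabolon-style platform:

1. every metabolite's abundances are divided by that metabolite's median
   across the cultivars in which it was detected (median-scaled relative
   abundance, median = 1 by construction);
2. a Z-score is computed per metabolite and cultivar,
   ``Z = (x − μ) / σ``, with μ and σ taken across cultivars for that same
   metabolite;
3. any (metabolite, cultivar) cell with ``|Z|`` strictly greater than a
   threshold (default 2.0) marks that metabolite as a discriminator of that
   cultivar, with direction "high" (Z > 0) or "low" (Z < 0).

Because μ and σ are estimated in-sample from c cultivars, a single extreme
cell can never exceed ``|Z| = (c − 1)/√c`` under the sample-σ convention
(≈ 3.880 for c = 17), which bounds how far any one cultivar can stand out.

No multiple-testing correction is applied: the Z-score rule is a screening
heuristic, not a calibrated test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, ValidationError

logger = logging.getLogger(__name__)

MIN_CULTIVARS_DEFAULT = 3


@dataclass
class ScaledMatrix:
    """Median-scaled relative abundances (same layout as AbundanceMatrix).

    Per metabolite, the median of present values equals 1; the missingness
    pattern is identical to the input.
    """

    values: pd.DataFrame = field(repr=False)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cultivar_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ZScoreMatrix:
    """Per metabolite × cultivar Z-scores with the row statistics behind them.

    ``z`` rows for constant metabolites (σ = 0) are all zero and listed in
    ``constant_metabolites``; metabolites with too few detected values are
    dropped and listed in ``excluded_metabolites``.
    """

    z: pd.DataFrame = field(repr=False)
    mu: pd.Series = field(repr=False)
    sigma: pd.Series = field(repr=False)
    sigma_convention: str = "sample"
    constant_metabolites: list[str] = field(default_factory=list)
    excluded_metabolites: list[str] = field(default_factory=list)


@dataclass
class DiscriminatorSet:
    """(metabolite, cultivar, Z, direction) entries passing the |Z| rule.

    ``entries`` columns: metabolite_id, cultivar_id, z_value, direction.
    ``z_value`` may be NaN for sets transcribed from published reports where
    only the direction is stated.
    """

    entries: pd.DataFrame = field(repr=False)
    threshold: float = 2.0

    @classmethod
    def from_entries(cls, entries: pd.DataFrame, threshold: float = 2.0) -> "DiscriminatorSet":
        df = entries.copy()
        if "z_value" not in df.columns:
            df["z_value"] = np.nan
        bad = set(df["direction"]) - {"high", "low"}
        if bad:
            raise ValidationError(f"invalid discriminator direction(s): {sorted(bad)}")
        cols = ["metabolite_id", "cultivar_id", "z_value", "direction"]
        return cls(df[cols].reset_index(drop=True), threshold=threshold)

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def metabolites(self) -> list[str]:
        """Distinct discriminating metabolites, in first-appearance order."""
        return list(dict.fromkeys(self.entries["metabolite_id"]))

    def metabolites_of(self, cultivar_id: str) -> list[str]:
        sub = self.entries[self.entries["cultivar_id"] == cultivar_id]
        return list(dict.fromkeys(sub["metabolite_id"]))

    def per_cultivar_counts(self) -> pd.Series:
        return self.entries.groupby("cultivar_id")["metabolite_id"].nunique()

    def to_frame(self) -> pd.DataFrame:
        return self.entries.copy()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def median_scale(ab: AbundanceMatrix | ScaledMatrix) -> ScaledMatrix:
    """Divide each metabolite by its median over detected values.

    Idempotent: scaling an already-scaled matrix changes nothing (the median
    of the scaled row is 1).  A metabolite with no detected values raises
    :class:`~oryzabran.io.ValidationError`.
    """
    df = ab.values
    medians = df.median(axis=1, skipna=True)
    if medians.isna().any():
        mid = medians.index[medians.isna()][0]
        raise ValidationError(f"metabolite {mid!r} has no detected values to scale")
    if (medians == 0).any():
        mid = medians.index[medians == 0][0]
        raise ValidationError(f"metabolite {mid!r} has zero median; cannot median-scale")
    return ScaledMatrix(df.div(medians, axis=0))


def impute_missing(s: ScaledMatrix, policy: str = "skip") -> ScaledMatrix:
    """Handle missing cells before Z-scoring.

    ``min_impute`` fills each metabolite's missing cells with that
    metabolite's minimum detected value (the convention for Metabolon-style
    tables, where non-detection usually means "below this run's limit");
    ``skip`` leaves missing cells alone, so downstream statistics use
    detected cells only.
    """
    if policy == "skip":
        return ScaledMatrix(s.values.copy())
    if policy == "min_impute":
        mins = s.values.min(axis=1, skipna=True)
        return ScaledMatrix(s.values.T.fillna(mins).T)
    raise ValueError(f"unknown missing-value policy: {policy!r}")


def compute_zscores(
    s: ScaledMatrix,
    sigma_convention: str = "sample",
    min_cultivars: int = MIN_CULTIVARS_DEFAULT,
) -> ZScoreMatrix:
    """Cross-cultivar Z-scores on median-scaled abundances.

    μ and σ are computed per metabolite over detected cells.  σ uses the
    sample convention (c − 1 denominator) by default; ``"population"``
    switches to the c denominator.  Metabolites detected in fewer than
    ``min_cultivars`` cultivars are excluded with a logged warning;
    zero-variance metabolites get Z = 0 everywhere and are flagged constant.
    """
    if sigma_convention not in ("sample", "population"):
        raise ValueError(f"unknown sigma convention: {sigma_convention!r}")
    ddof = 1 if sigma_convention == "sample" else 0

    df = s.values
    n_present = df.notna().sum(axis=1)
    excluded = list(df.index[n_present < min_cultivars])
    if excluded:
        logger.warning(
            "excluding %d metabolite(s) detected in fewer than %d cultivars: %s",
            len(excluded),
            min_cultivars,
            ", ".join(map(str, excluded[:5])) + ("..." if len(excluded) > 5 else ""),
        )
        df = df.drop(index=excluded)

    mu = df.mean(axis=1, skipna=True)
    sigma = df.std(axis=1, ddof=ddof, skipna=True)
    constant = list(df.index[sigma == 0])

    z = df.sub(mu, axis=0).div(sigma.replace(0.0, np.nan), axis=0)
    if constant:
        z.loc[constant] = z.loc[constant].where(df.loc[constant].isna(), 0.0)
    return ZScoreMatrix(
        z=z,
        mu=mu,
        sigma=sigma,
        sigma_convention=sigma_convention,
        constant_metabolites=constant,
        excluded_metabolites=excluded,
    )


def find_discriminators(z: ZScoreMatrix, threshold: float = 2.0) -> DiscriminatorSet:
    """Cells with |Z| strictly greater than ``threshold``.

    Direction is "high" for Z > 0 and "low" for Z < 0.  The inequality is
    strict, so raising the threshold can only remove entries.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    zdf = z.z
    mask = zdf.abs() > threshold
    rows = []
    for mid, cid in zip(*np.nonzero(mask.to_numpy())):
        zv = float(zdf.iat[mid, cid])
        rows.append(
            {
                "metabolite_id": zdf.index[mid],
                "cultivar_id": zdf.columns[cid],
                "z_value": zv,
                "direction": "high" if zv > 0 else "low",
            }
        )
    entries = pd.DataFrame(
        rows, columns=["metabolite_id", "cultivar_id", "z_value", "direction"]
    )
    return DiscriminatorSet(entries, threshold=threshold)


def write_discriminator_report(
    d: DiscriminatorSet, cat, path, delimiter: str = "\t"
) -> None:
    """Export discriminators as TSV with class and pathway annotation."""
    df = d.to_frame()
    df.insert(1, "chemical_class", [cat.class_of(m) for m in df["metabolite_id"]])
    df.insert(2, "pathway", [cat.pathway_of(m) for m in df["metabolite_id"]])
    df.to_csv(path, sep=delimiter, index=False)
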