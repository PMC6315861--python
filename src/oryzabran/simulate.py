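"""Synthetic cultivar × metabolite tables with known ground truth.

The generator emulates the statistical shape of a non-targeted, single-run
bran metabolomics feature table for a panel of cultivars:

* per-metabolite log-normal relative abundances — each metabolite has an
  arbitrary intensity scale (removed by median scaling) and multiplicative
  cultivar-to-cultivar noise of width ``sigma_log`` on the log scale;
* per-cell detection dropout (missing = not detected), calibrated by
  default so per-cultivar detected totals land in the high-300s/low-400s
  typical of a ~450-metabolite bran panel;
* a class/pathway catalog: each metabolite belongs to one pathway, each
  pathway to one chemical class, with class proportions matching the
  observed bran metabolome (lipids ≈ 39%);
* planted effects — selected (metabolite, cultivar) cells shifted by a
  chosen number of log-σ units, recorded in a truth table so detection
  sensitivity and false-discovery proportion can be measured.

It does not emulate correlated metabolite blocks, batch structure, or
intensity-dependent missingness; see the methods note for what that implies
about pipeline tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, AnnotationCatalog, MetaboliteAnnotation, ValidationError
from .scaling import DiscriminatorSet

#: Class proportions for generated catalogs: lipids at their observed ~39%
#: share, the rest at their relative shares in a typical bran panel.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "amino acids": 0.276,
    "carbohydrates": 0.124,
    "cofactors & vitamins": 0.064,
    "lipids": 0.390,
    "nucleotides": 0.084,
    "peptides": 0.016,
    "secondary metabolites": 0.046,
}

#: Named pathways available per class for generated catalogs; classes with
#: more allocated pathways than names get numbered placeholders.
_NAMED_PATHWAYS: dict[str, list[str]] = {
    "amino acids": [
        "aromatic amino acids (PEP-derived)",
        "aspartate family (OAA-derived)",
        "glutamate family (α-ketoglutarate-derived)",
        "serine family (phosphoglycerate-derived)",
    ],
    "carbohydrates": ["amino sugar and nucleotide sugar metabolism", "TCA cycle"],
    "cofactors & vitamins": ["tocopherol metabolism"],
    "lipids": [
        "free fatty acid",
        "glycerolipids (diacyl)",
        "glycerolipids (monoacyl)",
        "lyso-phospholipids",
        "oxylipins",
        "phospholipid metabolism",
    ],
    "nucleotides": ["purine metabolism"],
    "peptides": [],
    "secondary metabolites": ["benzenoids"],
}


@dataclass
class SimConfig:
    """Generator settings; defaults are the package's study conditions."""

    n_cultivars: int = 17
    n_metabolites: int = 450
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    n_pathways: int = 53
    sigma_log: float = 0.35
    dropout: float = 0.08
    #: planted effects as (metabolite index, cultivar index, shift in log-σ units)
    planted: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class proportions must sum to 1, got {total}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError("dropout must be in [0, 1)")
        if self.n_pathways > self.n_metabolites:
            raise ValidationError("cannot have more pathways than metabolites")
        if self.sigma_log <= 0:
            raise ValidationError("sigma_log must be positive")
        for mi, ci, _ in self.planted:
            if not (0 <= mi < self.n_metabolites) or not (0 <= ci < self.n_cultivars):
                raise ValidationError(f"planted effect out of range: ({mi}, {ci})")


@dataclass
class TruthTable:
    """Planted (metabolite, cultivar, shift, direction) entries."""

    entries: pd.DataFrame = field(repr=False)

    @property
    def n_planted(self) -> int:
        return len(self.entries)

    def planted_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.entries["metabolite_id"], self.entries["cultivar_id"]))


@dataclass
class RecoveryReport:
    sensitivity: float
    fdp: float
    n_planted: int
    n_reported: int
    direction_accuracy: float


def _allocate_pathways(cfg: SimConfig) -> dict[str, list[str]]:
    """Split n_pathways among classes by largest remainder, >= 1 per class."""
    classes = list(cfg.class_proportions)
    props = np.array([cfg.class_proportions[c] for c in classes])
    ideal = props * cfg.n_pathways
    base = np.maximum(np.floor(ideal).astype(int), 1)
    while base.sum() > cfg.n_pathways:
        base[np.argmax(base)] -= 1
    rem = ideal - base
    for _ in range(cfg.n_pathways - base.sum()):
        i = int(np.argmax(rem))
        base[i] += 1
        rem[i] = -np.inf
    out: dict[str, list[str]] = {}
    for cls, n_pw in zip(classes, base):
        named = _NAMED_PATHWAYS.get(cls, [])
        labels = list(named[:n_pw])
        labels += [f"{cls} pathway {i + 1}" for i in range(len(labels), n_pw)]
        out[cls] = labels
    return out


def generate(cfg: SimConfig) -> tuple[AbundanceMatrix, AnnotationCatalog, TruthTable]:
    """Generate an abundance table, catalog and truth table.

    Deterministic for a fixed ``cfg.seed``.  Abundances are
    ``scale_i * exp(sigma_log * (z + shift))`` with z standard normal and
    shift nonzero only for planted cells; dropout is applied independently
    per cell, but every metabolite keeps at least one detected cultivar.
    """
    rng = np.random.default_rng(cfg.seed)
    metabolites = [f"met_{i + 1:04d}" for i in range(cfg.n_metabolites)]
    cultivars = [f"cultivar_{j + 1:02d}" for j in range(cfg.n_cultivars)]

    # catalog: class per metabolite (multinomial), one pathway per metabolite
    pathways = _allocate_pathways(cfg)
    classes = list(cfg.class_proportions)
    probs = np.array([cfg.class_proportions[c] for c in classes])
    cls_draw = rng.choice(len(classes), size=cfg.n_metabolites, p=probs)
    records = []
    for mid, ci in zip(metabolites, cls_draw):
        cls = classes[ci]
        pw = pathways[cls][int(rng.integers(len(pathways[cls])))]
        records.append(MetaboliteAnnotation(mid, cls, pw))
    catalog = AnnotationCatalog(records)

    # abundances
    scale = np.exp(rng.normal(0.0, 1.0, size=(cfg.n_metabolites, 1)))
    z = rng.normal(0.0, 1.0, size=(cfg.n_metabolites, cfg.n_cultivars))
    shift = np.zeros_like(z)
    truth_rows = []
    for mi, ci, s in cfg.planted:
        shift[mi, ci] += s
        truth_rows.append(
            {
                "metabolite_id": metabolites[mi],
                "cultivar_id": cultivars[ci],
                "shift": float(s),
                "direction": "high" if s > 0 else "low",
            }
        )
    values = scale * np.exp(cfg.sigma_log * (z + shift))

    if cfg.dropout > 0:
        drop = rng.random(values.shape) < cfg.dropout
        all_dropped = drop.all(axis=1)
        for mi in np.nonzero(all_dropped)[0]:  # keep >= 1 detection per metabolite
            drop[mi, int(rng.integers(cfg.n_cultivars))] = False
        values = np.where(drop, np.nan, values)

    ab = AbundanceMatrix(pd.DataFrame(values, index=metabolites, columns=cultivars))
    truth = TruthTable(
        pd.DataFrame(
            truth_rows, columns=["metabolite_id", "cultivar_id", "shift", "direction"]
        )
    )
    return ab, catalog, truth


def random_planted(
    n_effects: int,
    shift: float,
    cfg: SimConfig | None = None,
    seed: int = 0,
    n_metabolites: int = 450,
    n_cultivars: int = 17,
) -> list[tuple[int, int, float]]:
    """Pick distinct metabolites and random cultivars for planted shifts."""
    if cfg is not None:
        n_metabolites, n_cultivars = cfg.n_metabolites, cfg.n_cultivars
    rng = np.random.default_rng(seed)
    mets = rng.choice(n_metabolites, size=n_effects, replace=False)
    cvs = rng.integers(0, n_cultivars, size=n_effects)
    return [(int(m), int(c), float(shift)) for m, c in zip(mets, cvs)]


def evaluate_recovery(d: DiscriminatorSet, truth: TruthTable) -> RecoveryReport:
    """Sensitivity and false-discovery proportion against the truth table.

    Sensitivity = planted (metabolite, cultivar) cells reported / planted;
    FDP = reported entries that were not planted / reported (0 if nothing
    reported).  Direction accuracy is computed over recovered entries.
    """
    planted = truth.planted_pairs()
    reported = list(zip(d.entries["metabolite_id"], d.entries["cultivar_id"]))
    n_planted = len(planted)
    n_reported = len(reported)
    recovered = [p for p in reported if p in planted]
    sensitivity = len(set(recovered)) / n_planted if n_planted else 1.0
    fdp = (n_reported - len(recovered)) / n_reported if n_reported else 0.0

    truth_dir = dict(
        zip(
            zip(truth.entries["metabolite_id"], truth.entries["cultivar_id"]),
            truth.entries["direction"],
        )
    )
    dirs = [
        truth_dir[pair] == drn
        for pair, drn in zip(reported, d.entries["direction"])
        if pair in planted
    ]
    direction_accuracy = float(np.mean(dirs)) if dirs else 1.0
    return RecoveryReport(
        sensitivity=float(sensitivity),
        fdp=float(fdp),
        n_planted=n_planted,
        n_reported=n_reported,
        direction_accuracy=direction_accuracy,
    )
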