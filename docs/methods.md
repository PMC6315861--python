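# Methods

This note documents the models, conventions and design choices behind
`oryzabran`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

A panel is a cultivar × metabolite table of relative abundances: unitless,
ion-intensity-derived, comparable *within* a metabolite across cultivars
but not between metabolites. A missing cell means "not detected in that
cultivar's run"; a stored zero is a legal detected value and is kept
distinct from missing throughout. Every metabolite must be detected in at
least one cultivar.

Annotation is deliberately simple: each metabolite has one chemical class
(from a seven-class vocabulary: amino acids, carbohydrates, cofactors &
vitamins, lipids, nucleotides, peptides, secondary metabolites; extra
labels can be allowed explicitly) and exactly one metabolic pathway, and a
pathway belongs to exactly one class. One-pathway-per-metabolite is a
strong simplification — real compounds participate in many pathways — but
it is the bookkeeping that makes the fold-enrichment score below
well-defined and conservation properties (Σk = n, Σm = N within a scope
unit) exact.

Metabolite names are the join key across tables, so all lookups pass
through a normalization step (trim, case-fold, collapse whitespace, NFC,
typographic primes/dashes → ASCII) plus a curated synonym table
(`oryzabran._normalize.SYNONYMS`) for the aliases that occur in practice:
salt/ester name variants ("l-quinate" → "quinate"), abbreviations ("GPC"),
and co-eluting isomer pairs reported as a single entity
("γ-tocopherol/β-tocopherol"). Co-reported entities are one metabolite
record.

## Median scaling

Each metabolite's abundances are divided by the median of its detected
values, making the per-metabolite median exactly 1 and removing arbitrary
per-metabolite intensity scales. The operation is idempotent and preserves
the missingness pattern. A metabolite whose median would be 0 (more than
half its detected values zero) cannot be scaled and is reported as an
error rather than silently propagating infinities.

## Z-scores and discriminator detection

For metabolite i and cultivar j, `Z_ij = (x_ij − μ_i)/σ_i` on the
median-scaled values, with μ_i and σ_i over cultivars with detected
values. Conventions, each chosen where the procedure is genuinely
underdetermined:

* **σ denominator** — sample (c − 1) by default, population (c) available
  via `sigma_convention`. Published descriptions of this style of analysis
  rarely state the choice; sample σ is the ecosystem default, and with 17
  cultivars the difference rescales Z by √(17/16) ≈ 1.031, enough to move
  borderline cells across the threshold, hence the explicit switch.
* **Missing cells** — default `skip`: μ, σ and Z use detected cells only.
  `min_impute` (fill each metabolite's missing cells with its minimum
  detected value, the common convention for MS platforms where
  non-detection usually means "below this run's floor") is offered; the
  default avoids inventing values.
* **min_cultivars = 3** — σ is undefined below 2 detected values, and with
  exactly 2 every Z is ±1/√2 (sample convention), carrying no information.
  Metabolites below the floor are excluded with a logged warning, not an
  error, so sparse compounds don't abort a run.
* **σ = 0 rows** — all detected cells get Z = 0 and the metabolite is
  flagged constant rather than producing 0/0.
* **Strict threshold** — a discriminator requires |Z| strictly greater
  than the threshold (default 2.0). Strictness only matters for cells
  landing exactly on the threshold, but it makes threshold monotonicity
  exact: raising the threshold never adds entries.

Because μ and σ are estimated in-sample, Z is bounded: one extreme cell
among c cultivars satisfies |Z| ≤ (c − 1)/√c (≈ 3.880 at c = 17, sample
convention). Two consequences worth keeping in mind: (a) the |Z| > 2 rule
cannot be given a Gaussian tail interpretation — the empirical exceedance
rate on null log-normal panels is about 4% of cells (measured by the test
suite and the acceptance script), not 2·Φ(−2) ≈ 4.6%, and on right-skewed
data most exceedances are high-side; (b) a *low* outlier is compressed:
scaled abundances are bounded below by 0, so the most negative achievable
deviation is about μ_i, giving |Z| ≈ μ_i/σ_i ≈ 2.1 for log-normal noise of
width 0.35 — barely over threshold. Strong positive spikes are therefore
always detectable (the bound argument), while equally strong *negative*
spikes on the log scale are detectable only when the metabolite's
cultivar-to-cultivar noise is modest. Real panels in which many low-side
discriminators are reported imply tighter per-metabolite σ than the
generator's default noise. The package's sensitivity-1.0 guarantees (tests
and acceptance runs) are accordingly stated for positive planted spikes;
direction correctness for recovered negative spikes is tested separately.

No multiple-testing correction is applied, deliberately: the procedure is
a screening heuristic whose output feeds descriptive enrichment and gene
lookup, not inference.

## Pathway enrichment score

For a scope unit and pathway, `PES = (k/m)/(n/N)` — the fraction of the
pathway's identified metabolites that discriminate, over the same fraction
in the whole scope. Computed in exact rational arithmetic (`fractions`)
and emitted as float; k = 0 gives 0, k = m with n = N gives exactly 1,
n = 0 or m = 0 is an error rather than a NaN. All four counts are over
*distinct* metabolites.

Scope is genuinely ambiguous in this style of analysis: enrichment can be
computed per cultivar (k, n from that cultivar's discriminators; m, N from
its detected metabolites) or globally (pooled distinct discriminators;
union of detected metabolites). Per-cultivar is the default because one
score per cultivar × pathway is the natural companion to per-cultivar
discriminator calls; `scope="global"` is a flag. Selection keeps records
with k ≥ 1 and score ≠ 1 (tolerance 1e−12), sorted descending. A
hypergeometric tail probability P(X ≥ k) is computed on request as a
modern sanity check but never used to select — PES is a descriptive fold
change and is reported as such.

## Gene linkage

The bundled gene map is a curated metabolite → rice-gene table in the
style of a PlantCyc/OryzaCyc export: per metabolite, a *direct* gene count
(genes specifically annotated to its biosynthesis) with enumerated gene
rows (internal IDs plus MSU `LOC_Os...` locus names, preserved verbatim),
and a *common* gene count (genes shared by the generic class pathway,
e.g. ~150 genes common to standard amino-acid biosynthesis). Conventions:

* The stored `direct_count` is authoritative; gene rows may be a partial
  "top genes" enumeration (e.g. 5 of glutamate's 91). Validation therefore
  tolerates enumerated-row counts differing from `direct_count`.
* Headline totals sum direct counts only. Common counts overlap heavily
  across metabolites; summing them would double-count wildly.
* A metabolite with `direct_count = 0` but present in the map (myristate)
  still counts as matched — the database knows the compound, it just has
  no specific gene.
* Taurine's rows are transporters, not biosynthesis, and carry
  `role="transport"`.

Joins use the shared name normalization; unmatched discriminators are a
report field, never an error.

## Reporting

Class-count tables flag all argmax/argmin cultivars on ties. The lipid
share headline is the mean over cultivars of per-cultivar lipid/total,
rounded half-up to an integer percent; the pooled ratio (summing counts
first) is exported alongside — on realistic panels the two agree to well
under a point, so the choice is documented rather than consequential.

Ordination is reporting plumbing: cultivars as observations, metabolites
as variables, columns mean-centered (unit-variance scaling behind a flag,
off by default since the input is already median-scaled), full-SVD PCA,
percent variance = squared singular value over total. Missing values must
be imputed first; the error message says so.

## Synthetic data generator

`generate(SimConfig)` emulates a single-run bran panel:

| parameter | default | rationale |
|---|---|---|
| `n_cultivars` | 17 | typical diversity-panel size for this workflow |
| `n_metabolites` | 450 | annotated-compound count of a full bran panel |
| `class_proportions` | lipids 0.390, amino acids 0.276, carbohydrates 0.124, nucleotides 0.084, cofactors & vitamins 0.064, secondary metabolites 0.046, peptides 0.016 | observed class shares of the bran metabolome (lipids ≈ 39%) |
| `n_pathways` | 53 | pathway count of the annotation vocabulary; split across classes by largest remainder, named pathways first, placeholders after |
| `sigma_log` | 0.35 | cultivar-to-cultivar log-abundance spread giving realistic Z behavior (~4% null exceedance) |
| `dropout` | 0.08 | calibrated so per-cultivar detected totals land in the 378–430 band of real panels (450 × 0.92 = 414 expected) |
| `planted` | `[]` | (metabolite, cultivar, shift) triples; shift in units of `sigma_log` on the log scale |
| `seed` | 0 | single `numpy` Generator stream; identical seed ⇒ identical outputs |

Abundances are `scale_i · exp(sigma_log · (z_ij + shift_ij))` with
`scale_i` log-normal (removed by median scaling) and z standard normal.
Dropout is i.i.d. per cell, with one detection per metabolite forced so
the table stays valid. The truth table records planted cells and
directions; `evaluate_recovery` scores sensitivity (planted cells
reported), false-discovery proportion (reported cells not planted) and
direction accuracy over recovered entries.

What the generator does **not** emulate — and hence what passing tests do
not establish about real panels: correlated metabolite blocks (real lipid
classes co-vary), intensity-dependent missingness (real dropout hits
low-abundance compounds), batch/injection-order structure, biological
replication within cultivar (one column = one cultivar here), or
heavy-tailed contamination. Recovery results on synthetic panels are
best-case; the FDP of the |Z| > 2 screen on null synthetic data (~4% of
cells) is the price of an uncorrected threshold rule and is reported, not
hidden.

## Bundled curated tables

The package ships three curated text fixtures (see
`oryzabran.datasets`): the 17-cultivar class-count table; the 71
discriminating metabolites with class/pathway annotation and their 74
(metabolite, cultivar, direction) calls; and the 34-metabolite gene map.
They are transcriptions of published summary tables, not raw data — the
underlying feature table is not publicly deposited, so per-metabolite
abundances, the printed per-cultivar enrichment scores, and the exact
53-pathway vocabulary (only 15 pathways are named in the summaries; the
generator fills the rest with placeholders) are not reproducible from
first principles. Two transcription choices were forced:

* The published amino-acid pathway membership counts (4 + 7 + 9 + 2) sum
  to 22 for 21 compounds; the fixture follows the gene-table family
  groupings (proline-derived compounds under the glutamate family,
  lysine-derived under the aspartate family), giving 4 + 7 + 8 + 2 = 21.
* The lipid enumeration names 34 (metabolite, cultivar) entries whose
  naive distinct count is 30, against stated totals of 33 lipids and 14
  diacylglycerols. Repeated lipid names across cultivars are resolved as
  separate co-reported isomer records (the "[1]/[2]" convention of MS
  reports), except oleoyl-oleoyl-glycerol (18:1/18:1), shared between two
  cultivars — the unique resolution consistent with all three printed
  totals simultaneously.

Z magnitudes for the curated discriminator set are not published, so its
`z_value` column is NaN; direction is the curated fact.

## Numerical choices

* PES in exact rational arithmetic; equality-with-1 tolerance 1e−12.
* Median-scale idempotence and Z row-moment identities hold to 1e−9 and
  are asserted at that tolerance.
* Abundance writing uses `repr(float)` and reading uses pandas'
  `float_precision="round_trip"`, making read→write→read the identity
  cell-for-cell, missing cells included.
* Rounding of headline percentages is half-up (`floor(x + 0.5)`), not
  banker's rounding.
* Seeds: one `numpy.random.default_rng` stream per generated panel;
  derived seeds are reduced mod 2³¹.

## Known limitations

* One pathway per metabolite is a modeling convenience; enrichment over
  overlapping pathway sets would need a different null.
* The |Z| > 2 screen has no error-rate control; with 17 cultivars its
  per-cell null exceedance is ~4%, so on a 450-metabolite panel dozens of
  entries are expected by chance. Downstream counts (pathway structure,
  gene totals) inherit that.
* The low-side detectability ceiling (|Z| ≲ μ/σ) means strong suppressions
  of noisy metabolites are structurally invisible to the rule.
* The gene map reflects a japonica-based pathway database; indica
  genotypes may differ, and enumerated gene lists for high-count
  metabolites are intentionally partial.
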