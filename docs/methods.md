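# Methods

## Scope and data model

`tdpquant` post-processes three table families from a FAIMS-split top-down
LC-MS/MS study: PrSM tables from an open-modification search engine
(TopPIC-style dialect, one row per proteoform-spectrum match), proteoform
exports from a PTM-database engine (TDPortal/TDViewer-style dialect), and
deconvoluted MS1 feature tables (ProMex-style dialect). Column dialects are
config mappings with shipped defaults, because engine versions rename
columns; the PTM-database export schema in particular varies, so its default
mapping is best-effort and fully overridable. RT units are normalized to
minutes at read time (the open-search dialect exports seconds). The on-disk
missing-value token is `NA`; in memory missing is `None`/NaN, never 0.
Readers reject malformed rows individually and report their indices, so
reads + rejects always account for every data row.

Run file names encode the FAIMS compensation voltage
(`..._CV40.raw` → CV −40 V); each (run, CV) pair is treated as one dataset.

## Retention-time alignment and mass recalibration

Within each CV, the run with the most PrSMs is the reference (ties:
lexicographically smallest run id). Anchors are proteoforms observed in both
the reference and the target run, keyed by (accession, proteoform string);
we deliberately key on the reported proteoform identity rather than a
rounded mass, because per-run calibration offsets of a few ppm displace
intact-protein masses by 0.05–0.2 Da — more than any fixed decimal rounding
absorbs. Each anchor pairs the apex PrSM (most intense; lowest E-value when
intensities are absent) of the proteoform in the two runs.

The RT warp is a LOESS regression of reference RT on target RT through the
anchors — span 0.5, locally linear, 2 robustness iterations (suitable for a
few hundred anchors with occasional outlier PrSMs; configurable). Outside
the anchor span the boundary trend continues linearly (slope from the outer
20% of anchors). Fewer than 5 anchors, or anchors without RT spread, fall
back to the identity warp with a warning.

Mass recalibration is a single per-run constant: the median ppm error of
anchor masses against the reference, removed as
`mass' = mass × (1 − offset×1e−6)`. A constant (rather than mass-trended)
correction is the minimal model matching how these offsets behave on
Orbitrap data; the median makes it robust to individual mis-assigned PrSMs.
The warp and offset fitted on the open-search PrSMs are applied to that
run's PrSMs and MS1 features. The PTM-database engine's records get the RT
warp only: its reported masses are database (theoretical) monoisotopic
masses, identical across runs, and carry no calibration error to remove.

## Proteoform clusters (PfCs)

Aligned, recalibrated PrSMs are partitioned by accession and single-linkage
clustered: two PrSMs link iff their masses agree within 15 ppm — evaluated
against the smaller mass, which is symmetric and conservative — and their
RTs within 4 min. Both thresholds default to the matching tolerances used
downstream and are configurable. Clusters with fewer than 3 PrSMs pool into
the accession's noise cluster (`<accession>_0`); noise is excluded from
quantitation but still competes, at lowest priority, to annotate feature
groups. The partition property (every PrSM in exactly one PfC) is asserted
at run time.

The cluster representative is the proteoform string backed by the most
PrSMs; ties break by lowest E-value, and the representative PrSM is that
proteoform's lowest-E-value PrSM.

Protein-level FDR filtering keeps proteins whose q-value is ≤ 0.01. When
only per-record q-values exist, the protein q-value is approximated by the
minimum over the protein's PrSMs (documented approximation; strict mode
errors when no q-values are present at all).

Ambiguity is graded on the five-level scale over four attributes — PTM
localization (A), PTM identity (B), sequence (C), gene (D). An unknown mass
shift sets both A and B (the open search reports a shift, not a PTM or
site); a named PTM without a confident site sets A alone; gene ambiguity
requires an accession→gene map and stays off (with a logged caveat) without
one; sequence ambiguity is never asserted since each engine reports a single
sequence. No flag → level 1; one flag → `2A`/`2B`/`2C`/`2D`; k ≥ 2 flags →
level 1+k.

## Feature groups and identification attachment

Per CV, feature lists are aligned across runs by a minimal
match-between-runs: a master list seeded from the run with most features,
greedy best-|ppm|-first matching within 15 ppm / 4 min with each feature
used once, unmatched features appended. This aligner is a deliberately small
stand-in presenting the same table contract as dedicated external alignment
tools (per-run columns, `NA` for missing).

All CVs are then concatenated and sorted by mass. Chained mass groups: a
mass joins the current group iff its gap to the immediate predecessor is
≤ 1 Da **and** ≤ 15 ppm (inclusive comparisons; predecessor-chaining is
single linkage on a line). Within each mass group, RTs sorted ascending
chain with gap ≤ 4 min. Each (mass group × RT group) cell is a feature
group: count, max monoisotopic mass (consensus), mean RT, per-sample median
intensity across member rows.

Identifications are collapsed to one candidate per proteoform — per PfC
(noise included, keyed by its `_0` id) for the open search; per (accession,
mass rounded to 2 decimals) for the PTM-database engine, which is safe
because those masses are theoretical — each represented by its
lowest-E-value proteoform. A candidate matches a group iff for some shift
k ∈ {0, ±1, ±2}, |ppm(mass + k·1.00235, consensus mass)| ≤ 15 and
|ΔRT| ≤ 4 min; shift 0 is preferred, then ascending |k|. The spacing is the
isotope spacing (1.00235 Da), not literal 1 Da: deconvolution off-by-one
errors are isotope-spacing multiples, and the residual versus 1.0 Da is
far below 15 ppm at protein masses either way. Note a ±1-spacing error
exceeds the 1-Da mass-chain gap, so deisotoped features form *separate*
groups by construction and are reabsorbed at the ID-matching step — the
group count is therefore expected to exceed the proteoform count in
error-bearing data.

Conflicts among candidates for one group resolve lexicographically: no
unknown modification first, then non-noise PfC, then smaller E-value;
remaining ties by smaller |shift|, open-search source first, then stable
input order.

## Quantitation

Stage order is one-way: filter → normalize → log2 → impute → test.

- **Filter**: rows observed in ≥ 2 samples (pre-imputation).
- **Normalize**: each sample's observed abundances divided by that sample's
  median (all CVs already combined into one value per sample per group),
  rescaled by the grand median of sample medians; afterwards all sample
  medians are equal. Normalization acts on raw intensities before log2 — a
  ratio on intensities is the natural reading of median normalization; a
  log-scale variant would be a constant shift of each column. One known
  consequence: when a nonzero fraction of rows is truly regulated, the two
  region groups' medians differ slightly and all fold-change *magnitudes*
  acquire a small constant bias; signs are unaffected, and the zero-noise
  recovery check asserts exactly that.
- **Impute**: per sample with observed log2 mean μ and sd σ, missing cells
  draw i.i.d. from N(μ − 1.8σ, (0.3σ)²) — the downshifted-normal model of
  detection-limit censoring. Deterministic given the seed; imputed values
  essentially never exceed the sample's observed median (6σ away).
- **Test**: unpaired two-sided t-test per row between the region groups;
  equal-variance (Student) by default with a Welch option, since nothing
  about the design implies unequal variances. log2FC = mean(cortex) −
  mean(hypothalamus). Raw p-values are primary; Benjamini–Hochberg q-values
  are provided as an extra column. Degenerate rows (zero variance, zero
  difference) are reported as t = 0, p = 1.
- **PCA**: samples as observations on row-centered data via SVD; with
  missing values (non-imputed variant) the sample covariance is computed
  pairwise-complete and eigendecomposed, scores being the scaled
  eigenvectors. Both paths share the same centering so they are comparable.

## MALDI annotation

The proteoform library (annotation + neutral monoisotopic mass) comes from
identified feature groups. Each peak is tested at charges 1..3 (MALDI
protein ions carry low charge) against predicted m/z = (M + z·1.007276)/z.
Two modes: *monoisotopic* (tolerance default 15 ppm) and *apex*, which adds
k = round(5.5×10⁻⁴ · M) isotope spacings to M before conversion — a linear,
averagine-like estimate of the envelope apex for isotopically unresolved
peaks (tolerance default 50 ppm, since the apex estimate is approximate; a
full isotope-pattern simulation is out of scope for peak-list inputs). The
best |ppm| hit per peak wins; annotation is deterministic and independent of
peak/library order.

## Synthetic data generator

The generator emulates the study design the pipeline assumes: 5 cortex + 4
hypothalamus samples, each split into CVs −30/−40/−50 V; proteoform masses
log-uniform 3.5–30 kDa; true RTs uniform 10–120 min; base abundances
log-normal (ln-scale sd 1 around 10⁷); 20% of proteoforms regulated two-fold
between regions; 30% of proteoforms carrying an unknown mass shift;
E-values log-uniform 10⁻¹⁵–10⁻²; two engines observing partially
overlapping proteoform subsets (P(both)=0.5, each-only 0.25/0.15). Per-run
nuisances: smooth monotone RT drift (slope sd 0.02, intercept sd 1 min,
plus a ≤0.5 min sine of 60-min period), ppm offsets uniform within ±6 ppm,
feature dropout 0.10, deisotoping errors 0.05 (±1 spacing, occasionally
±2), multiplicative abundance noise with CV 20%, RT jitter sd 0.15 min and
mass jitter sd 1 ppm. The first sample anchors the common timescale
(identity drift, one extra PrSM per proteoform so the reference choice is
deterministic). All randomness flows from one seed through per-stage
substreams; the same seed reproduces byte-identical tables. A `clean()`
parameter set zeroes every noise source for exact-recovery checks.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: chromatographic peak shapes and co-elution,
isotope-envelope and charge-state structure, correlated (batch-like) noise,
shared accessions between distinct proteoforms, decoy-based FDR behavior,
and engine-specific scoring quirks. Tests demonstrate the bookkeeping,
tolerance logic and statistics are correct under the stated model, not that
the search engines' outputs themselves are trustworthy.

## Numerical choices and problem sizes

Tolerance comparisons are inclusive (≤) everywhere; ppm between two masses
is evaluated against the smaller; ties in representative selection,
reference-run choice and conflict resolution are broken deterministically
(E-value, lexicographic id, stable input order) so reruns are
byte-identical. Clustering on the recalibrated precursor mass is the
default; an option clusters on the engine's shift-adjusted mass instead,
which folds unknown shifts back in and merges modified forms — kept for
comparison, not as default, because it conflates distinct proteoforms.

Test and acceptance simulations use 30–200 proteoforms and the 9-sample,
3-CV design — sizes at which every oracle comparison and end-to-end run
completes in seconds while the asymptotic checks (binomial CIs, type-I
error on 2000 null rows, 10⁴ imputation draws) retain their stated power.

## Known limitations

- The cross-run aligner is greedy, not globally optimal; at ≥98% correct
  correspondence under the stated noise it is adequate, but dense mass
  regions could benefit from optimal assignment.
- Protein-level q-values are approximated by the per-protein minimum when
  only record-level q-values exist.
- The constant-ppm recalibration has no mass-dependent trend; a hook exists
  to swap in a trended variant.
- Level-`2C` (sequence ambiguity) is representable but never produced.
- The apex-mode MALDI prediction is a heuristic; ~20 ppm systematic error
  at 11 kDa is typical, which is why its default tolerance is 50 ppm.
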