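# Methods

This note documents the models, conventions and design choices behind
`nhaneskit`, in the order the pipeline runs.

## Snapshot model

A snapshot is one self-contained build of a survey release: an embedded
SQLite store with three namespaces plus version information.

- **raw** — released tables loaded verbatim, one store table per released
  file. `SEQN` (the within-cycle respondent key) must be present and
  unique.
- **translated** — same shape, same columns, with categorical codes
  replaced by their codebook value descriptions.
- **metadata** — the documentation-derived tables
  `questionnaire_descriptions` (one row per released table),
  `questionnaire_variables` (one row per variable per table),
  `variable_codebook` (one row per possible value), and `version_info`
  (exactly two rows: `CONTAINER_VERSION`, `COLLECTION_DATE`). Column names
  are the snake_cased forms of the documentation's CamelCase headings
  (TableName → `table_name`, SasLabel → `sas_label`, CodeOrValue →
  `code_or_value`, and so on).

Namespaces are emulated with reserved table-name prefixes (`raw__`,
`translated__`, `metadata__`) behind the store's registry; any relational
backend implementing the same contract (a server-based deployment, say)
could replace SQLite without touching callers. Restricted-access tables
contribute metadata and documentation but never raw or translated data.
The original HTML pages are stored byte-identically, so the documentation
served for a table is always the documentation of the data actually
loaded. A single collection date covers the whole snapshot.

Environment discovery follows a three-variable contract
(`NHANES_DB_VARIANT`, `NHANES_DB_PORT`, `NHANES_TABLE_BASE`): with the full
set present a tool connects to the containerised store and local
documentation; with anything missing it reports absence (plus a warning
naming the gap for partial sets) and callers fall back to file-based
access, behaving identically either way. Only the documentation-base name
is an upstream convention; the other two are this toolkit's documented
constants. A client that only has a database connection can still read
both version fields with a plain SQL query.

## Codebook dialect

Documentation pages are parsed structurally, not against any specific
site's markup: a variable block is a `<dl>` definition list containing a
"Variable Name" field (recognized labels: Variable Name, SAS Label,
English Text, English Instructions, Target, Hard Edits), and its value
table is the next `<table>` in document order headed by Code or Value /
Value Description / Count / Cumulative / Skip to Item. Adapters for other
markups can transform into this shape. Decisions within the dialect:

- *Target* may repeat (one line per age/sex group) and is stored as a
  list; flattening would lose information.
- *English Instructions* and *Hard Edits* are stored as opaque strings;
  no semantics are attached to them.
- Unknown field labels are recorded in `parse_warnings`, never silently
  dropped. Thousands separators in counts are tolerated; a missing Count
  column yields absent (not zero) counts.
- End-of-section skip targets (any "End of Section" phrasing) are
  normalized to a single reserved sentinel.
- A page with no recognizable variable block raises
  `UnsupportedDialectError` with the byte offset where scanning gave up;
  the snapshot builder treats such tables as excluded and logs them,
  mirroring the practice of excluding files whose documentation is in a
  non-standard format.

Parsing is insensitive to whitespace-only changes (all extracted text is
whitespace-collapsed), so re-serialized pages parse identically.

## Translation

A variable's codebook group determines its kind:

- **continuous** — exactly one non-missing row and it is a textual range
  `"X to Y"`;
- **categorical** — only discrete codes;
- **mixed** — a range row coexisting with discrete codes (Refused /
  Don't-know sentinels alongside numeric values). Two distinct range rows
  are an ambiguous codebook and an error.

Categorical codes become plain strings (their value descriptions); ordered
categories are an explicit, separate step via `ordered_levels`, which
returns labels in codebook document order — the order the codebook intends
(e.g. ascending education levels) — excluding missing-class sentinels per
policy. Byte-identical duplicate labels are an error there; case-variant
near-duplicates deliberately pass, because identifiers and labels are
compared case-sensitively everywhere in the model layer and
case-insensitive comparison belongs to QC alone.

Mixed variables: every discrete code whose description is not "Range of
Values" is treated as special; the default policy maps specials to missing
and counts them per column. Unmapped categorical codes become missing with
a warning rather than an error — decades of releases guarantee stragglers,
and QC should surface them rather than crash the ETL. Translation always
preserves shape exactly and never touches `SEQN`.

## Skip logic

The codebook's Skip to Item column yields a directed flow structure: one
edge per (variable, answer code) with a target later in document order (or
the end-of-section sentinel). Backward targets and targets outside the
table are recorded as anomalies, never as edges. "Skipped" means strictly
between source and target: the target itself is the next question asked.

A variable V is *skippable* iff some edge whose source question is
**reachable** jumps from before V to after V. The reachability restriction
matters: an edge whose source can never be asked (because every answer of
an earlier question jumps past it) can never fire. Because jumps are
forward-only, this rule is exactly equivalent to "some answer vector
leaves V unasked" under the interview simulation, and the test suite
verifies that equivalence by exhaustive enumeration on every generated
questionnaire and on randomized ones.

Missingness classification partitions every cell into observed /
structurally skipped / item nonresponse: a missing cell is structurally
skipped iff one of the respondent's *answered* upstream values triggers an
edge jumping past the variable. When the gate answer is itself missing the
downstream cell is classified as item nonresponse — the conservative
choice, since nothing proves the question was skipped.

The right-censoring transform prepares (value, event) pairs for
survival-style analysis of gated duration questions (age started smoking,
gated by ever-smoked): respondents whose trigger answer caused the skip
get the censoring source's value (current age) with event 0, observed
values pass through with event 1, and other missing cells stay missing.
No survival model is fitted here.

## Quality control

All checks compare metadata across the tables carrying a variable and
report findings whose evidence partitions the tables by variant; nothing
is ever auto-corrected, since deciding whether two variants denote the
same quantity takes subject-matter review.

- `qc_var` — the four documentation-header dimensions: SAS label, target,
  English text, and presence in more than one table within a cycle.
  Additional checks are separate operations rather than folded in, so
  `qc_var`'s contract stays minimal.
- `qc_levels` — level spellings equal after normalization (case-fold,
  collapse internal whitespace, strip trailing punctuation) but not
  byte-equal are typographic variants (warn). Level sets that differ
  beyond normalization are reported at info severity: possibly genuine
  recodes. Nothing stronger than that normalization (no stemming, no edit
  distance) is applied, so every finding stays explainable by eye.
- `qc_units` — two signals: parenthesized unit tokens in labels differing
  across tables, and codebook range midpoints differing by ≥10×
  (configurable), which catches rescalings the labels do not admit.
- `qc_name_reuse` — token-set Jaccard similarity of the English texts;
  clusters split below 0.2 (configurable) mean one name covering
  different measurements (error severity).
- `qc_presence_matrix` — a variables × tables incidence matrix over a set
  of related tables; variables present in some but not all get a finding
  listing the absent tables. This automates half of the per-file-rename
  problem; the matrix itself is returned because deciding whether the
  differently-named variables measure the same thing remains manual.

Severity ranks (info/warn/error) are this package's own convention.

## Survey estimation

The estimator is the Hájek ratio mean with stratified with-replacement
first-stage Taylor linearization — the standard treatment of public-use
designs, where the released pseudo-strata/pseudo-PSU structure is designed
for exactly this approximation:

    ȳ_w = Σ_D w_i y_i / Σ_D w_i
    z_i  = w_i (y_i − ȳ_w) / Σ_D w_i,  zero outside the domain D
    Z_hj = Σ_{i∈PSU hj} z_i
    Var  = Σ_h n_h/(n_h−1) Σ_j (Z_hj − Z̄_h)²

Domain estimation keeps the full design and zeroes out-of-domain
residuals; rows are never subset first, so PSUs without domain members
still count in the design. Confidence intervals are t-based with
df = #PSUs − #strata (the common survey-software convention), counting the
full design. PSU identifiers are interpreted within stratum, since 1/2
numbering conventionally recycles across strata. Strata with a single PSU
break the formula; the policy is configurable — `fail` (default, naming
the stratum) or `center` (deviation from the grand mean of PSU totals, a
conservative conventional fallback).

An independent variance route, the Rao–Wu rescaling bootstrap (resample
n_h−1 PSUs with replacement per stratum, rescale weights by n_h/(n_h−1)
times the selection multiplicity), serves as a cross-check oracle in tests
and in the acceptance script — never as the production estimator. For the
linearized statistic the two agree in expectation; observed relative
differences on small designs (a few percent) reflect bootstrap Monte Carlo
noise plus the second-order ratio terms linearization omits.

Per-cycle series resolve a release family (base name plus underscore-letter
suffixes), join each cycle's value table to its demographic table on
`SEQN`, and estimate every cycle independently. Weight specifications may
be a single column name or an explicit per-cycle mapping, for families that
rename their weight variable per file; a missing column without a mapping
is an error naming the cycle and column.

Pooling respondents across cycles is refused by design: a secular trend
makes a common estimand dubious, and sampling weights are derived against
per-cycle reference populations that may differ. `pooled_analysis_guard`
emits a non-suppressible warning and computes nothing; the `acknowledge`
flag only records that the caller saw it.

## Synthetic fixture generator

The generator is the offline stand-in for the upstream source and defines
the conditions everything is tested under. Defaults:

- **3 cycles** (1999–2000 … 2003–2004) with the conventional
  base/`_B`/`_C` table-family suffixes; 150 questionnaire respondents per
  cycle, `SEQN` assigned per cycle and shared across that cycle's tables.
- **Questionnaire families**: an education table (10-level categorical in
  document order, plus a mixed income-ratio variable), a smoking table
  with the gate → skip pattern (answer codes 2/7/9 at the gate jump past
  two questions), and a laboratory table (continuous cadmium with a unit
  token in its label, plus a subsample weight variable). Item nonresponse
  rate 5%, special-code rate 8% for mixed variables — small but non-zero,
  so every missingness mechanism appears.
- **Survey population**: 15 strata × 2 PSUs × 10 respondents per cycle
  (the masked-variance design shape of a real public-use release, giving
  df = 15), outcome y = μ_c + b_psu + ε with μ_c = 26.0 + 0.5·cycle
  (a BMI-like level with a slow upward secular drift), PSU effects
  sd 0.8, residual sd 4.5, lognormal(σ=0.5) weights and uniform ages
  20–79, both independent of the outcome so the true domain mean is μ_c
  by construction and is written to the ground-truth sidecar.
- **Counts are exact**: codebook Count/Cumulative rows are computed from
  the realized data (range rows print the observed range, as real
  codebooks do), so count-reconciliation checks are identities, not
  statistical comparisons.
- **Determinism**: one seeded generator consumed in a fixed order; the
  same spec and seed produce byte-identical trees.
- **Injections** are deterministic spec transformations with a recorded
  ground truth (affected tables, variant values): level case-variants,
  unit changes (token swap + ×100 data/range rescale), description
  rewrites, full description replacement (name reuse), per-file weight
  renames, and within-cycle table duplication. A snapshot with no
  injections loads without warnings and produces zero QC findings.

Raw data is emitted as CSV by default, with a SAS transport (XPT v5)
writer behind a flag; the writer covers numeric columns with IBM-format
doubles and `.`-missing — exactly what released raw tables contain — and
round-trips through standard XPT readers, which the tests verify.

What the generator does **not** emulate: real variable names and
distributions beyond structural fidelity, oversampling (weights are
independent of everything), nonresponse adjustment in weights,
cross-section skip targets, or documentation markup quirks beyond the
supported dialect. Passing tests therefore demonstrate the machinery's
correctness on structurally faithful inputs, not robustness to arbitrary
real-world markup.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale sizes chosen to make
every check exact or statistically sharp: exhaustive skip-logic
enumeration on questionnaires of at most 8 variables; 50 seeded snapshots
for QC recall/precision; 20 random designs × 10,000 bootstrap replicates
(vectorized over per-PSU totals) for variance calibration; 1,000
population replicates for CI coverage, whose binomial tolerance motivates
the 93–97% band around the nominal 95%. Numeric ties and degenerate
inputs: zero between-PSU variation yields a zero SE and a degenerate
interval at the mean; empty domains, nonpositive df, and two-range
codebooks are errors; unmapped codes and missing censor sources degrade to
missing values with warnings.

## Known limitations

- `qc_name_reuse` depends on the English text; identical descriptions
  with silently changed semantics are undetectable by construction.
- The unit-change range heuristic needs range rows in the codebook; purely
  label-free unit changes with similar ranges escape it.
- No replicate-weight (BRR/jackknife) variance methods, no regression
  machinery, and no pooled multi-cycle estimator (deliberately refused).
- The store backend is single-file SQLite; concurrent multi-user service
  would use a server backend behind the same contract.
- Skip targets that jump between tables are recorded as anomalies rather
  than modelled; within-table forward flow is assumed.
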