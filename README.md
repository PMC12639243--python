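# nhaneskit

Offline data-management toolkit for NHANES-style complex surveys: codebook
metadata extraction, raw-to-labelled ETL snapshots, questionnaire skip-logic
analysis, cross-cycle consistency QC, and design-based survey estimation.

## The problem

Large public health surveys such as the Continuous NHANES release, every
2-year cycle, dozens of data files ("tables") as SAS transport files, each
with an HTML documentation page whose codebook lists every variable's codes,
value descriptions, counts, and the *Skip to Item* flow used during the
interview. Working across 20+ years of such releases is error-prone in
well-documented ways:

- categorical codes must be translated to labels using the right cycle's
  codebook, and the codebook's row order defines the ordering of levels;
- a question downstream of a gate (e.g. age started smoking, gated by
  "ever smoked 100 cigarettes?") is released as *Missing* for everyone the
  gate skipped — structural missingness that looks identical to item
  nonresponse;
- seemingly innocuous cross-cycle drift corrupts pooled analyses: a level
  respelled `10th Grade` → `10th grade` becomes two factor levels, a
  variable silently changes units, a name is recycled for an unrelated
  measurement, or a subsample weight is renamed per file;
- any estimate must respect the stratified two-stage design (strata, PSUs,
  unequal sampling weights), including correct *domain* (subgroup)
  estimation.

`nhaneskit` packages this workflow for analysts and data engineers who need
it reproducible and testable offline: a synthetic fixture generator stands
in for the live upstream source, so every behaviour — including the QC
checks' ability to catch injected inconsistencies — is exercised end to end
without a network.

## What is inside

| Module | Role |
| --- | --- |
| `metadata_model` | Domain types for the three metadata tables (QuestionnaireDescriptions, QuestionnaireVariables, VariableCodebook) + VersionInfo, with the `metadata_tab` / `metadata_var` / `metadata_cb` accessors |
| `codebook_parser` | HTML documentation pages and manifests → metadata |
| `translator` | Raw coded tables → labelled tables; variable-kind classification; ordered category levels; special-code policy |
| `skiplogic` | Skip graphs, `get_skip_info`, interview simulation, structural-missingness classification, right-censoring transform |
| `qc` | `qc_var`, `qc_levels`, `qc_units`, `qc_name_reuse`, `qc_presence_matrix` cross-cycle checks with evidence partitions |
| `dbbuild` | Versioned SQLite snapshot with `raw` / `translated` / `metadata` namespaces; environment-discovery contract; byte-identical documentation pass-through |
| `survey_est` | Hájek mean, stratified with-replacement Taylor-linearized variance, t-based CIs, per-cycle series, PSU bootstrap cross-check, pooled-analysis guard |
| `fixtures` | Deterministic synthetic snapshot generator with injectable inconsistencies and ground truth |
| `cli` | `nhaneskit` command binding it all together |

The design-based mean for a subgroup (domain) `D` is the Hájek ratio
ȳ_w = Σ_{i∈D} w_i y_i / Σ_{i∈D} w_i, with Taylor-linearized variance under
the stratified with-replacement first-stage approximation

    z_i = w_i (y_i − ȳ_w) / Σ_{D} w   (z_i = 0 outside the domain),
    Z_hj = Σ_{i ∈ PSU j of stratum h} z_i,
    Var(ȳ_w) = Σ_h n_h/(n_h−1) Σ_j (Z_hj − Z̄_h)²,

and t-based intervals with df = #PSUs − #strata. Out-of-domain respondents
are retained in the design (their residuals zeroed), never dropped first.

## Worked example

Generate a three-cycle synthetic snapshot with one injected typographic
inconsistency, build the store, and analyse it:

```
$ nhaneskit make-fixture --seed 11 --out fx --inject level_variant:DMDEDUC3
wrote 15 tables under fx
$ nhaneskit build --manifest fx/manifest.tsv --docs fx/docs --data fx/data \
      --store snap.sqlite --version 0.1.0 --date 2024-01-16
built snap.sqlite: 15 raw, 15 translated tables
$ nhaneskit version --store snap.sqlite
CONTAINER_VERSION	0.1.0
COLLECTION_DATE	2024-01-16
```

The level-spelling check finds the injected variant and partitions the
tables by spelling — two early cycles use one form, the last the other:

```
$ nhaneskit qc levels DMDEDUC3 --store snap.sqlite
# nhaneskit 0.1.0 | CONTAINER_VERSION=0.1.0 | COLLECTION_DATE=2024-01-16
check_id	variable	severity	detail	variants
level_variant	DMDEDUC3	warn	level 'less than 5th grade' spelled 2 ways	'Less Than 5th Grade': EDU,EDU_B; 'Less than 5th grade': EDU_C
```

Skip-logic analysis of the smoking questionnaire shows which questions a
gate answer can skip (answer codes 2/7/9 at SMQ020 jump to SMD070):

```
$ nhaneskit skip-info SMQ --store snap.sqlite
SMQ020	always asked
SMD030	skippable	SMQ020=['2', '7', '9']
SMD055	skippable	SMQ020=['2', '7', '9']
SMD070	always asked
```

Finally, per-cycle design-based mean BMI for 40–59 year olds, each cycle
estimated independently with its own weights, strata and PSUs:

```
$ nhaneskit estimate --store snap.sqlite --value BMXBMI@BMX \
      --domain "40 <= RIDAGEYR <= 59" --weight WTMEC2YR \
      --strata SDMVSTRA --psu SDMVPSU --demo-family DEMO
cycle	mean	se	ci_low	ci_high	df	n
1999-2000	26.1103	0.6534	24.7177	27.5030	15	105
2001-2002	26.8097	0.6544	25.4149	28.2046	15	94
2003-2004	26.1668	0.5054	25.0896	27.2439	15	94
```

Each row is one cycle's Hájek mean with its linearized standard error and
95% t-interval (df = 30 PSUs − 15 strata); `n` is the number of in-domain
respondents. The synthetic population draws these cycles around a true
domain mean of 26.0/26.5/27.0, and each interval brackets its truth.

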