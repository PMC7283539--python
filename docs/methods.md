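# Methods

## Setting and model

A cohort of $N$ patients accrues clinical events (diagnoses, labs,
medication orders, encounters, NLP-derived physician diagnoses) over a
study window (default 2010-01-01 … 2017-12-31, closed on both ends). Every
event is tagged with the institution that recorded it; the same real-world
event recorded by two institutions shares a `linkage_key` (record linkage is
assumed already resolved — the package does no probabilistic matching). A
*view* is the event subset visible to one institution or to a union of
institutions; union views keep one representative per linkage key (earliest
date, ties to the lexicographically smallest source id). Every view carries
the **full cohort roster**: a patient invisible to an institution has an
empty feature vector, not a missing row. This fixed-universe convention is
what makes TP+FP+TN+FN equal the cohort size in every confusion row.

Because no chart-review gold standard is available in this setting, the
calls computed on the union of all sources serve as the benchmark, and each
single-source view is scored against it. The four reported percentages are
sensitivity TP/(TP+FN), specificity TN/(FP+TN), PPV TP/(TP+FP) and FNR
FN/(TP+FN); raw values are kept at full precision and rounded half-up only
in the report layer (default one decimal). Zero denominators yield a null
metric with a warning, never an exception.

## The two phenotyping algorithms

**RA (regression-scored).** Patients with ≥ 1 RA diagnosis code form the
inclusion cohort and are scored with a fixed logistic model over six counts
(RA, SLE, PA diagnoses; RF lab tests; positive RF results, i.e. value ≥ a
configured 15 IU/mL; encounters). Counts enter through `log1p` to temper
skew; the weight signs are structural — RA diagnoses and positive RF
positive, SLE/PA/encounters negative — and validated at model load. A
screened patient with probability ≥ the cutoff (default 0.632, inclusive by
convention) is a case. Controls are patients with no RA diagnosis codes and
no exclusion codes; screened non-cases and exclusion-code carriers are
"neither". The weights themselves are configuration, not a fit: the
original model's coefficients are not public, so the defaults are chosen to
respect the sign structure and to put the case boundary between "one
isolated RA code" and "repeated RA codes with supporting serology"
(roughly: case ⇔ ≥ 2 RA codes with a positive RF, or ≥ 4 RA codes). Model
*fitting* is deliberately out of scope — the package applies a published
model class, it does not retrain it.

**T2DM (rule-based).** Per-patient evidence is aggregated from the view:
T1DM/T2DM diagnosis counts (with the physician-asserted subset counted
separately; both physician-entered and NLP-derived entries qualify),
medication-class flags and earliest order dates, abnormal labs (fasting
glucose ≥ 126 mg/dL, random glucose ≥ 200 mg/dL, HbA1c ≥ 6.5% — standard
diagnostic thresholds, configurable), in-person visit and glucose-measure
counts, diabetes-related diagnosis and supplies flags, and the
self-reported family-history flag. The case rule is an ordered disjunction
of five paths (P1 dx+med without T1DM dx; P2 dx+abnormal lab without med;
P3 med+abnormal lab without dx; P4 both med classes with the T2DM order
first when T1DM dx present; P5 T1DM dx with insulin and ≥ 2
physician-asserted T2DM diagnoses). The exact branch order of the original
flowchart is not recoverable from text, so the path set is *declared in
configuration* (`t2dm_rules.yaml`) and can be amended without code changes;
the bundled set reconstructs the published factor structure. The control
screen is the six-way conjunction listed in the README; when both rules are
composed, a case label takes precedence. Medication-order precedence is
null unless both medication classes are present.

## Missing-information attribution

For an error set (e.g. the false-negative cases of one source), each factor
extractor is evaluated on both the source and the union view, and a subject
counts toward a factor when the union value exceeds the source value (for
the non-monotone medication-precedence fact, when the values differ). The
published-style layouts use the binary factor columns of the original
tables plus, for RA, the aggregate encounter shortfall; the `full=True`
factor sets compare every evidence field (including RA exclusion-code
counts) and are provably complete on simulated data: calls are
deterministic functions of the evidence, a single-source view's events are
a subset of the union's, and every evidence field is either monotone in the
event set or handled by the difference comparison — so a flipped call
implies at least one detected difference.

## Synthetic cohort generator

The generator emulates a biobank-style cohort served by one **home EHR**
("Mayo") and one **record-linkage source** ("REP") that aggregates regional
providers. Each event occurs at the home institution with per-patient
probability `p_home` (drawn from a Beta distribution, mean 0.8,
concentration 10 — modelling a mix of medical-home and transient/referral
patients), otherwise at an outside provider whose records land in the
linkage source. Directional duplication then copies home events into the
linkage source (rate 0.9) and a small share of outside records back into
the home EHR (rate 0.1, representing externally sourced problem-list
entries). The home view is therefore systematically less complete than the
linkage view, and their union is complete — the asymmetry the evaluation
measures. A symmetric two-peer model (each patient "belonging" to one of
two equal institutions) was considered and rejected at design time: with
peers, an institution's false-negative rate is dominated by the patients
homed at the *other* institution, and scattering events can *reduce* that
error, which contradicts the monotone fragmentation phenomenon the harness
is built to exhibit. Setting `duplication_rate` to the scalar 1.0 removes
fragmentation entirely (every view sees every event), the limit used as a
self-check.

Latent RA status (prevalence 620/45,183 ≈ 1.37%) and T2DM status (cases
5,215/45,183 ≈ 11.5%; control-eligibles 6,293/45,183 ≈ 13.9%) follow the
benchmark proportions of the study cohort the generator emulates. Disease
recipes give affected patients evidence that satisfies the corresponding
algorithm on the union view with probability ≈ 1 — RA cases draw
2 + Poisson(2) RA codes and 1 + Poisson(0.5) RF tests (positive with
probability 0.9, and guaranteed one positive when codes are sparse); T2DM
cases are a mixture over the five paths (80% dx+med, 8% dx+lab, 4% med+lab,
5% dual-therapy with T2DM medication dated first, 3% insulin plus ≥ 2
physician-asserted diagnoses). Boundary populations make the rules
fallible: isolated RA codes on 4% of unaffected patients, SLE/PA confusers,
exclusion-code carriers (0.5%), prediabetes codes, abnormal labs without
diagnoses, supplies orders, and a 55/30/10/5% mixture of control-screen
disqualifiers among T2DM-neither patients. Event counts are Poisson with
the configured means; lab values are truncated Gaussians around normal and
abnormal levels; encounters are 2 + Poisson(8) per patient (85% in-person)
— a deliberately scaled-down visit volume chosen so that simulated cohorts
stay small and fast while preserving the count-based behaviour of the
scoring model. All counts, rates and distributions are declared in
`SimulationConfig` so tests can assert them.

The generator emulates the *structure* of fragmented EHR data, not its
clinical texture: no visit-level realism, no ICD ontology coverage beyond
the default code lists, no free-text notes (NLP-derived diagnoses appear as
pre-extracted structured events), no temporal disease progression, and
independence between the RA and T2DM processes. Passing tests therefore
demonstrate correctness of the algorithms and of the evaluation machinery
under a faithful fragmentation mechanism — not performance on real records.

## Determinism and numerical choices

A single master seed drives three `SeedSequence`-spawned streams (truth,
events, fragmentation); identical config and seed reproduce byte-identical
CSVs. Sweep cohorts derive their seeds by spawning from the base seed.
Generation is fully vectorized; per-patient random streams were considered
and rejected as needlessly slow at these cohort sizes. Code-list matching
is case-insensitive with literal dots and suffix-only `*` wildcards — a
deliberately small dialect that keeps vocabularies declarative and
testable. Dedup tie-breaks, the inclusive cutoff, and half-up report
rounding are fixed conventions stated above.

## Problem sizes

The test suite simulates cohorts of 300–2,000 patients; the fragmentation
monotonicity check sweeps `p_home` over {1.0, 0.8, 0.6} with 20 replicate
seeds at 2,000 patients per cohort, sizes at which the mean single-source
case FNR separates cleanly (≈ 3% → 10% → 20% for RA, ≈ 3% → 8% → 15% for
T2DM). `scripts/acceptance.py` uses a 4,000-patient cohort. These sizes
were chosen as the smallest at which sampling noise is comfortably below
the effects being demonstrated.

## Known limitations

- Default code lists, model weights and lab thresholds are illustrative
  configuration, not validated clinical vocabularies.
- The benchmark-vs-source design measures *internal consistency* under
  fragmentation; it cannot detect errors shared by all sources (the union
  itself is imperfect relative to chart review).
- Confidence intervals on the reported percentages are out of scope, as is
  any probabilistic record linkage.
- With more than two sources the generator spreads non-home events
  uniformly and applies duplication pairwise; the two-source configuration
  is the tested, documented default.
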