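# Methods

This note records the model behind `rba-select`, the defaults it ships,
and the design decisions taken where the method leaves choices open.

## The selection model

A food risk–benefit assessment (RBA) compares health impact across
dietary scenarios — here a substitution between two foods — by summing
component-level effects in a common metric (DALYs). The package does
*not* run that health-impact model; it implements the step before it:
deciding, transparently, which components the model should include.

Selection proceeds through three tiers. The **long list** is the union
of both foods' component universes, with two nutrition-specific rules: a
nutrient quantified in only one food is always included, and a nutrient
present in both is included only when the relative concentration
difference exceeds a threshold. Hazards are all included — any
contamination found matters. An **evidence gate** drops components whose
component–outcome association is not rated *convincing* (ratings are
curated inputs; no literature retrieval happens here). The **short
list** cuts a per-domain ranking by prioritization index at an inclusive
threshold, and the **final list** keeps short-listed components whose
data-availability checklist is complete, after expanding nutrients
symmetrically to both foods.

Each stage writes one ledger entry per component × food it evaluates
(decision + reason), so the set relationships — output ⊆ input, input =
kept ∪ logged exclusions — hold exactly at every tier and are asserted
by tests.

## Scoring

All sub-criteria use three levels; every class→level map, bin edge and
combiner below is a config key (`RunConfig`), with the shipped defaults
forming the case-study profile.

**Nutrition** (index ∈ [1, 243], threshold 108). Occurrence: presence in
analyzed samples (<10% → 1, all samples → 3, otherwise 2; national
repository values override single-sample results on conflict) ×
processing effect (large reduction 1 / moderate 2 /
preserved-or-concentrated 3). Severity: policy relevance (neither FBDGs
nor fortification anywhere → 1, either in all countries → 3, partial
→ 2) × intake contribution × bioavailability reduction (significant 1 →
mild/none 3). Intake contribution prefers layer 1 (the food's average
contribution fraction to population intake, cut at tertiles 1/3 and 2/3,
bottom-closed: f ≤ 1/3 → 1, f ≤ 2/3 → 2, else 3) and falls back to a
layer-2 qualitative composition-difference class only when no intake
survey covers the food. The five levels are multiplied; the 2-vs-3
sub-criterion split deliberately weights severity 3/5 against occurrence
2/5, because nutrients are naturally present and obtainable from many
foods. 108 = 2·2·3·3·3 is an attainable product, and the threshold is
inclusive so the printed limit is itself selectable; 107, a prime, is
unattainable and appears in tests only as a below-threshold probe.

**Microbiology** (index ∈ [1, 9], threshold 2). Occurrence multiplies
prevalence (low/moderate/high → 1–3) by process effect
(reduces-or-eliminates 1 / neutral 2 / can-introduce 3), then bands the
raw product back to 1–3 (1–2 → 1, 3–4 → 2, 6–9 → 3). The banding is this
package's resolution of a genuine tension in the method: the occurrence
product alone spans 1–9, yet the final index — occurrence × severity
with equal weight — must also span 1–9, which is only possible if
occurrence re-enters the multiplication on the 1–3 scale. The band map
is configurable and recorded in the report's config snapshot. Severity
bins mean DALYs per 1,000 cases at <10 / 10–99 / 100–1,000, closed on
the left (exactly 10 → 2, exactly 100 → 3); values above 1,000 exceed
the printed scale and clamp to 3 with a warning. DALY-per-case inputs
are accepted and scaled ×1,000 on load.

**Toxicology** (index ∈ [1, 9], threshold 2). Presence-vs-reference-dose:
below LOD/LOQ → 1; above it, 3 when total exposure exceeds the HBGV
(non-genotoxic path) or the margin of exposure is below 10,000
(genotoxic carcinogens), else 2 — exactly one path is consulted, chosen
by the genotoxicity flag, and both exceedance indicators arrive as
curated booleans (computing them from exposure distributions is a
downstream RBA stage). Contribution to total dietary exposure: <10% → 1,
10–50% → 2 (both ends closed, so exactly 10% and exactly 50% score 2),
>50% → 3. The two occurrence sub-scores combine by ceiling-of-mean
(default; min/max selectable) — the same 1–3 compression rationale as in
microbiology. Severity counts four statements (high incidence, fatal,
lifelong disability, rounded disability weight > 0.4): ≤1 → 1, 2 → 2,
≥3 → 3, a symmetric default since no printed map exists; statements (c)
and (d) are scored independently even where they overlap for chronic
conditions.

### Numerical conventions

The 20% rule uses |a − b| / mean(a, b) by default — symmetric and
scale-invariant, which fits a substitution with no privileged food; max
and reference-food denominators are selectable. The inequality is
strict (> 0.20). Both concentrations zero is an undefined difference
and an error; a pair with a missing numeric value is kept (the numeric
rule applies only when both numbers exist). Ranking ties break by
severity score (descending) then component id — the method never ranks
ties, so a deterministic convention was invented, severity-first to
match the severity emphasis in the nutrition weighting. All scores are
integers; no fractional levels exist in the method.

## The packaged case study

The fixture encodes the beef-vs-cricket substitution: the component
universes, short-list and final-list membership, a data-availability
checklist, and an illustrative component→outcome tree. The study's raw
sub-criterion scores are in a non-public supplement, so every attribute
value in the fixture was **synthesized to be consistent** with the
published membership under the default config, and is flagged as such in
`data/novrba/metadata.yaml`. Regression tests therefore assert
*membership*, never the synthesized scores. The metadata also records
the places where the published tables disagree with each other (count
narratives vs enumerable rows; the chemical-hazard attribution of
inorganic arsenic, which the source short-lists under cricket but
finally lists under beef — impossible under the subset invariant, so the
fixture resolves both chemical candidates at the checklist gate and
stores the printed alternative reading as metadata).

## Synthetic data and what the tests show

The generator draws each sub-criterion level from a configurable
probability vector, then inverts the scorers to produce raw attributes
encoding exactly those levels (e.g. presence level 2 → detection
fraction 0.5; a toxicology presence level 3 on the genotoxic path → MoE
flag true). Defaults mirror the case-study scale (40 nutrients, 12
microbiological and 10 chemical hazards per scenario) with moderate
level spreads, 15% weak-evidence components, 25% single-food nutrients,
and concentration ratios drawn to fall clearly inside (≤1.2×) or outside
(≥1.3×) the 20% rule. Alongside the profiles it emits ground truth from
a straight-line oracle — literal if/else restatements of every default
rule, sharing no code with the engine — covering indices and all stage
decisions including symmetry and the checklist gate.

Engine-vs-oracle equality on ~1,400 components across seeds, plus a
closed-form check that the empirical short-list inclusion rate matches
the enumerated probability mass of {index ≥ threshold} (±3% at
n = 5,000), are the package's strongest correctness evidence. What they
show is internal consistency of the rule implementations; what they
cannot show is fidelity to real composition databases: synthetic
attributes sit at clean band midpoints, real data cluster near bin
edges, carry unit heterogeneity, and correlate across sub-criteria in
ways the generator does not model. The oracle also encodes *default*
thresholds and maps only — runs under a modified config are outside its
reach and are covered by the per-module unit tests instead.

## Known limitations

- Concentration units are checked for equality across the two foods but
  never converted.
- Evidence ratings, exceedance flags and checklist availability are
  curated inputs; the package does not retrieve or grade literature.
- The health-impact model itself (dose–response, exposure, DALY
  aggregation) is out of scope by design.
- Allergenicity and environmental/economic extensions are not
  represented.
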