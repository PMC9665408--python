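# rba-select

Tiered selection of the components — nutrients, microbiological hazards,
and chemical hazards — to include in a food **risk–benefit assessment
(RBA)**.

When a dietary substitution is assessed (the packaged case study replaces
minced beef with house-cricket, *Acheta domesticus*, powder), the first
modelling decision is *which* food components the health-impact model
should carry. Done ad hoc, that choice silently shapes the result.
`rba-select` implements a harmonized, auditable three-tier screen:

1. **Long list** — every component found in either food. Nutrients
   quantified in only one food are always kept (a substitution changes
   their intake by definition); nutrients present in both are kept when
   the concentration difference exceeds 20% (|a − b| / mean(a, b) > 0.20
   by default: 10% analytical tolerance plus a minimum meaningful 10%
   difference); *all* microbiological and chemical hazards are kept. An
   evidence gate then removes components whose link to a health outcome
   is not classified *convincing*.
2. **Short list** — components whose prioritization index clears an
   inclusive threshold, where

   *index = occurrence score × severity score*

   with each criterion built from graded 1–3 sub-criteria. Nutrition
   multiplies all five sub-criterion levels (2 occurrence × 3 severity,
   index ∈ [1, 243], threshold 108 — deliberately weighting public-health
   severity 3/5 against occurrence 2/5); microbiology and toxicology
   combine each criterion to a single 1–3 score (index ∈ [1, 9],
   threshold 2, identical for both foods and both hazard domains).
   Severity in microbiology bins the mean burden per 1,000 cases in
   disability-adjusted life years (DALYs: <10, 10–99, 100–1,000);
   toxicology counts four severity statements (high incidence, fatal,
   lifelong disability, disability weight > 0.4) and grades occurrence
   from LOD/LOQ presence, HBGV exceedance or margin of exposure < 10,000,
   and the food's share of total dietary exposure (<10, 10–50, >50%).
3. **Final list** — short-listed components for which the quantitative
   DALY model is feasible: dose–response, incidence, intake,
   composition/contamination and DALY-per-case data all available
   (plus source attribution in microbiology). Nutrients short-listed for
   one food are symmetrically considered for the other; hazards are not
   (a contamination belongs to one food).

Every inclusion and exclusion, at every tier, is recorded in an
append-only selection ledger with its reason — components lost to data
gaps must be reported alongside the assessment, not silently dropped.

## Worked example

Run the packaged beef-vs-cricket case study:

```python
from rba_select import load_novrba_fixture, run_pipeline
from rba_select.io import render_report_text

fx = load_novrba_fixture()
report = run_pipeline(fx.config(), fx.profiles_a, fx.profiles_b,
                      fx.checklist, fx.outcome_links)
print(render_report_text(report))
```

prints (excerpt):

```
Scenario: novrba
Foods: beef vs cricket

Long list: 75 components (73 after evidence gate)

Short list — microbiology / cricket:
    1. Cronobacter sakazakii                    index   6 (occurrence 2 x severity 3)
    2. Salmonella spp.                          index   4 (occurrence 2 x severity 2)
    3. Clostridium botulinum                    index   3 (occurrence 1 x severity 3)
    ...

Final list (22 component x food entries):
  microbiology  Bacillus cereus                          cricket
  microbiology  Clostridium perfringens                  beef
  ...
  nutrition     Calcium                                  beef  [added by symmetry]
```

Cricket-powder *Salmonella* scores occurrence 2 (moderate prevalence ×
process-neutral, banded) and severity 2 (50 DALYs per 1,000 cases falls
in the 10–99 bin), so its index is 4 ≥ 2 and it is short-listed; the
final list then keeps it because every checklist datum is available. The
final nutrient list is identical for both foods (seven nutrients —
calcium, insoluble fiber, iron, magnesium, sodium, vitamin B12, zinc)
because the symmetry rule evaluates each short-listed nutrient on both
sides of the substitution.

The same pipeline is scriptable from the shell:

```bash
rba-select fixture --out fx/
rba-select report --food-a fx/profiles_beef.csv --food-b fx/profiles_cricket.csv \
    --checklist fx/checklist.csv --out report.json
rba-select simulate --seed 7 --out sim/   # synthetic profiles + ground truth
```

Fixture attribute values are *synthesized to be consistent* with the
published list membership (the study's raw score table is not public);
see `src/rba_select/data/novrba/metadata.yaml` for provenance notes and
every place the published tables disagree internally.

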