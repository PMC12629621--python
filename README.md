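# psaguide

Guideline-concordant decision support for prostate-specific antigen (PSA)
testing, with the evaluation harness needed to measure it.

PSA testing is the cornerstone of early prostate-cancer detection, but the
two major guideline sets — the European Association of Urology (EAU) and the
American Urological Association (AUA) — run to hundreds of pages, disagree
on populations and intervals, and are applied inconsistently in primary and
outpatient care. `psaguide` implements a complete, deterministic,
offline-testable version of a retrieval-augmented decision-support workflow
for this task:

1. **Life-expectancy gate.** The age-adjusted Charlson Comorbidity Index
   (CCI) is computed from coded comorbidities and age, and converted to an
   estimated 10-year survival with the classic transform
   `P = 0.983^exp(0.9·CCI)`. Men aged over 72 years, or not expected to
   survive ten years (estimated survival < 0.50 by default), are not
   offered screening and short-circuit the pipeline. Both gates are
   configurable and can be disabled.
2. **Dual-guideline engine.** The EAU and AUA PSA-testing rules quoted in
   the accompanying fixture corpus are encoded in a versioned YAML rule
   file (elevation threshold ≥ 3.0 ng/mL, "moderately elevated" up to
   10 ng/mL → confirmatory repeat after a few weeks, EAU 2-year and AUA
   2–4-year routine intervals for ages 50–69, special handling of
   UTI-spurious elevations and abnormal digital rectal examinations).
   Separate answers are generated per guideline and then reconciled:
   concordant pairs merge (interval intersection), discordant pairs are
   both presented, labelled by source.
3. **RAG architecture.** Paragraph-aligned chunking of a tagged guideline
   corpus, per-guideline Okapi BM25 retrieval (k1 = 1.2, b = 0.75),
   deterministic prompt assembly (expert persona, chain-of-thought
   instruction, constrain-to-context directive, example output structure),
   and a minimal text-in/text-out backend contract. A deterministic mock
   backend (delegating to the rule engine) and a scripted replay backend
   make the whole pipeline testable offline; every run carries a stage
   trace and a constrain-to-context audit of cited rule identifiers.
4. **Evaluation harness.** Binomial grading against gold labels (correct
   if concordant with *either* guideline), a four-way error taxonomy
   (unnecessary: short interval / did not require; missed: long interval /
   failed to offer), study-style aggregation, Fleiss κ with an
   item-bootstrap CI, and accuracy comparisons (two-sample t and
   two-proportion z).
5. **Synthetic cohorts.** A seeded generator reproducing the study design:
   44 gold-labelled vignettes in five categories (11/9/9/8/7; a 20/24
   screening/follow-up split), plus a rating degrader to simulate
   imperfect clinician arms.

## Worked example

```bash
python examples/run_single_case.py
```

```
CCI score 2 (comorbidity 1 + age 1); estimated 10-year survival 0.901
gate: eligible
EAU: routine_interval interval=(24, 24) rules=['eau.normal_psa_routine_interval']
AUA: routine_interval interval=(24, 48) rules=['aua.normal_psa_routine_interval']
final (concordant): routine_interval interval=(24, 24)
```

A 57-year-old with uncomplicated diabetes scores CCI 2 (one comorbidity
point, one age point), giving an estimated 10-year survival of 0.90 — well
above the 0.50 gate. His latest PSA (2.4 ng/mL) is below the 3.0 ng/mL
threshold, so both guidelines recommend routine interval follow-up; the
EAU 2-year and AUA 2–4-year intervals reconcile to 24 months. The other
examples reproduce the published accuracy table
(`examples/evaluate_published_table.py`: 95.5% / 62.3% / 74.1% overall
concordance for the LLM, closed-book and open-book clinician arms, κ = 1.000
on the LLM arm, p < .001 for both comparisons) and run a full
simulate-grade cycle (`examples/simulate_and_grade_cohort.py`: 100%
mock-pipeline accuracy on an engine-labelled cohort).

## Command line

```bash
psaguide build-index --corpus src/psaguide/data/corpus --out index.jsonl
psaguide recommend   --case case.json --backend mock
psaguide simulate    --seed 7 --out sim/
psaguide batch       --cases sim/cases --backend mock --out results/
psaguide evaluate    --results results/ --gold sim/gold.csv --report report.csv
psaguide evaluate    --fixture table1 --report report.csv
```

Every artifact-producing run writes a `manifest.json` (command, parameters,
seed, version) sufficient to re-run it bit-identically with the
deterministic backends.

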