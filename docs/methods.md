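# Methods

## Scope and design

`psaguide` is a deterministic re-implementation of a retrieval-augmented
clinical decision-support workflow for PSA testing. The original workflow
used commercial LLM and embedding APIs with a vector database; this
package replaces those service dependencies with contracts that preserve
the architecture while making every stage reproducible and testable
offline: lexical BM25 retrieval instead of embeddings, a text-in/text-out
generation-backend contract with deterministic mock and scripted
implementations, and a plain-text fixture corpus carrying the guideline
rule statements the engine encodes. The deterministic rule engine is both
the reference answer generator (gold labels) and the mock backend's brain,
so the end-to-end mock pipeline is correct by construction and any
deviation observed in tests localises a defect in retrieval, prompting,
response parsing or reconciliation.

## Life-expectancy gate

The Charlson Comorbidity Index is the sum of condition weights (original
1/2/3/6 tiers over 19 conditions) plus age points (+1 per decade from
50–59 to ≥ 80). When both a mild and a severe form of one organ system are
coded (diabetes, liver disease, solid tumour), only the severe weight
counts. Estimated 10-year survival is `0.983^exp(0.9·score)`, clamped to
[0, 1]; it is strictly decreasing in the score.

Two gates follow, both configurable in `data/cci_config.yaml`:

* **age gate**: age strictly greater than 72 years refuses screening.
  The boundary is deliberately exclusive — a 72-year-old may still be
  blocked, but by the survival gate, never by age.
* **survival gate**: estimated survival below 0.50 refuses screening.
  "Expected to live at least 10 years" is operationalised as
  P(survive 10 y) ≥ 0.50; no probability cutoff is standard in the
  guidance, and 50% is the natural reading of "expected". The threshold
  is a config value, and the whole gate can be disabled (clinician
  discretion), in which case every case proceeds.

The age gate is evaluated first; both reasons are reported when both
fail. The weight table is data, not code, so an alternative comorbidity
calculator (e.g. an updated weight revision) can be substituted without
touching the engine.

## Rule engine

The engine interprets `data/rules.yaml` with a fixed priority order: gate
refusal → abnormal-DRE referral → UTI-spurious-elevation deferral →
elevated-PSA workup → age-band screening rules. Key parameters:

| parameter | default | unit | anchor |
|---|---|---|---|
| PSA elevation threshold | 3.0 | ng/mL | most commonly applied EAU cutoff |
| "moderately elevated" upper bound | 10.0 | ng/mL | confirmatory-repeat range |
| EAU routine interval | [24, 24] | months | 2-year follow-up |
| AUA routine interval | [24, 48] | months | 2–4 years, ages 50–69 |
| routine band | 50–70 (EAU) / 50–69 (AUA) | years | guideline age bands |
| risk-adapted start | 45 (family history, African ancestry), 40 (BRCA) | years | extension |
| gate age limit | 72 | years | exclusive bound |
| gate survival threshold | 0.50 | probability | design choice |

A first moderate elevation (3–10 ng/mL) yields a confirmatory repeat
after a few weeks; a second reading ≥ 3.0 ng/mL in the history counts as
confirmation and yields referral, as does any value > 10 ng/mL. A value
*below* 3.0 ng/mL can never yield a confirmatory repeat — this is the
regression-tested behaviour on the worked failure case (55 years,
PSA 2.8 ng/mL), where a generative backend once hallucinated "moderately
elevated" and recommended an unnecessary repeat.

Rules the source material does not state (men under 50 or over 69 with
risk factors; the EAU band upper edge at 70) are marked as extensions in
the rule file; they exist so that every case category receives a
well-defined action.

Reconciliation: per-guideline answers are concordant when actions are
equal and (for interval recommendations) intervals overlap; the merged
final action carries the interval intersection and is labelled with a
`combined` source (the source enum is extended with this member precisely
for merged finals). Discordant answers are both presented, each labelled
by its guideline — matching the behaviour of presenting both
recommendations when the societies disagree.

## RAG pipeline

* **Chunking**: paragraph-aligned greedy packing to a 300-token target
  with a 50-token paragraph overlap (both configurable; the source
  pipeline's values are unstated). Chunk ids are content hashes, so
  chunking is stable across runs. Paragraphs may open with bracketed rule
  identifiers that are stripped into chunk metadata.
* **Retrieval**: Okapi BM25, k1 = 1.2, b = 0.75, idf = ln(1 + (N − df +
  0.5)/(df + 0.5)). Statistics (df, average length) are computed within
  each guideline namespace, so one index with a source filter behaves
  identically to two physical indexes — the per-guideline
  answers-then-combine design. Ties break on chunk id. Default k = 6
  with min_score = 0, which on the small fixture corpus retrieves every
  chunk of a source; context filtering matters for larger corpora and is
  exercised in tests via `min_score`.
* **Prompts**: a slotted text template (persona, source, case JSON,
  context blocks, reasoning instruction, output-schema example). The
  example output parses under the strict response parser, and rendering
  is byte-deterministic.
* **Backends**: any callable `str -> str`. Responses must be one strict
  JSON object (action, optional interval, cited rules, reasoning);
  unparseable responses raise a parse error carrying the raw text,
  distinct from backend failures. The mock backend re-reads the case and
  source out of the prompt and delegates to the rule engine; the scripted
  backend replays canned responses keyed by (case id, source).
* **Audit**: the pipeline trace records every executed stage; a
  constrain-to-context check flags any cited rule identifier without a
  retrieved supporting passage. Gate-refused cases short-circuit before
  retrieval and never reach a backend (asserted via trace in tests).

## Evaluation

Grading is binomial: a response is correct if any presented final action
matches any acceptable per-guideline answer (action equality; interval
overlap where both sides carry intervals). Incorrect responses receive
exactly one subtype by comparing the response's *implied test window*
(offer now = 0 months; confirmatory repeat ≈ 1–2 months; treat-UTI-then-
repeat ≈ 2–3 months; interval recommendations carry their own window;
referral and no-testing imply no PSA test) against the acceptable
windows: entirely earlier → unnecessary short interval; entirely later →
missed long interval; test offered when none acceptable → unnecessary
did-not-require; no test offered when one acceptable → missed
failed-to-offer. Overlapping-window action mismatches classify by
direction of the lower bound. Whether the original graders required
interval agreement or action agreement only is unspecified; interval
overlap is this package's explicit, documented choice.

Fleiss κ uses pooled category proportions ((P̄ − P̄e)/(1 − P̄e), via
statsmodels) and raises an explicit undefined-agreement error when every
rating falls in a single category (P̄e = 1) rather than returning a
number. The κ confidence interval is a nonparametric percentile bootstrap
over items (default B = 1000, seeded); degenerate resamples are skipped
and counted, and more than 50% degenerate is an error. The published
CIs of width ≈ 0.006 on 44 items are not reproducible by any standard
method and are not a target. Accuracy comparisons provide the two-sample
Student t test on 0/1 outcomes (the original analysis choice) and a
two-proportion z test (the statistically conventional default); on the
shipped fixture both agree qualitatively (p < .001).

The published-table fixture stores per-arm × category error-subtype
*counts* only (one cell's printed percentage is typographically
inconsistent; counts are internally consistent and are what the fixture
guarantees). Cells are filled case-major lexicographically: this places
the LLM arm's two all-five-raters error cases on one item each, making
its rating matrix unanimous per item (κ = 1 with both categories
present), while the human arms' within-category layout is arbitrary — κ
computed on the human fixture arms is therefore meaningless and is
asserted nowhere.

## Synthetic cohorts

The generator emulates the study design, not real patients: category
counts 11/9/9/8/7 (screening 20 / follow-up 24), per-category case
designs (eligible 50–69-year-olds without PSA history; age-gate and
survival-gate failures; normal-PSA follow-up < 3.0 ng/mL; unconfirmed /
confirmed / marked elevations in a 4/2/2 split; UTI-spurious, comorbid-
elevated and abnormal-DRE-normal-PSA "others" in a 3/2/2 split). Ages and
PSA values are drawn uniformly within clinically plausible per-design
ranges. All randomness flows from one seed through per-category
`SeedSequence` children; cohorts are bit-reproducible. Gold labels are
derived by running the rule engine, with bounded re-sampling until each
case satisfies its category's defining constraints; an unsatisfiable
configuration (e.g. gate-failure cases requested with the gate disabled)
raises after 50 attempts.

Because gold comes from the engine, passing end-to-end tests establish
internal consistency of the pipeline — they do not validate the rule
encoding against clinical judgment, do not expose the free-text-
interpretation errors a generative backend can make (those are injected
explicitly via the scripted backend and `degrade_ratings`), and do not
model the case-mix or ambiguity of real clinical vignettes. The `free_text`
field is carried but never parsed by the deterministic core.

## Numerical and degenerate-input choices

* Survival values are clamped to [0, 1]; negative CCI scores are domain
  errors.
* Interval intersection is used for overlapping concordant intervals;
  disjoint equal-action intervals are treated as discordant.
* Empty corpus documents produce zero chunks with a logged warning;
  retrieval from a source with no chunks is an error, as is k < 1.
* Identical zero-variance arms compare with p = 1 rather than NaN.
* Percentages are reported on the cases × raters denominators
  (e.g. 220 = 44 × 5 overall).

## Problem sizes

The shipped corpus is two documents (~700 words) chunking to three
chunks; cohorts are 44 cases; the evaluation fixture is 3 × 220 ratings;
bootstrap defaults to 1000 resamples. The full test suite and the
acceptance script each run in a few seconds on one CPU.
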