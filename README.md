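# cdmbench

A simulated clinical decision-making (CDM) environment and scoring stack
for evaluating diagnostic agents — language models or scripted policies —
on emergency-department abdominal-pain cases.

## The problem

Medical question-answering benchmarks hand a model all of the relevant
information upfront and ask for one answer from a list. Real clinical
decision-making is different: a clinician starts from a patient's history
of present illness (HPI) and must decide *which* information to gather —
physical examination, laboratory tests, imaging — before committing to a
diagnosis and treatment plan. An agent that is to be trusted anywhere near
that workflow must also follow diagnostic guidelines, recommend
appropriate treatment, interpret laboratory values against their
reference ranges, follow output-format instructions, and stay robust to
changes in prompt phrasing, information order and information quantity.

`cdmbench` implements that evaluation end to end for four common
abdominal pathologies — **appendicitis, cholecystitis, diverticulitis and
pancreatitis** — which share a chief complaint (acute abdominal pain) but
are separable with standard diagnostic tests:

- **Interactive CDM task** — the agent sees task instructions plus the
  HPI only, and iteratively requests `Physical Examination`,
  `Laboratory Tests` or `Imaging` until it issues a
  `Final Diagnosis` and `Treatment`. Free-text requests are mapped to
  canonical tests through a synonym/panel dictionary (unmatched requests
  return `NA`) and to (modality, region) pairs through keyword lists
  (`MRCP` → MRI abdomen, and so on). Format deviations never crash an
  episode; they are tallied as next-action errors, tool hallucinations
  and diagnosis format errors. A pluggable token budget (default 4,096
  tokens ≈ 2,400 words) triggers stepwise summarization of gathered
  observations and, once everything is summarized, a forced diagnosis.
- **Full-information (FI) task** — single-shot diagnosis with HPI,
  physical exam, guideline-relevant labs and abdominal imaging presented
  upfront, the substrate for the robustness experiments (instruction
  rephrasing, removal of system instructions or medical terminology,
  single-exam ablations, all 6 orderings of exam/labs/imaging with HPI
  fixed first, abnormal-labs-only filtering, summarization ablation).
- **Scoring** — per-class diagnostic accuracy (correct diagnoses over
  all patients of one pathology; only the *first* diagnosis mentioned
  counts, and descriptive findings such as plain "gallstones" do not);
  guideline adherence (at least one test requested from each required
  category, e.g. pancreas enzymes for pancreatitis); treatment
  appropriateness (essential treatments always expected, case-specific
  treatments only for patients who actually received the matching
  procedure, scored only on correctly diagnosed cases); laboratory
  interpretation (below/within/above the reference range, inclusive
  bounds); Welch two-sided t-tests with Bonferroni correction for group
  comparisons.
- **Dataset builder** — constructs case stores from MIMIC-IV-style
  relational tables: ICD filtering to exactly one target pathology,
  primary-discharge-diagnosis check, discharge-summary section
  extraction, a 24-hour pre-admission inclusion window for labs and
  radiology (first entry per repeated test; findings sections only),
  exclusion of cases without labs, physical exam or abdominal imaging,
  and censoring of residual diagnosis mentions to `___`. Every stage
  reports telescoping counts and per-admission exclusion reasons.
- **Synthetic generator** — deterministic template cases, raw tables
  (with optional planted rule violations), interpretation items and
  scripted agents, so the whole stack is testable with no data access.

Agents are plain callables `(prompt, stop_phrases) -> response`; real LLM
backends plug in behind that contract.

## Worked example

Score the guideline-following scripted agent on a synthetic cohort:

```python
from cdmbench import (GuidelineSpec, EnvConfig, run_episode,
                      score_episode, aggregate_scores, load_default_lexicons)
from cdmbench.synthetic import generate_cases, omniscient_script, scripted_agent

lab_lex, imaging_lex, dx_lex = load_default_lexicons()
guideline = GuidelineSpec.from_yaml()
config = EnvConfig(lab_lexicon=lab_lex, imaging_lexicon=imaging_lex)

cases = generate_cases(5, seed=2023)
scores = []
for case in cases:
    agent = scripted_agent(omniscient_script(case, guideline))
    episode = run_episode(case, agent, config)
    scores.append(score_episode(episode, case, guideline, dx_lex))

table = aggregate_scores(scores)
print(table[["pathology", "n", "diagnostic_accuracy", "pe_first_pct",
             "category_inflammation_pct"]].to_string(index=False))
```

```
     pathology  n  diagnostic_accuracy  pe_first_pct  category_inflammation_pct
  appendicitis  5                100.0         100.0                      100.0
 cholecystitis  5                100.0         100.0                      100.0
diverticulitis  5                100.0         100.0                      100.0
  pancreatitis  5                100.0         100.0                      100.0
```

Each row is one pathology: `diagnostic_accuracy` is the per-class percent
of correct first diagnoses, `pe_first_pct` the percent of episodes whose
first action was a physical examination, and the category column the
percent of episodes that requested at least one inflammation-marker test
(WBC or CRP). An agent that requests every required category, images the
abdomen and names the gold pathology scores 100 everywhere — the scoring
stack's calibration point.

The same workflow is scriptable from the shell:

```bash
cdmbench generate-synthetic --out cases.jsonl --n-per-pathology 5
cdmbench run-cdm --cases cases.jsonl --out episodes.jsonl --agent omniscient
cdmbench evaluate --episodes episodes.jsonl --cases cases.jsonl \
    --out scores.jsonl --aggregate-out aggregate.csv
```

To rebuild a case store from raw MIMIC-IV-style tables (real,
credentialed exports or the synthetic ones written by
`generate-synthetic --raw-tables-dir`):

```bash
cdmbench build-dataset --mimic-dir tables/ --out cases.jsonl --report-out report.json
```

## Layout

| Module | Role |
| --- | --- |
| `cdmbench.records` | Case/episode data model, JSONL case stores |
| `cdmbench.lexicon` | Lab synonym/panel, imaging keyword and diagnosis matchers |
| `cdmbench.builder` | Raw-table → case-store pipeline, FI prompt assembly |
| `cdmbench.synthetic` | Synthetic cases, raw tables, interpretation items, scripted agents |
| `cdmbench.environment` | Interaction loop, turn parsing, budget/summarization |
| `cdmbench.evaluation` | Scoring rules, interpretation, statistics |
| `cdmbench.experiments` | Robustness variants and the run matrix |

All lexicons, guideline categories, treatment keywords, ICD code sets and
reference ranges ship as editable YAML under `src/cdmbench/data/` and are
deliberate reconstructions of standard clinical vocabulary — swap in your
own with the `--*-lexicon` flags or the `from_yaml(path)` constructors.
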