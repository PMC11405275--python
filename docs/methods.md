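# Methods

## The simulated clinical environment

One episode models one emergency-department encounter. The agent is
prompted with task instructions and the patient's history of present
illness (HPI) and then alternates with the environment: each agent turn
states its thoughts and either requests information or terminates with a
final diagnosis and treatment plan. Responses are truncated at the first
occurrence of an observation marker (`Observation:`/`Observations:`,
case-insensitive), the point past which a generative model would start
hallucinating the result of its own request.

Three tools exist: physical examination, laboratory tests, imaging.
Serving rules:

- *Physical examination* returns the entire exam text regardless of the
  action input — a complete exam is best practice, and exam reports are
  too free-form to slice reliably.
- *Laboratory tests* are matched against a synonym dictionary
  (normalize → exact alias → panel name → longest alias substring, ties
  to the longest alias). Panels expand to their members. Each matched
  test renders as name, value, unit and reference range; anything
  unmatched or unavailable renders `NA`.
- *Imaging* requests are classified to (modality, region) by uniquely
  identifying keyword lists, with special-exam mappings (MRCP → MRI
  abdomen, CT urography → CT abdomen, KUB → radiograph abdomen) applied
  before the keyword scan. Repeated requests for the same combination
  walk the case's reports in chart order, one per request; exhaustion is
  reported explicitly.

Format deviations are tolerated and tallied, never fatal: a tool named in
prose without an `Action:` field is still served (free-text action), an
unknown tool draws a reminder of the available ones (tool hallucination),
and a final turn missing its required fields is a diagnosis format
error. This mirrors how such an agent would have to be supervised in
practice: the information flows, but every deviation costs.

### Token budget and summarization

Agents are assumed context-limited. The default budget is 4,096 tokens
with a word-based counter (words × 1.71, the 4,096-token ≈ 2,400-word
ratio) standing in for a real tokenizer, which can be plugged in. When
the conversation exceeds 90% of the limit (configurable), gathered
observations are summarized one at a time, oldest first, through the
agent's own summarizer — the instructions and HPI are never touched.
If everything is summarized and the conversation still approaches the
limit, the environment forces a diagnosis. A hard guard additionally
trims words from the newest summarizable spans so that every prompt
handed to the agent fits within limit minus a 25-token / 20-word reserve
for the diagnosis itself. Episodes are also capped at 15 actions
(configurable) so non-terminating agents still end in the forced path.

## Dataset construction

The builder consumes per-admission bundles of MIMIC-IV-shaped records
(also readable from CSV tables) and applies, in order: (1) ICD filtering
— keep admissions coded for exactly one of the four target pathologies
(code-prefix matching, dot-insensitive; configured families K35/540,
K81/575, K57/562, K85/577.0); (2) the primary-discharge-diagnosis rule —
the very first diagnosis listed in the discharge summary must be the
candidate pathology, else the admission is dropped (this mechanizes what
would otherwise be a manual chart review; the check reuses the diagnosis
matcher, so "1. Sepsis 2. Cholecystitis" fails); (3) section extraction
by configurable header patterns, dropping admissions whose HPI already
names the pathology (mostly transfers with an established diagnosis) or
that lack a physical exam; (4) collection of labs, microbiology and
radiology within the admission plus a window closed on both ends of
24 hours before admission for unlinked events — and only if the event is
not attributable to another admission of the same patient. Repeated
tests keep the chronologically first entry (ties by source row order) to
model a therapy-naive presentation; microbiology gets the same
first-entry rule. Radiology keeps only the findings section; impression
and conclusion sections contain the radiologist's diagnosis and would
trivialize the task. (5) Final cleaning drops admissions without labs or
abdominal imaging and censors any residual mention of the gold pathology
to `___`, MIMIC's censoring mark.

Every stage records in/out counts that telescope exactly, plus one
exclusion reason per dropped admission — the QC surface the tests pin
down with planted single-violation fixtures.

### Full-information prompts

The FI record presents, in order: HPI, physical examination, laboratory
results, abdominal imaging sorted by chart time. Laboratory results are
restricted to the union of all pathologies' guideline categories — the
tests relevant to the diagnosis and to ruling out its differentials.
Overflow handling is staged: summarize each report individually, then
all imaging at once, then delete words from the end of the final imaging
summary until the diagnosis reserve fits. A failing summarizer falls
through to word deletion.

## Scoring

*Diagnosis.* The final-diagnosis text is segmented at list markers,
newlines, semicolons, sentence breaks and "and"/"with" joins; only the
first segment is scanned, case-insensitively and at word boundaries, for
the gold pathology name or a configured medically equivalent phrasing.
Later mentions never rescue a wrong first diagnosis, and descriptive
findings without the inflammatory condition (plain "gallstones" for
cholecystitis) do not count. Per-class accuracy — correct diagnoses over
all patients of one pathology — is the only headline metric, because a
four-disease dataset has no realistic negative class from which to count
false positives.

*Guideline adherence.* Each pathology requires test categories
(inflammation for all four; liver/gallbladder function for
cholecystitis; pancreas enzymes and severity markers for pancreatitis);
a category is met when at least one member was requested. Physical-exam
ordering is recorded as PE-first (the first parsed action turn, format
errors included, requests PE) and PE-at-all. Imaging requests are
recorded but never penalized.

*Treatment.* Scored only on correctly diagnosed cases — a wrong
diagnosis makes the plan moot. Essential treatments (e.g. antibiotics;
supportive care) are always expected; case-specific treatments
(appendectomy, cholecystectomy, colectomy, drainage, ERCP) only for
patients who actually received the matching procedure, matched by
keyword or ICD-procedure-code predicates over the procedure records.
Supportive care is fluids / pain management / monitoring: any one
mention suffices for appendicitis, cholecystitis and diverticulitis; all
three are required for pancreatitis, where support is the mainstay of
treatment. Mentions are surface keyword matches with a small negation
guard (a keyword within a few words of "no/not/without/avoid/hold" does
not count).

*Laboratory interpretation.* A value is below/within/above its reference
range with inclusive bounds; a missing bound disables the corresponding
label; non-numeric values are not classifiable. The interpretation task
pairs this classifier against generated items with known labels,
including exact-boundary values.

*Statistics.* Group comparisons use Welch's two-sided t-test
(unequal variances) with Bonferroni correction, p_corr = min(1, p·m).
Two zero-variance samples with equal means compare at p = 1.

## Synthetic data

The generator is the test bed, not a clinical simulator. Each case is
drawn deterministically from (pathology, severity, seed) — seed 2023 is
the default everywhere. HPI and exam texts come from fixed per-pathology
templates with sampled age/sex/duration and never name the diagnosis;
labs are drawn uniformly inside standard adult reference ranges except
the pathology-typical derangements (e.g. lipase several-fold above its
upper limit for pancreatitis, cholestatic liver enzymes for
cholecystitis), placed strictly outside the range so the declared
direction is recoverable from the data; one abdominal report carries
pathology-consistent descriptors (a dilated appendix, gallbladder wall
thickening with a sonographic Murphy sign, sigmoid diverticula with fat
stranding, an edematous pancreas) plus a normal chest radiograph;
complicated profiles add the matching case-specific procedures
(colectomy for perforated diverticulitis, drainage of pancreatic
necrosis) and their report add-ons. Raw-table generation wraps the same
components into discharge summaries, event tables and radiology notes,
optionally planting admissions that each violate exactly one exclusion
rule; it also duplicates one lab later in the stay to exercise the
first-entry rule.

What the generator does not model: clinical prose style, comorbidity,
demographic structure, missingness, label noise, or ambiguous
presentations. Passing tests therefore demonstrate that the machinery —
parsing, serving, windowing, scoring, statistics — is correct, not that
any agent's score on synthetic cases predicts performance on real
records.

## Numerical and design choices

- Word-count token counter (× 1.71) by default; monotone under
  concatenation as the budget logic requires.
- "Approaching the limit" = 90% of the budget; unstated upstream, kept
  configurable.
- Turn cap 15 actions; prevents non-termination without constraining
  realistic episodes.
- Chronological ties (repeated labs, same-time reports) break by source
  row order.
- The 24-hour pre-admission window is closed on both ends.
- Lab values that arrive as text keep the raw string; a numeric view is
  derived only when the string parses as a plain number.
- Episode scoring counts an agent failure as an incorrect diagnosis
  rather than excluding the case (configurable in the run matrix, where
  failed cells are flagged but still aggregate).
- Lexicon content, guideline categories, treatment keywords, ICD code
  sets and reference ranges are editable YAML reconstructions of
  standard clinical vocabulary, built to be replaced wholesale by a
  site's own dictionaries.
- Problem sizes in the test and acceptance runs (200 episodes, 100-case
  omniscient cohort, 1,000-lab filter check, 3,000 interpretation items,
  100 Welch pairs) were chosen as the smallest sets that exercise every
  rule and boundary while keeping the suites fast on one CPU.

## Known limitations

- The shipped prompt templates paraphrase the task structure; site- or
  model-specific instruction text should replace them via `EnvConfig`.
- Diagnosis matching is lexical. A semantically correct diagnosis
  phrased outside the configured alternatives scores as wrong; the
  phrasing lists are deliberately small and editable.
- Treatment scoring is keyword-level with only a local negation guard;
  it does not parse dosages, sequencing or conditional plans.
- The imaging vocabulary covers CT, ultrasound, MRI and radiographs;
  nuclear-medicine exams (e.g. HIDA scans) are unclassifiable and
  dropped with a logged reason.
- Real-data reconstruction (credentialed MIMIC-IV exports) exercises the
  same code path as the synthetic tables but is necessarily untested
  here; header patterns and code sets may need adjustment against real
  discharge-summary variants.
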