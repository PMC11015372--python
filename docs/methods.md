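# Methods

## Pipeline model and assumptions

The package treats clinical feature extraction as a staged mapping from a
corpus of sectioned admission notes to a records × questions matrix. The
core assumptions are:

- **Notes are strongly sectioned.** Position-based pre-extraction relies on
  each record exposing the canonical sections (chief complaint; present,
  past, personal, family, menstrual-obstetric histories). Anchors resolve
  either to a section key or to (part of) the section's Chinese header.
- **Concept mentions are surface-recoverable.** Concept-sentence
  pre-extraction uses substring matching over synonyms (whitespace-collapsed,
  case-folded for Latin text), not tokenization or NER. This is exact and
  language-robust for CJK text but cannot bridge paraphrase; the synonym
  list is the lever for recall.
- **One model call per cell.** Cells are independent; the matrix is always
  complete, with failures and undecodable answers stored as nulls carrying
  error notes rather than aborting a run.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| temperature | 0.0 | greedy decoding; extraction should be deterministic |
| max_tokens (Q&A) | 20 | answer cap; short decisive answers, faster inference |
| concurrency | 3 | requests in flight; throughput optimum is hardware-specific |
| retries / backoff | 3 / 1 s exponential | transport errors only; protocol errors surface immediately |
| frequency threshold | 0.05 | strict record-level prevalence cut (*p* > 0.05); guideline terms bypass |
| allowed domains | Clinical finding, Observable entity | vocabulary filter |
| empty-context policy | negative_by_absence | see below |
| annotation subset | 1500 records | accuracy/precision denominator |

Binary answers are decided by configurable token lists (有/是/阳性/yes …
vs 没有/无/否/未/不/阴性/no …). Matching picks the **earliest** token
occurrence, preferring the **longest** token at equal position and positive
before negative only as a final tie-break. A naive positive-first scan
would misread 没有 ("not have") as positive via its trailing 有; the
earliest-longest rule resolves this without any language model. Latin
tokens match on word boundaries so "no" never fires inside "normal".

Null detection fires on: empty trimmed output; output with no letter,
digit or CJK character; any character repeated ≥ 8 times consecutively; or
text overrunning an explicit length bound. The repetition/symbol heuristic
is an operationalization of "meaningless output" and is deliberately
conservative — unexpected but well-formed text is *not* null, it simply
fails token matching (binary cells then also become null, by construction
of the cell vocabulary).

## Rounding and reporting conventions

Accuracy and precision are reported as percentages rounded half-up to one
decimal; ratio columns (positive/negative/null) and macro means to two.
Binary column ratios are exhaustive and exclusive, so each column sums to
100.00 within rounding (±0.02). Precision is undefined when a column has
no positive predictions; such columns are excluded from the macro
precision mean rather than scored zero, to avoid penalizing rare concepts
(micro averaging, which pools counts instead, is available via
`averaging="micro"`). Note that a few published per-question accuracy
fractions do not survive exact division at one decimal (e.g. 909/1500 is
60.6%, not 60.7%); this package always reports the exactly computed value.

## The synthetic generator

`qascale.synthetic` emulates Chinese obstetric admission narratives: a
gestational-age chief complaint plus per-concept template sentences placed
in the concept's home section. Ten default concepts cover symptoms
(headache 10%, abdominal pain 45%, vaginal bleeding 30%, edema 15%,
dizziness 7%), personal/past/family histories (drug allergy 10%, surgery
35%, family hypertension 4%), a menstrual item (dysmenorrhea 22%) and one
quantity (pregnancy weight gain, normal mean 13.7 kg, SD 5 kg truncated at
0 — the SD chosen as a clinically plausible spread for a per-record
measurement). Every template contains the concept synonym verbatim, so
concept-strategy recall is 1 on clean data and an oracle-backed run must
reproduce gold exactly — the pipeline's calibration point.

Negative draws are written as **explicit denials** (无X / 否认X) by
default, reflecting the pertinent-negative convention of Chinese admission
histories. The `omission_ratio` knob instead leaves a fraction of
negatives unmentioned; those cells then exercise the empty-context policy.
The default policy, `negative_by_absence`, answers binary questions
negative without a model call when both pre-extraction strategies come
back empty — mirroring the clinical convention that unmentioned findings
are absent. This is a modeling choice, not a fact about notes: with heavy
omission it inflates accuracy on truly-negative cells (they never pass
through the noisy model) and deflates it when absence is not ignorable.
The alternative `full_text` policy asks the model over the whole record.

What the generator does **not** emulate: free-form paraphrase, intra-record
contradictions, temporal qualifiers, misspellings, or documentation/recall
bias (systematic under-reporting can be approximated by setting a concept's
prevalence far below its real-world rate, which is how a paternal-smoking
style discrepancy would look). Passing tests therefore demonstrate the
pipeline's mechanics — aggregation arithmetic, filtering, pre-extraction
fidelity, normalization, metric computation, concurrency/seed determinism —
not model quality on real clinical language.

## The mock backend's noise channel

The scripted mock corrupts its gold-derived answer using a single uniform
draw per (record, question) key, seeded independently of call order, so
results are bit-identical across concurrency settings. The channel is
**nested**: `flip_rate` ε is the *total* corruption probability, and empty
outputs (`null_rate` ν) plus gibberish are realized within it — outcomes
are null with probability ν, gibberish with probability
η·(prompt chars)/100 (capped), flipped otherwise up to the total error
mass max(ε, ν + η_eff). Consequently a run with ε = 0.10, ν = 0.02 has
expected accuracy 0.90 and null ratio 0.02 — the two knobs read directly
as an error rate and a null rate, rather than compounding. The
context-length scaling of the gibberish channel makes long-context
degradation reproducible: with pre-extraction the prompt is short and the
effective rate low; over full notes it is strictly higher for every cell,
and because the same uniform drives both runs, the full-text error set is
a superset of the snippet error set — the ablation's accuracy ordering is
deterministic at any seed.

## Numerical and degenerate-input choices

- Sentence segmentation splits on 。！？!?;；and newline, terminators
  attached to the preceding sentence; the split is lossless (concatenation
  reconstructs the section), and delimiter-only runs form their own
  sentences so offsets always tile the text.
- Snippet union deduplicates by (section, start) and orders by document
  position; `combine` is commutative and idempotent.
- The 5% frequency cut is strict (> 0.05, not ≥); the boundary reading is
  ambiguous in prose, so the threshold and the comparison are config-exposed.
- Numeric answers parse the first decimal number in the raw text and drop
  non-finite values; numeric correctness uses an absolute tolerance of 1e-6.
- Rounding is decimal half-up (not banker's), matching how report tables
  are conventionally printed.
- Degenerate inputs: empty corpora, empty batches, zero-row fixtures and
  oversized annotation subsets raise typed errors; garbage concept output
  parses to an empty list rather than raising.

## Problem sizes

The shipped acceptance computations use a 2,000-record × 10-question
synthetic corpus with a 1,500-record annotated subset (noise checks use
3σ binomial margins at those sizes), and a 300-record corpus for the
ablation comparison. These sizes give sub-percent standard errors on the
recovered rates while keeping any single run in the seconds range.

## Known limitations

- Strategy-1 anchors must be declared per question; there is no learned
  section classifier.
- Substring synonym matching cannot resolve negation scope by itself; it
  relies on the model reading the extracted sentence.
- The vocabulary table ships as a small illustrative CSV; real deployments
  should point the config at a full licensed terminology export.
- The HTTP backend is synchronous and non-streaming by design; throughput
  scaling beyond bounded thread concurrency is out of scope.
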