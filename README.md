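# qascale

`qascale` turns free-text patient admission records — a chief complaint plus
sectioned medical histories (present, past, personal, family,
menstrual-obstetric) — into an analyzable 2-D **question-and-answer feature
matrix** using a chat-completion language model, and evaluates the result.
It is aimed at clinical researchers who need cohort-level features out of
unstructured Chinese (or English) admission narratives without manual field
extraction.

## The method

Instead of one monolithic prompt, the extraction path is modular:

1. **Concept preparation** — the model lists clinical concepts per record
   (prompt A); concepts are merged at record level and retained only when
   their record-level prevalence *p* exceeds a threshold (default
   *p* > 0.05), guideline-derived terms bypassing the filter; a rule-based
   vocabulary filter keeps terms in the Clinical finding / Observable entity
   domains; concepts embedded in structured text (dates, numbers) are
   excluded, with keep/drop overrides standing in for expert curation.
2. **Question generation** — each retained concept becomes a question
   template (prompt B) with a deterministic answer type
   (binary / numeric / categorical) and refinement overrides.
3. **Corpus pre-extraction** — records are deidentified, segmented into
   sentences, and each (record, question) pair is narrowed to a snippet by
   two strategies: the sections named by the question's anchors, and every
   sentence containing a concept synonym. The union is the model's context —
   the guard against feature hallucination on long notes.
4. **Q&A scale extraction** — one greedy-decoded call per cell
   (temperature 0, max_tokens 20, concurrency 3); raw answers are normalized
   to `positive` / `negative` / number / text, with empty or meaningless
   output (symbols, gibberish) detected as `null`.

Evaluation is three-fold: per-question **accuracy** (TP+TN)/n and
**precision** TP/(TP+FP) against gold annotations on a random record subset,
the **null ratio** over every cell, and per-question/per-record **timing**
distributions. Macro means are unweighted over question columns.

Every prompt follows a fixed 4-paragraph structure (context, instruction
with few-shot chain-of-thought examples, input data, output indicator), and
all stages run against either a real OpenAI-compatible endpoint or a fully
scripted, seeded **mock backend**, so the whole pipeline is testable offline.
A synthetic corpus generator emits sectioned records with known concept
prevalences, gold labels and the paired mock script.

## Worked example

```bash
qascale simulate --dir run --seed 3 --n-records 40
qascale qa --dir run
qascale evaluate --dir run
```

prints

```
[simulate] records=40 questions=10
[qa] records=40 questions=10 cells=400 null=0 resumed=0 elapsed=0.02s
[evaluate] annotated=40 mean_accuracy_pct=100.0 mean_precision_pct=100.0 mean_null_pct=0.0
```

400 cells (40 records × 10 questions) were extracted through the scripted
oracle backend; because the oracle answers from the gold labels, the
evaluation reports 100% macro accuracy and precision with a 0.00% null
ratio — the degenerate calibration point of the pipeline. Re-running with
`--flip-rate 0.1 --null-rate 0.02` at `simulate` time degrades accuracy to
≈90% and the null ratio to ≈2%, matching the configured corruption.
`matrix.csv`, `metrics.csv` and `table.csv` in the run directory hold the
cell values, per-question metrics and ratio table. The same steps run
against a live endpoint by setting `backend_url`/`backend_model` in
`config.yaml`; `qascale qa --skip-preextract` reproduces the full-text
ablation.

The library mirrors the CLI: `qascale.generate` / `preextract` /
`run_matrix` / `evaluate` compose in Python, as the test suite shows.

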