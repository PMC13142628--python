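# phenonote

Phenotype annotation from longitudinal free-text clinical notes, built for
settings where the notes cannot leave the institution and the classifier
has to be small: pre-filter each note down to the few sentences that could
possibly speak to the target condition, classify only those segments, and
aggregate by majority vote into subject- or visit-level annotations that
can be evaluated against ICD diagnosis codes as a reference standard.

It is aimed at clinical-NLP and EHR-phenotyping researchers who need the
*harness* around a classifier — filtering, vote aggregation, two-level
evaluation, and a fully synthetic test cohort — independent of which
language model (or rule engine) does the per-segment classification.

## The pipeline

1. **Pre-filtering.** Two interchangeable strategies locate
   condition-relevant text:
   * *Keyword (regex)*: all synonyms and flexible patterns for the target
     variable are compiled into one case-insensitive alternation; every
     sentence that matches yields a segment of the matching sentence plus
     its immediate neighbours (overlapping context windows are merged).
   * *Semantic retrieval*: every sentence is embedded and scored by cosine
     similarity against the target query; the p sentences (0 ≤ p ≤ s)
     that rank in the note's top *s* and exceed a similarity threshold
     form the note's single segment.

   A unit (subject or visit) whose notes produce no segment at all is
   annotated **NNF** ("no notes found") without any classifier call.
2. **Segment classification.** Each segment is wrapped in a zero- or
   few-shot prompt (n positive, n negative, n neutral worked examples)
   and classified **Yes / No / Unknown** by a pluggable backend. A
   deterministic offline mock backend ships with the package; its rules
   are shared with the synthetic generator so expected labels are known
   by construction.
3. **Majority vote.** Unknown labels are discarded; more Yes than No
   votes gives **Yes**, the reverse **No**, a tie (or nothing but
   Unknowns) **Undecided**. The keyword branch casts one vote per
   segment — a note with several distinct mentions votes several times —
   while the retrieval branch casts exactly one vote per note.

## Evaluation

With M_ICD / N_ICD the reference positive/negative units, M_LLM the units
annotated Yes, N_LLM those annotated No or Undecided, and N_NNF the NNF
units:

| metric | model level | system level |
|---|---|---|
| sensitivity | \|M_LLM ∩ M_ICD,eval\| / \|M_ICD,eval\| | \|M_LLM ∩ M_ICD\| / \|M_ICD\| |
| specificity | \|N_LLM ∩ N_ICD,eval\| / \|N_ICD,eval\| | \|(N_LLM ∪ N_NNF) ∩ N_ICD\| / \|N_ICD\| |

where M_ICD,eval = M_ICD − N_NNF and N_ICD,eval = N_ICD − N_NNF. Precision
\|M_LLM ∩ M_ICD\| / \|M_LLM\| is identical in both modes; F1 is the
harmonic mean of the mode's sensitivity with precision. Model-level
metrics ask "how good is the classifier on the notes we found"; system
level asks "how good is the whole pipeline", charging an NNF true
positive as a false negative and crediting an NNF true negative as a
correct rejection.

For dated diagnosis events, **time-sensitive sensitivity** runs the
pipeline on the notes inside an n-day window centred on each event date
t_ij and tallies per-event outcomes A_ij: N_c events annotated Yes, N_w
annotated No/Undecided, N_nn with an empty window, giving
Sens_model = N_c/(N_c+N_w) and Sens_system = N_c/(N_c+N_w+N_nn).
Specificity is deliberately undefined here — negative subjects have no
event date to anchor a window on.

## Worked example

```python
from phenonote import SyntheticConfig, TaskConfig, generate_cohort, run_pipeline

cfg = SyntheticConfig(n_subjects=300, prevalence=0.378, affirmative_rate=0.6,
                      negation_rate=0.3, pending_rate=0.1, seed=21)
cohort = generate_cohort(cfg)
task = TaskConfig(target_variable="metastasis", method="regex", backend="mock")
result = run_pipeline(cohort.notes, cohort.events, task)
print(result.model.to_dict())
print(result.system.to_dict())
```

prints (abridged):

```
model:  sensitivity 1.0000  specificity 1.0000  precision 1.0000  f1 1.0000
system: sensitivity 0.9646  specificity 1.0000  precision 1.0000  f1 0.9820
counts: 113 reference positives, 187 negatives, 109 annotated Yes, 28 NNF
```

Every positive subject whose notes mention the condition is classified
correctly (model metrics 1.0); the 4 positives whose notes never mention
it are NNF, so system sensitivity drops to 109/113 = 0.9646 — within
sampling error of the closed form 1 − (1 − q)^k returned by
`expected_system_sensitivity(cfg)` (0.9472 for these settings).

The `examples/` directory holds one short script per capability
(simulation and summaries, keyword pre-filtering, semantic retrieval,
end-to-end evaluation, time-sensitive windows); each prints the numbers
it computes and a line on what they mean. The same stages are available
from a shell via the `phenonote` command
(`simulate | filter | classify | annotate | evaluate | run`).

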