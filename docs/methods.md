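# Methods

## Model and assumptions

The package treats phenotype annotation from clinical notes as a
three-stage decision procedure. The underlying assumption is that
evidence for a clinical variable is *local*: it is articulated within a
sentence or two of a mention of the variable (or a semantically similar
term), so a classifier only needs those sentences plus minimal context.
The stages are:

1. **Pre-filter** each note into candidate segments. The keyword branch
   assumes a usable synonym list exists; the retrieval branch assumes
   only that relevant sentences are lexically/semantically closer to the
   target query than irrelevant ones. Both branches run per note, so no
   cross-note state exists at this stage.
2. **Classify** each segment independently into Yes / No / Unknown.
   Unknown is a first-class outcome (pending results, oblique mentions),
   not an error.
3. **Vote**: a unit's final annotation is the majority of its segment
   labels after discarding Unknowns, with ties and all-Unknown sets
   mapping to Undecided, and units with no segments at all mapping to
   NNF. Votes are deliberately unweighted; temporal decay or confidence
   weighting is out of scope.

Evaluation treats ICD codes as a reference standard, not clinical truth.
Units present in the truth file but without any notes are excluded from
the evaluation denominators: they are not annotatable and would
otherwise conflate data availability with pipeline quality. Annotated
No and Undecided are pooled as "non-positive" for metric purposes.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| context window | sentences kept around a keyword hit | ±1 sentence | evidence-locality assumption; fixed, not tunable |
| `rag_top_s` | max sentences retrieved per note | 3 | small enough to keep segments shorter than notes, large enough for multi-sentence evidence |
| `rag_threshold` | strict cosine floor for retrieval | 0.25 (CLI) | below typical single-shared-token scores of the hashing embedder would admit noise; package choice, task-dependent |
| `shots_n` | worked examples per class in the prompt | 0 | zero-shot is the default paradigm; n > 0 embeds n Yes + n No + n Unknown examples |
| `window_days` | total event-window length n (days) | 20 | windows of 20–40 days around a diagnosis date are the standard design envelope here; 20 is the preferred value |
| half-window | days either side of the anchor | floor(n/2), endpoints inclusive | day-resolution timestamps; odd n floors |

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:
subjects with per-subject note streams, dated ICD anchor events for the
positive fraction, and notes assembled from four sentence templates —
affirmative (keyword + affirmative marker), negated (keyword + negation
marker), pending (keyword, no marker), and noise (no keyword). The
marker vocabulary is shared with the mock classifier backend, so the
label of every segment, and hence every unit annotation, is known by
construction: a positive subject is annotated Yes exactly when at least
one of its notes carries the affirmative template, giving the closed
form P(Yes | positive) = 1 − (1 − f·q)^k for k notes, in-window fraction
f, and per-note affirmative rate q. Defaults are chosen once as a
scaled-down realistic cohort: prevalence 0.378 (a head-and-neck-cancer
cohort's ICD-positive fraction), 2–6 notes per subject and 4–8 sentences
per note (real oncology streams run to hundreds of notes per subject;
desk-scale sizes keep the suite fast without changing any tested
property), affirmative rate 0.6, negation rate 0.3, pending rate 0.1.

What passing tests on synthetic cohorts **do** show: the plumbing is
correct — filtering finds every planted mention, votes are counted per
the declared rules, metrics implement their formulas, windows select the
right notes, and the end-to-end system recovers the analytically known
detection probability. What they **do not** show: performance on real
clinical language. Real notes have misspellings, section structure,
negation scope ambiguity, copy-forwarded text and non-template phrasing;
nothing here measures a real classifier's accuracy on them.

## Numerical and design choices

* **Percentages** in cohort summaries are rounded half-up (not banker's)
  at the declared precision, so printed descriptive tables are
  reproduced bit-exactly from their count pairs.
* **Retrieval threshold is strict** (score > threshold, not ≥); a
  sentence exactly at the threshold is excluded. Retrieval ties break by
  earlier sentence position; retrieved sentences are re-ordered to
  document order before forming the segment so the classifier reads
  coherent context. Sentences with an empty embedding (no tokens) have
  undefined cosine and are never retrieved.
* **Overlapping or adjacent context windows** within one note are merged
  into a single segment that casts a single vote: the same sentence is
  never double-counted, while well-separated mentions still vote
  separately.
* **Sentence splitting** is rule-based and deterministic (line breaks
  always split; terminator runs split unless a single period follows a
  known clinical/title abbreviation). It loses no text — joining the
  sentences reconstructs the input modulo whitespace — which is the only
  property segmenting relies on.
* **Undefined metrics** (empty denominator, nothing annotated Yes) are
  reported as explicit nulls with a reason, never as 0.
* **Visit definition precedence**: explicit visit identifiers (admission
  style) when present; otherwise date windows around dated diagnosis
  events. A note falling inside two overlapping event windows votes
  independently in each — windows are separate pipeline runs and event
  outcomes are deliberately not deduplicated.
* **Backend failures**: each call is retried a bounded number of times;
  a backend that has never succeeded is treated as unavailable (fatal),
  while a failure after earlier successes degrades that segment to
  Unknown.
* **Label parsing** scans the raw response for the first standalone
  yes/no/unknown token and conservatively maps anything unresolvable to
  Unknown, so the parser's range is exactly the three labels and it
  never raises.
* The bundled embedder is a deterministic feature-hashing bag-of-words
  model (blake2b token hashing, signed buckets, default dimension 256):
  hermetic, reproducible bit-for-bit across machines, and adequate for
  lexical-overlap retrieval. It captures no synonymy or word order; a
  production deployment would plug a sentence-embedding model into the
  same `Embedder` protocol. Likewise the mock backend is the only
  shipped classifier; real LLM backends implement the two-method
  `Backend` protocol.

## Problem sizes

The test suite and the acceptance script use cohorts of up to 500
subjects, 1,000 randomized truth/annotation cohorts of ≤ 50 units for
the formula oracles, exhaustive vote-rule checks over all label
multisets of size ≤ 6, and a 3-binomial-SE band for stochastic
end-to-end recovery at 250 positives per configuration — sizes at which
every tested property is already fully exercised.

## Known limitations

* Keyword lists shipped under `EXAMPLE_KEYWORD_SPECS` are illustrative
  minima, not curated clinical vocabularies.
* The regex branch cannot see mentions outside its synonym list;
  the retrieval branch's recall depends entirely on the embedder.
* ICD reference codes are a proxy: coding lag and omissions mean
  "reference negative" units may be truly positive, which biases
  measured specificity on real data.
* Admission-level evaluation requires the caller to supply an
  admission-keyed truth set; the package derives truth automatically
  only at the subject level.
* No de-identification, ontology expansion, or EHR-system connectors.
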