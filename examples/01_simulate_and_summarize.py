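"""Generate a synthetic cohort and print its descriptive summary.

Builds a 200-subject longitudinal cohort (37.8% carrying a dated
metastasis ICD event), writes the note/event tables, reads them back and
summarizes keyword coverage the way a cohort-descriptives table would.
"""

from pathlib import Path

from phenonote import (
    SyntheticConfig,
    compile_pattern,
    generate_cohort,
    read_icd_events,
    read_notes,
    summarize_cohort,
    write_icd_events,
    write_notes,
)

out = Path("scratch/example01")
out.mkdir(parents=True, exist_ok=True)

cohort = generate_cohort(SyntheticConfig(seed=11))
write_notes(cohort.notes, out / "notes.csv")
write_icd_events(cohort.events, out / "events.csv")

notes = read_notes(out / "notes.csv")
events = read_icd_events(out / "events.csv")
summary = summarize_cohort(notes, events, compile_pattern(cohort.keyword_spec))

for key, value in summary.to_dict().items():
    print(f"{key:28s} {value}")
print()
print("pct_icd_positive is the fraction of subjects with notes that carry a")
print("reference diagnosis code; pct_keyword_notes is the share of notes the")
print("keyword pre-filter would forward to the classifier.")
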