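"""Keyword pre-filtering: three-sentence segments around each mention.

Shows boundary clipping (a mention in the first sentence has no
predecessor) and merging of overlapping context windows, and that a note
with several well-separated mentions yields several segments (votes).
"""

from phenonote import ClinicalNote, EXAMPLE_KEYWORD_SPECS, compile_pattern, extract_segments

matcher = compile_pattern(EXAMPLE_KEYWORD_SPECS["metastasis"])

note = ClinicalNote(
    note_id="n1",
    subject_id="s1",
    text=(
        "Metastatic disease was discussed with the patient. "
        "She tolerated the last cycle well. "
        "Vitals stable today. "
        "Diet and activity reviewed. "
        "Repeat imaging shows new metastasis in the liver. "
        "Plan to adjust therapy. "
        "Family present for the conversation."
    ),
)

for seg in extract_segments(note, matcher):
    a, b = seg.sentence_span
    print(f"sentences {a}-{b}  keywords={seg.match_info}")
    print(f"  {seg.text}")
print()
print("Each segment is the mention sentence plus its immediate neighbours,")
print("clipped at the note boundary; each will cast one vote after")
print("classification, so two separated mentions mean two votes.")
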