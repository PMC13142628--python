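"""Semantic-retrieval pre-filtering with the bundled hashing embedder.

Scores every sentence of a note against the target query by cosine
similarity, keeps the top-s above the threshold, and forms one segment
per note (one vote, however many mentions the note contains).
"""

from phenonote import ClinicalNote, HashingEmbedder, build_rag_segments, retrieve_sentences

note = ClinicalNote(
    note_id="n1",
    subject_id="s1",
    text=(
        "Patient seen for routine follow up. "
        "Imaging confirmed metastasis in two sites. "
        "Diet and exercise were discussed. "
        "Further metastasis workup is scheduled. "
        "No medication changes today."
    ),
)

embedder = HashingEmbedder()
hits = retrieve_sentences(note, "metastasis", s=3, threshold=0.25, embedder=embedder)
for h in hits:
    print(f"sentence {h.index}  score={h.score:.3f}  {h.text}")

segments, nnf = build_rag_segments({"s1": [note]}, "metastasis", 3, 0.25, embedder)
print()
print(f"segments for subject s1: {len(segments['s1'])} (one per note with hits)")
print("Both mention sentences land in ONE segment: retrieval casts a single")
print("vote per note, unlike the keyword branch which votes per mention.")
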