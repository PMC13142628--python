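"""Small illustrative keyword specifications.

These example lists exist so the pipeline can be exercised end to end;
they are deliberately minimal and are **not** curated clinical keyword
lists — production use should supply a reviewed KeywordSpec file.
"""

from __future__ import annotations

from .config import KeywordSpec

EXAMPLE_KEYWORD_SPECS: dict[str, KeywordSpec] = {
    "metastasis": KeywordSpec(
        target_variable="metastasis",
        literal_synonyms=["metastasis", "metastases", "metastatic"],
        flexible_patterns=[r"\bmets\b"],
    ),
    "insulin use": KeywordSpec(
        target_variable="insulin use",
        literal_synonyms=["insulin"],
        # optional-hyphen structural variant
        flexible_patterns=[r"\binsulin[- ]dependent\b"],
    ),
    "hypertension": KeywordSpec(
        target_variable="hypertension",
        literal_synonyms=["hypertension", "hypertensive"],
        flexible_patterns=[r"\bhigh blood[- ]pressure\b"],
    ),
}
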