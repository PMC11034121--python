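"""Ignorance-category vocabulary.

Statements of ignorance (SOIs) are sentences expressing knowledge that does
not exist yet.  Each SOI carries exactly one of thirteen category labels;
five of them signal an actionable research direction and define the pool of
recommendation candidates.
"""

from __future__ import annotations

import re
import unicodedata

#: The closed 13-label category scheme, in canonical lowercase form.
CATEGORIES: tuple[str, ...] = (
    "question answered by this work",
    "full unknown",
    "explicit question",
    "incomplete evidence",
    "superficial relationship",
    "probable understanding",
    "anomaly or curious finding",
    "alternative options or controversy",
    "difficult task",
    "problem or complication",
    "future work",
    "future prediction",
    "important consideration",
)

#: Categories that indicate a pursuable research direction and are therefore
#: eligible as recommendation candidates.
RECOMMENDABLE_CATEGORIES: frozenset[str] = frozenset(
    {
        "full unknown",
        "explicit question",
        "problem or complication",
        "future work",
        "future prediction",
    }
)

_WS = re.compile(r"\s+")


class UnknownCategoryError(ValueError):
    """Raised for a label outside the 13-category scheme."""


def normalize_category(label: str) -> str:
    """Map a category label to its canonical form.

    Comparison is case-insensitive after Unicode NFC and whitespace
    normalization; a slash is read as "or" so that e.g.
    ``"Problem/complication"`` and ``"problem or complication"`` coincide.
    """
    s = unicodedata.normalize("NFC", label).lower()
    s = s.replace("/", " or ")
    s = _WS.sub(" ", s).strip()
    if s not in _CANONICAL:
        raise UnknownCategoryError(f"unknown ignorance category: {label!r}")
    return s


_CANONICAL = frozenset(CATEGORIES)
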