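"""EC-number labels and curated truth labels.

Enzyme Commission (EC) numbers are dotted identifiers of one to four
fields (e.g. ``2.7.1.1``); trailing fields may be the wildcard ``-`` for
incomplete classifications (e.g. ``3.1.-.-``).  A curated gene label is
either a set of EC numbers (isozymes and complexes can legitimately carry
several) or the explicit "not an enzyme" marker.
"""

from __future__ import annotations

import re
from typing import FrozenSet, Union

__all__ = [
    "NOT_ENZYME",
    "NO_EC",
    "NotEnzyme",
    "TruthLabel",
    "is_valid_ec",
    "validate_ec",
    "parse_truth_label",
    "format_truth_label",
]

#: Proposed-annotation placeholder when the scorer has no EC candidate.
NO_EC = "none"

_EC_RE = re.compile(r"^\d+(\.(\d+|-)){0,3}$")


class NotEnzyme:
    """Singleton marker for curated "not an enzyme" entries."""

    _instance = None

    def __new__(cls) -> "NotEnzyme":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NOT_ENZYME"


NOT_ENZYME = NotEnzyme()

TruthLabel = Union[NotEnzyme, FrozenSet[str]]

#: Literal used for NOT_ENZYME in standard-of-truth TSV files.
NOT_ENZYME_LITERAL = "NONE"


def is_valid_ec(ec: str) -> bool:
    """True if ``ec`` matches the dotted EC pattern.

    One to four dot-separated fields; the first is numeric and trailing
    fields may be ``-``, but a numeric field may not follow a wildcard.
    """
    if not isinstance(ec, str) or not _EC_RE.match(ec):
        return False
    fields = ec.split(".")
    seen_wild = False
    for f in fields:
        if f == "-":
            seen_wild = True
        elif seen_wild:
            return False
    return True


def validate_ec(ec: str) -> str:
    if not is_valid_ec(ec):
        raise ValueError(f"malformed EC number: {ec!r}")
    return ec


def parse_truth_label(raw: str) -> TruthLabel:
    """Parse a curated label: ``NONE`` or a comma-separated EC set."""
    raw = raw.strip()
    if raw.upper() == NOT_ENZYME_LITERAL:
        return NOT_ENZYME
    ecs = frozenset(part.strip() for part in raw.split(",") if part.strip())
    if not ecs:
        raise ValueError("empty curated label (expected EC set or 'NONE')")
    for ec in ecs:
        validate_ec(ec)
    return ecs


def format_truth_label(label: TruthLabel) -> str:
    if isinstance(label, NotEnzyme):
        return NOT_ENZYME_LITERAL
    return ",".join(sorted(label))
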