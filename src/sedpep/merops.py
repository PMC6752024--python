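"""MEROPS-style peptidase clan/family code validation.

A compact list of family codes commonly annotated in sediment metagenomes,
plus a structural pattern (catalytic-type letter + number + optional
subfamily letter).  Labels failing both checks pass with a warning — real
annotation pipelines emit free-text descriptors alongside MEROPS codes.
"""

from __future__ import annotations

import re
import warnings

# Catalytic types: A aspartic, C cysteine, G glutamic, M metallo,
# N asparagine, P mixed, S serine, T threonine, U unknown.
FAMILY_PATTERN = re.compile(r"^[ACGMNPSTU]\d{1,3}[A-Z]?$")

KNOWN_FAMILIES = frozenset({
    "A1", "A8", "A22", "A24",
    "C1", "C2", "C11", "C13", "C14", "C25", "C26", "C39", "C40", "C56",
    "G1",
    "M1", "M3", "M4", "M13", "M14", "M15", "M16", "M17", "M18", "M20",
    "M23", "M24", "M25", "M28", "M29", "M38", "M40", "M41", "M48", "M50",
    "M60", "M61", "M79",
    "N1",
    "S1", "S8", "S9", "S10", "S11", "S12", "S13", "S14", "S16", "S24",
    "S26", "S33", "S41", "S45", "S46", "S49", "S53", "S54",
    "T1", "T2", "T3",
    "U32", "U62",
})


def validate_family(label: str) -> bool:
    """True if ``label`` is a recognized or well-formed family code.

    Unknown labels warn and return False but are never rejected.
    """
    label = str(label).strip()
    if label in KNOWN_FAMILIES or FAMILY_PATTERN.match(label):
        return True
    warnings.warn(f"unrecognized peptidase family label: {label!r}", stacklevel=2)
    return False
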