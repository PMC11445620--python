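"""SNOMED CT identifier utilities.

Real SCTIDs are 6-18 decimal digits without a leading zero and carry a
Verhoeff check digit as their last digit.  Synthetic fixture identifiers
follow the same length/shape rules but skip the checksum, so checksum
validation is opt-in.
"""

from __future__ import annotations

# Verhoeff dihedral-group tables.
_D = (
    (0, 1, 2, 3, 4, 5, 6, 7, 8, 9),
    (1, 2, 3, 4, 0, 6, 7, 8, 9, 5),
    (2, 3, 4, 0, 1, 7, 8, 9, 5, 6),
    (3, 4, 0, 1, 2, 8, 9, 5, 6, 7),
    (4, 0, 1, 2, 3, 9, 5, 6, 7, 8),
    (5, 9, 8, 7, 6, 0, 4, 3, 2, 1),
    (6, 5, 9, 8, 7, 1, 0, 4, 3, 2),
    (7, 6, 5, 9, 8, 2, 1, 0, 4, 3),
    (8, 7, 6, 5, 9, 3, 2, 1, 0, 4),
    (9, 8, 7, 6, 5, 4, 3, 2, 1, 0),
)
_P = (
    (0, 1, 2, 3, 4, 5, 6, 7, 8, 9),
    (1, 5, 7, 6, 2, 8, 3, 0, 9, 4),
    (5, 8, 0, 3, 7, 9, 6, 1, 4, 2),
    (8, 9, 1, 6, 0, 4, 3, 5, 2, 7),
    (9, 4, 5, 3, 1, 2, 6, 8, 7, 0),
    (4, 2, 8, 6, 5, 7, 3, 9, 0, 1),
    (2, 7, 9, 3, 8, 0, 6, 4, 1, 5),
    (7, 0, 4, 6, 9, 1, 3, 2, 5, 8),
)
_INV = (0, 4, 3, 2, 1, 5, 6, 7, 8, 9)


def verhoeff_check_digit(digits: str) -> int:
    """Check digit to append to ``digits`` so the whole string validates."""
    c = 0
    for i, ch in enumerate(reversed(digits)):
        c = _D[c][_P[(i + 1) % 8][int(ch)]]
    return _INV[c]


def verhoeff_valid(number: str) -> bool:
    """True iff the last digit of ``number`` is its Verhoeff checksum."""
    c = 0
    for i, ch in enumerate(reversed(number)):
        c = _D[c][_P[i % 8][int(ch)]]
    return c == 0


def is_well_formed(concept_id: str, check_digit: bool = False) -> bool:
    """Shape check for a concept identifier.

    6-18 decimal digits, no leading zero; optionally also verify the
    Verhoeff check digit (real release content only).
    """
    if not concept_id.isdigit():
        return False
    if not 6 <= len(concept_id) <= 18:
        return False
    if concept_id[0] == "0":
        return False
    if check_digit and not verhoeff_valid(concept_id):
        return False
    return True
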