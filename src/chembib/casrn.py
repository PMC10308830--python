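"""CAS Registry Number (CASRN) validation and canonicalization.

A CASRN is a hyphenated identifier of the form ``NNNNNNN-NN-N``: a first
segment of two to seven digits, a two-digit second segment, and a single
check digit. The check digit is computed positionally: number the non-check
digits 1, 2, 3, ... starting from the digit immediately left of the check
digit and moving leftward, multiply each digit by its position, and take the
sum modulo 10. For 1746-01-6 the non-check digits right-to-left are
1,0,6,4,7,1, giving 1*1 + 0*2 + 6*3 + 4*4 + 7*5 + 1*6 = 76 and a check
digit of 6.

CASRNs are identifiers, not numbers: they are stored and compared as
canonical hyphenated strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "CASRN_PATTERN",
    "CasrnValidation",
    "check_digit",
    "validate_casrn",
    "is_valid_casrn",
    "canonicalize",
]

CASRN_PATTERN = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")

#: failure reason codes
MALFORMED = "malformed pattern"
CHECKSUM = "checksum mismatch"


@dataclass(frozen=True)
class CasrnValidation:
    """Outcome of validating one raw token.

    ``casrn`` holds the canonical hyphenated form when ``ok`` is True;
    ``reason`` distinguishes "malformed pattern" from "checksum mismatch"
    when it is False. Failures are values, not exceptions, so corpus
    readers can tally them.
    """

    ok: bool
    casrn: str | None = None
    reason: str | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def check_digit(body: str) -> int:
    """Check digit for a digit string ``body`` (the CASRN without its
    check digit and without hyphens)."""
    total = sum(int(d) * i for i, d in enumerate(reversed(body), start=1))
    return total % 10


def _canonical_segments(first: str, second: str, check: str) -> str:
    # Drop leading zeros in the first segment, but keep at least two digits
    # so the canonical form still matches the CASRN pattern.
    stripped = first.lstrip("0")
    if len(stripped) < 2:
        stripped = first[-2:]
    return f"{stripped}-{second}-{check}"


def validate_casrn(text: str) -> CasrnValidation:
    """Validate a raw token as a CASRN.

    Returns the canonical form iff the token matches the hyphenated
    pattern AND the mod-10 positional checksum passes. Canonicalization
    is idempotent: validating a canonical CASRN returns it unchanged.
    """
    token = text.strip()
    m = CASRN_PATTERN.match(token)
    if m is None:
        return CasrnValidation(False, reason=MALFORMED)
    first, second, check = m.groups()
    if check_digit(first + second) != int(check):
        return CasrnValidation(False, reason=CHECKSUM)
    return CasrnValidation(True, casrn=_canonical_segments(first, second, check))


def is_valid_casrn(text: str) -> bool:
    return validate_casrn(text).ok


def canonicalize(text: str) -> str:
    """Canonical form of a valid CASRN; raises ``ValueError`` otherwise."""
    result = validate_casrn(text)
    if not result.ok:
        raise ValueError(f"invalid CASRN {text!r}: {result.reason}")
    assert result.casrn is not None
    return result.casrn


def make_casrn(body: str) -> str:
    """Build a valid CASRN from a digit body (first+second segments,
    4-9 digits) by appending the correct check digit.

    Used by the synthetic corpus generator and by tests that need
    arbitrary valid registry numbers.
    """
    if not body.isdigit() or not 4 <= len(body) <= 9:
        raise ValueError("body must be 4-9 digits")
    first, second = body[:-2], body[-2:]
    return _canonical_segments(first, second, str(check_digit(body)))
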