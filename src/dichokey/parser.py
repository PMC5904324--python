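"""Non-interactive import of bracketed plain-text keys.

The supported preparation convention: one lead per line, a tab character in
each lead line before the pointer or endpoint.  A line whose first
non-whitespace token is an integer opens a new couplet; subsequent non-blank
lines add leads to it.  Parsing never raises on malformed structure — problems
that the line rules can recover from are reported as diagnostics, and
structural defects (three-lead couplets, duplicate numbers, bad pointers) are
left in the Key for the validator to find, matching the import-then-validate
workflow of traditional key preparation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .model import Couplet, InvalidReferenceError, Key, Lead, classify_reference

__all__ = ["ParseDiagnostic", "parse_key_text", "DIAGNOSTIC_CODES"]

#: Diagnostic codes emitted by :func:`parse_key_text`.
DIAGNOSTIC_CODES = (
    "missing-separator",
    "no-couplet-number",
    "empty-lead-text",
    "orphan-line",
)


@dataclass(frozen=True)
class ParseDiagnostic:
    """One recoverable problem found while importing a text key.

    ``line_number`` is 1-based and refers to a line of the input.
    """

    line_number: int
    code: str
    message: str

    def __str__(self) -> str:
        return f"line {self.line_number}: {self.code}: {self.message}"


# Couplet-opening line: optional indentation, an integer, optionally one
# parenthesized back-reference group ("12(3)" dialect), optionally one of the
# common punctuation marks after the number, then the first lead.
_OPENING_RE = re.compile(r"^\s*(\d+)(?:\((\d+)\))?\s*[.)'–]?\s?(.*)$")

# Dash markers that introduce a continuation lead in printed keys.
_DASH_RE = re.compile(r"^\s*(?:--|[-–—])\s*")


def _strip_dash(text: str) -> str:
    return _DASH_RE.sub("", text, count=1)


def _parse_lead(
    raw: str, line_number: int, diagnostics: list[ParseDiagnostic]
) -> Lead | None:
    """Turn one lead line (dash already stripped) into a Lead, or None.

    The text after the LAST tab is the reference; text before it is the lead
    text (it may itself contain tabs from sloppy preparation).  A line with no
    tab — or nothing usable after the tab — is recovered best-effort: the
    trailing whitespace-delimited token becomes an endpoint label, with a
    ``missing-separator`` diagnostic.
    """
    text_part, sep, ref_part = raw.rpartition("\t")
    if sep and ref_part.strip():
        lead_text = text_part.strip()
        reference = classify_reference(ref_part)
    else:
        diagnostics.append(
            ParseDiagnostic(
                line_number,
                "missing-separator",
                "no tab before the reference; took the trailing word as an endpoint",
            )
        )
        words = raw.split()
        if not words:
            return None
        lead_text = " ".join(words[:-1])
        try:
            reference = classify_reference(words[-1])
        except InvalidReferenceError:  # pragma: no cover - words[-1] is non-empty
            return None
    if not lead_text:
        diagnostics.append(
            ParseDiagnostic(line_number, "empty-lead-text", "lead has no descriptive text")
        )
    return Lead(lead_text, reference)


def parse_key_text(lines: Iterable[str]) -> tuple[Key, list[ParseDiagnostic]]:
    """Parse a prepared bracketed-format text key into a Key.

    Parameters
    ----------
    lines:
        Decoded text lines (trailing newlines tolerated); blank lines are
        permitted anywhere.

    Returns
    -------
    (Key, diagnostics):
        The parsed key — possibly structurally unsound, to be checked by the
        validator — and the ordered recoverable-problem diagnostics.

    Parsing never raises on malformed structure; only unreadable input is an
    error, and that happens before the lines reach this function.
    """
    diagnostics: list[ParseDiagnostic] = []
    # Accumulate (number, leads) pairs; Couplet objects require >= 1 lead so
    # they are materialized only at the end.
    pending: list[tuple[int, list[Lead]]] = []
    current_leads: list[Lead] | None = None
    current_number: int | None = None

    for line_number, raw_line in enumerate(lines, start=1):
        line = raw_line.rstrip("\r\n")
        if not line.strip():
            continue

        opening = None if _DASH_RE.match(line) else _OPENING_RE.match(line)
        if opening is not None:
            number = int(opening.group(1))
            # "1'."-style repeats of the current number continue the current
            # couplet rather than opening a new one (dialect risk: see docs).
            if number < 1 or number == current_number:
                opening = None

        if opening is not None:
            current_number = int(opening.group(1))
            current_leads = []
            pending.append((current_number, current_leads))
            first_lead_raw = opening.group(3)
            if first_lead_raw.strip():
                lead = _parse_lead(first_lead_raw, line_number, diagnostics)
                if lead is not None:
                    current_leads.append(lead)
            continue

        if current_leads is None:
            code, msg = (
                ("no-couplet-number", "lead line appears before any couplet number")
                if "\t" in line
                else ("orphan-line", "content line before the first couplet; skipped")
            )
            diagnostics.append(ParseDiagnostic(line_number, code, msg))
            continue

        lead = _parse_lead(_strip_dash(line), line_number, diagnostics)
        if lead is not None:
            current_leads.append(lead)

    key = Key(couplets=[Couplet(n, leads) for n, leads in pending if leads])
    return key, diagnostics
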