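"""Core domain types for dichotomous (single-access) identification keys.

A key is an ordered sequence of numbered *couplets*; each couplet holds an
ordered sequence of *leads* (normally exactly two).  A lead pairs descriptive
text with a *reference*, which is either a :class:`Pointer` to another couplet
or an :class:`Endpoint` naming a taxon (or other terminal text).

Row order of couplets is stored independently of couplet numbers: editing
operations may leave the numbering non-consecutive or out of row order, and
structural soundness is checked exclusively by :mod:`dichokey.validator`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Union

__all__ = [
    "Pointer",
    "Endpoint",
    "Reference",
    "Lead",
    "Couplet",
    "Key",
    "InvalidReferenceError",
    "classify_reference",
    "unique_endpoints",
]


class InvalidReferenceError(ValueError):
    """Raised when a reference token is empty or whitespace-only."""


@dataclass(frozen=True)
class Pointer:
    """A reference that continues identification at another couplet.

    ``target`` is the couplet number pointed to (>= 1).
    """

    target: int

    def __post_init__(self) -> None:
        if self.target < 1:
            raise ValueError(f"pointer target must be >= 1, got {self.target}")


@dataclass(frozen=True)
class Endpoint:
    """A reference that finishes identification with a taxon label."""

    label: str

    def __post_init__(self) -> None:
        if not self.label.strip():
            raise ValueError("endpoint label must be non-empty")


Reference = Union[Pointer, Endpoint]


@dataclass
class Lead:
    """One half of a couplet: character-state text plus a reference.

    ``text`` may be empty only in a freshly created dummy couplet; the
    validator emits an ``empty-lead`` warning for empty lead text.
    """

    text: str
    reference: Reference

    def copy(self) -> "Lead":
        return Lead(self.text, self.reference)


@dataclass
class Couplet:
    """A numbered identification step holding an ordered sequence of leads.

    A key passing validation has exactly two leads per couplet; the parser may
    transiently produce three or more for polytomous source keys.
    """

    number: int
    leads: list[Lead]

    def __post_init__(self) -> None:
        if self.number < 1:
            raise ValueError(f"couplet number must be >= 1, got {self.number}")
        if not self.leads:
            raise ValueError("a couplet must hold at least one lead")

    def copy(self) -> "Couplet":
        return Couplet(self.number, [lead.copy() for lead in self.leads])


@dataclass
class Key:
    """An ordered sequence of couplets plus optional metadata.

    No structural invariant is enforced at construction: a Key may hold any
    intermediate editing state (duplicate numbers, dangling pointers, broken
    consecutive numbering).  Use :func:`dichokey.validator.validate` to check
    soundness before export or traversal.
    """

    couplets: list[Couplet] = field(default_factory=list)
    title: str | None = None
    source_path: str | None = None
    image_dir: str | None = None

    def copy(self) -> "Key":
        return replace(self, couplets=[c.copy() for c in self.couplets])

    def numbers(self) -> list[int]:
        """Couplet numbers in row order (may contain duplicates)."""
        return [c.number for c in self.couplets]

    def by_number(self) -> dict[int, Couplet]:
        """Map couplet number -> couplet (first row wins on duplicates)."""
        out: dict[int, Couplet] = {}
        for c in self.couplets:
            out.setdefault(c.number, c)
        return out

    def max_number(self) -> int:
        """Largest couplet number in use, or 0 for an empty key."""
        return max((c.number for c in self.couplets), default=0)

    def iter_leads(self) -> Iterator[tuple[Couplet, int, Lead]]:
        for couplet in self.couplets:
            for i, lead in enumerate(couplet.leads):
                yield couplet, i, lead


# Pointer dialects accepted: "7", "7.", "(7)", "(7.)".  Anything else,
# including labels with embedded digits such as "sp. 2", is an endpoint.
_POINTER_RE = re.compile(r"^\((\d+)\.?\)$|^(\d+)\.?$")


def classify_reference(token: str) -> Reference:
    """Classify a reference token as a pointer or an endpoint.

    A trimmed token that, after stripping at most one layer of surrounding
    parentheses and at most one trailing period, consists solely of decimal
    digits is a pointer with that integer value; any other token is an
    endpoint whose label is the trimmed original token.

    Raises
    ------
    InvalidReferenceError
        If the token is empty or whitespace-only.
    """
    trimmed = token.strip()
    if not trimmed:
        raise InvalidReferenceError("reference token is empty")
    m = _POINTER_RE.match(trimmed)
    if m:
        digits = m.group(1) or m.group(2)
        value = int(digits)
        if value >= 1:
            return Pointer(value)
    return Endpoint(trimmed)


def unique_endpoints(key: Key) -> list[str]:
    """Distinct endpoint labels of a key, in first-occurrence order.

    Labels are compared by exact trimmed, case-sensitive match; a taxon that
    appears at several leads (reticulation) is listed once.  A key whose every
    lead is a pointer yields an empty list.
    """
    seen: dict[str, None] = {}
    for _, _, lead in key.iter_leads():
        if isinstance(lead.reference, Endpoint):
            seen.setdefault(lead.reference.label.strip(), None)
    return list(seen)
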