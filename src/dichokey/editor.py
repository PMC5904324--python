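"""Mutating operations on keys: insert, remove, move, copy, append, renumber,
and polytomy splitting.

All operations are pure: they return a new Key and leave the input untouched.
Following the deferred-renumbering model, edits never renumber automatically —
new and copied couplets take the number max+1 so numbers stay unique, and the
consecutive numbering may be transiently broken until :func:`renumber` is
called.  Structural fallout (dangling pointers after a removal, the
unreferenced first couplet of an appended key) is intentionally left for the
validator to report.
"""

from __future__ import annotations

from .model import Couplet, Endpoint, Key, Lead, Pointer
from .validator import is_valid, validate

__all__ = [
    "EditError",
    "RenumberRefusedError",
    "insert_couplet",
    "remove_couplet",
    "move_couplet",
    "copy_couplet",
    "cut_couplet",
    "paste_couplet",
    "append_key",
    "renumber",
    "split_polytomous",
]


class EditError(ValueError):
    """An editing operation was asked to do something impossible."""


class RenumberRefusedError(EditError):
    """Renumbering refused because the key's graph is ill-defined.

    ``blocking_codes`` names the validation-issue codes that must be fixed
    first (duplicate numbers or dangling pointers).
    """

    def __init__(self, blocking_codes: tuple[str, ...]):
        self.blocking_codes = blocking_codes
        super().__init__(
            "renumber refused; fix these issues first: " + ", ".join(blocking_codes)
        )


def _dummy_couplet(number: int) -> Couplet:
    return Couplet(number, [Lead("", Endpoint("?")), Lead("", Endpoint("?"))])


def insert_couplet(key: Key, row_position: int) -> Key:
    """Insert a dummy couplet (two empty leads, "?" endpoints) at a row.

    The new couplet is numbered max+1 (1 for an empty key); no renumbering
    occurs, so row order and numbering may diverge until :func:`renumber`.
    """
    if not 0 <= row_position <= len(key.couplets):
        raise EditError(f"row position {row_position} out of range")
    out = key.copy()
    out.couplets.insert(row_position, _dummy_couplet(key.max_number() + 1))
    return out


def remove_couplet(key: Key, number: int) -> Key:
    """Delete the couplet with the given number.

    Pointers elsewhere that targeted it are left dangling for the validator
    to report; no renumbering occurs.
    """
    if number not in set(key.numbers()):
        raise EditError(f"no couplet numbered {number}")
    out = key.copy()
    out.couplets = [c for c in out.couplets if c.number != number]
    return out


def move_couplet(key: Key, from_row: int, to_row: int) -> Key:
    """Move a row to another position; numbers and references are untouched."""
    n = len(key.couplets)
    if not (0 <= from_row < n and 0 <= to_row < n):
        raise EditError(f"row index out of range (key has {n} rows)")
    out = key.copy()
    couplet = out.couplets.pop(from_row)
    out.couplets.insert(to_row, couplet)
    return out


def copy_couplet(key: Key, number: int, row_position: int) -> Key:
    """Duplicate a couplet at a row, numbering the copy max+1.

    Lead texts and references are copied verbatim — pointers are NOT remapped,
    so the copy typically makes its endpoint labels and pointer targets
    reticulated.
    """
    source = key.by_number().get(number)
    if source is None:
        raise EditError(f"no couplet numbered {number}")
    if not 0 <= row_position <= len(key.couplets):
        raise EditError(f"row position {row_position} out of range")
    out = key.copy()
    duplicate = source.copy()
    duplicate.number = key.max_number() + 1
    out.couplets.insert(row_position, duplicate)
    return out


def cut_couplet(key: Key, number: int) -> tuple[Key, Couplet]:
    """Remove a couplet and hand back its payload for a later paste."""
    source = key.by_number().get(number)
    if source is None:
        raise EditError(f"no couplet numbered {number}")
    return remove_couplet(key, number), source.copy()


def paste_couplet(key: Key, payload: Couplet, row_position: int) -> Key:
    """Insert a previously cut/copied couplet payload, renumbered to max+1."""
    if not 0 <= row_position <= len(key.couplets):
        raise EditError(f"row position {row_position} out of range")
    out = key.copy()
    pasted = payload.copy()
    pasted.number = key.max_number() + 1
    out.couplets.insert(row_position, pasted)
    return out


def append_key(key: Key, other: Key) -> Key:
    """Combine two keys: the content of ``other`` is added at the end.

    Every couplet number and every pointer target of ``other`` is offset by
    the maximum couplet number of ``key``, so numbers stay unique and the
    appended key's internal structure is preserved.  Endpoints are untouched.
    The appended key's first couplet is initially unreferenced; the validator
    flags it until a pointer lead into it is added.
    """
    if not is_valid(other):
        raise EditError("the key to append has validation errors; fix it first")
    offset = key.max_number()
    out = key.copy()
    for couplet in other.couplets:
        moved = couplet.copy()
        moved.number += offset
        for lead in moved.leads:
            if isinstance(lead.reference, Pointer):
                lead.reference = Pointer(lead.reference.target + offset)
        out.couplets.append(moved)
    return out


def renumber(key: Key) -> Key:
    """Assign numbers 1..N in row order and remap every pointer target.

    Row order is unchanged.  Refused (with the blocking issue codes) while
    duplicate numbers or dangling pointers exist, because the old-to-new
    number map would then be ill-defined.
    """
    blocking = tuple(
        sorted({i.code for i in validate(key) if i.code in ("dup-number", "dangling-pointer")})
    )
    if blocking:
        raise RenumberRefusedError(blocking)
    mapping = {c.number: row + 1 for row, c in enumerate(key.couplets)}
    out = key.copy()
    for couplet in out.couplets:
        couplet.number = mapping[couplet.number]
        for lead in couplet.leads:
            if isinstance(lead.reference, Pointer):
                lead.reference = Pointer(mapping[lead.reference.target])
    return out


def split_polytomous(key: Key, number: int) -> Key:
    """Convert a polytomous couplet (k >= 3 leads) into a dichotomous chain.

    The couplet becomes a chain of k-1 two-lead couplets: chain couplet i
    keeps original lead i as its first lead and gains a synthesized second
    lead — the remaining original lead texts joined with " OR " — pointing to
    the next chain couplet; the final chain couplet keeps original leads k-1
    and k verbatim.  New couplets take numbers max+1, max+2, ... and sit in
    rows directly after the original; the endpoint multiset is preserved
    exactly.  The synthesized " OR " texts are meant to be reworded by the
    key's author afterwards.

    A couplet that is already dichotomous (k <= 2) is left unchanged (no-op).
    """
    source = key.by_number().get(number)
    if source is None:
        raise EditError(f"no couplet numbered {number}")
    k = len(source.leads)
    if k <= 2:
        return key.copy()

    out = key.copy()
    row = next(i for i, c in enumerate(out.couplets) if c.number == number)
    original = out.couplets[row].leads
    next_number = key.max_number()

    chain: list[Couplet] = []
    chain_numbers = [number] + [next_number + i for i in range(1, k - 1)]
    for i in range(k - 1):
        if i < k - 2:
            rest = " OR ".join(lead.text for lead in original[i + 1 :])
            leads = [original[i].copy(), Lead(rest, Pointer(chain_numbers[i + 1]))]
        else:
            leads = [original[i].copy(), original[i + 1].copy()]
        chain.append(Couplet(chain_numbers[i], leads))

    out.couplets[row : row + 1] = chain
    return out
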