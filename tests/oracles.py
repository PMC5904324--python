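"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (breadth-first
search, naive recursion, path enumeration, markup stripping) without calling
the code paths they verify.
"""

from __future__ import annotations

import re
from collections import deque

from dichokey.model import Endpoint, Key, Pointer


def bfs_reachable(key: Key, start: int) -> set[int]:
    """Breadth-first reachability over pointer references."""
    by_number = {}
    for c in key.couplets:
        assert c.number not in by_number, "oracle requires unique numbers"
        by_number[c.number] = c
    seen = {start}
    queue = deque([start])
    while queue:
        couplet = by_number[queue.popleft()]
        for lead in couplet.leads:
            if isinstance(lead.reference, Pointer):
                target = lead.reference.target
                if target not in seen:
                    seen.add(target)
                    queue.append(target)
    return seen


def recursive_remaining(key: Key, current: int) -> set[str]:
    """remaining(c) = endpoints(c) ∪ ⋃ remaining(targets(c)), naive recursion."""
    by_number = {c.number: c for c in key.couplets}

    def rec(n: int, visiting: frozenset[int]) -> set[str]:
        if n in visiting:
            return set()
        out: set[str] = set()
        for lead in by_number[n].leads:
            if isinstance(lead.reference, Endpoint):
                out.add(lead.reference.label.strip())
            else:
                out |= rec(lead.reference.target, visiting | {n})
        return out

    return rec(current, frozenset())


def enumerate_transcripts(key: Key) -> list[tuple[tuple[str, ...], str]]:
    """Every root-to-endpoint choice path as (lead texts, final taxon label).

    Paths never revisit a couplet (matching the session cycle guard); the
    result is sorted so it can be compared across renumberings.
    """
    by_number = {c.number: c for c in key.couplets}
    transcripts: list[tuple[tuple[str, ...], str]] = []

    def walk(n: int, texts: tuple[str, ...], on_path: frozenset[int]) -> None:
        for lead in by_number[n].leads:
            step = texts + (lead.text,)
            if isinstance(lead.reference, Endpoint):
                transcripts.append((step, lead.reference.label.strip()))
            elif lead.reference.target not in on_path:
                walk(lead.reference.target, step, on_path | {n})

    walk(1, (), frozenset({1}))
    return sorted(transcripts)


_RTF_UNICODE = re.compile(r"\\u(-?\d+)\?")
_RTF_CONTROL = re.compile(r"\\([a-z]+)(-?\d+)? ?")


def rtf_to_text(rtf: str) -> str:
    """Strip RTF markup down to plain text (tabs and paragraph breaks kept)."""
    body = rtf.strip()
    assert body.startswith("{\\rtf1") and body.endswith("}")
    assert body.count("{") == body.count("}"), "unbalanced RTF groups"
    # Drop the font table group entirely.
    body = re.sub(r"\{\\fonttbl.*?\}\}", "", body, flags=re.S)
    body = _RTF_UNICODE.sub(lambda m: chr(int(m.group(1)) % 65536), body)

    def control(m: re.Match) -> str:
        word = m.group(1)
        if word == "par":
            return "\n"
        if word == "tab":
            return "\t"
        return ""

    body = _RTF_CONTROL.sub(control, body)
    body = body.replace("\\{", "{").replace("\\}", "}").replace("\\\\", "\\")
    body = body.replace("{", "").replace("}", "")
    return "\n".join(line.strip() for line in body.replace("\r", "").split("\n"))
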