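"""Structural validation of keys: logical errors and reticulation warnings.

The restrictions on a sound key are: couplet numbers are unique, start at 1
and are consecutive; every pointer resolves to an existing couplet; every
couplet other than couplet 1 is referenced by at least one pointer; and every
couplet is reachable from couplet 1.  A couplet must hold exactly two leads.
Reticulation — the same endpoint label occurring more than once, or a couplet
referred to by more than one couplet — is allowed but reported as a warning,
as are cycles and empty lead texts.

``validate`` never mutates the key; issues are reported in check order, then
by ascending couplet number, so diagnostic output is stable.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .model import Endpoint, Key, Pointer

__all__ = ["ValidationIssue", "validate", "is_valid", "ERROR_CODES", "WARNING_CODES"]

ERROR_CODES = (
    "dup-number",
    "not-starting-at-1",
    "not-consecutive",
    "dangling-pointer",
    "unreferenced-couplet",
    "unreachable-couplet",
    "bad-lead-count",
)
WARNING_CODES = (
    "reticulated-endpoint",
    "reticulated-couplet",
    "cycle",
    "empty-lead",
)


@dataclass(frozen=True)
class ValidationIssue:
    """One structural error or warning.

    ``couplets`` lists the involved couplet numbers (for a reticulated
    endpoint: the couplets carrying the label; for a reticulated couplet: the
    target couplet; for a cycle: the members of the cycle).
    """

    severity: str  # "error" | "warning"
    code: str
    couplets: tuple[int, ...]
    message: str
    label: str | None = field(default=None, compare=False)

    def __str__(self) -> str:
        nums = ", ".join(str(n) for n in self.couplets)
        return f"{self.severity.upper()} {self.code} couplet(s) {nums}: {self.message}"


def _pointer_edges(key: Key) -> list[tuple[int, int]]:
    """(source couplet number, target couplet number) for every pointer lead."""
    return [
        (couplet.number, lead.reference.target)
        for couplet, _, lead in key.iter_leads()
        if isinstance(lead.reference, Pointer)
    ]


def _reachable(adjacency: dict[int, list[int]], start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        for nxt in adjacency.get(stack.pop(), ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def validate(key: Key) -> list[ValidationIssue]:
    """Return all structural issues of a key, in deterministic order.

    Any key state is accepted, including transiently broken editing states.
    An empty issue list means the key is valid.  Reachability and cycle checks
    are suppressed while duplicate numbers or dangling pointers exist (the
    couplet graph is then ill-defined) and when no couplet is numbered 1.
    """
    issues: list[ValidationIssue] = []
    numbers = key.numbers()
    number_counts = Counter(numbers)
    number_set = set(numbers)
    edges = _pointer_edges(key)

    # dup-number
    duplicated = sorted(n for n, c in number_counts.items() if c > 1)
    for n in duplicated:
        issues.append(
            ValidationIssue(
                "error", "dup-number", (n,),
                f"couplet number {n} appears on {number_counts[n]} rows",
            )
        )

    # not-starting-at-1 (skipped for an empty key)
    if numbers and min(numbers) != 1:
        issues.append(
            ValidationIssue(
                "error", "not-starting-at-1", (min(numbers),),
                f"the smallest couplet number is {min(numbers)}, not 1",
            )
        )

    # not-consecutive
    distinct = sorted(number_set)
    if numbers and distinct != list(range(1, len(distinct) + 1)):
        issues.append(
            ValidationIssue(
                "error", "not-consecutive", tuple(distinct),
                "couplet numbers are not the consecutive sequence 1..N",
            )
        )

    # dangling-pointer
    dangling = sorted({(src, tgt) for src, tgt in edges if tgt not in number_set})
    for src, tgt in dangling:
        issues.append(
            ValidationIssue(
                "error", "dangling-pointer", (src,),
                f"couplet {src} points to couplet {tgt}, which does not exist",
            )
        )

    # unreferenced-couplet
    targeted = {tgt for _, tgt in edges}
    for n in distinct:
        if n != 1 and n not in targeted:
            issues.append(
                ValidationIssue(
                    "error", "unreferenced-couplet", (n,),
                    f"no pointer in the key refers to couplet {n}",
                )
            )

    graph_ok = not duplicated and not dangling and 1 in number_set
    adjacency: dict[int, list[int]] = defaultdict(list)
    for src, tgt in edges:
        adjacency[src].append(tgt)

    # unreachable-couplet (only on a well-defined graph)
    if graph_ok:
        reachable = _reachable(adjacency, 1)
        for n in distinct:
            if n not in reachable:
                issues.append(
                    ValidationIssue(
                        "error", "unreachable-couplet", (n,),
                        f"couplet {n} cannot be reached from couplet 1",
                    )
                )

    # bad-lead-count
    for couplet in sorted(key.couplets, key=lambda c: c.number):
        if len(couplet.leads) != 2:
            issues.append(
                ValidationIssue(
                    "error", "bad-lead-count", (couplet.number,),
                    f"couplet {couplet.number} has {len(couplet.leads)} leads instead of 2",
                )
            )

    # reticulated-endpoint: the same endpoint label occurs in more than one lead
    label_couplets: dict[str, list[int]] = defaultdict(list)
    label_leads: Counter[str] = Counter()
    for couplet, _, lead in key.iter_leads():
        if isinstance(lead.reference, Endpoint):
            label = lead.reference.label.strip()
            label_leads[label] += 1
            label_couplets[label].append(couplet.number)
    for label in sorted(label_leads, key=lambda lb: (min(label_couplets[lb]), lb)):
        if label_leads[label] > 1:
            nums = tuple(sorted(set(label_couplets[label])))
            issues.append(
                ValidationIssue(
                    "warning", "reticulated-endpoint", nums,
                    f"endpoint {label!r} occurs in {label_leads[label]} leads",
                    label=label,
                )
            )

    # reticulated-couplet: a couplet targeted by pointers from >1 distinct couplet
    sources_by_target: dict[int, set[int]] = defaultdict(set)
    for src, tgt in edges:
        sources_by_target[tgt].add(src)
    for tgt in sorted(sources_by_target):
        sources = sources_by_target[tgt]
        if len(sources) > 1 and tgt in number_set:
            issues.append(
                ValidationIssue(
                    "warning", "reticulated-couplet", (tgt,),
                    f"couplet {tgt} is referred to by couplets "
                    + ", ".join(str(s) for s in sorted(sources)),
                )
            )

    # cycle: following pointers from couplet 1 can revisit a couplet
    if graph_ok:
        cyclic = sorted(
            n for n in _reachable(adjacency, 1)
            if n in number_set and any(n in _reachable(adjacency, t) for t in adjacency.get(n, ()))
        )
        if cyclic:
            issues.append(
                ValidationIssue(
                    "warning", "cycle", tuple(cyclic),
                    "pointer cycles can revisit these couplets during identification",
                )
            )

    # empty-lead
    for couplet in sorted(key.couplets, key=lambda c: c.number):
        if any(not lead.text.strip() for lead in couplet.leads):
            issues.append(
                ValidationIssue(
                    "warning", "empty-lead", (couplet.number,),
                    f"couplet {couplet.number} has a lead with empty text",
                )
            )

    return issues


def is_valid(key: Key) -> bool:
    """True iff ``validate`` finds no error-severity issue.

    Warnings (reticulation, cycles, empty lead texts) are permitted, since
    reticulate key structures are legal.
    """
    return not any(issue.severity == "error" for issue in validate(key))
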