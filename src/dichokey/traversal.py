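"""Key-graph analytics and stepwise identification sessions.

These operations power the interactive browser: reachability over the pointer
graph, the remaining/excluded endpoint partition shown beside the current
couplet, and identification sessions with a clickable history (backtracking).

Under reticulation, "remaining" follows reachability semantics: a taxon is
remaining at a couplet if ANY of its endpoint occurrences sits on a couplet
reachable from there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .model import Endpoint, Key, Pointer, unique_endpoints
from .validator import is_valid

__all__ = [
    "TraversalError",
    "CycleDetectedError",
    "EndpointPartition",
    "IdentificationSession",
    "reachable_couplets",
    "partition_endpoints",
    "start_session",
    "choose_lead",
    "backtrack",
]


class TraversalError(ValueError):
    """Raised when a traversal operation's precondition is violated."""


class CycleDetectedError(TraversalError):
    """Choosing this lead would revisit a couplet already on the path."""


@dataclass(frozen=True)
class EndpointPartition:
    """The remaining/excluded split of a key's taxa at a couplet.

    ``remaining`` lists the taxa that can still be reached from the current
    couplet; ``excluded`` those that no longer can.  Together they are exactly
    the key's unique endpoints; the two lists are disjoint and both keep the
    key's first-occurrence label order.
    """

    remaining: tuple[str, ...]
    excluded: tuple[str, ...]


def _check_graph(key: Key) -> dict[int, list[int]]:
    """Adjacency map of the pointer graph; rejects ill-defined graphs."""
    numbers = key.numbers()
    if len(set(numbers)) != len(numbers):
        raise TraversalError("key has duplicate couplet numbers")
    number_set = set(numbers)
    adjacency: dict[int, list[int]] = {n: [] for n in numbers}
    for couplet, _, lead in key.iter_leads():
        if isinstance(lead.reference, Pointer):
            if lead.reference.target not in number_set:
                raise TraversalError(
                    f"couplet {couplet.number} has a dangling pointer "
                    f"to {lead.reference.target}"
                )
            adjacency[couplet.number].append(lead.reference.target)
    return adjacency


def reachable_couplets(key: Key, start: int) -> set[int]:
    """Couplet numbers reachable from ``start`` (inclusive) via pointers.

    Requires a well-defined graph: unique couplet numbers, no dangling
    pointers, and an existing start couplet.
    """
    adjacency = _check_graph(key)
    if start not in adjacency:
        raise TraversalError(f"no couplet numbered {start}")
    seen = {start}
    stack = [start]
    while stack:
        for nxt in adjacency[stack.pop()]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def partition_endpoints(key: Key, current: int) -> EndpointPartition:
    """Split the key's taxa into remaining and excluded at a couplet.

    Remaining are the endpoint labels on leads of any couplet reachable from
    ``current``; excluded are all other taxa of the key.  At couplet 1 every
    taxon is remaining and the excluded list is empty.
    """
    reachable = reachable_couplets(key, current)
    by_number = key.by_number()
    remaining_set = {
        lead.reference.label.strip()
        for n in reachable
        for lead in by_number[n].leads
        if isinstance(lead.reference, Endpoint)
    }
    everything = unique_endpoints(key)
    return EndpointPartition(
        remaining=tuple(t for t in everything if t in remaining_set),
        excluded=tuple(t for t in everything if t not in remaining_set),
    )


@dataclass(frozen=True)
class IdentificationSession:
    """State of one stepwise identification.

    ``current`` is the couplet now displayed; ``path`` is the history of
    (couplet number, chosen lead index) pairs leading here — replaying it from
    couplet 1 reproduces ``current``.  When an endpoint lead is chosen the
    session is finished and ``result`` holds the taxon label.  Path couplet
    numbers are pairwise distinct (cycle guard).
    """

    key: Key
    current: int
    path: tuple[tuple[int, int], ...] = ()
    result: str | None = None

    @property
    def finished(self) -> bool:
        return self.result is not None

    def partition(self) -> EndpointPartition:
        """Remaining/excluded taxa at the current couplet."""
        return partition_endpoints(self.key, self.current)


def start_session(key: Key) -> IdentificationSession:
    """Begin identification at couplet 1 with an empty path.

    Refused for keys with validation errors (warnings are fine: reticulated
    keys are traversable; cycles are guarded per step).
    """
    if not is_valid(key):
        raise TraversalError("cannot start a session on a key with validation errors")
    return IdentificationSession(key=key, current=1)


def choose_lead(session: IdentificationSession, lead_index: int) -> IdentificationSession:
    """Follow one lead of the current couplet.

    A pointer lead advances to its target couplet; an endpoint lead finishes
    the session with that taxon label.  Advancing into a couplet already on
    the path is refused (cycle guard for reticulated keys with cycles).
    """
    if session.finished:
        raise TraversalError("the identification is already finished")
    couplet = session.key.by_number()[session.current]
    if not 0 <= lead_index < len(couplet.leads):
        raise TraversalError(f"lead index {lead_index} out of range")
    reference = couplet.leads[lead_index].reference
    path = session.path + ((session.current, lead_index),)
    if isinstance(reference, Endpoint):
        return replace(session, path=path, result=reference.label.strip())
    if any(reference.target == n for n, _ in path):
        raise CycleDetectedError(
            f"couplet {reference.target} is already on the identification path"
        )
    return replace(session, path=path, current=reference.target)


def backtrack(session: IdentificationSession, path_position: int) -> IdentificationSession:
    """Return to an earlier identification step by truncating the history.

    The path is cut to ``path_position`` entries and the current couplet
    becomes the couplet of the first removed entry (unchanged if nothing is
    removed); any finished state is cleared.  ``backtrack(s, 0)`` resets to
    the start of identification.
    """
    if not 0 <= path_position <= len(session.path):
        raise TraversalError(f"path position {path_position} out of range")
    if path_position == len(session.path):
        return replace(session, result=None)
    current = session.path[path_position][0]
    return replace(session, path=session.path[:path_position], current=current, result=None)
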