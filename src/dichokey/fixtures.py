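"""Deterministic synthetic-key generation and error injection.

``generate_key`` builds random but reproducible dichotomous keys with the
canonical structure: a binary tree of couplets numbered 1..N in breadth-first
order whose leaves are taxon endpoints, optionally rewired into a (still
valid) reticulate key.  ``inject_error`` plants exactly one class of
structural defect so validator behaviour can be exercised without external
data.  Everything is a pure function of its spec/seed, byte-exact through the
text serialization.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .model import Couplet, Endpoint, Key, Lead, Pointer
from .validator import ERROR_CODES

__all__ = ["FixtureSpec", "generate_key", "inject_error", "INJECTABLE_CODES"]

#: Error codes :func:`inject_error` can plant.
INJECTABLE_CODES = (
    "dup-number",
    "dangling-pointer",
    "unreferenced-couplet",
    "not-consecutive",
    "bad-lead-count",
)

# Small vocabulary for plausible-looking lead texts.
_CHARACTERS = (
    "antenna", "forewing", "pronotum", "tarsus", "ocellus",
    "mandible", "elytron", "tergite", "palp", "spiracle",
)
_STATES = (
    "smooth", "punctate", "carinate", "setose", "glabrous",
    "dark brown", "yellowish", "elongate", "reduced", "bilobed",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic key.

    ``couplets`` internal nodes, reticulation rewiring probability per
    endpoint lead, RNG seed, and the prefix for generated taxon labels.
    """

    couplets: int = 7
    reticulation: float = 0.0
    seed: int = 0
    taxon_prefix: str = "Taxon"

    def __post_init__(self) -> None:
        if self.couplets < 1:
            raise ValueError("couplet count must be >= 1")
        if not 0.0 <= self.reticulation <= 1.0:
            raise ValueError("reticulation probability must be in [0, 1]")


def _lead_text(rng: random.Random) -> str:
    return f"{rng.choice(_CHARACTERS).capitalize()} {rng.choice(_STATES)}"


def generate_key(spec: FixtureSpec) -> Key:
    """Generate a deterministic, always-valid synthetic key.

    A random binary-tree shape with ``spec.couplets`` internal nodes is grown
    first; internal nodes become couplets numbered 1..N in breadth-first
    order and leaves become endpoints labeled ``<prefix>-001`` onward.  With
    probability ``spec.reticulation`` an endpoint lead is then rewired: it
    either duplicates another taxon label (reticulated endpoint) or becomes a
    pointer to a higher-numbered couplet (reticulated couplet).  Rewiring
    only ever adds pointers toward higher numbers, so the key stays acyclic
    and every couplet stays referenced and reachable: the result always
    passes validation (warnings aside).
    """
    rng = random.Random(spec.seed)
    n = spec.couplets

    # Tree shape: children[i] = [left, right]; entries are ("node", j) for an
    # internal child or ("leaf", None) placeholders refined below.
    children: dict[int, list[int | None]] = {0: [None, None]}
    # Slots available to become internal nodes: (parent, side).
    slots: list[tuple[int, int]] = [(0, 0), (0, 1)]
    for new_node in range(1, n):
        parent, side = slots.pop(rng.randrange(len(slots)))
        children[parent][side] = new_node
        children[new_node] = [None, None]
        slots.extend([(new_node, 0), (new_node, 1)])

    # Breadth-first numbering of internal nodes.
    order: list[int] = [0]
    for node in order:
        order.extend(c for c in children[node] if c is not None)
    number_of = {node: i + 1 for i, node in enumerate(order)}

    taxon_counter = 0
    couplets: list[Couplet] = []
    for node in order:
        leads = []
        for child in children[node]:
            if child is None:
                taxon_counter += 1
                ref: Pointer | Endpoint = Endpoint(
                    f"{spec.taxon_prefix}-{taxon_counter:03d}"
                )
            else:
                ref = Pointer(number_of[child])
            leads.append(Lead(_lead_text(rng), ref))
        couplets.append(Couplet(number_of[node], leads))
    key = Key(couplets=couplets, title=f"Synthetic key ({n} couplets, seed {spec.seed})")

    if spec.reticulation > 0:
        labels = [
            f"{spec.taxon_prefix}-{i:03d}" for i in range(1, taxon_counter + 1)
        ]
        for couplet in key.couplets:
            for i, lead in enumerate(couplet.leads):
                if not isinstance(lead.reference, Endpoint):
                    continue
                if rng.random() >= spec.reticulation:
                    continue
                higher = [c.number for c in key.couplets if c.number > couplet.number]
                other_labels = [lb for lb in labels if lb != lead.reference.label]
                # Re-point toward a higher-numbered couplet (keeps the graph
                # acyclic) or duplicate an existing taxon label.
                if higher and (not other_labels or rng.random() < 0.5):
                    couplet.leads[i] = Lead(lead.text, Pointer(rng.choice(higher)))
                elif other_labels:
                    couplet.leads[i] = Lead(
                        lead.text, Endpoint(rng.choice(other_labels))
                    )
    return key


def inject_error(key: Key, code: str, seed: int = 0) -> Key:
    """Return a minimally mutated copy for which validation reports ``code``.

    Supported codes: dup-number, dangling-pointer, unreferenced-couplet,
    not-consecutive, bad-lead-count.  The input key is never modified.
    Raises ``ValueError`` when the defect cannot exist (dup-number in a
    one-couplet key) or the code is not injectable.
    """
    if code not in INJECTABLE_CODES:
        known = ", ".join(INJECTABLE_CODES)
        raise ValueError(f"cannot inject {code!r}; injectable codes: {known}")
    assert code in ERROR_CODES
    rng = random.Random(seed)
    out = key.copy()
    couplets = out.couplets

    if code == "dup-number":
        if len(couplets) < 2:
            raise ValueError("dup-number needs at least two couplets")
        a, b = rng.sample(range(len(couplets)), 2)
        couplets[a].number = couplets[b].number
    elif code == "dangling-pointer":
        bogus = out.max_number() + 99
        pointer_slots = [
            (c, i)
            for c in couplets
            for i, lead in enumerate(c.leads)
            if isinstance(lead.reference, Pointer)
        ]
        if pointer_slots:
            couplet, i = rng.choice(pointer_slots)
            couplet.leads[i].reference = Pointer(bogus)
        else:  # one-couplet key: sacrifice an endpoint lead
            couplet = rng.choice(couplets)
            i = rng.randrange(len(couplet.leads))
            couplet.leads[i].reference = Pointer(bogus)
    elif code == "unreferenced-couplet":
        number = out.max_number() + 1
        couplets.append(
            Couplet(number, [Lead("", Endpoint("?")), Lead("", Endpoint("?"))])
        )
    elif code == "not-consecutive":
        target = rng.choice([c for c in couplets if c.number != 1] or couplets)
        old, new = target.number, out.max_number() + 2
        target.number = new
        for c in couplets:
            for lead in c.leads:
                if isinstance(lead.reference, Pointer) and lead.reference.target == old:
                    lead.reference = Pointer(new)
    elif code == "bad-lead-count":
        couplet = rng.choice(couplets)
        couplet.leads.append(Lead("(extra state)", Endpoint("Taxon-extra")))
    return out
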