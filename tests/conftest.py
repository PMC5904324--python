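import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from dichokey.model import Couplet, Endpoint, Key, Lead, Pointer


@pytest.fixture
def minimal_key() -> Key:
    """Single couplet, two endpoint leads: the smallest valid key."""
    return Key(
        couplets=[
            Couplet(
                1,
                [
                    Lead("Wings present", Endpoint("Taxon A")),
                    Lead("Wings absent", Endpoint("Taxon B")),
                ],
            )
        ]
    )


@pytest.fixture
def chain_key() -> Key:
    """Three couplets in a chain 1 -> 2 -> 3, four taxa."""
    return Key(
        couplets=[
            Couplet(1, [Lead("Large", Pointer(2)), Lead("Small", Endpoint("A"))]),
            Couplet(2, [Lead("Dark", Pointer(3)), Lead("Pale", Endpoint("B"))]),
            Couplet(3, [Lead("Smooth", Endpoint("C")), Lead("Rough", Endpoint("D"))]),
        ]
    )


@pytest.fixture
def balanced_key() -> Key:
    """1 -> (2, 3); 2 -> (A, B); 3 -> (C, D)."""
    return Key(
        couplets=[
            Couplet(1, [Lead("Winged", Pointer(2)), Lead("Wingless", Pointer(3))]),
            Couplet(2, [Lead("Dark", Endpoint("A")), Lead("Pale", Endpoint("B"))]),
            Couplet(3, [Lead("Smooth", Endpoint("C")), Lead("Rough", Endpoint("D"))]),
        ]
    )


WINGS_TEXT = (
    "1. Wings present\t2\n"
    "– Wings absent\tApterygota\n"
    "2. Two pairs of wings\tPterygota A\n"
    "– One pair of wings\tPterygota B\n"
)


@pytest.fixture
def wings_lines() -> list[str]:
    return WINGS_TEXT.splitlines()
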