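"""Split a three-lead couplet into dichotomous couplets, then renumber.

Printed keys occasionally contain trichotomies.  To stay dichotomous, such a
couplet is converted into a chain of two-lead couplets: each chain step keeps
one original lead and gains a synthesized "... OR ..." lead pointing onward
(meant to be reworded by the author).  The new couplets take numbers above the
current maximum, so a final renumbering restores consecutive 1..N order.
"""

from dichokey import parse_key_text, renumber, split_polytomous, to_text, validate

RAW = """\
1. Stem woody\t2
– Stem herbaceous\tHerbacea
2. Leaves opposite\tOppositifolia
– Leaves alternate\tAlternifolia
– Leaves whorled\tVerticillata
"""

key, _ = parse_key_text(RAW.splitlines())
print("before repair, the validator finds:")
for issue in validate(key):
    print(" ", issue)

split = split_polytomous(key, 2)      # couplet 2 becomes a chain of 2 couplets
repaired = renumber(split)            # numbers 1..3 again, pointers remapped
print("\nafter split + renumber (0 errors):")
print(to_text(repaired))
# The trichotomy became couplets 2 and 3; every couplet now has two leads.
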