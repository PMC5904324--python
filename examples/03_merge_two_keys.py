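"""Combine two keys: append one at the end of the other.

Appending offsets the second key's couplet numbers and pointers by the first
key's maximum number, so both keys keep their internal structure.  The
appended key's first couplet is initially unreferenced — the validator flags
it until the author adds a pointer lead into it (here: replacing an endpoint
of the host key with a pointer to the appended root).
"""

from dichokey import (
    FixtureSpec, Lead, Pointer, append_key, generate_key, to_text, validate,
)

families = generate_key(FixtureSpec(couplets=3, seed=5, taxon_prefix="Family"))
genera = generate_key(FixtureSpec(couplets=2, seed=8, taxon_prefix="Genus"))

merged = append_key(families, genera)
print(f"merged: {len(merged.couplets)} couplets "
      f"(3 + 2, appended part renumbered 4..5)")
for issue in validate(merged):
    print(" ", issue)

# Wire the appended sub-key in: one family endpoint now continues at couplet 4.
lead = merged.couplets[2].leads[1]
merged.couplets[2].leads[1] = Lead(lead.text, Pointer(4))
print("\nafter adding a pointer into the appended root:")
print(to_text(merged))
print("errors now:", sum(i.severity == "error" for i in validate(merged)))
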