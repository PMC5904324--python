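"""Import a prepared plain-text key and validate its structure.

A bracketed key is prepared with one lead per line and a tab before each
reference.  The parser is deliberately forgiving — structural defects are
left in the key and reported by the validator, so the author can fix the
source text and re-import.
"""

from dichokey import parse_key_text, validate

RAW = """\
1. Wings present\t2
– Wings absent\tApterygota
2. Two pairs of wings\t3
– One pair of wings\tDiptera
3. Wings membranous\tHymenoptera
– Forewings hardened\tColeoptera
"""

key, diagnostics = parse_key_text(RAW.splitlines())
print(f"parsed {len(key.couplets)} couplets, {len(diagnostics)} parse diagnostics")

issues = validate(key)
if not issues:
    print("validation: clean — numbering consecutive, all pointers resolve,")
    print("every couplet reachable from couplet 1, two leads everywhere.")
for issue in issues:
    print(issue)
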