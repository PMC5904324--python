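# dichokey

A library and command-line tool for editing, validating, traversing and
publishing **dichotomous identification keys** (also called single-access
keys) — the numbered-couplet keys that remain the standard identification
tool in taxonomy.

Most taxonomists build such keys in a plain text editor, where the mechanical
part — keeping couplet numbers consecutive and pointers consistent while
couplets are inserted, removed, moved or merged — is tedious and error-prone,
especially for keys with hundreds of couplets. `dichokey` is aimed at two
audiences: taxonomic experts preparing keys for publication, and users who
want an existing printed key as a clickable, offline identification page.

## The data model

A key is an ordered sequence of numbered **couplets**; each couplet holds two
contrasting **leads**, and each lead ends in a **reference** — either a
**pointer** to another couplet or an **endpoint** naming a taxon.
Identification starts at couplet 1 and follows pointers until an endpoint is
reached. A structurally sound key satisfies:

* couplet numbers are unique, start at 1 and are consecutive (1..N);
* every pointer resolves to an existing couplet;
* every couplet except couplet 1 is referenced by at least one pointer, and
  every couplet is reachable from couplet 1;
* every couplet has exactly two leads.

**Reticulation** — the same taxon at several endpoints, or a couplet reached
over more than one path — is legal but reported as a warning, as are pointer
cycles and empty lead texts. Editing operations deliberately do **not**
renumber automatically: numbering may stay transiently broken while you work,
and `renumber()` restores 1..N (in row order, remapping all pointers) when
you decide — typically right before export.

During traversal the key's taxa split, at every couplet, into **remaining**
(still reachable) and **excluded** (no longer reachable) endpoints; along any
choice path the remaining set only shrinks and the excluded set only grows.

## Worked example: import, repair a trichotomy, republish

Printed keys occasionally contain a couplet with three leads. Import the key,
split the polytomy into a dichotomous chain, renumber, and export:

```python
from dichokey import parse_key_text, renumber, split_polytomous, to_text, validate

RAW = """\
1. Stem woody\t2
– Stem herbaceous\tHerbacea
2. Leaves opposite\tOppositifolia
– Leaves alternate\tAlternifolia
– Leaves whorled\tVerticillata
"""

key, diagnostics = parse_key_text(RAW.splitlines())
for issue in validate(key):
    print(issue)
repaired = renumber(split_polytomous(key, 2))
print(to_text(repaired))
```

prints

```
ERROR bad-lead-count couplet(s) 2: couplet 2 has 3 leads instead of 2
1. Stem woody	2
– Stem herbaceous	Herbacea
2. Leaves opposite	Oppositifolia
– Leaves alternate OR Leaves whorled	3
3. Leaves alternate	Alternifolia
– Leaves whorled	Verticillata
```

The three-lead couplet 2 became two dichotomous couplets (the synthesized
"… OR …" lead is meant to be reworded by the author); renumbering closed the
numbering gap, and the repaired key validates with zero errors. The
`examples/` directory holds one short narrative script per capability:
import/validation, polytomy repair, merging keys, identification sessions
with remaining/excluded partitions, and publishing (text, XML, RTF, and the
self-contained interactive HTML browser with its five panels — two leads,
path, remaining and excluded endpoints).

## Command line

```sh
dichokey gen --couplets 8 --seed 1 -o key.xml     # synthetic key
dichokey validate key.xml                          # errors + warnings, exit code
dichokey convert key.xml --to text -o key.txt      # text/xml/html/rtf
dichokey merge a.xml b.xml -o merged.xml           # append b at the end of a
dichokey split key.xml 2 -o fixed.xml              # split a polytomous couplet
dichokey renumber fixed.xml -o final.xml           # consecutive 1..N
dichokey browse final.xml -o key.html --images figs/
dichokey identify final.xml                        # stepwise session in the terminal
```

Input format (bracketed text vs XML) is auto-detected by content.

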