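# Methods

This note records the model this package implements, the behaviour contracts
it guarantees, and the design decisions taken where the problem left room.

## The key model and its soundness rules

A dichotomous key is stored as an ordered list of couplets; **row order and
couplet numbers are independent**. This is the one structural decision
everything else follows from: editing operations (insert, remove, move, copy,
append) may leave numbering non-consecutive or out of row order without
losing the author's intended layout, and no invariant is enforced at
construction time. Soundness is checked exclusively by the validator, which
reports, as **errors**: duplicate couplet numbers, numbering not starting at
1 or not consecutive, dangling pointers, couplets (other than 1) referenced
by no pointer, couplets unreachable from couplet 1, and couplets without
exactly two leads; and as **warnings**: reticulated endpoints (a label on
more than one lead), reticulated couplets (targeted from more than one
couplet), pointer cycles, and empty lead texts. Reticulation is legal; a key
"is valid" iff it has no errors.

Two cascade-suppression choices keep diagnostics readable: reachability and
cycle checks are skipped while duplicate numbers or dangling pointers exist
(the pointer graph is then ill-defined), and also when no couplet is numbered
1 (every couplet would otherwise be reported unreachable on top of the
not-starting-at-1 error). Cycles are a warning rather than an error: nothing
in the soundness rules forbids them, and identification sessions guard
against them independently. A pointer back to couplet 1 is legal. Issues are
emitted in fixed check order, then by ascending couplet number, so output is
stable for tests and diffs.

## Parsing

The importer accepts the *bracketed* text convention: one lead per line, a
tab before each reference. A line opening with an integer (optionally
followed by `.` `)` `'` `–`, and optionally a single parenthesized
back-reference group, the `12(3)` dialect) starts a new couplet; subsequent
non-blank lines add leads, with one leading dash marker (`–`, `—`, `-`,
`--`) stripped. The **last** tab in a line splits lead text from reference —
lead text pasted from PDFs may itself contain tabs. Reference tokens that
are digits after stripping at most one layer of parentheses and one trailing
period (`7`, `7.`, `(7)`) are pointers; everything else, including labels
with embedded digits such as `sp. 2`, is an endpoint, treated as opaque text
(no taxon-name normalization; identity is exact trimmed case-sensitive
match).

Parsing never raises on malformed structure. Recoverable line problems
become diagnostics: `missing-separator` (no usable tab; the trailing word is
taken as an endpoint best-effort), `empty-lead-text`, `orphan-line` (content
before the first couplet), and `no-couplet-number` (a tab-bearing, lead-like
line before any couplet has opened — the distinction from `orphan-line` is
this package's interpretation). Structural defects — three-lead couplets,
duplicate numbers, bad pointers — are deliberately left in the key for the
validator, supporting the import → validate → fix source → re-import loop.
Joining of hard-wrapped lead lines is not attempted automatically; that fix
belongs in the source text. A second-lead line repeating the current couplet
number (e.g. `1'.`) is treated as continuing the couplet, a documented
dialect risk. Encoding is fixed to UTF-8.

## Editing semantics

New, copied and pasted couplets always take number max+1, so numbers remain
unique at all times and renumbering stays a separate, user-triggered step.
`renumber` assigns 1..N **in row order** (the table layout is the author's
intent; no traversal-order renumbering) and remaps every pointer through the
old→new map; it refuses to run while duplicate numbers or dangling pointers
make that map ill-defined. `append_key` offsets the appended key's numbers
and internal pointers by the host key's maximum; its first couplet is then
legitimately unreferenced (and its whole subtree unreachable) until the
author wires a pointer into it — the validator flagging this is the intended
workflow, not a defect. Removal leaves dangling pointers for the validator
rather than silently rewriting leads. Cut/paste is modeled as remove +
insert-with-payload; there is no system clipboard, undo stack, or automatic
couplet-ordering optimization.

`split_polytomous` linearizes a k-lead couplet (k ≥ 3) into a chain of k−1
dichotomous couplets: chain step i keeps original lead i and gains a
synthesized second lead joining the remaining lead texts with `" OR "`,
pointing at the next step; the last step keeps the final two leads verbatim.
The `" OR "` text is visibly synthetic so an expert can reword it. The
operation is never run implicitly; the endpoint multiset is preserved
exactly. Renumbering transcripts: the full set of root-to-endpoint
identification transcripts (lead-text sequences plus final taxon) is
invariant under renumbering, and under move+renumber provided row 0 keeps
the root — moving a different couplet into row 0 deliberately changes which
couplet becomes number 1, which is a semantic edit, not a renumbering
artifact; tests and the acceptance script therefore move non-root rows.

## Traversal

`reachable_couplets` is transitive closure over pointer references;
`partition_endpoints` splits the key's taxa at a couplet into remaining
(label on any reachable couplet) and excluded (the rest), both in the key's
first-occurrence order. Under reticulation, *remaining* uses reachability
semantics — a taxon is remaining if **any** of its occurrences is reachable —
rather than path-consistency semantics; consequently a taxon can sit in the
remaining list even when the specific path taken has passed one of its other
occurrences. Along any choice path remaining sets are nested decreasing and
excluded sets nested increasing, because reachable sets are.

Identification sessions start at couplet 1 (valid keys only), record
(couplet, chosen-lead) pairs, finish on an endpoint, and refuse a choice
into a couplet already on the path (cycle guard — the validator warns about
cycles globally; the session guard makes traversal terminate regardless).
Backtracking truncates the history to a given position and resumes at the
couplet of the first removed entry; backtracking to position 0 is a full
reset. Partitions are recomputed per couplet; with key sizes in the
hundreds of couplets this is well below interactive latency, so no
incremental update is maintained.

## Serialization

* **Text** — the canonical bracketed dialect the parser re-reads exactly:
  `N. text<TAB>ref` / `– text<TAB>ref`, LF, UTF-8, no blank lines. Export
  refuses duplicate numbers (renumber first). Round-trip identity
  (`parse ∘ to_text = id`) holds for generated keys; a hand-built key whose
  endpoint label is itself digits-only would reparse as a pointer — a
  documented dialect limit of the text format (XML has no such ambiguity).
* **XML** — this project's own versioned schema (`<dkey version="1">`,
  `<couplet number>`, `<lead><text> + <pointer>|<endpoint>`), chosen as the
  save/exchange format because it survives any editing state, including
  broken ones, and carries international characters safely. Reading other
  tools' formats is out of scope. Schema errors name the offending element;
  well-formedness errors carry line/column from the XML parser.
* **HTML** — one page, anchors `couplet-N`, pointers as in-page links,
  endpoints emphasized, text escaped, figures inlined next to their lead.
* **RTF** — intentionally minimal (header, one paragraph per lead, bold
  couplet numbers, non-ASCII as signed `\uN?` escapes): valid and
  word-processor-openable, with content identical to the text export modulo
  markup; no attempt at journal styling.
* **Browser** — a single self-contained HTML file with the key, precomputed
  per-couplet partitions, and images embedded as data URIs; a small script
  renders the five panels and handles advancing, backtracking and the final
  taxon display. Generating a static file (rather than shipping a GUI)
  keeps the repository free of a widget toolkit while reproducing the
  browser semantics exactly; panel contents equal the library's
  `partition_endpoints` output by construction and by test.

Figure linking searches lead texts for `Fig.`/`Figs` followed by
comma/dash-separated integers (`Figs 3–5` yields {3, 5}; ranges are not
expanded) and binds figure n to the first existing `fig<n>.*` or
`figure<n>.*` file (png/jpg/jpeg/gif/svg, case-insensitive) in the image
directory; the stem patterns are configurable. Unmatched numbers are
skipped silently, so a key with partial figure coverage still exports.

## Synthetic keys and what tests show

The fixture generator grows a uniformly random binary-tree *shape* with N
internal nodes, numbers the internal nodes 1..N breadth-first (yielding the
human-plausible consecutive layout of published keys), labels leaves
`Taxon-001`… and fills lead texts from a small morphological vocabulary.
With reticulation probability p (default 0; 0.2 in the round-trip suites,
matching a modest level of taxon duplication), each endpoint lead is
independently rewired: half the time re-pointed at a higher-numbered couplet
(creating a reticulated couplet while provably preserving acyclicity,
reachability and referencedness — breadth-first numbering increases along
tree edges), otherwise relabeled to another existing taxon (reticulated
endpoint). Generated keys therefore always validate error-free, p = 0 keys
are exact binary trees (n couplets ⇒ n+1 endpoint leads), and generation is
byte-deterministic in the seed through the text serialization.

What this emulates: the *structure* of published keys at realistic sizes
(the suites run up to 200 couplets, the oracle comparisons at ≤ 12 couplets
across ~100 seeds — sizes chosen so brute-force path enumeration stays
instant). What it does not emulate: real morphological prose, hard-wrapped
OCR text, inconsistent punctuation dialects, or cyclic keys. Passing tests
show the engine's graph logic and round-trips are correct on well-formed and
mildly reticulated keys; they do not show the parser recovers every
real-world formatting variant — that is what the diagnostic-driven re-import
loop is for. The error injector plants one defect class per call
(dup-number, dangling-pointer, unreferenced-couplet, not-consecutive,
bad-lead-count), minimally and reproducibly, so validator tests separate
cleanly from generator tests.

## Numerical and degenerate-input choices

No floating point is involved anywhere. Tie-breaks are lexicographic or
by ascending couplet number throughout. Degenerate inputs: an empty key
validates clean and serializes to empty text; a one-couplet key is the
minimal valid key; `split_polytomous` on a dichotomous couplet is a no-op;
`append_key` with an empty key is the identity; duplicate-number injection
into a one-couplet key is refused as impossible. All randomness is funneled
through explicit seeds; the acceptance script derives all generator seeds
from its single `--seed` argument.

## Known limitations

Indented-format import, byte compatibility with other editors' save files,
automatic key construction from character matrices, multi-access (matrix)
keys, PDF export and undo/redo are out of scope. The text dialect cannot
represent digits-only endpoint labels or lead texts containing newlines;
the XML format represents both.
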