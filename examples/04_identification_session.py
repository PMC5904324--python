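"""Step through an identification, watching the endpoint partition.

At every step the taxa split into *remaining* (still reachable from the
current couplet) and *excluded* (no longer reachable).  At the start nothing
is excluded; the remaining list shrinks with each choice until an endpoint
finishes the identification.  Backtracking truncates the path history.
"""

from dichokey import (
    FixtureSpec, backtrack, choose_lead, generate_key, start_session,
)

key = generate_key(FixtureSpec(couplets=6, seed=2))
session = start_session(key)

while not session.finished:
    part = session.partition()
    print(f"couplet {session.current}: remaining={list(part.remaining)} "
          f"excluded={list(part.excluded)}")
    session = choose_lead(session, 0)  # always take the first lead

print(f"identified as: {session.result}  (after {len(session.path)} choices)")

rewound = backtrack(session, 1)
print(f"backtracked to step 1: couplet {rewound.current}, "
      f"path length {len(rewound.path)}, finished={rewound.finished}")
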