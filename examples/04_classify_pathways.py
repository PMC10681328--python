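"""Refolding-pathway classification on scripted (Q, ⟨G′⟩) series.

Each scripted series dwells at the centroids of the named landscape regions
(U unfolded, IT non-entangled near-native trap, IE- entangled near-unfolded
intermediate, F folded).  The classifier rolls a centred window over both
reaction coordinates and labels the trajectory from its last states before
folding: fast folding (never traps), threading (straight out of the trap),
backtracking (trap -> unfolded -> fast channel), or trapped.
"""

from lassofold.fixtures import make_scripted_series
from lassofold.landscape import classify_pathway

scripts = {
    "direct through IE-":            [("U", 120), ("IE-", 60), ("F", 120)],
    "via the IT trap":               [("U", 120), ("IT", 120), ("F", 120)],
    "trap, escape, then fast":       [("U", 120), ("IT", 120), ("U", 120),
                                      ("IE-", 60), ("F", 120)],
    "stuck in the trap":             [("U", 120), ("IT", 200)],
}

for name, script in scripts.items():
    series = make_scripted_series(script, seed=1)
    rec = classify_pathway(series, window=25)
    t = "-" if rec.folding_time is None else f"{rec.folding_time:.0f} MD"
    print(f"{name:28} -> {rec.label:13} visited {'>'.join(rec.visited):22} "
          f"folding time {t}")
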