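"""Langevin refolding of a 12-residue toy β-hairpin.

Draws an unfolded start from a high-temperature run, then integrates the
Cα Go model at 0.9 T_f (T_f ≈ 0.85 ε for this hairpin from a pilot ladder).
The potential energy relaxes quickly from the high-energy unfolded start;
because this tiny hairpin's folding barrier is well below k_B T, Q then
flickers between the folded and unfolded basins — a weakly two-state toy.
The first passage to Q ≥ 0.9 is the folding time.
"""

import numpy as np

from lassofold.dynamics import run_refolding_batch, sample_unfolded
from lassofold.fixtures import make_toy_native
from lassofold.forcefield import GoParameters

topo, native = make_toy_native(12, "hairpin")
params = GoParameters()
t_f = 0.85

initials = sample_unfolded(topo, params, t_f, c=1.5, n_samples=2,
                           decorrelation_interval=10, seed=3, burn_in=50)
series, finals, meta = run_refolding_batch(topo, params, 0.9 * t_f,
                                           initials, 60, seeds=[11, 12])

print(f"hairpin: {topo.n_residues} residues, {topo.n_contacts} contacts; "
      f"refolding at T = {0.9 * t_f:.2f}")
for k, s in enumerate(series):
    print(f"\ntrajectory {k} (seed {meta['seeds'][k]}):")
    print("  step    Q      E")
    for t in range(0, len(s.step), 8):
        print(f"  {s.step[t]:4d}  {s.q[t]:.2f}  {s.energy[t]:+7.2f}")
    first = np.flatnonzero(s.q >= 0.9)
    when = f"step {s.step[first[0]]}" if len(first) else "never"
    print(f"  reached Q >= 0.9 at: {when}")
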