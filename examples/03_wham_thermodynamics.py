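"""WHAM thermodynamics of the toy hairpin.

Runs a short equilibrium temperature ladder, combines the Q histograms with
the weighted-histogram equations into an entropy S(Q), and prints the
folding temperature and the free-energy profile F(Q) = <E>_Q - T·S(Q).
At T_f the folded and unfolded minima are degenerate and separated by a
barrier; on this five-bin toy T_f is located by that equal-depth criterion
(the specific-heat peak, its equivalent, needs many more Q bins to
resolve).
"""

import numpy as np

from lassofold.dynamics import run_equilibrium_ladder
from lassofold.fixtures import make_toy_native
from lassofold.forcefield import GoParameters
from lassofold.wham import (barrier_height, build_wham_input,
                            free_energy_profile, solve_wham)

topo, _ = make_toy_native(12, "hairpin")
params = GoParameters()
temps = np.linspace(0.8, 1.2, 6)
print(f"ladder: {len(temps)} temperatures x 150 MD steps "
      "(scaled-down demonstration)")
series = run_equilibrium_ladder(topo, params, temps, 150, seed=42)
for t, s in zip(temps, series):
    print(f"  T = {t:.3f}: <Q> = {s.q.mean():.2f}")

inp = build_wham_input(series, temps, topo.n_contacts,
                       n_residues=topo.n_residues)
sol = solve_wham(inp)
print(f"\nWHAM converged in {sol.iterations} iterations")
t_grid = np.linspace(temps[0], temps[-1], 81)
gaps = []
for temp in t_grid:
    q, f = free_energy_profile(sol, temp)
    gaps.append(abs(f[q < 0.5].min() - f[q >= 0.5].min()))
t_f = float(t_grid[int(np.argmin(gaps))])
print(f"folding temperature T_f = {t_f:.3f} "
      "(folded/unfolded minima degenerate)")
q, f = free_energy_profile(sol, t_f)
print("F(Q)/eps at T_f: " +
      ", ".join(f"Q={qq:.2f}: {ff:.2f}" for qq, ff in zip(q, f)))
try:
    print(f"barrier dF = {barrier_height(f):.2f} eps "
          f"= {barrier_height(f) / t_f:.2f} k_B T_f")
except ValueError as err:
    print(f"barrier: {err}")
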