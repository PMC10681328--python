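# Methods

`lassofold` implements a complete coarse-grained machinery for studying how
non-covalent lasso-like entanglement shapes protein folding kinetics: a Cα
structure-based (Go-like) model with Langevin dynamics, a per-configuration
entanglement indicator ⟨G′⟩ used as a second reaction coordinate beside the
fraction of native contacts Q, weighted-histogram thermodynamics on Q,
two-dimensional (Q, ⟨G′⟩) landscape and refolding-pathway analysis, and
per-contact exponential folding kinetics.

## The structure-based model

A protein of N residues is a chain of beads at the Cα positions.  The
potential is

    V = Σ ε_r (r^{i,i+1} − r0)²  +  Σ ε_θ (θ_i − θ0)²
      + Σ ε_φ {[1 − cos(φ_i − φ0)] + ½[1 − cos 3(φ_i − φ0)]}
      + Σ_{native, j ≥ i+4} V_LJ(r_ij)  +  Σ_{non-native, j ≥ i+2} V_NN(r_ij)

with all reference values ("0" subscripts) taken from the native structure.
Energies are in units of ε (= the contact energy), lengths in Å, k_B = 1.

* **Parameters** (uniform over residues): ε_r = 100 ε, ε_θ = 20 ε,
  ε_φ = ε_C = ε_NN = ε.
* **Native contacts**: residue pairs with any two heavy (non-hydrogen)
  atoms closer than 4.5 Å in the all-atom native structure and sequence
  separation j − i ≥ 4 (so no contact shares a pseudo-bond or
  pseudo-dihedral with the bonded terms).  The equilibrium length r0_ij is
  the native Cα–Cα distance.
* **Contact potential**, two flavours:
  - `12-6` (default): 4ε_C[(σ/r)¹² − (σ/r)⁶] with σ = 2^{−1/6} r0, plain
    cut (no shift, no tail correction) at 2.5 σ;
  - `12-10`: ε_C[5(r0/r)¹² − 6(r0/r)¹⁰], minimum −ε_C at r0.  The
    truncation radius of this flavour is an open choice; we use a plain cut
    at 3 r0 and record the choice in output metadata.
* **Excluded volume**: non-native pairs with j ≥ i + 2 interact through a
  repulsive 12-6 term with σ_NN = 4 Å, cut at 2^{1/6} σ_NN and shifted so
  the potential vanishes at the cut-off.
* A conformational contact is **formed** when r_ij < g·r0_ij with g = 1.2;
  Q is the formed fraction.  The boundary is strict (r = 1.2 r0 is not
  formed).

Analytic forces for every term are verified against central finite
differences to < 10⁻⁵ relative error in the test-suite.  Angle gradients
regularise cos θ by clamping into (−1 + 10⁻¹⁰, 1 − 10⁻¹⁰); degenerate
(collinear) dihedral quadruples contribute no force.

## Langevin dynamics

The equation of motion m r̈ = −γ ṙ − ∇V + R(t), with white noise of
variance 2 k_B T γ, is integrated with the Grønbech-Jensen–Farago (GJF)
Langevin velocity-Verlet scheme.  The literature this model family comes
from specifies "velocity-Verlet with a Langevin thermostat" without fixing
the discretisation; GJF is chosen because it gives correct configurational
sampling at finite Δt, and the choice is recorded in run metadata.  Reduced
units: m = 1, ε = 1, a = 1 Å; m/γ = 0.1 and Δt = 0.001 reduced time.  Time
is reported in **MD steps**, 1 MD step = 24 000 integration steps, and
observables (Q, ⟨G′⟩, potential energy, RMSD to native by Kabsch
superposition) are recorded every MD step by default so both reaction
coordinates share one time base.

Velocities are initialised Maxwell–Boltzmann at the run temperature unless
supplied.  Noise comes from numpy's PCG64 generator seeded from the run
seed, generated in one chunk per MD step and consumed by a compiled
(numba) kernel; identical seeds give bit-identical trajectories on a given
build.  Thermostat fidelity is checked by equipartition on a free particle
(⟨v²⟩ = T/m) and a bent three-bead harmonic chain (⟨V⟩ = ½k_BT per
quadratic mode; the 90° bend avoids the measure degeneracy of a straight
θ0 = π chain).

Protocols: equilibrium runs start from the native structure at a ladder of
temperatures spanning the specific-heat peak; unfolded initial conditions
for refolding are uncorrelated snapshots from a run at T = c·T_f with
c > 1, after a burn-in; refolding batches run one independent noise stream
per trajectory at T = 0.9 T_f.

## Gaussian entanglement and the ⟨G′⟩ indicator

For chain portions γ_i = (i1..i2) (a **loop**, closed by a native contact
between residues i1 and i2) and γ_j = (j1..j2) (a **thread**), with bond
midpoints R and bond vectors ΔR,

    G′(γ_i, γ_j) = (1/4π) Σ_{i=i1}^{i2−1} Σ_{j=j1}^{j2−1}
                   (R_i − R_j)/|R_i − R_j|³ · (ΔR_i × ΔR_j),

the discretisation of the Gauss linking integral; for two closed curves it
is the integer linking number.  Minimum lengths m_i = 4 (loop) and m_j = 10
(thread).  Threads may share a loop endpoint residue but no bond
(j2 ≤ i1 or j1 ≥ i2) — the loosest reading that never double-counts a bond
pair.  For each loop the thread maximising |G′| over all contiguous
candidates on either side is selected; because G′ of an interval is a
difference of prefix sums of the loop-row column profile, the scan is
linear after one O(N²) pass, and it is tested for exact agreement with
exhaustive enumeration.  Ties resolve to the smaller j1, then j2.

The whole-configuration indicator is the Hill-weighted average over the
loops of the contacts *formed* in that configuration:

    ⟨G′⟩ = Σ G′ h(|G′|) / Σ h(|G′|),   h(g) = 1/(1 + (g0/g)^m),

with activation threshold g0 = 0.5 and cooperativity m = 3, so loops with
near-integer |G′| dominate.  Conventions: h(0) = 0 (the limit); a snapshot
with no formed contact (or all-zero weights) has ⟨G′⟩ = 0, flagged; loops
whose complement admits no thread contribute G′ = 0 rather than being
dropped, keeping the normalisation an average over all formed loops.
During trajectory analysis the maximal thread is re-searched on every
analysed frame rather than frozen to the native assignment, since misfolded
configurations can be entangled by non-native threads (including
opposite-chirality ones).  ⟨G′⟩ is evaluated at the same cadence as Q.

## WHAM on Q

Histograms N_i(Q) from R equilibrium runs at inverse temperatures β_i are
combined via the self-consistent pair

    S(Q) = ln[Σ_i N_i(Q)] − ln[Σ_j n_j e^{−β_j⟨E⟩_Q + f_j}],
    e^{−f_k} = Σ_Q e^{−β_k⟨E⟩_Q + S(Q)},

iterated from S = 0, f = 0 until the mean absolute change of both falls
below 10⁻¹⁴, with every sum in log space (no overflow up to β·E ~ 10⁴).
Q bins are the integer formed-contact counts (Q bins naturally); empty bins
are excluded from both sums; the first 10% of every run is discarded as
burn-in.  ⟨E⟩_Q is the across-run mean of per-run bin-mean energies.
S is reported anchored to max S = 0; free-energy *differences* are the
gauge-invariant quantities and are tested as such (single-run identity
F = −T ln N(Q) + const; invariance under duplicating a run and under a
uniform energy shift).

From the solution: F(Q;T) = ⟨E⟩_Q − T·S(Q); thermal averages reweighted
with weights e^{S(Q) − ⟨E⟩_Q/T}; Cv(T) = (⟨E²⟩_T − ⟨E⟩_T²)/(T²N) using
bin-mean energies (the intra-bin energy variance is deliberately ignored —
the standard Q-binned approximation, accurate when energy is strongly
correlated with Q); T_f is the Cv-peak temperature refined by a quadratic
through the three grid points around the argmax.  On very small toys with a
handful of Q bins the bin-mean Cv is a blunt instrument and T_f estimates
carry tens-of-percent uncertainty; the free-energy profile itself remains
well behaved, which is why the correctness tests rest on the closed-form
identities (two-level system with planted degeneracy Ω and gap E0 crossing
at T* = E0/ln Ω) rather than on toy T_f values.

The barrier ΔF is measured between the two lowest minima of F(Q) after a
centred 3-bin moving average (shrunken windows at the ends; profiles
shorter than twice the window are used raw), as barrier-top minus the
lower-Q minimum.

## Landscapes, regions and pathway classification

The 2-D refolding landscape is −log of a Gaussian *product*-kernel density
over (Q, ⟨G′⟩) samples, bandwidth per dimension = sample σ · n^{−1/6}
(Scott's rule for d = 2), shifted so the minimum is 0; contour levels step
0.4 log-histogram units.  Named ensembles are closed-form areas in that
plane: U = [0, 0.375] × [−0.25, 0.25]; F = [0.75, 1] × [−1, −0.5]; the
rhomboids IT (Q ∈ [0.5, 0.75], −0.2Q < ⟨G′⟩ < −0.2Q + 0.2) and IE−
(Q ∈ [0.32, 0.46], −1.07Q − 0.26 < ⟨G′⟩ < −1.07Q − 0.11); the TSE is
Q ∈ [0.5 ± 0.03].  Box bounds are closed, rhomboid inequalities strict,
exactly as printed above.

Trajectories are classified from a centred rolling mean (window 555 MD
steps; endpoints use shrunken windows) of both coordinates: frames map to
region labels, unlabelled frames are dropped and consecutive duplicates
merged.  A trajectory that reaches F without visiting IT is
**fast_folding**; one that visited IT is **threading** if its last
IT-vs-U passage before F was IT, **backtracking** if U; one that never
reaches F and ends labelled IT is **trapped**; anything else is reported
"unclassified" rather than silently dropped.  Folding times use 250-MD-step
block averages: the first block with Q ≥ 0.75 *and* ⟨G′⟩ ≤ −0.5
(two-coordinate mode, for natively entangled chains) or Q ≥ 0.7
(Q-only mode).

Ensemble contact maps are per-contact formation fractions over the
conformations collected in a region.  Contact selections compare
probability Z-scores z_i = (p_i − ⟨p⟩)/σ_p (population σ, no Bessel
correction): **trap-avoiding** contacts have z^{IE−} > 1 and z^{IT} < 1;
**first-entangling** contacts have z^{IE−} > 0 among the natively
entangled set.

## Per-contact kinetics

The binary indicator σ_ij(t) (contact formed at time t) is averaged over
refolding trajectories — optionally a pathway-selected subset — into
formation curves ⟨σ_ij⟩(t), block-averaged (non-overlapping blocks, centre
timestamps, trailing partial block kept; default window 100 MD steps) and
fit by bounded nonlinear least squares to A − B·exp(−kt)
(A, B ∈ [0, 1.2], k > 0; initialisation A₀ = last block, B₀ = A₀ − first
block, k₀ = 3/span).  Unweighted residuals are used.  Flat or decreasing
curves are flagged "no-kinetics" instead of forcing a rate.  p_U and its
binomial standard error come from an independent ensemble of unfolded
conformations.

## Synthetic generators: what they emulate and what they do not

The `fixtures` module generates every test input with known ground truth:

* **Linked rings** — polygonal circles with analytic linking number 0, ±1,
  ±2 (torus-wound curves for |k| = 2); the oracle for the Gauss sums.
* **Open lassos** — a near-closed planar loop plus a straight terminal
  segment through (or beside) its centre; chirality by mirror reflection,
  which negates G′ exactly.
* **Toy natives** — hairpin (two strands, contacts via pseudo side-chain
  beads under the real 4.5 Å rule), helix (ideal α geometry, i→i+4
  contacts), lasso (a 12-bead loop closed by one contact, threaded by the
  terminus; closing-contact G′ ≈ +0.82).  These are self-avoiding, with
  bond lengths near 3.8 Å, and are small enough that every simulation-based
  test runs in seconds-to-minutes.
* **Bernoulli kinetics** — independent draws from p(t) = A − B e^{−kt};
  the parameter-recovery ground truth.
* **Scripted series** — (Q, ⟨G′⟩) dwelling at region centroids with 0.02
  additive jitter (small against region sizes); the classifier fixture.

What they do *not* emulate: real side-chain packing and Ramachandran
statistics, the size (≈ 60 residues, 120+ contacts) and contact-order
spectrum of real single-domain proteins, or a deeply two-state folder —
the 12-bead hairpin's barrier is below k_BT, so it flickers rather than
commits.  Passing tests therefore demonstrate the correctness of the
machinery (integrals, forces, estimators, classifiers), not biological
realism; applying the pipeline to a real structure only requires a PDB
file.

## Problem sizes used by the acceptance analysis

`scripts/acceptance.py` re-runs everything from scratch at desk scale, the
package's own choice of scaled-down study conditions: 200-segment rings;
100 random 60-bead coils for the thread-search cross-check; 20
finite-difference conformations per flavour; 3 000-MD-step thermostat runs;
an 8-temperature × 300-MD-step equilibrium ladder and a 10-trajectory ×
60-MD-step refolding batch on the 12-residue hairpin (whose T_f is located
by the equal-depth criterion on F(Q), equivalent to the Cv peak but robust
on a five-bin toy); the
(A, B, k) = (0.9, 0.7, 10⁻⁴) Bernoulli fixture with 100 trajectories of
5·10⁴ steps; 100 scripted classification replicates.

## Known limitations

* Single chain, single model, no insertion codes; mmCIF is not parsed.
* The 12-10 flavour's truncation radius is a documented convention, not a
  literature value.
* Cv from bin-mean energies underestimates intra-bin heat capacity;
  T_f on few-contact toys is correspondingly noisy.
* Bit-level reproducibility holds per build (numba/numpy versions), not
  across builds.
* No knot detection or minimal-surface lasso variants: entanglement is
  quantified by the Gauss double sum only.
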