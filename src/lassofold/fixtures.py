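"""Synthetic inputs with analytic ground truth.

Everything the test-suite and the acceptance analysis consume is generated
here: polygonal ring pairs with a known linking number (the oracle for the
discrete Gauss double sum), open lasso chains that do or do not pierce their
own loop, toy native structures (hairpin / helix / lasso motifs) small enough
to fold in seconds, Bernoulli contact-formation series with known exponential
kinetics, and scripted (Q, ⟨G′⟩) series that walk through named landscape
regions.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcefield import Conformation
from .structure_io import (AtomRecord, NativeTopology, build_contact_map,
                           extract_native_geometry)

__all__ = ["CurvePair", "discrete_linking_number", "make_linked_rings",
           "make_open_lasso", "make_toy_native", "make_synthetic_kinetics",
           "make_scripted_series", "REGION_CENTROIDS", "toy_native_pdb_text"]


@dataclass
class CurvePair:
    """Two polygonal curves and the analytic linking number of their smooth
    counterparts."""

    curve_a: np.ndarray
    curve_b: np.ndarray
    closed: bool
    true_linking: int


def discrete_linking_number(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Discrete Gauss double sum between two *closed* polygonal curves.

    Closure is implied by wrap-around: the segment from the last vertex back
    to the first is included.  Converges to the integer linking number as the
    discretisation is refined.
    """
    a = np.asarray(curve_a, float)
    b = np.asarray(curve_b, float)
    da = np.roll(a, -1, axis=0) - a
    db = np.roll(b, -1, axis=0) - b
    ra = a + 0.5 * da
    rb = b + 0.5 * db
    diff = ra[:, None, :] - rb[None, :, :]
    dist3 = np.linalg.norm(diff, axis=-1) ** 3
    cross = np.cross(da[:, None, :], db[None, :, :])
    return float((np.einsum("ijk,ijk->ij", diff, cross) / dist3).sum()
                 / (4.0 * np.pi))


def make_linked_rings(n_segments: int, linking: int,
                      separation: float = 10.0, radius: float = 10.0,
                      ) -> CurvePair:
    """Polygonal ring pairs with linking number 0, ±1 or ±2.

    Ring A is a circle of the given radius in the xy-plane.  For |linking|=k
    ≥ 1, ring B is a closed curve on the torus around A's core winding k
    times poloidally per toroidal turn, giving linking number k with A; the
    sign is set by B's orientation.  linking = 0 gives two coplanar circles
    separated by ``separation`` between their rims.
    """
    if n_segments < 16:
        raise ValueError("need n_segments >= 16")
    if linking not in (0, 1, -1, 2, -2):
        raise ValueError("supported linking numbers: 0, ±1, ±2")
    t = np.linspace(0.0, 2.0 * np.pi, n_segments, endpoint=False)
    a = np.stack([radius * np.cos(t), radius * np.sin(t),
                  np.zeros_like(t)], axis=1)
    if linking == 0:
        shift = 2.0 * radius + separation
        b = a + np.array([shift, 0.0, 0.0])
        return CurvePair(a, b, closed=True, true_linking=0)
    k = abs(linking)
    r_tube = 0.5 * radius
    b = np.stack([(radius + r_tube * np.cos(k * t)) * np.cos(t),
                  (radius + r_tube * np.cos(k * t)) * np.sin(t),
                  r_tube * np.sin(k * t)], axis=1)
    # orientation of B sets the sign; the torus curve above links -k with A,
    # so traverse it backwards for positive linking
    if linking > 0:
        b = b[::-1].copy()
    return CurvePair(a, b, closed=True, true_linking=linking)


def _polyline(start: np.ndarray, stop: np.ndarray, spacing: float,
              include_start: bool = False) -> np.ndarray:
    """Straight run of points from start to stop at roughly the given spacing."""
    length = float(np.linalg.norm(stop - start))
    n = max(int(np.ceil(length / spacing)), 1)
    ts = np.linspace(0.0, 1.0, n + 1)
    pts = start[None, :] + ts[:, None] * (stop - start)[None, :]
    return pts if include_start else pts[1:]


def make_open_lasso(loop_radius: float = 10.0, thread_halflength: float = 100.0,
                    pierce: bool = True, chirality: int = 1,
                    n_loop: int = 40, spacing: float = 2.0,
                    ) -> tuple[np.ndarray, tuple[int, int]]:
    """A single open chain: a near-closed loop plus a straight terminal thread.

    The loop sits in the xy-plane; its two endpoints are within contact
    distance.  The terminal segment runs parallel to z, through the loop
    centre when ``pierce`` else displaced well outside.  ``chirality = -1``
    mirrors the chain through the xy-plane, exactly negating every Gauss
    term.  Returns (coords, (loop_start_index, loop_end_index)).
    """
    if thread_halflength < loop_radius:
        raise ValueError("require thread_halflength >= loop_radius")
    if chirality not in (1, -1):
        raise ValueError("chirality must be ±1")
    gap = 4.0 / loop_radius  # endpoint gap ≈ 4 length units
    ang = np.linspace(0.5 * gap, 2.0 * np.pi - 0.5 * gap, n_loop)
    loop = np.stack([loop_radius * np.cos(ang), loop_radius * np.sin(ang),
                     np.zeros_like(ang)], axis=1)
    x_thread = 0.0 if pierce else 4.0 * loop_radius
    bottom = np.array([x_thread, 0.0, -thread_halflength])
    top = np.array([x_thread, 0.0, thread_halflength])
    connector = _polyline(loop[-1], bottom, spacing=4.0)
    thread = _polyline(bottom, top, spacing=spacing)
    coords = np.vstack([loop, connector, thread])
    if chirality == -1:
        coords = coords * np.array([1.0, 1.0, -1.0])
    return coords, (0, n_loop - 1)


def _hairpin_atoms(n: int) -> list[AtomRecord]:
    m = (n - 2) // 2
    extra = n - 2 - 2 * m  # odd n: one extra residue on strand B
    sep, rise = 5.5, 3.8
    length = rise * (m - 1)
    pos = [np.array([0.0, rise * k, 0.0]) for k in range(m)]
    # two turn residues on an arc above the strand ends
    centre = np.array([sep / 2.0, length, 0.0])
    rad = sep / 2.0
    turn1 = centre + np.array([-rad * np.cos(np.pi / 3.0),
                               rad * np.sin(np.pi / 3.0) + 1.0, 0.0])
    turn2 = centre + np.array([rad * np.cos(np.pi / 3.0),
                               rad * np.sin(np.pi / 3.0) + 1.0, 0.0])
    pos += [turn1, turn2]
    for k in range(m + extra):
        pos.append(np.array([sep, length - rise * k, 0.0]))
    atoms = []
    for idx, p in enumerate(pos):
        atoms.append(AtomRecord(idx * 2 + 1, "CA", "C", "ALA", idx + 1, "A",
                                "", p))
        on_a = idx < m
        on_b = idx >= m + 2
        if on_a or on_b:
            cb = p + np.array([1.5 if on_a else -1.5, 0.0, 0.0])
            atoms.append(AtomRecord(idx * 2 + 2, "CB", "C", "ALA", idx + 1,
                                    "A", "", cb))
    return atoms


def _helix_atoms(n: int) -> list[AtomRecord]:
    radius, rise, turn = 2.3, 1.5, np.deg2rad(100.0)
    atoms = []
    for k in range(n):
        ang = k * turn
        ca = np.array([radius * np.cos(ang), radius * np.sin(ang), rise * k])
        cb = ca + np.array([0.0, 0.0, -1.9])
        atoms.append(AtomRecord(2 * k + 1, "CA", "C", "ALA", k + 1, "A", "", ca))
        atoms.append(AtomRecord(2 * k + 2, "CB", "C", "ALA", k + 1, "A", "", cb))
    return atoms


def _lasso_atoms(n: int) -> list[AtomRecord]:
    n_loop = max(12, n - 18)
    gap = 4.4
    bond = 3.8
    radius = ((n_loop - 1) * bond + gap) / (2.0 * np.pi)
    gap_ang = gap / radius
    ang = np.linspace(0.5 * gap_ang, 2.0 * np.pi - 0.5 * gap_ang, n_loop)
    loop = np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.zeros_like(ang)], axis=1)
    # leave the rim outwards and dive below the plane before rising through
    # the centre along +z, keeping the thread clear of the loop beads
    out_pt = np.array([1.3 * radius, 0.0, -0.9 * radius])
    below = np.array([0.0, 0.0, -1.2 * radius])
    descent = np.vstack([_polyline(loop[-1], out_pt, spacing=bond),
                         _polyline(out_pt, below, spacing=bond)])
    n_up = n - n_loop - len(descent)
    up = below + np.array([0.0, 0.0, bond]) * np.arange(1, n_up + 1)[:, None]
    pos = np.vstack([loop, descent, up])[:n]
    return [AtomRecord(k + 1, "CA", "C", "ALA", k + 1, "A", "", p)
            for k, p in enumerate(pos)]


def make_toy_native(n_residues: int, motif: str,
                    ) -> tuple[NativeTopology, Conformation]:
    """Self-avoiding toy native structure with a 4.5 Å-rule contact list.

    ``motif`` is one of ``hairpin`` (two strands, cross-strand contacts via
    pseudo side-chain beads), ``helix`` (ideal α-helix geometry, i→i+4
    contacts) or ``lasso`` (a loop closed by a terminal contact whose thread
    pierces it; at least one contact has |G′| > 0.75).
    """
    if n_residues < 10:
        raise ValueError("need n_residues >= 10")
    builders = {"hairpin": _hairpin_atoms, "helix": _helix_atoms,
                "lasso": _lasso_atoms}
    if motif not in builders:
        raise ValueError(f"unknown motif {motif!r}")
    atoms = builders[motif](n_residues)
    contacts = build_contact_map(atoms)
    topology = extract_native_geometry(atoms, contacts)
    return topology, Conformation(topology.ca_coords.copy())


def toy_native_pdb_text(atoms_or_motif, n_residues: int | None = None) -> str:
    """Minimal PDB text (ATOM records) for a toy native; consumes either an
    AtomRecord list or a motif name plus size."""
    if isinstance(atoms_or_motif, str):
        builders = {"hairpin": _hairpin_atoms, "helix": _helix_atoms,
                    "lasso": _lasso_atoms}
        atoms = builders[atoms_or_motif](n_residues)
    else:
        atoms = atoms_or_motif
    lines = []
    for a in atoms:
        x, y, z = a.position
        lines.append(
            f"ATOM  {a.serial:>5} {a.atom_name:<4}{a.residue_name:<3} "
            f"{a.chain_id}{a.residue_seq:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {a.element:>2}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_synthetic_kinetics(a: float, b: float, k: float, n_traj: int,
                            n_steps: int, seed: int) -> np.ndarray:
    """Bernoulli contact time series with p(t) = A - B·exp(-k t).

    Returns an (n_traj, n_steps) 0/1 array; trajectories are independent.
    """
    if not (0.0 <= a - b <= a <= 1.0):
        raise ValueError("require 0 <= A - B <= A <= 1")
    if k <= 0:
        raise ValueError("require k > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_steps, dtype=float)
    p = a - b * np.exp(-k * t)
    return (rng.random((n_traj, n_steps)) < p[None, :]).astype(np.int8)


#: (Q, ⟨G′⟩) centroids of the named landscape regions
REGION_CENTROIDS = {
    "U": (0.1875, 0.0),
    "IT": (0.625, -0.025),
    "IE-": (0.39, -1.07 * 0.39 - 0.185),
    "F": (0.875, -0.75),
}


def make_scripted_series(script: list[tuple[str, int]], seed: int = 0,
                         jitter: float = 0.02):
    """A (Q, ⟨G′⟩) series visiting region centroids for scripted durations.

    ``script`` lists (state_label, duration_in_MD_steps) with labels in
    {U, IT, IE-, F}; small additive Gaussian jitter is applied to both
    coordinates.  Returns an ObservableSeries (energy/rmsd zero-filled).
    """
    from .dynamics import ObservableSeries
    rng = np.random.default_rng(seed)
    qs, gs = [], []
    for label, duration in script:
        if label not in REGION_CENTROIDS:
            raise ValueError(f"unknown state label {label!r}")
        cq, cg = REGION_CENTROIDS[label]
        qs.append(np.full(duration, cq))
        gs.append(np.full(duration, cg))
    q = np.concatenate(qs) + rng.normal(0.0, jitter, sum(d for _, d in script))
    g = np.concatenate(gs) + rng.normal(0.0, jitter, len(q))
    n = len(q)
    return ObservableSeries(step=np.arange(n), q=q, gprime=g,
                            energy=np.zeros(n), rmsd=np.zeros(n),
                            formed=np.zeros((n, 0), dtype=bool))
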