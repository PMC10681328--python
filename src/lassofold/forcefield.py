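"""Go-model potential, forces, fraction of native contacts Q, and RMSD.

The potential is the classic Cα structure-based form: stiff harmonic
pseudo-bonds (100ε) and angles (20ε), a two-term cosine dihedral (ε),
attractive Lennard-Jones interactions only between native-contact pairs, and
a purely repulsive excluded-volume term between all other pairs (σ_NN = 4 Å,
cut and shifted at 2^{1/6}σ_NN).  ε = 1 sets the energy scale and k_B = 1,
so temperatures are in ε.  A conformational contact (i, j) is "formed" when
r_ij < g·r0_ij with g = 1.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .structure_io import NativeTopology

__all__ = ["GoParameters", "Conformation", "potential_energy", "forces",
           "fraction_native", "formed_contacts", "rmsd_to_native", "kabsch_rmsd"]


@dataclass(frozen=True)
class GoParameters:
    """Uniform energy-scale parameters of the structure-based model."""

    epsilon: float = 1.0
    eps_bond: float = 100.0
    eps_angle: float = 20.0
    eps_dihedral: float = 1.0
    eps_contact: float = 1.0
    eps_nn: float = 1.0
    sigma_nn: float = 4.0           # Å
    lj_flavour: str = "12-6"        # or "12-10"
    contact_formed_factor: float = 1.2

    def __post_init__(self):
        if self.lj_flavour not in ("12-6", "12-10"):
            raise ValueError("lj_flavour must be '12-6' or '12-10'")

    @property
    def flavour_code(self) -> int:
        return _kernels.LJ_12_6 if self.lj_flavour == "12-6" else _kernels.LJ_12_10


@dataclass
class Conformation:
    """Bead positions (Å), optional reduced-unit velocities, time in MD steps."""

    coords: np.ndarray
    velocities: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self):
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")


def _native_mask(topology: NativeTopology) -> np.ndarray:
    n = topology.n_residues
    mask = np.zeros((n, n), dtype=np.bool_)
    for i, j, _ in topology.contacts:
        mask[i, j] = mask[j, i] = True
    return mask


def _kernel_args(topology: NativeTopology, params: GoParameters):
    ci, cj, cr0 = topology.contact_arrays()
    return (np.ascontiguousarray(topology.bond_lengths_r0),
            np.ascontiguousarray(topology.angles_theta0),
            np.ascontiguousarray(topology.dihedrals_phi0),
            ci, cj, cr0, _native_mask(topology),
            params.eps_bond, params.eps_angle, params.eps_dihedral,
            params.eps_contact, params.eps_nn, params.sigma_nn,
            params.flavour_code)


def potential_energy(conf: Conformation, topology: NativeTopology,
                     params: GoParameters = GoParameters(),
                     ) -> tuple[float, dict[str, float]]:
    """Total potential (ε) and its bond/angle/dihedral/native/non-native parts."""
    if conf.coords.shape[0] != topology.n_residues:
        raise ValueError("conformation size does not match topology")
    _, eb, ea, ed, en, enn = _kernels.energy_forces(
        conf.coords, *_kernel_args(topology, params))
    comps = {"bond": eb, "angle": ea, "dihedral": ed,
             "native": en, "nonnative": enn}
    return float(sum(comps.values())), comps


def forces(conf: Conformation, topology: NativeTopology,
           params: GoParameters = GoParameters()) -> np.ndarray:
    """Analytic forces -∇V, shape (N, 3), in ε/Å."""
    if conf.coords.shape[0] != topology.n_residues:
        raise ValueError("conformation size does not match topology")
    f, *_ = _kernels.energy_forces(conf.coords, *_kernel_args(topology, params))
    return f


def formed_contacts(coords: np.ndarray, topology: NativeTopology,
                    g: float = 1.2) -> list[tuple[int, int]]:
    """Native contacts with r_ij < g·r0_ij in the given coordinates."""
    out = []
    for i, j, r0 in topology.contacts:
        r = float(np.linalg.norm(coords[j] - coords[i]))
        if r < g * r0:
            out.append((i, j))
    return out


def fraction_native(conf: Conformation, topology: NativeTopology,
                    g: float = 1.2) -> tuple[float, list[tuple[int, int]]]:
    """Q = fraction of formed native contacts, plus the formed-contact list."""
    if topology.n_contacts == 0:
        raise ValueError("topology has no native contacts")
    formed = formed_contacts(conf.coords, topology, g=g)
    return len(formed) / topology.n_contacts, formed


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD of point sets a onto b over proper rotations + translation."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("point sets must have equal shape")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = (rot @ ac.T).T - bc
    return float(np.sqrt((diff ** 2).sum() / len(a)))


def rmsd_to_native(conf: Conformation, topology: NativeTopology) -> float:
    """Cα RMSD to the native structure after optimal superposition, Å."""
    return kabsch_rmsd(conf.coords, topology.ca_coords)
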