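"""Structure parsing and native-topology extraction for the Cα Go model.

The coarse-grained model is defined entirely by the native structure: one
bead per residue at the Cα position, native pseudo-bond lengths, pseudo-bond
angles and pseudo-dihedrals, and a native contact map.  Two residues form a
native contact when any two of their heavy (non-hydrogen) atoms are closer
than 4.5 Å in the all-atom structure and the pair is at least four residues
apart along the chain (so that no contact shares a pseudo-bond or
pseudo-dihedral with the bonded terms).  The contact's equilibrium length is
the native Cα–Cα distance.

Internally residues are indexed 0..N-1; user-facing labels combine the
one-letter amino-acid code with the PDB residue number (e.g. ``N14``).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "NativeTopology",
    "read_pdb",
    "build_contact_map",
    "extract_native_geometry",
    "topology_from_pdb",
    "write_topology_json",
    "read_topology_json",
    "write_xyz",
    "read_xyz",
    "write_observables_tsv",
    "read_observables_tsv",
]

#: default heavy-atom distance defining a native contact, Å
CONTACT_CUTOFF = 4.5
#: minimum sequence separation |j - i| of a native contact
MIN_SEQ_SEP = 4

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of the retained chain (first model, single altloc)."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    altloc: str
    position: np.ndarray  # shape (3,), Å


@dataclass
class NativeTopology:
    """Cα coarse-grained reference geometry extracted from a native structure.

    ``contacts`` is a sorted, duplicate-free list of ``(i, j, r0_ij)`` with
    0-based indices, ``j - i >= 4`` and ``r0_ij`` the native Cα–Cα distance.
    """

    n_residues: int
    ca_coords: np.ndarray                   # (N, 3) Å
    residue_labels: list[str]               # e.g. "N14"
    bond_lengths_r0: np.ndarray             # (N-1,) Å
    angles_theta0: np.ndarray               # (N-2,) rad
    dihedrals_phi0: np.ndarray              # (N-3,) rad
    contacts: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def contact_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Contacts as parallel arrays (i, j, r0) for numerical kernels."""
        if not self.contacts:
            return (np.empty(0, np.int64), np.empty(0, np.int64),
                    np.empty(0, np.float64))
        ci = np.array([c[0] for c in self.contacts], np.int64)
        cj = np.array([c[1] for c in self.contacts], np.int64)
        r0 = np.array([c[2] for c in self.contacts], np.float64)
        return ci, cj, r0

    def label(self, i: int) -> str:
        return self.residue_labels[i]


def _atoms_from_array(arr: bst.AtomArray) -> list[AtomRecord]:
    records = []
    for k in range(arr.array_length()):
        records.append(AtomRecord(
            serial=k + 1,
            atom_name=str(arr.atom_name[k]),
            element=str(arr.element[k]),
            residue_name=str(arr.res_name[k]),
            residue_seq=int(arr.res_id[k]),
            chain_id=str(arr.chain_id[k]),
            altloc="",
            position=np.array(arr.coord[k], dtype=np.float64),
        ))
    return records


def read_pdb(source: str | Path, chain: str | None = None,
             include_hetero: bool = False) -> list[AtomRecord]:
    """Read heavy-atom records of one chain from PDB text or a PDB file.

    Keeps the first model only; drops hydrogens, waters and (by default) all
    HETATM records; resolves alternate locations by highest occupancy
    (biotite's convention, ties to the first listed).  Retains ``chain`` or,
    when ``None``, the first chain present.

    Raises ``ValueError`` for an empty selection, a residue without a Cα, or
    insertion codes (not supported; neither study system has them).
    """
    text_mode = isinstance(source, str) and "\n" in source
    pdb = PDBFile.read(io.StringIO(source) if text_mode else str(source))
    arr = pdb.get_structure(model=1, altloc="occupancy", extra_fields=[])

    if np.any(arr.ins_code != ""):
        raise ValueError("insertion codes are not supported")
    if not include_hetero:
        arr = arr[~arr.hetero]
    arr = arr[arr.element != "H"]
    arr = arr[arr.res_name != "HOH"]
    if arr.array_length() == 0:
        raise ValueError("no heavy atoms retained from the PDB source")

    chains = list(dict.fromkeys(arr.chain_id))
    target = chain if chain is not None else chains[0]
    arr = arr[arr.chain_id == target]
    if arr.array_length() == 0:
        raise ValueError(f"chain {target!r} not present")

    # every retained residue must carry a Calpha
    for res_id in np.unique(arr.res_id):
        res_mask = arr.res_id == res_id
        if not np.any(arr.atom_name[res_mask] == "CA"):
            name = str(arr.res_name[res_mask][0])
            raise ValueError(f"residue {name}{int(res_id)} is missing its CA atom")
    return _atoms_from_array(arr)


def build_contact_map(atoms: list[AtomRecord],
                      cutoff: float = CONTACT_CUTOFF,
                      min_seq_sep: int = MIN_SEQ_SEP,
                      ) -> list[tuple[int, int, float]]:
    """Heavy-atom native contact map with Cα–Cα equilibrium distances.

    Pair ``(i, j)`` (0-based chain positions) is a contact iff the minimal
    heavy-atom distance between the residues is strictly below ``cutoff`` and
    ``j - i >= min_seq_sep``.  Returns a sorted list of ``(i, j, r0_ij)``.
    """
    res_ids = sorted({a.residue_seq for a in atoms})
    index_of = {r: k for k, r in enumerate(res_ids)}
    coords_by_res: dict[int, list[np.ndarray]] = {r: [] for r in res_ids}
    ca_by_res: dict[int, np.ndarray] = {}
    for a in atoms:
        coords_by_res[a.residue_seq].append(a.position)
        if a.atom_name == "CA":
            ca_by_res[a.residue_seq] = a.position
    missing = [r for r in res_ids if r not in ca_by_res]
    if missing:
        raise ValueError(f"residues missing CA: {missing}")

    stacks = {r: np.asarray(v) for r, v in coords_by_res.items()}
    contacts = []
    for a_pos, ra in enumerate(res_ids):
        for rb in res_ids[a_pos + 1:]:
            i, j = index_of[ra], index_of[rb]
            if j - i < min_seq_sep:
                continue
            d = np.linalg.norm(stacks[ra][:, None, :] - stacks[rb][None, :, :],
                               axis=-1)
            if d.min() < cutoff:
                r0 = float(np.linalg.norm(ca_by_res[ra] - ca_by_res[rb]))
                contacts.append((i, j, r0))
    contacts.sort()
    return contacts


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral in (-pi, pi] about the b1-b2 virtual bond."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    phi = float(np.arctan2(y, x))
    return np.pi if phi == -np.pi else phi


def extract_native_geometry(atoms: list[AtomRecord],
                            contacts: list[tuple[int, int, float]],
                            ) -> NativeTopology:
    """Build the NativeTopology (bonded geometry + contacts) from atoms.

    Requires a contiguous chain of >= 4 residues, each with a Cα.
    """
    res_ids = sorted({a.residue_seq for a in atoms})
    n = len(res_ids)
    if n < 4:
        raise ValueError("need at least 4 residues to define a dihedral")
    ca = np.zeros((n, 3))
    labels = []
    names = {}
    for a in atoms:
        names[a.residue_seq] = a.residue_name
        if a.atom_name == "CA":
            ca[res_ids.index(a.residue_seq)] = a.position
    for r in res_ids:
        one = _THREE_TO_ONE.get(names[r], "X")
        labels.append(f"{one}{r}")

    bonds = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    angles = np.empty(n - 2)
    for k in range(n - 2):
        v1 = ca[k] - ca[k + 1]
        v2 = ca[k + 2] - ca[k + 1]
        c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angles[k] = np.arccos(np.clip(c, -1.0, 1.0))
    dihedrals = np.empty(n - 3)
    for k in range(n - 3):
        dihedrals[k] = _dihedral(ca[k], ca[k + 1], ca[k + 2], ca[k + 3])

    return NativeTopology(
        n_residues=n, ca_coords=ca, residue_labels=labels,
        bond_lengths_r0=bonds, angles_theta0=angles, dihedrals_phi0=dihedrals,
        contacts=sorted(set(contacts)),
    )


def topology_from_pdb(source: str | Path, chain: str | None = None,
                      cutoff: float = CONTACT_CUTOFF,
                      min_seq_sep: int = MIN_SEQ_SEP) -> NativeTopology:
    """Convenience: PDB source → NativeTopology in one call."""
    atoms = read_pdb(source, chain=chain)
    contacts = build_contact_map(atoms, cutoff=cutoff, min_seq_sep=min_seq_sep)
    return extract_native_geometry(atoms, contacts)


# ---------------------------------------------------------------------------
# serialisation

def write_topology_json(topology: NativeTopology, path: str | Path) -> None:
    doc = {
        "n_residues": topology.n_residues,
        "residue_labels": topology.residue_labels,
        "ca_coords": topology.ca_coords.tolist(),
        "bond_lengths_r0": topology.bond_lengths_r0.tolist(),
        "angles_theta0": topology.angles_theta0.tolist(),
        "dihedrals_phi0": topology.dihedrals_phi0.tolist(),
        "contacts": [[i, j, r0] for i, j, r0 in topology.contacts],
    }
    Path(path).write_text(json.dumps(doc))


def read_topology_json(path: str | Path) -> NativeTopology:
    doc = json.loads(Path(path).read_text())
    return NativeTopology(
        n_residues=doc["n_residues"],
        ca_coords=np.asarray(doc["ca_coords"], float),
        residue_labels=list(doc["residue_labels"]),
        bond_lengths_r0=np.asarray(doc["bond_lengths_r0"], float),
        angles_theta0=np.asarray(doc["angles_theta0"], float),
        dihedrals_phi0=np.asarray(doc["dihedrals_phi0"], float),
        contacts=[(int(i), int(j), float(r)) for i, j, r in doc["contacts"]],
    )


def write_xyz(frames: np.ndarray, path: str | Path,
              comment: str = "lassofold frame") -> None:
    """Write (n_frames, N, 3) coordinates as multi-frame XYZ (CA beads)."""
    frames = np.atleast_3d(np.asarray(frames, float))
    if frames.ndim == 3 and frames.shape[-1] != 3:
        raise ValueError("frames must be (n_frames, N, 3)")
    with open(path, "w") as fh:
        for t, frame in enumerate(frames):
            fh.write(f"{len(frame)}\n{comment} {t}\n")
            for x, y, z in frame:
                fh.write(f"CA {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str | Path) -> np.ndarray:
    frames = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    k = 0
    while k < len(lines) and lines[k].strip():
        n = int(lines[k])
        block = lines[k + 2: k + 2 + n]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        k += 2 + n
    return np.asarray(frames, float)


OBSERVABLE_HEADER = "step\tQ\tGprime\tE\tRMSD"


def write_observables_tsv(series, path: str | Path) -> None:
    """Write an observable table with the canonical step/Q/Gprime/E/RMSD header."""
    with open(path, "w") as fh:
        fh.write(OBSERVABLE_HEADER + "\n")
        for step, q, g, e, r in zip(series.step, series.q, series.gprime,
                                    series.energy, series.rmsd):
            fh.write(f"{int(step)}\t{q:.8g}\t{g:.8g}\t{e:.10g}\t{r:.8g}\n")


def read_observables_tsv(path: str | Path):
    import pandas as pd
    return pd.read_csv(path, sep="\t")
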