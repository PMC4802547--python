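"""Core data model: atoms, systems, trajectories and protein domain partitions.

Internal unit conventions used throughout the package:

* length — ångström (Å); GRO files (nm) are converted at the I/O boundary
* time — nanoseconds
* angle — degrees

Residue numbering is global, 1-based and continuous across chains (a
two-chain 42-residue dimer spans residues 1..84); chain-local numbering is
available as a derived view.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "System",
    "Trajectory",
    "DomainPartition",
    "MoleculeClass",
    "DEFAULT_RESIDUE_CLASSES",
    "AMINO_ACIDS_3TO1",
    "AMINO_ACIDS_1TO3",
    "build_dimer",
    "build_backbone",
    "truncate_cterm",
    "assign_domains",
]

# Residue-name -> molecule-class table.  Overridable wherever a System is
# constructed from a file; this default covers the 20 standard amino acids,
# common phospholipids and water models.
AMINO_ACIDS_3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AMINO_ACIDS_1TO3: dict[str, str] = {v: k for k, v in AMINO_ACIDS_3TO1.items()}

MoleculeClass = str  # one of {"protein", "lipid", "water", "other"}

DEFAULT_RESIDUE_CLASSES: dict[str, MoleculeClass] = {
    **{name: "protein" for name in AMINO_ACIDS_3TO1},
    "POPC": "lipid", "POPS": "lipid", "DPPC": "lipid", "LIP": "lipid",
    "SOL": "water", "HOH": "water", "WAT": "water",
}


def classify_residue(
    residue_name: str,
    table: Mapping[str, MoleculeClass] | None = None,
) -> MoleculeClass:
    """Map a residue name to a molecule class; unknown names become "other"."""
    table = DEFAULT_RESIDUE_CLASSES if table is None else table
    return table.get(residue_name.strip().upper(), "other")


@dataclass(frozen=True)
class Atom:
    """One atom: identity, residue/chain membership and position in Å."""

    serial: int
    name: str
    element: str
    residue_index: int          # global, 1-based
    residue_name: str
    chain_id: str
    position: np.ndarray        # shape (3,), Å
    molecule_id: int
    molecule_class: MoleculeClass = "other"

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.serial <= 0:
            raise ValueError("atom serial must be positive")
        if self.residue_index <= 0:
            raise ValueError("residue_index must be positive (1-based)")

    @property
    def is_hydrogen(self) -> bool:
        if self.element:
            return self.element.strip().upper() == "H"
        return self.name[:1] in ("H", "1", "2", "3")


class System:
    """An ordered atom collection with an orthorhombic box.

    Parameters
    ----------
    atoms
        Atoms in file order.  Serials must be unique and atoms sharing a
        ``molecule_id`` must share a ``molecule_class``.
    box
        (Lx, Ly, Lz) in Å, or None for a non-periodic system.
    """

    def __init__(self, atoms: Iterable[Atom], box: Sequence[float] | None = None):
        self.atoms: list[Atom] = list(atoms)
        if box is None:
            self.box = None
            self.periodic = False
        else:
            b = np.asarray(box, dtype=float)
            if b.shape != (3,) or np.any(b <= 0):
                raise ValueError("box must be a positive 3-vector (Lx, Ly, Lz) in Å")
            self.box = b
            self.periodic = True
        self._validate()

    def _validate(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a System")
        mol_class: dict[int, str] = {}
        for a in self.atoms:
            prev = mol_class.setdefault(a.molecule_id, a.molecule_class)
            if prev != a.molecule_class:
                raise ValueError(
                    f"molecule {a.molecule_id} mixes classes {prev!r} and "
                    f"{a.molecule_class!r}"
                )

    # ---- derived views -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.position for a in self.atoms])

    def with_positions(self, positions: np.ndarray) -> "System":
        """Copy of the system with every atom moved to the given coordinates."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise ValueError(
                f"need shape ({len(self.atoms)}, 3), got {positions.shape}"
            )
        atoms = [dataclasses.replace(a, position=p) for a, p in zip(self.atoms, positions)]
        return System(atoms, box=self.box)

    @property
    def chains(self) -> list[str]:
        """Chain ids in first-appearance order."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            if a.molecule_class == "protein":
                seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain_residues(self, chain_id: str) -> list[int]:
        """Sorted global residue indices of one protein chain."""
        out = sorted({a.residue_index for a in self.atoms
                      if a.chain_id == chain_id and a.molecule_class == "protein"})
        return out

    def mask(self, *, molecule_class: str | None = None, chain_id: str | None = None,
             atom_name: str | None = None, residue_index: int | None = None,
             heavy_only: bool = False) -> np.ndarray:
        """Boolean atom-selection mask built from simple attribute filters."""
        m = np.ones(len(self.atoms), dtype=bool)
        for i, a in enumerate(self.atoms):
            if molecule_class is not None and a.molecule_class != molecule_class:
                m[i] = False
            if chain_id is not None and a.chain_id != chain_id:
                m[i] = False
            if atom_name is not None and a.name != atom_name:
                m[i] = False
            if residue_index is not None and a.residue_index != residue_index:
                m[i] = False
            if heavy_only and a.is_hydrogen:
                m[i] = False
        return m

    def atom_position(self, residue_index: int, atom_name: str) -> np.ndarray:
        for a in self.atoms:
            if a.residue_index == residue_index and a.name == atom_name:
                return a.position
        raise KeyError(f"no atom {atom_name!r} in residue {residue_index}")

    def translated(self, shift: Sequence[float]) -> "System":
        return self.with_positions(self.positions + np.asarray(shift, dtype=float))


class Trajectory:
    """Time-ordered coordinate frames over one shared topology.

    ``frames[k]`` is an ``(n_atoms, 3)`` array in Å holding the positions of
    ``system.atoms`` at time ``times[k]`` (ns).  Times must strictly increase.
    """

    def __init__(self, system: System, times: Sequence[float],
                 frames: Sequence[np.ndarray]):
        self.system = system
        self.times = np.asarray(times, dtype=float)
        self.frames = [np.asarray(f, dtype=float) for f in frames]
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        n = len(system.atoms)
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {k}: expected {n} atom positions, got shape {f.shape}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def frame_system(self, k: int) -> System:
        """The topology with frame k's coordinates substituted in."""
        return self.system.with_positions(self.frames[k])

    def __iter__(self):
        for k in range(len(self)):
            yield self.times[k], self.frame_system(k)


@dataclass
class DomainPartition:
    """Per-chain split into an N-terminal and a C-terminal domain.

    ``domains[chain]["N"]`` / ``["C"]`` are lists of *global* residue indices.
    The default split places chain-local residues 1..17 in N.
    """

    split_residue: int
    domains: dict[str, dict[str, list[int]]] = field(default_factory=dict)

    def domain_of(self, residue_index: int) -> tuple[str, str]:
        """(chain_id, "N"|"C") of a global residue index."""
        for chain, dom in self.domains.items():
            if residue_index in dom["N"]:
                return chain, "N"
            if residue_index in dom["C"]:
                return chain, "C"
        raise KeyError(f"residue {residue_index} not covered by partition")

    @property
    def residues(self) -> list[int]:
        out: list[int] = []
        for dom in self.domains.values():
            out.extend(dom["N"])
            out.extend(dom["C"])
        return sorted(out)


# ---------------------------------------------------------------------------
# Backbone construction
# ---------------------------------------------------------------------------

# Ideal backbone internal coordinates (lengths in Å, angles in degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement of atom D from A-B-C with given C-D internals."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(sequence: str, phi: float, psi: float) -> np.ndarray:
    """Ideal backbone coordinates for one chain at uniform (φ, ψ).

    Returns an ``(n_res, 4, 3)`` array of N, CA, C, O positions in Å with
    trans peptide bonds (ω = 180°).  The carbonyl O is placed anti to the
    following amide N (dihedral N-CA-C-O = ψ − 180°).
    """
    n_res = len(sequence)
    if n_res < 1:
        raise ValueError("sequence must be non-empty")
    coords = np.zeros((n_res, 4, 3))
    # seed residue: N at origin, CA along +x, C in the xy-plane
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (BOND_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(n_res):
        n_i, ca_i, c_i = coords[i, 0], coords[i, 1], coords[i, 2]
        coords[i, 3] = _place_atom(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, psi - 180.0)
        if i + 1 < n_res:
            n_next = _place_atom(n_i, ca_i, c_i, BOND_C_N, ANGLE_CA_C_N, psi)
            ca_next = _place_atom(ca_i, c_i, n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
            c_next = _place_atom(c_i, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi)
            coords[i + 1, 0] = n_next
            coords[i + 1, 1] = ca_next
            coords[i + 1, 2] = c_next
    return coords


_BACKBONE_NAMES = ("N", "CA", "C", "O")
_BACKBONE_ELEMENTS = ("N", "C", "C", "O")


def _chain_atoms(sequence: str, coords: np.ndarray, chain_id: str,
                 first_residue: int, first_serial: int,
                 molecule_id: int) -> list[Atom]:
    atoms: list[Atom] = []
    serial = first_serial
    for i, letter in enumerate(sequence):
        res3 = AMINO_ACIDS_1TO3[letter]
        for j, (name, elem) in enumerate(zip(_BACKBONE_NAMES, _BACKBONE_ELEMENTS)):
            atoms.append(Atom(
                serial=serial, name=name, element=elem,
                residue_index=first_residue + i, residue_name=res3,
                chain_id=chain_id, position=coords[i, j],
                molecule_id=molecule_id, molecule_class="protein",
            ))
            serial += 1
    return atoms


def build_dimer(sequence: str, n_chains: int = 2,
                phi: float = 180.0, psi: float = 180.0) -> System:
    """Multi-chain extended-conformation backbone built from a 1-letter sequence.

    Chains are labelled A, B, ... and offset laterally by 10 Å each to avoid
    clashes.  Global residue numbering runs continuously: chain A holds
    residues 1..L, chain B residues L+1..2L, and so on.  Each residue carries
    the four backbone atoms N, CA, C, O at ideal bond geometry.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("sequence must be non-empty")
    for pos, letter in enumerate(seq, start=1):
        if letter not in AMINO_ACIDS_1TO3:
            raise ValueError(f"invalid amino-acid letter {letter!r} at position {pos}")
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    coords = build_backbone(seq, phi=phi, psi=psi)
    length = len(seq)
    atoms: list[Atom] = []
    for c in range(n_chains):
        chain_id = chr(ord("A") + c)
        shifted = coords + np.array([0.0, 10.0 * c, 0.0])
        atoms.extend(_chain_atoms(
            seq, shifted, chain_id,
            first_residue=c * length + 1,
            first_serial=c * length * 4 + 1,
            molecule_id=c + 1,
        ))
    return System(atoms)


def truncate_cterm(system: System, n_remove: int) -> System:
    """Drop the C-terminal ``n_remove`` residues from every protein chain.

    Residue numbering is recomputed so global indices stay continuous
    (a 42+42 dimer truncated by 2 becomes residues 1..40 and 41..80).
    """
    if n_remove < 0:
        raise ValueError("n_remove must be >= 0")
    if n_remove == 0:
        return System(list(system.atoms), box=system.box)
    keep: set[int] = set()
    for chain in system.chains:
        residues = system.chain_residues(chain)
        if n_remove >= len(residues):
            raise ValueError(
                f"cannot remove {n_remove} residues from chain {chain!r} "
                f"of length {len(residues)}"
            )
        keep.update(residues[:-n_remove])
    kept_atoms = [a for a in system.atoms
                  if a.molecule_class != "protein" or a.residue_index in keep]
    # renumber protein residues continuously, preserving order
    old_protein = sorted({a.residue_index for a in kept_atoms
                          if a.molecule_class == "protein"})
    renumber = {old: new for new, old in enumerate(old_protein, start=1)}
    atoms = []
    for i, a in enumerate(kept_atoms):
        idx = renumber.get(a.residue_index, a.residue_index) \
            if a.molecule_class == "protein" else a.residue_index
        atoms.append(dataclasses.replace(a, serial=i + 1, residue_index=idx))
    return System(atoms, box=system.box)


def assign_domains(system: System, split_residue: int = 17) -> DomainPartition:
    """Partition every protein chain into N (chain-local 1..split) and C (rest)."""
    chains = system.chains
    if not chains:
        raise ValueError("system contains no protein chains")
    shortest = min(len(system.chain_residues(c)) for c in chains)
    if not 1 <= split_residue < shortest:
        raise ValueError(
            f"split_residue {split_residue} out of range [1, {shortest - 1}]"
        )
    domains: dict[str, dict[str, list[int]]] = {}
    for chain in chains:
        residues = system.chain_residues(chain)
        domains[chain] = {
            "N": residues[:split_residue],
            "C": residues[split_residue:],
        }
    return DomainPartition(split_residue=split_residue, domains=domains)
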