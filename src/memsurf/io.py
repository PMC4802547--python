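"""Text readers/writers for PDB (single- and multi-model) and GRO structures.

PDB columns follow wwPDB v3.3; insertion codes and alternate locations are
rejected rather than silently dropped.  GRO coordinates are nm on disk and
converted to the package's Å convention on read (and back on write).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np

from .model import Atom, DEFAULT_RESIDUE_CLASSES, MoleculeClass, System, Trajectory, classify_residue

__all__ = [
    "ParseError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "read_classification_table",
]

NM_TO_A = 10.0


class ParseError(ValueError):
    """Malformed structure-file content; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


def read_classification_table(text: str) -> dict[str, MoleculeClass]:
    """Parse a two-column (residue_name, class) plain-text table."""
    table: dict[str, MoleculeClass] = {}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError("expected two columns: residue_name class", ln)
        name, cls = parts
        if cls not in ("protein", "lipid", "water", "other"):
            raise ParseError(f"unknown molecule class {cls!r}", ln)
        table[name.upper()] = cls
    return table


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_pdb_atoms(lines: Sequence[tuple[int, str]],
                     table: Mapping[str, MoleculeClass] | None) -> list[Atom]:
    atoms: list[Atom] = []
    mol_ids: dict[tuple[str, int, str], int] = {}
    next_mol = 1
    for ln, line in lines:
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            altloc = line[16:17].strip()
            # extended residue-name field (columns 18-21) fits lipid names
            res_name = line[17:21].strip()
            chain_id = line[21:22]
            res_seq = int(line[22:26])
            icode = line[26:27].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            element = line[76:78].strip() if len(line) >= 78 else ""
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed ATOM/HETATM record: {exc}", ln) from None
        if altloc:
            raise ParseError(f"alternate location {altloc!r} not supported", ln)
        if icode:
            raise ParseError(f"insertion code {icode!r} not supported", ln)
        cls = classify_residue(res_name, table)
        # one molecule per (chain, residue) for non-protein, one per chain for protein
        key = (chain_id, 0, "protein") if cls == "protein" else (chain_id, res_seq, res_name)
        if key not in mol_ids:
            mol_ids[key] = next_mol
            next_mol += 1
        atoms.append(Atom(
            serial=serial, name=name, element=element,
            residue_index=res_seq, residue_name=res_name, chain_id=chain_id,
            position=np.array([x, y, z]),
            molecule_id=mol_ids[key], molecule_class=cls,
        ))
    return atoms


def _read_pdb(text: str, table: Mapping[str, MoleculeClass] | None) -> System:
    box = None
    atom_lines: list[tuple[int, str]] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
            except (ValueError, IndexError):
                raise ParseError("malformed CRYST1 record", ln) from None
        elif rec in ("ATOM", "HETATM"):
            atom_lines.append((ln, line))
    atoms = _parse_pdb_atoms(atom_lines, table)
    return System(atoms, box=box)


def _format_pdb_atom(a: Atom) -> str:
    if len(a.residue_name) > 4 or len(a.chain_id) > 1:
        raise ValueError(
            f"atom {a.serial}: residue/chain field exceeds PDB column width"
        )
    if a.serial > 99999 or a.residue_index > 9999:
        raise ValueError(f"atom {a.serial}: serial/residue number overflows PDB width")
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    x, y, z = a.position
    return (
        f"ATOM  {a.serial:5d} {name:<4s} {a.residue_name:<4s}"
        f"{a.chain_id:1s}{a.residue_index:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{a.element:>2s}"
    )


def _write_pdb(system: System, models: Sequence[np.ndarray] | None = None) -> str:
    lines: list[str] = []
    if system.periodic:
        bx, by, bz = system.box
        lines.append(
            f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    def emit(atoms):
        prev_chain = None
        for a in atoms:
            if prev_chain is not None and a.chain_id != prev_chain \
                    and a.molecule_class == "protein":
                lines.append("TER")
            lines.append(_format_pdb_atom(a))
            prev_chain = a.chain_id if a.molecule_class == "protein" else prev_chain
    if models is None:
        emit(system.atoms)
    else:
        import dataclasses as _dc
        for k, coords in enumerate(models, start=1):
            lines.append(f"MODEL     {k:4d}")
            emit([_dc.replace(a, position=p) for a, p in zip(system.atoms, coords)])
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def _read_gro(text: str, table: Mapping[str, MoleculeClass] | None) -> System:
    lines = text.splitlines()
    if len(lines) < 3:
        raise ParseError("GRO file needs title, atom count, atoms and box lines", len(lines))
    try:
        n_atoms = int(lines[1].strip())
    except ValueError:
        raise ParseError("second line must be the atom count", 2) from None
    if len(lines) < n_atoms + 3:
        raise ParseError(f"expected {n_atoms} atom lines", len(lines))
    atoms: list[Atom] = []
    mol_ids: dict[tuple[int, str], int] = {}
    next_mol = 1
    protein_mol: int | None = None
    for i in range(n_atoms):
        ln = 3 + i
        line = lines[2 + i]
        try:
            res_seq = int(line[0:5])
            res_name = line[5:10].strip()
            name = line[10:15].strip()
            serial = int(line[15:20])
            x = float(line[20:28]) * NM_TO_A
            y = float(line[28:36]) * NM_TO_A
            z = float(line[36:44]) * NM_TO_A
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed GRO atom record: {exc}", ln) from None
        cls = classify_residue(res_name, table)
        if cls == "protein":
            if protein_mol is None:
                protein_mol = next_mol
                next_mol += 1
            mol = protein_mol
        else:
            key = (res_seq, res_name)
            if key not in mol_ids:
                mol_ids[key] = next_mol
                next_mol += 1
            mol = mol_ids[key]
        atoms.append(Atom(
            serial=serial if serial > 0 else i + 1,
            name=name, element="", residue_index=res_seq,
            residue_name=res_name, chain_id="A",
            position=np.array([x, y, z]), molecule_id=mol, molecule_class=cls,
        ))
    box_ln = 3 + n_atoms
    box_fields = lines[2 + n_atoms].split()
    if len(box_fields) < 3:
        raise ParseError("box line needs at least three fields", box_ln)
    try:
        box = np.array([float(v) for v in box_fields[:3]]) * NM_TO_A
    except ValueError:
        raise ParseError("malformed box line", box_ln) from None
    return System(atoms, box=box)


def _write_gro(system: System) -> str:
    lines = ["memsurf structure", f"{len(system.atoms):5d}"]
    for a in system.atoms:
        if len(a.residue_name) > 5 or len(a.name) > 5:
            raise ValueError(f"atom {a.serial}: name field exceeds GRO column width")
        x, y, z = a.position / NM_TO_A
        lines.append(
            f"{a.residue_index % 100000:5d}{a.residue_name:<5s}{a.name:>5s}"
            f"{a.serial % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    if system.periodic:
        bx, by, bz = system.box / NM_TO_A
        lines.append(f"{bx:10.5f}{by:10.5f}{bz:10.5f}")
    else:
        lines.append(f"{0.0:10.5f}{0.0:10.5f}{0.0:10.5f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_structure(text: str, format: str,
                   classes: Mapping[str, MoleculeClass] | None = None) -> System:
    """Parse PDB or GRO text into a System (coordinates in Å).

    ``classes`` overrides the default residue-name → molecule-class table.
    """
    fmt = format.lower()
    if fmt == "pdb":
        return _read_pdb(text, classes)
    if fmt == "gro":
        return _read_gro(text, classes)
    raise ValueError(f"unknown structure format {format!r}; use 'pdb' or 'gro'")


def write_structure(system: System, format: str) -> str:
    """Serialize a System to PDB or GRO text."""
    if not system.atoms:
        raise ValueError("cannot write an empty System")
    fmt = format.lower()
    if fmt == "pdb":
        return _write_pdb(system)
    if fmt == "gro":
        return _write_gro(system)
    raise ValueError(f"unknown structure format {format!r}; use 'pdb' or 'gro'")


def write_trajectory(traj: Trajectory) -> str:
    """Serialize a Trajectory as a multi-model PDB."""
    return _write_pdb(traj.system, models=traj.frames)


def _split_models(text: str) -> list[str]:
    """Split a multi-model PDB into per-model texts (shared header kept)."""
    header: list[str] = []
    models: list[list[str]] = []
    current: list[str] | None = None
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            current = []
        elif rec == "ENDMDL":
            if current is not None:
                models.append(current)
            current = None
        elif current is not None:
            current.append(line)
        elif rec in ("ATOM", "HETATM"):
            current = [line]  # model-less PDB: treat body as single model
        else:
            header.append(line)
    if current:
        models.append(current)
    if not models:
        raise ParseError("no coordinate models found")
    return ["\n".join(header + m) + "\n" for m in models]


def read_trajectory(texts: str | Sequence[str],
                    times: Sequence[float] | None = None,
                    stride: float | None = None,
                    classes: Mapping[str, MoleculeClass] | None = None) -> Trajectory:
    """Build a Trajectory from a multi-model PDB or a sequence of model texts.

    Provide either explicit ``times`` (ns, one per model) or a uniform
    ``stride`` (ns between models, starting at 0).  All models must be
    congruent with the first (same atom count and names).
    """
    if isinstance(texts, str):
        model_texts = _split_models(texts)
    else:
        model_texts = list(texts)
    systems = [read_structure(t, "pdb", classes=classes) for t in model_texts]
    first = systems[0]
    n = len(first.atoms)
    for k, s in enumerate(systems[1:], start=1):
        if len(s.atoms) != n:
            raise ValueError(
                f"model {k} has {len(s.atoms)} atoms, expected {n} (congruence)"
            )
    if times is None:
        if stride is None:
            stride = 1.0
        times = [stride * k for k in range(len(systems))]
    times = np.asarray(list(times), dtype=float)
    if len(times) != len(systems):
        raise ValueError(f"got {len(times)} times for {len(systems)} models")
    frames = [s.positions for s in systems]
    return Trajectory(first, times, frames)
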