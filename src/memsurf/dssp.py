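"""Secondary-structure assignment from backbone hydrogen-bond patterns
(Kabsch–Sander dictionary), reduced hydrogen-bonded classes, and per-domain
time histograms.

The assignment works on backbone geometry alone.  An amide hydrogen is
placed geometrically on each eligible nitrogen, every donor→acceptor pair is
scored with the Kabsch–Sander electrostatic energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   kcal/mol,

a hydrogen bond is declared when E < −0.5 kcal/mol, and the bond pattern is
turned into n-turns, helices (G/H/I), bridges and ladders (B/E), turns (T)
and bends (S).  Positions between chains in flattened per-residue output use
the chain-separator code X, giving the 9-letter alphabet
H, G, I, E, B, T, S, C, X.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np

from .model import Atom, DomainPartition, System, Trajectory

__all__ = [
    "SS_CODES",
    "HB_ENERGY_CUTOFF",
    "SSMatrix",
    "ReducedCounts",
    "hbond_energy",
    "place_amide_hydrogens",
    "assign_ss",
    "ss_matrix",
    "reduce_counts",
]

logger = logging.getLogger(__name__)

#: the 9-state alphabet: 8 structural codes plus the chain separator X
SS_CODES = ("H", "G", "I", "E", "B", "T", "S", "C", "X")

HB_ENERGY_CUTOFF = -0.5      # kcal/mol
_HB_CONST = 0.084 * 332.0    # partial charges x electrostatic factor
_BEND_ANGLE = 70.0           # degrees
_CA_DIST_CUTOFF = 9.0        # Å, pair prescreen
_SEPARATOR_RESIDUE = 0       # residue-index sentinel for X rows


def hbond_energy(pos_n: np.ndarray, pos_h: np.ndarray,
                 pos_c: np.ndarray, pos_o: np.ndarray) -> float:
    """Kabsch–Sander electrostatic H-bond energy of a donor(N-H)/acceptor(C=O)
    pair, kcal/mol.  Distances below 0.5 Å raise a geometry error."""
    r_on = float(np.linalg.norm(pos_o - pos_n))
    r_ch = float(np.linalg.norm(pos_c - pos_h))
    r_oh = float(np.linalg.norm(pos_o - pos_h))
    r_cn = float(np.linalg.norm(pos_c - pos_n))
    for r, pair in ((r_on, "O-N"), (r_ch, "C-H"), (r_oh, "O-H"), (r_cn, "C-N")):
        if r <= 0.5:
            raise ValueError(f"clashing geometry: {pair} distance {r:.3f} Å <= 0.5 Å")
    return _HB_CONST * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


# ---------------------------------------------------------------------------
# backbone extraction
# ---------------------------------------------------------------------------

@dataclass
class _Residue:
    index: int                       # global residue index
    chain: str
    name: str
    n: np.ndarray | None = None
    ca: np.ndarray | None = None
    c: np.ndarray | None = None
    o: np.ndarray | None = None
    h: np.ndarray | None = None

    @property
    def complete(self) -> bool:
        return all(p is not None for p in (self.n, self.ca, self.c, self.o))


def _extract_residues(system: System) -> list[_Residue]:
    by_index: dict[int, _Residue] = {}
    for a in system.atoms:
        if a.molecule_class != "protein":
            continue
        res = by_index.setdefault(
            a.residue_index, _Residue(a.residue_index, a.chain_id, a.residue_name))
        if a.name == "N":
            res.n = a.position
        elif a.name == "CA":
            res.ca = a.position
        elif a.name == "C":
            res.c = a.position
        elif a.name == "O":
            res.o = a.position
        elif a.name in ("H", "HN"):
            res.h = a.position
    return [by_index[i] for i in sorted(by_index)]


def place_amide_hydrogens(system: System) -> System:
    """Return a copy with a geometric amide H on every eligible backbone N.

    The H sits 1.0 Å from N along the reversed carbonyl direction of the
    preceding residue (the standard geometric convention for structures that
    carry no explicit hydrogens).  Prolines and chain-initial residues get no
    H; a residue whose predecessor lacks C/O is skipped with a warning.
    Existing amide hydrogens are preserved.
    """
    residues = _extract_residues(system)
    prev_by_index = {r.index: p for p, r in zip(residues, residues[1:])
                     if p.chain == r.chain and p.index == r.index - 1}
    have_h = {r.index for r in residues if r.h is not None}
    new_atoms = list(system.atoms)
    serial = max((a.serial for a in system.atoms), default=0) + 1
    for res in residues:
        if res.name == "PRO" or res.index in have_h or res.n is None:
            continue
        prev = prev_by_index.get(res.index)
        if prev is None:
            continue  # chain-initial residue: no amide H
        if prev.c is None or prev.o is None:
            logger.warning("residue %d: previous residue incomplete, no H placed",
                           res.index)
            continue
        direction = prev.c - prev.o
        norm = np.linalg.norm(direction)
        if norm == 0:
            logger.warning("residue %d: degenerate C=O, no H placed", res.index)
            continue
        h_pos = res.n + direction / norm
        new_atoms.append(Atom(
            serial=serial, name="H", element="H",
            residue_index=res.index, residue_name=res.name,
            chain_id=res.chain, position=h_pos,
            molecule_id=next(a.molecule_id for a in system.atoms
                             if a.residue_index == res.index
                             and a.molecule_class == "protein"),
            molecule_class="protein",
        ))
        serial += 1
    return System(new_atoms, box=system.box)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def _hbond_matrix(residues: list[_Residue]) -> np.ndarray:
    """bond[d, a] — NH of residue d donates to C=O of residue a."""
    n = len(residues)
    bond = np.zeros((n, n), dtype=bool)
    cas = np.array([r.ca if r.ca is not None else [np.nan] * 3 for r in residues])
    for d, rd in enumerate(residues):
        if rd.h is None or rd.n is None:
            continue
        for a, ra in enumerate(residues):
            if a == d or ra.c is None or ra.o is None:
                continue
            if np.linalg.norm(cas[d] - cas[a]) > _CA_DIST_CUTOFF:
                continue
            try:
                e = hbond_energy(rd.n, rd.h, ra.c, ra.o)
            except ValueError:
                continue
            if e < HB_ENERGY_CUTOFF:
                bond[d, a] = True
    return bond


def _adjacent(residues: list[_Residue], i: int, j: int) -> bool:
    """True when residues i and j are sequence neighbours in one chain."""
    if not (0 <= i < len(residues) and 0 <= j < len(residues)):
        return False
    ri, rj = residues[i], residues[j]
    return ri.chain == rj.chain and abs(ri.index - rj.index) == 1


def _run_of_same_chain(residues: list[_Residue], i: int, n: int) -> bool:
    """Residues i..i+n exist consecutively within one chain."""
    if i < 0 or i + n >= len(residues):
        return False
    first = residues[i]
    for k in range(1, n + 1):
        r = residues[i + k]
        if r.chain != first.chain or r.index != first.index + k:
            return False
    return True


def assign_ss(frame: System) -> dict[int, str]:
    """Per-residue secondary-structure codes for one frame.

    Returns a mapping global residue index → code from the 8 structural
    letters (X appears only in flattened matrix output).  Residues with an
    incomplete backbone are coded C with a warning.  Amide hydrogens are
    placed automatically if absent.
    """
    residues = _extract_residues(frame)
    if not residues:
        raise ValueError("frame contains no protein residues")
    if any(r.h is None and r.name != "PRO" for r in residues[1:]):
        residues = _extract_residues(place_amide_hydrogens(frame))
    n = len(residues)
    codes = np.array(["C"] * n, dtype="<U1")
    incomplete = [r.index for r in residues if not r.complete]
    for idx in incomplete:
        logger.warning("residue %d: incomplete backbone, coded C", idx)

    bond = _hbond_matrix(residues)

    # n-turns: CO of residue i accepts NH of residue i+k (same chain)
    turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in turn:
        for i in range(n - k):
            if _run_of_same_chain(residues, i, k) and bond[i + k, i]:
                turn[k][i] = True

    # bridges: i, j non-adjacent in sequence (|sep| > 2 or different chains)
    par = np.zeros((n, n), dtype=bool)
    anti = np.zeros((n, n), dtype=bool)
    def hb(a: int, b: int) -> bool:
        # Kabsch-Sander HBond(a, b): CO of a accepts NH of b
        return 0 <= a < n and 0 <= b < n and bond[b, a]
    for i in range(1, n - 1):
        for j in range(i + 1, n - 1):
            ri, rj = residues[i], residues[j]
            if ri.chain == rj.chain and abs(ri.index - rj.index) <= 2:
                continue
            if (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1)):
                par[i, j] = par[j, i] = True
            if (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1)):
                anti[i, j] = anti[j, i] = True

    # ladders: consecutive bridges of one type; isolated bridges stay B
    bridge_partner = [set() for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if par[i, j] or anti[i, j]:
                bridge_partner[i].add(j)
    in_ladder = np.zeros(n, dtype=bool)
    for mat, jstep_set in ((par, (1, -1)), (anti, (1, -1))):
        for i in range(n):
            for j in range(n):
                if not mat[i, j]:
                    continue
                for jstep in jstep_set:
                    if _adjacent(residues, i, i + 1) and 0 <= j + jstep < n \
                            and _adjacent(residues, j, j + jstep) \
                            and mat[i + 1, j + jstep]:
                        in_ladder[[i, i + 1, j, j + jstep]] = True

    has_bridge = np.array([len(p) > 0 for p in bridge_partner])

    # helices from consecutive turns; residues i..i+k-1 marked
    helix = {4: np.zeros(n, dtype=bool), 3: np.zeros(n, dtype=bool),
             5: np.zeros(n, dtype=bool)}
    for k in (4, 3, 5):
        for i in range(1, n - k):
            if turn[k][i - 1] and turn[k][i]:
                helix[k][i:i + k] = True

    # bends
    bend = np.zeros(n, dtype=bool)
    for i in range(2, n - 2):
        if not (_run_of_same_chain(residues, i - 2, 2)
                and _run_of_same_chain(residues, i, 2)):
            continue
        r = residues
        if any(x.ca is None for x in (r[i - 2], r[i], r[i + 2])):
            continue
        u = r[i].ca - r[i - 2].ca
        v = r[i + 2].ca - r[i].ca
        denom = np.linalg.norm(u) * np.linalg.norm(v)
        if denom == 0:
            continue
        ang = math.degrees(math.acos(np.clip(np.dot(u, v) / denom, -1, 1)))
        if ang > _BEND_ANGLE:
            bend[i] = True

    # turn T: interior residues of any n-turn
    is_turn = np.zeros(n, dtype=bool)
    for k in (3, 4, 5):
        for i in range(n - k):
            if turn[k][i]:
                is_turn[i + 1:i + k] = True

    # priority: H > B/E > G > I > T > S > C
    for i in range(n):
        if not residues[i].complete:
            codes[i] = "C"
        elif helix[4][i]:
            codes[i] = "H"
        elif has_bridge[i]:
            codes[i] = "E" if in_ladder[i] else "B"
        elif helix[3][i]:
            codes[i] = "G"
        elif helix[5][i]:
            codes[i] = "I"
        elif is_turn[i]:
            codes[i] = "T"
        elif bend[i]:
            codes[i] = "S"
        else:
            codes[i] = "C"
    return {r.index: str(codes[i]) for i, r in enumerate(residues)}


# ---------------------------------------------------------------------------
# matrices and reduced classes
# ---------------------------------------------------------------------------

@dataclass
class SSMatrix:
    """Residues × frames matrix of 9-state codes.

    ``residues`` lists global residue indices; the sentinel 0 marks
    chain-separator rows, whose codes are constantly X.
    """

    residues: list[int]
    times: np.ndarray
    codes: np.ndarray           # (n_rows, n_frames) of single characters

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.codes = np.asarray(self.codes, dtype="<U1")
        if self.codes.shape != (len(self.residues), len(self.times)):
            raise ValueError("codes shape must be (len(residues), len(times))")
        bad = set(self.codes.ravel()) - set(SS_CODES)
        if bad:
            raise ValueError(f"codes outside the 9-state alphabet: {sorted(bad)}")

    def row(self, residue_index: int) -> np.ndarray:
        return self.codes[self.residues.index(residue_index)]


@dataclass
class ReducedCounts:
    """Residue counts per reduced hydrogen-bonded class and per domain.

    ``counts[domain][cls]`` is a per-time array; domains are "N" and "C"
    (aggregated over chains), classes BE, GHI, T and their sum BEGHIT.
    Bend (S), coil (C) and the separator (X) belong to no reduced class.
    """

    times: np.ndarray
    counts: dict[str, dict[str, np.ndarray]]


REDUCED_CLASSES: dict[str, tuple[str, ...]] = {
    "BE": ("B", "E"),
    "GHI": ("G", "H", "I"),
    "T": ("T",),
}


def ss_matrix(traj: Trajectory) -> SSMatrix:
    """Secondary structure of every residue at every frame.

    Rows follow global residue numbering; one X separator row is inserted
    between consecutive chains (the 9th state of the alphabet).
    """
    first = traj.frame_system(0)
    residues_by_chain: list[list[int]] = [
        first.chain_residues(c) for c in first.chains]
    if not any(residues_by_chain):
        raise ValueError("trajectory contains no protein residues")
    row_residues: list[int] = []
    for ci, chain_res in enumerate(residues_by_chain):
        if ci > 0:
            row_residues.append(_SEPARATOR_RESIDUE)
        row_residues.extend(chain_res)
    n_frames = len(traj)
    codes = np.full((len(row_residues), n_frames), "X", dtype="<U1")
    for k in range(n_frames):
        assigned = assign_ss(traj.frame_system(k))
        for r, idx in enumerate(row_residues):
            if idx != _SEPARATOR_RESIDUE:
                codes[r, k] = assigned.get(idx, "C")
    return SSMatrix(row_residues, traj.times.copy(), codes)


def reduce_counts(matrix: SSMatrix, partition: DomainPartition) -> ReducedCounts:
    """Count residues in the reduced classes BE, GHI, T (and the sum BEGHIT)
    per time point, aggregated into the N- and C-terminal domains."""
    domain_rows: dict[str, list[int]] = {"N": [], "C": []}
    for r, idx in enumerate(matrix.residues):
        if idx == _SEPARATOR_RESIDUE:
            continue
        _, label = partition.domain_of(idx)   # KeyError -> residue not covered
        domain_rows[label].append(r)
    counts: dict[str, dict[str, np.ndarray]] = {}
    for label, rows in domain_rows.items():
        block = matrix.codes[rows] if rows else np.empty((0, len(matrix.times)), "<U1")
        per_class = {
            cls: np.isin(block, members).sum(axis=0)
            for cls, members in REDUCED_CLASSES.items()
        }
        per_class["BEGHIT"] = per_class["BE"] + per_class["GHI"] + per_class["T"]
        counts[label] = per_class
    return ReducedCounts(matrix.times.copy(), counts)
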