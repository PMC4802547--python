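"""Synthetic test systems with analytically known ground truth.

Three families of fixtures stand in for MD data that cannot ship with the
package:

* pseudo-lipid bilayers — two leaflets of 3-atom caricature lipids (one "P"
  headgroup on a jittered square grid, two tail beads pointing to the
  midplane).  Only leaflet topology, lipid counts and the headgroup planes
  matter to the analyses; conformational realism is explicitly not a goal.
* binding trajectories — a rigid protein dimer lowered onto the upper
  leaflet so that the exact protein–lipid minimum distance follows
  d(t) = max(plateau, d0 − rate·t), with optional Gaussian jitter applied to
  the whole-protein z offset.  Because the noise is rigid-body, the
  noiseless distance trace stays analytically known frame by frame.
* ideal secondary-structure geometries — α-helical and paired antiparallel
  β-strand backbones at textbook dihedrals, used as ground truth for the
  structure assigner.

Every generator is a pure function of its spec (including the seed): equal
seeds give byte-identical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Atom, System, Trajectory, build_backbone, build_dimer

__all__ = [
    "BilayerSpec",
    "BindingTraceSpec",
    "make_bilayer",
    "make_binding_trajectory",
    "make_ideal_helix",
    "make_beta_pair",
]

# α-helix and β-strand dihedrals (degrees)
HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0
#: inter-strand spacing of the β-pair fixture, Å
STRAND_SPACING = 4.8


@dataclass(frozen=True)
class BilayerSpec:
    """Pseudo-bilayer parameters: per-leaflet lipid counts, target area per
    lipid (Å²), headgroup-plane separation (Å) and the jitter seed."""

    n_upper: int
    n_lower: int
    apl: float = 65.0
    leaflet_sep: float = 38.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_upper < 1 or self.n_lower < 1:
            raise ValueError("each leaflet needs at least one lipid")
        if self.apl <= 0:
            raise ValueError("area per lipid must be positive")
        if self.leaflet_sep <= 0:
            raise ValueError("leaflet separation must be positive")


@dataclass(frozen=True)
class BindingTraceSpec:
    """Prescribed decline-then-plateau minimum-distance trace.

    The decline rate is derived as (d0 − plateau) / t_attach so the clean
    trace reaches the plateau exactly at ``t_attach`` (ns).
    """

    t_attach: float
    d0: float = 50.0
    plateau: float = 2.5
    noise_sd: float = 0.0
    t_end: float = 60.0
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.t_attach < self.t_end:
            raise ValueError("need 0 < t_attach < t_end")
        if self.plateau >= self.d0:
            raise ValueError("plateau must lie below the initial distance d0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def decline_rate(self) -> float:
        """Å/ns decline of the clean trace."""
        return (self.d0 - self.plateau) / self.t_attach

    def clean_distance(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.maximum(self.plateau, self.d0 - self.decline_rate * np.asarray(t))


_TAIL_OFFSETS = (5.0, 10.0)  # Å below (upper) / above (lower) the headgroup


def make_bilayer(spec: BilayerSpec) -> System:
    """Two-leaflet pseudo-lipid bilayer.

    Headgroup "P" atoms sit exactly on z = ±leaflet_sep/2 on a laterally
    jittered square grid; two tail beads per lipid point toward the
    midplane.  Both leaflets share one lateral box of area
    max(n_upper, n_lower) · apl.
    """
    rng = np.random.default_rng(spec.seed)
    area = max(spec.n_upper, spec.n_lower) * spec.apl
    side = float(np.sqrt(area))
    box_z = spec.leaflet_sep + 2 * _TAIL_OFFSETS[1] + 10.0
    atoms: list[Atom] = []
    serial = 1
    mol = 1
    res = 1
    for n_lipids, sign in ((spec.n_upper, +1.0), (spec.n_lower, -1.0)):
        grid = int(np.ceil(np.sqrt(n_lipids)))
        spacing = side / grid
        cells = [(ix, iy) for ix in range(grid) for iy in range(grid)][:n_lipids]
        jitter = rng.uniform(-0.2 * spacing, 0.2 * spacing, size=(n_lipids, 2))
        z_head = sign * spec.leaflet_sep / 2.0
        for (ix, iy), (jx, jy) in zip(cells, jitter):
            x = (ix + 0.5) * spacing + jx
            y = (iy + 0.5) * spacing + jy
            positions = [
                ("P", "P", np.array([x, y, z_head])),
                ("C1", "C", np.array([x, y, z_head - sign * _TAIL_OFFSETS[0]])),
                ("C2", "C", np.array([x, y, z_head - sign * _TAIL_OFFSETS[1]])),
            ]
            for name, elem, pos in positions:
                atoms.append(Atom(
                    serial=serial, name=name, element=elem,
                    residue_index=res, residue_name="POPC", chain_id="M",
                    position=pos, molecule_id=mol, molecule_class="lipid",
                ))
                serial += 1
            mol += 1
            res += 1
    return System(atoms, box=(side, side, box_z))


def make_binding_trajectory(spec: BindingTraceSpec, bilayer: BilayerSpec,
                            sequence: str) -> Trajectory:
    """Rigid-body approach of a protein dimer toward the upper leaflet.

    At every time t the protein is translated so that its lowest atom sits
    exactly ``spec.clean_distance(t)`` (plus the z jitter) above the upper
    headgroup plane, laterally aligned with one headgroup atom.  With
    ``noise_sd=0`` the measured protein–lipid minimum distance therefore
    equals the prescribed trace to machine precision.
    """
    if spec.plateau < 0:
        raise ValueError("geometric infeasibility: plateau distance < 0")
    membrane = make_bilayer(bilayer)
    protein = build_dimer(sequence)
    rng = np.random.default_rng(spec.seed)

    # anchor headgroup: upper-leaflet P nearest the lateral box centre
    side = membrane.box[0]
    z_head = bilayer.leaflet_sep / 2.0
    heads = [a for a in membrane.atoms if a.name == "P" and a.position[2] > 0]
    centre = np.array([side / 2, side / 2])
    anchor = min(heads, key=lambda a: np.linalg.norm(a.position[:2] - centre))

    ppos = protein.positions
    low = ppos[:, 2].argmin()
    # lateral alignment of the lowest protein atom over the anchor headgroup
    lateral_shift = np.array([anchor.position[0] - ppos[low, 0],
                              anchor.position[1] - ppos[low, 1], 0.0])
    ppos = ppos + lateral_shift
    height = ppos[:, 2].max() - ppos[:, 2].min()

    # box tall enough that z minimum images never wrap through the boundary
    box_z = 2.0 * (z_head + spec.d0 + height + 10.0)
    box = (side, side, box_z)

    n_frames = int(round(spec.t_end / spec.dt)) + 1
    times = np.arange(n_frames) * spec.dt
    clean = spec.clean_distance(times)
    noise = rng.normal(0.0, spec.noise_sd, size=n_frames) if spec.noise_sd > 0 \
        else np.zeros(n_frames)

    # merge topologies: membrane first, then protein (fresh serials/mol ids)
    import dataclasses as _dc
    atoms = list(membrane.atoms)
    serial = len(atoms) + 1
    max_mol = max(a.molecule_id for a in atoms)
    for a in protein.atoms:
        atoms.append(_dc.replace(a, serial=serial, molecule_id=max_mol + a.molecule_id))
        serial += 1
    topology = System(atoms, box=box)

    mem_xyz = membrane.positions
    frames = []
    for k in range(n_frames):
        dz = (z_head + clean[k] + noise[k]) - ppos[low, 2]
        frame = np.vstack([mem_xyz, ppos + np.array([0.0, 0.0, dz])])
        frames.append(frame)
    return Trajectory(topology, times, frames)


def _backbone_system(coords: np.ndarray, chain_id: str, first_residue: int,
                     first_serial: int, molecule_id: int) -> list[Atom]:
    names = ("N", "CA", "C", "O")
    elems = ("N", "C", "C", "O")
    atoms = []
    serial = first_serial
    for i in range(coords.shape[0]):
        for j in range(4):
            atoms.append(Atom(
                serial=serial, name=names[j], element=elems[j],
                residue_index=first_residue + i, residue_name="ALA",
                chain_id=chain_id, position=coords[i, j],
                molecule_id=molecule_id, molecule_class="protein",
            ))
            serial += 1
    return atoms


def make_ideal_helix(n_res: int) -> System:
    """Ideal α-helical backbone (φ=−57°, ψ=−47°), single chain.

    Needs at least 6 residues so that i→i+4 hydrogen bonds can form.
    """
    if n_res < 6:
        raise ValueError("helix fixture needs n_res >= 6 (i->i+4 bonding)")
    coords = build_backbone("A" * n_res, HELIX_PHI, HELIX_PSI)
    return System(_backbone_system(coords, "A", 1, 1, 1))


#: registry offset (Å) of the rotated partner strand along the strand axis;
#: chosen so the two inter-strand hydrogen bonds of each antiparallel pair
#: form simultaneously at ~2.9 Å N···O with no backbone clash
_STRAND_REGISTRY_DX = -1.9


def _aligned_strand(n_res: int) -> np.ndarray:
    """Ideal strand centred at the origin with its axis along +x.

    The principal CA axis is rotated onto x so that the carbonyl/amide
    directions (which alternate along ±z for a pleated strand) face the
    partner strand placed above it.
    """
    coords = build_backbone("A" * n_res, STRAND_PHI, STRAND_PSI)
    ca = coords[:, 1, :]
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    axes = vt.copy()
    if axes[0] @ (ca[-1] - ca[0]) < 0:
        axes[0] *= -1
    axes[2] = np.cross(axes[0], axes[1])
    return (coords - centroid) @ axes.T


def make_beta_pair(n_res: int) -> System:
    """Two antiparallel ideal strands (φ=−139°, ψ=135°) as chains A and B.

    Strand B is strand A rotated 180° about the sheet normal (the two-fold
    symmetry of an antiparallel pair) and offset 4.8 Å along it, in the
    hydrogen-bonding registry, so interior residues of both strands form the
    E-ladder bond pattern.
    """
    if n_res < 3:
        raise ValueError("beta-pair fixture needs n_res >= 3 per strand")
    strand_a = _aligned_strand(n_res)
    strand_b = strand_a.copy()
    strand_b[..., 0] *= -1.0
    strand_b[..., 1] *= -1.0
    strand_b += np.array([_STRAND_REGISTRY_DX, 0.0, STRAND_SPACING])
    atoms = _backbone_system(strand_a, "A", 1, 1, 1)
    atoms += _backbone_system(strand_b, "B", n_res + 1, 4 * n_res + 1, 2)
    return System(atoms)
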