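"""Sorting of lipids and waters into annular (AL) and non-annular (nAL)
regions around a membrane-bound protein.

A whole molecule is annular when any of its atoms comes within the cutoff
of any protein atom.  The default criterion is lateral (x–y projected,
periodic in x and y), matching the top-down view of an annular shell around
a surface-bound protein; a 3D ("spatial") criterion is one flag away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import pairwise_distances, pairwise_lateral_distances
from .model import System

__all__ = ["RegionLabels", "sort_regions", "region_census"]


@dataclass
class RegionLabels:
    """Per-molecule annular / non-annular labels for lipids and waters."""

    labels: dict[int, str]          # molecule_id -> "annular" | "non_annular"
    cutoff: float                   # Å
    mode: str                       # "lateral" | "spatial"
    n_atoms: int                    # of the frame that produced the labels

    def annular_ids(self) -> set[int]:
        return {m for m, lab in self.labels.items() if lab == "annular"}


def sort_regions(frame: System, cutoff: float = 6.0,
                 mode: str = "lateral") -> RegionLabels:
    """Label every lipid and water molecule annular or non-annular.

    A molecule is annular iff the minimum distance from any of its atoms to
    any protein atom is ≤ cutoff — measured in the x–y projection
    (``mode="lateral"``, minimum image in x and y) or in full 3D
    (``mode="spatial"``).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mode not in ("lateral", "spatial"):
        raise ValueError(f"unknown mode {mode!r}; use 'lateral' or 'spatial'")
    protein = frame.positions[frame.mask(molecule_class="protein")]
    if len(protein) == 0:
        raise ValueError("frame contains no protein atoms")
    box = frame.box if frame.periodic else None
    molecules: dict[int, list[np.ndarray]] = {}
    for a in frame.atoms:
        if a.molecule_class in ("lipid", "water"):
            molecules.setdefault(a.molecule_id, []).append(a.position)
    if not molecules:
        raise ValueError("frame contains no lipid or water molecules")
    labels: dict[int, str] = {}
    for mol_id, atoms in molecules.items():
        pts = np.asarray(atoms)
        if mode == "lateral":
            d = pairwise_lateral_distances(pts, protein, box).min()
        else:
            d = pairwise_distances(pts, protein, box).min()
        labels[mol_id] = "annular" if d <= cutoff else "non_annular"
    return RegionLabels(labels=labels, cutoff=cutoff, mode=mode,
                        n_atoms=len(frame.atoms))


def region_census(labels: RegionLabels, frame: System) -> dict[str, int]:
    """Count annular / non-annular lipids per leaflet and waters overall.

    Leaflets are assigned from headgroup z relative to the bilayer midplane
    (see :func:`memsurf.asymmetry.assign_leaflets`).
    """
    from .asymmetry import assign_leaflets

    if labels.n_atoms != len(frame.atoms):
        raise ValueError("labels were computed on a different frame")
    mol_class = {a.molecule_id: a.molecule_class for a in frame.atoms}
    missing = [m for m in mol_class
               if mol_class[m] in ("lipid", "water") and m not in labels.labels]
    if missing:
        raise ValueError(f"labels missing for molecules {missing[:5]}")
    leaflet = assign_leaflets(frame) if any(
        c == "lipid" for c in mol_class.values()) else {}
    census = {
        "annular_lipids_upper": 0, "annular_lipids_lower": 0,
        "non_annular_lipids_upper": 0, "non_annular_lipids_lower": 0,
        "annular_waters": 0, "non_annular_waters": 0,
    }
    for mol_id, label in labels.labels.items():
        cls = mol_class[mol_id]
        if cls == "lipid":
            key = f"{label}_lipids_{leaflet[mol_id]}"
        else:
            key = f"{label}_waters"
        census[key] += 1
    return census
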