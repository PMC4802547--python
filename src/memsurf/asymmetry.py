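"""Leaflet assignment and transbilayer asymmetry (mismatch) metrics.

Two percentages characterize how asymmetric a bilayer is:

* lipid-number mismatch  = |n_a − n_b| / max(n_a, n_b) · 100
* surface-area-per-lipid mismatch = |apl_a − apl_b| / max(apl_a, apl_b) · 100

When both leaflets share one lateral box area A (so apl_x = A / n_x), the
two percentages coincide exactly — both reduce to (1 − n_min/n_max)·100 —
which is why the metric is independent of system size.  Deviations between
them can only arise from per-leaflet areas measured independently, which
this module accepts as optional inputs but never computes.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "LeafletStats",
    "assign_leaflets",
    "number_mismatch",
    "sapl_mismatch",
    "leaflet_stats",
]

from .model import System


@dataclass
class LeafletStats:
    """Per-leaflet lipid counts, areas per lipid (Å²) and mismatch %."""

    n_upper: int
    n_lower: int
    area: float                 # lateral box area, Å²
    apl_upper: float
    apl_lower: float
    number_mismatch_pct: float
    sapl_mismatch_pct: float


def assign_leaflets(frame: System, headgroup_atom: str = "P") -> dict[int, str]:
    """Map each lipid molecule_id to "upper" or "lower".

    The bilayer midplane is the mean z of all headgroup atoms; a lipid is
    upper iff its headgroup sits above it.  A headgroup exactly on the
    midplane is ambiguous and raises.
    """
    heads: dict[int, float] = {}
    lipid_ids = set()
    for a in frame.atoms:
        if a.molecule_class != "lipid":
            continue
        lipid_ids.add(a.molecule_id)
        if a.name == headgroup_atom:
            heads[a.molecule_id] = a.position[2]
    missing = sorted(lipid_ids - set(heads))
    if missing:
        raise ValueError(
            f"lipid molecule(s) {missing[:5]} lack headgroup atom {headgroup_atom!r}"
        )
    if not heads:
        raise ValueError("frame contains no lipids")
    midplane = sum(heads.values()) / len(heads)
    labels: dict[int, str] = {}
    for mol, z in heads.items():
        if z == midplane:
            raise ValueError(
                f"lipid {mol}: headgroup exactly on the midplane (ambiguous)"
            )
        labels[mol] = "upper" if z > midplane else "lower"
    return labels


def number_mismatch(n_a: int, n_b: int) -> float:
    """Lipid-number mismatch %: |n_a − n_b| / max(n_a, n_b) · 100."""
    if n_a < 1 or n_b < 1:
        raise ValueError("leaflet lipid counts must be >= 1")
    return abs(n_a - n_b) / max(n_a, n_b) * 100.0


def sapl_mismatch(apl_a: float, apl_b: float) -> float:
    """Surface-area-per-lipid mismatch %: |Δapl| / max(apl) · 100."""
    if apl_a <= 0 or apl_b <= 0:
        raise ValueError("areas per lipid must be positive")
    return abs(apl_a - apl_b) / max(apl_a, apl_b) * 100.0


def leaflet_stats(frame: System, headgroup_atom: str = "P",
                  area_upper: float | None = None,
                  area_lower: float | None = None) -> LeafletStats:
    """Leaflet counts, areas per lipid and both mismatch percentages.

    Per-leaflet areas default to the shared lateral box area Lx·Ly; pass
    ``area_upper`` / ``area_lower`` to use externally estimated areas
    instead (e.g. Voronoi-based), in Å².
    """
    if not frame.periodic:
        raise ValueError("leaflet statistics need a periodic frame")
    labels = assign_leaflets(frame, headgroup_atom)
    n_upper = sum(1 for v in labels.values() if v == "upper")
    n_lower = sum(1 for v in labels.values() if v == "lower")
    if n_upper == 0 or n_lower == 0:
        raise ValueError("both leaflets must contain at least one lipid")
    box_area = float(frame.box[0] * frame.box[1])
    a_up = box_area if area_upper is None else float(area_upper)
    a_lo = box_area if area_lower is None else float(area_lower)
    apl_upper = a_up / n_upper
    apl_lower = a_lo / n_lower
    return LeafletStats(
        n_upper=n_upper, n_lower=n_lower, area=box_area,
        apl_upper=apl_upper, apl_lower=apl_lower,
        number_mismatch_pct=number_mismatch(n_upper, n_lower),
        sapl_mismatch_pct=sapl_mismatch(apl_upper, apl_lower),
    )
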