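"""Residue–residue minimum-distance contact maps, the 10-zone domain
directory for a two-chain dimer, and window/replicate averaging with SEMs.

Contact maps are reported in nm (the conventional scale for such maps)
while all internal geometry stays in Å; the conversion happens once, at the
map boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np

from .geometry import pairwise_distances
from .model import DomainPartition, System

__all__ = [
    "ContactMap",
    "ZoneDirectory",
    "ZoneStats",
    "contact_map",
    "zone_directory",
    "average_maps",
    "zone_stats",
]

A_TO_NM = 0.1


@dataclass
class ContactMap:
    """Symmetric residue × residue minimum-distance matrix in nm."""

    residues: list[int]
    matrix: np.ndarray
    frame_count: int = 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        r = len(self.residues)
        if self.matrix.shape != (r, r):
            raise ValueError("matrix must be square over the residue list")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class ZoneDirectory:
    """The 10 unordered pairings of the domains N_A, C_A, N_B, C_B.

    Zones 1–3 pair domains within chain A, 4–6 within chain B, and 7–10
    couple the two chains.
    """

    zones: dict[int, frozenset[str]]
    partition: DomainPartition = field(repr=False, default=None)

    def zone_of(self, res_i: int, res_j: int) -> int:
        """Zone id of an unordered residue pair."""
        chain_i, dom_i = self.partition.domain_of(res_i)
        chain_j, dom_j = self.partition.domain_of(res_j)
        pair = frozenset({f"{dom_i}_{chain_i}", f"{dom_j}_{chain_j}"})
        for zid, members in self.zones.items():
            if members == pair:
                return zid
        raise KeyError(f"no zone for residue pair ({res_i}, {res_j})")


@dataclass
class ZoneStats:
    """Cross-replicate mean and SEM of the zone-average distances (nm).

    With a single replicate the SEM is NaN (not available), never zero.
    """

    means: dict[int, float]
    sems: dict[int, float]
    n_replicates: int


def contact_map(frame: System, heavy_only: bool = True) -> ContactMap:
    """Minimum inter-atomic distance between every protein residue pair, nm.

    ``heavy_only`` drops hydrogens before measuring (fixtures may carry
    placed amide hydrogens that would bias the minima).
    """
    residues: dict[int, list[np.ndarray]] = {}
    for a in frame.atoms:
        if a.molecule_class != "protein":
            continue
        if heavy_only and a.is_hydrogen:
            continue
        residues.setdefault(a.residue_index, []).append(a.position)
    if len(residues) < 2:
        raise ValueError("need at least two protein residues for a contact map")
    index = sorted(residues)
    box = frame.box if frame.periodic else None
    r = len(index)
    mat = np.zeros((r, r))
    coords = [np.asarray(residues[i]) for i in index]
    for i in range(r):
        for j in range(i + 1, r):
            d = pairwise_distances(coords[i], coords[j], box).min()
            mat[i, j] = mat[j, i] = d * A_TO_NM
    return ContactMap(index, mat, frame_count=1)


def zone_directory(partition: DomainPartition) -> ZoneDirectory:
    """Enumerate the 10 domain-pair zones of a two-chain partition."""
    chains = list(partition.domains)
    if len(chains) != 2:
        raise ValueError(f"zone directory needs exactly 2 chains, got {len(chains)}")
    a, b = chains
    order = [
        {f"N_{a}"}, {f"N_{a}", f"C_{a}"}, {f"C_{a}"},
        {f"N_{b}"}, {f"N_{b}", f"C_{b}"}, {f"C_{b}"},
        {f"N_{a}", f"N_{b}"}, {f"N_{a}", f"C_{b}"},
        {f"C_{a}", f"N_{b}"}, {f"C_{a}", f"C_{b}"},
    ]
    zones = {zid: frozenset(members) for zid, members in enumerate(order, start=1)}
    return ZoneDirectory(zones=zones, partition=partition)


def _window_frames(maps: Sequence[tuple[float, ContactMap]],
                   window_ns: float, replicate: str) -> list[ContactMap]:
    times = [t for t, _ in maps]
    if len(maps) > 1 and (times[-1] - times[0]) < window_ns:
        raise ValueError(
            f"replicate {replicate!r} spans {times[-1] - times[0]:g} ns, "
            f"shorter than the {window_ns:g} ns window"
        )
    t_end = times[-1]
    return [m for t, m in maps if t >= t_end - window_ns]


def _check_congruent(maps: Sequence[ContactMap]) -> list[int]:
    residues = maps[0].residues
    for m in maps[1:]:
        if m.residues != residues:
            raise ValueError("contact maps cover different residue sets")
    return residues


def average_maps(maps_by_replicate: Mapping[str, Sequence[tuple[float, ContactMap]]],
                 window_ns: float = 50.0) -> ContactMap:
    """Two-stage average: per replicate over the trailing time window, then
    unweighted across replicates."""
    if not maps_by_replicate:
        raise ValueError("no replicates given")
    replicate_means = []
    residues = None
    for rep, maps in maps_by_replicate.items():
        selected = _window_frames(maps, window_ns, rep)
        residues = _check_congruent([m for _, m in maps])
        replicate_means.append(np.mean([m.matrix for m in selected], axis=0))
    mean = np.mean(replicate_means, axis=0)
    total = sum(len(v) for v in maps_by_replicate.values())
    return ContactMap(residues, mean, frame_count=total)


def _zone_pairs(directory: ZoneDirectory, residues: list[int]) -> dict[int, list[tuple[int, int]]]:
    """Residue-index pairs per zone: i<j within a domain (diagonal excluded),
    the full cross-product between distinct domains."""
    pos = {r: k for k, r in enumerate(residues)}
    pairs: dict[int, list[tuple[int, int]]] = {z: [] for z in directory.zones}
    for i_idx in range(len(residues)):
        for j_idx in range(i_idx + 1, len(residues)):
            zid = directory.zone_of(residues[i_idx], residues[j_idx])
            pairs[zid].append((i_idx, j_idx))
    return pairs


def zone_stats(maps_by_replicate: Mapping[str, Sequence[tuple[float, ContactMap]]],
               directory: ZoneDirectory, window_ns: float = 50.0) -> ZoneStats:
    """Zone-average distances per replicate (over the trailing window), then
    cross-replicate mean and SEM (sd with n−1 denominator over √n)."""
    if not maps_by_replicate:
        raise ValueError("no replicates given")
    per_rep_zone_means: list[dict[int, float]] = []
    for rep, maps in maps_by_replicate.items():
        selected = _window_frames(maps, window_ns, rep)
        residues = _check_congruent([m for _, m in maps])
        window_mean = np.mean([m.matrix for m in selected], axis=0)
        pairs = _zone_pairs(directory, residues)
        per_rep_zone_means.append({
            z: float(np.mean([window_mean[i, j] for i, j in plist]))
            for z, plist in pairs.items()
        })
    n = len(per_rep_zone_means)
    means: dict[int, float] = {}
    sems: dict[int, float] = {}
    for z in directory.zones:
        vals = np.array([d[z] for d in per_rep_zone_means])
        means[z] = float(vals.mean())
        sems[z] = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    return ZoneStats(means=means, sems=sems, n_replicates=n)
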