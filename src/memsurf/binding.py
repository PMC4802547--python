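"""Surface-binding kinetics: minimum-distance traces, attachment-time
detection by two-line extrapolation, and membrane-orientation angles.

The attachment time of a protein approaching a bilayer is read off a
protein–lipid minimum-distance trace the way it is done graphically: a
straight line is fitted to the initial sharp decline, a horizontal line to
the stabilized plateau, and the attachment time is the abscissa of their
intersection.  The breakpoint between the two regimes is found by an
exhaustive least-squares grid search, which is deterministic and free of
starting-value sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import min_distance
from .model import System, Trajectory

__all__ = [
    "DistanceSeries",
    "AttachmentResult",
    "OrientationSeries",
    "NoAttachmentError",
    "min_distance_series",
    "detect_attachment",
    "orientation_series",
]


@dataclass
class DistanceSeries:
    """A minimum-distance trace in Å over time in ns."""

    times: np.ndarray
    values: np.ndarray
    selection_a: str = ""
    selection_b: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class AttachmentResult:
    """Two-line fit of a binding trace.

    ``t_attach`` (ns) is where the fitted decline line crosses the fitted
    plateau level, clamped to the observed time range; ``sse`` is the total
    squared residual of the optimal two-segment fit (Å²).
    """

    t_attach: float
    decline_slope: float     # Å/ns, negative
    plateau_level: float     # Å
    breakpoint_index: int
    sse: float


@dataclass
class OrientationSeries:
    """Orientation angle (degrees, [0, 180]) of a residue→residue vector
    relative to the bilayer normal (+z), per frame."""

    times: np.ndarray
    angles: np.ndarray
    from_residue: int
    to_residue: int


class NoAttachmentError(RuntimeError):
    """The trace has no decline-then-plateau shape."""


def min_distance_series(traj: Trajectory, sel_a: np.ndarray, sel_b: np.ndarray,
                        label_a: str = "", label_b: str = "") -> DistanceSeries:
    """Per-frame minimum-image minimum distance between two atom selections.

    ``sel_a`` / ``sel_b`` are boolean masks or index arrays over the
    trajectory's atoms (see :meth:`memsurf.model.System.mask`).
    """
    sel_a = np.asarray(sel_a)
    sel_b = np.asarray(sel_b)
    if sel_a.dtype == bool and not sel_a.any():
        raise ValueError("selection A is empty")
    if sel_b.dtype == bool and not sel_b.any():
        raise ValueError("selection B is empty")
    box = traj.system.box if traj.system.periodic else None
    values = np.empty(len(traj))
    for k, frame in enumerate(traj.frames):
        values[k] = min_distance(frame[sel_a], frame[sel_b], box)
    return DistanceSeries(traj.times.copy(), values,
                          selection_a=label_a, selection_b=label_b)


def _prefix(x: np.ndarray) -> np.ndarray:
    out = np.zeros(len(x) + 1)
    np.cumsum(x, out=out[1:])
    return out


def detect_attachment(series: DistanceSeries,
                      plateau_fraction: float = 0.25) -> AttachmentResult:
    """Two-segment fit of a decline-then-plateau trace.

    For every interior breakpoint ``k`` a least-squares line is fitted to
    samples ``0..k`` and a horizontal line (the mean) to samples ``k..end``
    (sample ``k`` is shared, pinning both fits to the transition); the ``k``
    minimizing the total squared error wins, earliest ``k`` on ties.
    ``plateau_fraction`` caps how late the breakpoint may sit: at least that
    fraction of samples must remain in the plateau segment.

    Raises :class:`NoAttachmentError` if the optimal decline slope is not
    negative (e.g. a flat or rising trace).
    """
    t, y = series.times, series.values
    n = len(t)
    if n < 8:
        raise ValueError(f"need at least 8 samples, got {n}")
    if np.allclose(y, y[0]):
        raise NoAttachmentError("series is globally flat")

    st, sy = _prefix(t), _prefix(y)
    stt, sty, syy = _prefix(t * t), _prefix(t * y), _prefix(y * y)

    min_plateau = max(2, int(np.ceil(plateau_fraction * n)))
    k_lo, k_hi = 2, n - min_plateau  # decline gets >= 3 points
    if k_hi < k_lo:
        k_hi = k_lo
    best = None
    for k in range(k_lo, k_hi + 1):
        m = k + 1                       # samples 0..k
        St, Sy = st[m], sy[m]
        Stt, Sty = stt[m], sty[m]
        Syy = syy[m]
        det = m * Stt - St * St
        if det <= 0:
            continue
        slope = (m * Sty - St * Sy) / det
        intercept = (Sy - slope * St) / m
        sse_line = (Syy - 2 * slope * Sty - 2 * intercept * Sy
                    + slope * slope * Stt + 2 * slope * intercept * St
                    + m * intercept * intercept)
        p = n - k                       # samples k..n-1
        Py = sy[n] - sy[k]
        Pyy = syy[n] - syy[k]
        mean = Py / p
        sse_plateau = Pyy - p * mean * mean
        sse = sse_line + sse_plateau
        if best is None or sse < best[0] - 1e-12:
            best = (sse, k, slope, intercept, mean)
    if best is None:
        raise NoAttachmentError("no valid breakpoint found")
    sse, k, slope, intercept, plateau = best
    if slope >= 0:
        raise NoAttachmentError(
            f"no attachment detected: decline slope {slope:.3g} >= 0"
        )
    t_attach = (plateau - intercept) / slope
    t_attach = float(np.clip(t_attach, t[0], t[-1]))
    return AttachmentResult(
        t_attach=t_attach,
        decline_slope=float(slope),
        plateau_level=float(plateau),
        breakpoint_index=int(k),
        sse=float(max(sse, 0.0)),
    )


def orientation_series(traj: Trajectory, from_res: int, to_res: int,
                       atom_name: str = "CA") -> OrientationSeries:
    """Angle between the from→to residue vector and +z, per frame, in degrees.

    The convention keeps the full [0, 180] range: 0 means the vector points
    along the bilayer normal, 180 against it.
    """
    atoms = traj.system.atoms
    idx_from = [i for i, a in enumerate(atoms)
                if a.residue_index == from_res and a.name == atom_name]
    idx_to = [i for i, a in enumerate(atoms)
              if a.residue_index == to_res and a.name == atom_name]
    if not idx_from:
        raise ValueError(f"residue {from_res} has no atom {atom_name!r}")
    if not idx_to:
        raise ValueError(f"residue {to_res} has no atom {atom_name!r}")
    i, j = idx_from[0], idx_to[0]
    angles = np.empty(len(traj))
    for k, frame in enumerate(traj.frames):
        v = frame[j] - frame[i]
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"degenerate geometry at frame {k}: zero-length vector")
        angles[k] = np.degrees(np.arccos(np.clip(v[2] / norm, -1.0, 1.0)))
    return OrientationSeries(traj.times.copy(), angles, from_res, to_res)
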