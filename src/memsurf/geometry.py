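"""Minimum-image distance kernels for orthorhombic periodic boxes."""

from __future__ import annotations

import numpy as np

__all__ = ["pairwise_distances", "min_distance", "pairwise_lateral_distances"]

_CHUNK = 2048  # rows of A per block; bounds peak memory at ~CHUNK*len(B)*3 floats


def _min_image(deltas: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is not None:
        deltas = deltas - box * np.round(deltas / box)
    return deltas


def pairwise_distances(a: np.ndarray, b: np.ndarray,
                       box: np.ndarray | None = None) -> np.ndarray:
    """(len(a), len(b)) Euclidean distances under the minimum-image convention.

    For an orthorhombic box the per-axis nearest image minimizes each squared
    component independently, so this equals the minimum over all 27 periodic
    images of each pair.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    out = np.empty((len(a), len(b)))
    for start in range(0, len(a), _CHUNK):
        block = a[start:start + _CHUNK]
        d = _min_image(block[:, None, :] - b[None, :, :], box)
        out[start:start + _CHUNK] = np.sqrt((d * d).sum(axis=-1))
    return out


def min_distance(a: np.ndarray, b: np.ndarray,
                 box: np.ndarray | None = None) -> float:
    """Minimum minimum-image distance between two point sets."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty selection in distance computation")
    best = np.inf
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    for start in range(0, len(a), _CHUNK):
        block = a[start:start + _CHUNK]
        d = _min_image(block[:, None, :] - b[None, :, :], box)
        best = min(best, float(np.sqrt((d * d).sum(axis=-1)).min()))
    return best


def pairwise_lateral_distances(a: np.ndarray, b: np.ndarray,
                               box: np.ndarray | None = None) -> np.ndarray:
    """x-y-projected minimum-image distances (periodic in x and y only)."""
    a2 = np.atleast_2d(np.asarray(a, dtype=float))[:, :2]
    b2 = np.atleast_2d(np.asarray(b, dtype=float))[:, :2]
    box2 = None if box is None else np.asarray(box, dtype=float)[:2]
    d = _min_image(a2[:, None, :] - b2[None, :, :], box2)
    return np.sqrt((d * d).sum(axis=-1))
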