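"""Minimum-image helpers for cubic periodic boxes."""

from __future__ import annotations

import numpy as np


def wrap(coords: np.ndarray, box_edge: float) -> np.ndarray:
    """Fold coordinates into [0, box_edge)."""
    return np.mod(coords, box_edge)


def min_image_vec(delta: np.ndarray, box_edge: float) -> np.ndarray:
    """Minimum-image displacement for one or many delta vectors."""
    return delta - box_edge * np.round(delta / box_edge)


def min_image_dist(a: np.ndarray, b: np.ndarray, box_edge: float) -> np.ndarray:
    """Minimum-image Euclidean distance between points (broadcastable)."""
    d = min_image_vec(np.asarray(a, float) - np.asarray(b, float), box_edge)
    return np.sqrt(np.sum(d * d, axis=-1))


def pairwise_min_image_dist(coords: np.ndarray, box_edge: float) -> np.ndarray:
    """Dense (n, n) minimum-image distance matrix. O(n^2) memory."""
    c = np.asarray(coords, float)
    d = min_image_vec(c[:, None, :] - c[None, :, :], box_edge)
    return np.sqrt(np.sum(d * d, axis=-1))
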