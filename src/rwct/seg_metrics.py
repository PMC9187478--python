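"""Segmentation evaluation metrics: Dice coefficient and Hausdorff distance.

Dice measures volume overlap between a segmentation R1 and a gold standard
R2: 2|R1 ∩ R2| / (|R1| + |R2|), in [0, 1].  The Hausdorff distance is the
symmetric max-of-min Euclidean distance between the two foreground pixel
sets (pixel centers, scaled by physical spacing); the percentile variant
replaces the max of each directed distance distribution by a percentile,
which is robust to single outlier pixels.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def _as_mask(arr: np.ndarray) -> np.ndarray:
    m = np.asarray(arr)
    return m.astype(bool)


def dice(r1: np.ndarray, r2: np.ndarray) -> float:
    """Dice overlap 2|R1∩R2|/(|R1|+|R2|); two empty masks agree perfectly (1.0)."""
    a, b = _as_mask(r1), _as_mask(r2)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _directed_distances(pts_a: np.ndarray, pts_b: np.ndarray) -> np.ndarray:
    """Distance from each point of A to its nearest neighbour in B."""
    return cKDTree(pts_b).query(pts_a)[0]


def hausdorff(
    r1: np.ndarray,
    r2: np.ndarray,
    percentile: float = 100.0,
    spacing: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Symmetric Hausdorff distance between two binary masks.

    ``percentile < 100`` gives the robust variant (e.g. 95 for HD95): the
    given percentile of each directed nearest-neighbour distance
    distribution, symmetrized by the max of the two directions.
    """
    a, b = _as_mask(r1), _as_mask(r2)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    if not (0 < percentile <= 100):
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    sp_ = np.asarray(spacing, dtype=np.float64)
    pts_a = np.argwhere(a) * sp_
    pts_b = np.argwhere(b) * sp_
    d_ab = _directed_distances(pts_a, pts_b)
    d_ba = _directed_distances(pts_b, pts_a)
    if percentile == 100:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))
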