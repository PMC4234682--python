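"""Region labelling for luminance rasters.

The model consumes region-level photometry, so it needs the image divided
into labelled regions of (near-)uniform luminance.  A full image-segmentation
front-end is out of scope; this module provides a deterministic stand-in: a
tolerance-based connected-component labeller.  Adjacent pixels are merged
into one region while each stays within a relative tolerance of the region's
running geometric-mean luminance.  Users with a preferred segmentation can
supply label rasters directly.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = ["LabelConfig", "label_regions", "region_adjacency"]


@dataclass(frozen=True)
class LabelConfig:
    """Parameters of the tolerance-based labeller.

    tolerance : relative luminance tolerance for merging a pixel into a
        region (``|L/gm - 1| <= tolerance`` against the running geometric
        mean ``gm``); 0 merges only exactly equal neighbours.
    connectivity : 4 (edge neighbours) or 8 (edge + corner neighbours).
    """

    tolerance: float = 0.01
    connectivity: int = 4

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError(f"tolerance must be >= 0, got {self.tolerance}")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")


_OFFSETS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS8 = _OFFSETS4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def label_regions(luminance: np.ndarray, cfg: LabelConfig | None = None) -> np.ndarray:
    """Label connected regions of near-uniform luminance.

    Pixels are visited in raster-scan order; a breadth-first flood grows each
    region, admitting a neighbouring pixel while its luminance stays within
    ``cfg.tolerance`` (relative) of the region's running geometric mean.
    Labels are consecutive integers starting at 0 in first-encounter order,
    which makes the output deterministic for identical input.
    """
    cfg = cfg or LabelConfig()
    lum = np.asarray(luminance, dtype=float)
    if lum.size == 0:
        raise ValueError("empty luminance raster")
    if lum.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {lum.shape}")
    if not np.all(np.isfinite(lum)) or np.any(lum <= 0):
        raise ValueError("luminance raster must be strictly positive and finite")

    offsets = _OFFSETS4 if cfg.connectivity == 4 else _OFFSETS8
    nrow, ncol = lum.shape
    labels = np.full((nrow, ncol), -1, dtype=np.int64)
    loglum = np.log(lum)
    next_label = 0
    for r0 in range(nrow):
        for c0 in range(ncol):
            if labels[r0, c0] >= 0:
                continue
            labels[r0, c0] = next_label
            logsum = loglum[r0, c0]
            count = 1
            queue = deque([(r0, c0)])
            while queue:
                r, c = queue.popleft()
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < nrow and 0 <= cc < ncol):
                        continue
                    if labels[rr, cc] >= 0:
                        continue
                    gm = np.exp(logsum / count)
                    if abs(lum[rr, cc] / gm - 1.0) <= cfg.tolerance:
                        labels[rr, cc] = next_label
                        logsum += loglum[rr, cc]
                        count += 1
                        queue.append((rr, cc))
            next_label += 1
    return labels


def region_adjacency(labels: np.ndarray, connectivity: int = 4) -> dict[int, set[int]]:
    """Adjacency sets between labelled regions.

    Two regions are adjacent when any of their pixels touch under the given
    connectivity.  Every label present in the raster appears as a key, even
    if isolated.
    """
    lab = np.asarray(labels)
    if lab.ndim != 2:
        raise ValueError(f"expected a 2-D label raster, got shape {lab.shape}")
    adjacency: dict[int, set[int]] = {int(v): set() for v in np.unique(lab)}
    pairs = []
    pairs.append((lab[:, :-1], lab[:, 1:]))
    pairs.append((lab[:-1, :], lab[1:, :]))
    if connectivity == 8:
        pairs.append((lab[:-1, :-1], lab[1:, 1:]))
        pairs.append((lab[:-1, 1:], lab[1:, :-1]))
    elif connectivity != 4:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    for a, b in pairs:
        mask = a != b
        for x, y in zip(a[mask].ravel(), b[mask].ravel()):
            adjacency[int(x)].add(int(y))
            adjacency[int(y)].add(int(x))
    return adjacency
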