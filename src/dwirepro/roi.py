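"""ROI extraction: probability thresholding, mask erosion, masked means,
and assembly of the long-format measurement table.

Tissue masks come either from integer label volumes (named regions) or
from per-class probability maps thresholded at a strict cut (default
0.95). Masks are eroded by one voxel (6-connected by default) before
averaging, which removes boundary voxels contaminated by partial-volume
mixing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LabelMask",
    "threshold_probability_map",
    "erode_mask",
    "roi_mean",
    "build_measurement_table",
]

logger = logging.getLogger(__name__)


class TableError(ValueError):
    """Invalid measurement-table construction."""


@dataclass(frozen=True)
class LabelMask:
    """Integer label volume with a label -> region-name mapping.

    Label 0 is background and must not be named.
    """

    labels: np.ndarray
    region_names: dict

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise TableError("labels must be a 3-D integer array")
        if 0 in self.region_names:
            raise TableError("label 0 is background and cannot be named")
        object.__setattr__(self, "labels", lab)

    def region_mask(self, name: str) -> np.ndarray:
        for lab, n in self.region_names.items():
            if n == name:
                return self.labels == lab
        raise KeyError(name)

    def __iter__(self):
        for lab, name in self.region_names.items():
            yield name, self.labels == lab


def threshold_probability_map(prob_map: np.ndarray,
                              threshold: float = 0.95) -> np.ndarray:
    """Binary mask of voxels with probability strictly above ``threshold``.

    The comparison is strict ('>'), so a uniform map exactly at the
    threshold yields an empty mask.
    """
    if not 0 < threshold <= 1:
        raise TableError(f"threshold must be in (0, 1], got {threshold}")
    p = np.asarray(prob_map, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise TableError("probability map values must lie in [0, 1]")
    return p > threshold


# face-adjacent (6-connected) structuring element; the conservative
# standard choice for "one voxel" erosion. 26-connectivity available.
_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def erode_mask(mask: np.ndarray, iterations: int = 1,
               connectivity: int = 6) -> np.ndarray:
    """Morphological erosion of a binary mask (output is a subset of input)."""
    if connectivity not in _STRUCTS:
        raise TableError("connectivity must be 6 or 26")
    m = np.asarray(mask).astype(bool)
    if iterations == 0:
        return m.copy()
    return ndimage.binary_erosion(m, structure=_STRUCTS[connectivity],
                                  iterations=iterations)


def roi_mean(param_map: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    """Mean of in-mask, non-sentinel (non-NaN) voxels, with the count used.

    An empty or all-sentinel mask returns ``(nan, 0)`` rather than
    raising, mirroring how sessions with failed segmentations are dropped
    instead of aborting the analysis.
    """
    p = np.asarray(param_map, dtype=float)
    m = np.asarray(mask).astype(bool)
    if p.shape != m.shape:
        raise TableError(f"map shape {p.shape} != mask shape {m.shape}")
    vals = p[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)


def build_measurement_table(sessions) -> pd.DataFrame:
    """Assemble the long-format ROI table from per-session maps and masks.

    Parameters
    ----------
    sessions:
        Iterable of dicts with keys ``scanner``, ``volunteer``,
        ``session``, ``maps`` (metric name -> 3-D parameter map) and
        ``masks`` (region name -> binary mask).

    Returns one row per (session, region, metric) with columns
    ``scanner, volunteer, session, region, metric, value``. Regions whose
    mask is empty (or covers only sentinel voxels) produce no row and a
    warning is logged. Duplicate session keys raise.
    """
    rows = []
    seen = set()
    for sess in sessions:
        key = (sess["scanner"], sess["volunteer"], sess["session"])
        if key in seen:
            raise TableError(f"duplicate session key {key}")
        seen.add(key)
        for region, mask in sess["masks"].items():
            for metric, pmap in sess["maps"].items():
                value, count = roi_mean(pmap, mask)
                if count == 0:
                    logger.warning(
                        "empty ROI: session=%s region=%s metric=%s -- row "
                        "omitted", sess["session"], region, metric,
                    )
                    continue
                rows.append((*key, region, metric, value))
    return pd.DataFrame(
        rows, columns=["scanner", "volunteer", "session", "region",
                       "metric", "value"]
    )
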