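"""Equidistant cortical depth surfaces, volume-to-surface sampling and
inter-region surface distances.

"Equidistant" is taken literally: intermediate surfaces sit at equal
Euclidean spacing along the straight inner-to-outer segment of each vertex.
Surfaces and volumes share a right-handed world frame in millimetres; the
voxel-to-world affine follows the volume header with 0-based voxel indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class DepthSurfaceSet:
    """Ordered per-depth vertex coordinate arrays with matching fractions."""

    surfaces: tuple[np.ndarray, ...]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        if len(self.surfaces) != len(self.fractions):
            raise ValueError("one surface per depth fraction required")


def equidistant_surfaces(inner: np.ndarray, outer: np.ndarray,
                         n_intermediate: int = 9) -> DepthSurfaceSet:
    """``n_intermediate`` surfaces between the boundaries (11 depth levels
    for the default nine), at fractions k / (n_intermediate + 1).

    Vertex coordinates are affine in the fraction along the inner-to-outer
    segment: ``surface_k = inner + fraction_k * (outer - inner)``.
    """
    inner = np.asarray(inner, dtype=float)
    outer = np.asarray(outer, dtype=float)
    if inner.shape != outer.shape:
        raise ValueError("inner and outer surfaces must share vertex count")
    if n_intermediate < 0:
        raise ValueError("n_intermediate must be >= 0")
    fractions = np.linspace(0.0, 1.0, n_intermediate + 2)
    surfaces = tuple(inner + f * (outer - inner) for f in fractions)
    return DepthSurfaceSet(surfaces=surfaces, fractions=fractions)


def sample_volume_to_surface(volume: np.ndarray, surface: np.ndarray,
                             voxel_affine: np.ndarray) -> np.ndarray:
    """Trilinear sampling of a 3-D (or 4-D) volume at surface vertices.

    Vertices mapping outside the volume return NaN (the missing marker);
    downstream analyses exclude such vertices via the shared field-of-view
    mask.  For 4-D input a (n_vertices, n_t) array is returned.
    """
    volume = np.asarray(volume, dtype=float)
    surface = np.asarray(surface, dtype=float)
    try:
        inv = np.linalg.inv(np.asarray(voxel_affine, dtype=float))
    except np.linalg.LinAlgError as err:
        raise ValueError("voxel_affine must be invertible") from err
    vox = inv[:3, :3] @ surface.T + inv[:3, 3:4]
    if volume.ndim == 3:
        return ndimage.map_coordinates(volume, vox, order=1, mode="constant",
                                       cval=np.nan)
    if volume.ndim == 4:
        out = np.empty((surface.shape[0], volume.shape[3]))
        for t in range(volume.shape[3]):
            out[:, t] = ndimage.map_coordinates(volume[..., t], vox, order=1,
                                                mode="constant", cval=np.nan)
        return out
    raise ValueError("volume must be 3-D or 4-D")


def min_distance_to_region(surface: np.ndarray, region_label: np.ndarray,
                           source_region, target_region):
    """Per-source-vertex minimum Euclidean distance to the target region.

    ``source_region``/``target_region`` may be single labels or collections
    (e.g. ("V3a", "V3b")).  Returns ``(distances, summary)`` where summary
    holds the mean and a histogram (counts, bin edges in mm).
    """
    surface = np.asarray(surface, dtype=float)
    labels = np.asarray(region_label)

    def _mask(which) -> np.ndarray:
        names = (which,) if isinstance(which, str) else tuple(which)
        return np.isin(labels, names)

    src = _mask(source_region)
    tgt = _mask(target_region)
    if not src.any() or not tgt.any():
        raise ValueError("source and target regions must be non-empty")
    tree = cKDTree(surface[tgt])
    dist, _ = tree.query(surface[src])
    counts, edges = np.histogram(dist, bins=20)
    summary = {"mean_mm": float(dist.mean()), "min_mm": float(dist.min()),
               "hist_counts": counts, "hist_edges_mm": edges}
    return dist, summary
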