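"""Unsigned distance field and automatic seed/band construction.

Given the current binary shape, every stage of graph construction is driven by
the unsigned Euclidean distance to the shape's surface (foreground voxels with
at least one background 6-neighbor):

* hard **source seeds**: interior voxels deeper than ``phi_s``;
* hard **sink region**: exterior voxels farther than ``phi_t`` — these are not
  graph nodes, they are collapsed into the sink terminal;
* the **band** (graph domain): all interior voxels plus exterior voxels closer
  than ``phi_t``.

Distances are in mm (anisotropic spacing) by default, or in voxel index units
when ``units="voxels"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from shapecut.volume_io import LabelVolume

__all__ = [
    "DistanceField",
    "GraphDomain",
    "surface_mask",
    "unsigned_distance_field",
    "build_graph_domain",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def surface_mask(fg: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one background 6-neighbor (or on the volume face)."""
    eroded = ndimage.binary_erosion(fg, structure=_FACE_STRUCT, border_value=0)
    return fg & ~eroded


@dataclass
class DistanceField:
    """Per-voxel unsigned distance to the shape surface, with inside/outside kept separately."""

    dist: np.ndarray            # float64, >= 0, == 0 exactly on surface voxels
    inside: np.ndarray          # bool, True on shape foreground (surface included)
    surface: np.ndarray         # bool, the zero-distance set
    spacing: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dist.shape


def unsigned_distance_field(
    shape_mask: LabelVolume, units: str = "mm"
) -> DistanceField:
    """Exact unsigned Euclidean distance to the surface of a binary shape.

    dist(p) = min over surface voxels s of the (anisotropic) physical distance
    between the voxel centers of p and s. Raises ValueError when the mask has
    no foreground or no background (no surface exists).
    """
    fg = shape_mask.binary()
    if not fg.any():
        raise ValueError("shape mask is empty: no surface exists")
    if fg.all():
        raise ValueError("shape mask fills the volume: no surface exists")
    if units == "mm":
        sampling = shape_mask.spacing
    elif units == "voxels":
        sampling = (1.0, 1.0, 1.0)
    else:
        raise ValueError(f"unknown units {units!r}")
    surf = surface_mask(fg)
    # EDT measures distance to the nearest zero voxel -> zero out the surface
    dist = ndimage.distance_transform_edt(~surf, sampling=sampling)
    return DistanceField(
        dist=np.asarray(dist, dtype=np.float64),
        inside=fg,
        surface=surf,
        spacing=shape_mask.spacing,
    )


@dataclass
class GraphDomain:
    """Seed sets and band of the s-t graph, with a deterministic node enumeration."""

    source_seeds: np.ndarray    # bool volume; subset of band
    sink_seeds: np.ndarray      # bool volume; disjoint from band (terminal-only)
    band: np.ndarray            # bool volume; the graph nodes
    node_index: np.ndarray      # int32 volume; node id in lexicographic (x,y,z) order, -1 off-band
    band_coords: np.ndarray     # (n_band, 3) int voxel coordinates, node id == row
    source_fallback: bool       # True when phi_s exceeded the inradius and the argmax set was used

    @property
    def n_nodes(self) -> int:
        return self.band_coords.shape[0]


def build_graph_domain(
    df: DistanceField, phi_s: float, phi_t: float
) -> GraphDomain:
    """Derive source seeds, sink region and band from a distance field.

    When no interior voxel is deeper than phi_s (shape thinner than the
    threshold everywhere) the deepest interior voxels are used as source seeds
    instead, with a warning — this keeps small shapes segmentable.
    """
    if phi_s <= 0 or phi_t <= 0:
        raise ValueError("phi_s and phi_t must be positive")
    inside, dist = df.inside, df.dist
    source = inside & (dist > phi_s)
    fallback = False
    if not source.any():
        dmax = dist[inside].max()
        source = inside & (dist >= dmax)
        fallback = True
        warnings.warn(
            f"phi_s={phi_s} exceeds the shape inradius ({dmax:.3g}); "
            "using the deepest interior voxels as source seeds",
            stacklevel=2,
        )
    sink = ~inside & (dist > phi_t)
    band = inside | (~inside & (dist < phi_t))
    if not band.any():
        raise ValueError("graph band is empty")
    node_index = np.full(df.shape, -1, dtype=np.int32)
    # lexicographic (x, y, z): np.argwhere on an (x, y, z)-ordered array is already sorted
    band_coords = np.argwhere(band)
    node_index[band_coords[:, 0], band_coords[:, 1], band_coords[:, 2]] = np.arange(
        band_coords.shape[0], dtype=np.int32
    )
    return GraphDomain(
        source_seeds=source,
        sink_seeds=sink,
        band=band,
        node_index=node_index,
        band_coords=band_coords,
        source_fallback=fallback,
    )
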