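"""Segmentation evaluation: Dice plus the MICCAI'07-style volume and surface measures.

Surface distances are measured between the voxel-center point sets of the two
masks' 6-connectivity border voxels, in mm with anisotropic spacing. This is
deliberately the same surface definition used for graph construction, and it
is exactly checkable against a brute-force all-pairs oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from shapecut.graph_domain import surface_mask
from shapecut.volume_io import LabelVolume, require_same_grid

__all__ = ["EvalReport", "dice", "volume_measures", "surface_measures", "evaluate"]


@dataclass
class EvalReport:
    """All six measures; ``asd_mm <= rmsd_mm <= msd_mm`` always holds."""

    dice: float
    voe_pct: float
    srvd_pct: float
    asd_mm: float
    rmsd_mm: float
    msd_mm: float

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "voe_pct": self.voe_pct,
            "srvd_pct": self.srvd_pct,
            "asd_mm": self.asd_mm,
            "rmsd_mm": self.rmsd_mm,
            "msd_mm": self.msd_mm,
        }


def dice(seg: LabelVolume, ref: LabelVolume) -> float:
    """Dice = 2|seg AND ref| / (|seg| + |ref|) on voxel counts.

    Convention: both masks empty -> 1.0; exactly one empty -> 0.0.
    """
    require_same_grid(seg, ref, "dice")
    a, b = seg.binary(), ref.binary()
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / (na + nb)


def volume_measures(seg: LabelVolume, ref: LabelVolume) -> tuple[float, float]:
    """(VOE %, SRVD %): 100*(1 - |AND|/|OR|) and 100*(|seg|-|ref|)/|ref|.

    Over-segmentation gives positive SRVD. The reference must be nonempty.
    """
    require_same_grid(seg, ref, "volume_measures")
    a, b = seg.binary(), ref.binary()
    nb = int(b.sum())
    if nb == 0:
        raise ValueError("reference mask is empty")
    inter = int(np.logical_and(a, b).sum())
    union = int(np.logical_or(a, b).sum())
    voe = 100.0 * (1.0 - inter / union)
    srvd = 100.0 * (int(a.sum()) - nb) / nb
    return voe, srvd


def surface_measures(
    seg: LabelVolume, ref: LabelVolume, spacing: tuple[float, float, float] | None = None
) -> tuple[float, float, float, np.ndarray]:
    """Symmetric surface distances in mm: (ASD, RMSD, MSD, distance_map).

    Distances are collected from every seg-border voxel to the nearest
    ref-border voxel and vice versa; ASD/RMSD/MSD are the mean, root mean
    square and maximum of the pooled distances. ``distance_map`` assigns each
    seg-border voxel its distance to the ref border (zero elsewhere), for
    surface-distance renderings.
    """
    require_same_grid(seg, ref, "surface_measures")
    if spacing is None:
        spacing = seg.spacing
    a, b = seg.binary(), ref.binary()
    if not a.any() or not b.any():
        raise ValueError("surface measures need two nonempty masks")
    sa = np.argwhere(surface_mask(a)).astype(np.float64)
    sb = np.argwhere(surface_mask(b)).astype(np.float64)
    sp = np.asarray(spacing, dtype=np.float64)
    pa, pb = sa * sp, sb * sp
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    pooled = np.concatenate([d_ab, d_ba])
    asd = float(pooled.mean())
    rmsd = float(np.sqrt((pooled ** 2).mean()))
    msd = float(pooled.max())
    dmap = np.zeros(a.shape, dtype=np.float64)
    ia = sa.astype(int)
    dmap[ia[:, 0], ia[:, 1], ia[:, 2]] = d_ab
    return asd, rmsd, msd, dmap


def evaluate(seg: LabelVolume, ref: LabelVolume) -> tuple[EvalReport, np.ndarray]:
    """Full report plus the seg-surface distance map."""
    d = dice(seg, ref)
    voe, srvd = volume_measures(seg, ref)
    asd, rmsd, msd, dmap = surface_measures(seg, ref)
    return EvalReport(dice=d, voe_pct=voe, srvd_pct=srvd,
                      asd_mm=asd, rmsd_mm=rmsd, msd_mm=msd), dmap
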