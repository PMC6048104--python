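"""Multi-atlas initialization: NMI-based atlas selection and weighted voting.

The module's contract starts at atlases already warped onto the target grid.
Registration itself is external; a recipe for producing warped atlases with
``elastix`` (affine followed by B-spline FFD, adaptive stochastic gradient
descent) is given in the README.

Atlas ranking uses normalized mutual information of target and warped atlas
intensities over a region around the expected organ, normalized by the best
atlas; atlases whose ratio meets a threshold are fused by weighted majority
voting with the ratio as weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from shapecut.volume_io import LabelVolume, Volume, require_same_grid

__all__ = ["AtlasScore", "nmi", "score_and_select", "weighted_majority_vote", "fuse"]


@dataclass
class AtlasScore:
    """Per-atlas selection result: raw NMI, best-normalized ratio, selection mask."""

    nmi: np.ndarray        # (N,) raw NMI values
    r: np.ndarray          # (N,) ratios r_i = NMI_i / max_j NMI_j, in (0, 1]
    selected: np.ndarray   # (N,) bool, r_i >= phi
    weights: np.ndarray    # (N,) fusion weights; r_i where selected, 0 otherwise

    def __post_init__(self) -> None:
        if not np.isclose(self.r.max(), 1.0):
            raise ValueError("ratio normalization broken: max r_i != 1")
        if not self.selected.any():
            raise ValueError("no atlas selected")


def nmi(a: Volume, b: Volume, region: LabelVolume, bins: int = 32) -> float:
    """Normalized mutual information (H(a) + H(b)) / H(a, b) inside a region.

    The joint histogram uses `bins` equal-width bins per image spanning each
    image's intensity range within the region. Entropies are in nats; the
    value is >= 1, reaching 2 for identical non-constant images.

    Raises ValueError for an empty or single-voxel region and for images that
    are constant inside the region (zero marginal entropy would make the
    normalization meaningless, so it is treated as an error rather than
    silently clamped).
    """
    require_same_grid(a, b, "nmi")
    require_same_grid(a, region, "nmi region")
    mask = region.binary()
    n = int(mask.sum())
    if n < 2:
        raise ValueError(f"nmi region must contain at least 2 voxels, got {n}")
    va = a.data[mask]
    vb = b.data[mask]
    if va.min() == va.max() or vb.min() == vb.max():
        raise ValueError("image constant inside region: marginal entropy is zero")
    joint, _, _ = np.histogram2d(va, vb, bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def _entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    h_ab = _entropy(p.ravel())
    return (_entropy(pa) + _entropy(pb)) / h_ab


def _fusion_region(
    target: Volume,
    atlases: list[tuple[Volume, LabelVolume]],
    policy: str,
    dilate_mm: float,
) -> LabelVolume:
    if policy == "whole_image":
        return LabelVolume(np.ones(target.shape, dtype=np.int32), target.spacing, target.origin)
    if policy != "atlas_union_dilated":
        raise ValueError(f"unknown region_policy {policy!r}")
    union = np.zeros(target.shape, dtype=bool)
    for _, lab in atlases:
        union |= lab.binary()
    if dilate_mm > 0 and union.any():
        # dilate by thresholding the EDT of the complement at dilate_mm
        d = ndimage.distance_transform_edt(~union, sampling=target.spacing)
        union = d <= dilate_mm
    return LabelVolume(union.astype(np.int32), target.spacing, target.origin)


def score_and_select(
    target: Volume,
    atlases: list[tuple[Volume, LabelVolume]],
    phi: float = 0.8,
    region_policy: str = "atlas_union_dilated",
    bins: int = 32,
    region_dilate_mm: float = 5.0,
) -> AtlasScore:
    """Rank warped atlases by NMI against the target and select by ratio.

    r_i = NMI_i / max_j NMI_j; atlas i is selected iff r_i >= phi. The argmax
    atlas always has r = 1 and is therefore always selected. Selected atlases
    get fusion weight r_i.
    """
    if len(atlases) < 1:
        raise ValueError("need at least one atlas")
    if not 0 < phi <= 1:
        raise ValueError("phi must lie in (0, 1]")
    region = _fusion_region(target, atlases, region_policy, region_dilate_mm)
    values = np.empty(len(atlases))
    for i, (intensity, _) in enumerate(atlases):
        try:
            values[i] = nmi(target, intensity, region, bins=bins)
        except ValueError as exc:
            raise ValueError(f"atlas {i}: {exc}") from exc
    r = values / values.max()
    selected = r >= phi
    weights = np.where(selected, r, 0.0)
    return AtlasScore(nmi=values, r=r, selected=selected, weights=weights)


def weighted_majority_vote(
    labels: list[LabelVolume], weights: list[float] | np.ndarray
) -> LabelVolume:
    """Fuse label maps by weighted per-voxel voting.

    Per voxel the class maximizing the normalized weighted agreement wins;
    ties break toward the smaller class index, so background is preferred.
    The result is invariant to atlas order and to rescaling all weights.
    """
    if len(labels) < 1:
        raise ValueError("need at least one label volume")
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(labels):
        raise ValueError("weights and labels must have equal length")
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    ref = labels[0]
    for i, lab in enumerate(labels[1:], start=1):
        require_same_grid(ref, lab, f"atlas label {i}")

    classes = sorted(set().union(*(lab.label_set for lab in labels)))
    scores = np.zeros((len(classes),) + ref.shape)
    for lab, w in zip(labels, weights):
        for ci, c in enumerate(classes):
            scores[ci] += w * (lab.data == c)
    # argmax over the class axis returns the first (smallest) class on ties
    winner = np.argmax(scores, axis=0)
    fused = np.asarray(classes, dtype=np.int32)[winner]
    return LabelVolume(fused, ref.spacing, ref.origin)


def fuse(
    target: Volume,
    atlases: list[tuple[Volume, LabelVolume]],
    phi: float = 0.8,
    region_policy: str = "atlas_union_dilated",
    bins: int = 32,
    region_dilate_mm: float = 5.0,
) -> tuple[LabelVolume, AtlasScore]:
    """Full initialization: select atlases, then fuse the selected labels."""
    for i, (intensity, lab) in enumerate(atlases):
        require_same_grid(target, intensity, f"atlas intensity {i}")
        require_same_grid(target, lab, f"atlas label {i}")
    score = score_and_select(
        target, atlases, phi=phi, region_policy=region_policy,
        bins=bins, region_dilate_mm=region_dilate_mm,
    )
    chosen = [lab for (_, lab), keep in zip(atlases, score.selected) if keep]
    w = score.weights[score.selected]
    return weighted_majority_vote(chosen, w), score
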