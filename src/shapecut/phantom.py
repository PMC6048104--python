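"""Synthetic 3D phantoms with ground truth for end-to-end testing.

Each phantom emulates a known failure mode of intensity-driven segmentation:
an adjacent structure with identical mean intensity (separable only by
texture and shape), internal low-intensity lesions, thin protrusions next to
tube-like structures, and a flat interface against a large equal-intensity
mass. Atlases are derived from the ground truth by smooth random displacement
fields, standing in for inter-subject registration residual.

Geometry parameters are in voxel index units; physical anisotropy enters
through the spacing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from shapecut.volume_io import LabelVolume, Volume

__all__ = ["Ellipsoid", "Sphere", "PhantomSpec", "PhantomCase", "generate", "standard_suite"]


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")
        q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, self.center, self.radii))
        return q <= 1.0


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float
    delta: float  # intensity offset relative to the organ

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")
        q = sum((g - c) ** 2 for g, c in zip(grids, self.center))
        return q <= self.radius ** 2


@dataclass
class PhantomSpec:
    """Everything needed to deterministically build one phantom case."""

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    organ: Ellipsoid = field(default_factory=lambda: Ellipsoid((24, 24, 24), (12, 12, 12)))
    lobe: Ellipsoid | None = None               # merged into the organ
    neighbor: Ellipsoid | None = None           # adjacent confounder structure
    neighbor_delta: float = 0.0                 # 0 emulates the equal-intensity regime
    lesions: tuple[Sphere, ...] = ()
    mu_organ: float = 100.0
    mu_background: float = 20.0
    texture_amp: float = 0.0                    # texture amplitude inside the organ
    #: 0 -> iid salt-pepper; > 0 -> spatially correlated (smoothed-noise) texture.
    #: Correlated texture is needed for LBP contrast: contrast-invariant binary
    #: patterns cannot tell iid salt-pepper from plain additive noise.
    texture_sigma: float = 0.0
    #: > 0 -> piecewise-constant block texture of this block size (voxels).
    #: Combined with quantization this reproduces how smooth parenchyma looks
    #: to binary patterns on integer-valued CT: neighbor ties (s(0)=1) bias
    #: codes toward the all-ones pattern.
    texture_block: int = 0
    #: extra iid noise inside the neighbor structure (e.g. moving blood or
    #: heterogeneous stomach content) - gives it balanced, uniform-ish codes
    neighbor_noise_sd: float = 0.0
    #: round the final image to integers, like CT gray values
    quantize: bool = False
    #: smooth intensity heterogeneity outside organ+neighbor (tissue-like
    #: background); keeps the background model realistically broad
    bg_texture_amp: float = 0.0
    bg_texture_sigma: float = 4.0
    noise_sd: float = 0.0
    n_atlases: int = 3
    jitter_amp: float = 3.0                     # max per-atlas displacement in voxels
    jitter_sigma: float = 6.0                   # smoothness of the displacement field
    jitter_bias_amp: float = 0.0                # shared displacement across atlases
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_atlases < 1:
            raise ValueError("need at least one atlas")


@dataclass
class PhantomCase:
    image: Volume
    truth: LabelVolume
    atlases: list[tuple[Volume, LabelVolume]]
    spec: PhantomSpec


def _organ_mask(spec: PhantomSpec) -> np.ndarray:
    mask = spec.organ.mask(spec.shape)
    if spec.lobe is not None:
        mask |= spec.lobe.mask(spec.shape)
    return ndimage.binary_fill_holes(mask)


def _smooth_displacement(rng: np.random.Generator, shape, sigma: float, amp: float) -> np.ndarray:
    disp = np.stack([
        ndimage.gaussian_filter(rng.standard_normal(shape), sigma) for _ in range(3)
    ])
    peak = np.abs(disp).max()
    if peak > 0:
        disp *= amp / peak
    return disp


def _warp(data: np.ndarray, disp: np.ndarray, order: int) -> np.ndarray:
    idx = np.indices(data.shape, dtype=np.float64)
    return ndimage.map_coordinates(data, idx + disp, order=order, mode="nearest")


def generate(spec: PhantomSpec) -> PhantomCase:
    """Build the phantom: image, ground truth, and jittered atlases.

    Deterministic for a fixed spec (including its seed). Raises ValueError if
    the organ and the neighbor structure overlap.
    """
    rng = np.random.default_rng(spec.seed)
    organ = _organ_mask(spec)
    if not organ.any():
        raise ValueError("organ mask is empty")
    img = np.full(spec.shape, spec.mu_background, dtype=np.float64)
    if spec.bg_texture_amp > 0:
        bg_tex = ndimage.gaussian_filter(rng.standard_normal(spec.shape),
                                         spec.bg_texture_sigma)
        bg_tex *= spec.bg_texture_amp / bg_tex.std()
        img += np.abs(bg_tex)  # one-sided: background tissues brighter than base
    img[organ] = spec.mu_organ
    if spec.neighbor is not None:
        nb = spec.neighbor.mask(spec.shape)
        if (organ & nb).any():
            raise ValueError("organ and neighbor structures overlap")
        img[nb] = spec.mu_organ + spec.neighbor_delta
    for lesion in spec.lesions:
        lm = lesion.mask(spec.shape) & organ
        img[lm] = spec.mu_organ + lesion.delta
    if spec.texture_amp > 0:
        if spec.texture_block > 0:
            b = spec.texture_block
            coarse = rng.normal(0.0, 1.0, tuple(-(-n // b) for n in spec.shape))
            tex = np.kron(coarse, np.ones((b, b, b)))[
                : spec.shape[0], : spec.shape[1], : spec.shape[2]]
            tex *= spec.texture_amp / max(tex.std(), 1e-12)
            img[organ] += tex[organ]
        elif spec.texture_sigma > 0:
            tex = ndimage.gaussian_filter(rng.standard_normal(spec.shape), spec.texture_sigma)
            tex *= spec.texture_amp / tex.std()
            img[organ] += tex[organ]
        else:
            img[organ] += spec.texture_amp * rng.choice([-1.0, 1.0], size=int(organ.sum()))
    if spec.neighbor_noise_sd > 0 and spec.neighbor is not None:
        nbm = spec.neighbor.mask(spec.shape)
        img[nbm] += rng.normal(0.0, spec.neighbor_noise_sd, size=int(nbm.sum()))
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    if spec.quantize:
        img = np.round(img)

    image = Volume(img, spec.spacing)
    truth = LabelVolume(organ.astype(np.int32), spec.spacing)

    atlases: list[tuple[Volume, LabelVolume]] = []
    # shared bias models the systematic part of registration residual, which
    # majority voting cannot average away
    bias = (
        _smooth_displacement(rng, spec.shape, spec.jitter_sigma, spec.jitter_bias_amp)
        if spec.jitter_bias_amp > 0
        else 0.0
    )
    for _ in range(spec.n_atlases):
        disp = bias + _smooth_displacement(rng, spec.shape, spec.jitter_sigma, spec.jitter_amp)
        lab = _warp(organ.astype(np.float64), disp, order=0).astype(np.int32)
        wimg = _warp(img, disp, order=1)
        atlases.append((Volume(wimg, spec.spacing), LabelVolume(lab, spec.spacing)))
    return PhantomCase(image=image, truth=truth, atlases=atlases, spec=spec)


def standard_suite(seed: int = 7) -> list[PhantomCase]:
    """The four canonical difficulty cases, each at most 64^3 voxels.

    1. adjacent equal-intensity structure, organ texture-contrasted (64^3);
    2. internal low-intensity lesions;
    3. thin protrusion plus a tube-like equal-intensity structure;
    4. flat interface against a large equal-intensity mass.
    """
    common = dict(
        texture_amp=25.0, noise_sd=0.3, quantize=True,
        bg_texture_amp=12.0, bg_texture_sigma=4.0,
        jitter_amp=3.0, jitter_sigma=8.0, jitter_bias_amp=6.0,
    )
    specs = [
        PhantomSpec(
            shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0),
            organ=Ellipsoid((26, 32, 32), (14, 16, 15)),
            lobe=Ellipsoid((33, 39, 32), (8, 8, 8)),
            neighbor=Ellipsoid((51, 32, 32), (8, 12, 12)),
            neighbor_delta=0.0, seed=seed, **common,
        ),
        # coarse initialization regime: the shared registration bias here is
        # deliberately large, mirroring the gap between initialization and
        # final rows of the reference evaluations
        dataclasses.replace(
            PhantomSpec(
                shape=(48, 48, 48), spacing=(1.5, 1.5, 2.0),
                organ=Ellipsoid((24, 24, 24), (13, 13, 11)),
                lesions=(Sphere((20, 20, 24), 4.0, -60.0), Sphere((29, 27, 20), 3.0, -55.0)),
                seed=seed + 1, **common,
            ),
            jitter_bias_amp=12.0,
        ),
        PhantomSpec(
            shape=(48, 48, 48), spacing=(1.5, 1.5, 2.0),
            organ=Ellipsoid((20, 24, 24), (10, 11, 10)),
            lobe=Ellipsoid((30, 24, 24), (9, 4, 4)),
            neighbor=Ellipsoid((43, 24, 24), (2.5, 2.5, 16.0)),
            neighbor_delta=0.0, seed=seed + 2, **common,
        ),
        PhantomSpec(
            shape=(48, 48, 48), spacing=(1.5, 1.5, 2.0),
            organ=Ellipsoid((18, 24, 24), (10, 12, 11)),
            neighbor=Ellipsoid((37, 24, 24), (6, 16, 15)),
            neighbor_delta=0.0, seed=seed + 3, **common,
        ),
    ]
    return [generate(s) for s in specs]
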