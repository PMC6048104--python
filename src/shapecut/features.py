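"""Per-voxel features consumed by the segmentation energy.

* a 2-channel feature stack (raw intensity + Gaussian blur at scale sigma);
* a d-dimensional Gaussian model fitted on seed regions and its negative
  log-likelihood data term;
* volume local binary patterns, simplified to three orthogonal planes
  (XY, XZ, YZ), pooled over a window into per-voxel cumulative histograms;
* the L1 Wasserstein distance between cumulative histograms and the derived
  appearance term;
* a rotation-invariant spin-image-like 2D (distance, intensity) descriptor and
  the EMD-based boundary weight between neighboring descriptors.

Border policy: volumes are edge-replicated for every windowed or neighborhood
operator, so every voxel of the domain stays computable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage

from shapecut.volume_io import Volume

__all__ = [
    "FeatureStack",
    "GaussianModel",
    "LBPHistograms",
    "feature_stack",
    "fit_gaussian",
    "data_term",
    "data_term_values",
    "vlbp_code",
    "lbp_plane_codes",
    "pooled_code_histograms",
    "lbp_top_histograms",
    "wasserstein_l1",
    "appearance_term",
    "appearance_values",
    "spin_descriptor",
    "spin_descriptors",
    "emd",
    "emd_weight",
]

SIGMA0_FLOOR = 1e-6
COV_REL_REG = 1e-6
COV_ABS_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# feature stack and Gaussian data term
# ---------------------------------------------------------------------------

@dataclass
class FeatureStack:
    """Per-voxel d-dimensional feature vectors on a volume grid."""

    x: np.ndarray  # (nx, ny, nz, d) float64
    spacing: tuple[float, float, float]

    @property
    def d(self) -> int:
        return self.x.shape[-1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.x.shape[:3]

    def at(self, coords: np.ndarray) -> np.ndarray:
        """Feature vectors at (n, 3) voxel coordinates -> (n, d)."""
        coords = np.atleast_2d(coords)
        return self.x[coords[:, 0], coords[:, 1], coords[:, 2]]


def feature_stack(v: Volume, sigma_blur: float = 1.0) -> FeatureStack:
    """Channel 0: raw intensity; channel 1: Gaussian blur at ``sigma_blur`` voxels."""
    if sigma_blur <= 0:
        raise ValueError("sigma_blur must be positive")
    blurred = ndimage.gaussian_filter(v.data, sigma=sigma_blur, mode="nearest")
    return FeatureStack(x=np.stack([v.data, blurred], axis=-1), spacing=v.spacing)


@dataclass
class GaussianModel:
    """Mean and regularized covariance of a d-dimensional Gaussian."""

    mu: np.ndarray      # (d,)
    sigma: np.ndarray   # (d, d) symmetric positive-definite
    regularized: bool = False

    @property
    def d(self) -> int:
        return self.mu.shape[0]


def fit_gaussian(samples: np.ndarray | FeatureStack, region: np.ndarray | None = None) -> GaussianModel:
    """Fit a Gaussian to feature vectors.

    Accepts either an (n, d) sample matrix, or a FeatureStack plus a boolean
    region mask / (n, 3) coordinate array. The covariance uses the unbiased
    1/(n-1) estimator and is regularized by ``max(1e-6 * tr/d, 1e-8) * I`` so
    constant regions stay invertible. Requires at least d + 1 samples.
    """
    if isinstance(samples, FeatureStack):
        if region is None:
            raise ValueError("region required when fitting from a FeatureStack")
        region = np.asarray(region)
        if region.dtype == bool:
            x = samples.x[region]
        else:
            x = samples.at(region)
    else:
        x = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    n, d = x.shape
    if n < d + 1:
        raise ValueError(f"need at least d+1={d + 1} samples to fit a {d}-D Gaussian, got {n}")
    mu = x.mean(axis=0)
    xc = x - mu
    cov = (xc.T @ xc) / (n - 1)
    cov = 0.5 * (cov + cov.T)
    reg = max(COV_REL_REG * np.trace(cov) / d, COV_ABS_FLOOR)
    eigmin = np.linalg.eigvalsh(cov)[0]
    cov = cov + reg * np.eye(d)
    return GaussianModel(mu=mu, sigma=cov, regularized=bool(eigmin < reg))


def data_term(x_p: np.ndarray, model: GaussianModel) -> float:
    """Gaussian negative log-likelihood of one feature vector.

    0.5 * ln((2 pi)^d |sigma|) + 0.5 * (x - mu)^T sigma^-1 (x - mu); minimized
    at x = mu with value 0.5 * ln((2 pi)^d |sigma|).
    """
    return float(data_term_values(np.atleast_2d(np.asarray(x_p, dtype=float)), model)[0])


def data_term_values(x: np.ndarray, model: GaussianModel) -> np.ndarray:
    """Vectorized data term for an (n, d) sample matrix -> (n,)."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    d = model.d
    sign, logdet = np.linalg.slogdet(model.sigma)
    if sign <= 0:
        raise ValueError("model covariance is not positive-definite")
    diff = x - model.mu
    maha = np.einsum("ni,ni->n", diff, np.linalg.solve(model.sigma, diff.T).T)
    return 0.5 * (d * np.log(2.0 * np.pi) + logdet) + 0.5 * maha


# ---------------------------------------------------------------------------
# local binary patterns on three orthogonal planes
# ---------------------------------------------------------------------------

#: plane definitions: (first in-plane axis, second in-plane axis)
PLANES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}
PLANE_ORDER = ("xy", "xz", "yz")


def _plane_offsets(P: int, R: float, L: float, plane: str) -> np.ndarray:
    """(P, 3) float sampling offsets on the plane's ellipse.

    In-plane radius is R for both axes of the XY plane; the z-extent of the
    XZ/YZ planes is the inter-slice interval L. Near-integer components are
    snapped so exact-grid samples stay exact.
    """
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}")
    a1, a2 = PLANES[plane]
    r2 = R if plane == "xy" else L
    angles = 2.0 * np.pi * np.arange(P) / P
    offs = np.zeros((P, 3))
    offs[:, a1] = R * np.cos(angles)
    offs[:, a2] = r2 * np.sin(angles)
    snapped = np.round(offs)
    near = np.abs(offs - snapped) < 1e-9
    offs[near] = snapped[near]
    return offs


def _sample_trilinear(data: np.ndarray, point: np.ndarray) -> float:
    """Delta-form multilinear interpolation at a physical index point.

    Corner indices are clamped to the volume (edge replication). The delta
    form (base + frac * (next - base) per axis) returns the corner value
    exactly when the corners are equal, so constant volumes interpolate
    without rounding noise.
    """
    base = np.floor(point).astype(int)
    frac = point - base

    def rec(axis: int, idx: list[int]) -> float:
        if axis == 3:
            clamped = tuple(np.clip(idx[a], 0, data.shape[a] - 1) for a in range(3))
            return float(data[clamped])
        lo = rec(axis + 1, idx)
        if frac[axis] == 0.0:
            return lo
        idx2 = list(idx)
        idx2[axis] += 1
        hi = rec(axis + 1, idx2)
        return lo + frac[axis] * (hi - lo)

    return rec(0, list(base))


def vlbp_code(
    v: Volume | np.ndarray,
    c: tuple[int, int, int],
    L: int = 2,
    P: int = 8,
    R: float = 1.0,
    plane: str = "xy",
) -> int:
    """Binary pattern code at a center voxel: sum over neighbors of s(g_p - g_c) 2^p.

    s(x) = 1 iff x >= 0, so a constant volume yields the all-ones code 2^P - 1.
    Neighbors sit at P equal angles on the plane's sampling ellipse and are
    interpolated bilinearly; edges are handled by replication. Invariant under
    adding a constant to the volume or scaling it by a positive constant.
    """
    data = v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float64)
    offs = _plane_offsets(P, R, L, plane)
    gc = float(data[tuple(c)])
    code = 0
    center = np.asarray(c, dtype=np.float64)
    for k in range(P):
        gp = _sample_trilinear(data, center + offs[k])
        if gp >= gc:
            code |= 1 << k
    return code


def _shifted_plane_sample(padded: np.ndarray, pad: int, shape: tuple, axes: tuple,
                          o1: float, o2: float) -> np.ndarray:
    """Whole-volume bilinearly interpolated neighbor values for one plane offset."""
    i1, i2 = int(np.floor(o1)), int(np.floor(o2))
    f1, f2 = o1 - i1, o2 - i2

    def grab(a: int, b: int) -> np.ndarray:
        sl = [slice(pad, pad + n) for n in shape]
        sl[axes[0]] = slice(pad + i1 + a, pad + i1 + a + shape[axes[0]])
        sl[axes[1]] = slice(pad + i2 + b, pad + i2 + b + shape[axes[1]])
        return padded[tuple(sl)]

    v00 = grab(0, 0)
    if f2 != 0.0:
        v01 = grab(0, 1)
        lo = v00 + f2 * (v01 - v00)
    else:
        lo = v00
    if f1 == 0.0:
        return np.asarray(lo, dtype=np.float64)
    v10 = grab(1, 0)
    if f2 != 0.0:
        v11 = grab(1, 1)
        hi = v10 + f2 * (v11 - v10)
    else:
        hi = v10
    return lo + f1 * (hi - lo)


def lbp_plane_codes(
    v: Volume | np.ndarray, P: int = 8, R: float = 1.0, L: int = 2
) -> np.ndarray:
    """Per-voxel LBP codes on the three orthogonal planes -> (3, nx, ny, nz) int32."""
    data = v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float64)
    pad = int(np.ceil(max(R, L))) + 1
    padded = np.pad(data, pad, mode="edge")
    codes = np.zeros((3,) + data.shape, dtype=np.int32)
    for pi, plane in enumerate(PLANE_ORDER):
        offs = _plane_offsets(P, R, L, plane)
        axes = PLANES[plane]
        for k in range(P):
            o1, o2 = offs[k, axes[0]], offs[k, axes[1]]
            neigh = _shifted_plane_sample(padded, pad, data.shape, axes, o1, o2)
            codes[pi] |= (neigh >= data).astype(np.int32) << k
    return codes


def pooled_code_histograms(
    codes: np.ndarray,
    coords: np.ndarray,
    window: tuple[int, int, int],
    nbins: int,
) -> np.ndarray:
    """Normalized windowed code histograms at given voxels -> (n, 3, nbins) float32.

    For each requested voxel and each plane, the codes inside the (edge-
    replicated) window are counted and normalized by the window size.
    """
    wx, wy, wz = window
    if any(w % 2 == 0 or w < 1 for w in window):
        raise ValueError("window dims must be odd positive integers")
    shape = codes.shape[1:]
    if any(w > 2 * n for w, n in zip(window, shape)):
        # window may exceed the volume a little thanks to replication, but a
        # window more than twice the volume is certainly a mistake
        raise ValueError(f"window {window} too large for volume of shape {shape}")
    hx, hy, hz = wx // 2, wy // 2, wz // 2
    coords = np.atleast_2d(coords)
    n = coords.shape[0]
    wsize = wx * wy * wz

    ox, oy, oz = np.meshgrid(
        np.arange(-hx, hx + 1), np.arange(-hy, hy + 1), np.arange(-hz, hz + 1),
        indexing="ij",
    )
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)  # (wsize, 3)

    out = np.empty((n, 3, nbins), dtype=np.float32)
    chunk = max(1, int(4e6) // wsize)
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        pts = coords[lo:hi, None, :] + offsets[None, :, :]  # (m, wsize, 3)
        ix = np.clip(pts[..., 0], 0, shape[0] - 1)
        iy = np.clip(pts[..., 1], 0, shape[1] - 1)
        iz = np.clip(pts[..., 2], 0, shape[2] - 1)
        m = hi - lo
        rows = np.arange(m, dtype=np.int64)[:, None] * nbins
        for pi in range(3):
            gathered = codes[pi][ix, iy, iz]  # (m, wsize)
            counts = np.bincount(
                (rows + gathered).ravel(), minlength=m * nbins
            ).reshape(m, nbins)
            out[lo:hi, pi] = counts.astype(np.float32) / np.float32(wsize)
    return out


@dataclass
class LBPHistograms:
    """Per-voxel, per-plane cumulative LBP histograms plus the seed reference."""

    coords: np.ndarray       # (n, 3) voxel coordinates
    H: np.ndarray            # (n, 3, nbins) float32 cumulative histograms
    H0: np.ndarray           # (3, nbins) float64 mean cumulative histogram over seeds
    sigma0_sq: np.ndarray    # (3,) variances of seed-to-mean Wasserstein distances
    nbins: int
    _row_of: dict = None     # voxel tuple -> row

    def __post_init__(self) -> None:
        if self._row_of is None:
            self._row_of = {tuple(c): i for i, c in enumerate(np.asarray(self.coords))}

    def row(self, p: tuple[int, int, int]) -> int:
        try:
            return self._row_of[tuple(int(i) for i in p)]
        except KeyError:
            raise KeyError(f"no histogram computed at voxel {tuple(p)}") from None


def seed_reference(H_seed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean cumulative histogram and WD variance over seed voxels.

    sigma0_i^2 = mean over seeds q of WD(H_q^i, H0^i)^2, floored at 1e-6 so the
    appearance term stays finite on perfectly uniform seed textures.
    """
    H0 = H_seed.astype(np.float64).mean(axis=0)  # (3, nbins)
    wd = np.abs(H_seed - H0[None]).sum(axis=2)   # (n_seed, 3)
    sigma0_sq = np.maximum((wd ** 2).mean(axis=0), SIGMA0_FLOOR)
    return H0, sigma0_sq


def lbp_top_histograms(
    v: Volume | np.ndarray,
    window: tuple[int, int, int],
    P: int,
    R: float,
    seed_region: np.ndarray,
    L: int = 2,
    voxels: np.ndarray | None = None,
) -> LBPHistograms:
    """Windowed three-plane LBP cumulative histograms with a seed reference.

    ``seed_region`` is a boolean mask; ``voxels`` optionally restricts the
    per-voxel histograms to an (n, 3) coordinate set (seed voxels are always
    included). With a 1x1x1 window each histogram is a point mass at the
    voxel's own code.
    """
    data = v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float64)
    seed_region = np.asarray(seed_region, dtype=bool)
    if not seed_region.any():
        raise ValueError("seed region is empty")
    nbins = 2 ** P
    codes = lbp_plane_codes(data, P=P, R=R, L=L)
    seed_coords = np.argwhere(seed_region)
    if voxels is None:
        coords = np.argwhere(np.ones(data.shape, dtype=bool))
    else:
        coords = np.atleast_2d(np.asarray(voxels))
        have = set(map(tuple, coords))
        extra = [c for c in seed_coords if tuple(c) not in have]
        if extra:
            coords = np.vstack([coords, np.asarray(extra)])
    hist = pooled_code_histograms(codes, coords, window, nbins)
    # exact row normalization before accumulation
    hist /= hist.sum(axis=2, keepdims=True)
    H = np.cumsum(hist, axis=2)
    row_of = {tuple(c): i for i, c in enumerate(coords)}
    seed_rows = np.asarray([row_of[tuple(c)] for c in seed_coords])
    H0, sigma0_sq = seed_reference(H[seed_rows])
    return LBPHistograms(coords=coords, H=H, H0=H0, sigma0_sq=sigma0_sq,
                         nbins=nbins, _row_of=row_of)


def wasserstein_l1(ha: np.ndarray, hb: np.ndarray) -> float:
    """1D Wasserstein-1 distance between cumulative histograms, in bin units.

    Equals the L1 distance between the two CDFs: sum_k |Ha[k] - Hb[k]|.
    """
    ha = np.asarray(ha, dtype=np.float64)
    hb = np.asarray(hb, dtype=np.float64)
    if ha.shape != hb.shape:
        raise ValueError(f"cumulative histogram length mismatch: {ha.shape} vs {hb.shape}")
    return float(np.abs(ha - hb).sum())


def appearance_term(hists: LBPHistograms, p: tuple[int, int, int]) -> float:
    """Sum over the three planes of WD(H_p, H0) / sigma0^2."""
    r = hists.row(p)
    total = 0.0
    for pi in range(3):
        total += wasserstein_l1(hists.H[r, pi], hists.H0[pi]) / hists.sigma0_sq[pi]
    return total


def appearance_values(hists: LBPHistograms) -> np.ndarray:
    """Vectorized appearance term for every stored voxel -> (n,)."""
    wd = np.abs(hists.H.astype(np.float64) - hists.H0[None]).sum(axis=2)  # (n, 3)
    return (wd / hists.sigma0_sq[None]).sum(axis=1)


# ---------------------------------------------------------------------------
# spin descriptor
# ---------------------------------------------------------------------------

def _ball_offsets(r: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer offsets within Euclidean radius r (voxel units) and their distances."""
    rng = np.arange(-r, r + 1)
    ox, oy, oz = np.meshgrid(rng, rng, rng, indexing="ij")
    d2 = ox ** 2 + oy ** 2 + oz ** 2
    keep = d2 <= r * r
    offs = np.stack([ox[keep], oy[keep], oz[keep]], axis=1)
    return offs, np.sqrt(d2[keep].astype(np.float64))


def _distance_weights(dists: np.ndarray, r: int, nb_d: int, sigma_d: float) -> np.ndarray:
    """Gaussian soft-binning weights along the distance axis -> (K, nb_d)."""
    u = dists / r * nb_d  # map [0, r] -> [0, nb_d]
    centers = np.arange(nb_d) + 0.5
    return np.exp(-((u[:, None] - centers[None, :]) ** 2) / (2.0 * sigma_d ** 2))


def _intensity_weights(inten: np.ndarray, nb_i: int, sigma_i: float) -> np.ndarray:
    """Soft-binning weights along the intensity axis for (n, K) patch values.

    Intensities are min-max normalized per patch to [0, nb_i]. A zero-range
    (constant) patch puts all intensity mass in bin 0 exactly.
    """
    lo = inten.min(axis=1, keepdims=True)
    hi = inten.max(axis=1, keepdims=True)
    rngs = hi - lo
    degenerate = (rngs == 0).ravel()
    safe = np.where(rngs == 0, 1.0, rngs)
    u = (inten - lo) / safe * nb_i
    centers = np.arange(nb_i) + 0.5
    w = np.exp(-((u[..., None] - centers) ** 2) / (2.0 * sigma_i ** 2))
    if degenerate.any():
        w[degenerate] = 0.0
        w[degenerate, :, 0] = 1.0
    return w


def spin_descriptors(
    v: Volume | np.ndarray,
    coords: np.ndarray,
    r: int = 4,
    bins: tuple[int, int] = (4, 4),
    sigma_d: float = 0.5,
    sigma_i: float = 0.5,
) -> np.ndarray:
    """Spin-image-like descriptors at (n, 3) voxel coordinates -> (n, nb_d, nb_i).

    Every voxel q in the Euclidean ball of radius r (voxel units) around p
    contributes exp(-(d-d_b)^2/2 sigma_d^2 - (i-i_b)^2/2 sigma_i^2) to bin
    (d_b, i_b), where d = |q - p| mapped to [0, nb_d] and i is the patch
    min-max normalized intensity mapped to [0, nb_i]. Descriptors are
    normalized to unit mass. Rotation-invariant because d depends only on the
    radius; borders are edge-replicated via index clamping.
    """
    if r < 1:
        raise ValueError("patch radius must be a positive integer")
    data = v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float64)
    nb_d, nb_i = bins
    coords = np.atleast_2d(coords)
    offs, dists = _ball_offsets(r)
    wd = _distance_weights(dists, r, nb_d, sigma_d)  # (K, nb_d)
    n = coords.shape[0]
    out = np.empty((n, nb_d, nb_i), dtype=np.float64)
    chunk = max(1, int(2e6) // offs.shape[0])
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        pts = coords[lo:hi, None, :] + offs[None, :, :]
        ix = np.clip(pts[..., 0], 0, data.shape[0] - 1)
        iy = np.clip(pts[..., 1], 0, data.shape[1] - 1)
        iz = np.clip(pts[..., 2], 0, data.shape[2] - 1)
        inten = data[ix, iy, iz]                      # (m, K)
        wi = _intensity_weights(inten, nb_i, sigma_i)  # (m, K, nb_i)
        desc = np.einsum("kd,mki->mdi", wd, wi)
        out[lo:hi] = desc
    out /= out.sum(axis=(1, 2), keepdims=True)
    return out


def spin_descriptor(
    v: Volume | np.ndarray,
    p: tuple[int, int, int],
    r: int = 4,
    bins: tuple[int, int] = (4, 4),
    sigma_d: float = 0.5,
    sigma_i: float = 0.5,
) -> np.ndarray:
    """Single-voxel spin descriptor -> (nb_d, nb_i), unit mass."""
    return spin_descriptors(v, np.asarray([p]), r=r, bins=bins,
                            sigma_d=sigma_d, sigma_i=sigma_i)[0]


# ---------------------------------------------------------------------------
# earth mover's distance on the descriptor grid
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mcf_emd(supply: np.ndarray, tails: np.ndarray, heads: np.ndarray, n_nodes: int) -> float:
    """Uncapacitated min-cost flow with unit arc costs by successive shortest paths.

    With the grid's 4-neighbor arcs and unit costs, the shortest-path metric is
    exactly the L1 bin distance, so the optimal flow cost equals the EMD of the
    two histograms whose difference is ``supply``.
    """
    m = tails.shape[0]
    nd = 2 * m
    at = np.empty(nd, np.int64)
    ah = np.empty(nd, np.int64)
    for i in range(m):
        at[2 * i] = tails[i]
        ah[2 * i] = heads[i]
        at[2 * i + 1] = heads[i]
        ah[2 * i + 1] = tails[i]
    flow = np.zeros(nd, np.float64)
    deg = np.zeros(n_nodes, np.int64)
    for i in range(nd):
        deg[at[i]] += 1
    start = np.zeros(n_nodes + 1, np.int64)
    for vtx in range(n_nodes):
        start[vtx + 1] = start[vtx] + deg[vtx]
    adj = np.empty(nd, np.int64)
    pos = start[:-1].copy()
    for i in range(nd):
        adj[pos[at[i]]] = i
        pos[at[i]] += 1

    excess = supply.copy()
    pot = np.zeros(n_nodes, np.float64)
    INF = 1e18
    EPS = 1e-15
    while True:
        s = -1
        for vtx in range(n_nodes):
            if excess[vtx] > EPS:
                s = vtx
                break
        if s < 0:
            break
        dist = np.full(n_nodes, INF)
        dist[s] = 0.0
        visited = np.zeros(n_nodes, np.bool_)
        parent_arc = np.full(n_nodes, -1, np.int64)
        for _ in range(n_nodes):
            u = -1
            du = INF
            for vtx in range(n_nodes):
                if not visited[vtx] and dist[vtx] < du:
                    du = dist[vtx]
                    u = vtx
            if u < 0:
                break
            visited[u] = True
            for k in range(start[u], start[u + 1]):
                a = adj[k]
                vtx = ah[a]
                rev = a ^ 1
                c = -1.0 if flow[rev] > EPS else 1.0
                rc = c + pot[u] - pot[vtx]
                if du + rc < dist[vtx] - EPS:
                    dist[vtx] = du + rc
                    parent_arc[vtx] = a
        t = -1
        dt = INF
        for vtx in range(n_nodes):
            if excess[vtx] < -EPS and dist[vtx] < dt:
                dt = dist[vtx]
                t = vtx
        if t < 0:
            break
        amt = excess[s]
        if -excess[t] < amt:
            amt = -excess[t]
        vtx = t
        while vtx != s:
            a = parent_arc[vtx]
            rev = a ^ 1
            if flow[rev] > EPS and flow[rev] < amt:
                amt = flow[rev]
            vtx = at[a]
        vtx = t
        while vtx != s:
            a = parent_arc[vtx]
            rev = a ^ 1
            if flow[rev] > EPS:
                cancel = flow[rev] if flow[rev] < amt else amt
                flow[rev] -= cancel
                if amt - cancel > 0:
                    flow[a] += amt - cancel
            else:
                flow[a] += amt
            vtx = at[a]
        for vtx in range(n_nodes):
            if dist[vtx] < INF:
                pot[vtx] += dist[vtx]
        excess[s] -= amt
        excess[t] += amt
    total = 0.0
    for i in range(nd):
        total += flow[i]
    return total


def _grid_arcs(nr: int, nc: int) -> tuple[np.ndarray, np.ndarray]:
    tails, heads = [], []
    for row in range(nr):
        for col in range(nc):
            u = row * nc + col
            if col + 1 < nc:
                tails.append(u)
                heads.append(u + 1)
            if row + 1 < nr:
                tails.append(u)
                heads.append(u + nc)
    return np.asarray(tails, dtype=np.int64), np.asarray(heads, dtype=np.int64)


_ARC_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def emd(ha: np.ndarray, hb: np.ndarray) -> float:
    """Earth mover's distance between two 2D histograms under L1 bin distance.

    Both histograms must be normalized to unit mass. Solved exactly as a
    min-cost flow on the bin grid (L1 distance = shortest path with unit
    steps), which matches the transportation LP to ~1e-15.
    """
    ha = np.asarray(ha, dtype=np.float64)
    hb = np.asarray(hb, dtype=np.float64)
    if ha.shape != hb.shape or ha.ndim != 2:
        raise ValueError(f"histogram shape mismatch: {ha.shape} vs {hb.shape}")
    for name, h in (("first", ha), ("second", hb)):
        if h.min() < -1e-12:
            raise ValueError(f"{name} histogram has negative entries")
        if abs(h.sum() - 1.0) > 1e-8:
            raise ValueError(f"{name} histogram is not normalized to unit mass")
    key = ha.shape
    if key not in _ARC_CACHE:
        _ARC_CACHE[key] = _grid_arcs(*key)
    tails, heads = _ARC_CACHE[key]
    return float(_mcf_emd((ha - hb).ravel(), tails, heads, ha.size))


def emd_weight(ha: np.ndarray, hb: np.ndarray) -> float:
    """EMD between unit-mass descriptors, normalized to [0, 1] by the bin diameter."""
    ha = np.asarray(ha, dtype=np.float64)
    d_max = (ha.shape[0] - 1) + (ha.shape[1] - 1)
    return emd(ha, hb) / d_max
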