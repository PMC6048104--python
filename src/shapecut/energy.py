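"""Shape-constrained multi-dimensional graph-cut energy and its minimization.

The labeling energy over the banded graph domain is

    E(L) = sum_p [ alpha*D_p(L_p) + beta*J_p + gamma*S_p ]_(liver side)
         + sum_{p,q} B_pq * [L_p != L_q]

with a Gaussian data term D (foreground model for the liver label, background
model for the background label), the LBP appearance distance J and the
distance-field shape term S both charged to the *liver* label (texture unlike
the seeds and positions far outside the current shape are expensive to call
liver), and an EMD-weighted boundary term B on 6-neighbor pairs. The energy is
minimized exactly by an s-t min cut and iterated with shape updates.

The intensity-only baseline (`segment_intensity_only`) drops J and S, uses
1-D intensity features with a unit EMD weight, and performs a single cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from shapecut import features as ft
from shapecut.config import PipelineConfig
from shapecut.graph_domain import (
    DistanceField,
    GraphDomain,
    build_graph_domain,
    unsigned_distance_field,
)
from shapecut.volume_io import LabelVolume, Volume, require_same_grid

__all__ = [
    "EnergyWeights",
    "EnergyGraph",
    "ShapeTermField",
    "shape_term",
    "shape_term_field",
    "enclosing_radius",
    "boundary_capacity",
    "assemble_energy",
    "min_cut",
    "energy_of_labeling",
    "segment",
    "segment_intensity_only",
]

logger = logging.getLogger(__name__)

_AXIS_SHIFTS = ((1, 0, 0), (0, 1, 0), (0, 0, 1))


@dataclass
class EnergyWeights:
    """Coefficients of the energy and the iteration count."""

    alpha: float = 10.0
    beta: float = 10.0
    gamma: float = 80.0
    lam: float = 10.0
    sigma1: float = 0.1
    iterations: int = 5

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma, self.lam) < 0:
            raise ValueError("energy weights must be non-negative")
        if self.sigma1 <= 0:
            raise ValueError("sigma1 must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @classmethod
    def from_config(cls, cfg: PipelineConfig) -> "EnergyWeights":
        return cls(alpha=cfg.alpha, beta=cfg.beta, gamma=cfg.gamma,
                   lam=cfg.lam, sigma1=cfg.sigma1, iterations=cfg.iterations)


@dataclass
class ShapeTermField:
    """Per-voxel shape penalty S = 1 - exp(-d / r0), zero on and inside the shape."""

    S: np.ndarray   # float64 volume in [0, 1)
    r0: float


def shape_term_field(df: DistanceField, r0: float) -> ShapeTermField:
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    d = np.where(df.inside, 0.0, df.dist)
    return ShapeTermField(S=1.0 - np.exp(-d / r0), r0=r0)


def shape_term(df: DistanceField, r0: float, p: tuple[int, int, int]) -> float:
    """S_p = 1 - exp(-d(p, shape)/r0), with d forced to 0 for interior voxels."""
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    p = tuple(int(i) for i in p)
    d = 0.0 if df.inside[p] else float(df.dist[p])
    return 1.0 - float(np.exp(-d / r0))


def enclosing_radius(shape_mask: LabelVolume) -> float:
    """Radius of the centroid-centered sphere enclosing the shape, in mm.

    Floored at one voxel diagonal so degenerate single-voxel shapes still give
    a usable scale.
    """
    fg = shape_mask.binary()
    if not fg.any():
        raise ValueError("shape mask is empty")
    coords = np.argwhere(fg).astype(np.float64) * np.asarray(shape_mask.spacing)
    centroid = coords.mean(axis=0)
    r0 = float(np.linalg.norm(coords - centroid, axis=1).max())
    return max(r0, float(np.linalg.norm(shape_mask.spacing)))


def boundary_capacity(
    fs: ft.FeatureStack,
    spins,
    p: tuple[int, int, int],
    q: tuple[int, int, int],
    sigma1: float,
    spacing: tuple[float, float, float] | None = None,
) -> float:
    """Boundary term for one 6-neighbor pair.

    B = exp(-omega_pq * ||x_p - x_q||^2 / (2 sigma1^2)) / dist(p, q), with
    omega_pq the normalized EMD between the voxels' spin descriptors and
    dist the physical distance between the voxel centers. Symmetric in (p, q).
    ``spins`` is a mapping from voxel tuple to descriptor.
    """
    if spacing is None:
        spacing = fs.spacing
    p = tuple(int(i) for i in p)
    q = tuple(int(i) for i in q)
    omega = ft.emd_weight(spins[p], spins[q])
    xp, xq = fs.x[p], fs.x[q]
    diff2 = float(((xp - xq) ** 2).sum())
    dist = float(np.linalg.norm((np.asarray(p) - np.asarray(q)) * np.asarray(spacing)))
    return float(np.exp(-omega * diff2 / (2.0 * sigma1 ** 2)) / dist)


@dataclass
class EnergyGraph:
    """The assembled s-t graph: per-node terminal capacities plus n-links.

    ``cap_source[i]`` is the capacity of the edge to the source terminal (paid
    when node i ends on the background side); ``cap_sink[i]`` the capacity to
    the sink terminal (paid when node i ends on the liver side). ``edges``
    holds undirected 6-neighbor pairs of node ids with capacities ``caps``.
    """

    cap_source: np.ndarray       # (n,) float64
    cap_sink: np.ndarray         # (n,) float64
    edges: np.ndarray            # (m, 2) int32
    caps: np.ndarray             # (m,) float64
    infinite_capacity: float
    band_coords: np.ndarray      # (n, 3)
    volume_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    source_seed_nodes: np.ndarray  # (n,) bool

    @property
    def n_nodes(self) -> int:
        return self.cap_source.shape[0]


def _band_edges(domain: GraphDomain) -> tuple[np.ndarray, np.ndarray]:
    """Undirected 6-neighbor node pairs inside the band and their axis index."""
    idx = domain.node_index
    pairs, axes = [], []
    for axis, shift in enumerate(_AXIS_SHIFTS):
        a = idx[: idx.shape[0] - shift[0], : idx.shape[1] - shift[1], : idx.shape[2] - shift[2]]
        b = idx[shift[0]:, shift[1]:, shift[2]:]
        ok = (a >= 0) & (b >= 0)
        pairs.append(np.stack([a[ok], b[ok]], axis=1))
        axes.append(np.full(ok.sum(), axis, dtype=np.int8))
    return np.concatenate(pairs, axis=0), np.concatenate(axes)


def _rows_for(hists: ft.LBPHistograms, coords: np.ndarray) -> np.ndarray:
    return np.fromiter((hists.row(tuple(c)) for c in coords), dtype=np.int64, count=len(coords))


def assemble_energy(
    domain: GraphDomain,
    fs: ft.FeatureStack,
    hists: ft.LBPHistograms,
    spins,
    stf: ShapeTermField,
    fg_model: ft.GaussianModel,
    bg_model: ft.GaussianModel,
    w: EnergyWeights,
    omega_cache: dict | None = None,
) -> EnergyGraph:
    """Build the s-t graph realizing the energy on the band.

    Liver-label cost: alpha*D_fg + beta*J + gamma*S (on the sink t-link);
    background-label cost: alpha*D_bg (on the source t-link). Source seeds get
    an effectively uncuttable source t-link. ``spins`` may be an
    (n_band, nb, nb) array aligned with node ids or a mapping from voxel
    tuples; ``omega_cache`` (keyed by flat voxel index pairs) lets callers
    reuse EMD weights across iterations.
    """
    coords = domain.band_coords
    n = coords.shape[0]
    x = fs.at(coords)
    d_fg = ft.data_term_values(x, fg_model)
    d_bg = ft.data_term_values(x, bg_model)
    rows = _rows_for(hists, coords)
    j_all = ft.appearance_values(hists)
    j_band = j_all[rows]
    s_band = stf.S[coords[:, 0], coords[:, 1], coords[:, 2]]

    cost_liver = w.alpha * d_fg + w.beta * j_band + w.gamma * s_band
    cost_bg = w.alpha * d_bg
    # Gaussian log-likelihoods can go negative; shifting both t-links of a
    # voxel by a constant leaves the minimizer unchanged and keeps all
    # capacities non-negative, as max-flow requires.
    shift = np.minimum(np.minimum(cost_liver, cost_bg), 0.0)
    cost_liver = cost_liver - shift
    cost_bg = cost_bg - shift

    if isinstance(spins, np.ndarray):
        spin_rows = spins
    else:
        spin_rows = np.stack([spins[tuple(c)] for c in coords])
    edges, axes = _band_edges(domain)
    flat = np.ravel_multi_index(coords.T, domain.band.shape)
    m = edges.shape[0]
    omega = np.empty(m)
    for e in range(m):
        i, j = int(edges[e, 0]), int(edges[e, 1])
        key = (int(flat[i]), int(flat[j])) if flat[i] < flat[j] else (int(flat[j]), int(flat[i]))
        if omega_cache is not None and key in omega_cache:
            omega[e] = omega_cache[key]
        else:
            val = ft.emd_weight(spin_rows[i], spin_rows[j])
            omega[e] = val
            if omega_cache is not None:
                omega_cache[key] = val
    diff2 = ((x[edges[:, 0]] - x[edges[:, 1]]) ** 2).sum(axis=1)
    step = np.asarray(fs.spacing)[axes]
    caps = np.exp(-omega * diff2 / (2.0 * w.sigma1 ** 2)) / step

    for name, arr in (("source t-link", cost_bg), ("sink t-link", cost_liver), ("n-link", caps)):
        if not np.all(np.isfinite(arr)):
            bad = int(np.argmax(~np.isfinite(arr)))
            raise ValueError(f"non-finite {name} capacity at element {bad}")

    finite_max = max(float(cost_liver.max(initial=0.0)), float(cost_bg.max(initial=0.0)),
                     float(caps.max(initial=0.0)), 1.0)
    inf_cap = 1e6 * finite_max
    seeds = domain.source_seeds[coords[:, 0], coords[:, 1], coords[:, 2]]
    cap_source = np.where(seeds, inf_cap, cost_bg)
    cap_sink = np.where(seeds, 0.0, cost_liver)
    return EnergyGraph(
        cap_source=cap_source,
        cap_sink=cap_sink,
        edges=edges,
        caps=caps,
        infinite_capacity=inf_cap,
        band_coords=coords,
        volume_shape=domain.band.shape,
        spacing=fs.spacing,
        origin=(0.0, 0.0, 0.0),
        source_seed_nodes=seeds,
    )


def energy_of_labeling(g: EnergyGraph, node_labels: np.ndarray) -> float:
    """Energy of a node labeling (1 = liver/source side) under the graph's capacities."""
    node_labels = np.asarray(node_labels, dtype=bool)
    tcost = np.where(node_labels, g.cap_sink, g.cap_source).sum()
    cut = node_labels[g.edges[:, 0]] != node_labels[g.edges[:, 1]]
    return float(tcost + g.caps[cut].sum())


def min_cut(g: EnergyGraph) -> tuple[LabelVolume, float]:
    """Exact minimum s-t cut of the energy graph.

    Returns the labeling (1 = liver side) on the full volume grid (off-band
    voxels are background) and the cut value, recomputed as the energy of the
    returned labeling so the two are consistent by construction.
    """
    import igraph as ig

    n = g.n_nodes
    if n == 0:
        raise ValueError("energy graph has no nodes")
    src, snk = n, n + 1
    e_src = np.flatnonzero(g.cap_source > 0)
    e_snk = np.flatnonzero(g.cap_sink > 0)
    edges = np.concatenate([
        np.stack([np.full(e_src.size, src), e_src], axis=1),
        np.stack([e_snk, np.full(e_snk.size, snk)], axis=1),
        g.edges,
    ])
    caps = np.concatenate([g.cap_source[e_src], g.cap_sink[e_snk], g.caps])
    graph = ig.Graph(n + 2, edges.tolist())
    cut = graph.st_mincut(src, snk, capacity=caps.tolist())
    side = np.zeros(n + 2, dtype=bool)
    part = cut.partition[0] if src in cut.partition[0] else cut.partition[1]
    side[list(part)] = True
    node_labels = side[:n]
    value = energy_of_labeling(g, node_labels)
    vol = np.zeros(g.volume_shape, dtype=np.int32)
    lit = g.band_coords[node_labels]
    vol[lit[:, 0], lit[:, 1], lit[:, 2]] = 1
    return LabelVolume(vol, g.spacing, g.origin), value


# ---------------------------------------------------------------------------
# iterated pipeline
# ---------------------------------------------------------------------------

def largest_component_filled(mask: np.ndarray) -> np.ndarray:
    """Largest 6-connected component with fully enclosed holes filled."""
    labeled, nlab = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    if nlab == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, nlab + 1))
    keep = labeled == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(keep)


def _normalized(target: Volume, enable: bool) -> Volume:
    if not enable:
        return target
    lo, hi = float(target.data.min()), float(target.data.max())
    if hi == lo:
        return target
    return Volume((target.data - lo) / (hi - lo), target.spacing, target.origin)


def _fit_region_fg(domain: GraphDomain, df: DistanceField, min_count: int = 8) -> np.ndarray:
    """Foreground model region: source seeds, widened to the deepest interior half
    when the seed set is too small to estimate statistics."""
    region = domain.source_seeds
    if region.sum() >= min_count:
        return region
    inner = df.inside & (df.dist >= 0.5 * df.dist[df.inside].max())
    return inner if inner.sum() >= min_count else df.inside


def _fit_region_bg(df: DistanceField, phi_t: float, shell: float, min_count: int = 8) -> np.ndarray:
    """Background model region: exterior shell just beyond the band."""
    outside = ~df.inside
    region = outside & (df.dist > phi_t) & (df.dist <= phi_t + shell)
    if region.sum() >= min_count:
        return region
    region = outside & (df.dist > phi_t)
    return region if region.sum() >= min_count else outside


class _RowCache:
    """Grows a row store of per-voxel arrays keyed by flat voxel index."""

    def __init__(self, row_shape: tuple, dtype) -> None:
        self._index: dict[int, int] = {}
        self._rows: list[np.ndarray] = []
        self._row_shape = row_shape
        self._dtype = dtype

    def ensure(self, flat: np.ndarray, compute, coords: np.ndarray) -> None:
        missing = [i for i, f in enumerate(flat) if int(f) not in self._index]
        if missing:
            new_rows = compute(coords[missing])
            for i, row in zip(missing, new_rows):
                self._index[int(flat[i])] = len(self._rows)
                self._rows.append(np.asarray(row, dtype=self._dtype))

    def take(self, flat: np.ndarray) -> np.ndarray:
        out = np.empty((len(flat),) + self._row_shape, dtype=self._dtype)
        for i, f in enumerate(flat):
            out[i] = self._rows[self._index[int(f)]]
        return out


def segment(
    target: Volume,
    init_mask: LabelVolume,
    weights: EnergyWeights | None = None,
    cfg: PipelineConfig | None = None,
) -> tuple[LabelVolume, list[dict]]:
    """Iterated shape-constrained multi-dimensional graph cut.

    Each iteration rebuilds the distance field and graph domain from the
    current shape, refits the foreground/background models and the seed LBP
    reference (unless frozen via ``cfg.refit_models``), assembles the energy,
    solves the min cut, and keeps the largest connected component of the liver
    side as the next shape. Per-voxel LBP histograms, spin descriptors and
    pairwise EMD weights depend only on the image and are cached across
    iterations. Stops early when the shape stops changing or an empty cut
    forces a revert (flagged in the diagnostics).
    """
    cfg = cfg or PipelineConfig()
    w = weights or EnergyWeights.from_config(cfg)
    require_same_grid(target, init_mask, "segment")
    if not init_mask.binary().any():
        raise ValueError("initial mask is empty")

    vol = _normalized(target, cfg.normalize_intensity)
    fs = ft.feature_stack(vol, cfg.sigma_blur)
    codes = ft.lbp_plane_codes(vol, P=cfg.lbp_points, R=cfg.lbp_radius, L=cfg.lbp_interval)
    nbins = 2 ** cfg.lbp_points
    vshape = target.shape

    hist_cache = _RowCache((3, nbins), np.float32)
    spin_cache = _RowCache(tuple(cfg.spin_bins), np.float64)
    omega_cache: dict[tuple[int, int], float] = {}

    def hist_rows(coords: np.ndarray) -> np.ndarray:
        h = ft.pooled_code_histograms(codes, coords, cfg.window, nbins)
        h /= h.sum(axis=2, keepdims=True)
        return np.cumsum(h, axis=2)

    def spin_rows(coords: np.ndarray) -> np.ndarray:
        return ft.spin_descriptors(vol, coords, r=cfg.spin_radius, bins=cfg.spin_bins,
                                   sigma_d=cfg.sigma_d, sigma_i=cfg.sigma_i)

    shape = largest_component_filled(init_mask.binary())
    if not shape.any():
        raise ValueError("initial mask has no connected component")
    diagnostics: list[dict] = []
    frozen: tuple | None = None

    for it in range(w.iterations):
        mask_lv = LabelVolume(shape.astype(np.int32), target.spacing, target.origin)
        df = unsigned_distance_field(mask_lv, units=cfg.threshold_units)
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            domain = build_graph_domain(df, cfg.phi_s, cfg.phi_t)

        coords = domain.band_coords
        flat = np.ravel_multi_index(coords.T, vshape)
        hist_cache.ensure(flat, hist_rows, coords)
        spin_cache.ensure(flat, spin_rows, coords)
        H_band = hist_cache.take(flat)
        spins_band = spin_cache.take(flat)

        if frozen is None or cfg.refit_models:
            fg_region = _fit_region_fg(domain, df)
            bg_region = _fit_region_bg(df, cfg.phi_t, cfg.bg_shell)
            fg_model = ft.fit_gaussian(fs, fg_region)
            bg_model = ft.fit_gaussian(fs, bg_region)
            seed_flat = np.ravel_multi_index(np.argwhere(fg_region).T, vshape)
            seed_coords = np.argwhere(fg_region)
            hist_cache.ensure(seed_flat, hist_rows, seed_coords)
            H0, sigma0_sq = ft.seed_reference(hist_cache.take(seed_flat))
            if not cfg.refit_models:
                frozen = (fg_model, bg_model, H0, sigma0_sq)
        else:
            fg_model, bg_model, H0, sigma0_sq = frozen

        hists = ft.LBPHistograms(coords=coords, H=H_band, H0=H0, sigma0_sq=sigma0_sq,
                                 nbins=nbins)
        r0 = enclosing_radius(mask_lv)
        stf = shape_term_field(df, r0)
        graph = assemble_energy(domain, fs, hists, spins_band, stf,
                                fg_model, bg_model, w, omega_cache=omega_cache)
        labeling, energy = min_cut(graph)
        new_shape = largest_component_filled(labeling.binary())

        inter = np.logical_and(shape, new_shape).sum()
        dice_prev = 2.0 * inter / max(shape.sum() + new_shape.sum(), 1)
        diag = {
            "iteration": it,
            "energy": energy,
            "dice_vs_previous": float(dice_prev),
            "n_source_seeds": int(domain.source_seeds.sum()),
            "n_band": int(domain.n_nodes),
            "source_fallback": domain.source_fallback,
            "reverted": False,
            "component_size": int(new_shape.sum()),
        }
        logger.info(
            "iteration %d: energy=%.6g band=%d seeds=%d component=%d dice_prev=%.4f",
            it, energy, diag["n_band"], diag["n_source_seeds"],
            diag["component_size"], dice_prev,
        )
        if not new_shape.any():
            diag["reverted"] = True
            diagnostics.append(diag)
            break
        converged = bool(np.array_equal(new_shape, shape))
        shape = new_shape
        diagnostics.append(diag)
        if converged:
            break

    final = LabelVolume(shape.astype(np.int32), target.spacing, target.origin)
    return final, diagnostics


def segment_intensity_only(
    target: Volume,
    init_mask: LabelVolume,
    lam: float = 10.0,
    cfg: PipelineConfig | None = None,
) -> LabelVolume:
    """Intensity-only graph-cut baseline: lambda-weighted 1-D Gaussian regional
    terms plus the boundary term with a unit EMD weight; one cut, no shape term,
    no iteration. Seeds and band come from the same automatic construction."""
    cfg = cfg or PipelineConfig()
    if lam < 0:
        raise ValueError("lam must be non-negative")
    require_same_grid(target, init_mask, "segment_intensity_only")
    if not init_mask.binary().any():
        raise ValueError("initial mask is empty")
    vol = _normalized(target, cfg.normalize_intensity)
    shape = largest_component_filled(init_mask.binary())
    mask_lv = LabelVolume(shape.astype(np.int32), target.spacing, target.origin)
    df = unsigned_distance_field(mask_lv, units=cfg.threshold_units)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        domain = build_graph_domain(df, cfg.phi_s, cfg.phi_t)

    coords = domain.band_coords
    intens = vol.data[coords[:, 0], coords[:, 1], coords[:, 2]][:, None]
    fg_region = _fit_region_fg(domain, df)
    bg_region = _fit_region_bg(df, cfg.phi_t, cfg.bg_shell)
    fg_model = ft.fit_gaussian(vol.data[fg_region][:, None])
    bg_model = ft.fit_gaussian(vol.data[bg_region][:, None])
    d_fg = ft.data_term_values(intens, fg_model)
    d_bg = ft.data_term_values(intens, bg_model)
    shift = np.minimum(np.minimum(d_fg, d_bg), 0.0)
    d_fg = d_fg - shift
    d_bg = d_bg - shift

    edges, axes = _band_edges(domain)
    diff2 = (intens[edges[:, 0], 0] - intens[edges[:, 1], 0]) ** 2
    step = np.asarray(vol.spacing)[axes]
    caps = np.exp(-diff2 / (2.0 * cfg.sigma1 ** 2)) / step

    finite_max = max(float((lam * d_fg).max(initial=0.0)), float((lam * d_bg).max(initial=0.0)),
                     float(caps.max(initial=0.0)), 1.0)
    inf_cap = 1e6 * finite_max
    seeds = domain.source_seeds[coords[:, 0], coords[:, 1], coords[:, 2]]
    graph = EnergyGraph(
        cap_source=np.where(seeds, inf_cap, lam * d_bg),
        cap_sink=np.where(seeds, 0.0, lam * d_fg),
        edges=edges,
        caps=caps,
        infinite_capacity=inf_cap,
        band_coords=coords,
        volume_shape=target.shape,
        spacing=target.spacing,
        origin=target.origin,
        source_seed_nodes=seeds,
    )
    labeling, _ = min_cut(graph)
    return labeling
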