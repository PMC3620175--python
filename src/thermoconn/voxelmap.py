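"""Seed-based voxelwise connectivity maps with Monte Carlo cluster correction.

Workflow: carve a spherical seed (default: posterior cingulate /
precuneus at MNI [-2, -54, 27], 10 mm radius), average its voxels into
a reference time course, correlate it with every in-mask voxel,
Fisher-transform to a z map, run voxelwise group t-tests, and keep
only clusters whose extent survives a Monte Carlo (AlphaSim-style)
familywise threshold estimated from smoothed Gaussian noise fields.

Grids are axis-aligned: world_mm = index * voxel_size + origin, voxel
centers, 0-based indices.  No oblique affines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special

from . import statcore

__all__ = [
    "VolumeSeries",
    "ZMap",
    "ClusterRule",
    "ClusterRecord",
    "FWHM_TO_SIGMA",
    "sphere_roi_mask",
    "roi_mean_series",
    "seed_correlation_map",
    "smooth_gaussian",
    "label_clusters",
    "alphasim_min_cluster",
    "group_voxel_ttest",
]

#: sigma = FWHM * this constant (1 / (2 sqrt(2 ln 2)) = 1 / 2.3548...).
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class VolumeSeries:
    """4-D voxel time series on an axis-aligned grid."""

    values: np.ndarray
    voxel_size_mm: np.ndarray
    origin_world_mm: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        self.origin_world_mm = np.asarray(self.origin_world_mm, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be T x X x Y x Z")
        if self.voxel_size_mm.shape != (3,) or np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel sizes must be three positive numbers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def grid_shape(self) -> tuple:
        return self.values.shape[1:]

    def voxel_to_world(self, index) -> np.ndarray:
        return np.asarray(index, dtype=float) * self.voxel_size_mm + self.origin_world_mm


@dataclass
class ZMap:
    """Fisher-z seed-correlation map with its in-brain mask and geometry."""

    values: np.ndarray
    mask: np.ndarray
    voxel_size_mm: np.ndarray
    origin_world_mm: np.ndarray
    constant_voxels: np.ndarray | None = None


@dataclass
class ClusterRule:
    """Voxelwise threshold plus cluster-extent familywise correction."""

    voxel_p: float = 0.05
    fwhm_mm: float = 4.0
    alpha: float = 0.05
    min_cluster_voxels: int = 30
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not (0.0 < self.voxel_p < 1.0) or not (0.0 < self.alpha < 1.0):
            raise ValueError("voxel_p and alpha must lie in (0, 1)")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass(frozen=True)
class ClusterRecord:
    """One surviving cluster: where, how big, which direction."""

    peak_world_mm: tuple
    peak_t: float
    extent_voxels: int
    extent_mm3: float
    direction: str


def sphere_roi_mask(
    grid_shape, voxel_size_mm, origin_world_mm, center_world_mm, radius_mm
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within radius of the center.

    The seed-definition primitive: a voxel belongs to the ROI iff the
    Euclidean distance from its center to ``center_world_mm`` is at most
    ``radius_mm`` (inclusive boundary).
    """
    size = np.asarray(voxel_size_mm, dtype=float)
    origin = np.asarray(origin_world_mm, dtype=float)
    center = np.asarray(center_world_mm, dtype=float)
    lo = origin - size / 2.0
    hi = origin + (np.asarray(grid_shape) - 0.5) * size
    if np.any(center < lo) or np.any(center > hi):
        raise ValueError("sphere center lies outside the grid")
    coords = [np.arange(n) * s + o for n, s, o in zip(grid_shape, size, origin)]
    dx2 = [(c - cc) ** 2 for c, cc in zip(coords, center)]
    d2 = (
        dx2[0][:, None, None] + dx2[1][None, :, None] + dx2[2][None, None, :]
    )
    mask = d2 <= radius_mm**2 + 1e-9
    if not mask.any():
        raise ValueError("spherical ROI contains no voxels")
    return mask


def roi_mean_series(vol: VolumeSeries, mask: np.ndarray) -> np.ndarray:
    """Unweighted mean time course over the mask voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.grid_shape:
        raise ValueError("mask shape does not match the volume grid")
    if not mask.any():
        raise ValueError("empty ROI mask")
    return vol.values[:, mask].mean(axis=1)


def seed_correlation_map(
    vol: VolumeSeries, seed_series: np.ndarray, mask: np.ndarray | None = None
) -> ZMap:
    """Fisher-z map of the Pearson correlation of each voxel with the seed.

    Constant voxels (zero temporal variance) get z = 0 and are flagged
    in ``constant_voxels`` rather than raising.
    """
    seed = np.asarray(seed_series, dtype=float)
    T = vol.values.shape[0]
    if seed.shape != (T,):
        raise ValueError("seed series length must match the volume")
    if T < 3:
        raise ValueError("need at least 3 time points")
    if seed.std() == 0:
        raise ValueError("constant seed series")
    if mask is None:
        mask = np.ones(vol.grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    data = vol.values[:, mask]
    sd = seed - seed.mean()
    vd = data - data.mean(axis=0)
    denom = np.sqrt((sd @ sd) * np.einsum("ij,ij->j", vd, vd))
    constant = denom == 0
    denom[constant] = 1.0
    r = np.clip((sd @ vd) / denom, -1.0, 1.0)
    r[constant] = 0.0
    z = statcore.fisher_z(r)
    zmap = np.zeros(vol.grid_shape)
    zmap[mask] = z
    const_map = np.zeros(vol.grid_shape, dtype=bool)
    const_map[mask] = constant
    return ZMap(zmap, mask, vol.voxel_size_mm.copy(), vol.origin_world_mm.copy(), const_map)


def smooth_gaussian(volume: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Separable Gaussian smoothing specified in mm FWHM.

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis, converted to voxel units.
    Reflective (zero-flux) boundaries preserve total mass.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    vol = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return vol.copy()
    size = np.asarray(voxel_size_mm, dtype=float)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / size
    return ndimage.gaussian_filter(vol, sigma_vox, mode="reflect")


def label_clusters(binary_map: np.ndarray, connectivity: int = 26) -> list:
    """Connected components of a boolean 3-D map.

    Adjacency: 6 = faces, 18 = faces+edges, 26 = faces+edges+corners.
    Components are returned as index arrays ordered by size (largest
    first), ties broken by the lexicographically smallest voxel index.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(np.asarray(binary_map, dtype=bool), structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        clusters.append(idx)
    clusters.sort(key=lambda ix: (-len(ix), tuple(ix.min(axis=0))))
    return clusters


def alphasim_min_cluster(
    grid_shape,
    voxel_size_mm,
    mask: np.ndarray,
    voxel_p: float = 0.05,
    fwhm_mm: float = 4.0,
    alpha: float = 0.05,
    connectivity: int = 26,
    n_iterations: int = 1000,
    seed: int = 0,
) -> int:
    """Monte Carlo estimate of the familywise minimum cluster extent.

    Each iteration fills the mask's bounding grid with white Gaussian
    noise, smooths it to ``fwhm_mm``, standardizes within the mask,
    applies the two-tailed voxel threshold at ``voxel_p``, and records
    the largest suprathreshold cluster.  The returned extent k is the
    smallest integer for which the fraction of iterations whose maximum
    cluster reaches k is below ``alpha``: clusters of k or more voxels
    then have familywise false-positive probability < alpha.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(grid_shape):
        raise ValueError("mask shape must equal grid_shape")
    if not mask.any():
        raise ValueError("empty mask")
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    thr = special.ndtri(1.0 - voxel_p / 2.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    size = np.asarray(voxel_size_mm, dtype=float)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / size if fwhm_mm > 0 else None
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    max_extents = np.zeros(n_iterations, dtype=int)
    for it in range(n_iterations):
        noise = rng.standard_normal(tuple(grid_shape))
        if sigma_vox is not None:
            noise = ndimage.gaussian_filter(noise, sigma_vox, mode="reflect")
        vals = noise[mask]
        sd = vals.std()
        if sd == 0:
            continue
        z = (noise - vals.mean()) / sd
        supra = (np.abs(z) > thr) & mask
        if not supra.any():
            continue
        labels, n = ndimage.label(supra, structure=structure)
        if n:
            max_extents[it] = np.bincount(labels.ravel())[1:].max()
    # smallest k with P(max extent >= k) < alpha
    tail = np.sort(max_extents)[::-1]
    k = 1
    while True:
        frac = np.count_nonzero(max_extents >= k) / n_iterations
        if frac < alpha:
            return k
        k += 1


def _cluster_records(
    t_map: np.ndarray,
    supra: np.ndarray,
    direction: str,
    rule: ClusterRule,
    voxel_size_mm: np.ndarray,
    origin_world_mm: np.ndarray,
) -> list:
    voxel_volume = float(np.prod(voxel_size_mm))
    records = []
    for idx in label_clusters(supra, rule.connectivity):
        if len(idx) < rule.min_cluster_voxels:
            continue
        tvals = np.abs(t_map[tuple(idx.T)])
        best = np.flatnonzero(tvals == tvals.max())
        # ties: lexicographically smallest voxel index
        peak_idx = idx[best[np.lexsort(idx[best].T[::-1])[0]]]
        world = tuple(np.asarray(peak_idx) * voxel_size_mm + origin_world_mm)
        records.append(
            ClusterRecord(
                peak_world_mm=world,
                peak_t=float(t_map[tuple(peak_idx)]),
                extent_voxels=int(len(idx)),
                extent_mm3=float(len(idx) * voxel_volume),
                direction=direction,
            )
        )
    return records


def group_voxel_ttest(
    z_maps_a: list,
    z_maps_b: list | None = None,
    rule: ClusterRule | None = None,
):
    """Random-effects voxelwise t-test with cluster-extent thresholding.

    With one group: one-sample t against 0 per voxel.  With two groups:
    pooled two-sample t (positive t means group A > group B).  Voxels
    with p < ``rule.voxel_p`` (two-tailed) are kept, split by sign, and
    clusters smaller than ``rule.min_cluster_voxels`` are discarded.

    Returns ``(t_map, records)`` where records are sorted largest first
    within each direction (increases before decreases).
    """
    rule = rule or ClusterRule()
    if len(z_maps_a) < 2:
        raise ValueError("need at least 2 maps in group A")
    geom = z_maps_a[0]
    mask = geom.mask
    for m in z_maps_a + (z_maps_b or []):
        if m.values.shape != geom.values.shape or not np.array_equal(m.mask, mask):
            raise ValueError("all maps must share one grid and mask")
    stack_a = np.stack([m.values[mask] for m in z_maps_a])
    if z_maps_b is None:
        t, _, p = statcore.one_sample_t_array(stack_a)
    else:
        if len(z_maps_b) < 2:
            raise ValueError("need at least 2 maps in group B")
        stack_b = np.stack([m.values[mask] for m in z_maps_b])
        t, _, p = statcore.two_sample_t_array(stack_a, stack_b)
    t = np.nan_to_num(t)
    p = np.where(np.isfinite(p), p, 1.0)
    t_map = np.zeros(geom.values.shape)
    t_map[mask] = t
    supra = np.zeros(geom.values.shape, dtype=bool)
    supra[mask] = p < rule.voxel_p
    records = _cluster_records(
        t_map, supra & (t_map > 0), "increase", rule,
        geom.voxel_size_mm, geom.origin_world_mm,
    )
    records += _cluster_records(
        t_map, supra & (t_map < 0), "decrease", rule,
        geom.voxel_size_mm, geom.origin_world_mm,
    )
    return t_map, records
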