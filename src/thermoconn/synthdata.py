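"""Synthetic study generator with recorded ground truth.

Emulates the inputs of a two-group (heat-exposed HT vs normal-control
NC) resting-state study: band-limited regional BOLD driven by a group
covariance with planted edge differences on the Fisher-z scale, a
voxel-level fixture with a seed-coupled block for map recovery tests,
attention-network-test (ANT) trial tables, realignment-parameter
tables, and pre/post rectal-temperature and body-weight records.

Every generator is a pure function of its seed tuple: identical
arguments give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import MOTION_COLUMNS, RegionalSeries, bandpass_columns
from .statcore import fisher_z, inverse_fisher_z

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "AntSubjectParams",
    "default_altered_edges",
    "make_group_covariance",
    "simulate_regional_bold",
    "simulate_voxel_bold",
    "ant_condition_means",
    "simulate_ant_trials",
    "simulate_physiology",
    "simulate_motion",
    "simulate_study",
]

ANT_CUES = ("no", "center", "spatial")
ANT_TARGETS = ("congruent", "incongruent")

#: Printed group moments the physiology generator reproduces by default.
PHYSIO_DEFAULTS = {
    "HT": dict(temp_pre=(37.37, 0.36), temp_post=(37.87, 0.27),
               weight_pre=(65.0, 8.0), weight_loss=(0.51, 0.18)),
    "NC": dict(temp_pre=(37.35, 0.35), temp_post=(37.37, 0.34),
               weight_pre=(65.0, 8.0), weight_loss=(0.0, 0.10)),
}


@dataclass
class SimulationDesign:
    """Parameters of the synthetic resting-state study.

    Defaults follow the emulated acquisition: 200 volumes at TR = 2 s
    with the first 10 discarded downstream, 90 atlas regions, analyzed
    group sizes 15 (HT) and 17 (NC), signal band 0.01-0.08 Hz.
    ``altered_edges`` lists (i, j, delta_z) region pairs whose HT-group
    coupling is shifted by delta_z on the Fisher-z scale.
    """

    n_regions: int = 90
    n_volumes_acquired: int = 200
    n_discard: int = 10
    tr_seconds: float = 2.0
    n_ht: int = 15
    n_nc: int = 17
    base_correlation: float = 0.2
    altered_edges: tuple = ()
    band: tuple = (0.01, 0.08)
    noise_sd: float = 0.3
    drift_slope_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_correlation < 1.0):
            raise ValueError("base_correlation must lie in [0, 1)")
        seen = set()
        for i, j, _ in self.altered_edges:
            if i == j or not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                raise ValueError(f"invalid altered edge ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"altered edge ({i}, {j}) listed twice")
            seen.add(key)


@dataclass
class GroundTruth:
    """Everything a recovery test needs to score the pipeline's output."""

    group_by_subject: dict
    altered_edges: tuple
    rt_means_by_subject: dict = field(default_factory=dict)
    delta_t_by_subject: dict = field(default_factory=dict)
    weight_loss_by_subject: dict = field(default_factory=dict)

    @property
    def altered_edge_set(self) -> set:
        return {(min(i, j), max(i, j)) for i, j, _ in self.altered_edges}


def default_altered_edges(
    n_edges: int = 10,
    delta_z: float = 0.5,
    n_regions: int = 90,
    seed: int = 0,
    decrease_fraction: float = 0.7,
) -> tuple:
    """Draw a random planted-edge set, mostly decreases.

    Decreased coupling dominates (7:3 by default) to mirror the
    preponderance of connectivity losses under heat stress.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9001]))
    edges = []
    used = set()
    n_dec = int(round(n_edges * decrease_fraction))
    while len(edges) < n_edges:
        i, j = sorted(rng.choice(n_regions, size=2, replace=False).tolist())
        if (i, j) in used:
            continue
        used.add((i, j))
        sign = -1.0 if len(edges) < n_dec else 1.0
        edges.append((i, j, sign * delta_z))
    return tuple(edges)


def _nearest_psd_correlation(c: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues at 0 and renormalize to unit diagonal."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    if w.min() >= 0:
        return c
    w = np.clip(w, 0.0, None)
    rep = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(rep), 1e-12, None))
    rep = rep / np.outer(d, d)
    np.fill_diagonal(rep, 1.0)
    return rep


def make_group_covariance(design: SimulationDesign, group: str) -> np.ndarray:
    """Target correlation structure for one group.

    Off-diagonal entries equal tanh(z_base + delta_z) on edges planted
    for the HT group and tanh(z_base) elsewhere, then the matrix is
    repaired to the nearest positive semi-definite correlation matrix.
    """
    if group not in ("HT", "NC"):
        raise ValueError("group must be 'HT' or 'NC'")
    R = design.n_regions
    z_base = fisher_z(design.base_correlation) if design.base_correlation else 0.0
    c = np.full((R, R), float(inverse_fisher_z(z_base)))
    if group == "HT":
        for i, j, dz in design.altered_edges:
            r = inverse_fisher_z(z_base + dz)
            if abs(r) >= 1.0:
                raise ValueError(f"delta_z on edge ({i}, {j}) yields |r| >= 1")
            c[i, j] = c[j, i] = r
    np.fill_diagonal(c, 1.0)
    return _nearest_psd_correlation(c)


def _band_limited_noise(
    rng: np.random.Generator, T: int, n: int, tr: float, band: tuple
) -> np.ndarray:
    """Unit-variance columns with spectral support restricted to band."""
    w = rng.standard_normal((T, n))
    w = bandpass_columns(w, tr, band[0], band[1])
    sd = w.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return w / sd


def _matrix_sqrt(c: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(c)
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_regional_bold(
    design: SimulationDesign, group: str, subject_index: int
) -> RegionalSeries:
    """One subject's raw T x R regional series.

    Band-limited correlated Gaussian signal (mixed through the group
    covariance square root) plus a per-region linear drift and white
    noise.  The random stream is keyed by (seed, group, subject_index).
    """
    T = design.n_volumes_acquired
    low = design.band[0]
    if low > 0 and T * design.tr_seconds < 3.0 / low:
        import warnings

        warnings.warn(
            "series shorter than 3 cycles of the low band edge", stacklevel=2
        )
    group_code = {"HT": 1, "NC": 2}[group]
    rng = np.random.default_rng(
        np.random.SeedSequence([design.seed, group_code, subject_index])
    )
    cov = make_group_covariance(design, group)
    signal = _band_limited_noise(
        rng, T, design.n_regions, design.tr_seconds, design.band
    ) @ _matrix_sqrt(cov).T
    t = np.arange(T, dtype=float)[:, None]
    drift = t * rng.normal(0.0, design.drift_slope_sd, design.n_regions)[None, :]
    noise = rng.normal(0.0, design.noise_sd, (T, design.n_regions))
    return RegionalSeries(
        values=signal + drift + noise,
        tr_seconds=design.tr_seconds,
        region_ids=np.arange(1, design.n_regions + 1),
        subject_id=f"{group.lower()}{subject_index:02d}",
        group=group,
    )


DEFAULT_GRID_SHAPE = (26, 31, 26)
DEFAULT_VOXEL_SIZE = (3.0, 3.0, 3.0)
#: Places the grid over a posterior-medial MNI-like bounding box.
DEFAULT_ORIGIN = (-36.0, -90.0, -24.0)


def simulate_voxel_bold(
    grid_shape: tuple = DEFAULT_GRID_SHAPE,
    voxel_size_mm: tuple = DEFAULT_VOXEL_SIZE,
    roi_center_world: tuple = (-2.0, -54.0, 27.0),
    roi_radius_mm: float = 10.0,
    coupled_block: tuple = ((3, 4, 3), (6, 6, 6)),
    smooth_fwhm_mm: float = 4.0,
    T: int = 190,
    seed: int = 0,
    tr_seconds: float = 2.0,
    origin_world_mm: tuple = DEFAULT_ORIGIN,
    coupling: float = 1.0,
    block_coupling: float | None = None,
    noise_sd: float = 1.0,
    band: tuple = (0.01, 0.08),
):
    """Voxel-level fixture: a seed sphere and a coupled distant block.

    Voxels inside the seed sphere share one band-limited latent time
    course scaled by ``coupling`` plus independent noise; voxels inside
    ``coupled_block`` (a (corner_index, shape) pair) get the same latent
    scaled by ``block_coupling`` (defaults to ``coupling``); every other
    voxel is pure noise.  Each volume is then Gaussian-smoothed.  Group
    fixtures differ only in ``block_coupling``, so a between-group map
    contrast should isolate the block.  Returns a
    :class:`thermoconn.voxelmap.VolumeSeries`.
    """
    from scipy.ndimage import gaussian_filter

    from .voxelmap import FWHM_TO_SIGMA, VolumeSeries, sphere_roi_mask

    grid_shape = tuple(int(s) for s in grid_shape)
    corner, block_shape = (tuple(coupled_block[0]), tuple(coupled_block[1]))
    for c, s, g in zip(corner, block_shape, grid_shape):
        if c < 0 or c + s > g:
            raise ValueError("coupled block extends outside the grid")
    sphere = sphere_roi_mask(
        grid_shape, voxel_size_mm, origin_world_mm, roi_center_world, roi_radius_mm
    )
    block = np.zeros(grid_shape, dtype=bool)
    block[
        corner[0] : corner[0] + block_shape[0],
        corner[1] : corner[1] + block_shape[1],
        corner[2] : corner[2] + block_shape[2],
    ] = True

    if block_coupling is None:
        block_coupling = coupling
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    latent = _band_limited_noise(rng, T, 1, tr_seconds, band)[:, 0]
    field_flat = rng.normal(0.0, noise_sd, (T, int(np.prod(grid_shape))))
    field_flat[:, np.flatnonzero(sphere.ravel())] += coupling * latent[:, None]
    field_flat[:, np.flatnonzero((block & ~sphere).ravel())] += (
        block_coupling * latent[:, None]
    )
    vol = field_flat.reshape((T,) + grid_shape)
    if smooth_fwhm_mm > 0:
        sigma_vox = [
            smooth_fwhm_mm * FWHM_TO_SIGMA / s for s in voxel_size_mm
        ]
        for t in range(T):
            vol[t] = gaussian_filter(vol[t], sigma_vox, mode="reflect")
    return VolumeSeries(
        values=vol,
        voxel_size_mm=np.asarray(voxel_size_mm, dtype=float),
        origin_world_mm=np.asarray(origin_world_mm, dtype=float),
        tr_seconds=tr_seconds,
    )


@dataclass
class AntSubjectParams:
    """True condition-mean RTs (ms) for one simulated ANT subject."""

    mean_rt_ms: dict
    sigma_log: float = 0.15
    p_correct: float = 0.95

    def __post_init__(self) -> None:
        for cue in ANT_CUES:
            for tgt in ANT_TARGETS:
                m = self.mean_rt_ms.get((cue, tgt))
                if m is None or not (0.0 < m < 2000.0):
                    raise ValueError(
                        f"condition mean for ({cue}, {tgt}) must lie in (0, 2000) ms"
                    )


def ant_condition_means(
    base_congruent_ms: float = 520.0,
    alerting_ms: float = 50.0,
    orienting_ms: float = 50.0,
    executive_ms: float = 60.0,
) -> dict:
    """Build the six cue-by-target cell means from the three effects.

    Center-cue congruent RT is the base; no-cue adds the alerting cost,
    spatial-cue subtracts the orienting benefit, incongruent targets add
    the executive (conflict) cost.
    """
    cue_offset = {"no": alerting_ms, "center": 0.0, "spatial": -orienting_ms}
    tgt_offset = {"congruent": 0.0, "incongruent": executive_ms}
    return {
        (cue, tgt): base_congruent_ms + cue_offset[cue] + tgt_offset[tgt]
        for cue in ANT_CUES
        for tgt in ANT_TARGETS
    }


def simulate_ant_trials(subject_params: AntSubjectParams, seed: int = 0) -> pd.DataFrame:
    """216 ANT trials (6 runs of 36) for one subject.

    Each run balances the 3 cues x 2 targets design (6 trials per cell)
    in shuffled order.  RTs are log-normal around the condition mean and
    truncated at the 2000 ms response deadline; truncated trials carry
    ``responded = False``.
    """
    p = subject_params
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    rows = []
    cells = [(cue, tgt) for cue in ANT_CUES for tgt in ANT_TARGETS]
    for run in range(1, 7):
        trial_cells = cells * 6
        rng.shuffle(trial_cells)
        for trial, (cue, tgt) in enumerate(trial_cells, start=1):
            m = p.mean_rt_ms[(cue, tgt)]
            mu = np.log(m) - p.sigma_log**2 / 2.0
            rt = float(np.exp(rng.normal(mu, p.sigma_log)))
            responded = rt <= 2000.0
            if not responded:
                rt = 2000.0
            correct = bool(responded and rng.random() < p.p_correct)
            rows.append(
                dict(run=run, trial=trial, cue=cue, target=tgt,
                     rt_ms=round(rt, 3), responded=responded, correct=correct)
            )
    return pd.DataFrame(rows)


def simulate_physiology(
    group: str, n: int, params: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Pre/post rectal temperature (C) and body weight (kg) per subject.

    Defaults reproduce the study-condition group moments: HT ends near
    38 C having lost about half a kilogram; NC temperature and weight
    are stable.
    """
    if group not in PHYSIO_DEFAULTS:
        raise ValueError("group must be 'HT' or 'NC'")
    p = dict(PHYSIO_DEFAULTS[group])
    if params:
        p.update(params)
    for key, (_, sd) in p.items():
        if sd <= 0:
            raise ValueError(f"dispersion for {key} must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 55, 1 if group == "HT" else 2]))
    pre_t = rng.normal(*p["temp_pre"], n)
    post_t = rng.normal(*p["temp_post"], n)
    pre_w = rng.normal(*p["weight_pre"], n)
    loss = rng.normal(*p["weight_loss"], n)
    return pd.DataFrame(
        dict(
            subject_id=[f"{group.lower()}{i:02d}" for i in range(n)],
            group=group,
            rectal_pre_c=np.round(pre_t, 3),
            rectal_post_c=np.round(post_t, 3),
            weight_pre_kg=np.round(pre_w, 3),
            weight_post_kg=np.round(pre_w - loss, 3),
        )
    )


def simulate_motion(
    n_subjects: int,
    fraction_excluded: float = 0.0,
    seed: int = 0,
    n_volumes: int = 200,
    excluded_indices: tuple | None = None,
) -> list:
    """Realignment-parameter tables (3 translations mm, 3 rotations deg).

    Motion follows a small-amplitude random walk kept well under the
    exclusion thresholds; designated subjects get a > 1 mm translation
    excursion so they trip the quality-control rule.
    """
    if not (0.0 <= fraction_excluded <= 1.0):
        raise ValueError("fraction_excluded must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 63]))
    if excluded_indices is None:
        n_excl = int(round(fraction_excluded * n_subjects))
        excluded_indices = tuple(range(n_excl))
    tables = []
    for s in range(n_subjects):
        walk = np.cumsum(rng.normal(0.0, 0.015, (n_volumes, 6)), axis=0)
        walk = np.clip(walk, -0.6, 0.6)
        if s in excluded_indices:
            spike_at = int(rng.integers(n_volumes // 2, n_volumes))
            walk[spike_at:, 0] += 1.5
        tables.append(pd.DataFrame(walk, columns=list(MOTION_COLUMNS)))
    return tables


def simulate_study(design: SimulationDesign) -> dict:
    """All regional-series inputs for one synthetic study plus ground truth.

    Returns ``{"HT": [RegionalSeries...], "NC": [...], "truth": GroundTruth}``.
    Behavioral and physiological tables are generated separately by the
    runner so their effect sizes stay independently configurable.
    """
    out = {"HT": [], "NC": []}
    groups = {}
    for group, n in (("HT", design.n_ht), ("NC", design.n_nc)):
        for s in range(n):
            series = simulate_regional_bold(design, group, s)
            out[group].append(series)
            groups[series.subject_id] = group
    out["truth"] = GroundTruth(group_by_subject=groups, altered_edges=design.altered_edges)
    return out
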