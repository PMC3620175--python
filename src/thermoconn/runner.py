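"""Configuration-driven orchestration of the full analysis.

Stage order mirrors the study: simulate inputs, exclude high-motion
subjects, temporally clean each retained series (discard, detrend,
band-pass, confound regression), build per-subject connectivity
matrices, run the dual-criterion edge test, score per-subject
altered-edge counts, score the attention-network test, and correlate
the altered-edge burden with the executive-RT increase and the
physiological deltas.  An optional voxel stage runs the seed-map /
cluster-correction branch on a desk-scale grid.

One global seed expands into per-stage, per-subject substreams via
``numpy.random.SeedSequence`` so any execution order gives identical
results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, edgenet, io, preprocess, synthdata, voxelmap
from .preprocess import ConfoundSet, motion_flag
from .synthdata import AntSubjectParams, SimulationDesign, default_altered_edges


def _default_design() -> SimulationDesign:
    """The default study emulation: 15 vs 17 analyzed subjects with ten
    planted edges at |delta_z| = 0.5 (seven decreases, three increases)."""
    return SimulationDesign(altered_edges=default_altered_edges())

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger(__name__)

_VERSION = "0.1.0"


def _from_dict(cls, data: dict, context: str):
    """Strict dataclass construction: unknown keys are errors."""
    names = {f.name for f in dataclasses.fields(cls)}
    extra = set(data) - names
    if extra:
        raise ValueError(f"unknown {context} keys: {sorted(extra)}")
    return cls(**data)


@dataclass
class ExclusionConfig:
    """Enrollment bookkeeping: 18 + 18 enrolled, exclusions bring the
    analyzed groups to the design's n_ht / n_nc."""

    n_terminated_ht: int = 2
    n_motion_excluded_ht: int = 1
    n_motion_excluded_nc: int = 1


@dataclass
class AntConfig:
    base_congruent_ms: float = 520.0
    alerting_ms: float = 50.0
    orienting_ms: float = 50.0
    executive_nc_ms: float = 60.0
    executive_shift_ms: float = 40.0
    between_subject_sd_ms: float = 30.0
    #: Couples each HT subject's executive cost to their standardized
    #: altered-edge count, emulating the observed brain-behavior link.
    executive_nalt_slope_ms: float = 22.5


@dataclass
class EdgeConfig:
    q_level: float = 0.05
    criterion1_scope: str = "either"
    deviation_multiple: float = 1.96


@dataclass
class SeedMapConfig:
    enabled: bool = True
    n_per_group: int = 6
    n_volumes: int = 100
    alphasim_iterations: int = 300
    voxel_p: float = 0.05
    fwhm_mm: float = 4.0
    alpha: float = 0.05
    connectivity: int = 26


@dataclass
class PipelineConfig:
    out_dir: str = "thermoconn_run"
    seed: int = 0
    design: SimulationDesign = field(default_factory=_default_design)
    exclusions: ExclusionConfig = field(default_factory=ExclusionConfig)
    ant: AntConfig = field(default_factory=AntConfig)
    edges: EdgeConfig = field(default_factory=EdgeConfig)
    seedmap: SeedMapConfig = field(default_factory=SeedMapConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sub = {
            "design": SimulationDesign,
            "exclusions": ExclusionConfig,
            "ant": AntConfig,
            "edges": EdgeConfig,
            "seedmap": SeedMapConfig,
        }
        kwargs = {}
        for key, klass in sub.items():
            if key in data:
                kwargs[key] = _from_dict(klass, data.pop(key) or {}, key)
        top = {f.name for f in dataclasses.fields(cls)} - set(sub)
        extra = set(data) - top
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    config: dict
    version: str
    exclusions: list
    n_findings: int
    n_increase: int
    n_decrease: int
    findings: list
    n_alt: dict
    effect_tests: dict
    correlations: dict
    seedmap_clusters: list
    digests: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sub_seed(base: int, *stream) -> np.random.SeedSequence:
    return np.random.SeedSequence([base, *stream])


def _seed_int(base: int, *stream) -> int:
    """Stable 31-bit integer substream key derived from the global seed."""
    return int(_sub_seed(base, *stream).generate_state(1)[0] % (2**31))


def _simulate_and_qc(config: PipelineConfig):
    """Simulate enrolled subjects, apply motion QC, return retained series."""
    design = config.design
    exc = config.exclusions
    retained = {"HT": [], "NC": []}
    exclusions = []
    for group, n_analyzed in (("HT", design.n_ht), ("NC", design.n_nc)):
        n_motion = exc.n_motion_excluded_ht if group == "HT" else exc.n_motion_excluded_nc
        n_term = exc.n_terminated_ht if group == "HT" else 0
        n_scanned = n_analyzed + n_motion
        # terminated scans never reach the motion stage
        for k in range(n_term):
            exclusions.append(
                dict(subject_id=f"{group.lower()}x{k:02d}", group=group,
                     reason="scan terminated (thermal discomfort)", parameter=None)
            )
        motion_tables = synthdata.simulate_motion(
            n_scanned,
            seed=_seed_int(config.seed, 3, 1 if group == "HT" else 2),
            n_volumes=design.n_volumes_acquired,
            excluded_indices=tuple(range(n_analyzed, n_scanned)),
        )
        for s in range(n_scanned):
            series = synthdata.simulate_regional_bold(design, group, s)
            summary = motion_flag(motion_tables[s])
            if summary.excluded:
                exclusions.append(
                    dict(
                        subject_id=series.subject_id,
                        group=group,
                        reason="head motion",
                        parameter=dict(
                            max_abs_translation_mm=summary.max_abs_translation_mm,
                            max_abs_rotation_deg=summary.max_abs_rotation_deg,
                        ),
                    )
                )
                continue
            retained[group].append((series, motion_tables[s]))
    return retained, exclusions


def _clean(config: PipelineConfig, series, motion_table) -> preprocess.RegionalSeries:
    design = config.design
    out = preprocess.discard_initial(series, design.n_discard)
    out = preprocess.detrend_linear(out)
    out = preprocess.bandpass_ideal(out, *design.band)
    motion = motion_table.to_numpy(dtype=float)[design.n_discard :]
    global_mean = out.values.mean(axis=1, keepdims=True)
    confounds = ConfoundSet(
        np.column_stack([np.ones(out.n_volumes), motion, global_mean]),
        names=("intercept", *preprocess.MOTION_COLUMNS, "global"),
    )
    return preprocess.regress_confounds(out, confounds)


def _ant_stage(config: PipelineConfig, n_alt: dict, groups: dict):
    """Per-subject ANT tables and effects; HT executive cost optionally
    tracks the subject's altered-edge count."""
    ant = config.ant
    nalt_vals = np.array([n_alt[s] for s in sorted(n_alt)], dtype=float)
    nalt_sd = nalt_vals.std() if nalt_vals.size and nalt_vals.std() > 0 else 1.0
    nalt_mean = nalt_vals.mean() if nalt_vals.size else 0.0
    effects = {"HT": [], "NC": []}
    per_subject = {}
    for sid, group in sorted(groups.items()):
        rng = np.random.default_rng(
            _sub_seed(config.seed, 4, zlib.crc32(sid.encode()))
        )
        exec_mean = ant.executive_nc_ms
        if group == "HT":
            exec_mean += ant.executive_shift_ms
            if sid in n_alt:
                exec_mean += ant.executive_nalt_slope_ms * (n_alt[sid] - nalt_mean) / nalt_sd
        params = AntSubjectParams(
            synthdata.ant_condition_means(
                base_congruent_ms=ant.base_congruent_ms
                + rng.normal(0.0, ant.between_subject_sd_ms),
                alerting_ms=ant.alerting_ms + rng.normal(0.0, ant.between_subject_sd_ms / 2),
                orienting_ms=ant.orienting_ms + rng.normal(0.0, ant.between_subject_sd_ms / 2),
                executive_ms=exec_mean + rng.normal(0.0, ant.between_subject_sd_ms),
            )
        )
        trials = synthdata.simulate_ant_trials(
            params, seed=int(rng.integers(2**31))
        )
        eff = behavior.ant_effects(behavior.condition_rt_summary(trials))
        effects[group].append(eff)
        per_subject[sid] = eff
    return effects, per_subject


def _seedmap_stage(config: PipelineConfig):
    sm = config.seedmap
    block = ((3, 4, 3), (6, 6, 6))
    maps = {"HT": [], "NC": []}
    for group, block_c in (("HT", 1.0), ("NC", 0.0)):
        for s in range(sm.n_per_group):
            vol = synthdata.simulate_voxel_bold(
                coupled_block=block,
                smooth_fwhm_mm=sm.fwhm_mm,
                T=sm.n_volumes,
                seed=_seed_int(config.seed, 5, 1 if group == "HT" else 2, s),
                coupling=1.0,
                block_coupling=block_c,
            )
            sphere = voxelmap.sphere_roi_mask(
                vol.grid_shape, vol.voxel_size_mm, vol.origin_world_mm,
                (-2.0, -54.0, 27.0), 10.0,
            )
            seed_series = voxelmap.roi_mean_series(vol, sphere)
            maps[group].append(voxelmap.seed_correlation_map(vol, seed_series))
    k_min = voxelmap.alphasim_min_cluster(
        maps["HT"][0].values.shape,
        maps["HT"][0].voxel_size_mm,
        maps["HT"][0].mask,
        voxel_p=sm.voxel_p,
        fwhm_mm=sm.fwhm_mm,
        alpha=sm.alpha,
        connectivity=sm.connectivity,
        n_iterations=sm.alphasim_iterations,
        seed=_seed_int(config.seed, 6),
    )
    rule = voxelmap.ClusterRule(
        voxel_p=sm.voxel_p, fwhm_mm=sm.fwhm_mm, alpha=sm.alpha,
        min_cluster_voxels=k_min, connectivity=sm.connectivity,
    )
    _, records = voxelmap.group_voxel_ttest(maps["HT"], maps["NC"], rule)
    return [dataclasses.asdict(r) for r in records]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write the artifacts under ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("stage: simulate + motion QC")
    retained, exclusions = _simulate_and_qc(config)

    logger.info("stage: temporal cleaning + connectivity")
    z_mats = {"HT": [], "NC": []}
    groups = {}
    for group in ("HT", "NC"):
        for series, motion in retained[group]:
            cleaned = _clean(config, series, motion)
            z_mats[group].append(edgenet.connectivity_matrix(cleaned))
            groups[series.subject_id] = group

    logger.info("stage: dual-criterion edge test")
    findings = edgenet.dual_criterion_edges(
        z_mats["HT"], z_mats["NC"],
        q_level=config.edges.q_level,
        criterion1_scope=config.edges.criterion1_scope,
    )
    n_inc = sum(1 for f in findings if f.direction == "increase")
    n_dec = sum(1 for f in findings if f.direction == "decrease")

    n_alt = {}
    if findings:
        nc_mean, nc_sd = edgenet.nc_reference(z_mats["NC"])
        for m in z_mats["HT"]:
            n_alt[m.subject_id] = edgenet.per_subject_altered_count(
                m, findings, nc_mean, nc_sd, config.edges.deviation_multiple
            ).n_alt

    logger.info("stage: behavior + physiology")
    effects, per_subject_eff = _ant_stage(config, n_alt, groups)
    effect_tests = behavior.compare_group_effects(effects["HT"], effects["NC"])
    physio = pd.concat(
        [
            synthdata.simulate_physiology(
                g, len(z_mats[g]), seed=_seed_int(config.seed, 7)
            ).assign(subject_id=[m.subject_id for m in z_mats[g]])
            for g in ("HT", "NC")
        ],
        ignore_index=True,
    )
    deltas = behavior.physiology_delta_table(physio).set_index("subject_id")

    correlations = {}
    if n_alt:
        ht_ids = sorted(n_alt)
        nc_exec_mean = float(np.mean([e.executive_ms for e in effects["NC"]]))
        outcomes = pd.DataFrame(
            dict(
                delta_exec_ms=[per_subject_eff[s].executive_ms - nc_exec_mean for s in ht_ids],
                delta_t_c=[deltas.loc[s, "delta_t_c"] for s in ht_ids],
                weight_loss_kg=[deltas.loc[s, "weight_loss_kg"] for s in ht_ids],
            ),
            index=ht_ids,
        )
        nalt_series = pd.Series({s: n_alt[s] for s in ht_ids})
        try:
            correlations = {
                k: dict(r=v.statistic, df=v.df, p=v.p_two_tailed)
                for k, v in behavior.associate_network_outcomes(nalt_series, outcomes).items()
            }
        except ValueError as exc:  # e.g. constant n_alt under a null design
            logger.warning("correlation stage skipped: %s", exc)

    seedmap_clusters = []
    if config.seedmap.enabled:
        logger.info("stage: seed map + cluster correction")
        seedmap_clusters = _seedmap_stage(config)

    logger.info("stage: report")
    io.write_findings(findings, out_dir / "findings.tsv")
    pd.DataFrame(
        dict(subject_id=sorted(n_alt), n_alt=[n_alt[s] for s in sorted(n_alt)])
    ).to_csv(out_dir / "nalt.tsv", sep="\t", index=False)
    physio.to_csv(out_dir / "physiology.tsv", sep="\t", index=False)
    digests = {
        p.name: io.sha256_of(p)
        for p in sorted(out_dir.glob("*.tsv"))
    }
    report = RunReport(
        config=config.to_dict(),
        version=_VERSION,
        exclusions=exclusions,
        n_findings=len(findings),
        n_increase=n_inc,
        n_decrease=n_dec,
        findings=[dataclasses.asdict(f) for f in findings],
        n_alt=n_alt,
        effect_tests={
            k: dict(t=v.statistic, df=v.df, p=v.p_two_tailed)
            for k, v in effect_tests.items()
        },
        correlations=correlations,
        seedmap_clusters=seedmap_clusters,
        digests=digests,
    )
    (out_dir / "report.json").write_text(report.to_json())
    return report
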