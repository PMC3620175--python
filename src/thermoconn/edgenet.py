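"""Whole-brain parcellation connectivity and the dual-criterion edge test.

A 90-region atlas yields 90*89/2 = 4005 region pairs ("edges").  Each
subject contributes a symmetric Fisher-z connectivity matrix; group
inference declares an edge altered only when (1) its z values are
significantly nonzero within a group (one-sample t, BH-FDR across the
4005 edges) and (2) they differ between the groups (two-sample t,
BH-FDR across the same family).  The per-subject altered-edge count
N_alt then scores how far an individual deviates from the control
reference on the significant edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import statcore
from .preprocess import RegionalSeries
from .voxelmap import VolumeSeries

__all__ = [
    "ZEdgeMatrix",
    "EdgeFinding",
    "AlteredEdgeCount",
    "parcellate_means",
    "connectivity_matrix",
    "dual_criterion_edges",
    "nc_reference",
    "per_subject_altered_count",
]

logger = logging.getLogger(__name__)


@dataclass
class ZEdgeMatrix:
    """R x R symmetric Fisher-z connectivity matrix for one subject."""

    z: np.ndarray
    region_ids: np.ndarray
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        R = self.z.shape[0]
        if self.z.shape != (R, R) or R != self.region_ids.size:
            raise ValueError("z must be R x R matching region_ids")
        if not np.allclose(self.z, self.z.T, equal_nan=True):
            raise ValueError("z matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]

    def edge_vector(self) -> np.ndarray:
        """Upper-triangle (i < j) edge values in lexicographic order."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.z[iu]


@dataclass(frozen=True)
class EdgeFinding:
    """One significantly altered region pair (HT relative to NC)."""

    region_i: int
    region_j: int
    direction: str
    t_between: float
    p_between: float
    q_between: float
    within_group_significant: dict

    def __post_init__(self) -> None:
        if self.region_i >= self.region_j:
            raise ValueError("require region_i < region_j")
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")


@dataclass(frozen=True)
class AlteredEdgeCount:
    subject_id: str
    n_alt: int


def parcellate_means(vol: VolumeSeries, label_volume: np.ndarray) -> RegionalSeries:
    """Region-mean time series from an integer-labeled atlas volume.

    One column per positive label present, averaging all voxels carrying
    that label; columns are ordered by ascending label.
    """
    labels = np.asarray(label_volume)
    if labels.shape != vol.grid_shape:
        raise ValueError("label volume must match the data grid")
    present = np.unique(labels)
    present = present[present > 0]
    if present.size == 0:
        raise ValueError("label volume contains no positive labels")
    cols = []
    for lab in present:
        m = labels == lab
        if not m.any():
            raise ValueError(f"label {lab} covers zero voxels")
        cols.append(vol.values[:, m].mean(axis=1))
    return RegionalSeries(
        values=np.column_stack(cols),
        tr_seconds=vol.tr_seconds,
        region_ids=present.astype(int),
    )


def connectivity_matrix(series: RegionalSeries) -> ZEdgeMatrix:
    """Pairwise Pearson correlation of region series, Fisher-transformed.

    The diagonal is set to 0 and excluded from all downstream
    statistics.  Perfectly correlated pairs are clipped to the maximum
    finite z rather than producing infinities.
    """
    v = series.values
    if v.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    sd = v.std(axis=0)
    if np.any(sd == 0):
        bad = series.region_ids[sd == 0].tolist()
        raise ValueError(f"constant series for regions {bad}")
    r = np.corrcoef(v, rowvar=False)
    z = statcore.fisher_z(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ZEdgeMatrix(z, series.region_ids, series.subject_id, series.group)


def _stack_edges(mats: list) -> tuple:
    R = mats[0].n_regions
    ids = mats[0].region_ids
    for m in mats:
        if m.n_regions != R or not np.array_equal(m.region_ids, ids):
            raise ValueError("all matrices must share regions")
    return np.stack([m.edge_vector() for m in mats]), np.triu_indices(R, k=1)


def dual_criterion_edges(
    z_matrices_ht: list,
    z_matrices_nc: list,
    q_level: float = 0.05,
    criterion1_scope: str = "either",
) -> list:
    """Edges altered by the HT condition under the dual significance rule.

    Criterion (1): the edge is significantly nonzero within a group
    (one-sample two-tailed t, BH-FDR over the edge family of that
    group).  ``criterion1_scope`` decides whether one group suffices
    ("either", the default — a coupling destroyed in HT is still real
    in NC) or both must pass ("both").  Criterion (2): the edge differs
    between groups (two-sample two-tailed t, BH-FDR over its own
    family).  Findings are edges passing (1) AND (2), with direction
    from the sign of mean(HT) - mean(NC), sorted by between-group q.

    Edges with non-finite values or zero variance in either group are
    excluded from every family (a warning logs the count).
    """
    if len(z_matrices_ht) < 2 or len(z_matrices_nc) < 2:
        raise ValueError("need at least 2 subjects per group")
    if criterion1_scope not in ("either", "both"):
        raise ValueError("criterion1_scope must be 'either' or 'both'")
    ht, (iu, ju) = _stack_edges(z_matrices_ht)
    nc, _ = _stack_edges(z_matrices_nc)
    if ht.shape[1] != nc.shape[1]:
        raise ValueError("groups have inconsistent region counts")

    finite = np.all(np.isfinite(ht), axis=0) & np.all(np.isfinite(nc), axis=0)
    nonzero_var = (ht.std(axis=0) > 0) & (nc.std(axis=0) > 0)
    valid = finite & nonzero_var
    n_dropped = int(np.count_nonzero(~valid))
    if n_dropped:
        logger.warning("dropping %d degenerate edges from the families", n_dropped)

    _, _, p1_ht = statcore.one_sample_t_array(ht[:, valid])
    _, _, p1_nc = statcore.one_sample_t_array(nc[:, valid])
    t2, _, p2 = statcore.two_sample_t_array(ht[:, valid], nc[:, valid])

    sig1_ht = statcore.bh_fdr(p1_ht, q_level).rejected
    sig1_nc = statcore.bh_fdr(p1_nc, q_level).rejected
    fdr2 = statcore.bh_fdr(p2, q_level)
    if criterion1_scope == "either":
        crit1 = sig1_ht | sig1_nc
    else:
        crit1 = sig1_ht & sig1_nc
    hits = crit1 & fdr2.rejected

    ids = z_matrices_ht[0].region_ids
    valid_idx = np.flatnonzero(valid)
    findings = []
    for k in np.flatnonzero(hits):
        e = valid_idx[k]
        i, j = int(iu[e]), int(ju[e])
        findings.append(
            EdgeFinding(
                region_i=int(ids[i]),
                region_j=int(ids[j]),
                direction="increase" if t2[k] > 0 else "decrease",
                t_between=float(t2[k]),
                p_between=float(p2[k]),
                q_between=float(fdr2.adjusted_p[k]),
                within_group_significant={"HT": bool(sig1_ht[k]), "NC": bool(sig1_nc[k])},
            )
        )
    findings.sort(key=lambda f: (f.q_between, f.region_i, f.region_j))
    return findings


def nc_reference(z_matrices_nc: list) -> tuple:
    """Per-edge control-group mean and SD matrices (R x R)."""
    if len(z_matrices_nc) < 2:
        raise ValueError("need at least 2 control subjects")
    stack = np.stack([m.z for m in z_matrices_nc])
    return stack.mean(axis=0), stack.std(axis=0, ddof=1)


def per_subject_altered_count(
    subject_matrix: ZEdgeMatrix,
    findings: list,
    nc_mean: np.ndarray,
    nc_sd: np.ndarray,
    deviation_multiple: float = 1.96,
) -> AlteredEdgeCount:
    """Count finding edges on which the subject deviates from controls.

    An edge counts when the subject's z lies beyond
    ``deviation_multiple`` control SDs from the control mean *in the
    finding's direction* (above for increases, below for decreases).
    This is an explicit surrogate definition of the per-subject
    altered-edge burden; see the methods note.
    """
    if not findings:
        raise ValueError("findings list is empty")
    ids = subject_matrix.region_ids
    pos = {rid: k for k, rid in enumerate(ids)}
    n_alt = 0
    for f in findings:
        if f.region_i not in pos or f.region_j not in pos:
            raise ValueError(f"edge ({f.region_i}, {f.region_j}) missing from subject matrix")
        i, j = pos[f.region_i], pos[f.region_j]
        sd = nc_sd[i, j]
        if sd <= 0:
            raise ValueError(f"non-positive control SD on edge ({f.region_i}, {f.region_j})")
        dev = subject_matrix.z[i, j] - nc_mean[i, j]
        if f.direction == "increase" and dev > deviation_multiple * sd:
            n_alt += 1
        elif f.direction == "decrease" and dev < -deviation_multiple * sd:
            n_alt += 1
    return AlteredEdgeCount(subject_matrix.subject_id, n_alt)
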