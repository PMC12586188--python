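"""Seed-based discovery maps, bootstrap consistency masks and seed matrices.

The discovery procedure: extract each seed ROI's mean time course, correlate
it with every voxel, Fisher-transform the correlations, and test the
transformed values across subjects with a two-tailed one-sample t test.
Reliability is assessed by subject subsampling: in each of B iterations a
fraction f of the subjects is drawn without replacement (one shared draw per
iteration across all seeds), the subsample's group map is binarized at
positive connectivity with p < alpha, and the binary maps are summed into a
per-voxel survival count. Voxels surviving more than a cutoff (95% of B by
default) form the consistency mask applied to the full-sample t map.

Study-scale constants: B = 1000 iterations, f = 0.8 (90 subjects -> 72 per
subsample), alpha = 0.05, cutoff "more than 950 of 1000".
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from interomap.cohort import RoiSet, SubjectTimeSeries, VoxelGrid

#: default clipping bound before the Fisher transform
R_CLIP_EPS = 1e-7

VoxelCorrelation = namedtuple("VoxelCorrelation", ["r", "constant_voxels"])
GroupTest = namedtuple("GroupTest", ["t", "p", "degenerate"])


@dataclass
class StatMap:
    """Group-level voxel-wise statistics for one seed."""

    grid: VoxelGrid
    r_mean: np.ndarray
    z_mean: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n_subjects: int

    @property
    def df(self) -> int:
        return self.n_subjects - 1


@dataclass
class ConsistencyMap:
    """Per-voxel bootstrap survival counts (0..B)."""

    grid: VoxelGrid
    counts: np.ndarray
    B: int
    fraction: float
    alpha: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.B < 1 or not (0 < self.fraction <= 1):
            raise ValueError("need B >= 1 and 0 < fraction <= 1")
        if self.counts.min() < 0 or self.counts.max() > self.B:
            raise ValueError("counts must lie in [0, B]")


@dataclass
class BinaryMask:
    """A boolean voxel mask on a grid."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool).reshape(-1)
        if self.data.size != self.grid.n_voxels:
            raise ValueError("mask size does not match grid")

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.data)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class ConnectivityMatrix:
    """Seed-to-seed Fisher-z stack with group inference.

    ``z`` is subjects x seeds x seeds with NaN sentinels on the diagonal
    (per-subject r = 1 there, excluded from inference); ``t``/``p`` are the
    group one-sample test per off-diagonal pair; ``significant`` marks cells
    with p < alpha (two-tailed, uncorrected) — subthreshold cells are the
    complement, rendered gray in the study's matrices.
    """

    labels: list[str]
    z: np.ndarray
    t: np.ndarray
    p: np.ndarray
    alpha: float
    significant: np.ndarray = field(init=False)

    def __post_init__(self):
        self.significant = np.zeros_like(self.t, dtype=bool)
        off = ~np.eye(len(self.labels), dtype=bool)
        self.significant[off] = self.p[off] < self.alpha

    @property
    def n_subjects(self) -> int:
        return self.z.shape[0]

    def pair(self, a: str, b: str) -> tuple[float, float]:
        """(t, p) for an unordered seed pair."""
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.t[i, j]), float(self.p[i, j])

    def significant_positive(self, a: str, b: str) -> bool:
        i, j = self.labels.index(a), self.labels.index(b)
        return bool(self.significant[i, j] and self.t[i, j] > 0)


def subsample_size(n_subjects: int, fraction: float) -> int:
    """floor(f * n): e.g. 90 subjects at f = 0.8 -> 72 per subsample."""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return int(math.floor(fraction * n_subjects))


def consistency_cutoff(B: int, criterion: float = 0.95) -> int:
    """Survival-count cutoff: voxels must pass in MORE than this many of the
    B iterations (B = 1000 at the 95% criterion -> 950)."""
    return int(math.floor(B * criterion + 1e-9))


def extract_seed_timecourse(ts: SubjectTimeSeries, roi_voxels: np.ndarray) -> np.ndarray:
    """Per-frame arithmetic mean over the ROI's voxels."""
    roi_voxels = np.asarray(roi_voxels, dtype=np.intp)
    if roi_voxels.size == 0:
        raise ValueError("empty ROI")
    if roi_voxels.min() < 0 or roi_voxels.max() >= ts.n_voxels:
        raise ValueError("ROI voxels outside the data grid")
    return ts.data[roi_voxels].mean(axis=0)


def voxelwise_r(data: np.ndarray, seed_series: np.ndarray) -> VoxelCorrelation:
    """Pearson correlation of every voxel's series with the seed series.

    Constant voxels get r = 0 and are flagged; a constant seed series is an
    error. ``data`` is voxels x frames.
    """
    data = np.asarray(data, dtype=float)
    seed = np.asarray(seed_series, dtype=float)
    if data.shape[1] != seed.size:
        raise ValueError("frame count mismatch between data and seed series")
    if seed.size < 3:
        raise ValueError("need >= 3 frames for correlation")
    seed_c = seed - seed.mean()
    seed_ss = float(seed_c @ seed_c)
    if seed_ss <= 0:
        raise ValueError("constant seed series")
    dc = data - data.mean(axis=1, keepdims=True)
    vox_ss = np.einsum("ij,ij->i", dc, dc)
    constant = vox_ss <= 0
    denom = np.sqrt(np.where(constant, 1.0, vox_ss) * seed_ss)
    r = (dc @ seed_c) / denom
    r[constant] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return VoxelCorrelation(r=r, constant_voxels=constant)


def clip_r(r: np.ndarray | float, eps: float = R_CLIP_EPS) -> np.ndarray | float:
    """Clip correlations into (-1, 1) before the Fisher transform."""
    return np.clip(r, -1.0 + eps, 1.0 - eps)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z variance-stabilizing transform, z = atanh(r)."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) >= 1):
        raise ValueError("|r| >= 1: clip with clip_r before transforming")
    out = np.arctanh(r_arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def group_t(z_values: np.ndarray) -> GroupTest:
    """Two-tailed one-sample t test across subjects (axis 0).

    Returns per-cell t, p and a degeneracy flag. Cells with zero
    between-subject variance get p = 1 when the mean is also zero, else
    p = 0 with t = +/-inf (flagged degenerate).
    """
    z = np.asarray(z_values, dtype=float)
    n = z.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    zero_sd = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
        t = np.where(zero_sd & (mean == 0), 0.0, t)
        t = np.where(zero_sd & (mean != 0), np.sign(mean) * np.inf, t)
    p = np.where(
        np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0.0, t)), df=n - 1)
    )
    degenerate = zero_sd & (mean != 0)
    if z.ndim == 1:
        return GroupTest(float(t), float(p), bool(degenerate))
    return GroupTest(t, p, degenerate)


def binarize_positive(stat_map: StatMap, alpha: float = 0.05) -> BinaryMask:
    """Voxels with significant positive connectivity: p < alpha and t > 0."""
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return BinaryMask(grid=stat_map.grid, data=(stat_map.p < alpha) & (stat_map.t > 0))


def seed_zmaps(
    cohort: list[SubjectTimeSeries],
    rois: RoiSet,
    labels: list[str] | None = None,
) -> np.ndarray:
    """Per-subject voxel-wise Fisher-z maps for each seed.

    Returns an array of shape (subjects, seeds, voxels); the workhorse input
    to group maps, bootstrap consistency and clustering.
    """
    labels = list(labels or rois.labels)
    n_sub = len(cohort)
    V = cohort[0].n_voxels
    z = np.empty((n_sub, len(labels), V))
    for si, ts in enumerate(cohort):
        dc = ts.data - ts.data.mean(axis=1, keepdims=True)
        vox_ss = np.einsum("ij,ij->i", dc, dc)
        const_vox = vox_ss <= 0
        vox_norm = np.sqrt(np.where(const_vox, 1.0, vox_ss))
        for li, label in enumerate(labels):
            seed = dc[rois.members[label]].mean(axis=0)
            seed_ss = float(seed @ seed)
            if seed_ss <= 0:
                raise ValueError(f"constant seed series for {ts.subject_id}, seed {label!r}")
            r = (dc @ seed) / (vox_norm * math.sqrt(seed_ss))
            r[const_vox] = 0.0
            np.clip(r, -1.0, 1.0, out=r)
            z[si, li] = np.arctanh(clip_r(r))
    return z


def group_map(z_maps: np.ndarray, grid: VoxelGrid) -> StatMap:
    """Full-sample group statistics from one seed's (subjects, voxels) z stack."""
    t, p, _ = group_t(z_maps)
    z_mean = z_maps.mean(axis=0)
    return StatMap(
        grid=grid, r_mean=np.tanh(z_mean), z_mean=z_mean, t=t, p=p,
        n_subjects=z_maps.shape[0],
    )


def bootstrap_consistency(
    z_maps: np.ndarray,
    B: int = 1000,
    fraction: float = 0.8,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> np.ndarray:
    """Survival counts over B subject-subsampling iterations.

    ``z_maps`` is (subjects, seeds, voxels) — or (subjects, voxels) for a
    single seed. Each iteration draws floor(fraction * n) subjects without
    replacement (one draw shared by every seed), computes the subsample's
    group test, and adds the positive p < alpha voxels to the counts.
    Returns integer counts of shape (seeds, voxels) (or (voxels,) for a
    single-seed input).
    """
    z = np.asarray(z_maps, dtype=float)
    single = z.ndim == 2
    if single:
        z = z[:, None, :]
    n = z.shape[0]
    if B < 1:
        raise ValueError("B must be >= 1")
    m = subsample_size(n, fraction)
    if m < 3:
        raise ValueError(f"subsample size {m} < 3 (n={n}, fraction={fraction})")
    rng = np.random.default_rng(rng_seed)
    counts = np.zeros(z.shape[1:], dtype=int)
    for _ in range(B):
        idx = rng.choice(n, size=m, replace=False)
        t, p, _ = group_t(z[idx])
        counts += (p < alpha) & (t > 0)
    return counts[0] if single else counts


def consistency_mask(cmap: ConsistencyMap, min_count: int | None = None) -> BinaryMask:
    """Voxels surviving strictly more than ``min_count`` iterations.

    ``min_count`` defaults to the 95% criterion: floor(0.95 * B).
    """
    if min_count is None:
        min_count = consistency_cutoff(cmap.B)
    if not (0 <= min_count <= cmap.B):
        raise ValueError(f"min_count must be in [0, B], got {min_count}")
    return BinaryMask(grid=cmap.grid, data=cmap.counts > min_count)


def masked_group_map(stat_map: StatMap, mask: BinaryMask) -> StatMap:
    """Full-sample t map with values outside the consistency mask nulled."""
    if mask.grid != stat_map.grid:
        raise ValueError("mask grid does not match map grid")
    keep = mask.data
    return StatMap(
        grid=stat_map.grid,
        r_mean=np.where(keep, stat_map.r_mean, 0.0),
        z_mean=np.where(keep, stat_map.z_mean, 0.0),
        t=np.where(keep, stat_map.t, 0.0),
        p=np.where(keep, stat_map.p, 1.0),
        n_subjects=stat_map.n_subjects,
    )


def seed_timecourses(cohort: list[SubjectTimeSeries], rois: RoiSet,
                     labels: list[str] | None = None) -> np.ndarray:
    """(subjects, seeds, frames) stack of ROI mean time courses."""
    labels = list(labels or rois.labels)
    return np.stack(
        [[extract_seed_timecourse(ts, rois.members[l]) for l in labels] for ts in cohort]
    )


def seed_matrix(
    cohort: list[SubjectTimeSeries],
    rois: RoiSet,
    alpha: float = 0.05,
    labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Seed-to-seed connectivity: per-subject Pearson r between all ROI pairs,
    Fisher transform, and a group two-tailed one-sample t test per pair
    (uncorrected significance at ``alpha``)."""
    labels = list(labels or rois.labels)
    if len(labels) < 2:
        raise ValueError("need >= 2 ROIs")
    tc = seed_timecourses(cohort, rois, labels)
    n_sub, n_seed, _ = tc.shape
    z = np.empty((n_sub, n_seed, n_seed))
    for si in range(n_sub):
        sd = tc[si].std(axis=1)
        if np.any(sd == 0):
            bad = labels[int(np.argmax(sd == 0))]
            raise ValueError(
                f"constant seed series for {cohort[si].subject_id}, seed {bad!r}"
            )
        r = np.corrcoef(tc[si])
        z[si] = np.arctanh(clip_r(r))
        np.fill_diagonal(z[si], np.nan)
    # compute the upper triangle once and mirror it: exact symmetry
    iu, ju = np.triu_indices(n_seed, k=1)
    t = np.full((n_seed, n_seed), np.nan)
    p = np.full((n_seed, n_seed), np.nan)
    tt, pp, _ = group_t(z[:, iu, ju])
    t[iu, ju] = t[ju, iu] = tt
    p[iu, ju] = p[ju, iu] = pp
    return ConnectivityMatrix(labels=labels, z=z, t=t, p=p, alpha=alpha)
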