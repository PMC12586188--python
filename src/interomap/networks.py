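"""Conjunction maps, eta-squared similarity, k-means subsystems and Dice.

Aggregates per-seed group maps into system-level structure: conjunction
"connecting region" maps count how many binarized seed maps share each
voxel; pairwise eta-squared similarity between unthresholded group maps
feeds a k-means clustering over a range of k with Calinski-Harabasz model
selection; recovered network masks are compared with a labelled reference
parcellation through Dice overlap with a parcel-level label-permutation
null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from interomap.mapping import BinaryMask
from interomap.cohort import VoxelGrid


@dataclass
class ConjunctionMap:
    """Per-voxel count of contributing binarized maps."""

    grid: VoxelGrid
    counts: np.ndarray
    n_maps: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.min() < 0 or self.counts.max() > self.n_maps:
            raise ValueError("counts must lie in [0, n_maps]")


@dataclass
class SimilarityMatrix:
    """Pairwise eta-squared values between labelled group maps."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")


@dataclass
class ClusterSolution:
    """k-means clustering of maps with Calinski-Harabasz selection.

    ``labels`` maps each map name to a 1-based cluster id for the chosen k;
    ``ch_scores`` and ``inertia`` record the criterion and the best
    within-cluster sum of squared distances for every candidate k;
    ``labels_by_k`` keeps every candidate solution.
    """

    chosen_k: int
    labels: dict[str, int]
    ch_scores: dict[int, float]
    inertia: dict[int, float]
    labels_by_k: dict[int, dict[str, int]]


def conjunction(masks: list[BinaryMask]) -> ConjunctionMap:
    """Per-voxel count of masks containing each voxel."""
    if len(masks) < 2:
        raise ValueError("need >= 2 masks")
    grid = masks[0].grid
    if any(m.grid != grid for m in masks):
        raise ValueError("masks are not on a shared grid")
    counts = np.sum([m.data for m in masks], axis=0)
    return ConjunctionMap(grid=grid, counts=counts, n_maps=len(masks))


def connecting_regions(cmap: ConjunctionMap, min_overlap: int | None = None) -> BinaryMask:
    """Voxels present in at least ``min_overlap`` maps (default: all maps,
    the full conjunction; figure-style display floors are lower)."""
    if min_overlap is None:
        min_overlap = cmap.n_maps
    if not (1 <= min_overlap <= cmap.n_maps):
        raise ValueError(f"min_overlap must be in [1, {cmap.n_maps}], got {min_overlap}")
    return BinaryMask(grid=cmap.grid, data=cmap.counts >= min_overlap)


def eta_squared(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Eta-squared similarity between two spatial maps.

    eta^2 = 1 - sum_i[(a_i - m_i)^2 + (b_i - m_i)^2]
              / sum_i[(a_i - M)^2 + (b_i - M)^2]
    with m_i the voxel-wise pair mean and M the grand mean over both maps.
    1 for identical maps, 0 when all variance is within voxel pairs. Two
    identical constant maps are defined as 1; otherwise a zero total sum of
    squares yields NaN (undefined).
    """
    a = np.asarray(map_a, dtype=float).reshape(-1)
    b = np.asarray(map_b, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise ValueError("maps differ in size")
    if a.size < 2:
        raise ValueError("need >= 2 voxels")
    if np.array_equal(a, b):
        return 1.0
    m = 0.5 * (a + b)
    grand = m.mean()
    within = np.sum((a - m) ** 2 + (b - m) ** 2)
    total = np.sum((a - grand) ** 2 + (b - grand) ** 2)
    if total == 0:
        return float("nan")
    return float(1.0 - within / total)


def similarity_matrix(maps: np.ndarray, labels: list[str]) -> SimilarityMatrix:
    """All pairwise eta-squared values; diagonal is exactly 1."""
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] != len(labels):
        raise ValueError("one label per map required")
    if maps.shape[0] < 2:
        raise ValueError("need >= 2 maps")
    n = maps.shape[0]
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = eta_squared(maps[i], maps[j])
    return SimilarityMatrix(labels=list(labels), values=values)


def kmeans_over_k(
    similarity: SimilarityMatrix | np.ndarray,
    k_range: range | list[int] = range(2, 11),
    restarts: int = 10,
    max_iter: int = 1000,
    rng_seed: int = 0,
    labels: list[str] | None = None,
) -> ClusterSolution:
    """k-means over a range of k with Calinski-Harabasz model selection.

    The feature space is the rows of the similarity matrix (each map is
    represented by its similarity profile to all maps); a raw feature matrix
    with per-map rows may be passed instead. For each k, Lloyd's algorithm
    with squared-Euclidean distance runs ``restarts`` random initializations
    (keeping the lowest within-cluster sum of distances); the chosen k
    maximizes CH(k) = [B_k / (k - 1)] / [W_k / (n - k)], smallest k winning
    ties.
    """
    if isinstance(similarity, SimilarityMatrix):
        X = similarity.values
        names = similarity.labels
    else:
        X = np.asarray(similarity, dtype=float)
        names = list(labels) if labels is not None else [str(i) for i in range(X.shape[0])]
    n = X.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    if ks[0] < 2 or ks[-1] >= n:
        raise ValueError(f"k range must lie within [2, {n - 1}], got {ks}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(rng_seed)
    ch_scores: dict[int, float] = {}
    inertia: dict[int, float] = {}
    labels_by_k: dict[int, dict[str, int]] = {}
    for k in ks:
        km = KMeans(
            n_clusters=k,
            init="random",
            n_init=restarts,
            max_iter=max_iter,
            random_state=int(rng.integers(0, 2**31)),
        ).fit(X)
        if km.inertia_ <= 1e-12:
            # perfectly separable at this k: zero within-cluster scatter.
            # CH is +inf for every such k; the smallest-k tie-break decides.
            ch_scores[k] = float("inf")
        else:
            ch_scores[k] = float(calinski_harabasz_score(X, km.labels_))
        inertia[k] = float(km.inertia_)
        labels_by_k[k] = {name: int(c) + 1 for name, c in zip(names, km.labels_)}
    chosen_k = max(ks, key=lambda k: (ch_scores[k], -k))
    return ClusterSolution(
        chosen_k=chosen_k,
        labels=labels_by_k[chosen_k],
        ch_scores=ch_scores,
        inertia=inertia,
        labels_by_k=labels_by_k,
    )


def cluster_conjunctions(
    masks: dict[str, BinaryMask], labels: dict[str, int]
) -> dict[int, BinaryMask]:
    """Per-cluster intersection of its member maps' binary masks."""
    missing = [name for name in labels if name not in masks]
    if missing:
        raise ValueError(f"labels reference maps without masks: {missing}")
    out: dict[int, BinaryMask] = {}
    for cluster in sorted(set(labels.values())):
        members = [masks[name] for name, c in labels.items() if c == cluster]
        data = np.logical_and.reduce([m.data for m in members])
        out[cluster] = BinaryMask(grid=members[0].grid, data=data)
    return out


def dice(mask_a: BinaryMask | np.ndarray, mask_b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); two empty masks are defined 0."""
    a = mask_a.data if isinstance(mask_a, BinaryMask) else np.asarray(mask_a, dtype=bool)
    b = mask_b.data if isinstance(mask_b, BinaryMask) else np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks differ in size")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def dice_permutation_test(
    network_mask: BinaryMask | np.ndarray,
    parcel_ids: np.ndarray,
    parcel_labels: dict[int, int],
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Dice of a network mask against each label of a parcellation, with a
    parcel-level label-permutation null.

    ``parcel_ids`` assigns every voxel a parcel id (0 = background);
    ``parcel_labels`` maps each parcel id to a network label. The null
    permutes the parcel-to-label assignment while preserving parcel
    geometry; p = (1 + #{null >= observed}) / (1 + n_perm) per label.
    """
    mask = (
        network_mask.data if isinstance(network_mask, BinaryMask) else np.asarray(network_mask, dtype=bool)
    ).reshape(-1)
    parcel_ids = np.asarray(parcel_ids).reshape(-1)
    if parcel_ids.shape != mask.shape:
        raise ValueError("parcellation and mask differ in size")
    if n_perm < 99:
        raise ValueError("need n_perm >= 99")
    parcels = sorted(parcel_labels)
    label_values = sorted(set(parcel_labels.values()))
    if len(label_values) < 2:
        raise ValueError("parcellation must carry >= 2 labels")
    rng = np.random.default_rng(rng_seed)

    # per-parcel overlap with the mask and parcel sizes, computed once
    parcel_sizes = np.array([(parcel_ids == pid).sum() for pid in parcels], dtype=float)
    parcel_hits = np.array(
        [np.logical_and(mask, parcel_ids == pid).sum() for pid in parcels], dtype=float
    )
    mask_size = float(mask.sum())
    assignment = np.array([parcel_labels[pid] for pid in parcels])

    def dice_per_label(assign: np.ndarray) -> np.ndarray:
        out = np.empty(len(label_values))
        for li, lab in enumerate(label_values):
            sel = assign == lab
            denom = mask_size + parcel_sizes[sel].sum()
            out[li] = 0.0 if denom == 0 else 2.0 * parcel_hits[sel].sum() / denom
        return out

    observed = dice_per_label(assignment)
    exceed = np.zeros(len(label_values))
    for _ in range(n_perm):
        exceed += dice_per_label(rng.permutation(assignment)) >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({"label": label_values, "dice": observed, "p": p})
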