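"""Verification of functional connectivity against documented anatomy.

Scores each edge of a documented anatomical-connection list (derived from
tract-tracing literature, or the synthetic stand-in emitted by the cohort
simulator) against the functional results. An edge is confirmed either by a
significant positive seed-to-seed matrix cell, or — when the averaged time
courses fall below threshold — by a connectivity cluster of one seed's
discovery map inside the other seed's ROI. Per-category percent-confirmed
tallies are reported at integer precision alongside the raw fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import math
import numpy as np
import pandas as pd

from interomap.cohort import RoiSet, SubjectTimeSeries, edge_category
from interomap.mapping import (
    BinaryMask,
    ConnectivityMatrix,
    binarize_positive,
    bootstrap_consistency,
    consistency_cutoff,
    consistency_mask,
    ConsistencyMap,
    group_map,
    seed_matrix,
    seed_zmaps,
)

EDGE_COLUMNS = ("seed_a", "seed_b", "category")
CATEGORIES = ("cortico-cortical", "subcortico-cortical", "subcortico-subcortical")

MATRIX_SIGNIFICANT = "matrix_significant"
MAP_CLUSTER_ONLY = "map_cluster_only"
NO_EVIDENCE = "none"


@dataclass
class VerificationReport:
    """Per-edge evidence and per-category percent-confirmed tallies."""

    per_edge: pd.DataFrame
    per_category: pd.DataFrame
    overall_percent: float
    overall_fraction: float
    percent_decimals: int = 0

    def percent(self, category: str) -> float:
        row = self.per_category.loc[self.per_category["category"] == category]
        if row.empty:
            raise KeyError(f"no edges in category {category!r}")
        return float(row["percent_confirmed"].iloc[0])


def load_edge_list(path, rois: RoiSet | None = None) -> pd.DataFrame:
    """Read a documented-edge TSV (seed_a, seed_b, category[, supported, note]).

    Validates categories, optionally validates seed labels against a RoiSet,
    and deduplicates unordered pairs with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"edge list missing required columns: {missing}")
    for i, row in df.iterrows():
        if not row["seed_a"] or not row["seed_b"]:
            raise ValueError(f"malformed edge row at line {i + 2}: empty seed label")
        if row["category"] not in CATEGORIES:
            raise ValueError(
                f"malformed edge row at line {i + 2}: unknown category {row['category']!r}"
            )
    if rois is not None:
        known = set(rois.labels)
        for i, row in df.iterrows():
            for col in ("seed_a", "seed_b"):
                if row[col] not in known:
                    raise ValueError(f"unknown seed label {row[col]!r} at line {i + 2}")
    if "supported" in df.columns:
        df["supported"] = df["supported"].map(
            lambda v: str(v).strip().lower() in ("true", "1", "yes")
        )
    key = df.apply(lambda r: tuple(sorted((r["seed_a"], r["seed_b"]))), axis=1)
    dup = key.duplicated()
    if dup.any():
        warnings.warn(f"dropping {int(dup.sum())} duplicate unordered seed pair(s)")
        df = df.loc[~dup].reset_index(drop=True)
    return df


def min_cluster_voxels(roi_size: int, fraction: float = 0.05) -> int:
    """Minimum in-ROI cluster extent: max(1, ceil(fraction * ROI size))."""
    return max(1, int(math.ceil(fraction * roi_size)))


def edge_confirmed(
    edge: tuple[str, str],
    matrix: ConnectivityMatrix,
    maps: dict[str, BinaryMask],
    rois: RoiSet,
    rule: str = "matrix_or_map",
    min_voxel_fraction: float = 0.05,
) -> str:
    """Evidence tier for one documented edge.

    ``matrix_significant`` when the pair's group test is significant and
    positive; else ``map_cluster_only`` when either seed's binarized
    discovery map covers at least ``min_cluster_voxels`` of the other ROI
    (only under the default "matrix_or_map" rule); else ``none``.
    """
    a, b = edge
    if rule not in ("matrix_or_map", "matrix_only"):
        raise ValueError(f"unknown rule {rule!r}")
    for s in (a, b):
        if s not in matrix.labels:
            raise ValueError(f"seed {s!r} missing from connectivity matrix")
        if rule == "matrix_or_map" and s not in maps:
            raise ValueError(f"no discovery map for seed {s!r}")
    if matrix.significant_positive(a, b):
        return MATRIX_SIGNIFICANT
    if rule == "matrix_or_map":
        for src, dst in ((a, b), (b, a)):
            target = rois.members[dst]
            hits = int(maps[src].data[target].sum())
            if hits >= min_cluster_voxels(target.size, min_voxel_fraction):
                return MAP_CLUSTER_ONLY
    return NO_EVIDENCE


def verification_summary(
    edges: pd.DataFrame,
    evidence: dict[tuple[str, str], str],
    percent_decimals: int = 0,
) -> VerificationReport:
    """Tally per-category and overall percent confirmed.

    Every edge must be scored; confirmation means evidence other than
    ``none``. Percentages are rounded to ``percent_decimals`` (integer by
    default); raw fractions are carried alongside.
    """
    if len(edges) == 0:
        raise ValueError("empty edge list")
    norm_evidence = {tuple(sorted(k)): v for k, v in evidence.items()}
    rows = []
    for _, row in edges.iterrows():
        key = tuple(sorted((row["seed_a"], row["seed_b"])))
        if key not in norm_evidence:
            raise ValueError(f"edge {key} has not been scored")
        ev = norm_evidence[key]
        rows.append(
            {
                "seed_a": row["seed_a"],
                "seed_b": row["seed_b"],
                "category": row["category"],
                "evidence": ev,
                "confirmed": ev != NO_EVIDENCE,
            }
        )
    per_edge = pd.DataFrame(rows)
    cat_rows = []
    for cat, grp in per_edge.groupby("category", sort=True):
        n, k = len(grp), int(grp["confirmed"].sum())
        cat_rows.append(
            {
                "category": cat,
                "n_edges": n,
                "n_confirmed": k,
                "fraction_confirmed": k / n,
                "percent_confirmed": round(100.0 * k / n, percent_decimals),
            }
        )
    per_category = pd.DataFrame(cat_rows)
    n_all, k_all = len(per_edge), int(per_edge["confirmed"].sum())
    return VerificationReport(
        per_edge=per_edge,
        per_category=per_category,
        overall_percent=round(100.0 * k_all / n_all, percent_decimals),
        overall_fraction=k_all / n_all,
        percent_decimals=percent_decimals,
    )


def verify_cohort(
    cohort: list[SubjectTimeSeries],
    rois: RoiSet,
    edges: pd.DataFrame,
    alpha: float = 0.05,
    B: int = 1000,
    fraction: float = 0.8,
    consistency_criterion: float = 0.95,
    rule: str = "matrix_or_map",
    min_voxel_fraction: float = 0.05,
    rng_seed: int = 0,
    z_maps: np.ndarray | None = None,
) -> VerificationReport:
    """End-to-end scoring of a documented edge list on a (conditioned) cohort.

    Computes the seed-to-seed matrix and, for the map rule, per-seed
    binarized full-sample maps restricted to their bootstrap consistency
    masks (voxels surviving more than ``consistency_criterion`` of the B
    subsampling iterations). Only the seeds appearing in ``edges`` are
    mapped and tested. ``z_maps`` may supply precomputed
    (subjects, seeds, voxels) Fisher-z maps in that label order.
    """
    needed = set(edges["seed_a"]) | set(edges["seed_b"])
    labels = [l for l in rois.labels if l in needed]
    if len(labels) < 2:
        raise ValueError("edge list references fewer than 2 known seeds")
    matrix = seed_matrix(cohort, rois, alpha=alpha, labels=labels)
    maps: dict[str, BinaryMask] = {}
    if rule == "matrix_or_map":
        if z_maps is None:
            z_maps = seed_zmaps(cohort, rois, labels)
        grid = rois.grid
        counts = bootstrap_consistency(z_maps, B=B, fraction=fraction, alpha=alpha, rng_seed=rng_seed)
        cutoff = consistency_cutoff(B, consistency_criterion)
        for li, label in enumerate(labels):
            gmap = group_map(z_maps[:, li], grid)
            cmask = consistency_mask(
                ConsistencyMap(grid=grid, counts=counts[li], B=B, fraction=fraction, alpha=alpha),
                cutoff,
            )
            maps[label] = BinaryMask(grid=grid, data=binarize_positive(gmap, alpha).data & cmask.data)
    evidence = {}
    for _, row in edges.iterrows():
        pair = (row["seed_a"], row["seed_b"])
        evidence[tuple(sorted(pair))] = edge_confirmed(
            pair, matrix, maps, rois, rule=rule, min_voxel_fraction=min_voxel_fraction
        )
    return verification_summary(edges, evidence)
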