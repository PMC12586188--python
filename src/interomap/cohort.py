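"""Synthetic multi-subject BOLD cohorts with planted network structure.

The simulator emulates the ingredients the downstream analysis depends on: a
shared voxel grid carrying 7 cortical spherical seeds and 14 subcortical
seeds of heterogeneous size (small brainstem nuclei are noisier simply
because their mean time courses average fewer voxels), two overlapping
cortical latent networks that share hub seeds, three subcortical
projection-profile clusters, pairwise edge coupling through shared latent
components, AR(1) voxel noise, shared physiological confounds and random-walk
motion traces. Ground truth (network/cluster membership, the planted edge
list with designated "unsupported" exception edges) is carried alongside the
cohort so that recovery can be tested without any external data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

CORTICAL = "cortical"
SUBCORTICAL = "subcortical"

#: confound table columns: 6 rigid-body motion parameters (translations in
#: mm, rotations in radians) plus three tissue signals.
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
TISSUE_COLUMNS = ("white_matter", "csf", "aqueduct")
CONFOUND_COLUMNS = MOTION_COLUMNS + TISSUE_COLUMNS

#: Default seed names. 7 cortical seeds (anterior/mid cingulate and insular
#: subdivisions) and 14 subcortical seeds spanning thalamus, limbic nuclei
#: and brainstem.
DEFAULT_CORTICAL_SEEDS = ("sgACC", "pACC", "aMCC", "mvAIns", "lvAIns", "dmIns", "dpIns")
DEFAULT_SUBCORTICAL_SIZES = {
    "mdThal": 27,
    "LGN": 15,
    "hippocampus": 27,
    "dAmy": 18,
    "NAcc": 15,
    "SC": 12,
    "SN": 12,
    "VTA": 12,
    "hypothalamus": 10,
    "PAG": 8,
    "DR": 6,
    "PBN": 5,
    "LC": 5,
    "VSM": 6,
}

#: Cortical network membership: network 1 is a default-mode-like set, network
#: 2 a salience-like set; the two hub seeds load on both networks.
DEFAULT_NETWORK_OF_SEED = {
    "sgACC": 1,
    "pACC": 1,
    "aMCC": 1,
    "mvAIns": 1,
    "lvAIns": 2,
    "dmIns": 2,
    "dpIns": 2,
}
DEFAULT_HUB_SEEDS = ("aMCC", "dpIns")

#: Subcortical projection-profile clusters: small lower-brainstem nuclei,
#: small upper-brainstem nuclei plus hypothalamus, and the larger nuclei.
DEFAULT_CLUSTER_OF_SEED = {
    "LC": 1,
    "PBN": 1,
    "VSM": 1,
    "PAG": 2,
    "DR": 2,
    "hypothalamus": 2,
    "mdThal": 3,
    "LGN": 3,
    "hippocampus": 3,
    "dAmy": 3,
    "NAcc": 3,
    "SC": 3,
    "SN": 3,
    "VTA": 3,
}


@dataclass(frozen=True)
class VoxelGrid:
    """An isotropic 3D voxel grid shared by all subjects of a cohort."""

    dims: tuple[int, int, int]
    voxel_size_mm: float = 3.0

    def __post_init__(self):
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"grid dims must be 3 positive integers, got {self.dims}")
        if not self.voxel_size_mm > 0:
            raise ValueError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def ravel(self, ijk: np.ndarray) -> np.ndarray:
        """Flat voxel indices for an (m, 3) array of integer coordinates."""
        ijk = np.asarray(ijk)
        return np.ravel_multi_index((ijk[:, 0], ijk[:, 1], ijk[:, 2]), self.dims)

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])


@dataclass
class RoiSet:
    """Named voxel sets on a grid, each labelled cortical or subcortical."""

    grid: VoxelGrid
    members: dict[str, np.ndarray]  # label -> sorted flat voxel indices
    category: dict[str, str]  # label -> "cortical" | "subcortical"

    def __post_init__(self):
        for label, idx in self.members.items():
            idx = np.asarray(idx, dtype=np.intp)
            if idx.size == 0:
                raise ValueError(f"ROI {label!r} is empty")
            if idx.min() < 0 or idx.max() >= self.grid.n_voxels:
                raise ValueError(f"ROI {label!r} falls outside the grid")
            self.members[label] = np.sort(idx)

    @property
    def labels(self) -> list[str]:
        return list(self.members)

    def labels_of(self, category: str) -> list[str]:
        return [l for l in self.members if self.category[l] == category]

    @property
    def cortical_labels(self) -> list[str]:
        return self.labels_of(CORTICAL)

    @property
    def subcortical_labels(self) -> list[str]:
        return self.labels_of(SUBCORTICAL)

    def size(self, label: str) -> int:
        return int(self.members[label].size)

    def to_label_volume(self) -> np.ndarray:
        """Integer-labelled 3D volume (0 = background, i+1 = i-th ROI)."""
        vol = np.zeros(self.grid.n_voxels, dtype=np.int16)
        for i, label in enumerate(self.labels):
            vol[self.members[label]] = i + 1
        return vol.reshape(self.grid.dims)


@dataclass(frozen=True)
class RoiSpec:
    """Declarative ROI geometry: spherical cortical seeds and subcortical
    box-shaped nuclei with target voxel counts.

    ``cortical_radius_mm`` defaults to 6 mm so that on the default coarse
    3 mm synthetic grid each cortical sphere contains >= 20 voxels (a 4 mm
    sphere, the acquisition-scale convention, covers only ~7 voxels at 3 mm
    and is appropriate for finer grids).
    """

    cortical: tuple[str, ...] = DEFAULT_CORTICAL_SEEDS
    cortical_radius_mm: float = 6.0
    subcortical_sizes: tuple[tuple[str, int], ...] = tuple(
        DEFAULT_SUBCORTICAL_SIZES.items()
    )


def default_roi_spec() -> RoiSpec:
    return RoiSpec()


def _sphere_offsets(radius_vox: float) -> np.ndarray:
    r = int(math.floor(radius_vox))
    if radius_vox <= 0:
        return np.empty((0, 3), dtype=int)
    rng3 = np.arange(-r, r + 1)
    grid = np.stack(np.meshgrid(rng3, rng3, rng3, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = (grid**2).sum(axis=1) <= radius_vox**2
    return grid[keep]


def _box_shape(n_voxels: int) -> tuple[int, int, int]:
    """Smallest near-cubic box with >= n_voxels voxels."""
    side = int(math.ceil(n_voxels ** (1 / 3)))
    shape = [side, side, side]
    # shrink axes while the product still holds n_voxels
    for ax in range(3):
        while shape[ax] > 1 and (shape[ax] - 1) * np.prod(shape) / shape[ax] >= n_voxels:
            shape[ax] -= 1
    return tuple(shape)


def build_grid_rois(
    grid_spec: VoxelGrid | tuple = (24, 24, 24),
    roi_spec: RoiSpec | None = None,
    rng_seed: int = 0,
    voxel_size_mm: float = 3.0,
) -> tuple[VoxelGrid, RoiSet]:
    """Lay out cortical spherical seeds and subcortical nuclei on a grid.

    Cortical seeds are placed on a lattice in the upper third of the grid
    (z-axis), subcortical nuclei in the lower third; the lattice assignment
    is shuffled deterministically by ``rng_seed``. Raises if a label is
    duplicated or an ROI cannot be placed inside the grid.
    """
    grid = grid_spec if isinstance(grid_spec, VoxelGrid) else VoxelGrid(tuple(grid_spec), voxel_size_mm)
    spec = roi_spec or default_roi_spec()
    rng = np.random.default_rng(rng_seed)

    labels = list(spec.cortical) + [name for name, _ in spec.subcortical_sizes]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate ROI labels: {dup}")

    nx, ny, nz = grid.dims
    members: dict[str, np.ndarray] = {}
    category: dict[str, str] = {}

    # --- cortical spheres on a lattice in the upper part of the grid
    r_vox = spec.cortical_radius_mm / grid.voxel_size_mm
    offsets = _sphere_offsets(r_vox)
    if offsets.shape[0] == 0:
        raise ValueError(
            f"cortical sphere radius {spec.cortical_radius_mm} mm yields an "
            f"empty ROI at voxel size {grid.voxel_size_mm} mm"
        )
    r = int(math.floor(r_vox))
    spacing = 2 * r + 1
    xs = list(range(r, nx - r, spacing))
    ys = list(range(r, ny - r, spacing))
    z_cort = nz - r - 1
    centers = [(x, y, z_cort) for x in xs for y in ys]
    if len(centers) < len(spec.cortical):
        # fall back to a second z-plane, kept inside the cortical (upper) zone
        z2 = z_cort - spacing
        if z2 - r >= nz // 2:
            centers += [(x, y, z2) for x in xs for y in ys]
    if len(centers) < len(spec.cortical):
        raise ValueError(
            f"grid {grid.dims} too small to place {len(spec.cortical)} cortical "
            f"spheres of radius {spec.cortical_radius_mm} mm"
        )
    order = rng.permutation(len(centers))
    for label, ci in zip(spec.cortical, order):
        center = np.array(centers[ci])
        ijk = center + offsets
        members[label] = grid.ravel(ijk)
        category[label] = CORTICAL

    # --- subcortical boxes on a lattice in the lower part of the grid
    sizes = dict(spec.subcortical_sizes)
    if sizes:
        max_side = max(max(_box_shape(n)) for n in sizes.values())
        sp = max_side + 1
        sxs = list(range(0, nx - max_side + 1, sp))
        sys_ = list(range(0, ny - max_side + 1, sp))
        szs = list(range(0, nz // 2 - max_side + 1, sp)) or [0]
        corners = [(x, y, z) for z in szs for x in sxs for y in sys_]
        if len(corners) < len(sizes):
            raise ValueError(
                f"grid {grid.dims} too small to place {len(sizes)} subcortical ROIs"
            )
        order = rng.permutation(len(corners))
        for (label, n_vox), ci in zip(sizes.items(), order):
            if n_vox < 1:
                raise ValueError(f"ROI {label!r} requested with {n_vox} voxels")
            shape = _box_shape(n_vox)
            corner = np.array(corners[ci])
            if np.any(corner + shape > grid.dims):
                raise ValueError(f"ROI {label!r} falls outside the grid")
            box = np.stack(
                np.meshgrid(*[np.arange(c, c + s) for c, s in zip(corner, shape)], indexing="ij"),
                axis=-1,
            ).reshape(-1, 3)
            members[label] = grid.ravel(box[:n_vox])
            category[label] = SUBCORTICAL

    return grid, RoiSet(grid=grid, members=members, category=category)


def _norm_edge(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self edge {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort.

    ``network_loadings`` maps each cortical seed to per-network loadings
    (hub seeds carry loadings on both networks); ``cluster_of_seed`` assigns
    each subcortical seed to one of three projection-profile clusters;
    ``planted_edges`` maps unordered seed pairs to coupling weights w >= 0
    realized as shared latent components; ``unsupported_edges`` are
    documented edges with no coupling (w = 0), the simulation analogue of
    anatomical connections without observable functional connectivity.
    ``system_factors`` are broader shared latents (factor name -> per-seed
    loading) used to emulate densely interconnected functional systems:
    scenario builders construct them as a clique cover of the supported
    pair graph, so that exception edges share no latent component at all.
    ``coupling_sd`` is the between-subject s.d. (tau) of all loadings.
    """

    network_loadings: dict[str, dict[int, float]] = field(default_factory=dict)
    cluster_of_seed: dict[str, int] = field(default_factory=dict)
    cluster_loading: float = 0.9
    planted_edges: dict[tuple[str, str], float] = field(default_factory=dict)
    unsupported_edges: set[tuple[str, str]] = field(default_factory=set)
    system_factors: dict[str, dict[str, float]] = field(default_factory=dict)
    coupling_sd: float = 0.1

    def __post_init__(self):
        self.planted_edges = {_norm_edge(*e): float(w) for e, w in self.planted_edges.items()}
        self.unsupported_edges = {_norm_edge(*e) for e in self.unsupported_edges}
        bad = [e for e in self.unsupported_edges if self.planted_edges.get(e, 0.0) > 0]
        if bad:
            raise ValueError(f"unsupported edges carry positive weight: {bad}")
        for e, w in self.planted_edges.items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"edge {e} has invalid weight {w}")
        for a, b in self.unsupported_edges:
            shared = [
                f
                for f, loads in self.system_factors.items()
                if loads.get(a, 0) > 0 and loads.get(b, 0) > 0
            ]
            if shared:
                raise ValueError(
                    f"unsupported edge ({a}, {b}) shares system factor(s) {shared}"
                )

    @property
    def network_of_seed(self) -> dict[str, tuple[int, ...]]:
        return {s: tuple(sorted(nets)) for s, nets in self.network_loadings.items()}

    @property
    def documented_edges(self) -> list[tuple[str, str]]:
        """All documented edges: planted (w > 0) plus unsupported (w = 0)."""
        edges = set(self.planted_edges) | self.unsupported_edges
        return sorted(edges)

    def coupled_edges(self) -> dict[tuple[str, str], float]:
        return {e: w for e, w in self.planted_edges.items() if w > 0}

    def to_dict(self) -> dict:
        """JSON-serializable description of the planted structure."""
        return {
            "network_loadings": self.network_loadings,
            "cluster_of_seed": self.cluster_of_seed,
            "cluster_loading": self.cluster_loading,
            "planted_edges": {f"{a}|{b}": w for (a, b), w in self.planted_edges.items()},
            "unsupported_edges": [f"{a}|{b}" for a, b in sorted(self.unsupported_edges)],
            "system_factors": self.system_factors,
            "coupling_sd": self.coupling_sd,
        }


def default_ground_truth(
    primary_loading: float = 0.9,
    hub_secondary_loading: float = 0.25,
    cluster_loading: float = 0.9,
    coupling_sd: float = 0.1,
) -> GroundTruth:
    """Two overlapping cortical networks (hubs load on both) and three
    subcortical clusters; no edges planted."""
    loadings: dict[str, dict[int, float]] = {}
    for seed, net in DEFAULT_NETWORK_OF_SEED.items():
        loadings[seed] = {net: primary_loading}
        if seed in DEFAULT_HUB_SEEDS:
            other = 2 if net == 1 else 1
            loadings[seed][other] = hub_secondary_loading
    return GroundTruth(
        network_loadings=loadings,
        cluster_of_seed=dict(DEFAULT_CLUSTER_OF_SEED),
        cluster_loading=cluster_loading,
        coupling_sd=coupling_sd,
    )


def _round_robin_pairs(group_a: list[str], group_b: list[str]) -> list[tuple[str, str]]:
    """Deterministic enumeration of cross-group pairs that cycles through
    both groups evenly (so every seed participates early)."""
    pairs = []
    for shift in range(len(group_b)):
        for i, a in enumerate(group_a):
            b = group_b[(i + shift) % len(group_b)]
            pairs.append(_norm_edge(a, b))
    seen = set()
    out = []
    for p in pairs:
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


def exception_factor_cover(
    seeds: list[str],
    exceptions: list[tuple[str, str]],
    loading: float = 0.6,
    prefix: str = "sys",
) -> dict[str, dict[str, float]]:
    """Greedy clique cover of the complete graph on ``seeds`` minus the
    exception edges, returned as system factors.

    Every non-exception pair ends up sharing at least one factor (clique)
    while exception pairs share none, so planted couplings can stay dense
    without per-edge latent variance stacking up on high-degree seeds.
    """
    seeds = sorted(seeds)
    excl = {_norm_edge(*e) for e in exceptions}
    uncovered = {
        _norm_edge(a, b) for a, b in itertools.combinations(seeds, 2)
    } - excl
    factors: dict[str, dict[str, float]] = {}
    while uncovered:
        a, b = min(uncovered)
        clique = [a, b]
        for c in seeds:
            if c in clique:
                continue
            if all(_norm_edge(c, x) not in excl for x in clique):
                clique.append(c)
        factors[f"{prefix}{len(factors)}"] = {s: loading for s in clique}
        uncovered -= {_norm_edge(x, y) for x, y in itertools.combinations(clique, 2)}
    return factors


def cortico_cortical_scenario(
    edge_weight: float = 0.3, factor_loading: float = 0.6, **gt_kwargs
) -> GroundTruth:
    """All 21 cortico-cortical pairs documented and planted."""
    gt = default_ground_truth(**gt_kwargs)
    for a, b in itertools.combinations(DEFAULT_CORTICAL_SEEDS, 2):
        gt.planted_edges[_norm_edge(a, b)] = edge_weight
    gt.system_factors.update(
        exception_factor_cover(list(DEFAULT_CORTICAL_SEEDS), [], factor_loading, "cc")
    )
    return gt


DEFAULT_SUBCORTICO_CORTICAL_EXCEPTIONS = (("PAG", "dpIns"), ("PBN", "sgACC"))
DEFAULT_SUBCORTICO_SUBCORTICAL_EXCEPTIONS = (
    ("hypothalamus", "PBN"),
    ("hypothalamus", "LC"),
    ("hypothalamus", "VSM"),
)


def subcortico_cortical_scenario(
    n_edges: int = 50,
    unsupported: tuple[tuple[str, str], ...] = DEFAULT_SUBCORTICO_CORTICAL_EXCEPTIONS,
    edge_weight: float = 0.3,
    factor_loading: float = 0.6,
    **gt_kwargs,
) -> GroundTruth:
    """A documented subcortico-cortical edge list with exception edges.

    ``n_edges`` pairs are documented; the ``unsupported`` pairs are part of
    the documented list but carry no coupling, emulating anatomical
    connections that yield no functional connectivity.
    """
    gt = default_ground_truth(**gt_kwargs)
    sub = sorted(DEFAULT_CLUSTER_OF_SEED)
    cort = list(DEFAULT_CORTICAL_SEEDS)
    unsupported_norm = [_norm_edge(*e) for e in unsupported]
    chosen = list(unsupported_norm)
    for pair in _round_robin_pairs(sub, cort):
        if len(chosen) >= n_edges:
            break
        if pair not in chosen:
            chosen.append(pair)
    if len(chosen) < n_edges:
        raise ValueError(f"cannot select {n_edges} subcortico-cortical edges")
    for pair in chosen:
        if pair in unsupported_norm:
            gt.unsupported_edges.add(pair)
        else:
            gt.planted_edges[pair] = edge_weight
    gt.system_factors.update(
        exception_factor_cover(sub + cort, unsupported_norm, factor_loading, "sc")
    )
    return gt


def subcortico_subcortical_scenario(
    n_edges: int = 75,
    unsupported: tuple[tuple[str, str], ...] = DEFAULT_SUBCORTICO_SUBCORTICAL_EXCEPTIONS,
    edge_weight: float = 0.3,
    factor_loading: float = 0.6,
    **gt_kwargs,
) -> GroundTruth:
    """A documented subcortico-subcortical edge list with exception edges."""
    gt = default_ground_truth(**gt_kwargs)
    sub = sorted(DEFAULT_CLUSTER_OF_SEED)
    all_pairs = [_norm_edge(a, b) for a, b in itertools.combinations(sub, 2)]
    unsupported_norm = [_norm_edge(*e) for e in unsupported]
    chosen = list(unsupported_norm)
    for pair in all_pairs:
        if len(chosen) >= n_edges:
            break
        if pair not in chosen:
            chosen.append(pair)
    if len(chosen) < n_edges:
        raise ValueError(f"cannot select {n_edges} subcortico-subcortical edges")
    for pair in chosen:
        if pair in unsupported_norm:
            gt.unsupported_edges.add(pair)
        else:
            gt.planted_edges[pair] = edge_weight
    gt.system_factors.update(
        exception_factor_cover(sub, unsupported_norm, factor_loading, "ss")
    )
    return gt


@dataclass
class SubjectTimeSeries:
    """One subject's voxels x timepoints matrix plus run structure."""

    subject_id: str
    data: np.ndarray  # (n_voxels, n_frames)
    tr_s: float
    run_boundaries: tuple[int, ...]  # start frame of each run, first = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be voxels x timepoints")
        if not self.tr_s > 0:
            raise ValueError(f"tr_s must be > 0, got {self.tr_s}")
        rb = tuple(int(b) for b in self.run_boundaries)
        if not rb or rb[0] != 0 or any(b >= self.n_frames for b in rb) or list(rb) != sorted(set(rb)):
            raise ValueError(f"invalid run boundaries {rb} for {self.n_frames} frames")
        self.run_boundaries = rb

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_runs(self) -> int:
        return len(self.run_boundaries)

    def run_slices(self) -> list[slice]:
        stops = list(self.run_boundaries[1:]) + [self.n_frames]
        return [slice(b, s) for b, s in zip(self.run_boundaries, stops)]

    def with_data(self, data: np.ndarray) -> "SubjectTimeSeries":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults are desk-scale but large enough for group inference: 30
    subjects, three concatenated 200-frame runs at TR = 1 s, unit-variance
    AR(1) voxel noise (phi = 0.3), shared physiological confounds and
    random-walk motion with step sizes chosen so the framewise-displacement
    summary lands near resting-state values (~0.17 mm mean).
    """

    n_subjects: int = 30
    n_runs: int = 3
    frames_per_run: int = 200
    tr_s: float = 1.0
    ar_phi: float = 0.3
    noise_sd: float = 1.0
    territory_amp: float = 0.5
    network_territory_voxels: int = 150
    cluster_territory_voxels: int = 100
    private_amp: float = 0.7
    private_territory_voxels: int = 120
    physio_amp: float = 0.4
    motion_leak_amp: float = 0.2
    motion_trans_step_mm: float = 0.03
    motion_rot_step_rad: float = 0.0008

    def __post_init__(self):
        if not (0 <= self.ar_phi < 1):
            raise ValueError(f"AR(1) coefficient must be in [0, 1), got {self.ar_phi}")
        n_conf = len(CONFOUND_COLUMNS)
        if self.n_frames < 2 * (n_conf + 1):
            raise ValueError(
                f"{self.n_frames} frames is too small: need >= {2 * (n_conf + 1)} "
                f"frames for {n_conf} confound regressors"
            )
        if self.n_subjects < 1 or self.n_runs < 1:
            raise ValueError("n_subjects and n_runs must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.n_runs * self.frames_per_run

    @property
    def run_boundaries(self) -> tuple[int, ...]:
        return tuple(r * self.frames_per_run for r in range(self.n_runs))


def ar1_series(rng: np.random.Generator, shape: tuple[int, int], phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) processes, one per row."""
    n, t = shape
    white = rng.standard_normal((n, t))
    if phi == 0 or t == 1:
        return white
    out = np.empty((n, t))
    out[:, 0] = white[:, 0]  # stationary start: y_0 ~ N(0, 1)
    innov_sd = math.sqrt(1.0 - phi * phi)
    # direct-form II transposed state for a first-order filter is phi * y[-1]
    zi = (phi * out[:, 0])[:, None]
    out[:, 1:], _ = lfilter([innov_sd], [1.0, -phi], white[:, 1:], axis=1, zi=zi)
    return out


def _truncated_weight(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(max(0.0, rng.normal(mean, sd))) if sd > 0 else float(max(0.0, mean))


def simulate_cohort(
    grid: VoxelGrid,
    rois: RoiSet,
    ground_truth: GroundTruth,
    sim_config: SimConfig | None = None,
    rng_seed: int = 0,
) -> tuple[list[SubjectTimeSeries], list[pd.DataFrame]]:
    """Simulate a cohort of subjects on ``grid`` with the planted structure.

    Each seed-ROI voxel's series is a sum of its seed's latent components
    (network/cluster signals and per-edge shared latents, with per-subject
    loadings drawn from Normal(w, tau^2) truncated at 0), shared confound
    leakage, and per-voxel AR(1) noise. Non-seed voxels carry noise and
    confound leakage only, except for per-network / per-cluster "territory"
    voxels that receive a fixed loading on the corresponding latent so that
    discovery maps have spatial extent beyond the seeds themselves.

    Returns (subjects, confound tables); bit-identical for identical inputs.
    """
    cfg = sim_config or SimConfig()
    gt = ground_truth
    rng = np.random.default_rng(rng_seed)
    V, T = grid.n_voxels, cfg.n_frames

    unknown = [s for s in list(gt.network_loadings) + list(gt.cluster_of_seed) if s not in rois.members]
    unknown += [s for e in gt.documented_edges for s in e if s not in rois.members]
    if unknown:
        raise ValueError(f"ground truth references unknown seeds: {sorted(set(unknown))}")

    networks = sorted({n for loads in gt.network_loadings.values() for n in loads})
    clusters = sorted(set(gt.cluster_of_seed.values()))
    edges = sorted(gt.coupled_edges())
    factors = sorted(gt.system_factors)

    # carve disjoint territory voxel sets out of the non-seed background
    seed_voxels = np.unique(np.concatenate([rois.members[l] for l in rois.labels]))
    free = np.setdiff1d(np.arange(V), seed_voxels)
    free = rng.permutation(free)
    territories: dict[tuple[str, int], np.ndarray] = {}
    pos = 0
    for net in networks:
        take = min(cfg.network_territory_voxels, max(0, free.size - pos))
        territories[("net", net)] = free[pos : pos + take]
        pos += take
    for clu in clusters:
        take = min(cfg.cluster_territory_voxels, max(0, free.size - pos))
        territories[("clu", clu)] = free[pos : pos + take]
        pos += take
    # seed-specific projection territories: every seed also projects to a
    # small private voxel set, so no two seed maps are ever near-duplicates
    for seed in rois.labels:
        take = min(cfg.private_territory_voxels, max(0, free.size - pos))
        territories[("priv", seed)] = free[pos : pos + take]
        pos += take

    latent_keys = (
        [("net", n) for n in networks]
        + [("clu", c) for c in clusters]
        + [("edge", e) for e in edges]
        + [("fac", f) for f in factors]
        + [("priv", s) for s in rois.labels]
    )
    n_latent = len(latent_keys)
    latent_index = {key: i for i, key in enumerate(latent_keys)}

    subjects: list[SubjectTimeSeries] = []
    confounds: list[pd.DataFrame] = []
    for s in range(cfg.n_subjects):
        sub_rng = np.random.default_rng(rng.integers(0, 2**63))
        data = np.zeros((V, T))

        if n_latent:
            latents = ar1_series(sub_rng, (n_latent, T), cfg.ar_phi)
        else:
            latents = np.zeros((0, T))

        # network latents: cortical seed loadings + territory projections
        for net in networks:
            series = latents[latent_index[("net", net)]]
            for seed, loads in gt.network_loadings.items():
                if net in loads:
                    w = _truncated_weight(sub_rng, loads[net], gt.coupling_sd)
                    data[rois.members[seed]] += w * series
            data[territories[("net", net)]] += cfg.territory_amp * series
        # cluster latents: subcortical seed loadings + cortical territories
        for clu in clusters:
            series = latents[latent_index[("clu", clu)]]
            for seed, c in gt.cluster_of_seed.items():
                if c == clu:
                    w = _truncated_weight(sub_rng, gt.cluster_loading, gt.coupling_sd)
                    data[rois.members[seed]] += w * series
            data[territories[("clu", clu)]] += cfg.territory_amp * series
        # edge latents: one shared component per planted edge
        for edge in edges:
            series = latents[latent_index[("edge", edge)]]
            w = _truncated_weight(sub_rng, gt.planted_edges[edge], gt.coupling_sd)
            for seed in edge:
                data[rois.members[seed]] += w * series
        # system factors: broad shared components over factor member seeds
        for fac in factors:
            series = latents[latent_index[("fac", fac)]]
            for seed, loading in gt.system_factors[fac].items():
                w = _truncated_weight(sub_rng, loading, gt.coupling_sd)
                data[rois.members[seed]] += w * series
        # private seed components: own ROI + seed-specific territory
        if cfg.private_amp > 0:
            for seed in rois.labels:
                series = latents[latent_index[("priv", seed)]]
                w = _truncated_weight(sub_rng, cfg.private_amp, gt.coupling_sd)
                data[rois.members[seed]] += w * series
                data[territories[("priv", seed)]] += cfg.territory_amp * series

        # confounds: tissue signals (AR(1)) and random-walk motion
        tissue = ar1_series(sub_rng, (len(TISSUE_COLUMNS), T), cfg.ar_phi)
        steps = np.concatenate(
            [
                sub_rng.normal(0, cfg.motion_trans_step_mm, (3, T)),
                sub_rng.normal(0, cfg.motion_rot_step_rad, (3, T)),
            ]
        )
        motion = np.cumsum(steps, axis=1)
        conf = np.vstack([motion, tissue])
        amps = np.array([cfg.motion_leak_amp] * 6 + [cfg.physio_amp] * len(TISSUE_COLUMNS))
        if np.any(amps > 0):
            coeff = sub_rng.standard_normal((V, conf.shape[0])) * amps
            data += coeff @ conf

        data += cfg.noise_sd * ar1_series(sub_rng, (V, T), cfg.ar_phi)

        if not np.all(np.isfinite(data)):
            raise FloatingPointError("non-finite values in simulated data")

        subjects.append(
            SubjectTimeSeries(
                subject_id=f"sub-{s + 1:03d}",
                data=data,
                tr_s=cfg.tr_s,
                run_boundaries=cfg.run_boundaries,
            )
        )
        confounds.append(pd.DataFrame(conf.T, columns=list(CONFOUND_COLUMNS)))

    return subjects, confounds


def edge_category(edge: tuple[str, str], rois: RoiSet) -> str:
    cats = sorted(rois.category[s] for s in edge)
    if cats == [CORTICAL, CORTICAL]:
        return "cortico-cortical"
    if cats == [SUBCORTICAL, SUBCORTICAL]:
        return "subcortico-subcortical"
    return "subcortico-cortical"


def emit_edge_list(ground_truth: GroundTruth, rois: RoiSet) -> pd.DataFrame:
    """Documented anatomical-connection list as a TSV-serializable table.

    Columns: seed_a, seed_b, category, supported, note. Unsupported rows are
    the designated exception edges (documented anatomically, no planted
    functional coupling).
    """
    rows = []
    for a, b in ground_truth.documented_edges:
        supported = (a, b) not in ground_truth.unsupported_edges
        rows.append(
            {
                "seed_a": a,
                "seed_b": b,
                "category": edge_category((a, b), rois),
                "supported": supported,
                "note": "" if supported else "documented anatomical connection, no planted coupling",
            }
        )
    return pd.DataFrame(rows, columns=["seed_a", "seed_b", "category", "supported", "note"])
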