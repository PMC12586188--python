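"""Simulate a small synthetic BOLD cohort with planted network structure.

Builds the default 21-seed layout (7 cortical spheres, 14 subcortical
nuclei) on a 16^3 grid, plants the two overlapping cortical networks and
three subcortical clusters plus a documented cortico-cortical edge list,
and prints what the generator produced.
"""

from interomap import (
    SimConfig,
    build_grid_rois,
    cortico_cortical_scenario,
    emit_edge_list,
    framewise_displacement,
    simulate_cohort,
)

grid, rois = build_grid_rois((16, 16, 16), rng_seed=1)
gt = cortico_cortical_scenario()
cfg = SimConfig(n_subjects=4, frames_per_run=150)
cohort, confounds = simulate_cohort(grid, rois, gt, cfg, rng_seed=7)

print(f"grid: {grid.dims} voxels at {grid.voxel_size_mm} mm "
      f"({grid.n_voxels} voxels total)")
print(f"seeds: {len(rois.cortical_labels)} cortical "
      f"(e.g. sgACC: {rois.size('sgACC')} voxels), "
      f"{len(rois.subcortical_labels)} subcortical "
      f"(e.g. PBN: {rois.size('PBN')} voxels)")
print(f"cohort: {len(cohort)} subjects x {cohort[0].n_frames} frames "
      f"({cohort[0].n_runs} runs, TR = {cohort[0].tr_s} s)")

edges = emit_edge_list(gt, rois)
print(f"documented edges: {len(edges)} "
      f"({int(edges['supported'].sum())} with planted coupling)")

fd = framewise_displacement(confounds[0], voxel_size_mm=grid.voxel_size_mm)
print(f"subject 1 motion: FD mean = {fd.fd_mean:.3f} mm, "
      f"s.d. = {fd.fd_sd:.3f} mm, {100 * fd.frac_subvoxel:.1f}% subvoxel frames")
# FD summarizes frame-to-frame head movement; subvoxel means below the
# 3 mm voxel size, i.e. motion that cannot shift a voxel's identity.
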