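"""Score functional connectivity against a documented anatomical edge list.

Uses the subcortico-cortical scenario: 50 documented edges of which 2 are
designated "unsupported" (anatomically documented but carrying no planted
functional coupling — the exception edges). The scorer confirms an edge by
a significant positive seed-to-seed matrix cell, or by a consistency-masked
connectivity cluster of one seed's map inside the other seed's ROI.
"""

from interomap import (
    SimConfig,
    build_grid_rois,
    condition_subject,
    emit_edge_list,
    simulate_cohort,
    subcortico_cortical_scenario,
    verify_cohort,
)

grid, rois = build_grid_rois((16, 16, 16), rng_seed=1)
gt = subcortico_cortical_scenario()
cfg = SimConfig(n_subjects=30, frames_per_run=150)
cohort, confs = simulate_cohort(grid, rois, gt, cfg, rng_seed=13)
cohort = [condition_subject(ts, c)[0] for ts, c in zip(cohort, confs)]

edges = emit_edge_list(gt, rois)
report = verify_cohort(cohort, rois, edges, B=150, rng_seed=17)

row = report.per_category.iloc[0]
print(f"{row['category']}: {row['n_confirmed']}/{row['n_edges']} edges "
      f"confirmed = {row['percent_confirmed']:.0f}%")
print("evidence tiers:",
      report.per_edge["evidence"].value_counts().to_dict())
unconfirmed = report.per_edge.loc[~report.per_edge["confirmed"]]
print("unconfirmed edges:",
      [f"{r.seed_a}-{r.seed_b}" for r in unconfirmed.itertuples()])
# the two unconfirmed edges should be exactly the designated exceptions
# (PAG-dpIns, PBN-sgACC), reproducing a 96% confirmation tally.
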