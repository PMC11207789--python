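"""Hub-vulnerability band analysis.

Given a disrupted edge set (here: ground truth from a hub-targeted
simulation), slide a hubness band k +- 0.05 over the control group's
mean hubness and compare the proportion of disrupted edges touching the
band against random node sets of equal size.
"""

import numpy as np

from connectodiff import (
    AnalysisConfig,
    DisruptionSpec,
    SimulationSpec,
    composite_hubness,
    group_mean_hubness,
    node_metrics,
    simulate_cohort,
    vulnerability_curve,
)

cohort = simulate_cohort(
    SimulationSpec(
        n_nodes=100,
        groups=(("HC", 8), ("PATIENT", 8)),
        disruption=DisruptionSpec(mode="HUB_TARGETED", effect_size=0.5,
                                  target_fraction=0.1, hub_quantile=0.9),
        rng_seed=31,
    )
)
profiles = {
    sid: composite_hubness(sid, node_metrics(cohort.matrices[sid]))
    for sid in cohort.manifest.subjects_in("HC")
}
hubness = group_mean_hubness(profiles, cohort.manifest, "HC")
pos = {nid: i for i, nid in enumerate(cohort.node_table.node_ids)}
disrupted = np.array([[pos[a], pos[b]] for a, b in cohort.truth.disrupted_edges])

curve = vulnerability_curve(
    hubness, disrupted, "BAND", AnalysisConfig(n_null_nodesets=1000), seed=31
)
print(" k    observed  null_mean  ci_high  exceeds")
for k, o, m, h, e in zip(curve.k_grid, curve.observed, curve.null_mean,
                         curve.ci_high, curve.exceedances()):
    if np.isfinite(o):
        print(f"{k:.2f}   {o:.3f}     {m:.3f}    {h:.3f}   {'*' if e else ''}")
print("Stars above the 97.5th null percentile at high k show that disrupted")
print("edges preferentially attach to hub nodes, as planted.")
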