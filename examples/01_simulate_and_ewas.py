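"""Simulate a case/control islet cohort and run the per-site EWAS.

A cohort of 75 controls and 25 cases is generated with 10-percentage-point
methylation differences planted at 2% of sites.  Probes failing quality
flags are removed, M-values are regressed on group plus clinical
covariates, and the top associations are printed with their effect sizes
on the interpretable beta (%) scale.
"""

from isletepi import CohortConfig, filter_probes, run_ewas, simulate_cohort

cfg = CohortConfig(
    n_controls=75, n_cases=25, n_sites=2000, n_genes=200,
    frac_differential=0.02, planted_delta_pp=10.0,
    n_excluded_probes=50, seed=11,
)
matrix, samples, manifest, degs, truth = simulate_cohort(cfg)
print(f"cohort: {matrix.shape[0]} probes x {matrix.shape[1]} samples")

retained, report = filter_probes(manifest)
matrix = matrix.subset_probes([p for p in retained if p in set(matrix.probe_ids)])
removed = {k: v for k, v in report.items() if k != "retained" and v}
print(f"probe filter removed {removed}, retained {report['retained']}")

result = run_ewas(matrix, samples, "binary")
sig = result.significant(0.05)
print(f"{len(sig)} sites significant at q < 0.05 "
      f"(planted: {int(truth.sites['is_differential'].sum())})")

top = result.table.nsmallest(5, "q_value")
cols = ["probe_id", "delta_beta_pp", "relative_change_pct", "q_value"]
print("\ntop associations:")
print(top[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
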