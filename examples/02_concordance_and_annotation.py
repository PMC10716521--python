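"""Cross-phenotype concordance and regulatory annotation of EWAS hits.

The same cohort is analysed against case/control status and against
HbA1c.  Sites significant in both analyses with the same direction of
effect form the concordant set, which is then located relative to open
chromatin, transcription-factor tracks and chromatin states.
"""

from isletepi import (
    CohortConfig,
    concordant_sites,
    multi_track_membership,
    overlap_sites_track,
    run_ewas,
    simulate_annotation_tracks,
    simulate_cohort,
)

cfg = CohortConfig(n_sites=2000, n_genes=200, frac_differential=0.03, seed=5)
matrix, samples, manifest, degs, truth = simulate_cohort(cfg)
tracks = simulate_annotation_tracks(manifest, cfg, truth)

ewas_group = run_ewas(matrix, samples, "binary")
ewas_hba1c = run_ewas(matrix, samples, "continuous")

conc = concordant_sites(ewas_group, ewas_hba1c, q_threshold=0.05)
print(f"significant vs group only: {len(conc.a_only)}")
print(f"significant vs HbA1c only: {len(conc.b_only)}")
print(f"concordant (both, same sign): {len(conc.both)} "
      f"{conc.quadrant_counts}")

sites = manifest[manifest["probe_id"].isin(conc.both)][
    ["probe_id", "chromosome", "pos0"]
].reset_index(drop=True)

by_name = {t.name: t for t in tracks}
_, n_ocr = overlap_sites_track(sites, by_name["OCR"])
print(f"\nconcordant sites inside open chromatin: {n_ocr}/{len(sites)}")

tf_tracks = [t for t in tracks if t.name not in ("OCR", "regulome")]
member, tally, venn = multi_track_membership(sites, tf_tracks)
print("sites by number of binding TFs:")
print(tally.rename("n_sites").to_string())
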