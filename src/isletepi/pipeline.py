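"""End-to-end orchestration of the methylation-to-disease pipeline.

Stages: simulate (optional) -> probe filter -> EWAS (case/control) ->
EWAS (HbA1c) -> concordance -> regulatory/gene overlap -> methylation
risk scores -> matched-pair prospective validation.  Every stage writes
plain-text outputs under the run directory, and a machine-readable
manifest records the seed, the configuration echo and per-stage row
counts.  Re-running with the same configuration and seed reproduces
identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .arrayio import (
    filter_probes,
    read_deg_table,
    read_interval_track,
    read_methylation_matrix,
    read_probe_manifest,
    read_sample_table,
    write_interval_track,
)
from .ewas import run_ewas, write_ewas_table
from .integrate import (
    annotate_sites,
    concordant_sites,
    multi_track_membership,
    sites_in_gene_windows,
)
from .mrs import mrs_for_genes, mrs_table
from .prospective import (
    condlogit_table,
    conditional_logistic,
    read_matched_pairs,
    screen_candidate_sites,
    write_matched_pairs,
)
from .simulate import (
    CohortConfig,
    MatchedCohortConfig,
    config_to_dict,
    simulate_annotation_tracks,
    simulate_cohort,
    simulate_matched_blood_cohort,
    write_fixture_set,
)

logger = logging.getLogger("isletepi")

DEFAULT_COVARIATES = ("age", "bmi", "sex", "purity", "days_in_culture")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "isletepi_run"
    seed: int = 0
    # simulate mode: cohort generated in-run; run mode: paths must be set
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_pairs: int = 200
    matched_log_or_per_pp: float = 0.3
    # run-mode input paths
    methylation_path: str | None = None
    samples_path: str | None = None
    manifest_path: str | None = None
    degs_path: str | None = None
    track_paths: dict = field(default_factory=dict)   # name -> BED path
    pairs_path: str | None = None
    # analysis options
    covariates: tuple = DEFAULT_COVARIATES
    q_threshold: float = 0.05
    flank: int = 10_000
    window_anchor: str = "body"
    mrs_weight_scale: str = "beta_pct"
    detection_threshold: float = 0.01

    def validate(self) -> None:
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if not self.simulate:
            for name in ("methylation_path", "samples_path", "manifest_path",
                         "degs_path"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"run mode requires {name}")
                if not Path(path).exists():
                    raise ValueError(f"{name} does not exist: {path}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written
    as ``manifest.json`` in the run directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": {},
    }
    try:
        result = _run_stages(config, out, manifest)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n", encoding="utf-8")
        raise
    (out / "manifest.json").write_text(
        json.dumps(result, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    return result


def _config_echo(config: PipelineConfig) -> dict:
    echo = {
        k: v
        for k, v in vars(config).items()
        if k not in ("cohort",)
    }
    echo["covariates"] = list(config.covariates)
    echo["cohort"] = config_to_dict(config.cohort)
    return echo


def _run_stages(config: PipelineConfig, out: Path, manifest: dict) -> dict:
    stages = manifest["stages"]

    # --- stage: inputs ---------------------------------------------------
    if config.simulate:
        cohort_cfg = config.cohort
        cohort_cfg.seed = config.seed
        matrix, samples, probe_man, degs, truth = simulate_cohort(cohort_cfg)
        tracks = simulate_annotation_tracks(probe_man, cohort_cfg, truth)
        fixture_dir = out / "inputs"
        write_fixture_set(fixture_dir, matrix, samples, probe_man, degs, truth, tracks)
        logger.info("simulated cohort: %d probes x %d samples", *matrix.shape)
        stages["simulate"] = {
            "n_probes": matrix.shape[0],
            "n_samples": matrix.shape[1],
            "n_genes": len(degs),
            "n_planted": int(truth.sites["is_differential"].sum()),
        }
    else:
        matrix = read_methylation_matrix(config.methylation_path)
        samples = read_sample_table(config.samples_path)
        probe_man = read_probe_manifest(config.manifest_path)
        degs = read_deg_table(config.degs_path)
        tracks = [
            read_interval_track(path, name)
            for name, path in sorted(config.track_paths.items())
        ]
        truth = None
        stages["load"] = {"n_probes": matrix.shape[0], "n_samples": matrix.shape[1]}

    # --- stage: probe filter ----------------------------------------------
    retained, report = filter_probes(probe_man, config.detection_threshold)
    retained = [p for p in retained if p in set(matrix.probe_ids)]
    matrix = matrix.subset_probes(retained)
    stages["filter"] = dict(report)
    logger.info("probe filter retained %d probes", len(retained))

    # --- stage: EWAS ------------------------------------------------------
    ewas_bin = run_ewas(matrix, samples, "binary", config.covariates)
    write_ewas_table(ewas_bin, out / "ewas_binary.tsv", config.q_threshold)
    n_sig_bin = int((ewas_bin.table["q_value"] < config.q_threshold).sum())
    stages["ewas_binary"] = {"n_sites": len(ewas_bin.table), "n_significant": n_sig_bin}

    ewas_cont = run_ewas(matrix, samples, "continuous", config.covariates)
    write_ewas_table(ewas_cont, out / "ewas_hba1c.tsv", config.q_threshold)
    n_sig_cont = int((ewas_cont.table["q_value"] < config.q_threshold).sum())
    stages["ewas_hba1c"] = {"n_sites": len(ewas_cont.table), "n_significant": n_sig_cont}

    # --- stage: concordance -------------------------------------------------
    conc = concordant_sites(ewas_bin, ewas_cont, config.q_threshold)
    pd.DataFrame({"probe_id": conc.both}).to_csv(
        out / "concordant_sites.tsv", sep="\t", index=False
    )
    stages["concordance"] = {
        "a_only": len(conc.a_only),
        "b_only": len(conc.b_only),
        "both": len(conc.both),
        "discordant": len(conc.discordant),
        **conc.quadrant_counts,
    }

    # --- stage: overlaps ----------------------------------------------------
    man_kept = probe_man[probe_man["probe_id"].isin(matrix.probe_ids)]
    sig_ids = set(ewas_bin.significant(config.q_threshold)["probe_id"])
    sig_sites = man_kept[man_kept["probe_id"].isin(sig_ids)][
        ["probe_id", "chromosome", "pos0"]
    ].reset_index(drop=True)
    track_by_name = {t.name: t for t in tracks}
    ocr = track_by_name.get("OCR")
    regulome = track_by_name.get("regulome")
    tf_tracks = [t for t in tracks if t.name not in ("OCR", "regulome")]
    annotated = annotate_sites(
        sig_sites, ocr=ocr, tf_tracks=tf_tracks, regulome=regulome,
        genes=degs, flank=config.flank,
    )
    annotated.to_csv(out / "annotated_sites.tsv", sep="\t", index=False)
    overlap_counts = {}
    if ocr is not None:
        overlap_counts["in_ocr"] = int(annotated["in_ocr"].sum())
    if tf_tracks:
        _, tally, _ = multi_track_membership(sig_sites, tf_tracks)
        tally.rename("n_sites").to_csv(out / "tf_membership_tally.tsv", sep="\t",
                                       index_label="n_tfs")
        overlap_counts["tf_any"] = int(tally.iloc[1:].sum())
        overlap_counts["tf_all"] = int(tally.iloc[-1])
    stages["overlap"] = {"n_annotated": len(annotated), **overlap_counts}

    mapping, per_gene = sites_in_gene_windows(
        sig_sites, degs, flank=config.flank, anchor=config.window_anchor
    )
    mapping.to_csv(out / "site_gene_map.tsv", sep="\t", index=False)
    stages["gene_windows"] = {
        "n_pairs": len(mapping),
        "n_genes_hit": int((per_gene > 0).sum()),
    }

    # --- stage: MRS ---------------------------------------------------------
    records = mrs_for_genes(
        matrix, samples, ewas_bin, degs, mapping,
        q_threshold=config.q_threshold, covariates=config.covariates,
        weight_scale=config.mrs_weight_scale,
    )
    mtab = mrs_table(records)
    mtab.to_csv(out / "mrs.tsv", sep="\t", index=False, float_format="%.10g")
    stages["mrs"] = {"n_genes": len(mtab)}

    # --- stage: prospective ---------------------------------------------------
    candidates = screen_candidate_sites(conc, mapping, degs, man_kept)
    stages["screen"] = {"n_candidates": len(candidates)}
    results = []
    if candidates:
        if config.simulate:
            truth_dir = truth.sites.set_index("probe_id")["direction"]
            mc = MatchedCohortConfig(
                n_pairs=config.n_pairs,
                candidate_site_ids=candidates,
                log_or_per_pp=config.matched_log_or_per_pp,
                seed=config.seed,
            )
            pairs = simulate_matched_blood_cohort(mc)
            write_matched_pairs(pairs, out / "matched_pairs.tsv")
        elif config.pairs_path:
            pairs = read_matched_pairs(config.pairs_path)
        else:
            pairs = []
        if pairs:
            for sid in candidates:
                if sid in pairs[0].case_meth:
                    results.append(conditional_logistic(pairs, sid))
    ctab = condlogit_table(results)
    ctab.to_csv(out / "prospective.tsv", sep="\t", index=False, float_format="%.10g")
    stages["prospective"] = {"n_sites_tested": len(ctab)}

    return manifest
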