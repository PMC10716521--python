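"""Synthetic islet-methylation cohorts with planted ground truth.

The generator emulates the structure of a ~100-donor pancreatic-islet
case/control methylation study: a beta-value matrix over CpG sites, a
sample table with the clinical covariates used for adjustment (age, BMI,
sex, islet purity, days in culture), HbA1c for a continuous phenotype,
a probe manifest with genomic coordinates, a differential-expression
table with gene coordinates, regulatory interval tracks, and a
1:1-matched incident-disease blood cohort.  Every planted effect is
recorded in a truth table so downstream stages can be scored against
known truth.

Effects are planted additively on the M (logit) scale and calibrated
numerically — by Gauss-Hermite integration over the measurement noise —
so that the *expected* case-minus-control difference of beta equals the
requested percentage-point effect.  This keeps beta inside (0, 1)
without truncation artifacts.

Randomness: one master integer seed; each generator consumes a fixed,
documented sub-stream (``SeedSequence([seed, offset])``) so adding a new
generator never perturbs the draws of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .arrayio import (
    IntervalTrack,
    MethylationMatrix,
    write_deg_table,
    write_interval_track,
    write_methylation_matrix,
    write_probe_manifest,
    write_sample_table,
)
from .ewas import beta_to_m, m_to_beta

# sub-stream offsets off the master seed (never renumber; append only)
_SUB_BASELINE = 0
_SUB_COVARIATES = 1
_SUB_NOISE = 2
_SUB_TRACKS = 3
_SUB_MATCHED = 4
_SUB_GENES = 5

_LN2 = np.log(2.0)

#: islet-specific transcription factors whose binding tracks are emulated
TF_NAMES = ("FOXA2", "MAFB", "NKX2.2", "NKX6.1", "PDX1")
REGULOME_STATES = (
    "active_promoter",
    "enhancer_I",
    "enhancer_II",
    "enhancer_III",
    "strong_CTCF",
)


def _default_covariate_params() -> dict:
    # means/ranges emulate the islet donor characteristics: age ~61 y
    # (range 43-81), BMI ~26 kg/m^2, purity >=70%, mostly male donors
    return {
        "age": {"mean": 61.4, "sd": 9.0, "min": 43.0, "max": 81.0},
        "bmi": {"mean": 26.3, "sd": 3.5, "min": 18.0, "max": 40.0},
        "sex_male_fraction": 0.63,
        "purity": {"mean": 83.0, "sd": 7.0, "min": 70.0, "max": 100.0},
        "days_in_culture": {"mean": 2.5, "sd": 1.5, "min": 1.0, "max": 9.0},
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic case/control islet cohort."""

    n_controls: int = 75
    n_cases: int = 25
    n_sites: int = 5000
    n_genes: int = 400
    frac_differential: float = 0.02
    planted_delta_pp: float = 10.0
    hba1c_slope_pp_per_unit: float = 0.0
    covariate_params: dict = field(default_factory=_default_covariate_params)
    noise_sd_m: float = 0.5
    frac_hypo: float = 0.77          # fraction of planted sites losing methylation in cases
    sites_per_deg_gene: int = 8      # planted sites are concentrated in this many per gene
    track_overlap_fraction: float = 0.8
    n_excluded_probes: int = 0       # extra probes carrying exclusion flags
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_controls", "n_cases", "n_sites", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"CohortConfig.{name} must be >= 1")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("CohortConfig.frac_differential must lie in [0, 1]")
        if not 0.0 <= self.track_overlap_fraction <= 1.0:
            raise ValueError("CohortConfig.track_overlap_fraction must lie in [0, 1]")
        if self.noise_sd_m <= 0:
            raise ValueError("CohortConfig.noise_sd_m must be > 0")
        pur = self.covariate_params.get("purity", {})
        if pur and not (70.0 <= pur.get("min", 70.0) and pur.get("max", 100.0) <= 100.0):
            raise ValueError("CohortConfig.covariate_params purity must stay in [70, 100]")
        if self.sites_per_deg_gene < 1:
            raise ValueError("CohortConfig.sites_per_deg_gene must be >= 1")


@dataclass
class MatchedCohortConfig:
    """Parameters of the synthetic 1:1-matched prospective blood cohort."""

    n_pairs: int
    candidate_site_ids: list
    log_or_per_pp: float = 0.0
    true_site_ids: list | None = None   # defaults to all candidates
    baseline_mean_pct: float = 50.0
    baseline_sd_pct: float = 1.5
    matching_covariates: tuple = ("age", "sex")
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("MatchedCohortConfig.n_pairs must be >= 2")
        if not self.candidate_site_ids:
            raise ValueError("MatchedCohortConfig.candidate_site_ids must be nonempty")
        if self.true_site_ids is not None:
            extra = set(self.true_site_ids) - set(self.candidate_site_ids)
            if extra:
                raise ValueError(f"true_site_ids not among candidates: {sorted(extra)}")


@dataclass
class TruthTable:
    """Planted ground truth: per-site and per-gene structure."""

    sites: pd.DataFrame   # probe_id, is_differential, direction, planted_delta_pp, gene_id
    genes: pd.DataFrame   # gene_id, is_deg, expression_direction


@dataclass
class MatchedPair:
    """One case and its individually matched control."""

    pair_id: str
    case_meth: dict       # site id -> methylation %
    control_meth: dict
    matching: dict        # shared matching covariates
    case_adjust: dict = field(default_factory=dict)
    control_adjust: dict = field(default_factory=dict)


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(offset)]))


def _gh_nodes(order: int = 41):
    x, w = np.polynomial.hermite.hermgauss(order)
    return x, w / np.sqrt(np.pi)


_GH_X, _GH_W = _gh_nodes()


def expected_beta(m: float, noise_sd: float) -> float:
    """E[beta] when the M-value is N(m, noise_sd^2), by Gauss-Hermite."""
    vals = m_to_beta(m + noise_sd * np.sqrt(2.0) * _GH_X)
    return float(np.dot(_GH_W, vals))


def calibrate_m_shift(beta0: float, delta_pp: float, noise_sd: float) -> float:
    """M-scale shift whose expected beta difference equals delta_pp.

    Solves E[beta(m0 + dm)] - E[beta(m0)] = delta_pp/100 for dm, where the
    expectation integrates over the N(0, noise_sd^2) M-scale noise both
    groups share.  delta_pp may be negative.
    """
    if delta_pp == 0.0:
        return 0.0
    m0 = beta_to_m(beta0)
    base = expected_beta(m0, noise_sd)
    target = base + delta_pp / 100.0
    if not 0.0 < target < 1.0:
        raise ValueError(
            f"planted effect {delta_pp} pp infeasible at baseline beta {beta0:.3f}"
        )

    def f(dm):
        return expected_beta(m0 + dm, noise_sd) - target

    lo, hi = (0.0, 60.0) if delta_pp > 0 else (-60.0, 0.0)
    return float(brentq(f, lo, hi, xtol=1e-12))


def _draw_truncnorm(rng, params, size):
    vals = rng.normal(params["mean"], params["sd"], size)
    return np.clip(vals, params["min"], params["max"])


def _gene_layout(n_genes: int) -> pd.DataFrame:
    """Deterministic gene coordinates: genes of 20 kb spaced 100 kb apart
    along successive chromosomes (200 genes per chromosome), so +-10 kb
    windows never overlap between genes."""
    per_chrom = 200
    rows = []
    for g in range(n_genes):
        chrom = f"chr{g // per_chrom + 1}"
        start = 100_000 + (g % per_chrom) * 100_000
        rows.append((f"gene{g:04d}", chrom, start, start + 20_000, "+"))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])


def simulate_cohort(config: CohortConfig):
    """Generate a full synthetic cohort with planted differential sites.

    Returns
    -------
    (matrix, samples, manifest, degs, truth)
        MethylationMatrix (probes x samples), sample table, probe manifest
        (1-based positions), DEG table and TruthTable.  Bit-identical for
        identical configs (the config seed drives all randomness).
    """
    config.validate()
    n = config.n_controls + config.n_cases
    n_sites = config.n_sites
    n_diff = int(round(config.frac_differential * n_sites))

    rng_base = _rng(config.seed, _SUB_BASELINE)
    rng_cov = _rng(config.seed, _SUB_COVARIATES)
    rng_noise = _rng(config.seed, _SUB_NOISE)
    rng_genes = _rng(config.seed, _SUB_GENES)

    # --- samples & covariates -------------------------------------------
    group = np.array([0] * config.n_controls + [1] * config.n_cases)
    cp = config.covariate_params
    age = _draw_truncnorm(rng_cov, cp["age"], n)
    bmi = _draw_truncnorm(rng_cov, cp["bmi"], n)
    sex = (rng_cov.random(n) < cp["sex_male_fraction"]).astype(int)
    purity = _draw_truncnorm(rng_cov, cp["purity"], n)
    days = np.round(_draw_truncnorm(rng_cov, cp["days_in_culture"], n))
    # HbA1c: controls ~ N(37, 3), cases ~ N(50, 6), clipped to the
    # plausible clinical range [23, 86] mmol/mol
    hba1c = np.where(
        group == 0,
        rng_cov.normal(37.0, 3.0, n),
        rng_cov.normal(50.0, 6.0, n),
    )
    hba1c = np.clip(hba1c, 23.0, 86.0)

    sample_ids = [f"S{i:03d}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group,
            "hba1c": hba1c,
            "age": age,
            "bmi": bmi,
            "sex": sex,
            "purity": purity,
            "days_in_culture": days,
        }
    )

    # --- sites: truth assignment ----------------------------------------
    diff_idx = np.arange(n_diff)           # first n_diff sites are differential
    directions = np.zeros(n_sites, dtype=int)
    if n_diff:
        signs = np.where(rng_base.random(n_diff) < config.frac_hypo, -1, 1)
        directions[diff_idx] = signs

    delta = config.planted_delta_pp / 100.0
    beta0 = np.empty(n_sites)
    if n_diff:
        # keep planted sites away from the boundaries so the full effect fits
        lo = np.where(directions[diff_idx] > 0, 0.10, 0.10 + delta)
        hi = np.where(directions[diff_idx] > 0, 0.90 - delta, 0.90)
        beta0[diff_idx] = lo + rng_base.random(n_diff) * (hi - lo)
    # null sites: bimodal mixture typical of array methylation
    n_null = n_sites - n_diff
    if n_null:
        u = rng_base.random(n_null)
        b = np.empty(n_null)
        lowmask = u < 0.45
        himask = (u >= 0.45) & (u < 0.90)
        b[lowmask] = rng_base.beta(1.5, 8.0, lowmask.sum())
        b[himask] = rng_base.beta(8.0, 1.5, himask.sum())
        mid = ~(lowmask | himask)
        b[mid] = 0.05 + 0.90 * rng_base.random(mid.sum())
        beta0[n_diff:] = np.clip(b, 0.01, 0.99)

    # --- gene layout and site placement ---------------------------------
    genes = _gene_layout(config.n_genes)
    n_deg = int(np.ceil(n_diff / config.sites_per_deg_gene)) if n_diff else 0
    if n_deg > config.n_genes:
        raise ValueError("n_genes too small for the planted differential sites")
    site_gene = np.empty(n_sites, dtype=int)
    if n_diff:
        site_gene[diff_idx] = diff_idx // config.sites_per_deg_gene
    site_gene[n_diff:] = n_deg + (np.arange(n_null) % max(config.n_genes - n_deg, 1))
    positions = np.empty(n_sites, dtype=int)
    gstart = genes["start"].to_numpy()
    gend = genes["end"].to_numpy()
    for i in range(n_sites):
        g = site_gene[i]
        positions[i] = rng_genes.integers(gstart[g], gend[g])
    probe_ids = [f"cg{i:06d}" for i in range(n_sites)]

    manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": genes["chromosome"].to_numpy()[site_gene],
            "position": positions + 1,                 # manifest is 1-based
            "mean_detection_p": rng_genes.random(n_sites) * 0.005,
            "class_flags": [""] * n_sites,
            "gene_id": genes["gene_id"].to_numpy()[site_gene],
        }
    )
    if config.n_excluded_probes:
        flags = ["Y_chromosome", "rs_probe", "ch_probe", "cross_reactive", "polymorphic"]
        extra = pd.DataFrame(
            {
                "probe_id": [f"bad{i:04d}" for i in range(config.n_excluded_probes)],
                "chromosome": ["chrY"] * config.n_excluded_probes,
                "position": np.arange(1, config.n_excluded_probes + 1) * 1000,
                "mean_detection_p": rng_genes.random(config.n_excluded_probes) * 0.005,
                "class_flags": [flags[i % len(flags)] for i in range(config.n_excluded_probes)],
                "gene_id": [""] * config.n_excluded_probes,
            }
        )
        manifest = pd.concat([manifest, extra], ignore_index=True)
    manifest["pos0"] = manifest["position"].astype(int) - 1

    # --- methylation values ---------------------------------------------
    m0 = beta_to_m(beta0)
    dm_case = np.zeros(n_sites)
    slope_m = np.zeros(n_sites)
    for j in diff_idx:
        dm_case[j] = calibrate_m_shift(
            beta0[j], directions[j] * config.planted_delta_pp, config.noise_sd_m
        )
        if config.hba1c_slope_pp_per_unit:
            # local slope of M per unit beta, times the planted pp-per-unit
            dmdb = 1.0 / (_LN2 * beta0[j] * (1.0 - beta0[j]))
            slope_m[j] = directions[j] * config.hba1c_slope_pp_per_unit / 100.0 * dmdb

    # centre HbA1c within group so the slope effect leaves the planted
    # case-control mean difference untouched
    hb_centered = hba1c.copy()
    for g in (0, 1):
        hb_centered[group == g] -= hba1c[group == g].mean()

    M = (
        m0[:, None]
        + dm_case[:, None] * group[None, :]
        + slope_m[:, None] * hb_centered[None, :]
        + rng_noise.normal(0.0, config.noise_sd_m, (n_sites, n))
    )
    beta = m_to_beta(M)
    if config.n_excluded_probes:
        extra_beta = rng_noise.random((config.n_excluded_probes, n)) * 0.9 + 0.05
        beta = np.vstack([beta, extra_beta])
    matrix = MethylationMatrix(
        pd.DataFrame(beta, index=list(manifest["probe_id"]), columns=sample_ids)
    )

    # --- DEG table and truth --------------------------------------------
    is_deg = np.zeros(config.n_genes, dtype=bool)
    is_deg[:n_deg] = True
    # a few decoy DEGs without methylation signal keep selection honest
    n_decoy = min(max(config.n_genes // 20, 2), config.n_genes - n_deg)
    if n_decoy > 0:
        is_deg[n_deg:n_deg + n_decoy] = True
    expr_dir = np.zeros(config.n_genes, dtype=int)
    # expression change typically opposes the planted methylation change
    for g in range(n_deg):
        site_dirs = directions[diff_idx[site_gene[diff_idx] == g]]
        expr_dir[g] = -int(np.sign(site_dirs.sum())) or 1
    if n_decoy > 0:
        expr_dir[n_deg:n_deg + n_decoy] = np.where(
            rng_genes.random(n_decoy) < 0.5, -1, 1
        )
    q_expr = np.where(
        is_deg,
        rng_genes.random(config.n_genes) * 0.01 + 1e-6,
        0.2 + 0.8 * rng_genes.random(config.n_genes),
    )
    degs = genes.copy()
    degs["log2_fold_change"] = expr_dir * (0.4 + 0.6 * rng_genes.random(config.n_genes))
    degs["q_expression"] = q_expr

    truth_sites = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "is_differential": np.arange(n_sites) < n_diff,
            "direction": directions,
            "planted_delta_pp": np.where(
                np.arange(n_sites) < n_diff,
                directions * config.planted_delta_pp,
                0.0,
            ),
            "gene_id": genes["gene_id"].to_numpy()[site_gene],
        }
    )
    truth_genes = pd.DataFrame(
        {"gene_id": genes["gene_id"], "is_deg": is_deg, "expression_direction": expr_dir}
    )
    truth = TruthTable(sites=truth_sites, genes=truth_genes)
    return matrix, samples, manifest, degs, truth


def simulate_annotation_tracks(
    manifest: pd.DataFrame, config: CohortConfig, truth: TruthTable | None = None
):
    """Generate regulatory interval tracks anchored to the cohort layout.

    Returns an open-chromatin (OCR) track, one track per islet-specific
    TF, and a regulome track with chromatin-state labels.  A configurable
    fraction (``config.track_overlap_fraction``) of the planted
    differential sites is covered by each kind of track so the overlap
    stages see signal; background features are scattered over null
    positions.  Deterministic under the config seed.
    """
    if len(manifest) == 0:
        raise ValueError("probe manifest is empty")
    rng = _rng(config.seed, _SUB_TRACKS)
    man = manifest.set_index("probe_id")

    if truth is not None:
        diff_ids = truth.sites.loc[truth.sites["is_differential"], "probe_id"].tolist()
        null_ids = truth.sites.loc[~truth.sites["is_differential"], "probe_id"].tolist()
    else:
        diff_ids, null_ids = [], manifest["probe_id"].tolist()

    frac = config.track_overlap_fraction
    n_cover = int(round(frac * len(diff_ids)))
    covered = list(diff_ids[:n_cover])  # truth order; deterministic

    def _feat_around(pid, half=150):
        row = man.loc[pid]
        start = max(int(row["pos0"]) - half, 0)
        return (row["chromosome"], start, int(row["pos0"]) + half + 1)

    def _background(k):
        ids = list(rng.choice(null_ids, size=min(k, len(null_ids)), replace=False)) if null_ids else []
        return [_feat_around(pid) for pid in ids]

    tracks = []
    # OCR: every covered site plus background
    ocr_feats = [_feat_around(pid) for pid in covered] + _background(50)
    tracks.append(
        IntervalTrack(
            "OCR",
            pd.DataFrame(
                [(c, s, e, None) for c, s, e in ocr_feats],
                columns=["chromosome", "start", "end", "label"],
            ),
        )
    )
    # TF tracks: each covered site belongs to a random nonempty TF subset;
    # a handful of sites are bound by all five
    tf_feats = {tf: [] for tf in TF_NAMES}
    for i, pid in enumerate(covered):
        if i < 6:
            chosen = TF_NAMES
        else:
            k = 1 + rng.integers(0, len(TF_NAMES))
            chosen = tuple(rng.choice(TF_NAMES, size=k, replace=False))
        for tf in chosen:
            tf_feats[tf].append(_feat_around(pid))
    for tf in TF_NAMES:
        feats = tf_feats[tf] + _background(20)
        tracks.append(
            IntervalTrack(
                tf,
                pd.DataFrame(
                    [(c, s, e, tf) for c, s, e in feats],
                    columns=["chromosome", "start", "end", "label"],
                ),
            )
        )
    # regulome: covered sites get a state label, plus background states
    reg_feats = []
    for pid in covered:
        c, s, e = _feat_around(pid)
        reg_feats.append((c, s, e, REGULOME_STATES[rng.integers(0, len(REGULOME_STATES))]))
    for c, s, e in _background(40):
        reg_feats.append((c, s, e, REGULOME_STATES[rng.integers(0, len(REGULOME_STATES))]))
    tracks.append(
        IntervalTrack(
            "regulome",
            pd.DataFrame(reg_feats, columns=["chromosome", "start", "end", "label"]),
        )
    )
    return tracks


def simulate_matched_blood_cohort(config: MatchedCohortConfig):
    """Generate 1:1-matched case/control blood methylation pairs.

    Within each pair the matching covariates are identical by
    construction.  Two candidate methylation profiles are drawn per pair
    and which member becomes the incident case is sampled from the
    conditional-logistic likelihood: P(member A is the case) =
    sigmoid(sum_j beta_j (x_Aj - x_Bj)) with beta_j = log_or_per_pp at
    true candidate sites and 0 elsewhere.  The conditional-logistic
    estimator is therefore consistent for the planted log odds ratio.
    """
    config.validate()
    rng = _rng(config.seed, _SUB_MATCHED)
    sites = list(config.candidate_site_ids)
    true = set(config.true_site_ids if config.true_site_ids is not None else sites)
    beta = np.array([config.log_or_per_pp if s in true else 0.0 for s in sites])

    pairs = []
    for i in range(config.n_pairs):
        matching = {}
        if "age" in config.matching_covariates:
            matching["age"] = float(np.clip(rng.normal(50.0, 7.0), 30.0, 70.0))
        if "sex" in config.matching_covariates:
            matching["sex"] = int(rng.random() < 0.5)
        x_a = np.clip(rng.normal(config.baseline_mean_pct, config.baseline_sd_pct, len(sites)), 0.0, 100.0)
        x_b = np.clip(rng.normal(config.baseline_mean_pct, config.baseline_sd_pct, len(sites)), 0.0, 100.0)
        eta = float(beta @ (x_a - x_b))
        p_a_case = 1.0 / (1.0 + np.exp(-eta))
        a_is_case = rng.random() < p_a_case
        case, ctrl = (x_a, x_b) if a_is_case else (x_b, x_a)
        pairs.append(
            MatchedPair(
                pair_id=f"P{i:04d}",
                case_meth={s: float(v) for s, v in zip(sites, case)},
                control_meth={s: float(v) for s, v in zip(sites, ctrl)},
                matching=matching,
            )
        )
    return pairs


def write_fixture_set(outdir, matrix, samples, manifest, degs, truth, tracks) -> dict:
    """Serialize a full synthetic cohort as plain-text fixtures.

    Returns a mapping of artifact name to written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["methylation"] = outdir / "methylation.tsv"
    write_methylation_matrix(matrix, paths["methylation"])
    paths["samples"] = outdir / "samples.tsv"
    write_sample_table(samples, paths["samples"])
    paths["manifest"] = outdir / "manifest.tsv"
    write_probe_manifest(manifest, paths["manifest"])
    paths["degs"] = outdir / "degs.tsv"
    write_deg_table(degs, paths["degs"])
    paths["truth_sites"] = outdir / "truth_sites.tsv"
    truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False, float_format="%.10g")
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False, float_format="%.10g")
    for track in tracks:
        key = f"track_{track.name}"
        paths[key] = outdir / f"{track.name}.bed"
        write_interval_track(track, paths[key])
    return paths


def matched_pairs_to_frame(pairs) -> pd.DataFrame:
    """Long-format table of matched pairs (one row per member)."""
    rows = []
    for p in pairs:
        for is_case, meth, adj in (
            (1, p.case_meth, p.case_adjust),
            (0, p.control_meth, p.control_adjust),
        ):
            row = {"pair_id": p.pair_id, "is_case": is_case}
            row.update({f"meth_{k}": v for k, v in meth.items()})
            row.update(p.matching)
            row.update(adj)
            rows.append(row)
    return pd.DataFrame(rows)


def config_to_dict(config) -> dict:
    """Plain-dict echo of a config dataclass for run manifests."""
    return asdict(config)
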