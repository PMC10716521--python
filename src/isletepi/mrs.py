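"""Gene-level weighted methylation risk scores (MRS).

An MRS for a gene is the per-sample weighted sum of methylation
percentages over the differentially methylated CpG sites in or near
(+-10 kb) that gene, each weighted by its per-site regression effect
size.  Eligible genes are those with altered expression and more than
five (i.e. at least six) significant sites in their window.  Scores are
then related to disease status with covariate-adjusted linear and
logistic models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .arrayio import MethylationMatrix
from .ewas import beta_to_m

MIN_SITES = 6   # "more than five" differentially methylated sites


@dataclass
class MrsAssociation:
    """Linear and logistic association of one gene's MRS with disease."""

    gene_id: str
    site_ids: list
    weights: np.ndarray
    scores: pd.Series
    linear_beta: float
    linear_se: float
    linear_p: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    logit_p: float
    converged: bool
    separation: bool
    logit_method: str   # "ml", or "firth" when separation forced a penalized fit
    n_imputed: int


def select_mrs_genes(
    ewas,
    degs: pd.DataFrame,
    site_gene_map: pd.DataFrame,
    q_threshold: float = 0.05,
    min_sites: int = MIN_SITES,
):
    """Genes eligible for an MRS: differential expression plus >= min_sites
    significant methylation sites within their +-flank window.

    Parameters
    ----------
    ewas
        EwasResult or its table (needs probe_id, q_value).
    degs
        DEG table with gene_id and q_expression.
    site_gene_map
        probe_id/gene_id mapping from :func:`integrate.sites_in_gene_windows`.
    """
    table = ewas.table if hasattr(ewas, "table") else ewas
    if len(table) == 0 or len(degs) == 0 or len(site_gene_map) == 0:
        return []
    sig_sites = set(table.loc[table["q_value"] < q_threshold, "probe_id"])
    sig_map = site_gene_map[site_gene_map["probe_id"].isin(sig_sites)]
    counts = sig_map.groupby("gene_id")["probe_id"].nunique()
    deg_ids = set(degs.loc[degs["q_expression"] < q_threshold, "gene_id"])
    selected = [g for g, c in counts.items() if c >= min_sites and g in deg_ids]
    return sorted(selected)


def fit_site_weights(
    matrix: MethylationMatrix,
    samples: pd.DataFrame,
    site_ids,
    covariates=("age", "bmi", "sex", "purity", "days_in_culture"),
    scale: str = "beta_pct",
) -> pd.Series:
    """Per-site case/control effect sizes used as MRS weights.

    With ``scale="beta_pct"`` each weight is the group coefficient from an
    OLS of methylation % on group + covariates, so score units read per-%.
    ``scale="m"`` instead uses the M-scale coefficients from the primary
    inference model.
    """
    if scale not in ("beta_pct", "m"):
        raise ValueError("scale must be 'beta_pct' or 'm'")
    tab = samples.copy()
    if "sample_id" in tab.columns:
        tab = tab.set_index("sample_id")
    tab = tab.loc[list(matrix.sample_ids)]
    X = np.column_stack(
        [np.ones(len(tab)), tab["group"].to_numpy(dtype=float)]
        + [tab[c].to_numpy(dtype=float) for c in covariates]
    )
    weights = {}
    for sid in site_ids:
        y = matrix.beta.loc[sid].to_numpy(dtype=float)
        y = 100.0 * y if scale == "beta_pct" else beta_to_m(y)
        ok = ~np.isnan(y)
        coef, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        weights[sid] = float(coef[1])
    return pd.Series(weights, name="weight")


def compute_mrs(matrix: MethylationMatrix, site_ids, weights):
    """Per-sample weighted methylation score.

    score_s = sum_j w_j * (100 * beta_{s,j}).  Missing beta values are
    imputed with that site's cohort mean before summation.

    Returns
    -------
    (scores, n_imputed)
        Series of per-sample scores and the number of imputed cells.
    """
    site_ids = list(site_ids)
    w = np.asarray(weights, dtype=float)
    if len(site_ids) != len(w):
        raise ValueError("site_ids and weights must have equal length")
    unknown = [s for s in site_ids if s not in matrix.beta.index]
    if unknown:
        raise KeyError(f"unknown site id(s): {unknown}")
    block = matrix.beta.loc[site_ids].to_numpy(dtype=float) * 100.0
    n_imputed = int(np.isnan(block).sum())
    if n_imputed:
        site_means = np.nanmean(block, axis=1)
        idx = np.where(np.isnan(block))
        block[idx] = site_means[idx[0]]
    scores = pd.Series(w @ block, index=matrix.sample_ids, name="mrs")
    return scores, n_imputed


def _firth_logit(y: np.ndarray, X: np.ndarray, max_iter: int = 100,
                 tol: float = 1e-8):
    """Firth bias-reduced logistic regression; returns (coef, se) for the
    column-1 predictor.  The Jeffreys-prior penalty keeps estimates finite
    under complete separation."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        XtWX = (X * W[:, None]).T @ X
        try:
            XtWX_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            return float("nan"), float("nan")
        # hat-matrix diagonal h_i = W_i x_i' (X'WX)^-1 x_i
        h = W * np.einsum("ij,jk,ik->i", X, XtWX_inv, X)
        U = X.T @ (y - mu + h * (0.5 - mu))
        step = XtWX_inv @ U
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1.0 - mu)
    try:
        cov = np.linalg.inv((X * W[:, None]).T @ X)
    except np.linalg.LinAlgError:
        return float("nan"), float("nan")
    return float(beta[1]), float(np.sqrt(max(cov[1, 1], 0.0)))


def mrs_association(
    scores: pd.Series,
    samples: pd.DataFrame,
    covariates=("age", "bmi", "sex", "purity", "days_in_culture"),
):
    """Associate an MRS with case/control status.

    Linear: OLS of score on group + covariates (group coefficient is the
    adjusted score difference, cases minus controls).  Logistic: ML fit
    of group on score + covariates; the odds ratio is per unit score with
    a Wald 95% CI.  Complete separation or non-convergence is flagged and
    the model refit by Firth's bias-reduced method, whose penalized
    estimate stays finite; the record then carries ``separation=True``
    and ``logit_method="firth"``.

    Returns
    -------
    dict with keys linear_beta, linear_se, linear_p, odds_ratio,
    or_ci_low, or_ci_high, logit_p, converged, separation, logit_method.
    """
    tab = samples.copy()
    if "sample_id" in tab.columns:
        tab = tab.set_index("sample_id")
    tab = tab.loc[scores.index]
    group = tab["group"].to_numpy(dtype=float)
    cov = np.column_stack([tab[c].to_numpy(dtype=float) for c in covariates]) \
        if covariates else np.empty((len(tab), 0))
    s = scores.to_numpy(dtype=float)

    X_lin = sm.add_constant(np.column_stack([group, cov]), has_constant="add")
    lin = sm.OLS(s, X_lin).fit()
    linear_beta, linear_se, linear_p = lin.params[1], lin.bse[1], lin.pvalues[1]

    X_log = sm.add_constant(np.column_stack([s, cov]), has_constant="add")
    separation = False
    converged = True
    method = "ml"
    coef = se = logit_p = float("nan")
    try:
        import warnings

        with np.errstate(over="ignore", divide="ignore"), warnings.catch_warnings():
            # separation is detected and handled below; the fit-time
            # warnings would only duplicate that signal
            warnings.simplefilter("ignore")
            logit = sm.Logit(group, X_log).fit(disp=0, maxiter=100)
        converged = bool(logit.mle_retvals.get("converged", False))
        coef, se = logit.params[1], logit.bse[1]
        logit_p = float(logit.pvalues[1])
        # runaway coefficient relative to predictor spread = separation
        if not np.isfinite(se) or abs(coef) * np.std(s) > 15 or not converged:
            separation = True
    except Exception:
        separation = True
        converged = False
    if separation:
        # bias-reduced (Firth) fit: finite estimates even under complete
        # separation; reported with method="firth", never silently
        coef, se = _firth_logit(group, X_log)
        method = "firth"
        converged = np.isfinite(coef)
        from scipy import stats as _st
        logit_p = float(2.0 * _st.norm.sf(abs(coef) / se)) if se > 0 else float("nan")
    if not np.isfinite(coef):
        odds_ratio = ci_low = ci_high = logit_p = float("nan")
    else:
        odds_ratio = float(np.exp(coef))
        ci_low = float(np.exp(coef - 1.959963984540054 * se))
        ci_high = float(np.exp(coef + 1.959963984540054 * se))
    return {
        "logit_method": method,
        "linear_beta": float(linear_beta),
        "linear_se": float(linear_se),
        "linear_p": float(linear_p),
        "odds_ratio": odds_ratio,
        "or_ci_low": ci_low,
        "or_ci_high": ci_high,
        "logit_p": logit_p,
        "converged": converged,
        "separation": separation,
    }


def mrs_for_genes(
    matrix: MethylationMatrix,
    samples: pd.DataFrame,
    ewas,
    degs: pd.DataFrame,
    site_gene_map: pd.DataFrame,
    q_threshold: float = 0.05,
    covariates=("age", "bmi", "sex", "purity", "days_in_culture"),
    weight_scale: str = "beta_pct",
):
    """End-to-end MRS stage: select genes, fit weights, score, associate.

    Returns a list of :class:`MrsAssociation`, one per selected gene.
    """
    table = ewas.table if hasattr(ewas, "table") else ewas
    genes = select_mrs_genes(ewas, degs, site_gene_map, q_threshold)
    sig_sites = set(table.loc[table["q_value"] < q_threshold, "probe_id"])
    records = []
    for gene in genes:
        sites = sorted(
            set(site_gene_map.loc[site_gene_map["gene_id"] == gene, "probe_id"])
            & sig_sites
        )
        weights = fit_site_weights(matrix, samples, sites,
                                   covariates=covariates, scale=weight_scale)
        scores, n_imputed = compute_mrs(matrix, sites, weights.to_numpy())
        assoc = mrs_association(scores, samples, covariates=covariates)
        records.append(
            MrsAssociation(
                gene_id=gene,
                site_ids=sites,
                weights=weights.to_numpy(),
                scores=scores,
                n_imputed=n_imputed,
                **assoc,
            )
        )
    return records


def mrs_table(records) -> pd.DataFrame:
    """Tabulate MRS associations for serialization."""
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "n_sites": len(r.site_ids),
                "linear_beta": r.linear_beta,
                "linear_se": r.linear_se,
                "linear_p": r.linear_p,
                "odds_ratio": r.odds_ratio,
                "or_ci_low": r.or_ci_low,
                "or_ci_high": r.or_ci_high,
                "logit_p": r.logit_p,
                "converged": r.converged,
                "separation": r.separation,
                "logit_method": r.logit_method,
                "n_imputed": r.n_imputed,
            }
        )
    return pd.DataFrame(rows)
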