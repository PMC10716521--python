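"""Per-site epigenome-wide association of methylation with a phenotype.

Inference runs on the M scale (log2 odds of methylation), where array
measurement error is closer to homoscedastic, while effect sizes are
reported on the familiar beta (%) scale as unadjusted group means, the
convention used when quoting "absolute methylation differences" between
cases and controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arrayio import MethylationMatrix

#: clipping bound applied to beta before the logit transform, so M-values
#: stay finite at fully (un)methylated sites
BETA_EPS = 1e-6

__all__ = [
    "BETA_EPS",
    "beta_to_m",
    "m_to_beta",
    "bh_fdr",
    "effect_summary",
    "run_ewas",
    "EwasResult",
]


def beta_to_m(beta):
    """Convert methylation beta fractions to M-values, log2(b / (1 - b)).

    Beta is clipped to [BETA_EPS, 1 - BETA_EPS] first so the result is
    always finite.  Accepts scalars or arrays; NaN passes through.

    Raises
    ------
    ValueError
        If any non-missing value lies outside [0, 1].
    """
    b = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (b < 0) | (b > 1)
    if np.any(bad & ~np.isnan(b)):
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(b, BETA_EPS, 1.0 - BETA_EPS)
    out = np.log2(clipped / (1.0 - clipped))
    out = np.where(np.isnan(b), np.nan, out)
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(out)
    return out


def m_to_beta(m):
    """Inverse logit: M-value back to a beta fraction, 2^m / (1 + 2^m).

    Exact inverse of :func:`beta_to_m` away from the clipping bounds.

    Raises
    ------
    ValueError
        If any value is non-finite.
    """
    arr = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("M-values must be finite")
    # numerically stable in both tails
    out = np.where(arr >= 0, 1.0 / (1.0 + 2.0 ** (-arr)),
                   2.0 ** np.clip(arr, -1074, 0) / (1.0 + 2.0 ** np.clip(arr, -1074, 0)))
    if np.isscalar(m) or np.ndim(m) == 0:
        return float(out)
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1, returned in the input order.

    Raises
    ------
    ValueError
        If any p lies outside [0, 1] or is missing.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return np.array([])
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def effect_summary(mean_control_pct: float, mean_case_pct: float):
    """Absolute and relative methylation difference between group means.

    Parameters
    ----------
    mean_control_pct, mean_case_pct
        Group mean methylation in percent (0-100).

    Returns
    -------
    (delta_pp, relative_change_pct)
        delta = case - control in percentage points;
        relative = 100 * delta / control.  The relative change is NaN when
        the control mean is zero (undefined fold change).
    """
    for v in (mean_control_pct, mean_case_pct):
        if not 0.0 <= v <= 100.0:
            raise ValueError("group means must lie in [0, 100] percent")
    delta = mean_case_pct - mean_control_pct
    if mean_control_pct == 0.0:
        relative = 0.0 if delta == 0.0 else float("nan")
    else:
        relative = 100.0 * delta / mean_control_pct
    return delta, relative


@dataclass
class EwasResult:
    """Result of a per-site association scan."""

    table: pd.DataFrame          # one row per retained site
    phenotype: str               # "binary" or "continuous"
    covariates: list
    n_samples: int

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        """Rows with q strictly below the threshold."""
        return self.table[self.table["q_value"] < q_threshold]


def _ols_scan(Y: np.ndarray, X: np.ndarray):
    """Vectorised per-column OLS of Y (n x k sites) on shared design X (n x p).

    Returns coef, se, t, p for the column-1 (phenotype) coefficient, plus a
    rank-deficiency flag.  The phenotype must be column 1 of X (column 0 is
    the intercept).
    """
    n, p = X.shape
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < p:
        k = Y.shape[1]
        nan = np.full(k, np.nan)
        return nan, nan.copy(), nan.copy(), nan.copy(), True
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (X.T @ Y)                       # p x k
    resid = Y - X @ B
    dof = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    coef = B[1, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return coef, se, t, pvals, False


def run_ewas(
    matrix: MethylationMatrix,
    samples: pd.DataFrame,
    phenotype: str = "binary",
    covariates=("age", "bmi", "sex", "purity", "days_in_culture"),
    max_missing_frac: float = 0.10,
) -> EwasResult:
    """Covariate-adjusted linear-model scan of methylation on a phenotype.

    For each site, M-values are regressed on the phenotype plus covariates
    by ordinary least squares and the phenotype coefficient is tested with
    a two-sided t test; p-values across all retained sites are adjusted
    once with Benjamini-Hochberg.  In binary mode the table also carries
    unadjusted group means of beta (%) with the absolute (percentage-point)
    and relative (%) difference.

    Parameters
    ----------
    matrix
        Methylation beta values, probes x samples.
    samples
        Sample table indexed (or keyed by a ``sample_id`` column) to the
        matrix columns.  Binary mode needs a ``group`` column coded
        control=0 / case=1 (or the strings "control"/"case"); continuous
        mode needs an ``hba1c`` column.
    phenotype
        "binary" or "continuous".
    covariates
        Column names entered as adjustment terms.
    max_missing_frac
        Probes missing in more than this fraction of samples are dropped
        before modelling; remaining missing values are handled per site by
        complete-case analysis.
    """
    if phenotype not in ("binary", "continuous"):
        raise ValueError("phenotype must be 'binary' or 'continuous'")
    tab = samples.copy()
    if "sample_id" in tab.columns:
        tab = tab.set_index("sample_id")
    tab = tab.loc[list(matrix.sample_ids)]

    pheno_col = "group" if phenotype == "binary" else "hba1c"
    if pheno_col not in tab.columns:
        raise ValueError(f"sample table lacks phenotype column '{pheno_col}'")
    missing_cov = [c for c in covariates if c not in tab.columns]
    if missing_cov:
        raise ValueError(f"sample table lacks covariate column(s) {missing_cov}")

    y_pheno = tab[pheno_col]
    if phenotype == "binary" and y_pheno.dtype == object:
        y_pheno = y_pheno.map({"control": 0, "case": 1})
        if y_pheno.isna().any():
            raise ValueError("group labels must be 'control'/'case' or 0/1")
    pheno = y_pheno.to_numpy(dtype=float)

    cov = tab.loc[:, list(covariates)].to_numpy(dtype=float)
    n = len(tab)
    X = np.column_stack([np.ones(n), pheno, cov])
    p = X.shape[1]

    beta = matrix.beta.to_numpy(dtype=float)      # probes x samples
    # drop probes with too many missing samples
    miss_frac = np.isnan(beta).mean(axis=1)
    keep = miss_frac <= max_missing_frac
    probe_ids = np.asarray(matrix.probe_ids)[keep]
    beta = beta[keep]
    M = beta_to_m(beta)

    row_bad = np.isnan(X).any(axis=1)
    k = beta.shape[0]
    coef = np.full(k, np.nan)
    se = np.full(k, np.nan)
    tstat = np.full(k, np.nan)
    pval = np.full(k, np.nan)
    n_used = np.zeros(k, dtype=int)
    flagged = np.zeros(k, dtype=bool)

    complete = ~np.isnan(M).any(axis=0) & ~row_bad   # samples complete everywhere
    site_complete = ~np.isnan(M[:, ~row_bad]).any(axis=1)

    # fast path: sites fully observed share one design matrix
    full_rows = ~row_bad
    fast = np.where(site_complete)[0]
    if fast.size:
        Yf = M[np.ix_(fast, np.where(full_rows)[0])].T
        Xf = X[full_rows]
        if Xf.shape[0] >= p + 2:
            c, s, t, pv, rd = _ols_scan(Yf, Xf)
            coef[fast], se[fast], tstat[fast], pval[fast] = c, s, t, pv
            n_used[fast] = Xf.shape[0]
            flagged[fast] = rd
        else:
            flagged[fast] = True
    # slow path: per-site complete cases
    for i in np.where(~site_complete)[0]:
        rows = full_rows & ~np.isnan(M[i])
        if rows.sum() < p + 2:
            flagged[i] = True
            continue
        c, s, t, pv, rd = _ols_scan(M[i, rows][:, None], X[rows])
        coef[i], se[i], tstat[i], pval[i] = c[0], s[0], t[0], pv[0]
        n_used[i] = int(rows.sum())
        flagged[i] = rd

    out = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "coefficient_m": coef,
            "se_m": se,
            "t_statistic": tstat,
            "p_value": pval,
            "n_used": n_used,
            "flagged": flagged,
        }
    )
    ok = out["p_value"].notna()
    q = np.full(k, np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_fdr(out.loc[ok, "p_value"].to_numpy())
    out["q_value"] = q

    if phenotype == "binary":
        with np.errstate(invalid="ignore"):
            ctrl_mean = np.nanmean(beta[:, pheno == 0], axis=1) * 100.0
            case_mean = np.nanmean(beta[:, pheno == 1], axis=1) * 100.0
        delta = case_mean - ctrl_mean
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(ctrl_mean > 0, 100.0 * delta / ctrl_mean, np.nan)
        out["mean_beta_control_pct"] = ctrl_mean
        out["mean_beta_case_pct"] = case_mean
        out["delta_beta_pp"] = delta
        out["relative_change_pct"] = rel

    return EwasResult(table=out, phenotype=phenotype,
                      covariates=list(covariates), n_samples=n)


def write_ewas_table(result: EwasResult, path, q_threshold: float = 0.05) -> None:
    """Write an EWAS table as TSV with a provenance header comment."""
    from . import __version__

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# isletepi {__version__} EWAS: phenotype={result.phenotype} "
            f"covariates={','.join(result.covariates)} n={result.n_samples} "
            f"q_threshold={q_threshold}\n"
        )
        result.table.to_csv(fh, sep="\t", index=False)
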