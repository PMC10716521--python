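"""Prospective validation: candidate screening and matched-pair inference.

Candidate CpG sites are those associated with both disease status and
HbA1c in islets (sign-concordant) and lying within +-10 kb of a
differentially expressed gene.  Their association with incident disease
in blood is estimated from 1:1-matched case/control pairs by conditional
logistic regression, which for 1:1 matching is equivalent to logistic
regression without intercept on the within-pair (case - control)
differences of the predictor and adjustment covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MAX_ITER = 50
LL_TOL = 1e-10
SEPARATION_BOUND = 15.0   # |coefficient * predictor spread| beyond this flags separation


@dataclass
class CondLogitResult:
    """Conditional-logistic estimate for one candidate site."""

    site_id: str
    coefficient: float        # log odds per methylation %
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_informative_pairs: int
    converged: bool
    separation: bool


def screen_candidate_sites(concordance, site_gene_map: pd.DataFrame,
                           degs: pd.DataFrame, manifest: pd.DataFrame | None = None):
    """Sites in the concordant 'both' set that map to >= 1 DEG window.

    Ordering is deterministic: by chromosome then position when a manifest
    is supplied, lexicographic by probe id otherwise.
    """
    both = set(concordance.both if hasattr(concordance, "both") else concordance)
    if not both or len(site_gene_map) == 0 or len(degs) == 0:
        return []
    deg_ids = set(degs.loc[degs["q_expression"] < 0.05, "gene_id"]) \
        if "q_expression" in degs.columns else set(degs["gene_id"])
    mapped = set(
        site_gene_map.loc[site_gene_map["gene_id"].isin(deg_ids), "probe_id"]
    )
    candidates = both & mapped
    if manifest is not None:
        man = manifest.set_index("probe_id")
        key = {
            pid: (str(man.loc[pid, "chromosome"]), int(man.loc[pid, "position"]))
            for pid in candidates
        }
        return sorted(candidates, key=lambda pid: key[pid])
    return sorted(candidates)


def _pair_differences(pairs, site_id: str, adjust_covariates=()):
    """Case-minus-control difference matrix (pairs x predictors)."""
    rows = []
    for p in pairs:
        if site_id not in p.case_meth or site_id not in p.control_meth:
            raise KeyError(f"site {site_id!r} missing from pair {p.pair_id}")
        d = [p.case_meth[site_id] - p.control_meth[site_id]]
        for c in adjust_covariates:
            d.append(p.case_adjust[c] - p.control_adjust[c])
        rows.append(d)
    return np.asarray(rows, dtype=float)


def conditional_logistic(pairs, site_id: str, adjust_covariates=()) -> CondLogitResult:
    """Conditional logistic regression for 1:1 matched pairs at one site.

    Maximizes the conditional likelihood prod_i sigma(beta' d_i) over the
    within-pair differences d_i (case minus control) by Newton iterations
    with step-halving.  Pairs with zero difference in every predictor are
    non-informative and dropped from the likelihood.  Wald 95% CI; the
    predictor is methylation %, so the coefficient reads per percentage
    point.
    """
    if len(pairs) < 2:
        raise ValueError("at least 2 pairs required")
    D = _pair_differences(pairs, site_id, adjust_covariates)
    informative = ~np.all(D == 0.0, axis=1)
    D = D[informative]
    n_inf = int(informative.sum())

    def _flagged(converged=False, separation=False):
        nan = float("nan")
        return CondLogitResult(
            site_id=site_id, coefficient=nan, se=nan, odds_ratio=nan,
            ci_low=nan, ci_high=nan, p_value=nan,
            n_informative_pairs=n_inf, converged=converged, separation=separation,
        )

    if n_inf == 0:
        return _flagged()

    k = D.shape[1]
    beta = np.zeros(k)
    # RMS difference: nonzero whenever any pair is informative, so the
    # standardized-coefficient separation guard also catches one-sided data
    scale = float(np.sqrt(np.mean(D[:, 0] ** 2))) or 1.0

    def loglik(b):
        eta = D @ b
        # log sigma(eta), numerically stable
        return float(-np.sum(np.logaddexp(0.0, -eta)))

    ll = loglik(beta)
    converged = False
    separation = False
    for _ in range(MAX_ITER):
        eta = D @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        grad = D.T @ (1.0 - p)
        W = p * (1.0 - p)
        H = (D * W[:, None]).T @ D
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        # step-halving to guarantee likelihood ascent
        t = 1.0
        new_ll = loglik(beta + step)
        while new_ll < ll and t > 1e-8:
            t *= 0.5
            new_ll = loglik(beta + t * step)
        beta = beta + t * step
        if abs(beta[0]) * scale > SEPARATION_BOUND:
            separation = True
            break
        if abs(new_ll - ll) < LL_TOL:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    if separation:
        return _flagged(separation=True)

    eta = D @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    W = p * (1.0 - p)
    H = (D * W[:, None]).T @ D
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return _flagged(converged=converged, separation=True)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    coef = float(beta[0])
    z = 1.959963984540054
    from scipy import stats
    pval = float(2.0 * stats.norm.sf(abs(coef) / se)) if se > 0 else float("nan")
    return CondLogitResult(
        site_id=site_id,
        coefficient=coef,
        se=se,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p_value=pval,
        n_informative_pairs=n_inf,
        converged=converged,
        separation=False,
    )


def condlogit_table(results) -> pd.DataFrame:
    """Tabulate conditional-logistic results (one row per site)."""
    return pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "coefficient": r.coefficient,
                "se": r.se,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "n_informative_pairs": r.n_informative_pairs,
                "converged": r.converged,
                "separation": r.separation,
            }
            for r in results
        ]
    )


def read_matched_pairs(source):
    """Read matched pairs from TSV: one row per member, columns pair_id,
    is_case, meth_<site>..., plus optional covariate columns."""
    from .simulate import MatchedPair

    df = pd.read_csv(source, sep="\t")
    need = {"pair_id", "is_case"}
    if need - set(df.columns):
        raise ValueError("matched-pair table needs pair_id and is_case columns")
    meth_cols = [c for c in df.columns if c.startswith("meth_")]
    other = [c for c in df.columns if c not in need and not c.startswith("meth_")]
    pairs = []
    for pid, grp in df.groupby("pair_id", sort=True):
        if len(grp) != 2 or set(grp["is_case"]) != {0, 1}:
            raise ValueError(f"pair {pid!r} must have exactly one case and one control")
        case = grp[grp["is_case"] == 1].iloc[0]
        ctrl = grp[grp["is_case"] == 0].iloc[0]
        matching = {c: case[c] for c in other if case[c] == ctrl[c]}
        adjust = [c for c in other if c not in matching]
        pairs.append(
            MatchedPair(
                pair_id=str(pid),
                case_meth={c[5:]: float(case[c]) for c in meth_cols},
                control_meth={c[5:]: float(ctrl[c]) for c in meth_cols},
                matching=matching,
                case_adjust={c: float(case[c]) for c in adjust},
                control_adjust={c: float(ctrl[c]) for c in adjust},
            )
        )
    return pairs


def write_matched_pairs(pairs, path) -> None:
    from .simulate import matched_pairs_to_frame

    df = matched_pairs_to_frame(pairs)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
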