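"""Unit and property tests for the per-site association machinery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from isletepi import (
    CohortConfig,
    beta_to_m,
    bh_fdr,
    effect_summary,
    m_to_beta,
    run_ewas,
    simulate_cohort,
)
from isletepi.arrayio import MethylationMatrix


# ---------------------------------------------------------------- transforms

@pytest.mark.parametrize(
    "beta,expected_m",
    [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)],
)
def test_beta_to_m_known_values(beta, expected_m):
    assert beta_to_m(beta) == pytest.approx(expected_m, abs=1e-12)


@pytest.mark.parametrize("m,expected_beta", [(0.0, 0.5), (2.0, 0.8), (-2.0, 0.2)])
def test_m_to_beta_known_values(m, expected_beta):
    assert m_to_beta(m) == pytest.approx(expected_beta, abs=1e-12)


def test_beta_to_m_rejects_out_of_range():
    with pytest.raises(ValueError):
        beta_to_m(1.2)
    with pytest.raises(ValueError):
        beta_to_m(-0.1)


def test_m_to_beta_rejects_non_finite():
    with pytest.raises(ValueError):
        m_to_beta(float("inf"))


@settings(derandomize=True, max_examples=50)
@given(st.floats(min_value=-10.0, max_value=10.0))
def test_transform_round_trip(m):
    """beta_to_m(m_to_beta(m)) is the identity away from clipping."""
    assert beta_to_m(m_to_beta(m)) == pytest.approx(m, abs=1e-9)


def test_beta_to_m_clips_degenerate_beta():
    assert np.isfinite(beta_to_m(0.0))
    assert np.isfinite(beta_to_m(1.0))
    assert beta_to_m(0.0) == pytest.approx(-beta_to_m(1.0), rel=1e-9)


# ---------------------------------------------------------------- BH FDR

def _bh_oracle(p):
    """Literal step-up: q_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def test_bh_fdr_hand_example():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_fdr_degenerate_inputs():
    assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
    assert bh_fdr([0.3])[0] == pytest.approx(0.3)
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_bh_fdr_matches_oracles_on_random_vectors(seed):
    rng = np.random.default_rng(seed)
    p = rng.random(200)
    q = bh_fdr(p)
    assert np.allclose(q, _bh_oracle(p), atol=1e-12)
    assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
def test_bh_fdr_dominates_p_and_preserves_order(p):
    q = bh_fdr(p)
    assert np.all(q >= np.asarray(p) - 1e-15)
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(q[order]) >= -1e-15)


# ---------------------------------------------------------------- effect summary

def test_effect_summary_worked_example():
    """Group means 12.9% vs 23.3% give +10.4 pp and ~+80.6% relative."""
    delta, rel = effect_summary(12.9, 23.3)
    assert delta == pytest.approx(10.4, abs=1e-9)
    assert rel == pytest.approx(80.62015503875969, abs=1e-9)


@pytest.mark.parametrize(
    "ctrl,case,delta,rel",
    [(50.0, 50.0, 0.0, 0.0), (10.0, 5.0, -5.0, -50.0)],
)
def test_effect_summary_arithmetic(ctrl, case, delta, rel):
    d, r = effect_summary(ctrl, case)
    assert d == pytest.approx(delta)
    assert r == pytest.approx(rel)


def test_effect_summary_undefined_relative_change():
    d, r = effect_summary(0.0, 5.0)
    assert d == pytest.approx(5.0)
    assert np.isnan(r)


# ---------------------------------------------------------------- run_ewas

def _toy_samples(n, rng, binary=True):
    tab = pd.DataFrame(
        {
            "sample_id": [f"S{j:03d}" for j in range(n)],
            "age": rng.normal(60, 8, n),
            "bmi": rng.normal(26, 3, n),
            "sex": rng.integers(0, 2, n),
            "purity": rng.uniform(70, 100, n),
            "days_in_culture": rng.integers(1, 6, n),
        }
    )
    if binary:
        tab["group"] = (np.arange(n) >= n // 2).astype(int)
    tab["hba1c"] = rng.normal(40, 6, n)
    return tab


def test_run_ewas_exact_interpolation(rng):
    """Noise-free linear methylation is recovered with zero residual."""
    n = 30
    samples = _toy_samples(n, rng)
    covs = ["age", "bmi"]
    m_values = (
        0.3 * samples["group"].to_numpy()
        + 0.01 * samples["age"].to_numpy()
        - 0.02 * samples["bmi"].to_numpy()
    )
    beta = m_to_beta(m_values)
    mat = MethylationMatrix(
        pd.DataFrame([beta], index=["cg1"], columns=samples["sample_id"])
    )
    res = run_ewas(mat, samples, "binary", covariates=covs)
    row = res.table.iloc[0]
    assert row["coefficient_m"] == pytest.approx(0.3, abs=1e-9)
    assert row["se_m"] == pytest.approx(0.0, abs=1e-7)


@pytest.mark.parametrize("phenotype", ["binary", "continuous"])
def test_run_ewas_matches_statsmodels_oracle(rng, phenotype):
    """Coefficients, se and t equal a per-site statsmodels OLS fit."""
    n, k = 20, 50
    samples = _toy_samples(n, rng)
    beta = rng.uniform(0.05, 0.95, (k, n))
    mat = MethylationMatrix(
        pd.DataFrame(beta, index=[f"cg{i}" for i in range(k)],
                     columns=samples["sample_id"])
    )
    covs = ["age", "bmi", "sex"]
    res = run_ewas(mat, samples, phenotype, covariates=covs)
    pheno = samples["group" if phenotype == "binary" else "hba1c"].to_numpy(float)
    X = sm.add_constant(
        np.column_stack([pheno] + [samples[c].to_numpy(float) for c in covs])
    )
    for i, row in res.table.iterrows():
        fit = sm.OLS(beta_to_m(beta[i]), X).fit()
        assert row["coefficient_m"] == pytest.approx(fit.params[1], abs=1e-8)
        assert row["se_m"] == pytest.approx(fit.bse[1], abs=1e-8)
        assert row["t_statistic"] == pytest.approx(fit.tvalues[1], abs=1e-6)
        assert row["p_value"] == pytest.approx(fit.pvalues[1], abs=1e-8)


def test_run_ewas_q_dominates_p_and_binary_summaries(small_cohort):
    _, (mat, samples, _, _, _) = small_cohort
    res = run_ewas(mat, samples, "binary")
    tab = res.table
    assert (tab["q_value"] >= tab["p_value"] - 1e-12).all()
    expected_delta = tab["mean_beta_case_pct"] - tab["mean_beta_control_pct"]
    assert np.allclose(tab["delta_beta_pp"], expected_delta)
    assert (tab["n_used"] <= res.n_samples).all()


def test_run_ewas_missing_values_complete_case(rng):
    n = 40
    samples = _toy_samples(n, rng)
    beta = rng.uniform(0.2, 0.8, (3, n))
    beta[1, :3] = np.nan                      # 7.5% missing: kept, n_used drops
    beta[2, : int(n * 0.2)] = np.nan          # 20% missing: dropped
    mat = MethylationMatrix(
        pd.DataFrame(beta, index=["cgA", "cgB", "cgC"],
                     columns=samples["sample_id"])
    )
    res = run_ewas(mat, samples, "binary", covariates=["age"])
    assert list(res.table["probe_id"]) == ["cgA", "cgB"]
    assert res.table.set_index("probe_id").loc["cgB", "n_used"] == n - 3


def test_run_ewas_constant_covariate_flagged_not_crash(rng):
    n = 20
    samples = _toy_samples(n, rng)
    samples["purity"] = 80.0   # constant -> collinear with intercept
    beta = rng.uniform(0.2, 0.8, (4, n))
    mat = MethylationMatrix(
        pd.DataFrame(beta, index=[f"cg{i}" for i in range(4)],
                     columns=samples["sample_id"])
    )
    res = run_ewas(mat, samples, "binary", covariates=["age", "purity"])
    assert res.table["flagged"].all()
    assert res.table["p_value"].isna().all()


def test_run_ewas_missing_phenotype_errors(rng):
    samples = _toy_samples(10, rng).drop(columns=["group"])
    beta = rng.uniform(0.2, 0.8, (2, 10))
    mat = MethylationMatrix(
        pd.DataFrame(beta, index=["a", "b"], columns=samples["sample_id"])
    )
    with pytest.raises(ValueError, match="group"):
        run_ewas(mat, samples, "binary", covariates=["age"])


def test_power_monotone_in_effect_size():
    """Recovery of planted sites at q<0.05 never falls as the effect grows."""
    powers = []
    for delta in (2.0, 6.0, 12.0):
        cfg = CohortConfig(
            n_controls=60, n_cases=20, n_sites=400, n_genes=50,
            frac_differential=0.1, planted_delta_pp=delta, seed=7,
        )
        mat, samples, _, _, truth = simulate_cohort(cfg)
        res = run_ewas(mat, samples, "binary")
        tab = res.table.set_index("probe_id")
        true_ids = truth.sites.loc[truth.sites["is_differential"], "probe_id"]
        powers.append((tab.loc[true_ids, "q_value"] < 0.05).mean())
    assert powers[0] <= powers[1] <= powers[2]
    assert powers[2] > 0.8
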