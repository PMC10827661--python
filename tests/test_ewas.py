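"""Association testing: variability filter, surrogate variables, per-probe OLS,
and multiple-testing adjustment against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metwas import (
    CollinearityError,
    MethylationMatrix,
    SurrogateVariables,
    adjust_pvalues,
    estimate_surrogate_variables,
    filter_low_variability,
    run_ewas,
)
from conftest import minimal_pheno, random_matrix


# --- low-variability filter ---------------------------------------------------

def test_filter_removes_lowest_sd_probe():
    rng = np.random.default_rng(0)
    beta = rng.uniform(0.2, 0.8, size=(10, 8))
    beta[4] = 0.5 + rng.normal(0, 1e-4, 8)  # near-constant probe
    matrix = MethylationMatrix([f"cg{i}" for i in range(10)], [f"s{i}" for i in range(8)], beta)
    out = filter_low_variability(matrix, 0.10)
    assert out.n_probes == 9
    assert "cg4" not in set(out.probe_ids)
    # surviving probes keep their original order
    assert list(out.probe_ids) == [p for p in matrix.probe_ids if p != "cg4"]


def test_filter_fraction_zero_is_identity():
    rng = np.random.default_rng(1)
    matrix = random_matrix(rng, 5, 4)
    out = filter_low_variability(matrix, 0.0)
    np.testing.assert_array_equal(out.beta, matrix.beta)


def test_filter_ties_resolved_lexicographically():
    """Duplicated-SD probes drop in probe-id order, matching a brute-force sort."""
    rng = np.random.default_rng(2)
    row = rng.uniform(0.3, 0.7, 6)
    beta = np.vstack([row, row, row, rng.uniform(0.1, 0.9, (3, 6))])
    ids = ["cg_c", "cg_a", "cg_b", "cg_x", "cg_y", "cg_z"]
    matrix = MethylationMatrix(ids, [f"s{i}" for i in range(6)], beta)
    out = filter_low_variability(matrix, 0.34)  # ceil(0.34*6) = 3 probes removed
    sd = beta.std(axis=1, ddof=1)
    brute = [pid for _, pid in sorted(zip(sd, ids))][:3]
    assert set(matrix.probe_ids) - set(out.probe_ids) == set(brute)


def test_filter_rejects_fraction_one():
    rng = np.random.default_rng(3)
    with pytest.raises(ValueError):
        filter_low_variability(random_matrix(rng, 4, 4), 1.0)


# --- surrogate variables ------------------------------------------------------

def test_sv_zero_residuals_degenerate():
    """A matrix exactly spanned by its covariates leaves nothing for SVs."""
    pheno = minimal_pheno(["case"] * 5 + ["control"] * 5)
    status = (pheno["status"] == "case").to_numpy(float)
    beta = np.vstack([0.3 + 0.1 * status, 0.5 - 0.2 * status])
    matrix = MethylationMatrix(["cg0", "cg1"], pheno["sample_id"].to_numpy(), beta)
    svs = estimate_surrogate_variables(matrix, pheno, [], n_sv=2)
    assert svs.degenerate
    np.testing.assert_allclose(svs.components, 0.0)


def test_sv_recovers_hidden_batch():
    """A strong batch on half the probes shows up as the leading component."""
    rng = np.random.default_rng(4)
    n, p = 60, 300
    pheno = minimal_pheno(["case"] * 30 + ["control"] * 30, seed=4)
    batch = rng.permutation(np.repeat([0.0, 1.0], n // 2))
    beta = 0.5 + rng.normal(0, 0.02, (p, n))
    beta[: p // 2] += 0.15 * batch
    matrix = MethylationMatrix(
        [f"cg{i}" for i in range(p)], pheno["sample_id"].to_numpy(), np.clip(beta, 0, 1)
    )
    for method in ("ica", "pca"):
        svs = estimate_surrogate_variables(matrix, pheno, ["age"], n_sv=2, method=method)
        rs = [abs(stats.pearsonr(svs.components[:, j], batch)[0]) for j in range(2)]
        assert max(rs) > 0.9, method


def test_sv_zero_components_is_noop():
    rng = np.random.default_rng(5)
    pheno = minimal_pheno(["case"] * 6 + ["control"] * 6, seed=5)
    matrix = random_matrix(rng, 30, 12)
    svs = estimate_surrogate_variables(matrix, pheno, [], n_sv=0)
    assert svs.n_sv == 0 and svs.components.shape == (12, 0)
    with_sv = run_ewas(matrix, pheno, [], svs)
    without = run_ewas(matrix, pheno, [])
    np.testing.assert_array_equal(with_sv.p_value, without.p_value)


def test_sv_components_mean_zero_and_uncorrelated():
    rng = np.random.default_rng(6)
    pheno = minimal_pheno(["case"] * 20 + ["control"] * 20, seed=6)
    matrix = random_matrix(rng, 100, 40)
    svs = estimate_surrogate_variables(matrix, pheno, ["age", "sex"], n_sv=3)
    np.testing.assert_allclose(svs.components.mean(axis=0), 0.0, atol=1e-9)
    corr = np.corrcoef(svs.components.T)
    assert np.abs(corr - np.eye(3)).max() < 1e-6


# --- per-probe regression -----------------------------------------------------

def test_coefficient_matches_two_sample_t():
    """No-covariate OLS on one probe reproduces the pooled two-sample t-test."""
    pheno = minimal_pheno(["control", "control", "case", "case"])
    matrix = MethylationMatrix(
        ["cg0"], pheno["sample_id"].to_numpy(), np.array([[0.2, 0.3, 0.4, 0.5]])
    )
    res = run_ewas(matrix, pheno, [])
    assert res.coefficient[0] == pytest.approx(0.2, abs=1e-12)
    t, p = stats.ttest_ind([0.4, 0.5], [0.2, 0.3])
    assert t == pytest.approx(2.8284271, abs=1e-6)
    assert res.p_value[0] == pytest.approx(p, abs=1e-12)
    assert res.p_value[0] == pytest.approx(0.10557, abs=1e-4)


def test_null_pvalues_uniform():
    """Random status labels give uniform p-values across 2000 probes."""
    rng = np.random.default_rng(7)
    status = rng.permutation(["case"] * 30 + ["control"] * 30)
    pheno = minimal_pheno(list(status), seed=7)
    matrix = random_matrix(rng, 2000, 60)
    res = run_ewas(matrix, pheno, ["age", "sex"])
    assert stats.kstest(res.p_value, "uniform").pvalue > 0.01


def test_duplicate_covariate_raises_collinearity():
    rng = np.random.default_rng(8)
    pheno = minimal_pheno(["case"] * 10 + ["control"] * 10, seed=8)
    matrix = random_matrix(rng, 20, 20)
    base = run_ewas(matrix, pheno, ["age"])
    dup = SurrogateVariables(
        matrix.sample_ids,
        (pheno["age"].to_numpy() - pheno["age"].mean())[:, None],
        1,
    )
    with pytest.raises(CollinearityError, match="sv_1"):
        run_ewas(matrix, pheno, ["age"], dup)
    assert base is not None


def test_no_covariate_coefficient_is_group_mean_difference():
    rng = np.random.default_rng(9)
    pheno = minimal_pheno(["case"] * 12 + ["control"] * 15, seed=9)
    matrix = random_matrix(rng, 50, 27)
    res = run_ewas(matrix, pheno, [])
    case = matrix.beta[:, :12].mean(axis=1)
    ctrl = matrix.beta[:, 12:].mean(axis=1)
    np.testing.assert_allclose(res.coefficient, case - ctrl, atol=1e-10)


def test_orthogonal_covariate_leaves_status_coefficient():
    rng = np.random.default_rng(10)
    n = 24
    pheno = minimal_pheno(["case"] * 12 + ["control"] * 12, seed=10)
    matrix = random_matrix(rng, 40, n)
    base = run_ewas(matrix, pheno, [])
    # residualize a random covariate against [1, status] to force orthogonality
    status = (pheno["status"] == "case").to_numpy(float)
    Z = np.column_stack([np.ones(n), status])
    v = rng.normal(size=n)
    v -= Z @ np.linalg.lstsq(Z, v, rcond=None)[0]
    svs = SurrogateVariables(matrix.sample_ids, v[:, None], 1)
    with_cov = run_ewas(matrix, pheno, [], svs)
    np.testing.assert_allclose(with_cov.coefficient, base.coefficient, atol=1e-8)


def test_constant_probe_flagged_not_dropped():
    pheno = minimal_pheno(["case"] * 5 + ["control"] * 5)
    beta = np.vstack([np.full(10, 0.5), np.linspace(0.2, 0.8, 10)])
    matrix = MethylationMatrix(["cg0", "cg1"], pheno["sample_id"].to_numpy(), beta)
    res = run_ewas(matrix, pheno, [])
    assert res.probe_ids.size == 2
    assert res.degenerate[0] and not res.degenerate[1]
    assert res.p_value[0] == 1.0 and res.coefficient[0] == 0.0


def test_too_few_samples_raises():
    pheno = minimal_pheno(["case", "control"])
    matrix = MethylationMatrix(["cg0"], pheno["sample_id"].to_numpy(), [[0.4, 0.6]])
    with pytest.raises(ValueError):
        run_ewas(matrix, pheno, [])


# --- p-value adjustment -------------------------------------------------------

def brute_bh(p):
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


def brute_holm(p):
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 0.0
    for j, idx in enumerate(order):
        running = max(running, min(1.0, (m - j) * p[idx]))
        q[idx] = running
    return q


def test_bh_hand_example():
    np.testing.assert_allclose(
        adjust_pvalues(np.array([0.01, 0.02, 0.04]), "bh"), [0.03, 0.03, 0.04], atol=1e-12
    )


def test_bonferroni_single_test():
    assert adjust_pvalues(np.array([0.01]), "bonferroni")[0] == pytest.approx(0.01)


@pytest.mark.parametrize("method", ["bh", "holm", "bonferroni"])
def test_adjustment_matches_brute_force(method):
    oracle = {
        "bh": brute_bh,
        "holm": brute_holm,
        "bonferroni": lambda p: np.minimum(np.asarray(p) * len(p), 1.0),
    }[method]
    rng = np.random.default_rng(11)
    for _ in range(50):
        p = rng.uniform(1e-8, 1.0, rng.integers(1, 40))
        np.testing.assert_allclose(adjust_pvalues(p, method), oracle(p), atol=1e-12)


@pytest.mark.parametrize("method", ["bh", "holm", "bonferroni", "storey_q"])
def test_adjusted_never_below_raw(method):
    rng = np.random.default_rng(12)
    for _ in range(20):
        p = rng.uniform(1e-10, 1.0, 30)
        q = adjust_pvalues(p, method)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)


def test_unknown_method_rejected():
    with pytest.raises(ValueError, match="unknown adjustment"):
        adjust_pvalues(np.array([0.5]), "fdr_magic")
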