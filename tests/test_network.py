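"""Co-methylation network: adjacency, TOM, soft power, module detection,
eigenvectors and module-trait correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from metwas import (
    MethylationMatrix,
    adjacency,
    detect_modules,
    module_eigenvector,
    module_trait_correlation,
    pick_soft_power,
    tom_dissimilarity,
)
from metwas.network import UNASSIGNED, build_network


def make_matrix(beta, probes=None):
    beta = np.asarray(beta, float)
    probes = probes or [f"cg{i:04d}" for i in range(beta.shape[0])]
    return MethylationMatrix(probes, [f"s{i}" for i in range(beta.shape[1])], beta)


def two_block_matrix(seed=0, n_per_block=60, n_samples=80, case_effect=0.0):
    """Two planted correlation blocks; block 1 optionally carries a case effect."""
    rng = np.random.default_rng(seed)
    f1, f2 = rng.normal(size=n_samples), rng.normal(size=n_samples)
    status = np.array(["case"] * (n_samples // 2) + ["control"] * (n_samples - n_samples // 2))
    case = (status == "case").astype(float)
    top = 0.8 * f1 + case_effect * case + 0.3 * rng.normal(size=(n_per_block, n_samples))
    bottom = 0.8 * f2 + 0.3 * rng.normal(size=(n_per_block, n_samples))
    return make_matrix(expit(np.vstack([top, bottom]))), status


# --- adjacency ------------------------------------------------------------------

def test_adjacency_perfect_correlation():
    x = np.linspace(0.1, 0.9, 8)
    matrix = make_matrix(np.vstack([x, 0.1 + 0.5 * x]))
    a = adjacency(matrix, power=1)
    assert a[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_adjacency_power_shrinks_partial_correlations():
    rng = np.random.default_rng(1)
    matrix = make_matrix(rng.uniform(0.2, 0.8, (5, 20)))
    a1 = adjacency(matrix, 1)
    a3 = adjacency(matrix, 3)
    off = ~np.eye(5, dtype=bool)
    inside = (a1 > 0) & (a1 < 1) & off
    assert np.all(a3[inside] < a1[inside])


def test_adjacency_matches_correlation_oracle():
    rng = np.random.default_rng(2)
    beta = rng.uniform(0.1, 0.9, (3, 15))
    matrix = make_matrix(beta)
    a = adjacency(matrix, 4)
    for i in range(3):
        for j in range(3):
            expected = 1.0 if i == j else abs(stats.pearsonr(beta[i], beta[j])[0]) ** 4
            assert a[i, j] == pytest.approx(expected, abs=1e-12)


def test_adjacency_constant_probe_isolated():
    beta = np.vstack([np.full(10, 0.5), np.linspace(0.2, 0.8, 10)])
    a = adjacency(make_matrix(beta), 2)
    assert a[0, 1] == 0.0 and a[0, 0] == 1.0


# --- TOM -------------------------------------------------------------------------

def test_tom_three_node_hand_value():
    """All a = 0.5 on 3 nodes: TOM_12 = (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5."""
    a = np.full((3, 3), 0.5)
    np.fill_diagonal(a, 1.0)
    dis = tom_dissimilarity(a)
    assert dis[0, 1] == pytest.approx(0.5, abs=1e-12)
    assert np.all(np.diag(dis) == 0.0)


def test_tom_four_node_exact_loop_oracle():
    rng = np.random.default_rng(3)
    a = rng.uniform(0, 1, (4, 4))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    dis = tom_dissimilarity(a)
    k = [sum(a[i, u] for u in range(4) if u != i) for i in range(4)]
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(4) if u not in (i, j))
            tom = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
            assert dis[i, j] == pytest.approx(1 - tom, abs=1e-12)


def test_tom_disconnected_pair_fully_dissimilar():
    a = np.eye(2)
    dis = tom_dissimilarity(a)
    assert dis[0, 1] == pytest.approx(1.0)


def test_tom_symmetric_zero_diagonal_on_random_adjacency():
    rng = np.random.default_rng(4)
    beta = rng.uniform(0.1, 0.9, (10, 25))
    a = adjacency(make_matrix(beta), 3)
    dis = tom_dissimilarity(a)
    np.testing.assert_allclose(dis, dis.T, atol=1e-12)
    assert np.all(np.diag(dis) == 0.0)
    assert dis.min() >= 0.0 and dis.max() <= 1.0


# --- soft power ------------------------------------------------------------------

def test_soft_power_fit_table_complete():
    matrix, _ = two_block_matrix(seed=5)
    power, fits = pick_soft_power(matrix, candidate_powers=range(1, 8))
    assert set(fits) == set(range(1, 8))
    assert power >= 1
    assert fits[power] >= fits[1] - 1e-12


def test_soft_power_zero_threshold_returns_smallest():
    matrix, _ = two_block_matrix(seed=6)
    power, _ = pick_soft_power(matrix, candidate_powers=range(1, 6), fit_threshold=0.0)
    assert power == 1


def test_soft_power_constant_matrix_rejected():
    matrix = make_matrix(np.full((4, 6), 0.5))
    with pytest.raises(ValueError):
        pick_soft_power(matrix)


# --- module detection -------------------------------------------------------------

def recovery_agreement(labels, truth_split):
    """Best-case agreement between detected labels and the planted bipartition."""
    labels = np.asarray(labels)
    ids = [l for l in set(labels) if l != UNASSIGNED]
    best = 0.0
    for a in ids:
        for b in ids:
            if a == b:
                continue
            pred = np.where(labels == a, 0, np.where(labels == b, 1, -1))
            best = max(best, np.mean(pred == truth_split))
    return best


def test_planted_partition_recovered():
    matrix, _ = two_block_matrix(seed=7)
    _, modules = build_network(matrix, min_module_size=30)
    real = sorted(set(modules.labels) - {UNASSIGNED})
    assert len(real) == 2
    truth = np.array([0] * 60 + [1] * 60)
    assert recovery_agreement(modules.labels, truth) >= 0.95


def test_single_homogeneous_block_single_module():
    rng = np.random.default_rng(8)
    f = rng.normal(size=60)
    beta = expit(0.8 * f + 0.3 * rng.normal(size=(80, 60)))
    _, modules = build_network(make_matrix(beta), min_module_size=30)
    assert set(modules.labels) == {"module_1"}


def test_module_labels_invariant_to_probe_order():
    matrix, _ = two_block_matrix(seed=9)
    _, modules = build_network(matrix, min_module_size=30)
    rng = np.random.default_rng(9)
    perm = rng.permutation(matrix.n_probes)
    shuffled = MethylationMatrix(
        matrix.probe_ids[perm], matrix.sample_ids, matrix.beta[perm]
    )
    _, modules2 = build_network(shuffled, min_module_size=30)
    map1 = dict(zip(modules.probe_ids, modules.labels))
    map2 = dict(zip(modules2.probe_ids, modules2.labels))
    assert map1 == map2


def test_min_module_size_larger_than_probes_rejected():
    matrix, _ = two_block_matrix(seed=10, n_per_block=10)
    dis = tom_dissimilarity(adjacency(matrix, 2))
    with pytest.raises(ValueError):
        detect_modules(dis, matrix.probe_ids, min_module_size=50)


# --- module eigenvector -----------------------------------------------------------

def test_single_probe_eigenvector_is_standardized_probe():
    rng = np.random.default_rng(11)
    beta = rng.uniform(0.2, 0.8, (3, 12))
    matrix = make_matrix(beta)
    ev = module_eigenvector(matrix, [matrix.probe_ids[1]])
    z = (beta[1] - beta[1].mean()) / beta[1].std()
    np.testing.assert_allclose(np.abs(ev), np.abs(z), atol=1e-10)
    assert stats.pearsonr(ev, beta[1])[0] > 0  # sign convention


def test_eigenvector_matches_top_eigenvector():
    matrix, _ = two_block_matrix(seed=12, n_per_block=20)
    probes = list(matrix.probe_ids[:20])
    ev = module_eigenvector(matrix, probes)
    sub = matrix.select_probes(probes).beta
    z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
    evals, evecs = np.linalg.eigh(z.T @ z)
    top = evecs[:, -1]
    assert abs(stats.pearsonr(ev, top)[0]) == pytest.approx(1.0, abs=1e-10)
    assert ev.std() == pytest.approx(1.0, abs=1e-6)


def test_eigenvector_sign_stable_across_runs():
    matrix, _ = two_block_matrix(seed=13, n_per_block=15)
    probes = list(matrix.probe_ids[:15])
    ev1 = module_eigenvector(matrix, probes)
    ev2 = module_eigenvector(matrix, probes)
    np.testing.assert_array_equal(ev1, ev2)


def test_constant_module_rejected():
    matrix = make_matrix(np.full((3, 6), 0.4))
    with pytest.raises(ValueError):
        module_eigenvector(matrix, list(matrix.probe_ids))


# --- module-trait correlation -------------------------------------------------------

def test_trait_correlation_perfect_and_hand_value():
    status = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    ev = pd.DataFrame({"module_1": status - status.mean()})
    traits = pd.DataFrame({"status": status, "other": [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]})
    table = module_trait_correlation(ev, traits)
    r_status = table.loc[table["trait"] == "status", "r"].iloc[0]
    assert r_status == pytest.approx(1.0, abs=1e-12)
    r_other = table.loc[table["trait"] == "other", "r"].iloc[0]
    expected, _ = stats.pearsonr(status, traits["other"])
    assert r_other == pytest.approx(expected, abs=1e-12)


def test_trait_correlation_missing_values_restricted():
    rng = np.random.default_rng(14)
    ev = pd.DataFrame({"module_1": rng.normal(size=10)})
    sev = rng.normal(size=10)
    sev[5:] = np.nan  # controls have no severity
    table = module_trait_correlation(ev, pd.DataFrame({"severity": sev}))
    assert table["n"].iloc[0] == 5
    expected, _ = stats.pearsonr(ev["module_1"][:5], sev[:5])
    assert table["r"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_trait_zero_variance_flagged():
    ev = pd.DataFrame({"module_1": [0.1, 0.5, -0.2, 0.4]})
    table = module_trait_correlation(ev, pd.DataFrame({"flat": [1.0] * 4}))
    assert bool(table["undefined"].iloc[0])
    assert np.isnan(table["r"].iloc[0])


# --- pipeline-level invariance -------------------------------------------------------

def test_network_invariant_to_sample_order():
    matrix, _ = two_block_matrix(seed=15)
    rng = np.random.default_rng(15)
    perm = rng.permutation(matrix.n_samples)
    shuffled = MethylationMatrix(
        matrix.probe_ids, matrix.sample_ids[perm], matrix.beta[:, perm]
    )
    _, mods1 = build_network(matrix, min_module_size=30)
    _, mods2 = build_network(shuffled, min_module_size=30)
    assert dict(zip(mods1.probe_ids, mods1.labels)) == dict(
        zip(mods2.probe_ids, mods2.labels)
    )
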