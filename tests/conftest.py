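import numpy as np
import pandas as pd
import pytest

from metwas import MethylationMatrix, SimulationConfig, simulate_cohort


def split_sites(matrix, pheno):
    """(matrix, pheno) -> (m_disc, p_disc, m_repl, p_repl) by site, first site = discovery."""
    sites = list(dict.fromkeys(pheno["site"]))
    parts = []
    for site in (sites[0], sites[-1]):
        p = pheno[pheno["site"] == site].reset_index(drop=True)
        m = matrix.select_samples(p["sample_id"].tolist())
        parts.extend([m, p])
    return tuple(parts)


@pytest.fixture(scope="session")
def planted_cohort():
    """Small two-site cohort with strong injected DMPs, shared across tests."""
    config = SimulationConfig(
        n_probes=800,
        sites=(("Berlin", 40, 45), ("Bonn", 30, 28)),
        n_true_dmps=40,
        effect_size_m=0.8,
        seed=11,
    )
    matrix, pheno, truth = simulate_cohort(config)
    return config, matrix, pheno, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Two-site cohort with zero injected effect: the global null."""
    config = SimulationConfig(
        n_probes=1000,
        sites=(("Berlin", 40, 45), ("Bonn", 30, 28)),
        n_true_dmps=0,
        effect_size_m=0.0,
        seed=17,
    )
    matrix, pheno, truth = simulate_cohort(config)
    return config, matrix, pheno, truth


def random_matrix(rng, n_probes, n_samples, prefix="cg"):
    beta = rng.uniform(0.05, 0.95, size=(n_probes, n_samples))
    return MethylationMatrix(
        [f"{prefix}{i:05d}" for i in range(n_probes)],
        [f"s{i:03d}" for i in range(n_samples)],
        beta,
    )


def minimal_pheno(status, site="A", seed=0):
    rng = np.random.default_rng(seed)
    n = len(status)
    pheno = pd.DataFrame(
        {
            "sample_id": [f"s{i:03d}" for i in range(n)],
            "status": status,
            "site": site,
            "age": rng.uniform(20, 60, n),
            "sex": rng.choice(["male", "female"], n),
            "smoking": rng.choice(["yes", "no"], n, p=[0.1, 0.9]),
            "severity": np.nan,
            "severity_post": np.nan,
            "medication": None,
        }
    )
    cf = rng.dirichlet(np.ones(3) * 5, n)
    for k in range(3):
        pheno[f"cf_{k + 1}"] = cf[:, k]
    return pheno
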