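"""Synthetic two-site methylation cohorts.

Generates probe-by-sample beta-value matrices with the statistical structure a
case-control EWAS assumes: per-probe baselines on the logit ("M") scale,
covariate effects (age, sex, smoking, blood cell composition), a per-site batch
shift on a subset of probes, injected case-control effects at a known set of
differentially methylated positions (DMPs), and Gaussian M-scale noise.  A
phenotype table (case/control status, site, demographics, cell fractions,
symptom severity with a pre/post treatment arm) and a ground-truth record of
the injected effects accompany the matrix, so downstream selection procedures
can be scored against known truth.

Effects are additive on the M scale and mapped back to beta via the logistic
transform; this keeps beta in [0, 1] while the generating model stays linear
with approximately Gaussian errors.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SimulationConfig",
    "MethylationMatrix",
    "SimulationTruth",
    "SimulationError",
    "CohortIOError",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "beta_from_m",
    "m_from_beta",
    "PHENOTYPE_COLUMNS",
]

#: Fixed leading columns of the phenotype CSV; cell-fraction columns cf_1..cf_k follow.
PHENOTYPE_COLUMNS = [
    "sample_id",
    "status",
    "site",
    "age",
    "sex",
    "smoking",
    "severity",
    "severity_post",
    "medication",
]


class SimulationError(ValueError):
    """Invalid simulation configuration."""


class CohortIOError(ValueError):
    """Malformed cohort file; message names the file and offending line."""


def beta_from_m(m: np.ndarray) -> np.ndarray:
    """Map M-values (logit2 scale) to beta values in [0, 1]: beta = 2^M / (1 + 2^M)."""
    return expit(np.asarray(m, dtype=float) * np.log(2.0))


def m_from_beta(beta: np.ndarray) -> np.ndarray:
    """Map beta values in (0, 1) to M-values: M = log2(beta / (1 - beta))."""
    b = np.asarray(beta, dtype=float)
    return np.log2(b) - np.log2(1.0 - b)


@dataclass(frozen=True)
class MethylationMatrix:
    """Probes x samples beta-value matrix, the pipeline's universal carrier."""

    probe_ids: np.ndarray
    sample_ids: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        probe_ids = np.asarray(self.probe_ids, dtype=object)
        sample_ids = np.asarray(self.sample_ids, dtype=object)
        beta = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "probe_ids", probe_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "beta", beta)
        if beta.shape != (probe_ids.size, sample_ids.size):
            raise ValueError(
                f"beta shape {beta.shape} inconsistent with "
                f"{probe_ids.size} probes x {sample_ids.size} samples"
            )
        if len(set(probe_ids)) != probe_ids.size:
            raise ValueError("duplicate probe ids")
        if len(set(sample_ids)) != sample_ids.size:
            raise ValueError("duplicate sample ids")
        if beta.size and (np.nanmin(beta) < 0.0 or np.nanmax(beta) > 1.0):
            raise ValueError("beta values must lie in [0, 1]")
        if np.isnan(beta).any():
            raise ValueError("beta values must be finite")

    @property
    def n_probes(self) -> int:
        return self.probe_ids.size

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    def probe_index(self, probes: Sequence[str]) -> np.ndarray:
        """Row indices for the given probe ids; raises KeyError listing any missing."""
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probes if p not in lookup]
        if missing:
            raise KeyError(f"probes not in matrix: {sorted(missing)}")
        return np.array([lookup[p] for p in probes], dtype=int)

    def select_probes(self, probes: Sequence[str]) -> "MethylationMatrix":
        idx = self.probe_index(probes)
        return MethylationMatrix(self.probe_ids[idx], self.sample_ids, self.beta[idx])

    def select_samples(self, samples: Sequence[str]) -> "MethylationMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)}")
        idx = np.array([lookup[s] for s in samples], dtype=int)
        return MethylationMatrix(self.probe_ids, self.sample_ids[idx], self.beta[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.probe_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SimulationTruth:
    """Injected DMP identities and signed M-scale effects, for recovery scoring."""

    dmp_probe_ids: np.ndarray
    dmp_effects_m: np.ndarray
    covariate_loadings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dmp_probe_ids", np.asarray(self.dmp_probe_ids, dtype=object))
        object.__setattr__(self, "dmp_effects_m", np.asarray(self.dmp_effects_m, dtype=float))
        if self.dmp_probe_ids.size != self.dmp_effects_m.size:
            raise ValueError("dmp ids and effects differ in length")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-site cohort generator.

    Defaults emulate the reference study design: two recruitment sites with
    112/136 and 73/63 cases/controls, a desk-scale 20,000-probe array with 300
    injected DMPs, covariate and site-batch structure on the M scale, and a
    Y-BOCS-like severity score coupled to each case's true-DMP burden.

    Attributes
    ----------
    n_probes : total probes simulated.
    sites : (label, n_cases, n_controls) per recruitment site.
    n_true_dmps : probes receiving a case-control effect.
    effect_size_m : case effect magnitude on the M (logit2) scale; per-DMP sign
        is random unless ``effect_sign`` fixes it.  0.5 M-units near beta 0.5
        corresponds to a beta-scale difference of roughly 0.08, within the range
        of reported DMP coefficients.
    covariate_effects : M-scale loading SD per covariate; per-probe loadings are
        drawn N(0, effect^2) and multiply the standardized covariate.
    site_batch_fraction : fraction of probes receiving each site's batch shift.
    noise_sd : SD of per-observation Gaussian M-scale noise.
    severity_coupling : severity points per SD of standardized true-DMP burden
        among cases.
    treatment_effect : mean pre-to-post severity change in the treated arm
        (negative = improvement).
    """

    n_probes: int = 20_000
    sites: tuple = (("Berlin", 112, 136), ("Bonn", 73, 63))
    n_true_dmps: int = 300
    effect_size_m: float = 0.5
    effect_sign: int | None = None  # None: random +/- per DMP; else +1 or -1
    covariate_effects: dict = field(
        default_factory=lambda: {
            "age": 0.004,
            "sex": 0.10,
            "smoking": 0.10,
            "site_batch": 0.30,
            "cell_fraction": 0.40,
        }
    )
    baseline_m_mean: float = 0.0
    baseline_m_sd: float = 1.5
    noise_sd: float = 0.5
    site_batch_fraction: float = 0.20
    n_cell_types: int = 6
    cell_concentration: tuple = (6.0, 3.0, 1.5, 1.5, 2.0, 16.0)
    severity_base: float = 22.0
    severity_sd: float = 5.0
    severity_coupling: float = 2.0
    treatment_effect: float = -8.0
    treatment_sd: float = 5.0
    medication_rate: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes <= 0:
            raise SimulationError("n_probes must be positive")
        if not self.sites:
            raise SimulationError("at least one site required")
        for label, n_cases, n_controls in self.sites:
            if n_cases <= 0 or n_controls <= 0:
                raise SimulationError(f"site {label!r}: case/control counts must be positive")
        if self.n_true_dmps < 0:
            raise SimulationError("n_true_dmps must be >= 0")
        if self.n_true_dmps > self.n_probes:
            raise SimulationError(
                f"n_true_dmps ({self.n_true_dmps}) exceeds n_probes ({self.n_probes})"
            )
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be positive")
        if not 0.0 <= self.site_batch_fraction <= 1.0:
            raise SimulationError("site_batch_fraction must be in [0, 1]")
        if len(self.cell_concentration) != self.n_cell_types:
            raise SimulationError("cell_concentration length must equal n_cell_types")
        if self.effect_sign not in (None, 1, -1):
            raise SimulationError("effect_sign must be None, +1 or -1")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _spawn_rngs(seed: int, n: int) -> list:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[MethylationMatrix, pd.DataFrame, SimulationTruth]:
    """Draw one synthetic cohort: beta matrix, phenotype table, truth record.

    The generating model per probe j and sample i is

        M_ji = b_j + sum_c lambda_cj x_ci + batch_j(site_i) + delta_j * case_i + eps_ji

    with eps ~ N(0, noise_sd^2) and beta = 2^M / (1 + 2^M).  Case severity is
    base + coupling * z(burden) + noise where burden is the sample's signed
    true-DMP beta load.  Identical config (including seed) gives identical
    output arrays.
    """
    config.validate()
    (
        rng_cov,
        rng_load,
        rng_batch,
        rng_dmp,
        rng_noise,
        rng_sev,
        rng_cells,
    ) = _spawn_rngs(config.seed, 7)

    # --- samples and phenotypes ------------------------------------------------
    rows = []
    for label, n_cases, n_controls in config.sites:
        for k in range(n_cases):
            rows.append((f"{label}_case_{k + 1:03d}", "case", label))
        for k in range(n_controls):
            rows.append((f"{label}_ctrl_{k + 1:03d}", "control", label))
    sample_ids = np.array([r[0] for r in rows], dtype=object)
    status = np.array([r[1] for r in rows], dtype=object)
    site = np.array([r[2] for r in rows], dtype=object)
    n_samples = sample_ids.size

    age = np.clip(rng_cov.normal(34.0, 11.0, n_samples), 18.0, 75.0)
    sex = np.where(rng_cov.random(n_samples) < 0.42, "male", "female")
    smoking = np.where(rng_cov.random(n_samples) < 0.08, "yes", "no")
    cells = rng_cells.dirichlet(np.asarray(config.cell_concentration), size=n_samples)

    is_case = (status == "case").astype(float)
    x_age = (age - 35.0) / 10.0
    x_sex = (sex == "male").astype(float)
    x_smoke = (smoking == "yes").astype(float)
    cells_centered = cells - np.asarray(config.cell_concentration) / np.sum(
        config.cell_concentration
    )

    # --- probe-level structure -------------------------------------------------
    P = config.n_probes
    probe_ids = np.array([f"cg{j:08d}" for j in range(1, P + 1)], dtype=object)
    baseline = rng_load.normal(config.baseline_m_mean, config.baseline_m_sd, P)
    eff = config.covariate_effects
    lam_age = rng_load.normal(0.0, eff.get("age", 0.0) or 1e-300, P) if eff.get("age") else np.zeros(P)
    lam_sex = rng_load.normal(0.0, eff.get("sex", 0.0) or 1e-300, P) if eff.get("sex") else np.zeros(P)
    lam_smoke = (
        rng_load.normal(0.0, eff.get("smoking", 0.0) or 1e-300, P) if eff.get("smoking") else np.zeros(P)
    )
    cf_effect = eff.get("cell_fraction", 0.0)
    lam_cells = (
        rng_load.normal(0.0, cf_effect, (P, config.n_cell_types))
        if cf_effect
        else np.zeros((P, config.n_cell_types))
    )

    M = (
        baseline[:, None]
        + lam_age[:, None] * x_age[None, :]
        + lam_sex[:, None] * x_sex[None, :]
        + lam_smoke[:, None] * x_smoke[None, :]
        + lam_cells @ cells_centered.T
    )

    # per-site batch shift on a random subset of probes
    batch_effect = eff.get("site_batch", 0.0)
    batch_masks = {}
    if batch_effect and config.site_batch_fraction > 0:
        n_batch = int(round(config.site_batch_fraction * P))
        for label, _, _ in config.sites:
            mask = rng_batch.choice(P, size=n_batch, replace=False)
            batch_masks[label] = mask
            cols = np.flatnonzero(site == label)
            M[np.ix_(mask, cols)] += batch_effect

    # injected case-control effects
    dmp_idx = np.sort(rng_dmp.choice(P, size=config.n_true_dmps, replace=False))
    if config.effect_sign is None:
        signs = rng_dmp.choice([-1.0, 1.0], size=config.n_true_dmps)
    else:
        signs = np.full(config.n_true_dmps, float(config.effect_sign))
    dmp_effects = signs * config.effect_size_m
    case_cols = np.flatnonzero(is_case == 1.0)
    if config.n_true_dmps:
        M[np.ix_(dmp_idx, case_cols)] += dmp_effects[:, None]

    M += rng_noise.normal(0.0, config.noise_sd, M.shape)
    beta = beta_from_m(M)
    matrix = MethylationMatrix(probe_ids, sample_ids, beta)

    # --- severity coupled to true-DMP burden (cases only) ----------------------
    severity = np.full(n_samples, np.nan)
    if case_cols.size:
        if config.n_true_dmps:
            burden = dmp_effects @ beta[np.ix_(dmp_idx, case_cols)]
            sd = burden.std()
            z = (burden - burden.mean()) / sd if sd > 0 else np.zeros_like(burden)
        else:
            z = np.zeros(case_cols.size)
        sev = (
            config.severity_base
            + config.severity_coupling * z
            + rng_sev.normal(0.0, config.severity_sd, case_cols.size)
        )
        severity[case_cols] = np.clip(sev, 0.0, None)

    # treatment arm: cases of the first site have pre/post severity
    severity_post = np.full(n_samples, np.nan)
    first_site = config.sites[0][0]
    treated = np.flatnonzero((site == first_site) & (status == "case"))
    if treated.size:
        severity_post[treated] = np.clip(
            severity[treated]
            + config.treatment_effect
            + rng_sev.normal(0.0, config.treatment_sd, treated.size),
            0.0,
            None,
        )

    medication = np.full(n_samples, None, dtype=object)
    medication[case_cols] = np.where(
        rng_sev.random(case_cols.size) < config.medication_rate, "yes", "no"
    )

    pheno = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "status": status,
            "site": site,
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "severity": severity,
            "severity_post": severity_post,
            "medication": medication,
        }
    )
    for k in range(config.n_cell_types):
        pheno[f"cf_{k + 1}"] = cells[:, k]

    truth = SimulationTruth(
        dmp_probe_ids=probe_ids[dmp_idx],
        dmp_effects_m=dmp_effects,
        covariate_loadings={
            "age": lam_age,
            "sex": lam_sex,
            "smoking": lam_smoke,
            "cell_fraction": lam_cells,
            "site_batch_probes": {k: probe_ids[v] for k, v in batch_masks.items()},
        },
    )
    return matrix, pheno, truth


# --- cohort I/O ---------------------------------------------------------------

_MATRIX_FILE = "beta_matrix.tsv"
_PHENO_FILE = "phenotypes.csv"
_TRUTH_FILE = "truth.tsv"


def write_cohort(
    matrix: MethylationMatrix,
    phenotypes: pd.DataFrame,
    truth: SimulationTruth | None,
    directory: str | Path,
) -> dict:
    """Write the cohort triple as plain text; returns a name -> path map.

    Beta matrix: TSV, first column ``probe_id``, one column per sample.
    Phenotypes: CSV with the fixed header ``sample_id,status,site,age,sex,
    smoking,severity,severity_post,medication,cf_1..cf_k``.
    Truth: TSV ``probe_id<TAB>effect_m``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    mpath = directory / _MATRIX_FILE
    frame = matrix.to_frame()
    frame.index.name = "probe_id"
    frame.to_csv(mpath, sep="\t", float_format="%.10g")
    paths["matrix"] = mpath

    ppath = directory / _PHENO_FILE
    cf_cols = [c for c in phenotypes.columns if c.startswith("cf_")]
    phenotypes[PHENOTYPE_COLUMNS + cf_cols].to_csv(ppath, index=False, float_format="%.10g")
    paths["phenotypes"] = ppath

    if truth is not None:
        tpath = directory / _TRUTH_FILE
        with open(tpath, "w") as fh:
            fh.write("probe_id\teffect_m\n")
            for pid, eff in zip(truth.dmp_probe_ids, truth.dmp_effects_m):
                fh.write(f"{pid}\t{eff:.10g}\n")
        paths["truth"] = tpath
    return paths


def read_matrix(path: str | Path) -> MethylationMatrix:
    """Read a beta-matrix TSV, enforcing the [0,1] range and unique ids."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    probe_ids = frame.index.to_numpy(dtype=object)
    seen: set = set()
    for lineno, pid in enumerate(probe_ids, start=2):  # header is line 1
        if pid in seen:
            raise CohortIOError(f"{path}:{lineno}: duplicate probe id {pid!r}")
        seen.add(pid)
    beta = frame.to_numpy(dtype=float)
    bad = np.argwhere(~((beta >= 0.0) & (beta <= 1.0)))
    if bad.size:
        r, c = bad[0]
        raise CohortIOError(
            f"{path}:{r + 2}: beta value {beta[r, c]!r} for probe "
            f"{probe_ids[r]!r} outside [0, 1]"
        )
    return MethylationMatrix(probe_ids, frame.columns.to_numpy(dtype=object), beta)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    pheno = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing:
        raise CohortIOError(f"{path}:1: missing phenotype columns {missing}")
    cf_cols = [c for c in pheno.columns if c.startswith("cf_")]
    if cf_cols:
        sums = pheno[cf_cols].sum(axis=1).to_numpy()
        off = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
        if off.size:
            raise CohortIOError(
                f"{path}:{off[0] + 2}: cell fractions sum to {sums[off[0]]:.6f}, not 1"
            )
    bad_sev = pheno.loc[(pheno["status"] == "control") & pheno["severity"].notna()]
    if len(bad_sev):
        lineno = int(bad_sev.index[0]) + 2
        raise CohortIOError(f"{path}:{lineno}: severity present for a control sample")
    return pheno


def read_truth(path: str | Path) -> SimulationTruth:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    if list(frame.columns) != ["probe_id", "effect_m"]:
        raise CohortIOError(f"{path}:1: expected header 'probe_id\\teffect_m'")
    return SimulationTruth(
        dmp_probe_ids=frame["probe_id"].to_numpy(dtype=object),
        dmp_effects_m=frame["effect_m"].to_numpy(dtype=float),
    )


def read_cohort(
    directory: str | Path,
) -> tuple[MethylationMatrix, pd.DataFrame, SimulationTruth | None]:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    matrix = read_matrix(directory / _MATRIX_FILE)
    pheno = read_phenotypes(directory / _PHENO_FILE)
    extra = set(pheno["sample_id"]) - set(matrix.sample_ids)
    if extra:
        raise CohortIOError(
            f"{directory / _PHENO_FILE}: samples absent from matrix: {sorted(extra)}"
        )
    tpath = directory / _TRUTH_FILE
    truth = read_truth(tpath) if tpath.exists() else None
    if truth is not None:
        unknown = set(truth.dmp_probe_ids) - set(matrix.probe_ids)
        if unknown:
            raise CohortIOError(f"{tpath}: truth probes absent from matrix: {sorted(unknown)}")
    return matrix, pheno, truth
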