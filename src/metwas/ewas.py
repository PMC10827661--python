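"""Per-probe covariate-adjusted association testing within one cohort.

The core model is an ordinary least-squares regression of each probe's beta
value on case/control status plus known covariates (age, sex, smoking, blood
cell fractions) and data-driven surrogate variables capturing unmeasured
confounding.  All probes share one design matrix, so the fit is vectorized:
one normal-equation solve yields every probe's coefficient, standard error and
two-sided t-test p-value.

Also here: the low-variability probe filter applied before testing, a
simplified independent-surrogate-variable estimator (independent components of
the residual matrix after removing protected covariates, with a PCA fallback),
and p-value adjustment (Benjamini-Hochberg, Holm, Bonferroni, Storey q).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simcohort import MethylationMatrix, m_from_beta

__all__ = [
    "EwasResult",
    "SurrogateVariables",
    "CollinearityError",
    "filter_low_variability",
    "estimate_surrogate_variables",
    "run_ewas",
    "adjust_pvalues",
    "build_design",
    "ADJUST_METHODS",
]

ADJUST_METHODS = ("bh", "holm", "bonferroni", "storey_q")

_TINY_P = float(np.finfo(float).tiny)


class CollinearityError(ValueError):
    """Design matrix is rank-deficient; message names the collinear columns."""


@dataclass(frozen=True)
class SurrogateVariables:
    """Data-driven confounder components, one column per surrogate variable."""

    sample_ids: np.ndarray
    components: np.ndarray  # samples x n_sv, each column mean-zero
    n_sv: int
    method: str = "ica"
    degenerate: bool = False  # True when the residual matrix had no variance

    def __post_init__(self) -> None:
        comps = np.atleast_2d(np.asarray(self.components, dtype=float))
        if comps.size == 0:
            comps = np.zeros((len(self.sample_ids), 0))
        object.__setattr__(self, "components", comps)
        if comps.shape != (len(self.sample_ids), self.n_sv):
            raise ValueError("components shape inconsistent with sample_ids / n_sv")
        if self.n_sv and not self.degenerate:
            means = comps.mean(axis=0)
            if np.abs(means).max() > 1e-9:
                raise ValueError("surrogate components must be mean-zero")


@dataclass(frozen=True)
class EwasResult:
    """Per-probe association summary for one cohort."""

    probe_ids: np.ndarray
    coefficient: np.ndarray
    std_error: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    method_adjust: str
    n_samples: int
    covariate_names: tuple = ()
    degenerate: np.ndarray | None = None  # flags constant probes (p forced to 1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_ids", np.asarray(self.probe_ids, dtype=object))
        for name in ("coefficient", "std_error", "p_value", "q_value"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.probe_ids.size
        for name in ("coefficient", "std_error", "p_value", "q_value"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} not aligned to probe_ids")
        for name in ("p_value", "q_value"):
            v = getattr(self, name)
            if v.size and (np.nanmin(v) <= 0.0 or np.nanmax(v) > 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.degenerate is None:
            object.__setattr__(self, "degenerate", np.zeros(n, dtype=bool))

    def restrict(self, probes: Sequence[str]) -> "EwasResult":
        """Sub-result for the given probes, in the given order (KeyError if missing)."""
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probes if p not in lookup]
        if missing:
            raise KeyError(f"probes not in result: {sorted(missing)}")
        idx = np.array([lookup[p] for p in probes], dtype=int)
        return EwasResult(
            probe_ids=self.probe_ids[idx],
            coefficient=self.coefficient[idx],
            std_error=self.std_error[idx],
            p_value=self.p_value[idx],
            q_value=self.q_value[idx],
            method_adjust=self.method_adjust,
            n_samples=self.n_samples,
            covariate_names=self.covariate_names,
            degenerate=self.degenerate[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "coefficient": self.coefficient,
                "std_error": self.std_error,
                "p_value": self.p_value,
                "q_value": self.q_value,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def filter_low_variability(
    matrix: MethylationMatrix, fraction: float = 0.10
) -> MethylationMatrix:
    """Drop the ``ceil(fraction * P)`` probes with the lowest beta standard deviation.

    Removing the least variable probes reduces the multiple-testing burden with
    negligible power cost: near-constant probes cannot discriminate groups.
    Ties at the cutoff are broken by probe-id lexicographic order; surviving
    probes keep their original order.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if fraction == 0.0 or matrix.n_probes == 0:
        return matrix
    k = math.ceil(fraction * matrix.n_probes)
    sd = matrix.beta.std(axis=1, ddof=1) if matrix.n_samples > 1 else np.zeros(matrix.n_probes)
    order = sorted(range(matrix.n_probes), key=lambda i: (sd[i], matrix.probe_ids[i]))
    drop = set(order[:k])
    keep = np.array([i for i in range(matrix.n_probes) if i not in drop], dtype=int)
    return MethylationMatrix(matrix.probe_ids[keep], matrix.sample_ids, matrix.beta[keep])


def _encode_column(pheno: pd.DataFrame, name: str) -> np.ndarray:
    col = pheno[name]
    if name == "status":
        return (col.to_numpy() == "case").astype(float)
    if name == "sex":
        return (col.to_numpy() == "male").astype(float)
    if name in ("smoking", "medication"):
        return (col.to_numpy() == "yes").astype(float)
    return col.to_numpy(dtype=float)


def build_design(
    phenotypes: pd.DataFrame,
    covariate_names: Sequence[str],
    svs: SurrogateVariables | None = None,
    include_status: bool = True,
) -> tuple[np.ndarray, list]:
    """Assemble the samples x terms design matrix.

    ``covariate_names`` entries name phenotype columns; the keyword ``"cells"``
    expands to the first k-1 cell-fraction columns (the last is omitted because
    fractions sum to one and would be collinear with the intercept).  Binary
    phenotypes are coded 0/1 (case=1, male=1, yes=1).  Raises
    :class:`CollinearityError` naming offending columns when rank-deficient.
    """
    cols: list[np.ndarray] = [np.ones(len(phenotypes))]
    names: list[str] = ["intercept"]
    if include_status:
        cols.append(_encode_column(phenotypes, "status"))
        names.append("status")
    for name in covariate_names:
        if name == "cells":
            cf_cols = sorted(
                (c for c in phenotypes.columns if c.startswith("cf_")),
                key=lambda c: int(c.split("_")[1]),
            )
            for c in cf_cols[:-1]:
                cols.append(phenotypes[c].to_numpy(dtype=float))
                names.append(c)
        else:
            cols.append(_encode_column(phenotypes, name))
            names.append(name)
    if svs is not None and svs.n_sv:
        for j in range(svs.n_sv):
            cols.append(svs.components[:, j])
            names.append(f"sv_{j + 1}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        guilty = []
        running = X[:, :1]
        for j in range(1, X.shape[1]):
            trial = np.column_stack([running, X[:, j]])
            if np.linalg.matrix_rank(trial) == running.shape[1]:
                guilty.append(names[j])
            else:
                running = trial
        raise CollinearityError(f"collinear design columns: {guilty}")
    return X, names


def estimate_surrogate_variables(
    matrix: MethylationMatrix,
    phenotypes: pd.DataFrame,
    known_covariates: Sequence[str],
    n_sv: int,
    method: str = "ica",
    seed: int = 0,
) -> SurrogateVariables:
    """Estimate surrogate variables from covariate-adjusted residuals.

    Each probe is regressed on status plus the known covariates; the surrogate
    components are then independent components (default, FastICA) or principal
    components of the samples x probes residual matrix.  Components are
    mean-zero and mutually uncorrelated, and deterministic given ``seed``.
    With ``n_sv = 0`` an empty component set is returned.
    """
    sample_ids = matrix.sample_ids
    n = matrix.n_samples
    if n_sv == 0:
        return SurrogateVariables(sample_ids, np.zeros((n, 0)), 0, method)
    if n_sv >= n - len(known_covariates) - 2:
        raise ValueError("n_sv too large for the sample size")
    X, _ = build_design(phenotypes, known_covariates, include_status=True)
    coef, *_ = np.linalg.lstsq(X, matrix.beta.T, rcond=None)
    resid = matrix.beta.T - X @ coef  # samples x probes
    if float(np.abs(resid).max(initial=0.0)) < 1e-12:
        return SurrogateVariables(sample_ids, np.zeros((n, n_sv)), n_sv, method, degenerate=True)
    resid = resid - resid.mean(axis=0, keepdims=True)
    if method == "pca":
        u, s, _ = np.linalg.svd(resid, full_matrices=False)
        comps = u[:, :n_sv] * s[:n_sv]
    elif method == "ica":
        from sklearn.decomposition import FastICA

        ica = FastICA(
            n_components=n_sv, random_state=seed, whiten="unit-variance", max_iter=1000
        )
        comps = ica.fit_transform(resid)
    else:
        raise ValueError(f"unknown surrogate-variable method {method!r}")
    comps = comps - comps.mean(axis=0, keepdims=True)
    return SurrogateVariables(sample_ids, comps, n_sv, method)


def run_ewas(
    matrix: MethylationMatrix,
    phenotypes: pd.DataFrame,
    covariate_names: Sequence[str] = (),
    svs: SurrogateVariables | None = None,
    adjust_method: str = "bh",
    on_m_scale: bool = False,
) -> EwasResult:
    """Per-probe OLS of methylation on case/control status plus covariates.

    The reported coefficient is the status term (case minus control,
    covariate-adjusted, on the beta scale unless ``on_m_scale``); the p-value
    is the two-sided t-test with ``n - p`` residual degrees of freedom.
    Constant probes are retained with coefficient 0 and p = 1, flagged in
    ``degenerate``, so probe indices stay comparable across cohorts.
    """
    order = phenotypes["sample_id"].to_numpy(dtype=object)
    if not np.array_equal(order, matrix.sample_ids):
        matrix = matrix.select_samples(order)
    X, names = build_design(phenotypes, covariate_names, svs, include_status=True)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} samples cannot identify {p} parameters")

    Y = matrix.beta.T  # samples x probes
    if on_m_scale:
        Y = m_from_beta(np.clip(Y, 1e-6, 1.0 - 1e-6))
    xtx_inv = np.linalg.inv(X.T @ X)
    coef_all = xtx_inv @ (X.T @ Y)  # p x P
    resid = Y - X @ coef_all
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    status_idx = names.index("status")
    coef = coef_all[status_idx]
    var_factor = xtx_inv[status_idx, status_idx]
    se = np.sqrt(var_factor * sigma2)

    constant = Y.std(axis=0) == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    pvals = np.clip(pvals, _TINY_P, 1.0)
    coef = np.where(constant, 0.0, coef)
    se = np.where(constant | (se == 0.0), np.inf, se)
    pvals = np.where(constant, 1.0, pvals)

    qvals = adjust_pvalues(pvals, adjust_method)
    return EwasResult(
        probe_ids=matrix.probe_ids,
        coefficient=coef,
        std_error=se,
        p_value=pvals,
        q_value=qvals,
        method_adjust=adjust_method,
        n_samples=n,
        covariate_names=tuple(names[2:]),
        degenerate=constant,
    )


def adjust_pvalues(p_values: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: ``bh``, ``holm``, ``bonferroni`` or ``storey_q``.

    ``storey_q`` scales Benjamini-Hochberg values by the Storey estimate of the
    true-null proportion, floored element-wise at the raw p-value so adjusted
    values never drop below raw ones.  All outputs are clipped to <= 1; BH
    values satisfy step-up monotonicity.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) <= 0.0 or np.nanmax(p) > 1.0:
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "holm":
        return multipletests(p, method="holm")[1]
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "storey_q":
        from .twostage import storey_pi0

        pi0 = storey_pi0(p)
        q = np.minimum(pi0 * multipletests(p, method="fdr_bh")[1], 1.0)
        return np.maximum(q, p)
    raise ValueError(f"unknown adjustment method {method!r}; choose from {ADJUST_METHODS}")
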