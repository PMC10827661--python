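"""Methylation profile scores (MPS) and classifier evaluation.

An MPS is a polygenic-score analogue on CpGs: for individual i,

    MPS_i = sum_j beta_j * m_ji

where m_ji is the beta value of probe j and beta_j is that probe's
case-control association coefficient taken from the discovery cohort only, so
scoring the replication cohort is leakage-free.  A scan over adjusted-p
thresholds builds one score per threshold from the discovery summary
statistics and selects the threshold maximizing out-of-sample AU-ROC (ties
broken toward fewer CpGs).  AU-ROC uses the rank (Mann-Whitney) formulation
with ties counted one half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ewas import EwasResult
from .simcohort import MethylationMatrix

__all__ = [
    "MpsModel",
    "ScanRow",
    "DEFAULT_THRESHOLDS",
    "compute_mps",
    "auroc",
    "threshold_scan",
    "intersect_models",
    "pca_project",
]

#: Adjusted-p thresholds of the top-down scan, loosest first.
DEFAULT_THRESHOLDS = (0.05, 0.01, 1e-4, 1e-5, 1e-10, 1e-20, 1e-30, 1e-40)


@dataclass(frozen=True)
class MpsModel:
    """Ordered probe set with per-probe weights; applying it to a matrix yields one score per sample."""

    probe_ids: np.ndarray
    weights: np.ndarray
    label: str = "mps"
    threshold: float | None = None
    empty: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_ids", np.asarray(self.probe_ids, dtype=object))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.probe_ids.size != self.weights.size:
            raise ValueError("weights not aligned to probe_ids")
        if len(set(self.probe_ids)) != self.probe_ids.size:
            raise ValueError("duplicate probes in model")

    @property
    def n_probes(self) -> int:
        return int(self.probe_ids.size)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        header = {"label": self.label, "threshold": self.threshold, "n_probes": self.n_probes}
        with open(path, "w") as fh:
            fh.write(f"# {json.dumps(header)}\n")
            fh.write("probe_id\tweight\n")
            for pid, w in zip(self.probe_ids, self.weights):
                fh.write(f"{pid}\t{w:.10g}\n")

    @classmethod
    def read(cls, path: str | Path) -> "MpsModel":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first[1:].strip()) if first.startswith("#") else {}
        frame = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            probe_ids=frame["probe_id"].to_numpy(dtype=object),
            weights=frame["weight"].to_numpy(dtype=float),
            label=meta.get("label", "mps"),
            threshold=meta.get("threshold"),
        )


@dataclass(frozen=True)
class ScanRow:
    """One threshold of the scan: probe count and train/test AU-ROC."""

    threshold: float
    n_cpgs: int
    auroc_train: float
    auroc_test: float


def compute_mps(model: MpsModel, matrix: MethylationMatrix) -> np.ndarray:
    """Score every sample: MPS_i = sum_j w_j * beta_ji (raw betas, linear in weights)."""
    if model.n_probes == 0:
        return np.zeros(matrix.n_samples)
    idx = matrix.probe_index(model.probe_ids)  # raises KeyError listing missing probes
    return model.weights @ matrix.beta[idx]


def auroc(scores: np.ndarray, labels: Sequence[str]) -> float:
    """Probability a random case outscores a random control; ties count 1/2.

    Computed from midranks (Mann-Whitney U normalized by n_case * n_control),
    equivalent to brute-force pair counting.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    is_case = labels == "case"
    n1 = int(is_case.sum())
    n0 = scores.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("auroc requires both cases and controls")
    ranks = rankdata(scores)
    u = ranks[is_case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def threshold_scan(
    result_disc: EwasResult,
    matrix_disc: MethylationMatrix,
    pheno_disc: pd.DataFrame,
    matrix_repl: MethylationMatrix,
    pheno_repl: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> tuple[list, MpsModel | None]:
    """Build one MPS per adjusted-p threshold and evaluate both cohorts.

    For each threshold t (descending), the model holds the discovery probes
    with q <= t weighted by their discovery coefficients; ``auroc_train`` is
    in-sample (discovery), ``auroc_test`` out-of-sample (replication).  The
    returned best model maximizes ``auroc_test``; ties prefer fewer CpGs.
    Thresholds selecting zero probes yield a row with NaN AU-ROCs.  The best
    model is chosen on the test cohort only, never on in-sample values.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted in descending order")

    labels_disc = pheno_disc["status"].to_numpy(dtype=object)
    labels_repl = pheno_repl["status"].to_numpy(dtype=object)
    rows: list[ScanRow] = []
    best: MpsModel | None = None
    best_key: tuple | None = None
    for t in thresholds:
        mask = result_disc.q_value <= t
        n_cpgs = int(mask.sum())
        if n_cpgs == 0:
            rows.append(ScanRow(t, 0, float("nan"), float("nan")))
            continue
        model = MpsModel(
            probe_ids=result_disc.probe_ids[mask],
            weights=result_disc.coefficient[mask],
            label="discovery",
            threshold=t,
        )
        a_train = auroc(compute_mps(model, matrix_disc), labels_disc)
        a_test = auroc(compute_mps(model, matrix_repl), labels_repl)
        rows.append(ScanRow(t, n_cpgs, a_train, a_test))
        key = (a_test, -n_cpgs)
        if best_key is None or key > best_key:
            best, best_key = model, key
    return rows, best


def intersect_models(models: Sequence[MpsModel]) -> MpsModel:
    """Intersection of probe sets; weights come from the first model.

    An empty intersection returns an empty model flagged ``empty`` rather than
    failing, so callers can branch on it.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to intersect")
    common = set(models[0].probe_ids)
    for m in models[1:]:
        common &= set(m.probe_ids)
    first = models[0]
    keep = [i for i, p in enumerate(first.probe_ids) if p in common]
    return MpsModel(
        probe_ids=first.probe_ids[keep],
        weights=first.weights[keep],
        label="common",
        threshold=None,
        empty=len(keep) == 0,
    )


def pca_project(
    matrix: MethylationMatrix, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Centered principal-component projection of samples.

    Returns (coordinates: samples x n_components, explained variance per
    component, non-increasing).  The sign of each component is fixed by making
    its largest-magnitude probe loading positive, so output is deterministic.
    """
    if n_components > min(matrix.n_probes, matrix.n_samples):
        raise ValueError("n_components exceeds matrix rank bound")
    X = matrix.beta.T  # samples x probes
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0.0):
        raise ValueError("constant matrix has no principal components")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    coords = u[:, :n_components] * s[:n_components]
    var = (s**2) / (X.shape[0] - 1)
    return coords, var[:n_components]
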