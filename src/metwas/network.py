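"""Weighted co-methylation network analysis over a probe subset.

Follows the weighted-correlation-network recipe: an unsigned adjacency
a_ij = |cor(i,j)|^beta with the soft power beta chosen for approximate
scale-free topology, the topological overlap measure (TOM) turning shared
neighborhood into similarity, average-linkage hierarchical clustering of
1 - TOM with a simplified single-height tree cut into modules of a minimum
size, module eigenvectors (first principal component of the standardized
module submatrix), and module-trait Pearson correlations.

The tree cut here is deliberately simpler than the dynamic hybrid algorithm:
candidate cut heights are the midpoints of the largest merge-distance gaps,
and a multi-module cut is accepted only when its between-module minus
within-module dissimilarity separation clears a margin — otherwise the probes
form a single module.  Undersized branches are reported as unassigned, kept
separate from real modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .simcohort import MethylationMatrix

__all__ = [
    "ComethylationNetwork",
    "ModuleSet",
    "pick_soft_power",
    "adjacency",
    "tom_dissimilarity",
    "detect_modules",
    "module_eigenvector",
    "module_trait_correlation",
    "build_network",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ComethylationNetwork:
    probe_ids: np.ndarray
    power: int
    adjacency: np.ndarray
    tom_dissimilarity: np.ndarray
    scale_free_fit: dict


@dataclass(frozen=True)
class ModuleSet:
    """Module label per probe plus per-module eigenvectors and sizes."""

    probe_ids: np.ndarray
    labels: np.ndarray  # module id per probe; UNASSIGNED for leftovers
    eigenvectors: pd.DataFrame  # samples x modules, unit variance columns
    sizes: dict

    def probes_in(self, module: str) -> np.ndarray:
        return self.probe_ids[self.labels == module]


def adjacency(matrix: MethylationMatrix, power: int) -> np.ndarray:
    """Unsigned soft adjacency a_ij = |pearson(probe_i, probe_j)|^power, diagonal 1.

    Constant probes have undefined correlations; their entries are set to 0
    (isolated node) rather than propagating NaN.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    X = matrix.beta
    sd = X.std(axis=1)
    constant = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    a = np.abs(corr) ** power
    np.fill_diagonal(a, 1.0)
    if constant.any():
        a[constant, :] = 0.0
        a[:, constant] = 0.0
        a[np.diag_indices_from(a)] = 1.0
    return a


def pick_soft_power(
    matrix: MethylationMatrix,
    candidate_powers: Sequence[int] = tuple(range(1, 21)),
    fit_threshold: float = 0.85,
    n_bins: int = 10,
) -> tuple[int, dict]:
    """Choose the soft power approximating scale-free topology.

    For each candidate power, node connectivities k_i = sum_{j != i} a_ij are
    binned on log10 scale and log10(frequency) is regressed on log10(k); the
    fit index is the sign-corrected R^2 (negative slope counts positive).
    Returns the smallest power whose index reaches ``fit_threshold``, else the
    argmax, together with the full power -> index table.
    """
    if matrix.n_probes < 3:
        raise ValueError("need at least 3 probes")
    if matrix.beta.std(axis=1).max() == 0.0:
        raise ValueError("all probes constant; no network structure")
    fits: dict[int, float] = {}
    for power in candidate_powers:
        a = adjacency(matrix, power)
        k = a.sum(axis=1) - 1.0  # exclude the self-edge
        k = k[k > 0]
        if k.size < 3:
            fits[power] = 0.0
            continue
        logk = np.log10(k)
        edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
        counts, _ = np.histogram(logk, bins=edges)
        centers = (edges[:-1] + edges[1:]) / 2.0
        keep = counts > 0
        if keep.sum() < 3:
            fits[power] = 0.0
            continue
        x = centers[keep]
        y = np.log10(counts[keep])
        slope, _, r, _, _ = stats.linregress(x, y)
        fits[power] = float(-np.sign(slope) * r**2)
    for power in candidate_powers:
        if fits[power] >= fit_threshold:
            return power, fits
    best = max(fits, key=lambda p: fits[p])
    return best, fits


def tom_dissimilarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap dissimilarity 1 - TOM, diagonal 0.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i the connectivity excluding the self-edge; high overlap means two
    probes share neighbors as well as a direct edge.
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    shared = a0 @ a0  # entry ij sums a_iu a_uj over u != i, j (diag of a0 is 0)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    if np.any(denom <= 0):
        raise RuntimeError("non-positive TOM denominator; adjacency invalid")
    tom = (shared + a0) / denom
    np.fill_diagonal(tom, 1.0)
    dis = 1.0 - tom
    np.fill_diagonal(dis, 0.0)
    return np.clip(dis, 0.0, 1.0)


def detect_modules(
    tom_dis: np.ndarray,
    probe_ids: Sequence[str],
    min_module_size: int = 30,
    separation_margin: float = 0.05,
) -> np.ndarray:
    """Assign a module label per probe from average-linkage clustering of 1 - TOM.

    Simplified single-height tree cut: candidate heights are midpoints of the
    gaps between consecutive merge distances, tried from the largest gap down.
    The first candidate producing at least two modules of ``min_module_size``
    whose mean between-module minus mean within-module dissimilarity clears
    ``separation_margin`` wins; if none does, all probes form one module.
    Probes in undersized branches are labelled ``unassigned``.  Labels are
    deterministic and invariant to probe order (modules are numbered by size,
    ties by smallest member probe id).
    """
    probe_ids = np.asarray(probe_ids, dtype=object)
    n = probe_ids.size
    if min_module_size > n:
        raise ValueError(f"min_module_size {min_module_size} exceeds {n} probes")
    order = np.argsort(probe_ids)  # canonical order: probe-id sort
    d_sorted = tom_dis[np.ix_(order, order)]
    link = hierarchy.linkage(squareform(d_sorted, checks=False), method="average")

    merge_h = np.sort(link[:, 2])
    gaps = np.diff(merge_h)
    candidates = []
    if gaps.size:
        for gi in np.argsort(gaps)[::-1][:10]:
            if gaps[gi] <= 0:
                continue
            candidates.append((merge_h[gi] + merge_h[gi + 1]) / 2.0)

    best_labels = None
    for height in candidates:  # largest gap first
        cl = hierarchy.fcluster(link, t=height, criterion="distance")
        ids, counts = np.unique(cl, return_counts=True)
        big = ids[counts >= min_module_size]
        if big.size < 2:
            continue
        masks = [cl == i for i in big]
        within, between = [], []
        for i, mi in enumerate(masks):
            sub = d_sorted[np.ix_(mi, mi)]
            within.append(sub[np.triu_indices_from(sub, k=1)].mean())
            for mj in masks[i + 1:]:
                between.append(d_sorted[np.ix_(mi, mj)].mean())
        if float(np.mean(between) - np.mean(within)) > separation_margin:
            best_labels = cl
            break
    labels_sorted = np.full(n, UNASSIGNED, dtype=object)
    if best_labels is not None:
        ids, counts = np.unique(best_labels, return_counts=True)
        big = [(c, i) for i, c in zip(ids, counts) if c >= min_module_size]
        # number modules by decreasing size; ties by smallest member probe id
        keyed = sorted(
            big,
            key=lambda ci: (-ci[0], min(probe_ids[order][best_labels == ci[1]])),
        )
        for rank, (_, cid) in enumerate(keyed, start=1):
            labels_sorted[best_labels == cid] = f"module_{rank}"
    else:
        labels_sorted[:] = "module_1"
    labels = np.empty(n, dtype=object)
    labels[order] = labels_sorted
    return labels


def module_eigenvector(matrix: MethylationMatrix, module_probes: Sequence[str]) -> np.ndarray:
    """First principal component of the standardized module submatrix.

    One value per sample, unit variance, sign aligned so the correlation with
    the module's mean methylation profile is non-negative.
    """
    module_probes = list(module_probes)
    if not module_probes:
        raise ValueError("module is empty")
    sub = matrix.select_probes(module_probes).beta  # probes x samples
    sd = sub.std(axis=1)
    effectively_constant = sd <= 1e-12 * np.maximum(1.0, np.abs(sub).max(axis=1))
    if np.all(effectively_constant):
        raise ValueError("constant module submatrix")
    z = (sub - sub.mean(axis=1, keepdims=True)) / np.where(
        effectively_constant, 1.0, sd
    )[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    ev = vt[0]
    ev = ev / ev.std()
    mean_profile = sub.mean(axis=0)
    if mean_profile.std() > 0 and np.corrcoef(ev, mean_profile)[0, 1] < 0:
        ev = -ev
    return ev


def module_trait_correlation(
    eigenvectors: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and two-sided p per (module, trait), pairwise-complete.

    Traits must be numeric (binary ones coded 0/1 upstream); rows with a
    missing trait value (e.g. severity for controls) are dropped per cell.
    Zero-variance cells are reported with NaN and flagged ``undefined``.
    """
    records = []
    for module in eigenvectors.columns:
        ev = eigenvectors[module].to_numpy(dtype=float)
        for trait in traits.columns:
            tv = traits[trait].to_numpy(dtype=float)
            ok = ~np.isnan(tv) & ~np.isnan(ev)
            n = int(ok.sum())
            if n < 3 or np.std(tv[ok]) == 0.0 or np.std(ev[ok]) == 0.0:
                records.append((module, trait, float("nan"), float("nan"), n, True))
                continue
            r, p = stats.pearsonr(ev[ok], tv[ok])
            records.append((module, trait, float(r), float(p), n, False))
    return pd.DataFrame(
        records, columns=["module", "trait", "r", "p", "n", "undefined"]
    )


def encode_traits(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Numeric trait table for module-trait correlation: status, age, sex, site, smoking, severity."""
    sites = sorted(pd.unique(phenotypes["site"]))
    return pd.DataFrame(
        {
            "status": (phenotypes["status"] == "case").astype(float),
            "age": phenotypes["age"].astype(float),
            "sex": (phenotypes["sex"] == "male").astype(float),
            "site": (phenotypes["site"] == sites[-1]).astype(float),
            "smoking": (phenotypes["smoking"] == "yes").astype(float),
            "severity": phenotypes["severity"].astype(float),
        }
    )


def build_network(
    matrix: MethylationMatrix,
    probes: Sequence[str] | None = None,
    candidate_powers: Sequence[int] = tuple(range(1, 21)),
    fit_threshold: float = 0.85,
    min_module_size: int = 30,
) -> tuple[ComethylationNetwork, ModuleSet]:
    """Soft power -> adjacency -> TOM -> modules -> eigenvectors, in one call."""
    sub = matrix.select_probes(probes) if probes is not None else matrix
    power, fits = pick_soft_power(sub, candidate_powers, fit_threshold)
    adj = adjacency(sub, power)
    dis = tom_dissimilarity(adj)
    labels = detect_modules(dis, sub.probe_ids, min_module_size)
    net = ComethylationNetwork(sub.probe_ids, power, adj, dis, fits)
    modules = sorted(set(labels) - {UNASSIGNED})
    evs = {}
    sizes = {}
    for mod in modules:
        members = sub.probe_ids[labels == mod]
        sizes[mod] = int(members.size)
        evs[mod] = module_eigenvector(sub, members)
    sizes[UNASSIGNED] = int((labels == UNASSIGNED).sum())
    ev_frame = pd.DataFrame(evs, index=sub.sample_ids)
    return net, ModuleSet(sub.probe_ids, labels, ev_frame, sizes)
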