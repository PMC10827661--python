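"""Discovery -> replication probe selection and the two-stage FDR estimator.

A lenient nominal p-value threshold (c1, default 0.05) in the discovery cohort
passes probes forward; the replication cohort then applies a stringent
adjusted-p threshold (c2, default 0.01) computed over the discovery-pass set
only.  Replicated probes whose coefficients disagree in sign between cohorts
are pruned.  The false discovery rate of the whole procedure is estimated by
decomposing the chance that a probe survives both stages while null, with the
doubly-null term measured empirically by re-running both stages on cohorts
whose case/control labels have been permuted within recruitment site:

    FDR = P(p2<=d2 | D2=0, D1=0, p1<=d1) / P(p2<=d2 | p1<=d1) * FDR1
        + d2 / P(p2<=d2 | p1<=d1) * pi0_2

where d_j is the smallest stage-j p-value above the stage-j threshold, D_j
indicates a real stage-j effect, pi0_2 is the Storey estimate of the true-null
proportion among stage-2 tests, and FDR1 is the Storey-style stage-1 estimate
pi0_1 * d1 / P(p1 <= d1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import EwasResult, SurrogateVariables, adjust_pvalues, estimate_surrogate_variables, run_ewas
from .simcohort import MethylationMatrix

__all__ = [
    "TwoStageConfig",
    "TwoStageResult",
    "discovery_filter",
    "replication_filter",
    "direction_consistency",
    "coefficient_correlation",
    "storey_pi0",
    "estimate_twostage_fdr",
    "expected_stage1_false_positives",
    "expected_false_dmps",
]


@dataclass(frozen=True)
class TwoStageConfig:
    """Thresholds and permutation settings for the two-stage procedure.

    ``alpha1`` is the discovery nominal-p threshold (c1), ``q2`` the
    replication adjusted-p threshold (c2); both are inclusive (<=).
    Permutations shuffle case/control labels within site; surrogate variables
    are re-estimated per permutation unless ``reestimate_sv`` is off.
    """

    alpha1: float = 0.05
    q2: float = 0.01
    adjust_method: str = "bh"
    n_permutations: int = 100
    seed: int = 0
    covariate_names: tuple = ("age", "sex", "smoking", "cells")
    n_sv: int = 5
    sv_method: str = "ica"
    reestimate_sv: bool = True
    pi0_lambda: float = 0.5

    def validate(self) -> None:
        if not 0.0 < self.alpha1 < 1.0:
            raise ValueError("alpha1 must be in (0, 1)")
        if not 0.0 < self.q2 < 1.0:
            raise ValueError("q2 must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.pi0_lambda < 1.0:
            raise ValueError("pi0_lambda must be in (0, 1)")


@dataclass
class TwoStageResult:
    """Selection sets and FDR intermediates of one two-stage run."""

    discovery_pass: set
    replicated_dmps: set
    consistent_dmps: set
    removed_discordant: set
    fdr_estimate: float
    pi0_stage2: float
    d1: float
    d2: float
    coefficient_correlation_all: float
    coefficient_correlation_dmps: float
    fdr1: float = float("nan")
    term_null_both: float = float("nan")  # P(p2<=d2 | D2=0, D1=0, p1<=d1), permutation estimate
    denominator: float = float("nan")  # P(p2<=d2 | p1<=d1), observed
    flags: list = field(default_factory=list)
    result_discovery: EwasResult | None = None
    result_replication: EwasResult | None = None
    q_replication: dict | None = None  # probe -> adjusted p over the discovery-pass set

    def __post_init__(self) -> None:
        if not self.consistent_dmps <= self.replicated_dmps <= self.discovery_pass:
            raise ValueError("set inclusions violated: consistent <= replicated <= discovery")
        if self.removed_discordant != self.replicated_dmps - self.consistent_dmps:
            raise ValueError("removed_discordant must equal replicated minus consistent")


class ZeroVarianceError(ValueError):
    """Correlation undefined: one of the coefficient vectors has zero variance."""


def discovery_filter(result: EwasResult, alpha1: float) -> set:
    """Probes with discovery p-value <= alpha1 (boundary inclusive)."""
    if not 0.0 < alpha1 < 1.0:
        raise ValueError("alpha1 must be in (0, 1)")
    mask = result.p_value <= alpha1
    return set(result.probe_ids[mask])


def replication_filter(
    result_repl: EwasResult,
    discovery_pass: Sequence[str],
    q2: float,
    adjust_method: str = "bh",
) -> tuple[set, dict]:
    """Replication-significant probes among the discovery-pass set.

    The multiple-testing adjustment is computed over the discovery-pass probes
    only — the replication stage tests only those hypotheses.  Returns the
    selected set and the probe -> adjusted-p map.  Raises KeyError listing
    probes missing from the replication result.
    """
    probes = sorted(discovery_pass)
    if not probes:
        return set(), {}
    sub = result_repl.restrict(probes)
    q = adjust_pvalues(sub.p_value, adjust_method)
    qmap = dict(zip(sub.probe_ids, q))
    return {p for p, qv in qmap.items() if qv <= q2}, qmap


def direction_consistency(
    result_disc: EwasResult, result_repl: EwasResult, dmps: Sequence[str]
) -> tuple[set, set]:
    """Split DMPs by coefficient sign agreement between cohorts.

    A probe is consistent iff sign(coef_disc) * sign(coef_repl) > 0; a zero
    coefficient in either cohort counts as discordant (no reproducible
    direction can be claimed).
    """
    probes = sorted(dmps)
    disc = result_disc.restrict(probes)
    repl = result_repl.restrict(probes)
    prod = np.sign(disc.coefficient) * np.sign(repl.coefficient)
    consistent = {p for p, v in zip(probes, prod) if v > 0}
    return consistent, set(probes) - consistent


def coefficient_correlation(
    result_disc: EwasResult, result_repl: EwasResult, probes: Sequence[str]
) -> tuple[float, float]:
    """Pearson correlation (r, p) of discovery vs replication coefficients."""
    probes = sorted(probes)
    if len(probes) < 3:
        raise ValueError("need at least 3 probes for a correlation")
    x = result_disc.restrict(probes).coefficient
    y = result_repl.restrict(probes).coefficient
    if x.std() == 0.0 or y.std() == 0.0:
        raise ZeroVarianceError("coefficient vector has zero variance; r undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def storey_pi0(p_values: np.ndarray, lam: float = 0.5) -> float:
    """Storey estimate of the true-null proportion: #{p > lam} / (m (1 - lam)).

    Under the null, p-values are uniform, so the density above ``lam`` counts
    (almost) only nulls; the raw estimate is clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("storey_pi0 requires at least one p-value")
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must be in (0, 1)")
    raw = np.count_nonzero(p > lam) / (p.size * (1.0 - lam))
    return float(min(max(raw, 0.0), 1.0))


def expected_stage1_false_positives(alpha1: float, n_probes: int) -> float:
    """Expected count of null probes passing the discovery filter: alpha1 * P."""
    return alpha1 * n_probes


def expected_false_dmps(fdr: float, n_probes: int) -> int:
    """Expected false DMP count implied by a two-stage FDR over P probes, rounded."""
    return int(round(fdr * n_probes))


def _permute_within_site(pheno: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    out = pheno.copy()
    status = out["status"].to_numpy(dtype=object).copy()
    for site in pd.unique(out["site"]):
        idx = np.flatnonzero(out["site"].to_numpy() == site)
        status[idx] = status[idx[rng.permutation(idx.size)]]
    out["status"] = status
    return out


def _stage_pvalues(
    matrix: MethylationMatrix,
    pheno: pd.DataFrame,
    config: TwoStageConfig,
    svs: SurrogateVariables | None,
    seed: int,
) -> EwasResult:
    if config.n_sv and (svs is None):
        svs = estimate_surrogate_variables(
            matrix, pheno, config.covariate_names, config.n_sv, config.sv_method, seed
        )
    return run_ewas(matrix, pheno, config.covariate_names, svs, config.adjust_method)


def estimate_twostage_fdr(
    matrix_disc: MethylationMatrix,
    pheno_disc: pd.DataFrame,
    matrix_repl: MethylationMatrix,
    pheno_repl: pd.DataFrame,
    config: TwoStageConfig | None = None,
) -> TwoStageResult:
    """Run the full two-stage selection and estimate its FDR by permutation.

    The doubly-null survival probability is estimated by re-running both
    stages on ``config.n_permutations`` within-site label permutations and
    pooling, over permutations, the fraction of permuted discovery-pass probes
    whose permuted stage-2 adjusted p falls at or below d2.  The denominator
    is the observed fraction of discovery-pass probes that are stage-2
    significant.  When the observed stage-2 rejection set is empty the FDR is
    defined as 0 and flagged ``empty_rejection_set``; when no probe lies above
    a threshold, d falls back to the threshold itself and is flagged.
    """
    config = config or TwoStageConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    flags: list[str] = []

    svs_disc = svs_repl = None
    if config.n_sv:
        svs_disc = estimate_surrogate_variables(
            matrix_disc, pheno_disc, config.covariate_names, config.n_sv,
            config.sv_method, config.seed,
        )
        svs_repl = estimate_surrogate_variables(
            matrix_repl, pheno_repl, config.covariate_names, config.n_sv,
            config.sv_method, config.seed + 1,
        )
    res_disc = run_ewas(matrix_disc, pheno_disc, config.covariate_names, svs_disc,
                        config.adjust_method)
    res_repl = run_ewas(matrix_repl, pheno_repl, config.covariate_names, svs_repl,
                        config.adjust_method)

    discovery_pass = discovery_filter(res_disc, config.alpha1)
    replicated, qmap = replication_filter(
        res_repl, discovery_pass, config.q2, config.adjust_method
    )
    if replicated:
        consistent, discordant = direction_consistency(res_disc, res_repl, replicated)
    else:
        consistent, discordant = set(), set()

    shared = sorted(set(res_disc.probe_ids) & set(res_repl.probe_ids))
    try:
        r_all, _ = coefficient_correlation(res_disc, res_repl, shared)
    except (ValueError, ZeroVarianceError):
        r_all = float("nan")
        flags.append("correlation_all_undefined")
    try:
        r_dmps, _ = coefficient_correlation(res_disc, res_repl, replicated)
    except (ValueError, ZeroVarianceError):
        r_dmps = float("nan")
        flags.append("correlation_dmps_undefined")

    # d1: smallest discovery p above c1; d2: smallest stage-2 adjusted p above c2
    above1 = res_disc.p_value[res_disc.p_value > config.alpha1]
    if above1.size:
        d1 = float(above1.min())
    else:
        d1 = config.alpha1
        flags.append("d1_fallback_threshold")
    qvals = np.array(sorted(qmap.values())) if qmap else np.array([])
    above2 = qvals[qvals > config.q2] if qvals.size else np.array([])
    if above2.size:
        d2 = float(above2.min())
    else:
        d2 = config.q2
        flags.append("d2_fallback_threshold")

    m1 = res_disc.p_value.size
    pi0_1 = storey_pi0(res_disc.p_value, config.pi0_lambda)
    p_pass_d1 = np.count_nonzero(res_disc.p_value <= d1) / m1
    fdr1 = min(pi0_1 * d1 / p_pass_d1, 1.0) if p_pass_d1 > 0 else 0.0

    # pi0 for stage 2 comes from the raw replication p-values of the tested set
    if discovery_pass:
        p_stage2 = res_repl.restrict(sorted(discovery_pass)).p_value
        pi0_2 = storey_pi0(p_stage2, config.pi0_lambda)
    else:
        pi0_2 = 1.0

    n_pass = len(discovery_pass)
    n_sig2 = len(replicated)
    denominator = n_sig2 / n_pass if n_pass else 0.0

    # permutation estimate of P(p2 <= d2 | D=0 both stages, p1 <= d1)
    perm_hits = 0
    perm_pass = 0
    for b in range(config.n_permutations):
        pd_perm = _permute_within_site(pheno_disc, rng)
        pr_perm = _permute_within_site(pheno_repl, rng)
        perm_seed = config.seed + 1000 + b
        svs_d = svs_disc if (config.n_sv and not config.reestimate_sv) else None
        svs_r = svs_repl if (config.n_sv and not config.reestimate_sv) else None
        cfg_nsv = config.n_sv if config.reestimate_sv else 0
        perm_cfg = TwoStageConfig(
            alpha1=config.alpha1, q2=config.q2, adjust_method=config.adjust_method,
            n_permutations=1, seed=perm_seed, covariate_names=config.covariate_names,
            n_sv=cfg_nsv, sv_method=config.sv_method,
        )
        rd = _stage_pvalues(matrix_disc, pd_perm, perm_cfg, svs_d, perm_seed)
        pass_b = rd.p_value <= config.alpha1
        n_b = int(pass_b.sum())
        if n_b == 0:
            continue
        rr = _stage_pvalues(matrix_repl, pr_perm, perm_cfg, svs_r, perm_seed + 1)
        probes_b = rd.probe_ids[pass_b]
        sub = rr.restrict(sorted(probes_b))
        q_b = adjust_pvalues(sub.p_value, config.adjust_method)
        perm_hits += int(np.count_nonzero(q_b <= d2))
        perm_pass += n_b
    term_null_both = perm_hits / perm_pass if perm_pass else 0.0
    if perm_pass == 0:
        flags.append("no_permutation_pass_probes")

    if n_sig2 == 0:
        fdr_estimate = 0.0
        flags.append("empty_rejection_set")
    else:
        fdr_estimate = (term_null_both / denominator) * fdr1 + (d2 / denominator) * pi0_2
        fdr_estimate = float(min(max(fdr_estimate, 0.0), 1.0))

    return TwoStageResult(
        discovery_pass=discovery_pass,
        replicated_dmps=replicated,
        consistent_dmps=consistent,
        removed_discordant=discordant,
        fdr_estimate=fdr_estimate,
        pi0_stage2=pi0_2,
        d1=d1,
        d2=d2,
        coefficient_correlation_all=r_all,
        coefficient_correlation_dmps=r_dmps,
        fdr1=fdr1,
        term_null_both=term_null_both,
        denominator=denominator,
        flags=flags,
        result_discovery=res_disc,
        result_replication=res_repl,
        q_replication=qmap,
    )
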