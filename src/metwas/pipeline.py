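"""End-to-end orchestration: simulate -> filter -> EWAS x2 -> two-stage ->
network -> MPS -> clinical, driven by one TOML config.

Every stage's inputs, outputs and seeds are recorded in a JSON run manifest so
any stage can be re-run from its recorded inputs.  Identical config and seed
give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import (
    median_split_analysis,
    records_from_phenotypes,
    severity_correlation,
    treatment_response_model,
)
from .ewas import estimate_surrogate_variables, filter_low_variability, run_ewas
from .mps import DEFAULT_THRESHOLDS, MpsModel, compute_mps, intersect_models, threshold_scan
from .network import UNASSIGNED, build_network, encode_traits, module_trait_correlation
from .simcohort import MethylationMatrix, SimulationConfig, read_cohort, simulate_cohort, write_cohort
from .twostage import TwoStageConfig, estimate_twostage_fdr

logger = logging.getLogger("metwas")

__all__ = ["validate_config", "run_pipeline", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "simulate": {"seed": 0},  # remaining keys default to SimulationConfig fields
    "filter": {"fraction": 0.10},
    "ewas": {"covariates": ["age", "sex", "smoking", "cells"], "n_sv": 5,
             "sv_method": "ica", "adjust": "bh"},
    "twostage": {"alpha1": 0.05, "q2": 0.01, "n_permutations": 100},
    "mps": {"thresholds": list(DEFAULT_THRESHOLDS)},
    "network": {"min_module_size": 30, "fit_threshold": 0.85},
    "clinical": {"include_mps_main": True},
}


def load_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _merged(config: dict) -> dict:
    merged = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in config.items():
        if section in merged and isinstance(values, dict):
            merged[section].update(values)
        else:
            merged[section] = values
    return merged


def validate_config(config: dict | str | Path) -> list:
    """Full schema check; returns a list of error strings (empty means valid)."""
    if not isinstance(config, dict):
        try:
            config = load_config(config)
        except (OSError, tomllib.TOMLDecodeError) as exc:
            return [f"cannot read config: {exc}"]
    cfg = _merged(config)
    errors: list[str] = []
    known = set(DEFAULT_CONFIG) | {"cohorts"}
    for section in config:
        if section not in known:
            errors.append(f"unknown section [{section}]")

    sim = cfg["simulate"]
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    for key in sim:
        if key not in sim_fields:
            errors.append(f"[simulate] unknown field {key!r}")
    try:
        _sim_config(sim).validate()
    except Exception as exc:  # surfaced as a config error, not a crash
        errors.append(f"[simulate] {exc}")

    frac = cfg["filter"].get("fraction", 0.10)
    if not 0.0 <= frac < 1.0:
        errors.append(f"[filter] fraction must be in [0, 1), got {frac}")

    ew = cfg["ewas"]
    if ew.get("adjust") not in ("bh", "holm", "bonferroni", "storey_q"):
        errors.append(f"[ewas] unknown adjust method {ew.get('adjust')!r}")
    if ew.get("n_sv", 0) < 0:
        errors.append("[ewas] n_sv must be >= 0")

    ts = cfg["twostage"]
    if not 0.0 < ts.get("alpha1", 0.05) < 1.0:
        errors.append(f"[twostage] alpha1 must be in (0, 1), got {ts.get('alpha1')}")
    if not 0.0 < ts.get("q2", 0.01) < 1.0:
        errors.append(f"[twostage] q2 must be in (0, 1), got {ts.get('q2')}")
    if ts.get("n_permutations", 100) < 1:
        errors.append("[twostage] n_permutations must be >= 1")

    thresholds = cfg["mps"].get("thresholds", list(DEFAULT_THRESHOLDS))
    if not thresholds:
        errors.append("[mps] thresholds must be non-empty")
    elif any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        errors.append("[mps] thresholds must be sorted in descending order")

    if cfg["network"].get("min_module_size", 30) < 2:
        errors.append("[network] min_module_size must be >= 2")
    return errors


def _sim_config(sim: dict) -> SimulationConfig:
    kwargs = dict(sim)
    if "sites" in kwargs:
        kwargs["sites"] = tuple(tuple(s) for s in kwargs["sites"])
    return SimulationConfig(**kwargs)


def run_pipeline(config: dict | str | Path, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute all stages in order and return the run manifest (also written as JSON).

    ``seed`` overrides the simulation seed from the config.  User-supplied
    cohorts can replace the simulator via a ``[cohorts]`` section with
    ``discovery`` / ``replication`` directories in the cohort exchange format.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    cfg = _merged(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "stages": [],
        "seeds": {},
        "outputs": {},
    }

    def stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        # --- cohorts ---------------------------------------------------------
        stage("simulate")
        if "cohorts" in cfg:
            m_disc, p_disc, _ = read_cohort(cfg["cohorts"]["discovery"])
            m_repl, p_repl, _ = read_cohort(cfg["cohorts"]["replication"])
            sites = [str(p_disc["site"].iloc[0]), str(p_repl["site"].iloc[0])]
            matrix = MethylationMatrix(
                m_disc.probe_ids,
                np.concatenate([m_disc.sample_ids, m_repl.sample_ids]),
                np.concatenate([m_disc.beta, m_repl.beta], axis=1),
            )
            pheno = pd.concat([p_disc, p_repl], ignore_index=True)
            truth = None
        else:
            sim_cfg = _sim_config(cfg["simulate"])
            if seed is not None:
                sim_cfg = sim_cfg.replace(seed=seed)
            manifest["seeds"]["simulate"] = sim_cfg.seed
            matrix, pheno, truth = simulate_cohort(sim_cfg)
            sites = [s[0] for s in sim_cfg.sites]
            paths = write_cohort(matrix, pheno, truth, out_dir / "cohort")
            manifest["outputs"]["cohort"] = {k: str(v) for k, v in paths.items()}
        logger.info("cohort: %d probes x %d samples", matrix.n_probes, matrix.n_samples)

        # --- low-variability filter on the pooled cohorts --------------------
        stage("filter")
        before = matrix.n_probes
        matrix = filter_low_variability(matrix, cfg["filter"]["fraction"])
        logger.info("variability filter: %d -> %d probes", before, matrix.n_probes)

        disc_site, repl_site = sites[0], sites[-1]
        disc_ids = pheno.loc[pheno["site"] == disc_site, "sample_id"].tolist()
        repl_ids = pheno.loc[pheno["site"] == repl_site, "sample_id"].tolist()
        m_disc = matrix.select_samples(disc_ids)
        m_repl = matrix.select_samples(repl_ids)
        p_disc = pheno[pheno["site"] == disc_site].reset_index(drop=True)
        p_repl = pheno[pheno["site"] == repl_site].reset_index(drop=True)

        # --- two-stage EWAS (includes both per-cohort EWAS runs) -------------
        stage("twostage")
        ew = cfg["ewas"]
        ts = cfg["twostage"]
        ts_seed = ts.get("seed", cfg["simulate"].get("seed", 0) if seed is None else seed)
        manifest["seeds"]["twostage"] = ts_seed
        ts_cfg = TwoStageConfig(
            alpha1=ts["alpha1"],
            q2=ts["q2"],
            adjust_method=ew["adjust"],
            n_permutations=ts["n_permutations"],
            seed=ts_seed,
            covariate_names=tuple(ew["covariates"]),
            n_sv=ew["n_sv"],
            sv_method=ew["sv_method"],
            reestimate_sv=ts.get("reestimate_sv", True),
        )
        result = estimate_twostage_fdr(m_disc, p_disc, m_repl, p_repl, ts_cfg)
        logger.info(
            "discovery pass %d, replicated %d, consistent %d, FDR %.3g",
            len(result.discovery_pass), len(result.replicated_dmps),
            len(result.consistent_dmps), result.fdr_estimate,
        )
        _write_twostage(result, out_dir, manifest)

        res_disc = result.result_discovery
        consistent = sorted(result.consistent_dmps)

        # --- co-methylation network over the consistent DMPs ------------------
        nw = cfg["network"]
        if len(consistent) >= nw["min_module_size"]:
            stage("network")
            net, modules = build_network(
                matrix, consistent,
                fit_threshold=nw["fit_threshold"], min_module_size=nw["min_module_size"],
            )
            traits = encode_traits(pheno)
            trait_corr = module_trait_correlation(modules.eigenvectors, traits)
            pd.DataFrame(
                {"probe_id": modules.probe_ids, "module_label": modules.labels}
            ).to_csv(out_dir / "modules.tsv", sep="\t", index=False)
            ev = modules.eigenvectors.copy()
            ev.insert(0, "sample_id", matrix.sample_ids)
            ev.to_csv(out_dir / "module_eigenvectors.tsv", sep="\t", index=False,
                      float_format="%.10g")
            trait_corr.to_csv(out_dir / "module_trait_correlation.tsv", sep="\t",
                              index=False, float_format="%.10g")
            manifest["outputs"]["network"] = {
                "power": net.power,
                "module_sizes": modules.sizes,
                "modules": str(out_dir / "modules.tsv"),
                "eigenvectors": str(out_dir / "module_eigenvectors.tsv"),
                "trait_correlation": str(out_dir / "module_trait_correlation.tsv"),
            }
            logger.info("network power %d, modules %s", net.power, modules.sizes)
        else:
            modules = None
            logger.info("network skipped: %d consistent DMPs < min module size", len(consistent))

        # --- MPS threshold scan + models --------------------------------------
        stage("mps")
        rows, best = threshold_scan(
            res_disc, m_disc, p_disc, m_repl, p_repl, cfg["mps"]["thresholds"]
        )
        scan_frame = pd.DataFrame(
            [(r.threshold, r.n_cpgs, r.auroc_train, r.auroc_test) for r in rows],
            columns=["threshold", "n_cpgs", "auroc_train", "auroc_test"],
        )
        scan_frame.to_csv(out_dir / "mps_scan.tsv", sep="\t", index=False,
                          float_format="%.10g")
        manifest["outputs"]["mps_scan"] = str(out_dir / "mps_scan.tsv")

        models: dict[str, MpsModel] = {}
        if consistent:
            sub = res_disc.restrict(consistent)
            models["two_step"] = MpsModel(sub.probe_ids, sub.coefficient, "two_step")
        if modules is not None:
            for mod in sorted(set(modules.labels) - {UNASSIGNED}):
                members = sorted(modules.probes_in(mod))
                sub = res_disc.restrict(members)
                models[mod] = MpsModel(sub.probe_ids, sub.coefficient, mod)
        if best is not None:
            models["discovery"] = best
        common = None
        if best is not None and "two_step" in models:
            parts = [models["discovery"], models["two_step"]]
            if modules is not None and modules.sizes:
                biggest = max(
                    (m for m in modules.sizes if m != UNASSIGNED),
                    key=lambda m: modules.sizes[m],
                    default=None,
                )
                if biggest is not None:
                    parts.append(models[biggest])
            common = intersect_models(parts)
            models["common"] = common
        for label, model in models.items():
            path = out_dir / f"mps_model_{label}.tsv"
            model.write(path)
            manifest["outputs"][f"mps_model_{label}"] = str(path)
        logger.info("mps models: %s", {k: m.n_probes for k, m in models.items()})

        # --- clinical correlates with the common (fallback two-step) MPS ------
        stage("clinical")
        clinical_model = common if (common is not None and common.n_probes) else models.get("two_step")
        manifest["outputs"]["clinical"] = {}
        if clinical_model is not None and clinical_model.n_probes:
            scores = compute_mps(clinical_model, matrix)
            score_map = dict(zip(matrix.sample_ids, scores))
            case_mask = (pheno["status"] == "case").to_numpy()
            sev = pheno["severity"].to_numpy(dtype=float)
            mps_vec = np.array([score_map[s] for s in pheno["sample_id"]])
            try:
                r, p, n = severity_correlation(mps_vec, sev, case_mask)
                manifest["outputs"]["clinical"]["severity_correlation"] = {
                    "r": r, "p": p, "n": n
                }
            except ValueError as exc:
                manifest["outputs"]["clinical"]["severity_correlation"] = str(exc)
            records = records_from_phenotypes(pheno, score_map)
            if len(records) > 12:
                summary = treatment_response_model(
                    records, include_mps_main=cfg["clinical"]["include_mps_main"]
                )
                summary.to_frame().to_csv(out_dir / "treatment_model.tsv", sep="\t",
                                          index=False, float_format="%.10g")
                manifest["outputs"]["clinical"]["treatment_model"] = str(
                    out_dir / "treatment_model.tsv"
                )
                try:
                    low, high, split, sizes = median_split_analysis(records)
                    low.to_frame().to_csv(out_dir / "treatment_low.tsv", sep="\t",
                                          index=False, float_format="%.10g")
                    high.to_frame().to_csv(out_dir / "treatment_high.tsv", sep="\t",
                                           index=False, float_format="%.10g")
                    manifest["outputs"]["clinical"]["median_split"] = {
                        "split": split, "sizes": list(sizes),
                        "low": str(out_dir / "treatment_low.tsv"),
                        "high": str(out_dir / "treatment_high.tsv"),
                    }
                except ValueError as exc:
                    manifest["outputs"]["clinical"]["median_split"] = str(exc)
        else:
            logger.info("clinical stage skipped: no non-empty MPS model")
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest


def _write_twostage(result, out_dir: Path, manifest: dict) -> None:
    res_d, res_r = result.result_discovery, result.result_replication
    lookup_r = {p: i for i, p in enumerate(res_r.probe_ids)}
    qmap = result.q_replication or {}
    rows = []
    for i, pid in enumerate(res_d.probe_ids):
        j = lookup_r.get(pid)
        rows.append(
            (
                pid,
                res_d.p_value[i],
                res_d.coefficient[i],
                res_r.p_value[j] if j is not None else float("nan"),
                qmap.get(pid, float("nan")),
                res_r.coefficient[j] if j is not None else float("nan"),
                pid in result.discovery_pass,
                pid in result.replicated_dmps,
                pid in result.consistent_dmps,
            )
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "probe_id", "p_disc", "coef_disc", "p_repl", "q_repl", "coef_repl",
            "in_discovery_pass", "replicated", "consistent",
        ],
    )
    path = out_dir / "twostage.tsv"
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "fdr_estimate": result.fdr_estimate,
        "pi0_stage2": result.pi0_stage2,
        "fdr1": result.fdr1,
        "d1": result.d1,
        "d2": result.d2,
        "coefficient_correlation_all": result.coefficient_correlation_all,
        "coefficient_correlation_dmps": result.coefficient_correlation_dmps,
        "n_discovery_pass": len(result.discovery_pass),
        "n_replicated": len(result.replicated_dmps),
        "n_consistent": len(result.consistent_dmps),
        "flags": result.flags,
    }
    spath = out_dir / "twostage_summary.json"
    with open(spath, "w") as fh:
        json.dump(sidecar, fh, indent=2, default=float)
    manifest["outputs"]["twostage"] = str(path)
    manifest["outputs"]["twostage_summary"] = str(spath)
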