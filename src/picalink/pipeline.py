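"""End-to-end orchestration: QC -> pre-filter -> site regression ->
parallel ICA -> association statistics -> report.

Holds the run-level configuration (paths, stage thresholds, seed) and the
seed-splitting scheme: one global seed spawns named substreams for
simulation, decomposition, permutation and fold assignment, so every
stochastic stage is reproducible and logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .datatypes import (
    DecompositionConfig,
    GenotypeTable,
    ModalityMatrix,
    as_design_matrix,
)
from .fa_prep import check_site_by_diagnosis, load_fa_stack, regress_out_site
from .genotype_qc import ancestry_correct, prefilter_group_difference, run_qc
from .pica import run_parallel_ica, threshold_component, top_fraction, zscore_component
from .stats import (
    group_difference_loadings,
    identify_linked_pair,
    kfold_reproducibility,
    permutation_test,
)

log = logging.getLogger("picalink")

COVARIATE_PRESETS = {
    # covariate sets used when adjusting the linked-pair correlation
    "abstract": ("site", "ethnicity", "age", "sex"),
    "results": ("age", "sex"),
}


@dataclass
class PipelineConfig:
    """Paths, stage thresholds and the global seed for one analysis run.

    Numeric defaults are the conventional settings of the procedure:
    call-rate floors 0.9, HWE p floor 1e-6, MAF floor 0.05, pre-filter
    alpha 0.01, constraint threshold 0.3, endurance -1e-5, 5000
    permutations, 10 folds, |Z| > 3.5 map threshold, top 5% SNP weights.
    """

    fa_matrix: str | None = None
    fa_images: list[str] | None = None
    mask: str | None = None
    genotypes: str | None = None  # dosage TSV or PLINK prefix
    covariates: str | None = None
    out_dir: str = "picalink_run"

    subject_call_rate_min: float = 0.9
    snp_call_rate_min: float = 0.9
    hwe_p_min: float = 1e-6
    maf_min: float = 0.05
    ld_r2_min: float = 0.8
    ld_window: int = 50
    ancestry_max_pcs: int = 10
    prefilter_alpha: float = 0.01
    decomposition: DecompositionConfig = field(default_factory=DecompositionConfig)
    covariate_preset: str = "abstract"
    n_permutations: int = 5000
    k_folds: int = 10
    z_min: float = 3.5
    top_fraction: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        dec = raw.pop("decomposition", None)
        cfg = cls(**raw)
        if dec:
            cfg.decomposition = DecompositionConfig(**dec)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["config_hash"] = hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return d


def stage_seeds(seed: int, names=("simulate", "decompose", "permute", "folds")
                ) -> dict[str, int]:
    """Named per-stage seeds derived from the global seed (all < 2**31)."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1))
            for n, c in zip(names, children)}


def load_inputs(cfg: PipelineConfig
                ) -> tuple[ModalityMatrix, GenotypeTable, pd.DataFrame]:
    """Read the FA matrix (text or NIfTI stack), genotypes and covariates."""
    if cfg.covariates is None:
        raise FileNotFoundError("a covariates file is required")
    cov_path = Path(cfg.covariates)
    if not cov_path.exists():
        raise FileNotFoundError(f"covariates file not found: {cov_path}")
    cov = pio.read_covariates(cov_path)

    if cfg.fa_matrix:
        fa = pio.read_matrix(cfg.fa_matrix, modality="fa")
    elif cfg.fa_images:
        fa = load_fa_stack(cfg.fa_images, cfg.mask)
    else:
        raise FileNotFoundError("provide fa_matrix or fa_images")

    gpath = Path(cfg.genotypes or "")
    if gpath.with_suffix(".bed").exists():
        geno = pio.read_plink(gpath)
    elif gpath.exists():
        geno = pio.read_dosage(gpath)
    else:
        raise FileNotFoundError(f"genotypes not found: {cfg.genotypes}")
    return fa, geno, cov


def run_analysis(cfg: PipelineConfig, fa: ModalityMatrix, geno: GenotypeTable,
                 cov: pd.DataFrame, write: bool = True) -> dict:
    """The full chain on in-memory inputs; returns the report dict."""
    seeds = stage_seeds(cfg.seed)
    out = Path(cfg.out_dir)

    # --- genotype QC ---------------------------------------------------
    control_ids = cov.loc[cov["diagnosis"] == 0, "id"].tolist()
    geno_qc, qc_reports = run_qc(
        geno, control_ids,
        subject_min=cfg.subject_call_rate_min, snp_min=cfg.snp_call_rate_min,
        r2_min=cfg.ld_r2_min, window=cfg.ld_window,
        hwe_p_min=cfg.hwe_p_min, maf_min=cfg.maf_min,
    )
    kept = set(geno_qc.subjects)
    cov = cov[cov["id"].isin(kept)].reset_index(drop=True)
    fa = fa.subset_subjects(np.array([s in kept for s in fa.subjects]))

    # --- ancestry correction + diagnosis pre-filter ---------------------
    dosage = geno_qc.to_modality_matrix()
    dosage_corr, removed_pcs = ancestry_correct(
        dosage, cov["ethnicity"].to_numpy(), max_pcs=cfg.ancestry_max_pcs)
    selected = prefilter_group_difference(
        dosage_corr, cov["diagnosis"].to_numpy(), alpha=cfg.prefilter_alpha)
    if len(selected) < cfg.decomposition.n_comp_snp:
        raise RuntimeError(
            f"pre-filter kept {len(selected)} SNPs, fewer than "
            f"{cfg.decomposition.n_comp_snp} components")
    snp_matrix = ModalityMatrix(
        subjects=list(dosage_corr.subjects),
        variables=[dosage_corr.variables[j] for j in selected],
        values=dosage_corr.values[:, selected],
        modality="snp",
    )

    # --- site regression -------------------------------------------------
    fa_corr = regress_out_site(fa, cov["site"].to_numpy())

    # --- decomposition ---------------------------------------------------
    dcfg = dataclasses.replace(cfg.decomposition, seed=seeds["decompose"])
    result = run_parallel_ica(fa_corr, snp_matrix, dcfg)
    if not result.converged:
        log.warning("decomposition did not meet the weight-change tolerance "
                    "in %d iterations", dcfg.max_iterations)

    # --- association statistics -----------------------------------------
    preset = COVARIATE_PRESETS[cfg.covariate_preset]
    design = as_design_matrix(cov, [c for c in preset if c in cov.columns])
    pair = identify_linked_pair(result, design, covariate_names=list(preset))
    t, p_group, means = group_difference_loadings(
        result.A1[:, pair.fa_component], cov["diagnosis"].to_numpy())
    site_check = check_site_by_diagnosis(
        result.A1[:, pair.fa_component], cov["site"].to_numpy(),
        cov["diagnosis"].to_numpy())
    z_fa = zscore_component(result.S1[pair.fa_component])
    fa_voxels = threshold_component(z_fa, cfg.z_min)
    snp_top = top_fraction(result.S2[pair.snp_component], cfg.top_fraction)

    report = {
        "config": cfg.echo(),
        "stage_seeds": seeds,
        "qc": [{ "step": r.step, "subjects_removed": r.n_subjects_removed,
                 "snps_removed": r.n_snps_removed} for r in qc_reports],
        "ancestry_pcs_removed": removed_pcs,
        "n_snps_prefiltered": int(len(selected)),
        "linked_pair": dataclasses.asdict(pair),
        "fa_group_difference": {"t": t, "p": p_group, **means},
        "site_by_diagnosis": {
            "consistent_direction": site_check["consistent_direction"],
            "interaction_p": site_check["interaction_p"],
        },
        "n_fa_voxels_above_z": int(len(fa_voxels)),
        "n_top_snps": int(len(snp_top)),
        "converged": result.converged,
        "n_iterations": result.n_iterations,
    }
    if write:
        out.mkdir(parents=True, exist_ok=True)
        pio.write_result_bundle(result, out / "decomposition", covariates=cov)
        np.savetxt(out / "prefiltered_snp_indices.tsv", selected, fmt="%d")
        pio.write_report(report, out, stem="report")
    report["_result"] = result
    report["_covariates"] = cov
    report["_snp_matrix"] = snp_matrix
    report["_fa_matrix"] = fa_corr
    return report


def run_permutation(cfg: PipelineConfig, fa_corr, snp_matrix,
                    reduced_iterations: int | None = 64) -> dict:
    seeds = stage_seeds(cfg.seed)
    dcfg = dataclasses.replace(cfg.decomposition, seed=seeds["decompose"])
    perm_cfg = dcfg.reduced(reduced_iterations) if reduced_iterations else None
    res = permutation_test(fa_corr, snp_matrix, dcfg,
                           n_perm=cfg.n_permutations, seed=seeds["permute"],
                           perm_config=perm_cfg)
    return {
        "observed_top_abs_corr": res.observed,
        "empirical_p": res.empirical_p,
        "n_permutations": res.n_permutations,
        "profile": res.profile,
        "null_median": float(np.median(res.null_values)),
        "null_values": res.null_values,
    }


def run_crossval(cfg: PipelineConfig, fa_corr, snp_matrix, diagnosis) -> dict:
    seeds = stage_seeds(cfg.seed)
    dcfg = dataclasses.replace(cfg.decomposition, seed=seeds["decompose"])
    folds = kfold_reproducibility(fa_corr, snp_matrix, dcfg,
                                  diagnosis=diagnosis, k=cfg.k_folds,
                                  seed=seeds["folds"],
                                  snp_top_fraction=cfg.top_fraction)
    rs = [f.pair_correlation for f in folds]
    ov = [f.overlap_ratio for f in folds]
    return {
        "k": cfg.k_folds,
        "fold_correlations": rs,
        "median_abs_correlation": float(np.median(np.abs(rs))),
        "overlap_ratios": ov,
        "median_overlap_ratio": float(np.median(ov)),
    }
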