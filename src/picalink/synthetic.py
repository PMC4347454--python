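"""Synthetic two-modality cohorts with a planted linked component pair.

Emulates the study design the pipeline targets: two diagnostic groups
(default 73 patients / 87 controls) scanned at several sites, a
subjects-by-voxels FA matrix built as ``A1 @ S1`` plus additive per-site
voxel offsets and Gaussian noise, and a subjects-by-SNPs genotype matrix
obtained by quantile-discretizing a latent ``A2 @ S2 + noise`` to 0/1/2
dosages whose marginals follow Hardy-Weinberg equilibrium at a per-SNP
minor-allele frequency.

One FA component and one SNP component are "linked": their subject loading
columns are constructed with an exact in-sample correlation at the target
value (default -0.37) and carry opposite-direction group mean shifts, so the
linkage is detectable both as a loading correlation and as a group effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .datatypes import (
    DecompositionResult,
    GenotypeTable,
    ModalityMatrix,
    RecoveryReport,
)

ETHNICITY_LEVELS = ("caucasian", "african_american", "other")
ETHNICITY_PROBS = (0.78, 0.12, 0.10)


@dataclass
class SyntheticConfig:
    """Study conditions for the generated cohort.

    Defaults mirror the target cohort: 73 cases / 87 controls across 4
    acquisition sites, a planted cross-modality loading correlation of
    -0.37, ~5000 voxels and a pre-filtered-scale SNP panel (~1000 markers),
    with 9 FA and 7 SNP components.
    """

    n_cases: int = 73
    n_controls: int = 87
    n_voxels: int = 5000
    n_snps: int = 1000
    n_components_fa: int = 9
    n_components_snp: int = 7
    linked_corr_target: float = -0.37
    group_effect_fa: float = 1.0
    group_effect_snp: float = 1.2
    sparsity_fa: float = 0.05
    sparsity_snp: float = 0.10
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_sites: int = 4
    site_effect_sd: float = 0.01
    noise_sd_fa: float = 0.02
    noise_sd_snp: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    fa_baseline: float = 0.5
    fa_signal_scale: float = 0.02

    def __post_init__(self) -> None:
        if self.n_cases + self.n_controls < 20:
            raise ValueError("need at least 20 subjects in total")
        if abs(self.linked_corr_target) > 1:
            raise ValueError("|linked_corr_target| must be <= 1")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        for s in (self.sparsity_fa, self.sparsity_snp):
            if not (0 < s < 1):
                raise ValueError("sparsity fractions must lie in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        n = self.n_cases + self.n_controls
        if self.n_components_fa > min(n, self.n_voxels):
            raise ValueError("n_components_fa exceeds min(subjects, voxels)")
        if self.n_components_snp > min(n, self.n_snps):
            raise ValueError("n_components_snp exceeds min(subjects, snps)")


@dataclass
class SyntheticGroundTruth:
    """Planted components, loadings and covariates for recovery scoring."""

    true_S1: np.ndarray
    true_S2: np.ndarray
    true_A1: np.ndarray
    true_A2: np.ndarray
    linked_pair: tuple[int, int] | None
    covariates: pd.DataFrame  # id, diagnosis, site, age, sex, ethnicity
    active_fa: np.ndarray  # voxel index set of the linked FA component
    active_snp: np.ndarray
    site_offsets: np.ndarray  # n_sites x n_voxels
    realized_group_effect_fa: float
    realized_group_effect_snp: float
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def linked_corr(self) -> float | None:
        if self.linked_pair is None:
            return None
        i, j = self.linked_pair
        return float(np.corrcoef(self.true_A1[:, i], self.true_A2[:, j])[0, 1])


def _rng_streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """Independent substreams derived from one seed (documented splitting)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _blob_component(n_vars: int, sparsity: float, rng: np.random.Generator,
                    blob_len: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Sparse row of contiguous half-sine runs, scaled to unit variance."""
    s = np.zeros(n_vars)
    target = max(blob_len, int(round(sparsity * n_vars)))
    n_blobs = max(1, target // blob_len)
    active: list[np.ndarray] = []
    for _ in range(n_blobs):
        start = int(rng.integers(0, max(1, n_vars - blob_len)))
        idx = np.arange(start, min(start + blob_len, n_vars))
        amp = rng.choice((-1.0, 1.0)) * (0.5 + rng.random())
        s[idx] += amp * np.sin(np.linspace(0, np.pi, len(idx)))
        active.append(idx)
    s /= s.std()
    return s, np.unique(np.concatenate(active))


def _sparse_component(n_vars: int, sparsity: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sparse row with Gaussian-valued active entries, unit variance."""
    k = max(3, int(round(sparsity * n_vars)))
    idx = rng.choice(n_vars, size=k, replace=False)
    s = np.zeros(n_vars)
    s[idx] = rng.standard_normal(k)
    s /= s.std()
    return s, np.sort(idx)


def _exact_corr_partner(x: np.ndarray, raw: np.ndarray, target: float) -> np.ndarray:
    """Adjust `raw` along standardized `x` so corr(x, result) == target exactly.

    Decompose the centered partner as c*xhat + z (z orthogonal to xhat) and
    shift its xhat coefficient to t*||z||/sqrt(1-t^2), which pins the sample
    correlation at t without touching the orthogonal structure.
    """
    xc = x - x.mean()
    xhat = xc / np.linalg.norm(xc)
    rc = raw - raw.mean()
    c = rc @ xhat
    z = rc - c * xhat
    s = np.linalg.norm(z)
    if abs(target) >= 1.0:
        return np.sign(target) * xhat * max(s, 1.0) + raw.mean()
    lam = target * s / np.sqrt(1.0 - target**2) - c
    return raw + lam * xhat


def _covariates(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_cases + cfg.n_controls
    diagnosis = np.array([1] * cfg.n_cases + [0] * cfg.n_controls)
    # balanced-ish random site assignment
    site = np.tile(np.arange(cfg.n_sites), n // cfg.n_sites + 1)[:n]
    rng.shuffle(site)
    age = np.clip(rng.normal(34.0, 11.0, n), 18, 65).round(1)
    sex = rng.integers(0, 2, n)
    ethnicity = rng.choice(ETHNICITY_LEVELS, size=n, p=ETHNICITY_PROBS)
    return pd.DataFrame(
        {
            "id": [f"S{i:04d}" for i in range(n)],
            "diagnosis": diagnosis,
            "site": site,
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
        }
    )


def _linked_loadings(cfg: SyntheticConfig, diagnosis: np.ndarray,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Linked loading columns: group shifts + exact target correlation.

    FA loading is lower in cases (controls > patients); the SNP loading is
    higher in cases, so a negative cross-modality correlation is the natural
    direction.
    """
    n = len(diagnosis)
    g = diagnosis - diagnosis.mean()
    g = g / g.std() if g.std() > 0 else np.zeros(n)
    a_fa = -cfg.group_effect_fa * g + rng.standard_normal(n)
    raw_snp = cfg.group_effect_snp * g + rng.standard_normal(n)
    a_snp = _exact_corr_partner(a_fa, raw_snp, cfg.linked_corr_target)

    def smd(col: np.ndarray) -> float:
        if (diagnosis == 1).sum() == 0 or (diagnosis == 0).sum() == 0:
            return 0.0
        m1, m0 = col[diagnosis == 1].mean(), col[diagnosis == 0].mean()
        return float((m1 - m0) / col.std(ddof=1))

    return a_fa, a_snp, smd(a_fa), smd(a_snp)


def _discretize_hwe(latent: np.ndarray, mafs: np.ndarray) -> np.ndarray:
    """Per-column rank cutpoints giving HWE marginals at each SNP's MAF.

    The largest latent values become minor-allele homozygotes, so dosage is
    a monotone function of the latent score and linear structure survives
    discretization (attenuated).
    """
    n, p = latent.shape
    calls = np.zeros((n, p))
    n2 = np.round(mafs**2 * n).astype(int)
    n1 = np.round(2 * mafs * (1 - mafs) * n).astype(int)
    n1 = np.minimum(n1, n - n2)
    for j in range(p):
        order = np.argsort(latent[:, j], kind="stable")
        calls[order[n - n2[j]:], j] = 2.0
        calls[order[n - n2[j] - n1[j]: n - n2[j]], j] = 1.0
    return calls


def generate_linked_dataset(
    config: SyntheticConfig,
) -> tuple[ModalityMatrix, GenotypeTable, pd.DataFrame, SyntheticGroundTruth]:
    """Generate an FA matrix, genotype table, covariates and ground truth.

    Fully deterministic given ``config.seed``; all randomness flows through
    named substreams spawned from that seed.
    """
    cfg = config
    rngs = _rng_streams(
        cfg.seed,
        ("covariates", "fa_comp", "snp_comp", "loadings", "site", "noise_fa",
         "noise_snp", "maf", "missing"),
    )
    cov = _covariates(cfg, rngs["covariates"])
    n = len(cov)
    diagnosis = cov["diagnosis"].to_numpy()

    # components
    S1 = np.empty((cfg.n_components_fa, cfg.n_voxels))
    fa_active: list[np.ndarray] = []
    for c in range(cfg.n_components_fa):
        S1[c], act = _blob_component(cfg.n_voxels, cfg.sparsity_fa, rngs["fa_comp"])
        fa_active.append(act)
    S2 = np.empty((cfg.n_components_snp, cfg.n_snps))
    snp_active: list[np.ndarray] = []
    for c in range(cfg.n_components_snp):
        S2[c], act = _sparse_component(cfg.n_snps, cfg.sparsity_snp, rngs["snp_comp"])
        snp_active.append(act)

    # loadings: iid standard normal, linked pair overwritten
    A1 = rngs["loadings"].standard_normal((n, cfg.n_components_fa))
    A2 = rngs["loadings"].standard_normal((n, cfg.n_components_snp))
    plant = not (cfg.linked_corr_target == 0 and cfg.group_effect_fa == 0
                 and cfg.group_effect_snp == 0)
    li, lj = 0, 0
    a_fa, a_snp, smd_fa, smd_snp = _linked_loadings(cfg, diagnosis, rngs["loadings"])
    A1[:, li] = a_fa
    A2[:, lj] = a_snp

    # FA modality
    site = cov["site"].to_numpy()
    site_offsets = rngs["site"].normal(0.0, cfg.site_effect_sd,
                                       (cfg.n_sites, cfg.n_voxels))
    X1 = (
        cfg.fa_baseline
        + cfg.fa_signal_scale * (A1 @ S1)
        + site_offsets[site]
        + rngs["noise_fa"].normal(0.0, cfg.noise_sd_fa, (n, cfg.n_voxels))
    )
    fa = ModalityMatrix(
        subjects=list(cov["id"]),
        variables=[f"v{j}" for j in range(cfg.n_voxels)],
        values=X1,
        modality="fa",
    )

    # SNP modality: latent -> HWE dosages
    latent = A2 @ S2 + rngs["noise_snp"].normal(0.0, cfg.noise_sd_snp,
                                                (n, cfg.n_snps))
    mafs = rngs["maf"].uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_snps)
    calls = _discretize_hwe(latent, mafs)
    if cfg.missing_rate > 0:
        miss = rngs["missing"].random((n, cfg.n_snps)) < cfg.missing_rate
        calls[miss] = np.nan
    snp_meta = pd.DataFrame(
        {
            "snp": [f"rs{j:06d}" for j in range(cfg.n_snps)],
            "chrom": np.full(cfg.n_snps, 1),
            "pos": np.arange(1, cfg.n_snps + 1) * 1000,
            "a1": ["A"] * cfg.n_snps,
            "a2": ["G"] * cfg.n_snps,
        }
    )
    geno = GenotypeTable(subjects=list(cov["id"]), snps=snp_meta, calls=calls)

    truth = SyntheticGroundTruth(
        true_S1=S1,
        true_S2=S2,
        true_A1=A1,
        true_A2=A2,
        linked_pair=(li, lj) if plant else None,
        covariates=cov,
        active_fa=fa_active[li],
        active_snp=snp_active[lj],
        site_offsets=site_offsets,
        realized_group_effect_fa=smd_fa,
        realized_group_effect_snp=smd_snp,
        config=cfg,
    )
    return fa, geno, cov, truth


def generate_null_dataset(
    config: SyntheticConfig,
) -> tuple[ModalityMatrix, GenotypeTable, pd.DataFrame, SyntheticGroundTruth]:
    """Same construction with no planted link and no group effects."""
    cfg = replace(config, linked_corr_target=0.0, group_effect_fa=0.0,
                  group_effect_snp=0.0)
    return generate_linked_dataset(cfg)


def score_recovery(result: DecompositionResult,
                   truth: SyntheticGroundTruth) -> RecoveryReport:
    """Match estimated to true components and score the planted pair.

    Components are matched per modality by optimal assignment on absolute
    row correlations (invariant to permutation and sign flips of the
    estimate). The pair check asks whether the estimated top loading pair
    maps onto the planted pair under that matching.
    """
    if result.S1.shape[1] != truth.true_S1.shape[1]:
        raise ValueError("FA variable dimension mismatch between result and truth")
    if result.S2.shape[1] != truth.true_S2.shape[1]:
        raise ValueError("SNP variable dimension mismatch between result and truth")

    def match(true_S: np.ndarray, est_S: np.ndarray):
        c = np.corrcoef(true_S, est_S)[: len(true_S), len(true_S):]
        rows, cols = linear_sum_assignment(-np.abs(c))
        rec = np.abs(c[rows, cols])
        signs = np.sign(c[rows, cols])
        assign = np.full(len(true_S), -1, dtype=int)
        assign[rows] = cols
        return assign, rec, signs

    fa_match, fa_rec, fa_sg = match(truth.true_S1, result.S1)
    snp_match, snp_rec, snp_sg = match(truth.true_S2, result.S2)
    ei, ej, er = result.top_pair()
    matched = (
        truth.linked_pair is not None
        and fa_match[truth.linked_pair[0]] == ei
        and snp_match[truth.linked_pair[1]] == ej
    )
    aligned = er
    if matched:
        li, lj = truth.linked_pair
        aligned = er * fa_sg[li] * snp_sg[lj]
    return RecoveryReport(
        fa_match=fa_match,
        snp_match=snp_match,
        fa_recovery=fa_rec,
        snp_recovery=snp_rec,
        fa_signs=fa_sg,
        snp_signs=snp_sg,
        pair_matched=bool(matched),
        estimated_pair=(ei, ej),
        estimated_pair_corr=er,
        estimated_pair_corr_aligned=float(aligned),
    )
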