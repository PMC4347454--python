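"""Pairing statistics, permutation null, and reproducibility analyses.

The linkage claim rests on the correlation between one FA loading column
and one SNP loading column. This module computes the full pair matrix,
covariate-adjusted (partial) correlations, Bonferroni control over the
n_fa x n_snp pair tests, a max-statistic permutation null obtained by
re-decomposing subject-permuted data, and a k-fold subset reproducibility
analysis with top-SNP overlap ratios.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    DecompositionConfig,
    DecompositionResult,
    FoldResult,
    LinkedPair,
    ModalityMatrix,
    PermutationResult,
    as_design_matrix,
)
from .pica import run_parallel_ica, top_fraction


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def pair_correlation_matrix(A1: np.ndarray, A2: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p for every loading-column pair."""
    A1, A2 = np.asarray(A1, float), np.asarray(A2, float)
    if A1.shape[0] != A2.shape[0]:
        raise ValueError("loading matrices must share subjects")
    if A1.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    r = np.empty((A1.shape[1], A2.shape[1]))
    p = np.empty_like(r)
    for i in range(A1.shape[1]):
        for j in range(A2.shape[1]):
            r[i, j], p[i, j] = stats.pearsonr(A1[:, i], A2[:, j])
    return r, p


def partial_correlation(a, b, covariate_design) -> tuple[float, float]:
    """Correlation of a and b after residualizing both on the covariates.

    Both vectors are regressed on an intercept plus the design columns; the
    Pearson correlation of the residuals is tested on n - 2 - q degrees of
    freedom (q = number of covariate columns).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    Z = np.asarray(covariate_design, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, q = len(a), Z.shape[1]
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate design is rank deficient")
    ra = a - design @ np.linalg.lstsq(design, a, rcond=None)[0]
    rb = b - design @ np.linalg.lstsq(design, b, rcond=None)[0]
    # a vector explained (numerically) perfectly by the covariates has no
    # residual variation left to correlate
    if (np.linalg.norm(ra) <= 1e-8 * max(np.linalg.norm(a - a.mean()), 1e-300)
            or np.linalg.norm(rb) <= 1e-8 * max(np.linalg.norm(b - b.mean()),
                                                1e-300)):
        return 0.0, 1.0
    r = float(np.clip(ra @ rb / (np.linalg.norm(ra) * np.linalg.norm(rb)),
                      -1.0, 1.0))
    df = n - 2 - q
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Per-test significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def group_difference_loadings(loadings, diagnosis) -> tuple[float, float, dict]:
    """Two-sample (pooled-variance) t-test of a loading column by group."""
    x = np.asarray(loadings, float)
    dx = np.asarray(diagnosis)
    g1, g0 = x[dx == 1], x[dx == 0]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, p = stats.ttest_ind(g1, g0, equal_var=True)
    return float(t), float(p), {"case_mean": float(g1.mean()),
                                "control_mean": float(g0.mean())}


def within_group_partial_correlation(a, b, covariate_design, group_mask
                                     ) -> tuple[float, float]:
    """Partial correlation restricted to the subjects in ``group_mask``."""
    mask = np.asarray(group_mask, bool)
    Z = np.asarray(covariate_design, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    q = Z.shape[1]
    if mask.sum() < q + 4:
        raise ValueError("group too small for the covariate design")
    return partial_correlation(np.asarray(a)[mask], np.asarray(b)[mask], Z[mask])


def identify_linked_pair(result: DecompositionResult,
                         covariate_design,
                         covariate_names=None,
                         alpha: float = 0.05) -> LinkedPair:
    """Top loading pair with raw and covariate-adjusted statistics.

    The Bonferroni flag corrects the raw p over all n_fa x n_snp pair tests.
    """
    r, p = pair_correlation_matrix(result.A1, result.A2)
    i, j = np.unravel_index(np.argmax(np.abs(r)), r.shape)
    pr, pp = partial_correlation(result.A1[:, i], result.A2[:, j],
                                 covariate_design)
    m = r.size
    return LinkedPair(
        fa_component=int(i),
        snp_component=int(j),
        raw_r=float(r[i, j]),
        raw_p=float(p[i, j]),
        partial_r=pr,
        partial_p=pp,
        covariates=list(covariate_names or []),
        passes_bonferroni=bool(p[i, j] < bonferroni_threshold(alpha, m)),
    )


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def empirical_p(observed: float, null_values) -> float:
    """Tail probability count(null >= observed) / n, no +1 correction."""
    null_values = np.asarray(null_values, float)
    return float((null_values >= observed).sum() / len(null_values))


def permutation_test(X1, X2, config: DecompositionConfig, n_perm: int = 5000,
                     seed: int = 0, observed: float | None = None,
                     perm_config: DecompositionConfig | None = None
                     ) -> PermutationResult:
    """Max-statistic permutation null for the top |loading correlation|.

    Each permutation shuffles the subject order of the SNP modality
    (breaking cross-modality alignment while preserving within-modality
    structure) and reruns the full decomposition; the top absolute loading
    correlation from each run forms the null sample. ``perm_config`` may
    declare a reduced-iteration profile for the permuted reruns; the
    observed statistic always comes from the full ``config`` unless given.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    M1 = X1.values if isinstance(X1, ModalityMatrix) else np.asarray(X1, float)
    M2 = X2.values if isinstance(X2, ModalityMatrix) else np.asarray(X2, float)
    if observed is None:
        res = run_parallel_ica(M1, M2, config)
        observed = abs(res.top_pair()[2])
    run_cfg = perm_config or config
    profile = "full" if perm_config is None else (
        f"reduced(max_iterations={run_cfg.max_iterations})")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(M2.shape[0])
        cfg_b = replace(run_cfg, seed=int(rng.integers(0, 2**31 - 1)))
        res_b = run_parallel_ica(M1, M2[perm], cfg_b)
        null[b] = abs(res_b.top_pair()[2])
    return PermutationResult(
        observed=float(observed),
        null_values=null,
        n_permutations=n_perm,
        empirical_p=empirical_p(observed, null),
        profile=profile,
    )


# ---------------------------------------------------------------------------
# k-fold reproducibility
# ---------------------------------------------------------------------------

def overlap_ratio(subset_top, full_top) -> float:
    """|subset_top ∩ full_top| / |full_top|."""
    full = set(np.asarray(full_top).tolist())
    if not full:
        raise ValueError("full-data top set is empty")
    sub = set(np.asarray(subset_top).tolist())
    return len(sub & full) / len(full)


def _stratified_folds(diagnosis: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint held-out blocks, stratified by diagnosis after a shuffle."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for level in np.unique(diagnosis):
        idx = np.flatnonzero(diagnosis == level)
        rng.shuffle(idx)
        for f, part in enumerate(np.array_split(idx, k)):
            folds[f].extend(part.tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def kfold_reproducibility(X1, X2, config: DecompositionConfig,
                          diagnosis=None, k: int = 10, seed: int = 0,
                          snp_top_fraction: float = 0.05,
                          full_result: DecompositionResult | None = None
                          ) -> list[FoldResult]:
    """Rerun the decomposition on k 90%-subject subsets and score stability.

    Each fold drops one disjoint block (diagnosis-stratified when labels are
    given), reruns with the same parameters, matches fold components to the
    full-data components by maximal |correlation| of weight vectors, and
    records the matched top pair's loading correlation plus the overlap of
    top-fraction SNP sets.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    M1 = X1.values if isinstance(X1, ModalityMatrix) else np.asarray(X1, float)
    M2 = X2.values if isinstance(X2, ModalityMatrix) else np.asarray(X2, float)
    n = M1.shape[0]
    subjects = (list(X1.subjects) if isinstance(X1, ModalityMatrix)
                else [str(i) for i in range(n)])
    dx = np.zeros(n, dtype=int) if diagnosis is None else np.asarray(diagnosis)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(dx, k, rng)

    if full_result is None:
        full_result = run_parallel_ica(M1, M2, config)
    fi, fj, _ = full_result.top_pair()
    full_snp_top = top_fraction(full_result.S2[fj], snp_top_fraction)

    out: list[FoldResult] = []
    for f, held in enumerate(folds):
        keep = np.setdiff1d(np.arange(n), held)
        res = run_parallel_ica(M1[keep], M2[keep], config)
        mi = _best_match(full_result.S1[fi], res.S1)
        mj = _best_match(full_result.S2[fj], res.S2)
        r = float(stats.pearsonr(res.A1[:, mi], res.A2[:, mj])[0])
        ov = overlap_ratio(top_fraction(res.S2[mj], snp_top_fraction),
                           full_snp_top)
        out.append(FoldResult(
            fold=f,
            kept_subjects=[subjects[s] for s in keep],
            matched_fa_component=mi,
            matched_snp_component=mj,
            pair_correlation=r,
            overlap_ratio=ov,
        ))
    return out


def _best_match(reference_row: np.ndarray, S: np.ndarray) -> int:
    c = np.abs([np.corrcoef(reference_row, S[c])[0, 1] for c in range(len(S))])
    return int(np.argmax(c))


# ---------------------------------------------------------------------------
# Subgroup rerun
# ---------------------------------------------------------------------------

def subgroup_rerun(X1, X2, covariates: pd.DataFrame, subgroup_mask,
                   config: DecompositionConfig,
                   covariate_columns=("site", "age", "sex")
                   ) -> tuple[DecompositionResult, LinkedPair]:
    """Re-analysis restricted to a subject subset (e.g., one ancestry group)."""
    mask = np.asarray(subgroup_mask, bool)
    M1 = X1.values if isinstance(X1, ModalityMatrix) else np.asarray(X1, float)
    M2 = X2.values if isinstance(X2, ModalityMatrix) else np.asarray(X2, float)
    sub_cov = covariates.loc[mask].reset_index(drop=True)
    if "diagnosis" in covariates.columns:
        groups = sub_cov["diagnosis"].nunique()
        if groups < 2:
            raise ValueError("subgroup removes one diagnostic group entirely")
    result = run_parallel_ica(M1[mask], M2[mask], config)
    design = as_design_matrix(sub_cov, [c for c in covariate_columns
                                        if c in sub_cov.columns])
    pair = identify_linked_pair(result, design,
                                covariate_names=list(covariate_columns))
    return result, pair
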