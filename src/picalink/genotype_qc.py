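"""SNP quality control, encoding, ancestry correction and pre-filtering.

The QC chain mirrors standard GWAS practice on additive minor-allele
dosages: call-rate filters (subjects before SNPs), LD-based replacement of
missing calls, an exact Hardy-Weinberg test within controls, a minor-allele
frequency floor, removal of ethnicity-associated principal components, and
a diagnosis-based pre-filter that reduces the panel to markers weakly
separating the groups before the multivariate decomposition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .datatypes import GenotypeTable, ModalityMatrix, QCReport


# ---------------------------------------------------------------------------
# Call-rate filtering
# ---------------------------------------------------------------------------

def filter_call_rate(table: GenotypeTable, subject_min: float = 0.9,
                     snp_min: float = 0.9) -> tuple[GenotypeTable, QCReport]:
    """Drop subjects then SNPs whose call rate is not strictly above the
    threshold (call rate > 90% at both levels by default)."""
    if not (0 < subject_min <= 1 and 0 < snp_min <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    out = table
    removed_subjects: list[str] = []
    removed_snps: list[str] = []
    # iterate subject-then-SNP passes to a fixed point: removals change the
    # rates the next pass sees, and the fixed point makes the filter
    # idempotent
    while True:
        keep_sub = out.call_rate_subjects() > subject_min
        t1 = out.subset(subject_idx=keep_sub)
        keep_snp = t1.call_rate_snps() > snp_min
        removed_subjects += [s for s, k in zip(out.subjects, keep_sub) if not k]
        removed_snps += [s for s, k in zip(t1.snp_ids, keep_snp) if not k]
        out = t1.subset(snp_idx=keep_snp)
        if out.n_subjects == 0 or out.n_snps == 0:
            raise ValueError("call-rate filter removed all subjects or SNPs")
        if keep_sub.all() and keep_snp.all():
            break
    report = QCReport(
        step="call_rate",
        n_subjects_in=table.n_subjects,
        n_snps_in=table.n_snps,
        n_subjects_removed=len(removed_subjects),
        n_snps_removed=len(removed_snps),
        removed_subjects=removed_subjects,
        removed_snps=removed_snps,
        details={"subject_min": subject_min, "snp_min": snp_min},
    )
    return out, report


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided HWE p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed table. Probabilities are computed in log space via
    log-gamma:

        P(h | nA, N) = N! / (n_hom_A! h! n_hom_a!) * 2^h * nA! na! / (2N)!
    """
    counts = (int(n_AA), int(n_Aa), int(n_aa))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    N = sum(counts)
    if N < 1:
        raise ValueError("need at least one genotype")
    nA = 2 * counts[0] + counts[1]
    hets, pvals = hwe_pvalues_given_alleles(N, nA)
    return float(pvals[hets == counts[1]][0])


def hwe_pvalues_given_alleles(N: int, nA: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact two-sided p-value for every admissible heterozygote count
    given ``N`` genotypes carrying ``nA`` copies of one allele."""
    hets, logp = _hwe_log_distribution(N, nA)
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    order = np.argsort(prob, kind="stable")
    csum = np.cumsum(prob[order])
    # p(h) = sum of probabilities <= prob(h); ties all included
    pvals = np.empty_like(prob)
    sorted_prob = prob[order]
    for pos, idx in enumerate(order):
        # include every entry with probability <= prob[idx] (plus tolerance)
        last = np.searchsorted(sorted_prob, prob[idx] * (1 + 1e-12),
                               side="right") - 1
        pvals[idx] = csum[last]
    return hets, np.minimum(pvals, 1.0)


def _hwe_log_distribution(N: int, nA: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of every admissible het count."""
    h_max = min(nA, 2 * N - nA)
    hets = np.arange(nA % 2, h_max + 1, 2)
    homA = (nA - hets) // 2
    homa = N - hets - homA
    na = 2 * N - nA
    logp = (
        gammaln(N + 1) - gammaln(homA + 1) - gammaln(hets + 1) - gammaln(homa + 1)
        + hets * np.log(2.0)
        + gammaln(nA + 1) + gammaln(na + 1) - gammaln(2 * N + 1)
    )
    return hets, logp


def filter_hwe(table: GenotypeTable, control_ids, p_min: float = 1e-6
               ) -> tuple[GenotypeTable, QCReport]:
    """Remove SNPs violating HWE in the control subjects (p < p_min)."""
    control_ids = set(control_ids)
    ctrl = [i for i, s in enumerate(table.subjects) if s in control_ids]
    if not ctrl:
        raise ValueError("no control subjects found in the table")
    calls = table.calls[ctrl]
    pvals = np.ones(table.n_snps)
    for j in range(table.n_snps):
        col = calls[:, j]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            continue
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        pvals[j] = hwe_test(n2, n1, n0)
    keep = pvals >= p_min
    out = table.subset(snp_idx=keep)
    if out.n_snps == 0:
        raise ValueError("HWE filter removed all SNPs")
    report = QCReport(
        step="hwe",
        n_subjects_in=table.n_subjects,
        n_snps_in=table.n_snps,
        n_snps_removed=int((~keep).sum()),
        removed_snps=[s for s, k in zip(table.snp_ids, keep) if not k],
        details={"p_min": p_min, "hwe_pvalues": pvals},
    )
    return out, report


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def snp_maf(table: GenotypeTable) -> np.ndarray:
    """Frequency of the rarer allele per SNP over non-missing calls."""
    with np.errstate(invalid="ignore"):
        f = np.nanmean(table.calls, axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def filter_maf(table: GenotypeTable, maf_min: float = 0.05
               ) -> tuple[GenotypeTable, QCReport]:
    """Keep SNPs with MAF strictly above the floor; recode any column whose
    counted-allele frequency exceeds 0.5 so the minor allele is counted."""
    f = np.nanmean(table.calls, axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    keep = maf > maf_min
    out = table.subset(snp_idx=keep)
    if out.n_snps == 0:
        raise ValueError("MAF filter removed all SNPs")
    flip = np.nanmean(out.calls, axis=0) / 2.0 > 0.5
    if flip.any():
        calls = out.calls.copy()
        calls[:, flip] = 2.0 - calls[:, flip]
        snps = out.snps.copy()
        a1 = snps.loc[flip, "a1"].copy()
        snps.loc[flip, "a1"] = snps.loc[flip, "a2"]
        snps.loc[flip, "a2"] = a1
        out = GenotypeTable(subjects=out.subjects, snps=snps, calls=calls)
    report = QCReport(
        step="maf",
        n_subjects_in=table.n_subjects,
        n_snps_in=table.n_snps,
        n_snps_removed=int((~keep).sum()),
        removed_snps=[s for s, k in zip(table.snp_ids, keep) if not k],
        details={"maf_min": maf_min, "maf": maf, "n_recoded": int(flip.sum())},
    )
    return out, report


# ---------------------------------------------------------------------------
# LD-based missing-call replacement
# ---------------------------------------------------------------------------

def impute_missing_by_ld(table: GenotypeTable, r2_min: float = 0.8,
                         window: int = 50) -> tuple[GenotypeTable, QCReport]:
    """Fill each missing call from the best in-window LD proxy, else drop
    the SNP.

    For SNP j the proxy is the SNP k with |k - j| <= window maximizing the
    squared dosage correlation (computed over subjects non-missing at both),
    provided r^2 >= r2_min. The fill is the same subject's genotype at k,
    complemented to 2 - g when the correlation is negative (allele
    alignment). SNPs with any call that cannot be filled are removed, so the
    output has no missing values.
    """
    calls = table.calls.copy()
    n, p = calls.shape
    drop = np.zeros(p, dtype=bool)
    n_filled = 0
    for j in range(p):
        miss = np.isnan(calls[:, j])
        if not miss.any():
            continue
        lo, hi = max(0, j - window), min(p, j + window + 1)
        best_k, best_r = -1, 0.0
        for k in range(lo, hi):
            if k == j:
                continue
            both = ~np.isnan(table.calls[:, j]) & ~np.isnan(table.calls[:, k])
            if both.sum() < 3:
                continue
            a, b = table.calls[both, j], table.calls[both, k]
            if a.std() == 0 or b.std() == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if r * r > best_r * best_r:
                best_k, best_r = k, r
        if best_k < 0 or best_r**2 < r2_min:
            drop[j] = True
            continue
        proxy = table.calls[:, best_k]
        fill = proxy if best_r > 0 else 2.0 - proxy
        fillable = miss & ~np.isnan(proxy)
        calls[fillable, j] = fill[fillable]
        n_filled += int(fillable.sum())
        if np.isnan(calls[:, j]).any():  # proxy itself missing there
            drop[j] = True
    out = GenotypeTable(subjects=table.subjects, snps=table.snps,
                        calls=calls).subset(snp_idx=~drop)
    report = QCReport(
        step="ld_impute",
        n_subjects_in=table.n_subjects,
        n_snps_in=table.n_snps,
        n_snps_removed=int(drop.sum()),
        removed_snps=[s for s, d in zip(table.snp_ids, drop) if d],
        details={"r2_min": r2_min, "window": window, "n_filled": n_filled},
    )
    return out, report


# ---------------------------------------------------------------------------
# Ancestry (population-structure) correction
# ---------------------------------------------------------------------------

def ancestry_correct(X2: ModalityMatrix, ethnicity, max_pcs: int = 10,
                     alpha: float = 0.05) -> tuple[ModalityMatrix, list[int]]:
    """Project out dosage principal components associated with ethnicity.

    Subject-space PC scores of the column-centered dosage matrix are tested
    against the ethnicity labels with a one-way ANOVA, Bonferroni-corrected
    over the ``max_pcs`` PCs examined; flagged PC subspaces are removed by
    projection. Dimensions are never changed; values are column-centered.
    """
    X = np.asarray(X2.values, float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("ancestry correction needs at least 3 subjects")
    labels = np.asarray(ethnicity)
    Xc = X - X.mean(axis=0)
    groups = np.unique(labels)
    removed: list[int] = []
    if len(groups) >= 2:
        U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
        m = min(max_pcs, (sv > 1e-10 * sv[0]).sum())
        scores = U[:, :m] * sv[:m]
        for c in range(m):
            samples = [scores[labels == g, c] for g in groups]
            if any(len(s) < 2 for s in samples):
                continue
            p = stats.f_oneway(*samples)[1]
            if p * m < alpha:
                removed.append(c)
        if removed:
            Xc = Xc - scores[:, removed] @ Vt[removed, :]
    out = ModalityMatrix(subjects=list(X2.subjects), variables=list(X2.variables),
                         values=Xc, modality=X2.modality)
    return out, removed


# ---------------------------------------------------------------------------
# Diagnosis-based pre-filter
# ---------------------------------------------------------------------------

def prefilter_group_difference(X2, diagnosis, alpha: float = 0.01,
                               method: str = "welch") -> np.ndarray:
    """Indices of variables separating the groups at p < alpha, uncorrected.

    Per-SNP two-sample Welch t-test on additive dosage by default; a
    Cochran-Armitage-style chi-square trend test is available via
    ``method="trend"``. Genomic (input) order is preserved.
    """
    X = X2.values if isinstance(X2, ModalityMatrix) else np.asarray(X2, float)
    dx = np.asarray(diagnosis)
    g1, g0 = X[dx == 1], X[dx == 0]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("each diagnostic group needs at least 2 subjects")
    if alpha >= 1.0:  # no filtering: every p-value passes
        return np.arange(X.shape[1])
    if method == "welch":
        p = stats.ttest_ind(g1, g0, axis=0, equal_var=False)[1]
    elif method == "trend":
        p = np.array([_trend_p(X[:, j], dx) for j in range(X.shape[1])])
    else:
        raise ValueError(f"unknown method {method!r}")
    return np.flatnonzero(p < alpha)


def _trend_p(dosage: np.ndarray, dx: np.ndarray) -> float:
    """Chi-square(1) trend test via the corr^2 * n approximation."""
    if dosage.std() == 0:
        return 1.0
    r = np.corrcoef(dosage, dx)[0, 1]
    return float(stats.chi2.sf(len(dx) * r * r, df=1))


# ---------------------------------------------------------------------------
# Chained QC convenience
# ---------------------------------------------------------------------------

def run_qc(table: GenotypeTable, control_ids, subject_min: float = 0.9,
           snp_min: float = 0.9, r2_min: float = 0.8, window: int = 50,
           hwe_p_min: float = 1e-6, maf_min: float = 0.05
           ) -> tuple[GenotypeTable, list[QCReport]]:
    """Full chain: subject/SNP call rate -> LD imputation -> HWE -> MAF.

    Imputation precedes the frequency-based filters so they see filled data.
    """
    reports = []
    t, r = filter_call_rate(table, subject_min, snp_min)
    reports.append(r)
    t, r = impute_missing_by_ld(t, r2_min, window)
    reports.append(r)
    t, r = filter_hwe(t, control_ids, hwe_p_min)
    reports.append(r)
    t, r = filter_maf(t, maf_min)
    reports.append(r)
    return t, reports
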