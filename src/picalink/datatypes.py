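"""Shared containers for the two-modality decomposition pipeline.

The central objects mirror the generative model ``X = A @ S`` per modality:
``X`` is a subjects-by-variables data matrix, ``A`` the subjects-by-components
loading (mixing) matrix, and ``S`` the components-by-variables source maps.
Cross-modality links are correlations between columns of the two loading
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = np.nan


@dataclass
class ModalityMatrix:
    """Subjects x variables numeric matrix with aligned identifiers.

    For the FA modality, variables are voxel linear indices within a mask and
    values are fractional anisotropy (approximately within [0, 1] before site
    correction). For the genetic modality, variables are SNP IDs and values
    are additive minor-allele dosages.
    """

    subjects: list[str]
    variables: list[str]
    values: np.ndarray
    modality: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), len(self.variables)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variables)} variables"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def subset_subjects(self, mask: np.ndarray) -> "ModalityMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ModalityMatrix(
            subjects=[self.subjects[i] for i in idx],
            variables=list(self.variables),
            values=self.values[idx],
            modality=self.modality,
        )


@dataclass
class GenotypeTable:
    """Discrete genotype calls with per-SNP metadata.

    ``calls`` is float subjects x SNPs with values in {0, 1, 2, NaN}; the
    value counts copies of the designated minor allele (0 = none, 1 = one,
    2 = two). ``snps`` carries id, chromosome, position and allele labels
    (a1 = counted/minor, a2 = other/major).
    """

    subjects: list[str]
    snps: pd.DataFrame  # columns: snp, chrom, pos, a1, a2
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.subjects), len(self.snps)):
            raise ValueError("calls shape does not match subjects x snps")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype calls must be in {0, 1, 2, missing}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp"])

    def call_rate_subjects(self) -> np.ndarray:
        return 1.0 - np.isnan(self.calls).mean(axis=1)

    def call_rate_snps(self) -> np.ndarray:
        return 1.0 - np.isnan(self.calls).mean(axis=0)

    def subset(self, subject_idx=None, snp_idx=None) -> "GenotypeTable":
        si = np.arange(self.n_subjects) if subject_idx is None else np.asarray(subject_idx)
        ji = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if ji.dtype == bool:
            ji = np.flatnonzero(ji)
        return GenotypeTable(
            subjects=[self.subjects[i] for i in si],
            snps=self.snps.iloc[ji].reset_index(drop=True),
            calls=self.calls[np.ix_(si, ji)],
        )

    def to_modality_matrix(self) -> ModalityMatrix:
        """Dosage matrix for decomposition; requires complete calls."""
        if np.isnan(self.calls).any():
            raise ValueError("genotype table still contains missing calls; run QC first")
        return ModalityMatrix(
            subjects=list(self.subjects),
            variables=self.snp_ids,
            values=self.calls.copy(),
            modality="snp",
        )


@dataclass
class QCReport:
    """Bookkeeping for one QC step: what was removed and why."""

    step: str
    n_subjects_in: int
    n_snps_in: int
    n_subjects_removed: int = 0
    n_snps_removed: int = 0
    removed_subjects: list[str] = field(default_factory=list)
    removed_snps: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    @property
    def n_subjects_out(self) -> int:
        return self.n_subjects_in - self.n_subjects_removed

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - self.n_snps_removed


@dataclass
class DecompositionConfig:
    """Tuning parameters for the constrained parallel decomposition.

    ``constraint_threshold`` is the minimum absolute loading correlation at
    which the cross-modality enhancement engages (0.3 by convention);
    ``endurance`` bounds the admissible per-iteration drop of the infomax
    entropy term while the constraint is active (default -1e-5).
    """

    n_comp_fa: int = 9
    n_comp_snp: int = 7
    learning_rate: float = 0.1
    constraint_rate: float = 0.1
    max_iterations: int = 512
    constraint_threshold: float = 0.3
    max_constrained_pairs: int = 1
    endurance: float = -1e-5
    anneal_factor: float = 0.9
    convergence_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.constraint_threshold <= 1.0):
            raise ValueError("constraint_threshold must lie in [0, 1]")
        if self.endurance >= 0:
            raise ValueError("endurance must be negative")
        if not (0.0 < self.anneal_factor < 1.0):
            raise ValueError("anneal_factor must lie in (0, 1)")

    def reduced(self, max_iterations: int = 64) -> "DecompositionConfig":
        """Reduced-iteration profile for permutation/fold sweeps."""
        return replace(self, max_iterations=max_iterations)


@dataclass
class DecompositionResult:
    """Output of a (parallel) ICA run, in subject space.

    ``A1 @ S1`` reconstructs the rank-reduced, row-centered FA matrix;
    likewise for the SNP modality. Component rows are unit-variance with the
    largest-magnitude weight positive; the scale/sign is absorbed into A.
    """

    A1: np.ndarray
    A2: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    W1: np.ndarray
    W2: np.ndarray
    W0_1: np.ndarray
    W0_2: np.ndarray
    entropy_history_1: np.ndarray
    entropy_history_2: np.ndarray
    constrained_pair: tuple[int, int] | None
    constraint_corr_history: np.ndarray
    converged: bool
    n_iterations: int
    config: DecompositionConfig
    subjects: list[str] = field(default_factory=list)

    def loading_correlations(self) -> np.ndarray:
        """|n_comp_fa x n_comp_snp| matrix of loading-column Pearson r."""
        from scipy import stats as _st

        out = np.empty((self.A1.shape[1], self.A2.shape[1]))
        for i in range(self.A1.shape[1]):
            for j in range(self.A2.shape[1]):
                out[i, j] = _st.pearsonr(self.A1[:, i], self.A2[:, j])[0]
        return out

    def top_pair(self) -> tuple[int, int, float]:
        r = self.loading_correlations()
        i, j = np.unravel_index(np.argmax(np.abs(r)), r.shape)
        return int(i), int(j), float(r[i, j])


@dataclass
class LinkedPair:
    """A matched (FA component, SNP component) pairing with its statistics."""

    fa_component: int
    snp_component: int
    raw_r: float
    raw_p: float
    partial_r: float
    partial_p: float
    covariates: list[str]
    passes_bonferroni: bool

    def __post_init__(self) -> None:
        for r in (self.raw_r, self.partial_r):
            if abs(r) > 1 + 1e-12:
                raise ValueError("correlation outside [-1, 1]")
        for p in (self.raw_p, self.partial_p):
            if not (0.0 <= p <= 1.0):
                raise ValueError("p-value outside [0, 1]")


@dataclass
class PermutationResult:
    """Max-statistic permutation null for the top loading correlation."""

    observed: float
    null_values: np.ndarray
    n_permutations: int
    empirical_p: float
    profile: str = "full"

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if len(self.null_values) != self.n_permutations:
            raise ValueError("null sample length must equal n_permutations")


@dataclass
class FoldResult:
    """One cross-validation fold: matched-pair correlation and SNP overlap."""

    fold: int
    kept_subjects: list[str]
    matched_fa_component: int
    matched_snp_component: int
    pair_correlation: float
    overlap_ratio: float


@dataclass
class RecoveryReport:
    """Recovery of planted structure by an estimated decomposition."""

    fa_match: np.ndarray  # estimated index per true FA component
    snp_match: np.ndarray
    fa_recovery: np.ndarray  # |corr| per true FA component
    snp_recovery: np.ndarray
    fa_signs: np.ndarray
    snp_signs: np.ndarray
    pair_matched: bool
    estimated_pair: tuple[int, int]
    estimated_pair_corr: float
    # estimated top-pair correlation with the ICA sign indeterminacy
    # resolved against the true components (comparable to the planted value)
    estimated_pair_corr_aligned: float = np.nan


def as_design_matrix(covariates: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    """Numeric design from covariate columns; categoricals are dummy-coded."""
    parts = []
    for c in columns:
        col = covariates[c]
        if col.dtype.kind in "ifu" and col.nunique() > 2:
            parts.append(col.to_numpy(float)[:, None])
        else:
            d = pd.get_dummies(col, drop_first=True)
            parts.append(d.to_numpy(float))
    if not parts:
        return np.empty((len(covariates), 0))
    return np.hstack(parts)
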