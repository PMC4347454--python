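"""FA matrix assembly from pre-aligned volumes and site-effect removal.

Consumes the products of upstream tensor fitting / registration /
smoothing: per-subject scalar FA volumes on a common grid plus a binary
mask. Site effects are removed voxelwise by ordinary least squares on site
indicators, preserving each voxel's grand mean.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .datatypes import ModalityMatrix


def load_fa_stack(image_paths, mask) -> ModalityMatrix:
    """One row per subject of within-mask voxel values.

    ``mask`` is a NIfTI path or boolean array; voxel order is the row-major
    (C-order) linear index of the flattened mask. Subject IDs default to the
    file stem.
    """
    import nibabel as nib

    if isinstance(mask, (str, Path)):
        mask_arr = np.asanyarray(nib.load(str(mask)).dataobj)
    else:
        mask_arr = np.asarray(mask)
    mask_bool = mask_arr.astype(bool)
    if not mask_bool.any():
        raise ValueError("mask selects no voxels")
    flat_idx = np.flatnonzero(mask_bool.ravel(order="C"))

    rows, subjects = [], []
    for p in image_paths:
        img = nib.load(str(p))
        vol = np.asanyarray(img.dataobj)
        if vol.shape != mask_bool.shape:
            raise ValueError(f"{p}: grid {vol.shape} != mask grid {mask_bool.shape}")
        rows.append(vol.ravel(order="C")[flat_idx].astype(float))
        subjects.append(Path(p).name.split(".")[0])
    return ModalityMatrix(
        subjects=subjects,
        variables=[f"v{i}" for i in flat_idx],
        values=np.vstack(rows),
        modality="fa",
    )


def regress_out_site(X1: ModalityMatrix, site, allow_single_site: bool = False
                     ) -> ModalityMatrix:
    """Voxelwise OLS on site indicators; residuals plus the voxel grand mean.

    For a one-way site design the OLS fit equals the per-site voxel means,
    so the correction subtracts each subject's site mean and restores the
    grand mean: post-correction per-site voxel means are equal to numerical
    precision and voxel grand means are unchanged.
    """
    site = np.asarray(site)
    if len(site) != X1.n_subjects:
        raise ValueError("site labels must align with subjects")
    levels, inverse = np.unique(site, return_inverse=True)
    if len(levels) < 2:
        if allow_single_site:
            return ModalityMatrix(list(X1.subjects), list(X1.variables),
                                  X1.values.copy(), X1.modality)
        raise ValueError("site correction needs >= 2 sites "
                         "(pass allow_single_site=True to skip)")
    counts = np.bincount(inverse)
    if (counts < 2).any():
        bad = levels[counts < 2]
        raise ValueError(f"site(s) {list(bad)} have a single subject; "
                         "the voxelwise fit is ill-posed")
    X = X1.values
    grand = X.mean(axis=0)
    site_means = np.zeros((len(levels), X.shape[1]))
    for g in range(len(levels)):
        site_means[g] = X[inverse == g].mean(axis=0)
    corrected = X - site_means[inverse] + grand
    return ModalityMatrix(list(X1.subjects), list(X1.variables), corrected,
                          X1.modality)


def check_site_by_diagnosis(loadings, site, diagnosis) -> dict:
    """Post-hoc check that the diagnosis effect on a loading column points
    the same way at every site.

    Returns the per-site group-mean table, a consistent-direction flag
    (same sign of control-minus-patient mean difference at every site) and
    the site-by-diagnosis interaction F-test p-value.
    """
    df = pd.DataFrame({
        "loading": np.asarray(loadings, float),
        "site": pd.Categorical(site),
        "diagnosis": pd.Categorical(diagnosis),
    })
    means = df.groupby(["site", "diagnosis"], observed=True)["loading"].mean().unstack()
    diffs = means.iloc[:, 0] - means.iloc[:, 1]
    consistent = bool((diffs > 0).all() or (diffs < 0).all())
    fit = ols("loading ~ C(site) * C(diagnosis)", data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    inter_p = float(anova.loc["C(site):C(diagnosis)", "PR(>F)"])
    return {
        "means": means,
        "consistent_direction": consistent,
        "interaction_p": inter_p,
    }
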