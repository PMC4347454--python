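"""Readers and writers: delimited matrices, PLINK bed/bim/fam, NIfTI,
covariates, and analysis reports.

Delimited dialect: tab-separated with a header row; first column holds
subject IDs; missing marker "NA". The PLINK binary codec implements the
standard SNP-major .bed layout (magic bytes 0x6c 0x1b, mode 0x01; two bits
per call: 00 = two copies of allele 1, 10 = one copy, 11 = zero copies,
01 = missing) with allele 1 taken as the counted/minor allele.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeTable, ModalityMatrix

NA = "NA"

# dosage (copies of allele 1) -> 2-bit PLINK code, and back
_BED_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
_BED_DECODE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}


# ---------------------------------------------------------------------------
# Delimited matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: ModalityMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.subjects,
                      columns=matrix.variables)
    df.to_csv(path, sep="\t", index_label="id", na_rep=NA)


def read_matrix(path, modality: str = "generic") -> ModalityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    return ModalityMatrix(
        subjects=[str(s) for s in df.index],
        variables=[str(c) for c in df.columns],
        values=df.to_numpy(float),
        modality=modality,
    )


def write_dosage(table: GenotypeTable, path) -> None:
    """Genotypes as a subjects x SNPs dosage TSV (plus a .meta sidecar)."""
    df = pd.DataFrame(table.calls, index=table.subjects, columns=table.snp_ids)
    df.to_csv(path, sep="\t", index_label="id", na_rep=NA)
    table.snps.to_csv(str(path) + ".meta", sep="\t", index=False)


def read_dosage(path, missing=NA) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[missing, "-9"])
    meta_path = Path(str(path) + ".meta")
    if meta_path.exists():
        snps = pd.read_csv(meta_path, sep="\t")
    else:
        snps = pd.DataFrame({
            "snp": [str(c) for c in df.columns],
            "chrom": 0, "pos": 0, "a1": "A", "a2": "B",
        })
    return GenotypeTable(
        subjects=[str(s) for s in df.index],
        snps=snps,
        calls=df.to_numpy(float),
    )


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def write_plink(table: GenotypeTable, prefix) -> None:
    prefix = Path(prefix)
    n, p = table.calls.shape
    fam = pd.DataFrame({
        "fid": table.subjects, "iid": table.subjects,
        "pat": 0, "mat": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame({
        "chrom": table.snps["chrom"], "snp": table.snps["snp"],
        "cm": 0, "pos": table.snps["pos"],
        "a1": table.snps["a1"], "a2": table.snps["a2"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    bytes_per_snp = (n + 3) // 4
    out = bytearray([0x6C, 0x1B, 0x01])
    for j in range(p):
        buf = bytearray(bytes_per_snp)
        for i in range(n):
            g = table.calls[i, j]
            code = 0b01 if np.isnan(g) else _BED_CODE[g]
            buf[i // 4] |= code << (2 * (i % 4))
        out.extend(buf)
    prefix.with_suffix(".bed").write_bytes(bytes(out))


def read_plink(prefix) -> GenotypeTable:
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"])
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"])
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != bytes([0x6C, 0x1B, 0x01]):
        raise ValueError("not a SNP-major PLINK .bed file")
    n, p = len(fam), len(bim)
    bytes_per_snp = (n + 3) // 4
    calls = np.empty((n, p))
    body = raw[3:]
    for j in range(p):
        chunk = body[j * bytes_per_snp:(j + 1) * bytes_per_snp]
        for i in range(n):
            code = (chunk[i // 4] >> (2 * (i % 4))) & 0b11
            calls[i, j] = _BED_DECODE[code]
    snps = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeTable(subjects=[str(s) for s in fam["iid"]], snps=snps,
                         calls=calls)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def write_fa_volumes(matrix: ModalityMatrix, out_dir, grid_shape,
                     mask: np.ndarray | None = None) -> tuple[list[Path], Path]:
    """One synthetic-grid NIfTI volume per subject, plus the mask volume.

    Within-mask voxels are filled in C order from the matrix row; voxels
    outside the mask are zero.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if mask is None:
        if int(np.prod(grid_shape)) != matrix.n_variables:
            raise ValueError("grid size must match variable count without a mask")
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    flat_idx = np.flatnonzero(mask.ravel(order="C"))
    if len(flat_idx) != matrix.n_variables:
        raise ValueError("mask voxel count must match variable count")
    affine = np.eye(4)
    paths = []
    for s, sid in enumerate(matrix.subjects):
        vol = np.zeros(int(np.prod(grid_shape)))
        vol[flat_idx] = matrix.values[s]
        img = nib.Nifti1Image(vol.reshape(grid_shape), affine)
        path = out_dir / f"{sid}.nii"
        nib.save(img, str(path))
        paths.append(path)
    mask_path = out_dir / "mask.nii"
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(mask_path))
    return paths, mask_path


def component_to_volume(weights: np.ndarray, mask: np.ndarray, affine=None):
    """Back-project a component weight row into a NIfTI image via the mask."""
    import nibabel as nib

    mask = np.asarray(mask).astype(bool)
    vol = np.zeros(mask.size)
    vol[np.flatnonzero(mask.ravel(order="C"))] = np.asarray(weights, float)
    return nib.Nifti1Image(vol.reshape(mask.shape),
                           np.eye(4) if affine is None else affine)


# ---------------------------------------------------------------------------
# Covariates, ground truth, reports
# ---------------------------------------------------------------------------

def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(truth, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "true_S1.tsv", truth.true_S1, delimiter="\t")
    np.savetxt(out_dir / "true_S2.tsv", truth.true_S2, delimiter="\t")
    np.savetxt(out_dir / "true_A1.tsv", truth.true_A1, delimiter="\t")
    np.savetxt(out_dir / "true_A2.tsv", truth.true_A2, delimiter="\t")
    truth.covariates.to_csv(out_dir / "covariates.csv", index=False)
    meta = {
        "linked_pair": list(truth.linked_pair) if truth.linked_pair else None,
        "active_fa": truth.active_fa.tolist(),
        "active_snp": truth.active_snp.tolist(),
        "realized_group_effect_fa": truth.realized_group_effect_fa,
        "realized_group_effect_snp": truth.realized_group_effect_snp,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(meta, indent=2))


def write_result_bundle(result, out_dir, covariates: pd.DataFrame | None = None
                        ) -> None:
    """Loadings, component weights, histories and config echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subs = result.subjects or [f"S{i}" for i in range(len(result.A1))]
    for name, arr in (("loadings_fa", result.A1), ("loadings_snp", result.A2)):
        pd.DataFrame(arr, index=subs).to_csv(out_dir / f"{name}.csv",
                                             index_label="id")
    np.savetxt(out_dir / "components_fa.tsv", result.S1, delimiter="\t")
    np.savetxt(out_dir / "components_snp.tsv", result.S2, delimiter="\t")
    meta = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(result.config).items()},
        "converged": result.converged,
        "n_iterations": result.n_iterations,
        "constrained_pair": (list(result.constrained_pair)
                             if result.constrained_pair else None),
        "entropy_history_fa": result.entropy_history_1.tolist(),
        "entropy_history_snp": result.entropy_history_2.tolist(),
        "constraint_corr_history": result.constraint_corr_history.tolist(),
    }
    (out_dir / "decomposition.json").write_text(json.dumps(meta, indent=2))
    if covariates is not None:
        covariates.to_csv(out_dir / "covariates.csv", index=False)


def write_report(report: dict, out_dir, stem: str = "report") -> None:
    """JSON plus a short human-readable text rendering."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{stem}.json").write_text(
        json.dumps(report, indent=2, default=_jsonable))
    lines = [f"{k}: {v}" for k, v in report.items()]
    (out_dir / f"{stem}.txt").write_text("\n".join(lines) + "\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return str(obj)
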