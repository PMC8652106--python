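"""Reference-panel handling: allele frequencies and per-block LD matrices.

A :class:`GenotypePanel` holds diploid alt-allele dosages (samples x
variants, values in [0,2], NaN for missing) with a variant index keyed by
``chrom:pos:ref:alt``.  Panels are read from VCF (GT or DS fields, biallelic
SNPs only) via cyvcf2, or built in memory (the synthetic module does this).

LD matrices are dense Pearson correlation matrices over a block's variants,
aligned to the caller's variant order.  Sample correlation matrices from
small panels (or pairwise-complete computation with missingness) can fail to
be positive semi-definite; :func:`repair_psd` clips negative eigenvalues and
renormalizes the diagonal, recording that it did so.  Matrices can also be
precomputed once and reloaded per block (``.npz`` with an embedded variant
index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PSD_TOL = 1e-8


@dataclass
class LDMatrix:
    """Per-block SNP x SNP correlation matrix aligned to ``variants``."""

    variants: list[str]
    R: np.ndarray
    provenance: str = ""
    repaired: bool = False
    zero_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        R = self.R
        if R.shape != (len(self.variants), len(self.variants)):
            raise ValueError("LD matrix shape does not match variant list")
        if np.abs(R - R.T).max(initial=0.0) > PSD_TOL:
            raise ValueError("LD matrix is not symmetric")
        if len(self.variants) and np.abs(np.diag(R) - 1.0).max() > PSD_TOL:
            raise ValueError("LD matrix diagonal must be 1")

    def __len__(self) -> int:
        return len(self.variants)


def repair_psd(R: np.ndarray) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues to 0 and renormalize the diagonal to 1.

    Returns ``(matrix, repaired)``; matrices already PSD (to 1e-8) are
    returned untouched.
    """
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    if w.min(initial=0.0) >= -PSD_TOL:
        return R, False
    w = np.clip(w, 0.0, None)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.clip(np.diag(R2), 1e-12, None))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    R2 = (R2 + R2.T) / 2.0
    return R2, True


@dataclass
class GenotypePanel:
    """Diploid dosage matrix (samples x variants) plus a variant index.

    ``variants`` has columns ``chrom, pos, ref, alt, id``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage column count does not match variant index")
        if "id" not in self.variants.columns:
            v = self.variants
            self.variants = v.assign(
                id=v["chrom"].astype(str) + ":" + v["pos"].astype(str) + ":" + v["ref"] + ":" + v["alt"]
            )
        if not self.samples:
            self.samples = [f"S{i}" for i in range(self.dosages.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    def column_index(self, variant_ids) -> np.ndarray:
        """Positions of ``variant_ids`` in the panel (-1 where absent)."""
        lookup = pd.Series(np.arange(len(self.variants)), index=self.variants["id"])
        return lookup.reindex(list(variant_ids)).fillna(-1).to_numpy(dtype=np.int64)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypePanel":
        """Read biallelic SNPs from a VCF; DS preferred, else GT allele counts.

        Multi-allelic records and indels are skipped with a log entry.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        cols, rows = [], []
        n_skipped = 0
        for v in vcf:
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                n_skipped += 1
                continue
            try:
                ds = v.format("DS")
            except KeyError:
                ds = None
            if ds is not None:
                d = np.asarray(ds, dtype=float).reshape(-1)
            else:
                # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
                gt = v.gt_types
                d = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
            rows.append({"chrom": str(v.CHROM), "pos": int(v.POS), "ref": v.REF, "alt": v.ALT[0]})
            cols.append(d)
        if n_skipped:
            logger.info("from_vcf(%s): skipped %d non-biallelic-SNP records", path, n_skipped)
        if not cols:
            raise ValueError(f"no biallelic SNPs in {path}")
        return cls(np.column_stack(cols), pd.DataFrame(rows), samples)


def panel_frequencies(panel: GenotypePanel, variant_ids) -> pd.Series:
    """Alt-allele frequency per requested variant: mean dosage / 2 over
    non-missing samples.  Variants absent from the panel get NaN (reported)."""
    idx = panel.column_index(variant_ids)
    out = np.full(len(idx), np.nan)
    present = idx >= 0
    if present.any():
        with np.errstate(invalid="ignore"):
            out[present] = np.nanmean(panel.dosages[:, idx[present]], axis=0) / 2.0
    n_absent = int((~present).sum())
    if n_absent:
        logger.warning("panel_frequencies: %d requested variants absent from panel", n_absent)
    return pd.Series(out, index=list(variant_ids))


def _pairwise_corr(X: np.ndarray, min_overlap: int) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation with pairwise-complete observations.

    Returns (R, zero_variance_flags).  Pairs with fewer than ``min_overlap``
    complete observations, or involving a zero-variance column, get r = 0.
    """
    if not np.isnan(X).any():
        sd = X.std(axis=0)
        zero_var = sd == 0
        Xc = X - X.mean(axis=0)
        Xc[:, zero_var] = 0.0
        denom = np.where(zero_var, 1.0, sd)
        Z = Xc / denom
        R = (Z.T @ Z) / X.shape[0]
        R[zero_var, :] = 0.0
        R[:, zero_var] = 0.0
        np.fill_diagonal(R, 1.0)
        return R, zero_var
    # missing data: masked pairwise computation
    M = (~np.isnan(X)).astype(float)
    X0 = np.nan_to_num(X)
    n_pair = M.T @ M
    s1 = X0.T @ M
    s2 = (X0 ** 2).T @ M
    sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_i = s1 / n_pair
        cov = sxy / n_pair - mean_i * mean_i.T
        var_i = s2 / n_pair - mean_i ** 2
        R = cov / np.sqrt(var_i * var_i.T)
    zero_var = np.nanvar(X, axis=0) == 0
    bad = ~np.isfinite(R) | (n_pair < min_overlap)
    R = np.where(bad, 0.0, R)
    R[zero_var, :] = 0.0
    R[:, zero_var] = 0.0
    R = np.clip(R, -1.0, 1.0)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R, zero_var


def ld_matrix(
    panel: GenotypePanel,
    variant_ids,
    repair: bool = True,
    min_overlap: int = 30,
) -> LDMatrix:
    """Pearson LD matrix of the requested variants from panel dosages.

    Needs >= 2 samples.  Requested variants absent from the panel raise
    KeyError (align the block first; :func:`block_ld` drops them instead).
    """
    if panel.n_samples < 2:
        raise ValueError("LD computation needs at least 2 panel samples")
    idx = panel.column_index(variant_ids)
    if (idx < 0).any():
        missing = [v for v, i in zip(variant_ids, idx) if i < 0]
        raise KeyError(f"variants absent from panel: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    X = panel.dosages[:, idx].astype(float)
    R, zero_var = _pairwise_corr(X, min_overlap)
    repaired = False
    if repair:
        R, repaired = repair_psd(R)
    if zero_var.any():
        logger.warning("ld_matrix: %d zero-variance columns set to r=0", int(zero_var.sum()))
    return LDMatrix(list(variant_ids), R, provenance="panel", repaired=repaired, zero_variance=zero_var)


def save_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    """One compressed dense matrix per block with its variant index."""
    np.savez_compressed(path, R=ld.R, variants=np.asarray(ld.variants, dtype=object))


def load_ld_matrix(path: str | Path, variant_ids) -> tuple[LDMatrix, list[str]]:
    """Load a stored block matrix and re-order it to ``variant_ids``.

    Returns ``(ld, missing)`` where ``missing`` lists requested variants not
    present in the stored matrix (callers drop them from the block).
    """
    try:
        with np.load(path, allow_pickle=True) as f:
            R = f["R"]
            stored = [str(v) for v in f["variants"]]
    except Exception as e:  # corrupt/unreadable file
        raise ValueError(f"cannot read LD matrix {path}: {e}") from e
    lookup = {v: i for i, v in enumerate(stored)}
    requested = list(variant_ids)
    missing = [v for v in requested if v not in lookup]
    kept = [v for v in requested if v in lookup]
    if missing:
        logger.warning("load_ld_matrix(%s): %d requested variants missing", path, len(missing))
    idx = np.array([lookup[v] for v in kept], dtype=np.int64)
    sub = R[np.ix_(idx, idx)] if len(idx) else np.empty((0, 0))
    return LDMatrix(kept, sub, provenance=str(path)), missing
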