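"""Multi-causal PGS weights: per-block sum-of-single-effects fine-mapping.

Pipeline: p-value thinning (block level then variant level), then for each
surviving block obtain an LD matrix (from a reference panel, from
precomputed per-block files, or from any callable source), fit
:func:`finepgs.susie.susie_rss` on z = beta/se, and use the per-variant
posterior inclusion probability as the PGS weight.  Variants thinned away or
in skipped blocks simply receive no entry (weight 0 by omission).

The prior effect variance W can be fixed ("informed": the effect-scale W is
converted per-variant to the z scale as sigma0^2 = W / se^2) or estimated
per component during fitting ("auto", the recommended mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .ldref import GenotypePanel, LDMatrix, ld_matrix, load_ld_matrix
from .regions import ThinningSpec, ThinReport, thin
from .single import PriorSpec
from .sumstats import PGSModel, SumStats
from .susie import SusieFit, pip, susie_rss

logger = logging.getLogger(__name__)

#: LD source: a GenotypePanel, a directory of <block_id>.npz files, or a
#: callable (block_id, variant_ids) -> (LDMatrix, missing_variant_ids)
LDSource = GenotypePanel | str | Path | Callable


@dataclass
class BlockFitLog:
    block_id: str
    n_variants: int
    converged: bool
    n_iter: int
    status: str = "ok"  # ok | skipped_no_ld


def get_block_ld(source: LDSource, block_id: str, variant_ids) -> tuple[LDMatrix, list[str]]:
    """Resolve a block's LD matrix from whichever source was configured.

    Returns ``(ld, missing)``; ``missing`` lists requested variants the
    source cannot cover (they are dropped from the block).
    """
    if isinstance(source, GenotypePanel):
        idx = source.column_index(variant_ids)
        missing = [v for v, i in zip(variant_ids, idx) if i < 0]
        kept = [v for v, i in zip(variant_ids, idx) if i >= 0]
        if not kept:
            return LDMatrix([], np.empty((0, 0))), missing
        return ld_matrix(source, kept), missing
    if callable(source):
        return source(block_id, variant_ids)
    path = Path(source) / f"{block_id}.npz"
    if not path.exists():
        return LDMatrix([], np.empty((0, 0))), list(variant_ids)
    return load_ld_matrix(path, variant_ids)


def multi_weights(
    ss: SumStats,
    ld: LDSource,
    thinning: ThinningSpec | None = None,
    L: int | None = None,
    prior: PriorSpec | None = None,
    auto_w: bool = True,
    prior_weights: pd.Series | None = None,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> tuple[PGSModel, list[BlockFitLog], ThinReport]:
    """Multi-causal PGS: thin, fine-map each block, weight by PIP.

    Parameters
    ----------
    ss
        QC'd, block-annotated summary statistics.
    ld
        LD source (panel, precomputed directory, or callable).
    L
        Components per block; default ``min(10, p)`` per block.
    prior
        Supplies the effect-scale W for informed mode (resolved as in the
        single flavour when ``auto_w=False``).
    auto_w
        Estimate each component's prior variance internally (recommended).
    prior_weights
        Optional per-variant prior weights indexed like ``ss.variant_ids``;
        uniform within block by default.

    Returns the model, per-block convergence logs, and the thinning report.
    Weights equal PIP; a ``posterior_mean`` column carries the alternative
    (z-scale) posterior-mean effect per variant.
    """
    thinning = thinning or ThinningSpec()
    prior = prior or PriorSpec()
    if "block" not in ss.table.columns:
        raise ValueError("multi_weights needs a block-annotated table (run assign_blocks first)")
    thinned, thin_report = thin(ss, thinning)
    df = thinned.table
    logs: list[BlockFitLog] = []
    if df.empty:
        cols = ["chrom", "pos", "other_allele", "effect_allele", "beta", "weight_ppi", "weight", "posterior_mean"]
        return PGSModel(pd.DataFrame(columns=cols)), logs, thin_report

    W = None if auto_w else prior.resolve_w(thinned)
    vids_all = thinned.variant_ids
    pieces: list[pd.DataFrame] = []
    for block_id, idx in df.groupby("block", sort=False).indices.items():
        sub = df.iloc[idx]
        vids = vids_all.iloc[idx].tolist()
        ldm, missing = get_block_ld(ld, str(block_id), vids)
        if missing:
            keep = ~vids_all.iloc[idx].isin(missing).to_numpy()
            sub = sub[keep]
            vids = [v for v in vids if v not in set(missing)]
        if len(sub) == 0 or len(ldm) != len(sub):
            logger.error("block %s skipped: LD could not be aligned", block_id)
            logs.append(BlockFitLog(str(block_id), 0, False, 0, status="skipped_no_ld"))
            continue
        z = (sub["beta"] / sub["se"]).to_numpy()
        Lb = min(L if L is not None else 10, len(sub))
        if auto_w:
            fit = susie_rss(z, ldm, L=Lb, prior_variance=1.0, estimate_prior_variance=True,
                            prior_weights=None if prior_weights is None else prior_weights.reindex(vids).to_numpy(),
                            tol=tol, max_iter=max_iter)
        else:
            v0 = W / sub["se"].to_numpy() ** 2  # effect-scale W -> z scale
            fit = susie_rss(z, ldm, L=Lb, prior_variance=v0, estimate_prior_variance=False,
                            prior_weights=None if prior_weights is None else prior_weights.reindex(vids).to_numpy(),
                            tol=tol, max_iter=max_iter)
        logs.append(BlockFitLog(str(block_id), len(sub), fit.converged, fit.n_iter))
        w = np.minimum(pip(fit), np.nextafter(1.0, 0.0))
        piece = sub[["chrom", "pos", "other_allele", "effect_allele", "beta"]].copy()
        piece["weight_ppi"] = w
        piece["weight"] = piece["weight_ppi"] * piece["beta"]
        piece["posterior_mean"] = fit.posterior_mean
        pieces.append(piece)
    if not pieces:
        cols = ["chrom", "pos", "other_allele", "effect_allele", "beta", "weight_ppi", "weight", "posterior_mean"]
        return PGSModel(pd.DataFrame(columns=cols)), logs, thin_report
    model = PGSModel(pd.concat(pieces, ignore_index=True))
    n_fail = sum(1 for lg in logs if lg.status == "ok" and not lg.converged)
    if n_fail:
        logger.warning("%d/%d blocks did not converge within max_iter", n_fail, len(logs))
    return model, logs, thin_report
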