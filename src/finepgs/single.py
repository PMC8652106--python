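"""Single-causal-variant PGS weights from Wakefield approximate Bayes factors.

Within each LD block we assume at most one causal variant whose true effect
is drawn from N(0, W).  For a variant with estimated effect ``beta`` and
standard error ``se`` (V = se^2), the approximate Bayes factor comparing the
causal model against the null is the ratio of two normal densities evaluated
at ``beta``:

    BF = N(beta; 0, W + V) / N(beta; 0, V)

With a per-SNP prior probability of causality ``pi`` and null-model prior
``pi0 = 1 - n*pi`` for a block of n variants, the posterior probability that
variant i is the causal one is

    PP_i = pi * BF_i / (pi0 + sum_j pi * BF_j)

so that PP0 + sum_i PP_i = 1 and every PP_i < 1.  All arithmetic is on the
log scale with a log-sum-exp reduction: genome-wide-significant z-scores
produce log-BFs of several hundred, which overflow on the linear scale.

The PGS weight of a variant is its PP, and its contribution to the score is
PP_i * beta_i.  Defaults follow widely adopted fine-mapping values:
pi = 1e-4 and W = 0.2^2 for case-control traits; for quantitative traits W
is estimated from the trait heritability via :func:`estimate_w_quantitative`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import PGSModel, SumStats

logger = logging.getLogger(__name__)


@dataclass
class PriorSpec:
    """Priors for the causal model.

    pi
        Per-SNP prior probability of causality (default 1e-4).
    W
        Prior variance of the true effect size; ``None`` means "resolve
        later" (0.2^2 for case-control, heritability-based for quantitative).
    nu
        The per-variant causality prior used inside the W-estimation formula
        (default 1e-4).
    h2
        Trait heritability, needed to estimate W for quantitative traits.
    """

    pi: float = 1e-4
    W: float | None = None
    nu: float = 1e-4
    h2: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.pi < 1):
            raise ValueError("pi must lie in (0, 1)")
        if self.W is not None and self.W <= 0:
            raise ValueError("W must be positive")
        if not (0 < self.nu < 1):
            raise ValueError("nu must lie in (0, 1)")
        if self.h2 is not None and not (0 < self.h2 < 1):
            raise ValueError("h2 must lie in (0, 1)")

    def resolve_w(self, ss: SumStats) -> float:
        """Return W, estimating it for quantitative traits if not supplied."""
        if self.W is not None:
            return self.W
        if ss.trait_type == "cc":
            return 0.2 ** 2
        if self.h2 is None:
            raise ValueError("quantitative traits need either W or h2 to resolve the prior variance")
        df = ss.table
        if "n" not in df.columns:
            raise ValueError("estimating W needs a per-SNP n column")
        return estimate_w_quantitative(self.h2, df["se"].to_numpy(), df["n"].to_numpy(), self.nu)


@dataclass
class BlockPosterior:
    """Per-block posterior under the at-most-one-causal-variant model."""

    block_id: str
    log_bf: np.ndarray
    pp: np.ndarray
    pp0: float


def log_abf(beta, se, W):
    """Wakefield log approximate Bayes factor.

    ``log N(beta; 0, W+V) - log N(beta; 0, V)`` with V = se^2, in the
    numerically stable closed form

        0.5 * [ log(V / (V+W)) + z^2 * W / (V+W) ],  z = beta/se.

    Monotone increasing in |z| at fixed se and W; identically 0 at W = 0.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    W = np.asarray(W, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se)) and np.all(np.isfinite(W))):
        raise ValueError("log_abf inputs must be finite")
    if np.any(se <= 0) or np.any(W < 0):
        raise ValueError("log_abf needs se > 0 and W >= 0")
    V = se ** 2
    r = W / (V + W)  # in [0, 1)
    z2 = (beta / se) ** 2
    return 0.5 * (np.log1p(-r) + z2 * r)


def block_pp(log_bfs, pi: float = 1e-4) -> tuple[np.ndarray, float]:
    """Posterior probabilities of causality within one block.

    Returns ``(pp, pp0)`` with ``pp0 + pp.sum() == 1`` (log-sum-exp over the
    n variant terms plus the log(pi0) null term).  If ``n*pi >= 1`` (huge
    block) pi is rescaled to ``0.9/n`` with a warning so pi0 stays positive.
    """
    log_bfs = np.asarray(log_bfs, dtype=float)
    n = log_bfs.size
    if n < 1:
        raise ValueError("empty block")
    if n * pi >= 1:
        new_pi = 0.9 / n
        logger.warning("block of %d variants: n*pi >= 1, rescaling pi from %g to %g", n, pi, new_pi)
        pi = new_pi
    pi0 = 1.0 - n * pi
    terms = np.concatenate([[np.log(pi0)], np.log(pi) + log_bfs])
    denom = logsumexp(terms)
    pp = np.exp(np.log(pi) + log_bfs - denom)
    # PP < 1 holds exactly in real arithmetic (pi0 > 0); with log-BFs of
    # several hundred the null mass underflows relative to 1, so enforce
    # strictness at 1 ulp rather than return a rounded 1.0
    pp = np.minimum(pp, np.nextafter(1.0, 0.0))
    pp0 = float(np.exp(np.log(pi0) - denom))
    return pp, pp0


def estimate_w_quantitative(h2: float, se, n, nu: float = 1e-4) -> float:
    """Heritability-informed prior effect variance for quantitative traits:

        W = h^2 / (nu * sum_i 1 / (N_i * se_i^2))

    For a standardized trait 1/(N_i se_i^2) ~ var(G_i), so the denominator is
    nu times the total genotypic variance across the p variants, and nu*W*
    sum var(G_i) recovers the expected heritability.
    """
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if not (0 < h2 < 1) or not (0 < nu < 1):
        raise ValueError("h2 and nu must lie in (0, 1)")
    if np.any(se <= 0) or np.any(n <= 0):
        raise ValueError("se and n must be positive")
    denom = nu * np.sum(1.0 / (n * se ** 2))
    if not np.isfinite(denom) or denom <= 0:
        raise ValueError("degenerate denominator in W estimation")
    W = h2 / denom
    logger.info("estimated W = %.6g (implied per-SNP prior sd sqrt(W) = %.4g)", W, np.sqrt(W))
    return float(W)


def single_weights(ss: SumStats, prior: PriorSpec | None = None) -> tuple[PGSModel, list[BlockPosterior]]:
    """Single-causal-variant PGS: per-variant weight = its within-block PP.

    Requires a QC'd, block-annotated table (``block`` column).  Weights are
    independent of row order within the table.
    """
    prior = prior or PriorSpec()
    df = ss.table
    if "block" not in df.columns:
        raise ValueError("single_weights needs a block-annotated table (run assign_blocks first)")
    W = prior.resolve_w(ss)
    lbf_all = log_abf(df["beta"].to_numpy(), df["se"].to_numpy(), W)
    weight = np.empty(len(df))
    posteriors: list[BlockPosterior] = []
    for block_id, idx in df.groupby("block", sort=False).indices.items():
        pp, pp0 = block_pp(lbf_all[idx], prior.pi)
        weight[idx] = pp
        posteriors.append(BlockPosterior(str(block_id), lbf_all[idx], pp, pp0))
    out = df[["chrom", "pos", "other_allele", "effect_allele", "beta"]].copy()
    out["weight_ppi"] = weight
    out["weight"] = out["weight_ppi"] * out["beta"]
    return PGSModel(out.reset_index(drop=True)), posteriors
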