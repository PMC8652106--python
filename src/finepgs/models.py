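"""Model/Results interface over the PGS builders.

Two model classes mirror the two fine-mapping flavours:

* :class:`SingleCausalPGS` — closed-form Wakefield-ABF posteriors under the
  at-most-one-causal-variant-per-block assumption; needs no LD information.
* :class:`MultiCausalPGS` — per-block sum-of-single-effects variational
  fine-mapping on z-scores; needs an LD source (reference panel or
  precomputed matrices).

Both are constructed from data (a :class:`~finepgs.sumstats.SumStats` table
and an LD-block set) and ``fit()`` returns a :class:`PGSResults` carrying
the per-variant weights, per-block diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import qc as _qc
from .multi import BlockFitLog, LDSource, multi_weights
from .regions import LDBlockSet, ThinningSpec, ThinReport, assign_blocks, load_blocks
from .single import BlockPosterior, PriorSpec, single_weights
from .sumstats import PGSModel, SumStats, read_sumstats, write_pgs_model

__all__ = ["SingleCausalPGS", "MultiCausalPGS", "PGSResults"]


@dataclass
class PGSResults:
    """Fitted PGS weights plus diagnostics.

    ``weights`` is the serializable per-variant table (final weight =
    posterior probability x estimated effect).  ``block_posteriors`` holds
    the single-flavour per-block posteriors; ``fit_logs`` the multi-flavour
    per-block convergence records.
    """

    model: object
    weights: PGSModel
    prior: PriorSpec
    block_posteriors: list[BlockPosterior] | None = None
    fit_logs: list[BlockFitLog] | None = None
    thin_report: ThinReport | None = None
    qc_report: _qc.QCReport | None = None

    @property
    def params(self) -> pd.Series:
        """Final per-variant weights indexed by variant id."""
        return pd.Series(self.weights.table["weight"].to_numpy(), index=self.weights.variant_ids.to_numpy())

    def save(self, path: str | Path) -> None:
        write_pgs_model(self.weights, path)

    def score(self, dosages: pd.DataFrame) -> pd.Series:
        from .evaluate import score as _score

        return _score(self.weights, dosages)[0]

    def summary(self) -> str:
        t = self.weights.table
        lines = [
            f"{type(self.model).__name__} results",
            "=" * 40,
            f"variants with weights : {len(t)}",
            f"prior pi              : {self.prior.pi:g}",
        ]
        if self.prior.W is not None:
            lines.append(f"prior W               : {self.prior.W:g}")
        if len(t):
            lines += [
                f"sum of weights (PP)   : {t['weight_ppi'].sum():.4f}",
                f"max weight_ppi        : {t['weight_ppi'].max():.4f}",
            ]
            top = t.nlargest(min(5, len(t)), "weight_ppi")
            lines.append("top variants (chrom:pos  PP  final weight):")
            for _, r in top.iterrows():
                lines.append(f"  {r['chrom']}:{r['pos']}  {r['weight_ppi']:.4f}  {r['weight']:+.5f}")
        if self.thin_report is not None:
            tr = self.thin_report
            lines.append(
                f"thinning              : {tr.n_blocks_kept}/{tr.n_blocks_input} blocks, "
                f"{tr.n_variants_kept}/{tr.n_variants_input} variants kept"
            )
        if self.fit_logs is not None:
            ok = [lg for lg in self.fit_logs if lg.status == "ok"]
            lines.append(
                f"block fits            : {len(ok)} fitted, "
                f"{sum(lg.converged for lg in ok)} converged"
            )
        return "\n".join(lines)


class _PGSBase:
    """Shared construction: attach blocks, optional SD filter."""

    def __init__(self, sumstats: SumStats, blocks: LDBlockSet, prior: PriorSpec | None = None,
                 sd_filter: bool = False):
        self.prior = prior or PriorSpec()
        self.qc_report = None
        if sd_filter:
            sumstats, self.qc_report = _qc.sd_filter(sumstats)
        if "block" not in sumstats.table.columns:
            sumstats = assign_blocks(sumstats, blocks)
        self.sumstats = sumstats
        self.blocks = blocks


class SingleCausalPGS(_PGSBase):
    """At-most-one-causal-variant PGS model (no LD needed).

    Examples
    --------
    >>> model = SingleCausalPGS.from_files("sumstats.tsv", "blocks.bed", trait_type="cc")
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.save("weights.tsv")
    """

    @classmethod
    def from_files(cls, sumstats_path, blocks_path, trait_type: str = "cc",
                   column_map=None, prior: PriorSpec | None = None, sd_filter: bool = False):
        ss = read_sumstats(sumstats_path, column_map=column_map, trait_type=trait_type)
        return cls(ss, load_blocks(blocks_path), prior=prior, sd_filter=sd_filter)

    def fit(self) -> PGSResults:
        weights, posteriors = single_weights(self.sumstats, self.prior)
        resolved = PriorSpec(self.prior.pi, self.prior.W if self.prior.W is not None
                             else self.prior.resolve_w(self.sumstats),
                             self.prior.nu, self.prior.h2)
        return PGSResults(self, weights, resolved, block_posteriors=posteriors,
                          qc_report=self.qc_report)


class MultiCausalPGS(_PGSBase):
    """Multi-causal (sum-of-single-effects) PGS model.

    Parameters beyond the base: an LD source, the thinning thresholds, the
    number of components per block and the W mode (``auto_w=True`` estimates
    each component's prior variance internally).
    """

    def __init__(self, sumstats: SumStats, blocks: LDBlockSet, ld: LDSource,
                 thinning: ThinningSpec | None = None, L: int | None = None,
                 prior: PriorSpec | None = None, auto_w: bool = True,
                 sd_filter: bool = False, tol: float = 1e-3, max_iter: int = 100):
        super().__init__(sumstats, blocks, prior=prior, sd_filter=sd_filter)
        self.ld = ld
        self.thinning = thinning or ThinningSpec()
        self.L = L
        self.auto_w = auto_w
        self.tol = tol
        self.max_iter = max_iter

    @classmethod
    def from_files(cls, sumstats_path, blocks_path, ld, trait_type: str = "cc",
                   column_map=None, **kwargs):
        """``ld`` may be a panel VCF path, a directory of precomputed
        per-block matrices, or any in-memory LD source."""
        if isinstance(ld, (str, Path)) and str(ld).endswith((".vcf", ".vcf.gz")):
            from .ldref import GenotypePanel

            ld = GenotypePanel.from_vcf(ld)
        ss = read_sumstats(sumstats_path, column_map=column_map, trait_type=trait_type)
        return cls(ss, load_blocks(blocks_path), ld, **kwargs)

    def fit(self) -> PGSResults:
        weights, logs, thin_report = multi_weights(
            self.sumstats, self.ld, thinning=self.thinning, L=self.L,
            prior=self.prior, auto_w=self.auto_w, tol=self.tol, max_iter=self.max_iter,
        )
        return PGSResults(self, weights, self.prior, fit_logs=logs,
                          thin_report=thin_report, qc_report=self.qc_report)
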