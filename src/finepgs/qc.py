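"""Summary-statistic quality control.

Implements the LDpred2-style concordance filter between two estimates of the
per-SNP genotype standard deviation:

* ``SD_ss = 2 / (sqrt(N_eff) * SE)`` — implied by the reported standard
  error (for a log-OR from a balanced 2x2 table this approximates sd(G)),
* ``SD_val = sqrt(2 f (1 - f))`` — implied by the effect-allele frequency
  under Hardy-Weinberg.

Variants where the two disagree (wrong sample size, mis-scaled effects,
allele-frequency errors) are excluded by four rules:
``SD_ss < 0.5*SD_val``, ``SD_ss > SD_val + 0.1``, ``SD_ss < 0.1``,
``SD_val < 0.05``.

For case-control traits ``N_eff = 4 / (1/N_controls + 1/N_cases)``; for
quantitative traits the per-SNP N is used directly.  Note the 2/(sqrt(N)*SE)
form is calibrated for log-OR inputs — for a standardized quantitative trait
SD_ss sits near 2*SD_val, so inspect the SD scatter before filtering
quantitative data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import SumStats

logger = logging.getLogger(__name__)

SD_RULES = ("sd_ss_lt_half_sd_val", "sd_ss_gt_sd_val_plus_0.1", "sd_ss_lt_0.1", "sd_val_lt_0.05")


@dataclass
class QCReport:
    """Per-rule diagnostics from :func:`sd_filter`.

    ``rule_counts`` counts each rule independently (a variant failing several
    rules appears under each); ``n_removed`` counts unique removed variants,
    so ``n_input == n_output + n_removed``.
    """

    n_input: int = 0
    n_output: int = 0
    n_removed: int = 0
    rule_counts: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(
        default_factory=lambda: {"half_ratio": 0.5, "excess": 0.1, "min_sd_ss": 0.1, "min_sd_val": 0.05}
    )
    sd_ss: np.ndarray | None = None
    sd_val: np.ndarray | None = None
    kept: np.ndarray | None = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k in ("sd_ss", "sd_val", "kept"):
            d.pop(k)
        return json.dumps(d)


def effective_sample_size(n_cases, n_controls):
    """Effective sample size of a case-control GWAS,
    ``4 / (1/n_controls + 1/n_cases)``.  Equals ``2N`` for a balanced design
    of N cases and N controls, and never exceeds the total sample size."""
    n_cases = np.asarray(n_cases, dtype=float)
    n_controls = np.asarray(n_controls, dtype=float)
    if np.any(n_cases <= 0) or np.any(n_controls <= 0):
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_controls + 1.0 / n_cases)


def sd_summary(se, n_eff):
    """Genotype SD implied by the standard error: ``2 / (sqrt(n_eff) * se)``.

    Non-finite or non-positive inputs yield NaN (flagged, excluded by the
    filter) rather than raising."""
    se = np.asarray(se, dtype=float)
    n_eff = np.asarray(n_eff, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 2.0 / (np.sqrt(n_eff) * se)
    bad = ~np.isfinite(out) | (se <= 0) | (n_eff <= 0)
    return np.where(bad, np.nan, out)


def sd_validation(freq):
    """Genotype SD implied by the allele frequency: ``sqrt(2 f (1-f))``.

    Symmetric in f <-> 1-f, maximal (sqrt(0.5)) at f = 0.5.  Frequencies
    outside (0,1) yield NaN."""
    f = np.asarray(freq, dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.sqrt(2.0 * f * (1.0 - f))
    bad = ~((f > 0) & (f < 1))
    return np.where(bad, np.nan, out)


def annotate_sd(ss: SumStats) -> SumStats:
    """Attach ``n_eff``, ``sd_ss`` and ``sd_val`` columns.

    Case-control tables need ``n_cases``/``n_controls``; quantitative tables
    use the per-SNP ``n`` as N_eff."""
    df = ss.table.copy()
    if ss.trait_type == "cc":
        if not {"n_cases", "n_controls"} <= set(df.columns):
            raise ValueError("case-control SD annotation needs n_cases and n_controls columns")
        df["n_eff"] = effective_sample_size(df["n_cases"], df["n_controls"])
    else:
        if "n" not in df.columns:
            raise ValueError("quantitative SD annotation needs an n column")
        df["n_eff"] = df["n"].astype(float)
    df["sd_ss"] = sd_summary(df["se"], df["n_eff"])
    if "freq" not in df.columns:
        raise ValueError("sd_val needs an effect-allele frequency column (harmonize to a panel first)")
    df["sd_val"] = sd_validation(df["freq"])
    return SumStats(df, ss.trait_type, ss.source, ss.read_report)


def sd_filter(ss: SumStats) -> tuple[SumStats, QCReport]:
    """Apply the four SD concordance rules; returns the filtered table and a
    :class:`QCReport` retaining the (SD_ss, SD_val) pairs for plotting.

    Idempotent: a table that already passed is returned unchanged."""
    df = ss.table
    if not {"sd_ss", "sd_val"} <= set(df.columns):
        ss = annotate_sd(ss)
        df = ss.table
    sd_ss = df["sd_ss"].to_numpy(dtype=float)
    sd_val = df["sd_val"].to_numpy(dtype=float)

    with np.errstate(invalid="ignore"):
        fails = {
            "sd_ss_lt_half_sd_val": sd_ss < 0.5 * sd_val,
            "sd_ss_gt_sd_val_plus_0.1": sd_ss > sd_val + 0.1,
            "sd_ss_lt_0.1": sd_ss < 0.1,
            "sd_val_lt_0.05": sd_val < 0.05,
        }
    nonfinite = ~np.isfinite(sd_ss) | ~np.isfinite(sd_val)
    removed = nonfinite.copy()
    report = QCReport(n_input=len(df), sd_ss=sd_ss, sd_val=sd_val)
    if nonfinite.any():
        report.rule_counts["non_finite_sd"] = int(nonfinite.sum())
    for rule, mask in fails.items():
        report.rule_counts[rule] = int(mask.sum())
        removed |= mask
    report.kept = ~removed
    report.n_removed = int(removed.sum())
    report.n_output = int((~removed).sum())
    out = SumStats(df[~removed].reset_index(drop=True), ss.trait_type, ss.source, ss.read_report)
    if report.n_removed:
        logger.info("sd_filter removed %d/%d variants: %s", report.n_removed, report.n_input, report.rule_counts)
    return out, report


def restrict_to_set(ss: SumStats, variant_set) -> SumStats:
    """Keep only variants whose ``chrom:pos:other:effect`` id is in
    ``variant_set`` (e.g. a HapMap3-style list); order preserved.  An empty
    intersection is an error."""
    ids = ss.variant_ids
    keep = ids.isin(set(variant_set)).to_numpy()
    if not keep.any():
        raise ValueError("variant set shares no variants with the summary statistics")
    return SumStats(ss.table[keep].reset_index(drop=True), ss.trait_type, ss.source, ss.read_report)


def plot_sd_scatter(report: QCReport, path: str | Path) -> None:
    """SD_ss vs SD_val diagnostic scatter (kept vs removed), written to
    ``path``.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    kept = report.kept if report.kept is not None else np.ones(len(report.sd_ss), bool)
    ax.scatter(report.sd_val[kept], report.sd_ss[kept], s=4, alpha=0.5, label="kept")
    if (~kept).any():
        ax.scatter(report.sd_val[~kept], report.sd_ss[~kept], s=4, alpha=0.5, c="crimson", label="removed")
    lim = np.nanmax(np.concatenate([report.sd_val, report.sd_ss, [1.0]]))
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("SD_val = sqrt(2f(1-f))")
    ax.set_ylabel("SD_ss = 2/(sqrt(N_eff) SE)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
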