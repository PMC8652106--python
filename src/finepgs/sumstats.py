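"""Reading, harmonising and writing GWAS summary statistics and PGS weight tables.

Summary statistics arrive as delimited text with one row per biallelic SNP:
genomic coordinates, the effect and other allele, the marginal effect estimate
(log odds ratio for case-control traits, linear regression slope for
quantitative traits), its standard error, the effect-allele frequency, the
two-sided p-value and sample sizes.  Everything downstream assumes the table
has been read through :func:`read_sumstats` (which validates, de-duplicates
and sorts) and, when a reference panel is in play, passed through
:func:`harmonize_to_panel` so that the effect allele is always the panel's
alternate allele.

Coordinates are 1-based throughout this module (the summary-statistic and VCF
convention); LD-block intervals live in BED space and the conversion happens
in :mod:`finepgs.regions`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column names used throughout the package
REQUIRED_COLUMNS = ["chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval"]
OPTIONAL_COLUMNS = ["freq", "n", "n_cases", "n_controls"]

#: built-in dialect for GWAS-SSF-style headers
GWAS_SSF_MAP: dict[str, str] = {
    "chromosome": "chrom",
    "base_pair_location": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "standard_error": "se",
    "effect_allele_frequency": "freq",
    "p_value": "pval",
    "n": "n",
    "n_cases": "n_cases",
    "n_controls": "n_controls",
}

_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs that are their own reverse complement (strand-ambiguous)
AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

TRAIT_TYPES = ("cc", "quant")


@dataclass
class ReadReport:
    """Row-accounting for :func:`read_sumstats`.

    ``n_input`` equals ``n_output`` plus the sum of ``dropped`` counts.
    """

    n_input: int = 0
    n_output: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


@dataclass
class HarmonizeReport:
    n_input: int = 0
    n_output: int = 0
    n_flipped: int = 0
    n_ambiguous_resolved: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


@dataclass
class SumStats:
    """A validated, sorted table of per-variant GWAS summary statistics.

    Parameters
    ----------
    table
        DataFrame with the canonical columns (``chrom, pos, effect_allele,
        other_allele, beta, se, pval`` plus whichever of ``freq, n, n_cases,
        n_controls`` are available).  Extra annotation columns (``block``,
        ``sd_ss``, ``sd_val``, ``n_eff``) are added by downstream modules.
    trait_type
        ``"cc"`` (case-control; ``beta`` is a log odds ratio) or ``"quant"``.
    source
        Provenance label, typically the input path.
    """

    table: pd.DataFrame
    trait_type: str = "cc"
    source: str | None = None
    read_report: ReadReport | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"trait_type must be one of {TRAIT_TYPES}, got {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.table)

    def copy(self) -> "SumStats":
        return SumStats(self.table.copy(), self.trait_type, self.source, self.read_report)

    @property
    def variant_ids(self) -> pd.Series:
        """``chrom:pos:other:effect`` identifiers (panel orientation after
        harmonization: other=ref, effect=alt)."""
        t = self.table
        return (
            t["chrom"].astype(str)
            + ":"
            + t["pos"].astype(str)
            + ":"
            + t["other_allele"]
            + ":"
            + t["effect_allele"]
        )

    @property
    def z(self) -> np.ndarray:
        return (self.table["beta"] / self.table["se"]).to_numpy()


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Natural ordering: numeric chromosomes first, then lexicographic."""

    def key(c: str) -> tuple[int, int, str]:
        c = str(c).removeprefix("chr")
        try:
            return (0, int(c), "")
        except ValueError:
            return (1, 0, c)

    return chrom.map(key)


def _sort_table(df: pd.DataFrame) -> pd.DataFrame:
    out = df.assign(_ck=_chrom_sort_key(df["chrom"]))
    out = out.sort_values(["_ck", "pos"], kind="stable").drop(columns="_ck")
    return out.reset_index(drop=True)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | str | None = None,
    trait_type: str = "cc",
) -> SumStats:
    """Read a delimited summary-statistics file.

    Rows missing a required field, with invalid alleles (indels,
    multi-allelic, identical alleles), non-positive standard errors or
    p-values outside (0, 1] are dropped and counted in the attached
    :class:`ReadReport`.  Duplicate ``(chrom, pos, allele-pair)`` keys keep
    the first occurrence in file order.

    Parameters
    ----------
    column_map
        ``None`` (file already uses canonical names), ``"gwas-ssf"`` for the
        built-in GWAS-SSF dialect, or an explicit ``{file_name: canonical}``
        mapping.  Required columns that cannot be resolved raise ``ValueError``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype={"chrom": str})

    if column_map == "gwas-ssf":
        column_map = GWAS_SSF_MAP
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"required column(s) {missing} not found in {path.name}; "
            "supply a column_map resolving them"
        )
    keep_cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep_cols].copy()
    df["chrom"] = df["chrom"].astype(str)
    for allele_col in ("effect_allele", "other_allele"):
        df[allele_col] = df[allele_col].astype(str).str.upper()

    report = ReadReport(n_input=len(df))

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        n = int(mask.sum())
        if n:
            report.dropped[reason] = report.dropped.get(reason, 0) + n
            df = df[~mask]

    drop(df[REQUIRED_COLUMNS].isna().any(axis=1), "missing_required_field")
    drop(
        ~(df["effect_allele"].isin(_VALID_ALLELES) & df["other_allele"].isin(_VALID_ALLELES)),
        "non_snp_allele",
    )
    drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    drop(~(df["se"] > 0), "nonpositive_se")
    drop(~((df["pval"] > 0) & (df["pval"] <= 1)), "invalid_pval")
    drop(~(df["pos"] >= 1), "invalid_position")
    if "freq" in df.columns:
        bad_freq = df["freq"].notna() & ~((df["freq"] > 0) & (df["freq"] < 1))
        drop(bad_freq, "invalid_freq")

    # de-duplicate on the unordered allele pair, first occurrence wins
    a_lo = np.minimum(df["effect_allele"], df["other_allele"])
    a_hi = np.maximum(df["effect_allele"], df["other_allele"])
    key = df["chrom"] + ":" + df["pos"].astype(str) + ":" + a_lo + ":" + a_hi
    dup = key.duplicated(keep="first")
    drop(dup, "duplicate_key")

    if df.empty:
        raise ValueError(f"no rows in {path.name} survived validation")

    df["pos"] = df["pos"].astype(np.int64)
    df = _sort_table(df)
    report.n_output = len(df)
    if report.dropped:
        logger.info("read_sumstats(%s): dropped %s", path.name, report.dropped)
    return SumStats(df, trait_type=trait_type, source=str(path), read_report=report)


def flip_orientation(df: pd.DataFrame, mask: np.ndarray | pd.Series) -> pd.DataFrame:
    """Flip allele orientation for rows in ``mask``: swap alleles, negate
    beta, replace freq by 1-freq.  Applying it twice is the identity."""
    df = df.copy()
    m = np.asarray(mask, dtype=bool)
    ea = df.loc[m, "effect_allele"].copy()
    df.loc[m, "effect_allele"] = df.loc[m, "other_allele"]
    df.loc[m, "other_allele"] = ea
    df.loc[m, "beta"] = -df.loc[m, "beta"]
    if "freq" in df.columns:
        df.loc[m, "freq"] = 1.0 - df.loc[m, "freq"]
    return df


def harmonize_to_panel(
    ss: SumStats,
    panel_variants: pd.DataFrame,
    ambiguous_freq_margin: float = 0.05,
) -> tuple[SumStats, HarmonizeReport]:
    """Align a summary-statistics table to a reference panel's ref/alt alleles.

    After harmonization every surviving row has ``effect_allele == alt`` and
    ``other_allele == ref`` of the matching panel variant.  Rows whose allele
    pair matches in swapped orientation are flipped (beta negated, frequency
    complemented).  Strand flips (reverse-complement matches) are resolved by
    complementing; strand-ambiguous pairs (A/T, C/G) are resolved by
    frequency agreement against the panel and dropped when the two candidate
    orientations disagree by less than ``ambiguous_freq_margin`` or when a
    frequency is unavailable.  Variants absent from the panel, or with an
    irreconcilable allele pair, are dropped and counted.

    Parameters
    ----------
    panel_variants
        DataFrame with columns ``chrom, pos, ref, alt`` and optionally
        ``freq`` (panel alt-allele frequency, used for ambiguous SNPs and to
        fill missing summary-stat frequencies).
    """
    pv = panel_variants.copy()
    pv["chrom"] = pv["chrom"].astype(str)
    pv = pv.drop_duplicates(subset=["chrom", "pos"], keep="first")
    panel_cols = ["chrom", "pos", "ref", "alt"] + (["freq"] if "freq" in pv.columns else [])
    df = ss.table.merge(
        pv[panel_cols].rename(columns={"freq": "panel_freq"}),
        on=["chrom", "pos"],
        how="left",
    )
    report = HarmonizeReport(n_input=len(df))

    in_panel = df["ref"].notna()
    report.dropped["absent_from_panel"] = int((~in_panel).sum())
    df = df[in_panel].copy()

    ea, oa = df["effect_allele"], df["other_allele"]
    ref, alt = df["ref"], df["alt"]
    cea = ea.map(_COMPLEMENT)
    coa = oa.map(_COMPLEMENT)

    pair_is_ambiguous = (ea == oa.map(_COMPLEMENT))
    match_fwd = (ea == alt) & (oa == ref)
    match_rev = (ea == ref) & (oa == alt)
    match_comp_fwd = (cea == alt) & (coa == ref) & ~pair_is_ambiguous
    match_comp_rev = (cea == ref) & (coa == alt) & ~pair_is_ambiguous

    irreconcilable = ~(match_fwd | match_rev | match_comp_fwd | match_comp_rev)
    report.dropped["irreconcilable_alleles"] = int(irreconcilable.sum())
    df = df[~irreconcilable].copy()
    match_fwd, match_rev = match_fwd[~irreconcilable], match_rev[~irreconcilable]
    match_comp_fwd = match_comp_fwd[~irreconcilable]
    match_comp_rev = match_comp_rev[~irreconcilable]
    pair_is_ambiguous = pair_is_ambiguous[~irreconcilable]

    # strand flips: complement the reported alleles, orientation logic below
    comp_mask = (match_comp_fwd | match_comp_rev).to_numpy()
    if comp_mask.any():
        df.loc[comp_mask, "effect_allele"] = df.loc[comp_mask, "effect_allele"].map(_COMPLEMENT)
        df.loc[comp_mask, "other_allele"] = df.loc[comp_mask, "other_allele"].map(_COMPLEMENT)

    # ambiguous pairs: both orientations are allele-compatible; use frequency
    drop_ambiguous = np.zeros(len(df), dtype=bool)
    flip_mask = (match_rev | match_comp_rev).to_numpy()
    if pair_is_ambiguous.any():
        amb = pair_is_ambiguous.to_numpy()
        f_ss = df["freq"].to_numpy(dtype=float) if "freq" in df.columns else np.full(len(df), np.nan)
        f_panel = (
            df["panel_freq"].to_numpy(dtype=float)
            if "panel_freq" in df.columns
            else np.full(len(df), np.nan)
        )
        no_freq = np.isnan(f_ss) | np.isnan(f_panel)
        d_keep = np.abs(f_ss - f_panel)        # effect allele is panel alt
        d_flip = np.abs((1.0 - f_ss) - f_panel)  # effect allele is panel ref
        tie = np.abs(d_keep - d_flip) < ambiguous_freq_margin
        drop_ambiguous = amb & (no_freq | tie)
        resolved_flip = amb & ~drop_ambiguous & (d_flip < d_keep)
        flip_mask = np.where(amb, resolved_flip, flip_mask)
        report.n_ambiguous_resolved = int((amb & ~drop_ambiguous).sum())
    report.dropped["ambiguous_unresolved"] = int(drop_ambiguous.sum())
    df = df[~drop_ambiguous]
    flip_mask = flip_mask[~drop_ambiguous]

    df = flip_orientation(df, flip_mask)
    report.n_flipped = int(flip_mask.sum())

    # fill missing frequencies from the panel (now oriented to alt)
    if "panel_freq" in df.columns:
        if "freq" not in df.columns:
            df["freq"] = np.nan
        fill = df["freq"].isna() & df["panel_freq"].notna()
        df.loc[fill, "freq"] = df.loc[fill, "panel_freq"]
    df = df.drop(columns=[c for c in ("ref", "alt", "panel_freq") if c in df.columns])
    df = df.reset_index(drop=True)
    report.n_output = len(df)
    out = SumStats(df, trait_type=ss.trait_type, source=ss.source)
    return out, report


PGS_MODEL_COLUMNS = ["chrom", "pos", "other_allele", "effect_allele", "beta", "weight_ppi", "weight"]


@dataclass
class PGSModel:
    """Per-variant PGS weights: final weight = ``weight_ppi * beta``.

    ``weight_ppi`` is the posterior probability of causality (single-causal
    flavour) or the posterior inclusion probability (multi-causal flavour);
    it lies in [0, 1).  Extra columns (e.g. ``posterior_mean``) are allowed
    and preserved on round trip.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PGS_MODEL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"PGSModel table missing columns {missing}")
        w = self.table["weight_ppi"].to_numpy()
        if len(w) and (np.any(w < 0) or np.any(w >= 1)):
            raise ValueError("weight_ppi must lie in [0, 1)")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> pd.Series:
        t = self.table
        return (
            t["chrom"].astype(str)
            + ":"
            + t["pos"].astype(str)
            + ":"
            + t["other_allele"]
            + ":"
            + t["effect_allele"]
        )


def write_pgs_model(model: PGSModel, path: str | Path) -> None:
    """Write a PGS model as a TSV with fixed leading column order."""
    if len(model) == 0:
        raise ValueError("refusing to write an empty PGS model")
    extra = [c for c in model.table.columns if c not in PGS_MODEL_COLUMNS]
    model.table[PGS_MODEL_COLUMNS + extra].to_csv(path, sep="\t", index=False)


def read_pgs_model(path: str | Path) -> PGSModel:
    # round_trip parsing keeps weight == beta * weight_ppi bit-for-bit
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    return PGSModel(df)
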