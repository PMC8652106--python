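"""Synthetic GWAS fixture generator.

Simulates the generative model the PGS methods assume, end to end and with
no external downloads:

* block-structured reference panels: within each LD block, haplotypes follow
  a Markov copying process on a shared uniform variable, giving allele
  correlations that decay geometrically with SNP distance (adjacent-SNP
  correlation equal to ``ld_decay`` when frequencies are equal); blocks are
  mutually independent;
* a point-normal architecture: each SNP is causal with probability ``pi``
  and causal effects are drawn N(0, W), all other effects exactly 0;
* phenotypes: quantitative traits as G.effects plus normal noise scaled to a
  target heritability, binary traits by thresholding a liability at
  prevalence K;
* induced GWAS summary statistics: per-variant simple linear regression
  (quantitative) or allele-count 2x2 log odds ratios with Haldane 0.5
  correction (binary), with se, p, frequency and sample-size columns.

Everything is a pure function of (config, seed).  The writers emit the exact
file formats the pipeline consumes (sumstats TSV, BED blocks, VCF panel,
dosage and phenotype TSVs) so command-line integration tests can run on
generated files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ldref import GenotypePanel
from .regions import LDBlockSet
from .sumstats import SumStats

logger = logging.getLogger(__name__)

SNP_SPACING = 100  # bp between adjacent simulated SNPs
BLOCK_SPACING = 1_000_000  # bp between block starts


@dataclass
class SimConfig:
    """Study conditions for one synthetic GWAS.

    Defaults are the CI fixture scale (5 blocks x 200 SNPs x 2000
    individuals, runs in seconds); recovery experiments use the larger
    point-normal conditions (pi=1e-3, W=0.2^2, n_gwas=5e4) explicitly.
    """

    seed: int
    n_blocks: int = 5
    snps_per_block: int = 200
    ld_decay: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.95)
    pi: float = 1e-3
    W: float = 0.2 ** 2
    n_gwas: int = 2000
    trait_type: str = "quant"  # "quant" | "cc"
    h2: float | None = None    # target heritability; None = unit noise variance
    K: float = 0.1             # prevalence (binary traits)
    n_panel: int = 500
    n_validation: int = 500
    chrom: str = "1"

    def __post_init__(self) -> None:
        for name in ("n_blocks", "snps_per_block", "n_gwas", "n_panel", "n_validation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must lie in [0, 1)")
        if not (0 <= self.pi <= 1):
            raise ValueError("pi must lie in [0, 1]")
        if self.W < 0:
            raise ValueError("W must be non-negative")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.snps_per_block


def _block_haplotypes(n_hap: int, freqs: np.ndarray, rho: float, rng) -> np.ndarray:
    """Haplotypes (n_hap x p, int8) from the Markov copying process.

    A chain of uniforms u_1..u_p refreshes independently at each site with
    probability 1-rho; allele_j = 1{u_j < f_j}.  Marginal frequencies are
    exactly f_j, and for equal frequencies corr(allele_j, allele_{j+k}) =
    rho^k.
    """
    p = len(freqs)
    refresh = rng.random((n_hap, p)) >= rho
    refresh[:, 0] = True
    vals = rng.random((n_hap, p))
    idx = np.maximum.accumulate(np.where(refresh, np.arange(p), 0), axis=1)
    u = np.take_along_axis(vals, idx, axis=1)
    return (u < freqs).astype(np.int8)


def simulate_frequencies(cfg: SimConfig, rng=None) -> np.ndarray:
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lo, hi = cfg.maf_range
    return rng.uniform(lo, hi, size=cfg.n_variants)


def variant_table(cfg: SimConfig) -> pd.DataFrame:
    """Variant index shared by panel, GWAS and validation genotypes."""
    rows = []
    for b in range(cfg.n_blocks):
        start = b * BLOCK_SPACING
        for k in range(cfg.snps_per_block):
            rows.append((cfg.chrom, start + 1 + k * SNP_SPACING))
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    df["ref"] = "A"
    df["alt"] = "G"
    df["id"] = df["chrom"] + ":" + df["pos"].astype(str) + ":" + df["ref"] + ":" + df["alt"]
    return df


def block_set(cfg: SimConfig) -> LDBlockSet:
    rows = []
    for b in range(cfg.n_blocks):
        start = b * BLOCK_SPACING
        rows.append((cfg.chrom, start, start + cfg.snps_per_block * SNP_SPACING, f"{cfg.chrom}_{b}"))
    return LDBlockSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "block_id"]))


def simulate_genotypes(cfg: SimConfig, n_individuals: int, freqs: np.ndarray, rng) -> np.ndarray:
    """Diploid dosages (n x p, int8): two haplotypes per individual, blocks
    independent."""
    G = np.empty((n_individuals, cfg.n_variants), dtype=np.int8)
    for b in range(cfg.n_blocks):
        sl = slice(b * cfg.snps_per_block, (b + 1) * cfg.snps_per_block)
        h = _block_haplotypes(2 * n_individuals, freqs[sl], cfg.ld_decay, rng)
        G[:, sl] = h[0::2] + h[1::2]
    return G


def simulate_panel(cfg: SimConfig, rng=None) -> tuple[GenotypePanel, LDBlockSet]:
    """Reference panel (n_panel individuals) with its matching block set."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    freqs = simulate_frequencies(cfg, rng)
    G = simulate_genotypes(cfg, cfg.n_panel, freqs, rng)
    panel = GenotypePanel(G.astype(float), variant_table(cfg))
    return panel, block_set(cfg)


def simulate_architecture(cfg: SimConfig, rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Point-normal true effects: returns ``(effects, causal_mask)``.

    Causal indicators are Bernoulli(pi); causal effects ~ N(0, W);
    non-causal effects are exactly 0.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    causal = rng.random(cfg.n_variants) < cfg.pi
    effects = np.zeros(cfg.n_variants)
    effects[causal] = rng.normal(0.0, np.sqrt(cfg.W), size=int(causal.sum()))
    return effects, causal


def _genetic_values(G: np.ndarray, effects: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(effects)
    if len(nz) == 0:
        return np.zeros(G.shape[0])
    return G[:, nz].astype(float) @ effects[nz]


def _phenotype(cfg: SimConfig, g: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Returns (trait, liability).  Quantitative trait == liability."""
    var_g = g.var()
    if cfg.h2 is not None and var_g > 0:
        sigma_e = np.sqrt(var_g * (1.0 - cfg.h2) / cfg.h2)
    else:
        sigma_e = 1.0
    liab = g + rng.normal(0.0, sigma_e, size=len(g))
    if cfg.trait_type == "cc":
        thresh = np.quantile(liab, 1.0 - cfg.K)
        return (liab > thresh).astype(np.int8), liab
    return liab, liab


def _marginal_quantitative(G: np.ndarray, y: np.ndarray, chunk: int = 512):
    """Per-variant simple-OLS beta, se, p (vectorized, column-chunked)."""
    n, p = G.shape
    yc = y - y.mean()
    syy = float(yc @ yc)
    beta = np.empty(p)
    se = np.empty(p)
    for j0 in range(0, p, chunk):
        Gc = G[:, j0:j0 + chunk].astype(np.float64)
        Gc -= Gc.mean(axis=0)
        sxx = np.einsum("ij,ij->j", Gc, Gc)
        sxy = yc @ Gc
        with np.errstate(divide="ignore", invalid="ignore"):
            b = sxy / sxx
            resid_ss = np.maximum(syy - b * sxy, 0.0)
            s = np.sqrt(resid_ss / (n - 2) / sxx)
        beta[j0:j0 + chunk] = b
        se[j0:j0 + chunk] = s
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, pval


def _marginal_logor(G: np.ndarray, status: np.ndarray):
    """Allele-count 2x2 log-OR with Haldane 0.5 correction, per variant."""
    cases = status == 1
    n_case = int(cases.sum())
    n_ctrl = len(status) - n_case
    a = G[cases].sum(axis=0).astype(float)          # alt alleles in cases
    c = G[~cases].sum(axis=0).astype(float)         # alt alleles in controls
    b = 2.0 * n_case - a
    d = 2.0 * n_ctrl - c
    a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    beta = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, pval, n_case, n_ctrl


@dataclass
class SimData:
    """One complete synthetic study: all pipeline inputs plus the truth."""

    cfg: SimConfig
    panel: GenotypePanel
    blocks: LDBlockSet
    sumstats: SumStats
    effects: np.ndarray
    causal: np.ndarray
    variants: pd.DataFrame
    g_gwas: np.ndarray
    val_dosages: pd.DataFrame
    val_pheno: pd.DataFrame  # columns: trait, g_true
    gwas_dosages: np.ndarray | None = None


def simulate_study(cfg: SimConfig, keep_gwas_genotypes: bool = False) -> SimData:
    """Simulate panel, architecture, GWAS summary statistics and a held-out
    validation cohort, all from ``cfg.seed``.

    Variants monomorphic in the GWAS sample have no defined marginal effect
    and are dropped from the summary table with a log entry.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = simulate_frequencies(cfg, rng)
    variants = variant_table(cfg)
    blocks = block_set(cfg)
    panel_G = simulate_genotypes(cfg, cfg.n_panel, freqs, rng)
    panel = GenotypePanel(panel_G.astype(float), variants)

    effects, causal = simulate_architecture(cfg, rng)

    G = simulate_genotypes(cfg, cfg.n_gwas, freqs, rng)
    g = _genetic_values(G, effects)
    trait, _ = _phenotype(cfg, g, rng)

    emp_freq = G.mean(axis=0) / 2.0
    poly = (emp_freq > 0) & (emp_freq < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("simulate_study: dropped %d monomorphic variants from summary stats", n_mono)

    if cfg.trait_type == "cc":
        beta, se, pval, n_case, n_ctrl = _marginal_logor(G, trait)
    else:
        beta, se, pval = _marginal_quantitative(G, trait.astype(float))

    # p-values underflow for |z| beyond ~38; keep them in (0, 1]
    pval = np.maximum(pval, np.finfo(float).tiny)
    df = pd.DataFrame(
        {
            "chrom": variants["chrom"],
            "pos": variants["pos"],
            "effect_allele": variants["alt"],
            "other_allele": variants["ref"],
            "beta": beta,
            "se": se,
            "freq": emp_freq,
            "pval": pval,
        }
    )
    if cfg.trait_type == "cc":
        df["n_cases"] = n_case
        df["n_controls"] = n_ctrl
    else:
        df["n"] = cfg.n_gwas
    df = df[poly].reset_index(drop=True)
    ss = SumStats(df, trait_type=cfg.trait_type, source="synthetic")

    Gv = simulate_genotypes(cfg, cfg.n_validation, freqs, rng)
    gv = _genetic_values(Gv, effects)
    trait_v, _ = _phenotype(cfg, gv, rng)
    sample_ids = [f"V{i}" for i in range(cfg.n_validation)]
    val_dosages = pd.DataFrame(Gv, index=sample_ids, columns=variants["id"].tolist())
    val_pheno = pd.DataFrame({"trait": trait_v, "g_true": gv}, index=sample_ids)

    return SimData(
        cfg=cfg, panel=panel, blocks=blocks, sumstats=ss, effects=effects,
        causal=causal, variants=variants, g_gwas=g, val_dosages=val_dosages,
        val_pheno=val_pheno, gwas_dosages=G if keep_gwas_genotypes else None,
    )


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT genotypes (dosage 0/1/2 -> 0|0, 0|1, 1|1)."""
    path = Path(path)
    v = panel.variants
    D = np.rint(np.nan_to_num(panel.dosages, nan=0.0)).astype(int)
    gt_strings = np.array(["0|0", "0|1", "1|1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in v["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.samples) + "\n")
        for j in range(len(v)):
            row = v.iloc[j]
            gts = "\t".join(gt_strings[D[:, j]])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def write_fixture_set(sim: SimData, outdir: str | Path) -> dict[str, Path]:
    """Write every file the CLI pipeline consumes; returns a name->path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sumstats": outdir / "sumstats.tsv",
        "blocks": outdir / "blocks.bed",
        "panel_vcf": outdir / "panel.vcf",
        "val_dosages": outdir / "val_dosages.tsv",
        "val_pheno": outdir / "val_pheno.tsv",
    }
    sim.sumstats.table.to_csv(paths["sumstats"], sep="\t", index=False)
    sim.blocks.table[["chrom", "start", "end"]].to_csv(paths["blocks"], sep="\t", header=False, index=False)
    write_vcf(sim.panel, paths["panel_vcf"])
    sim.val_dosages.to_csv(paths["val_dosages"], sep="\t")
    sim.val_pheno.to_csv(paths["val_pheno"], sep="\t")
    return paths
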