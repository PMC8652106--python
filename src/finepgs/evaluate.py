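"""Scoring individuals and evaluating PGS predictions.

Scores are the weighted allele-dosage sums ``score_j = sum_i w_i beta_i
G_ji`` over the intersection of model and genotyped variants, after
reconciling effect-allele orientation with the genotype file.

Binary traits are evaluated by AUC: the score is residualized on covariates
(OLS with intercept), then a rank-based (Mann-Whitney) AUC of the
residualized score against case status is computed.  The AUC is converted to
r^2 on the liability scale using the population prevalence K (estimated as
the case fraction):

    t  = Phi^-1(1 - K)          threshold truncating prevalence K
    m  = phi(t) / K             mean liability of cases
    m2 = -m K / (1 - K)         mean liability of controls
    Q  = Phi^-1(AUC)
    r^2 = 2 Q^2 / ((m2 - m)^2 + Q^2 m (m - t) + m2 (m2 - t))

Quantitative traits are evaluated as the squared Pearson correlation between
the covariate-residualized trait and the score.  95% confidence intervals
come from a seeded 1000-resample bootstrap over individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import PGSModel

logger = logging.getLogger(__name__)


@dataclass
class EvalResult:
    kind: str  # "auc" | "r2"
    estimate: float
    ci_low: float
    ci_high: float
    n_individuals: int
    K: float | None = None
    r2_liability: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must contain the point estimate")


def score(model: PGSModel, dosages: pd.DataFrame) -> tuple[pd.Series, int]:
    """Per-individual PGS from a dosage matrix.

    ``dosages`` is individuals x variants with columns keyed by
    ``chrom:pos:ref:alt`` and entries in [0, 2] counting the alt allele
    (NaN allowed).  Model variants whose effect allele is the dosage ref are
    counted through ``2 - G``; model variants absent from the columns are
    skipped and counted in the returned integer.  Missing dosage entries are
    mean-imputed per variant (2 x alt frequency in the scored cohort).
    """
    cols = list(dosages.columns)
    col_set = set(cols)
    t = model.table
    fwd_ids = model.variant_ids  # other=ref, effect=alt
    rev_ids = (
        t["chrom"].astype(str) + ":" + t["pos"].astype(str)
        + ":" + t["effect_allele"] + ":" + t["other_allele"]
    )
    use_fwd = fwd_ids.isin(col_set).to_numpy()
    use_rev = ~use_fwd & rev_ids.isin(col_set).to_numpy()
    n_missing = int((~use_fwd & ~use_rev).sum())
    if not (use_fwd.any() or use_rev.any()):
        raise ValueError("no overlap between model variants and genotyped variants")
    if n_missing:
        logger.warning("score: %d model variants missing from genotypes", n_missing)

    w = t["weight"].to_numpy()
    total = np.zeros(len(dosages))
    for mask, flip in ((use_fwd, False), (use_rev, True)):
        if not mask.any():
            continue
        ids = (rev_ids if flip else fwd_ids)[mask]
        G = dosages[ids.tolist()].to_numpy(dtype=float)
        if np.isnan(G).any():
            col_mean = np.nanmean(G, axis=0)  # = 2 * alt frequency
            G = np.where(np.isnan(G), col_mean, G)
        if flip:
            G = 2.0 - G
        total += G @ w[mask]
    return pd.Series(total, index=dosages.index, name="score"), n_missing


def _residualize(y: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    """OLS residuals of y on covariates (with intercept); identity minus the
    mean when no covariates.  Rank-deficient covariates are a hard error
    naming the collinear columns."""
    if covariates is None or covariates.shape[1] == 0:
        return y - y.mean()
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(covariates, dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        names, bad = list(covariates.columns), []
        r_prev, Xc = 1, X[:, :1]
        for j, name in enumerate(names):
            Xc = np.column_stack([Xc, X[:, j + 1]])
            r = np.linalg.matrix_rank(Xc)
            if r == r_prev:
                bad.append(str(name))
            r_prev = r
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    return sm.OLS(y, X).fit().resid


def _mann_whitney_auc(x: np.ndarray, status: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties share 0.5)."""
    n1 = int(status.sum())
    n0 = len(status) - n1
    ranks = stats.rankdata(x)
    u = ranks[status == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc_to_liability_r2(auc: float, K: float) -> float:
    """Convert an AUC into r^2 on the liability scale at prevalence K.

    AUC = 0.5 maps to exactly 0; the result is strictly increasing in AUC.
    AUC < 0.5 raises (check effect-allele orientation).
    """
    if not (0 < K < 1):
        raise ValueError("prevalence K must lie in (0, 1)")
    if auc < 0.5:
        raise ValueError("AUC < 0.5: the score is anti-predictive; check allele orientation")
    if auc >= 1.0:
        raise ValueError("AUC must be < 1")
    t = stats.norm.isf(K)          # upper-K quantile
    m = stats.norm.pdf(t) / K      # mean liability of cases
    m2 = -m * K / (1.0 - K)        # mean liability of controls
    Q = stats.norm.ppf(auc)
    r2 = 2.0 * Q ** 2 / ((m2 - m) ** 2 + Q ** 2 * m * (m - t) + m2 * (m2 - t))
    return float(r2)


def _complete_cases(*frames) -> np.ndarray:
    ok = np.ones(len(frames[0]), dtype=bool)
    for f in frames:
        if f is None:
            continue
        arr = np.asarray(f, dtype=float)
        ok &= ~np.isnan(arr if arr.ndim == 1 else arr).reshape(len(ok), -1).any(axis=1)
    return ok


def auc_binary(
    status,
    covariates: pd.DataFrame | None,
    score,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalResult:
    """Covariate-adjusted AUC of a score for a binary trait.

    The score is residualized on the covariates and the Mann-Whitney AUC of
    the residualized score vs case status is computed; K is recorded as the
    case fraction and the liability-scale r^2 is attached.  Bootstrap CI over
    individuals, reproducible for a fixed seed.
    """
    status = np.asarray(status, dtype=float)
    score_arr = np.asarray(score, dtype=float)
    ok = _complete_cases(status, score_arr, covariates)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("auc_binary: dropped %d incomplete cases", n_dropped)
    status = status[ok].astype(int)
    score_arr = score_arr[ok]
    cov = covariates.iloc[ok].reset_index(drop=True) if covariates is not None else None
    if status.min() == status.max():
        raise ValueError("both cases and controls are required")
    resid = _residualize(score_arr, cov)
    auc = _mann_whitney_auc(resid, status)
    K = float(status.mean())

    rng = np.random.default_rng(seed)
    n = len(status)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        s = status[idx]
        if s.min() == s.max():
            boots[b] = np.nan
            continue
        boots[b] = _mann_whitney_auc(resid[idx], s)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    lo, hi = min(lo, auc), max(hi, auc)
    r2l = auc_to_liability_r2(auc, K) if auc >= 0.5 else None
    return EvalResult("auc", auc, float(lo), float(hi), n, K=K, r2_liability=r2l)


def r2_quantitative(
    trait,
    covariates: pd.DataFrame | None,
    score,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalResult:
    """Squared correlation between the covariate-residualized trait and the
    score, with a seeded bootstrap CI.  Rows with missing values are dropped
    (complete cases) and counted in the log."""
    trait = np.asarray(trait, dtype=float)
    score_arr = np.asarray(score, dtype=float)
    ok = _complete_cases(trait, score_arr, covariates)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("r2_quantitative: dropped %d incomplete cases", n_dropped)
    trait = trait[ok]
    score_arr = score_arr[ok]
    cov = covariates.iloc[ok].reset_index(drop=True) if covariates is not None else None
    resid = _residualize(trait, cov)
    r = np.corrcoef(resid, score_arr)[0, 1]
    r2 = float(r ** 2)

    rng = np.random.default_rng(seed)
    n = len(trait)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.std(resid[idx]) == 0 or np.std(score_arr[idx]) == 0:
            boots[b] = np.nan
            continue
        boots[b] = np.corrcoef(resid[idx], score_arr[idx])[0, 1] ** 2
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    lo, hi = min(lo, r2), max(hi, r2)
    return EvalResult("r2", r2, float(lo), float(hi), n)


def read_dosages(path: str | Path) -> pd.DataFrame:
    """Individuals x variants dosage matrix from TSV (first column = sample
    id, remaining columns keyed ``chrom:pos:ref:alt``) or from a VCF."""
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf") or path.name.endswith(".vcf.gz"):
        from .ldref import GenotypePanel

        panel = GenotypePanel.from_vcf(path)
        return pd.DataFrame(panel.dosages, index=panel.samples, columns=panel.variants["id"].tolist())
    return pd.read_csv(path, sep="\t", index_col=0)
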