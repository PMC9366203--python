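"""Sample/gene QC, TMM normalization, log2-CPM, precision weights, batch adjustment.

The processing chain mirrors standard bulk RNA-seq practice for donor
cohorts: drop samples under 10 million total reads, keep genes with
more than 0 FPKM in 95% of samples and mean FPKM above 1, compute
trimmed-mean-of-M-values (TMM) scale factors, transform to log2 counts
per million with a 0.5 prior count, and derive per-observation precision
weights from a lowess mean–variance trend.  Batch adjustment is a
parametric empirical-Bayes location/scale correction applied on the
log2-CPM scale (used on the eQTL path).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from isletview.errors import ConfigError, EmptyDatasetError, FormatError

logger = logging.getLogger(__name__)


@dataclass
class TmmFactors:
    """TMM scale factors with the trim parameters that produced them."""

    ref_sample: str
    factors: pd.Series  # per-sample positive scale factors, geometric mean 1
    trim_m: float = 0.30
    trim_a: float = 0.05

    def __post_init__(self):
        f = np.asarray(self.factors, dtype=float)
        if np.any(f <= 0):
            raise FormatError("TMM factors must be positive")
        gm = np.exp(np.mean(np.log(f)))
        if abs(gm - 1.0) > 1e-9:
            raise FormatError(f"TMM factors must have geometric mean 1 (got {gm})")


@dataclass
class ExpressionDataset:
    """Counts plus the matrices derived from them.

    All derived matrices share the counts' gene × sample layout;
    ``lib_sizes`` are the column sums of ``counts``.
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series = field(init=False)
    norm_factors: TmmFactors | None = None
    logcpm: pd.DataFrame | None = None
    weights: pd.DataFrame | None = None
    fpkm: pd.DataFrame | None = None

    def __post_init__(self):
        self.lib_sizes = self.counts.sum(axis=0)

    @property
    def effective_lib_sizes(self) -> pd.Series:
        if self.norm_factors is None:
            return self.lib_sizes
        return self.lib_sizes * self.norm_factors.factors


# ---------------------------------------------------------------------------
# QC filters


def filter_samples(counts: pd.DataFrame, min_reads: int = 10_000_000) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples with fewer than ``min_reads`` total reads (strict).

    Returns the retained matrix (sample order preserved) and the list of
    removed sample ids.
    """
    depths = counts.sum(axis=0)
    removed = depths.index[depths < min_reads].tolist()
    kept = counts.loc[:, depths >= min_reads]
    if kept.shape[1] == 0:
        raise EmptyDatasetError(f"all {counts.shape[1]} samples below {min_reads} reads")
    if removed:
        logger.info("filter_samples: removed %d of %d samples (< %d reads): %s",
                    len(removed), counts.shape[1], min_reads, removed)
    return kept, removed


def fpkm(counts: pd.DataFrame, lengths: pd.Series, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase of exonic length per million mapped reads."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise FormatError(f"no length for genes: {missing[:5]}")
    if (lengths < 1).any():
        raise FormatError("gene lengths must be >= 1 bp")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    if (lib_sizes <= 0).any():
        raise FormatError("zero library size")
    return counts * 1e9 / np.outer(lengths.to_numpy(), lib_sizes.to_numpy())


def filter_genes(
    fpkm_matrix: pd.DataFrame, frac_nonzero: float = 0.95, min_mean_fpkm: float = 1.0
) -> pd.Index:
    """Genes with FPKM > 0 in at least ``frac_nonzero`` of samples and mean FPKM above ``min_mean_fpkm``."""
    share_nonzero = (fpkm_matrix > 0).mean(axis=1)
    mean_fpkm = fpkm_matrix.mean(axis=1)
    keep = (share_nonzero >= frac_nonzero) & (mean_fpkm > min_mean_fpkm)
    logger.info("filter_genes: retained %d of %d genes", int(keep.sum()), len(keep))
    return fpkm_matrix.index[keep]


def expressed_mask(
    counts: pd.DataFrame,
    tissue_labels: pd.Series,
    cpm_min: float = 1.0,
    frac: float = 0.80,
) -> pd.DataFrame:
    """Per-gene expression call per tissue: CPM >= ``cpm_min`` in strictly more than ``frac`` of the tissue's samples."""
    tissue_labels = tissue_labels.reindex(counts.columns)
    if tissue_labels.isna().any():
        raise FormatError("tissue label missing for some samples")
    cpm = counts / counts.sum(axis=0) * 1e6
    out = {}
    for tissue in sorted(tissue_labels.unique()):
        cols = tissue_labels.index[tissue_labels == tissue]
        out[tissue] = (cpm[cols] >= cpm_min).mean(axis=1) > frac
    return pd.DataFrame(out, index=counts.index)


# ---------------------------------------------------------------------------
# TMM


def _quantile_factor(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.quantile(counts / lib[None, :], p, axis=0)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> TmmFactors:
    """Trimmed mean of M-values scale factors.

    The reference is the sample whose 75th CPM percentile is closest to the
    mean 75th percentile.  For each sample, per-gene log2 expression ratios
    (M) and mean log2 abundances (A) versus the reference are computed over
    genes nonzero in both; M is doubly trimmed by ``trim_m`` on M and
    ``trim_a`` on A, and the factor is 2 to the weighted mean of the retained
    M-values with inverse asymptotic (binomial) variances as weights.
    Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ConfigError("TMM requires at least 2 samples")
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if ref_sample is None:
        f75 = _quantile_factor(y, lib)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
        ref_sample = counts.columns[ref_idx]
    else:
        ref_idx = counts.columns.get_loc(ref_sample)
    yr, nr = y[:, ref_idx], lib[ref_idx]
    log_factors = np.zeros(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref_idx:
            continue
        log_factors[j] = _tmm_one(y[:, j], lib[j], yr, nr, trim_m, trim_a)
    factors = np.exp2(log_factors)
    factors /= np.exp(np.mean(np.log(factors)))
    return TmmFactors(
        ref_sample=str(ref_sample),
        factors=pd.Series(factors, index=counts.columns, name="tmm_factor"),
        trim_m=trim_m,
        trim_a=trim_a,
    )


def _tmm_one(
    y: np.ndarray, n: float, yr: np.ndarray, nr: float, trim_m: float, trim_a: float
) -> float:
    """log2 TMM factor of one sample versus the reference."""
    ok = (y > 0) & (yr > 0)
    if not np.any(ok):
        raise ConfigError("no genes nonzero in both sample and reference")
    y, yr = y[ok], yr[ok]
    m = np.log2((y / n) / (yr / nr))
    a = 0.5 * np.log2((y / n) * (yr / nr))
    w = (n - y) / (n * y) + (nr - yr) / (nr * yr)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    ng = len(m)
    lo_m = np.floor(ng * trim_m) + 1
    hi_m = ng + 1 - lo_m
    lo_a = np.floor(ng * trim_a) + 1
    hi_a = ng + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return 0.0 if not np.isfinite(f) else f


# ---------------------------------------------------------------------------
# log2-CPM and precision weights


def log2cpm(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    factors: TmmFactors | None = None,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 counts per million with a prior count.

    ``log2((count + prior) / (lib_size * factor + 2 * prior) * 1e6)``.
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    eff = lib_sizes.to_numpy(dtype=float)
    if factors is not None:
        eff = eff * factors.factors.reindex(counts.columns).to_numpy()
    denom = eff + 2.0 * prior
    return np.log2((counts + prior) / denom[None, :] * 1e6)


def precision_weights(
    counts: pd.DataFrame,
    design: np.ndarray,
    factors: TmmFactors | None = None,
    span: float = 0.5,
    prior: float = 0.5,
) -> pd.DataFrame:
    """Per-observation precision weights from the lowess mean–variance trend.

    A linear model is fitted to each gene's log2-CPM; the trend of
    sqrt(residual standard deviation) against average log2 count is
    smoothed by lowess (span ``span``) and each observation's weight is the
    predicted standard deviation at its fitted log2 count raised to the
    power −4.  With fewer than 10 genes the trend is flat (mean sd).
    """
    design = np.asarray(design, dtype=float)
    n_genes, n_samples = counts.shape
    if design.shape[0] != n_samples:
        raise ConfigError("design rows must match samples")
    p = design.shape[1]
    if np.linalg.matrix_rank(design) < p:
        raise ConfigError("design matrix is rank-deficient")
    if n_samples < p + 1:
        raise ConfigError("fewer samples than design columns + 1")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if factors is not None:
        lib = lib * factors.factors.reindex(counts.columns).to_numpy()
    y = log2cpm(counts, pd.Series(lib, index=counts.columns), None, prior)
    ym = y.to_numpy()
    # per-gene OLS: coefficients, fitted values, residual sd
    beta, _, _, _ = np.linalg.lstsq(design, ym.T, rcond=None)
    fitted = (design @ beta).T
    resid = ym - fitted
    dof = n_samples - p
    sigma = np.sqrt((resid ** 2).sum(axis=1) / dof)
    # mean-variance trend in (average log2 count, sqrt(sd)) space
    sx = ym.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    if n_genes < 10:
        pred = np.full_like(fitted, sy.mean())
    else:
        trend = sm_lowess(sy, sx, frac=span, return_sorted=True)
        tx, ty = trend[:, 0], trend[:, 1]
        tx, uniq = np.unique(tx, return_index=True)
        ty = ty[uniq]
        fitted_count = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
        pred = np.interp(np.clip(fitted_count, tx[0], tx[-1]), tx, ty)
    w = pred ** (-4.0)
    w = np.clip(w, 1e-12, None)
    return pd.DataFrame(w, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# batch adjustment (parametric empirical Bayes, location/scale)


def batch_adjust(
    logcpm_matrix: pd.DataFrame,
    batch: pd.Series,
    covariates: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch correction of log2-CPM.

    Per gene the data are standardized (protecting ``covariates``), per-batch
    location and scale effects are estimated, shrunk toward batch-level
    priors by moment matching, then removed.  A single-batch input is
    returned unchanged; a batch with one sample is an error.
    """
    batch = batch.reindex(logcpm_matrix.columns)
    if batch.isna().any():
        raise FormatError("batch label missing for some samples")
    levels = pd.Categorical(batch)
    n_batches = len(levels.categories)
    if n_batches == 1:
        return logcpm_matrix.copy()
    sizes = pd.Series(levels.codes).value_counts()
    for code, size in sizes.items():
        if size < 2:
            raise ConfigError(f"batch {levels.categories[code]!r} has a single sample")

    y = logcpm_matrix.to_numpy(dtype=float)
    n_genes, n_samples = y.shape
    batch_design = pd.get_dummies(pd.Series(levels.codes)).to_numpy(dtype=float)
    x = batch_design
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        # drop any intercept-like column: batch dummies already span it
        keep = [j for j in range(cov.shape[1]) if np.ptp(cov[:, j]) > 0]
        cov = cov[:, keep]
        if cov.size:
            x = np.hstack([batch_design, cov])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ConfigError("batch design with covariates is rank-deficient")

    beta, _, _, _ = np.linalg.lstsq(x, y.T, rcond=None)  # (p, genes)
    n_per_batch = batch_design.sum(axis=0)
    grand_mean = (n_per_batch / n_samples) @ beta[:n_batches]  # (genes,)
    var_pooled = ((y - (x @ beta).T) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = np.tile(grand_mean[:, None], (1, n_samples))
    if x.shape[1] > n_batches:
        stand_mean += (x[:, n_batches:] @ beta[n_batches:]).T
    z = (y - stand_mean) / np.sqrt(var_pooled)[:, None]

    adjusted = np.empty_like(z)
    for b in range(n_batches):
        cols = levels.codes == b
        zb = z[:, cols]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        gamma_star, delta_star = _eb_shrink(gamma_hat, delta_hat, zb, max_iter, tol)
        adjusted[:, cols] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]
    out = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean
    return pd.DataFrame(out, index=logcpm_matrix.index, columns=logcpm_matrix.columns)


def _eb_shrink(
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    zb: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative posterior means of per-gene batch location/scale effects."""
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1)
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    if s2 <= 0 or tau2 <= 0:
        return gamma_hat, np.maximum(delta_hat, 1e-12)
    a_prior = (2 * s2 + m ** 2) / s2
    b_prior = (m * s2 + m ** 3) / s2
    n_b = zb.shape[1]
    gamma = gamma_hat.copy()
    delta = delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (n_b * tau2 * gamma_hat + delta * gamma_bar) / (n_b * tau2 + delta)
        ssq = ((zb - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (0.5 * ssq + b_prior) / (n_b / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(gamma_new - gamma) / (np.abs(gamma) + 1e-12)),
            np.max(np.abs(delta_new - delta) / (np.abs(delta) + 1e-12)),
        )
        gamma, delta = gamma_new, delta_new
        if change < tol:
            break
    return gamma, np.maximum(delta, 1e-12)


# ---------------------------------------------------------------------------
# purity


def purity_correlation(logcpm_matrix: pd.DataFrame, purity: pd.Series) -> pd.DataFrame:
    """Spearman correlation of every gene's log2-CPM with islet purity.

    Returns a DataFrame indexed by gene with columns ``rho`` and ``p``
    (asymptotic t approximation).
    """
    purity = purity.reindex(logcpm_matrix.columns)
    if purity.isna().any():
        raise FormatError("purity missing for some samples")
    pv = purity.to_numpy(dtype=float)
    if np.ptp(pv) == 0:
        raise ConfigError("purity is constant across samples")
    n = len(pv)
    ranks_y = stats.rankdata(logcpm_matrix.to_numpy(), axis=1)
    ranks_p = stats.rankdata(pv)
    ry = ranks_y - ranks_y.mean(axis=1, keepdims=True)
    rp = ranks_p - ranks_p.mean()
    denom = np.sqrt((ry ** 2).sum(axis=1) * (rp ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ry @ rp) / denom
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(rho), np.where(np.abs(rho) >= 1.0, 0.0, p), np.nan)
    return pd.DataFrame({"rho": rho, "p": p}, index=logcpm_matrix.index)


# ---------------------------------------------------------------------------
# convenience


def normalize_dataset(
    counts: pd.DataFrame,
    lengths: pd.Series,
    design: np.ndarray | None = None,
    min_reads: int = 10_000_000,
    frac_nonzero: float = 0.95,
    min_mean_fpkm: float = 1.0,
) -> tuple[ExpressionDataset, dict]:
    """Run the full QC + normalization chain and return the dataset and a log.

    Filters samples by depth, genes by FPKM, computes TMM factors, log2-CPM
    and (when a design is given) precision weights.
    """
    kept_counts, removed_samples = filter_samples(counts, min_reads)
    fpkm_matrix = fpkm(kept_counts, lengths)
    kept_genes = filter_genes(fpkm_matrix, frac_nonzero, min_mean_fpkm)
    if len(kept_genes) == 0:
        raise EmptyDatasetError("no genes pass the FPKM filters")
    kept_counts = kept_counts.loc[kept_genes]
    ds = ExpressionDataset(counts=kept_counts)
    ds.fpkm = fpkm_matrix.loc[kept_genes]
    ds.norm_factors = tmm_factors(kept_counts)
    ds.logcpm = log2cpm(kept_counts, ds.lib_sizes, ds.norm_factors)
    if design is not None:
        ds.weights = precision_weights(kept_counts, design, ds.norm_factors)
    log = {
        "n_samples_in": int(counts.shape[1]),
        "n_samples_removed": len(removed_samples),
        "removed_samples": removed_samples,
        "n_genes_in": int(counts.shape[0]),
        "n_genes_retained": int(len(kept_genes)),
        "ref_sample": ds.norm_factors.ref_sample,
    }
    return ds, log
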