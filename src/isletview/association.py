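"""Covariate-adjusted association of gene expression with diabetes phenotypes.

Expression (log2-CPM, precision-weighted) is regressed per gene on one
phenotype at a time — T2D status, glycemic stratum, continuous HbA1c,
BMI, or stimulatory index — with islet purity, sex and age as covariates.
Inference uses empirical-Bayes variance moderation: per-gene residual
variances are shrunk toward a common prior fitted by moment-matching the
log residual variances against a scaled F distribution, yielding
moderated t (or F) statistics with augmented degrees of freedom.
P-values are BH-adjusted across genes and converted to percentage ranks.

Glycemic strata follow the HbA1c (NGSP, %) conventions: NGT below 6,
IGT in [6, 6.5), T2D at or above 6.5 or on clinical diagnosis.  Donors
who are T2D by HbA1c alone (no clinical diagnosis) are excluded from the
T2D-versus-control contrast but keep their stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from isletview.errors import ConfigError, FormatError

logger = logging.getLogger(__name__)

PHENOTYPES = ("t2d_status", "hba1c_stratum", "hba1c", "bmi", "stimulatory_index")
DEFAULT_COVARIATES = ("purity", "sex", "age")


# ---------------------------------------------------------------------------
# strata


def assign_strata(
    metadata: pd.DataFrame, igt_lower: float = 6.0, t2d_lower: float = 6.5
) -> pd.DataFrame:
    """Assign each donor a glycemic stratum and analysis-set flags.

    Returns a donor-indexed frame with columns ``stratum`` (NGT/IGT/T2D),
    ``in_de_contrast`` (False for donors T2D by HbA1c only, who are excluded
    from the T2D-versus-control contrast) and ``usable`` (False when both
    HbA1c and the clinical flag are missing).
    """
    hba1c = metadata["hba1c"]
    clinical = metadata["clinical_t2d"].fillna(False).astype(bool)
    usable = hba1c.notna() | metadata["clinical_t2d"].notna()
    if (~usable).any():
        logger.warning(
            "assign_strata: %d donors lack both HbA1c and clinical flag", int((~usable).sum())
        )
    stratum = pd.Series("NGT", index=metadata.index, dtype=object)
    stratum[(hba1c >= igt_lower) & (hba1c < t2d_lower)] = "IGT"
    stratum[clinical | (hba1c >= t2d_lower)] = "T2D"
    hba1c_only_t2d = (~clinical) & (hba1c >= t2d_lower)
    out = pd.DataFrame(
        {
            "stratum": stratum,
            "in_de_contrast": ~hba1c_only_t2d,
            "usable": usable,
        }
    )
    out.loc[~usable, "stratum"] = pd.NA
    return out


# ---------------------------------------------------------------------------
# design


@dataclass
class DesignInfo:
    """A model matrix with named columns and the phenotype-term index set."""

    matrix: np.ndarray  # samples × columns
    columns: list[str]
    term_cols: list[int]  # columns belonging to the phenotype term
    samples: pd.Index
    dropped: list[str] = field(default_factory=list)
    phenotype: str = ""


def build_design(
    metadata: pd.DataFrame,
    phenotype: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> DesignInfo:
    """Intercept + phenotype encoding + covariates, dropping unusable rows.

    ``t2d_status`` is a binary contrast restricted to donors flagged for the
    DE analysis set; ``hba1c_stratum`` yields two dummies (IGT, T2D) with
    NGT as reference; continuous phenotypes enter as numeric columns.
    Rows with a missing phenotype are dropped and reported; degenerate
    (constant) covariates are dropped with a warning.
    """
    if phenotype not in PHENOTYPES:
        raise ConfigError(f"unknown phenotype {phenotype!r}; choose from {PHENOTYPES}")
    strata = assign_strata(metadata)
    df = metadata.copy()
    df["stratum"] = strata["stratum"]

    keep = strata["usable"].astype(bool).to_numpy()
    if phenotype == "t2d_status":
        keep &= strata["in_de_contrast"].to_numpy()
        value = (df["stratum"] == "T2D").astype(float)
        term_frame = pd.DataFrame({"t2d_status": value})
    elif phenotype == "hba1c_stratum":
        term_frame = pd.DataFrame(
            {
                "stratum_IGT": (df["stratum"] == "IGT").astype(float),
                "stratum_T2D": (df["stratum"] == "T2D").astype(float),
            }
        )
    else:
        value = pd.to_numeric(df[phenotype], errors="coerce")
        keep &= value.notna().to_numpy()
        term_frame = pd.DataFrame({phenotype: value})
    for cov in covariates:
        if cov not in df.columns:
            raise ConfigError(f"covariate {cov!r} missing from metadata")
        keep &= df[cov].notna().to_numpy()

    dropped = df.index[~keep].tolist()
    if dropped:
        logger.info("build_design(%s): dropped %d donors with missing data", phenotype, len(dropped))
    df = df.loc[keep]
    term_frame = term_frame.loc[keep]

    columns = ["intercept"]
    blocks = [np.ones((len(df), 1))]
    blocks.append(term_frame.to_numpy(dtype=float))
    columns.extend(term_frame.columns)
    term_cols = list(range(1, 1 + term_frame.shape[1]))
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or str(col.dtype) == "category" or col.dtype == bool:
            levels = sorted(col.astype(str).unique())
            if len(levels) == 1:
                logger.warning("build_design: covariate %r is constant; dropped", cov)
                continue
            for lev in levels[1:]:
                blocks.append((col.astype(str) == lev).to_numpy(dtype=float)[:, None])
                columns.append(f"{cov}_{lev}")
        else:
            vals = col.to_numpy(dtype=float)
            if np.ptp(vals) == 0:
                logger.warning("build_design: covariate %r is constant; dropped", cov)
                continue
            blocks.append(vals[:, None])
            columns.append(cov)
    x = np.hstack(blocks)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = _collinear_columns(x, columns)
        raise ConfigError(f"design matrix rank-deficient; collinear columns: {bad}")
    return DesignInfo(
        matrix=x,
        columns=columns,
        term_cols=term_cols,
        samples=df.index,
        dropped=dropped,
        phenotype=phenotype,
    )


def _collinear_columns(x: np.ndarray, columns: list[str]) -> list[str]:
    bad = []
    for j in range(1, x.shape[1]):
        sub = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(x):
            bad.append(columns[j])
    return bad


# ---------------------------------------------------------------------------
# moderated weighted least squares


def _trigamma_inverse(y: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif / x) < 1e-8):
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Prior df and variance from moment matching of log residual variances.

    The log variances are matched against a scaled F distribution; returns
    ``(d0, s0_sq)`` with ``d0 = inf`` when the observed spread is no larger
    than expected from chi-square sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    z = np.log(s2[ok])
    if len(z) < 2:
        return np.inf, float(np.exp(np.mean(z))) if len(z) else 1.0
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * float(_trigamma_inverse(np.array([excess]))[0])
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def fit_linear(
    logcpm: pd.DataFrame,
    weights: pd.DataFrame | None,
    design: DesignInfo,
    moderation: bool = True,
) -> pd.DataFrame:
    """Per-gene weighted least squares with optional variance moderation.

    Returns a gene-indexed frame with ``beta``, ``se``, ``t``, ``r2``
    (partial coefficient of determination of the phenotype term given the
    covariates), ``p``, ``fdr`` and ``rank_pct``.  For a multi-column
    phenotype term (glycemic strata) the joint moderated F test supplies
    ``p`` and ``t`` holds the signed square root of F for the first
    contrast's sign; per-contrast slopes are reported as ``beta_<name>``.
    """
    x = design.matrix
    n, p_cols = x.shape
    d = n - p_cols
    if d <= 0:
        raise ConfigError("no residual degrees of freedom")
    y = logcpm[design.samples].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        bad = logcpm.index[~np.isfinite(y).all(axis=1)][:5].tolist()
        raise FormatError(f"non-finite expression for genes: {bad}")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = weights[design.samples].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ConfigError("weights must be positive")
    n_genes = y.shape[0]

    # batched WLS: per gene solve (X' W X) beta = X' W y
    xtwx = np.einsum("sp,gs,sq->gpq", x, w, x)
    xtwy = np.einsum("sp,gs->gp", x, w * y)
    xtwx_inv = np.linalg.inv(xtwx)
    beta = np.einsum("gpq,gq->gp", xtwx_inv, xtwy)
    fitted = beta @ x.T
    resid = y - fitted
    rss = np.einsum("gs,gs->g", w, resid ** 2)
    s2 = rss / d

    # reduced model without the phenotype term, for partial R^2 and the F test
    keep_cols = [j for j in range(p_cols) if j not in design.term_cols]
    x0 = x[:, keep_cols]
    xtwx0 = np.einsum("sp,gs,sq->gpq", x0, w, x0)
    xtwy0 = np.einsum("sp,gs->gp", x0, w * y)
    beta0 = np.einsum("gpq,gq->gp", np.linalg.inv(xtwx0), xtwy0)
    rss0 = np.einsum("gs,gs->g", w, (y - beta0 @ x0.T) ** 2)
    r2 = np.clip((rss0 - rss) / np.maximum(rss0, 1e-300), 0.0, 1.0)

    if moderation:
        d0, s0_sq = estimate_variance_prior(s2, d)
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
            df_total = d0 + d
    else:
        s2_tilde = s2
        df_total = d

    k = len(design.term_cols)
    j0 = design.term_cols[0]
    unscaled_se = np.sqrt(xtwx_inv[:, j0, j0])
    beta_term = beta[:, j0]
    se = unscaled_se * np.sqrt(s2_tilde)
    if k == 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta_term / se
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    else:
        f = (rss0 - rss) / k / s2_tilde
        f = np.maximum(f, 0.0)
        if np.isinf(df_total):
            p = stats.chi2.sf(f * k, df=k)
        else:
            p = stats.f.sf(f, k, df_total)
        t = np.sign(beta_term) * np.sqrt(f)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "beta": beta_term,
            "se": se,
            "t": t,
            "r2": r2,
            "p": p,
        },
        index=logcpm.index,
    )
    if k > 1:
        for pos, j in enumerate(design.term_cols):
            out[f"beta_{design.columns[j]}"] = beta[:, j]
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["rank_pct"] = percentage_rank(out["p"].to_numpy())
    out.insert(0, "phenotype", design.phenotype)
    return out


# ---------------------------------------------------------------------------
# multiple testing and ranks


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def percentage_rank(p: np.ndarray) -> np.ndarray:
    """Percentage rank of each p-value among all genes (ascending, average ties)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ConfigError("empty p-value vector")
    return 100.0 * stats.rankdata(p, method="average") / p.size
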