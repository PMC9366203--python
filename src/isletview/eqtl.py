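"""cis-eQTL scan: expression versus allele dosage within a 2 Mb window.

Pairs are formed between every gene and every variant on the same
chromosome whose position falls within ``window`` bp of the gene body
(start − window to end + window, boundary inclusive).  Expression and
dosage are residualized on the covariates (at minimum an intercept), the
per-pair correlation is converted to a t statistic with
``t = r sqrt(d / (1 − r²))`` on ``d = n − 1 − rank(covariates incl.
intercept)`` degrees of freedom, and BH adjustment is applied across all
tests in the scan.  The effect allele is always the alt allele; beta is
the expression change in log2-CPM units per alt allele.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from isletview.errors import ConfigError
from isletview.io_formats import GeneAnnotation, GenotypeMatrix
from isletview.association import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 2_000_000

EQTL_COLUMNS = ["variant_id", "gene_id", "beta", "se", "t", "p", "fdr", "distance", "ea"]


def cis_pairs(
    annotation: list[GeneAnnotation],
    genotypes: GenotypeMatrix,
    window: int = DEFAULT_WINDOW,
    anchor: str = "body",
) -> pd.DataFrame:
    """All (gene, variant) pairs within the cis window, with signed distances.

    With ``anchor="body"`` (default) a pair is included iff the variant lies
    in ``[start − window, end + window]`` on the gene's chromosome;
    ``anchor="tss"`` instead windows around the strand-aware transcription
    start site.  Distance is 0 inside the gene body, negative upstream of
    the start, positive downstream of the end.
    Columns: gene_id, variant_id, gene_idx, variant_idx, distance.
    """
    if anchor not in ("body", "tss"):
        raise ConfigError(f"unknown window anchor {anchor!r}")
    rows: dict[str, list] = {"gene_id": [], "variant_id": [], "gene_idx": [], "variant_idx": [], "distance": []}
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in np.unique(genotypes.chrom):
        idx = np.flatnonzero(genotypes.chrom == chrom)
        by_chrom[chrom] = idx[np.argsort(genotypes.pos[idx])]
    for gi, gene in enumerate(annotation):
        order = by_chrom.get(gene.chrom)
        if order is None:
            continue
        pos = genotypes.pos[order]
        if anchor == "tss":
            tss = gene.start if gene.strand == "+" else gene.end
            win_lo, win_hi = tss - window, tss + window
        else:
            win_lo, win_hi = gene.start - window, gene.end + window
        lo = np.searchsorted(pos, win_lo, side="left")
        hi = np.searchsorted(pos, win_hi, side="right")
        for vi in order[lo:hi]:
            p = int(genotypes.pos[vi])
            if p < gene.start:
                dist = p - gene.start
            elif p > gene.end:
                dist = p - gene.end
            else:
                dist = 0
            rows["gene_id"].append(gene.gene_id)
            rows["variant_id"].append(str(genotypes.variant_id[vi]))
            rows["gene_idx"].append(gi)
            rows["variant_idx"].append(int(vi))
            rows["distance"].append(dist)
    return pd.DataFrame(rows)


def residualize(matrix: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Replace each row by its OLS residual on the covariates plus intercept."""
    y = np.asarray(matrix, dtype=float)
    n = y.shape[-1]
    x = np.ones((n, 1))
    if covariates is not None and np.asarray(covariates).size:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        # avoid duplicating an intercept column
        cov = cov[:, np.ptp(cov, axis=0) > 0]
        x = np.hstack([x, cov])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ConfigError("covariate matrix is rank-deficient")
    q, _ = np.linalg.qr(x)
    return y - (y @ q) @ q.T


def covariate_rank(covariates: np.ndarray | None, n: int) -> int:
    """Rank of the fitted nuisance space (intercept always included)."""
    x = np.ones((n, 1))
    if covariates is not None and np.asarray(covariates).size:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov = cov[:, np.ptp(cov, axis=0) > 0]
        x = np.hstack([x, cov])
    return int(np.linalg.matrix_rank(x))


def eqtl_scan(
    expression: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pairs: pd.DataFrame,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Regression of residualized expression on residualized dosage per cis pair.

    Returns one row per tested pair with beta, se, t, p, scan-wide BH fdr,
    signed distance and the effect allele (alt).  Pairs whose dosage has
    zero variance after residualization are skipped and counted in the log.
    """
    samples = list(expression.columns)
    if samples != list(genotypes.samples):
        common = [s for s in samples if s in set(genotypes.samples)]
        if not common:
            raise ConfigError("expression and genotype samples are disjoint")
        expression = expression[common]
        col = {s: k for k, s in enumerate(genotypes.samples)}
        genotypes = GenotypeMatrix(
            variant_id=genotypes.variant_id,
            chrom=genotypes.chrom,
            pos=genotypes.pos,
            ref=genotypes.ref,
            alt=genotypes.alt,
            dosage=genotypes.dosage[:, [col[s] for s in common]],
            samples=common,
        )
    n = expression.shape[1]
    if pairs.empty:
        return pd.DataFrame(columns=EQTL_COLUMNS)
    # keep only pairs whose gene is present in the (possibly filtered) expression
    gene_pos = {g: i for i, g in enumerate(expression.index)}
    pairs = pairs[pairs["gene_id"].isin(gene_pos)].reset_index(drop=True)
    if pairs.empty:
        return pd.DataFrame(columns=EQTL_COLUMNS)

    # one df for the tested dosage on top of the nuisance space (incl. intercept)
    d = n - 1 - covariate_rank(covariates, n)
    if d <= 1:
        raise ConfigError("not enough samples for the scan")
    re = residualize(expression.to_numpy(dtype=float), covariates)
    rg = residualize(genotypes.dosage, covariates)
    sd_e = re.std(axis=1)
    sd_g = rg.std(axis=1)

    gi = np.array([gene_pos[g] for g in pairs["gene_id"]])
    vi = pairs["variant_idx"].to_numpy()
    ok = (sd_g[vi] > 0) & (sd_e[gi] > 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("eqtl_scan: skipped %d pairs with zero residual variance", n_skipped)
    pairs = pairs[ok].reset_index(drop=True)
    gi, vi = gi[ok], vi[ok]
    if pairs.empty:
        return pd.DataFrame(columns=EQTL_COLUMNS)

    ze = re[gi] / (sd_e[gi] * np.sqrt(n))[:, None]
    zg = rg[vi] / (sd_g[vi] * np.sqrt(n))[:, None]
    r = np.einsum("ps,ps->p", ze, zg)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(d / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=d)
    beta = r * sd_e[gi] / sd_g[vi]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(t != 0, beta / t, sd_e[gi] / sd_g[vi] / np.sqrt(d))
    out = pd.DataFrame(
        {
            "variant_id": pairs["variant_id"],
            "gene_id": pairs["gene_id"],
            "beta": beta,
            "se": np.abs(se),
            "t": t,
            "p": np.clip(p, np.finfo(float).tiny, 1.0),
            "fdr": np.nan,
            "distance": pairs["distance"],
            "ea": genotypes.alt[vi],
        }
    )
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def gene_summaries(records: pd.DataFrame, k: int = 10) -> dict[str, dict]:
    """Per-gene lead eQTL plus the top-``k`` list, sorted by p ascending.

    Ties on p resolve to the smaller |distance|, then variant id.
    """
    out: dict[str, dict] = {}
    if records.empty:
        return out
    df = records.copy()
    df["abs_distance"] = df["distance"].abs()
    df = df.sort_values(["p", "abs_distance", "variant_id"], kind="mergesort")
    for gene_id, grp in df.groupby("gene_id", sort=False):
        top = grp.drop(columns="abs_distance").head(k)
        out[gene_id] = {
            "lead": top.iloc[0].to_dict(),
            "top": top.to_dict(orient="records"),
            "n_tested": int(len(grp)),
        }
    return out
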