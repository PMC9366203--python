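"""Spearman coexpression against an empirical background-pair null.

Instead of asymptotic p-values, significance of a gene–gene correlation is
judged against a background distribution built by sampling one million
random gene pairs from the expression-filtered universe and recording
|Spearman ρ| for each.  The empirical p-value of an observed correlation
is the proportion of background pairs at least as extreme in absolute
value — a deliberately conservative two-sided rule that absorbs the
pervasive positive dependence (purity, depth) among genes.

The null carries a digest of the gene universe it was built on and is
refused (hash check) when queried against a different universe.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from isletview.errors import ConfigError, NotFoundError

logger = logging.getLogger(__name__)

HORMONES = ["INS", "GCG", "SST", "PPY", "IAPP", "GHRL"]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ConfigError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfigError("constant vector has no rank correlation")
    return float(stats.spearmanr(x, y).statistic)


def universe_hash(gene_ids) -> str:
    """Order-independent digest of a gene universe."""
    joined = "\n".join(sorted(map(str, gene_ids)))
    return hashlib.sha256(joined.encode()).hexdigest()


@dataclass
class CorrelationNull:
    """Sorted background |ρ| values defining empirical significance."""

    abs_rho_sorted: np.ndarray
    n_pairs: int
    seed: int
    gene_universe_hash: str

    def __post_init__(self):
        if self.n_pairs != len(self.abs_rho_sorted):
            raise ConfigError("n_pairs must equal the number of background values")
        if np.any(np.diff(self.abs_rho_sorted) < 0):
            raise ConfigError("background values must be sorted ascending")
        if self.n_pairs and (self.abs_rho_sorted[0] < 0 or self.abs_rho_sorted[-1] > 1):
            raise ConfigError("background |rho| values must lie in [0, 1]")

    def save(self, path) -> None:
        """Persist as a .npy array plus a JSON sidecar."""
        path = Path(path)
        np.save(path, self.abs_rho_sorted)
        sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npy" \
            else path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "n_pairs": self.n_pairs,
                    "seed": self.seed,
                    "gene_universe_hash": self.gene_universe_hash,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path) -> "CorrelationNull":
        path = Path(path)
        if path.suffix != ".npy":
            path = path.with_suffix(path.suffix + ".npy") if path.exists() else path
        arr = np.load(path)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        return cls(
            abs_rho_sorted=arr,
            n_pairs=meta["n_pairs"],
            seed=meta["seed"],
            gene_universe_hash=meta["gene_universe_hash"],
        )


def _rank_z(logcpm: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Row-standardized average ranks so that rho(a, b) = z_a · z_b.

    Constant genes (no rank variance) are excluded with a warning.
    """
    m = logcpm.to_numpy(dtype=float)
    ranks = stats.rankdata(m, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    ok = norms > 0
    if not np.all(ok):
        logger.warning("excluding %d constant genes from coexpression", int((~ok).sum()))
    z = centered[ok] / norms[ok][:, None]
    return logcpm.iloc[np.flatnonzero(ok)], z


def build_null(
    logcpm: pd.DataFrame, n_pairs: int = 1_000_000, seed: int = 0, chunk: int = 200_000
) -> CorrelationNull:
    """Background |Spearman ρ| from random gene pairs of the filtered universe.

    Pairs are drawn uniformly with replacement over unordered non-self
    pairs.  Deterministic for a given seed.
    """
    if n_pairs <= 0:
        raise ConfigError("n_pairs must be positive")
    kept, z = _rank_z(logcpm)
    n_genes = z.shape[0]
    if n_genes < 2:
        raise ConfigError("need at least 2 non-constant genes")
    rng = np.random.default_rng(seed)
    out = np.empty(n_pairs)
    done = 0
    while done < n_pairs:
        take = min(chunk, n_pairs - done)
        i = rng.integers(n_genes, size=take)
        j = rng.integers(n_genes, size=take)
        clash = i == j
        while np.any(clash):
            j[clash] = rng.integers(n_genes, size=int(clash.sum()))
            clash = i == j
        out[done: done + take] = np.abs(np.einsum("ps,ps->p", z[i], z[j]))
        done += take
    out.sort()
    return CorrelationNull(
        abs_rho_sorted=np.clip(out, 0.0, 1.0),
        n_pairs=n_pairs,
        seed=seed,
        gene_universe_hash=universe_hash(kept.index),
    )


def empirical_pvalue(rho, null: CorrelationNull, floor: bool = True):
    """Proportion of background pairs with |ρ| at least as extreme.

    With ``floor=True`` (default) a zero count is reported as
    ``1 / n_pairs`` so that downstream −log10 transforms stay finite;
    ``floor=False`` returns the raw proportion.
    """
    if null.n_pairs == 0:
        raise ConfigError("empty correlation null")
    scalar = np.isscalar(rho)
    a = np.abs(np.atleast_1d(np.asarray(rho, dtype=float)))
    count = null.n_pairs - np.searchsorted(null.abs_rho_sorted, a, side="left")
    p = count / null.n_pairs
    if floor:
        p = np.maximum(p, 1.0 / null.n_pairs)
    return float(p[0]) if scalar else p


def _check_universe(null: CorrelationNull, logcpm: pd.DataFrame) -> None:
    kept, _ = _rank_z(logcpm)
    if universe_hash(kept.index) != null.gene_universe_hash:
        raise ConfigError(
            "correlation null was built on a different gene universe; rebuild it"
        )


def coexpressed_with(
    gene: str, logcpm: pd.DataFrame, null: CorrelationNull, k: int = 100
) -> pd.DataFrame:
    """Top-``k`` genes by |Spearman ρ| with ``gene``, with empirical p-values.

    Sorted by |ρ| descending; ties broken by gene id.  The queried gene is
    not listed against itself.
    """
    if gene not in logcpm.index:
        raise NotFoundError(f"gene {gene!r} not in the expression universe")
    _check_universe(null, logcpm)
    kept, z = _rank_z(logcpm)
    idx = kept.index.get_loc(gene)
    rho = z @ z[idx]
    df = pd.DataFrame({"gene_a": gene, "gene_b": kept.index, "rho": rho})
    df = df[df["gene_b"] != gene]
    df["abs_rho"] = df["rho"].abs()
    df = df.sort_values(["abs_rho", "gene_b"], ascending=[False, True]).head(k)
    df["p_emp"] = empirical_pvalue(df["rho"].to_numpy(), null)
    return df.drop(columns="abs_rho").reset_index(drop=True)


def hormone_panel(
    gene: str,
    logcpm: pd.DataFrame,
    null: CorrelationNull,
    symbol_to_id: dict[str, str],
    hormones: list[str] = HORMONES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlation of ``gene`` with each islet hormone gene.

    ``symbol_to_id`` maps hormone symbols to gene ids in the expression
    matrix.  Hormones missing from the universe yield a partial result with
    a warning.  ``significant`` flags empirical p ≤ ``alpha``.
    """
    if gene not in logcpm.index:
        raise NotFoundError(f"gene {gene!r} not in the expression universe")
    _check_universe(null, logcpm)
    kept, z = _rank_z(logcpm)
    gi = kept.index.get_loc(gene)
    rows = []
    for hormone in hormones:
        hid = symbol_to_id.get(hormone)
        if hid is None or hid not in kept.index:
            logger.warning("hormone_panel: %s absent from universe; skipped", hormone)
            continue
        rho = float(z[kept.index.get_loc(hid)] @ z[gi])
        p = empirical_pvalue(rho, null)
        rows.append(
            {
                "hormone": hormone,
                "gene_id": hid,
                "rho": rho,
                "p_emp": p,
                "significant": p <= alpha,
            }
        )
    return pd.DataFrame(rows, columns=["hormone", "gene_id", "rho", "p_emp", "significant"])
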