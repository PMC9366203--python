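"""Bootstrap gene-set enrichment for coexpression with a target gene.

The statistic is the mean empirical coexpression p-value of the set
against the target (small mean = the set is unusually coexpressed with
the target).  Its null distribution is built by drawing random gene sets
of the same size from the filtered universe (10,000 iterations by
default) and recording the same mean; the bootstrap p-value is the
add-one-smoothed fraction of null means at or below the observed mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from isletview.errors import ConfigError, NotFoundError
from isletview.coexpression import CorrelationNull, _check_universe, _rank_z, empirical_pvalue


@dataclass
class EnrichmentResult:
    """Outcome of a bootstrap enrichment run."""

    set_size: int
    observed_stat: float  # mean empirical p of the set vs the target
    null_stats: np.ndarray  # B bootstrap means
    p_boot: float
    B: int
    seed: int

    def __post_init__(self):
        if len(self.null_stats) != self.B:
            raise ConfigError("null_stats length must equal B")


def bootstrap_enrichment(
    gene_set,
    target_gene: str,
    logcpm: pd.DataFrame,
    null: CorrelationNull,
    B: int = 10_000,
    seed: int = 0,
    two_sided: bool = False,
) -> EnrichmentResult:
    """Test whether ``gene_set`` is enriched for coexpression with ``target_gene``.

    ``gene_set`` (order-irrelevant, >= 2 genes) must be a subset of the
    expression universe.  Null sets are drawn uniformly without replacement
    from the universe excluding the target; the query set's genes are not
    excluded from the sampling pool.  One-sided by default (enrichment =
    small mean empirical p); ``two_sided=True`` doubles the smaller tail.
    """
    gene_set = sorted(set(gene_set))
    if len(gene_set) < 2:
        raise ConfigError("gene set must contain at least 2 distinct genes")
    if target_gene not in logcpm.index:
        raise NotFoundError(f"target gene {target_gene!r} not in universe")
    missing = [g for g in gene_set if g not in logcpm.index]
    if missing:
        raise NotFoundError(f"genes absent from universe: {missing[:10]}")
    _check_universe(null, logcpm)

    kept, z = _rank_z(logcpm)
    ti = kept.index.get_loc(target_gene)
    rho_all = z @ z[ti]
    p_all = empirical_pvalue(rho_all, null)
    pos = {g: i for i, g in enumerate(kept.index)}
    set_idx = np.array([pos[g] for g in gene_set])
    observed = float(p_all[set_idx].mean())

    pool = np.flatnonzero(np.arange(len(kept.index)) != ti)
    p_pool = p_all[pool]
    rng = np.random.default_rng(seed)
    m = len(set_idx)
    null_stats = np.empty(B)
    for b in range(B):
        pick = rng.choice(len(pool), size=m, replace=False)
        null_stats[b] = p_pool[pick].mean()
    lower = (1 + int(np.sum(null_stats <= observed))) / (B + 1)
    if two_sided:
        upper = (1 + int(np.sum(null_stats >= observed))) / (B + 1)
        p_boot = min(1.0, 2.0 * min(lower, upper))
    else:
        p_boot = lower
    return EnrichmentResult(
        set_size=m,
        observed_stat=observed,
        null_stats=null_stats,
        p_boot=float(p_boot),
        B=B,
        seed=seed,
    )
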