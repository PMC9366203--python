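"""Synthetic donor-islet cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a donor cohort with NGT/IGT/T2D strata (HbA1c consistent with the
stratum labels), an endocrine-purity confounder that both drives expression
of a configurable fraction of genes and differs between T2D and nondiabetic
donors, planted differential-expression effects on the T2D stratum,
hormone-anchored coexpression modules (INS, GCG, SST, PPY, IAPP, GHRL)
sharing a latent factor, per-batch location/scale perturbations, planted
cis-eQTLs with decoy variants beyond the cis window, and negative-binomial
counts at realistic sequencing depths.

All effects act additively on the per-gene log2 mean; counts are drawn as
gamma–Poisson mixtures (negative binomial) with a common dispersion.  A
given :class:`SimulationConfig` and seed reproduce the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from isletview.errors import ConfigError
from isletview.io_formats import GeneAnnotation, GenotypeMatrix

HORMONE_SYMBOLS = ["INS", "GCG", "SST", "PPY", "IAPP", "GHRL"]
HORMONE_NAMES = {
    "INS": "insulin",
    "GCG": "glucagon",
    "SST": "somatostatin",
    "PPY": "pancreatic polypeptide",
    "IAPP": "islet amyloid polypeptide",
    "GHRL": "ghrelin",
}

_N_CHROMS = 22
_GENE_SPACING = 1_000_000  # bp between gene starts on a chromosome
_DECOY_OFFSET = 2_500_000  # decoys placed beyond this distance from the gene


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Cohort composition defaults mirror the study population: 188 donors of
    whom 33 carry a clinical T2D diagnosis, 25 are T2D by HbA1c >= 6.5% only,
    and 30 are IGT (HbA1c in [6, 6.5)).  Half of the genes load on islet
    purity, the major expression confounder; T2D donors have systematically
    lower purity so that omitting the covariate inflates false positives.
    """

    n_donors: int = 188
    n_genes: int = 2000
    n_t2d: int = 33  # clinical T2D diagnoses
    n_t2d_hba1c_only: int = 25  # T2D stratum by HbA1c >= 6.5 without diagnosis
    n_igt: int = 30
    frac_purity_genes: float = 0.5
    purity_loading_sd: float = 0.02  # log2 units per purity percent
    purity_t2d_shift: float = 15.0  # upper purity bound reduction for T2D donors
    n_de_genes: int = 100
    de_log2fc: float = 1.0
    n_eqtl_genes: int = 50
    eqtl_beta: float = 1.0  # log2 units per alt allele
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_variants_per_gene: int = 5
    n_decoys_per_gene: int = 2
    coexpr_module_size: int = 30
    coexpr_loading: float = 1.0  # log2 units per latent-factor SD
    n_batches: int = 3
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.1
    obs_noise_sd: float = 0.2  # extra per-observation log2 noise, batch-scaled
    nb_dispersion: float = 0.1
    depth_range: tuple[float, float] = (15_000_000, 40_000_000)
    base_log2_mean: float = 0.0
    base_log2_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_t2d + self.n_t2d_hba1c_only + self.n_igt > self.n_donors:
            raise ConfigError("strata sizes exceed n_donors")
        if self.n_de_genes > self.n_genes:
            raise ConfigError("n_de_genes > n_genes")
        if self.n_eqtl_genes > self.n_genes:
            raise ConfigError("n_eqtl_genes > n_genes")
        if not 0 <= self.frac_purity_genes <= 1:
            raise ConfigError("frac_purity_genes outside [0, 1]")
        if self.coexpr_module_size * len(HORMONE_SYMBOLS) > self.n_genes:
            raise ConfigError("coexpression modules exceed gene universe")
        if self.depth_range[0] > self.depth_range[1]:
            raise ConfigError("depth_range lo > hi")
        if not 0 <= self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ConfigError("maf_range must satisfy 0 <= lo <= hi <= 0.5")
        for name in ("n_donors", "n_genes", "n_t2d", "n_t2d_hba1c_only", "n_igt",
                     "n_de_genes", "n_eqtl_genes", "n_variants_per_gene",
                     "n_decoys_per_gene", "n_batches", "coexpr_module_size"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_batches < 1:
            raise ConfigError("n_batches must be >= 1")
        if not np.isfinite(self.de_log2fc):
            raise ConfigError("de_log2fc must be finite")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(d["maf_range"])
        d["depth_range"] = list(d["depth_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("maf_range", "depth_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated cohort."""

    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed log2FC
    purity_genes: dict[str, float] = field(default_factory=dict)  # gene -> loading
    eqtl_pairs: list[tuple[str, str, float]] = field(default_factory=list)  # (variant, gene, beta)
    coexpr_modules: dict[str, list[str]] = field(default_factory=dict)  # anchor symbol -> member ids
    batch_assignments: dict[str, str] = field(default_factory=dict)  # donor -> batch

    def to_dict(self) -> dict:
        return {
            "de_genes": self.de_genes,
            "purity_genes": self.purity_genes,
            "eqtl_pairs": [list(t) for t in self.eqtl_pairs],
            "coexpr_modules": self.coexpr_modules,
            "batch_assignments": self.batch_assignments,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            de_genes=dict(d.get("de_genes", {})),
            purity_genes=dict(d.get("purity_genes", {})),
            eqtl_pairs=[tuple(t) for t in d.get("eqtl_pairs", [])],
            coexpr_modules={k: list(v) for k, v in d.get("coexpr_modules", {}).items()},
            batch_assignments=dict(d.get("batch_assignments", {})),
        )


def _make_annotation(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneAnnotation]:
    """Genes round-robin over 22 chromosomes at 1 Mb spacing."""
    hormone_idx = _hormone_gene_indices(cfg)
    idx_to_symbol = {v: k for k, v in hormone_idx.items()}
    ann = []
    spans = rng.integers(5_000, 50_000, size=cfg.n_genes)
    lengths = np.maximum(rng.lognormal(np.log(2_000), 0.5, size=cfg.n_genes), 200).astype(int)
    for i in range(cfg.n_genes):
        chrom = f"chr{i % _N_CHROMS + 1}"
        rank = i // _N_CHROMS
        start = 1_000_000 + rank * _GENE_SPACING
        symbol = idx_to_symbol.get(i, f"GENE{i:05d}")
        ann.append(
            GeneAnnotation(
                gene_id=f"SIMG{i:08d}",
                symbol=symbol,
                name=HORMONE_NAMES.get(symbol, f"simulated gene {i}"),
                chrom=chrom,
                start=start,
                end=start + int(spans[i]),
                strand="+" if i % 2 == 0 else "-",
                length=int(lengths[i]),
            )
        )
    return ann


def _hormone_gene_indices(cfg: SimulationConfig) -> dict[str, int]:
    """Fixed, well-spread indices for the six hormone anchor genes."""
    if cfg.n_genes < 2 * len(HORMONE_SYMBOLS):
        return {}
    step = cfg.n_genes // len(HORMONE_SYMBOLS)
    return {sym: 1 + k * step for k, sym in enumerate(HORMONE_SYMBOLS)}


def _simulate_metadata(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_donors
    donor_ids = [f"D{i:04d}" for i in range(n)]
    # stratum layout: clinical T2D first, then HbA1c-only T2D, then IGT, rest NGT
    stratum = np.array(["NGT"] * n, dtype=object)
    clinical = np.zeros(n, dtype=bool)
    stratum[: cfg.n_t2d] = "T2D"
    clinical[: cfg.n_t2d] = True
    stratum[cfg.n_t2d: cfg.n_t2d + cfg.n_t2d_hba1c_only] = "T2D"
    stratum[cfg.n_t2d + cfg.n_t2d_hba1c_only:
            cfg.n_t2d + cfg.n_t2d_hba1c_only + cfg.n_igt] = "IGT"
    order = rng.permutation(n)
    stratum, clinical = stratum[order], clinical[order]

    hba1c = np.empty(n)
    for i in range(n):
        if stratum[i] == "T2D":
            hba1c[i] = 6.5 + rng.exponential(0.8)
        elif stratum[i] == "IGT":
            hba1c[i] = rng.uniform(6.0, 6.5 - 1e-9)
        else:
            hba1c[i] = np.clip(rng.normal(5.4, 0.3), 4.0, 5.99)
    is_t2d = stratum == "T2D"
    purity = np.where(
        is_t2d,
        rng.uniform(40.0, 100.0 - cfg.purity_t2d_shift, size=n),
        rng.uniform(40.0, 100.0, size=n),
    )
    batches = np.array([f"B{i % cfg.n_batches + 1}" for i in range(n)])
    batches = batches[rng.permutation(n)]
    si = np.exp(rng.normal(np.log(2.0), 0.5, size=n))  # fold change, lognormal around 2
    meta = pd.DataFrame(
        {
            "donor_id": donor_ids,
            "tissue": "islet",
            "clinical_t2d": clinical,
            "hba1c": np.round(hba1c, 2),
            "bmi": np.round(np.clip(rng.normal(26.5, 4.0, size=n), 16, 45), 1),
            "sex": rng.choice(["M", "F"], size=n),
            "age": rng.integers(20, 80, size=n),
            "purity": np.round(purity, 1),
            "stimulatory_index": np.round(si, 3),
            "batch": batches,
        }
    ).set_index("donor_id", drop=False)
    return meta


def _nb_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma–Poisson draw: Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[GeneAnnotation], GenotypeMatrix, SyntheticTruth]:
    """Simulate a donor-islet cohort with planted ground truth.

    Returns ``(counts, metadata, annotation, genotypes, truth)`` where
    ``counts`` is gene × donor, ``metadata`` a donor-indexed phenotype table,
    ``annotation`` a gene list with coordinates, ``genotypes`` the variant
    dosage matrix (planted cis variants within ±1 Mb plus decoys beyond
    2.5 Mb) and ``truth`` the planted effects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ann = _make_annotation(config, rng)
    meta = _simulate_metadata(config, rng)
    gene_ids = [a.gene_id for a in ann]
    n_g, n_s = config.n_genes, config.n_donors
    truth = SyntheticTruth(batch_assignments=dict(zip(meta.index, meta["batch"])))

    # baseline abundance (log2 scale) — a log-normal over genes
    log2_mu = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n_g)[:, None] \
        * np.ones((1, n_s))

    # purity loadings
    n_purity = int(round(config.frac_purity_genes * n_g))
    purity_idx = rng.choice(n_g, size=n_purity, replace=False)
    loadings = rng.normal(0.0, config.purity_loading_sd, size=n_purity)
    purity_centered = meta["purity"].to_numpy() - 70.0
    log2_mu[purity_idx] += loadings[:, None] * purity_centered[None, :]
    truth.purity_genes = {gene_ids[i]: float(l) for i, l in zip(purity_idx, loadings)}

    # differential expression in the T2D stratum
    stratum_t2d = (meta["clinical_t2d"] | (meta["hba1c"] >= 6.5)).to_numpy()
    de_idx = rng.choice(n_g, size=config.n_de_genes, replace=False)
    de_signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    log2_mu[de_idx] += (de_signs * config.de_log2fc)[:, None] * stratum_t2d[None, :]
    truth.de_genes = {gene_ids[i]: float(s * config.de_log2fc) for i, s in zip(de_idx, de_signs)}

    # hormone-anchored coexpression modules
    if config.coexpr_module_size > 0:
        hormone_idx = _hormone_gene_indices(config)
        taken = set(hormone_idx.values())
        candidates = np.array([i for i in range(n_g) if i not in taken])
        rng.shuffle(candidates)
        offset = 0
        for sym, anchor in hormone_idx.items():
            members = [anchor] + list(
                candidates[offset: offset + config.coexpr_module_size - 1]
            )
            offset += config.coexpr_module_size - 1
            factor = rng.normal(0.0, 1.0, size=n_s)
            log2_mu[members] += config.coexpr_loading * factor[None, :]
            truth.coexpr_modules[sym] = [gene_ids[i] for i in members]
            taken.update(members)

    # genotypes: cis variants within ±1 Mb, one causal per eQTL gene, decoys beyond 2.5 Mb
    genotypes, eqtl = _simulate_genotypes(config, ann, rng)
    for vrow, gi, beta in eqtl:
        log2_mu[gi] += beta * genotypes.dosage[vrow]
        truth.eqtl_pairs.append((str(genotypes.variant_id[vrow]), gene_ids[gi], float(beta)))

    # batch location/scale effects + extra observation noise
    batch_codes = pd.Categorical(meta["batch"]).codes
    shifts = rng.normal(0.0, config.batch_shift_sd, size=(config.n_batches, n_g))
    scales = np.exp(rng.normal(0.0, config.batch_scale_sd, size=(config.n_batches, n_g)))
    eps = rng.normal(0.0, config.obs_noise_sd, size=(n_g, n_s))
    log2_mu += shifts[batch_codes].T + eps * scales[batch_codes].T

    # convert to expected counts at each donor's depth and draw NB
    depths = rng.uniform(*config.depth_range, size=n_s)
    theta = np.exp2(log2_mu)
    mu = theta / theta.sum(axis=0, keepdims=True) * depths[None, :]
    counts = _nb_counts(mu, config.nb_dispersion, rng)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=meta.index)
    return counts_df, meta, ann, genotypes, truth


def _simulate_genotypes(
    cfg: SimulationConfig, ann: list[GeneAnnotation], rng: np.random.Generator
) -> tuple[GenotypeMatrix, list[tuple[int, int, float]]]:
    """Variants for a random subset of genes plus decoys beyond the cis window.

    Returns the genotype matrix and a list of (variant row, gene index, beta)
    for the planted causal variants.
    """
    n_s = cfg.n_donors
    samples = [f"D{i:04d}" for i in range(n_s)]
    if cfg.n_eqtl_genes == 0 or cfg.n_variants_per_gene == 0:
        return (
            GenotypeMatrix(
                variant_id=np.array([], dtype=str),
                chrom=np.array([], dtype=str),
                pos=np.array([], dtype=np.int64),
                ref=np.array([], dtype=str),
                alt=np.array([], dtype=str),
                dosage=np.zeros((0, n_s)),
                samples=samples,
            ),
            [],
        )
    gene_idx = rng.choice(cfg.n_genes, size=cfg.n_eqtl_genes, replace=False)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    causal: list[tuple[int, int, float]] = []
    for gi in gene_idx:
        gene = ann[gi]
        causal_slot = int(rng.integers(cfg.n_variants_per_gene))
        for k in range(cfg.n_variants_per_gene):
            pos = int(rng.integers(max(1, gene.start - 1_000_000), gene.end + 1_000_000))
            maf = rng.uniform(*cfg.maf_range)
            dose = rng.binomial(2, maf, size=n_s).astype(float)
            while dose.var() == 0:  # keep planted variants informative
                dose = rng.binomial(2, maf, size=n_s).astype(float)
            vid = f"rs_{gene.gene_id}_{k}"
            ids.append(vid)
            chroms.append(gene.chrom)
            poss.append(pos)
            refs.append("A")
            alts.append("G")
            rows.append(dose)
            if k == causal_slot:
                causal.append((len(rows) - 1, int(gi), cfg.eqtl_beta))
        for k in range(cfg.n_decoys_per_gene):
            side = 1 if k % 2 == 0 else -1
            offset = _DECOY_OFFSET + int(rng.integers(1, 500_000))
            pos = gene.end + offset if side > 0 else gene.start - offset
            if pos < 1:
                pos = gene.end + offset
            maf = rng.uniform(*cfg.maf_range)
            ids.append(f"decoy_{gene.gene_id}_{k}")
            chroms.append(gene.chrom)
            poss.append(pos)
            refs.append("A")
            alts.append("G")
            rows.append(rng.binomial(2, maf, size=n_s).astype(float))
    gm = GenotypeMatrix(
        variant_id=np.array(ids),
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs),
        alt=np.array(alts),
        dosage=np.vstack(rows),
        samples=samples,
    )
    return gm, causal


def simulate_tissue_panel(
    config: SimulationConfig, n_per_tissue: int
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Simulate a four-tissue expression panel (fat, islet, liver, muscle).

    A designated 5% slice of genes per tissue is tissue-specific (strongly
    expressed only there); the remainder are ubiquitous.  Returns
    ``(counts, metadata, specific_sets)`` where ``specific_sets`` maps each
    tissue to its specific gene ids.
    """
    if n_per_tissue < 1:
        raise ConfigError("n_per_tissue must be >= 1")
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    tissues = ["fat", "islet", "liver", "muscle"]
    ann = _make_annotation(config, rng)
    gene_ids = [a.gene_id for a in ann]
    n_g = config.n_genes
    n_s = 4 * n_per_tissue
    labels = np.repeat(tissues, n_per_tissue)
    sample_ids = [f"{t}_{i:03d}" for t in tissues for i in range(n_per_tissue)]

    n_specific = max(1, n_g // 20)
    perm = rng.permutation(n_g)
    specific_sets = {
        t: sorted(gene_ids[i] for i in perm[k * n_specific: (k + 1) * n_specific])
        for k, t in enumerate(tissues)
    }
    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n_g)
    log2_mu = np.tile(base[:, None], (1, n_s))
    for k, t in enumerate(tissues):
        idx = perm[k * n_specific: (k + 1) * n_specific]
        in_tissue = labels == t
        # off-tissue expression pushed far below the 1-CPM call threshold
        log2_mu[np.ix_(idx, ~in_tissue)] = -14.0
        log2_mu[np.ix_(idx, in_tissue)] = base[idx][:, None] + 3.0
    log2_mu += rng.normal(0.0, config.obs_noise_sd, size=(n_g, n_s))
    depths = rng.uniform(*config.depth_range, size=n_s)
    theta = np.exp2(log2_mu)
    mu = theta / theta.sum(axis=0, keepdims=True) * depths[None, :]
    counts = _nb_counts(mu, config.nb_dispersion, rng)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    meta = pd.DataFrame(
        {
            "donor_id": sample_ids,
            "tissue": labels,
            "clinical_t2d": False,
            "hba1c": 5.4,
            "bmi": 25.0,
            "sex": rng.choice(["M", "F"], size=n_s),
            "age": rng.integers(20, 80, size=n_s),
            "purity": np.where(labels == "islet", 80.0, np.nan),
            "stimulatory_index": np.nan,
            "batch": "B1",
        }
    ).set_index("donor_id", drop=False)
    return counts_df, meta, specific_sets
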