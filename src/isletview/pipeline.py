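"""Pipeline configuration and stage orchestration.

``run_pipeline`` executes the stages in dependency order —
simulate → normalize → associate → coexpress → eqtl → enrich → report —
writing every output as TSV/JSON under the output directory and recording
a manifest with a content hash per file.  All randomness flows from named
per-stage seeds in the configuration; reruns with the same configuration
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import isletview
from isletview import association as assoc
from isletview import coexpression as coexpr
from isletview import eqtl as eqtl_mod
from isletview import normalization as norm
from isletview import report as report_mod
from isletview.enrichment import bootstrap_enrichment
from isletview.errors import ConfigError, IsletViewError, NotFoundError
from isletview.io_formats import (
    read_annotation,
    read_counts,
    read_genotypes,
    read_phenotypes,
    write_annotation,
    write_counts,
    write_genotypes_vcf,
    write_phenotypes,
)
from isletview.simulate import HORMONE_SYMBOLS, SimulationConfig, SyntheticTruth, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, paths, seeds and flags for a full run.

    Threshold defaults are the analysis constants of the islet resource:
    10 million minimum reads, FPKM > 0 in 95% of samples with mean above 1,
    the 1 CPM / 80% expression call, a 2 Mb cis window, one million
    background correlation pairs and 10,000 bootstrap iterations.
    """

    out_dir: str = "isletview_run"
    # inputs; empty string means "simulate them"
    counts: str = ""
    phenotypes: str = ""
    annotation: str = ""
    genotypes: str = ""
    celltype_table: str = ""
    # thresholds
    min_reads: int = 10_000_000
    frac_nonzero: float = 0.95
    min_mean_fpkm: float = 1.0
    cpm_min: float = 1.0
    frac_expressed: float = 0.80
    cis_window: int = 2_000_000
    n_pairs: int = 1_000_000
    bootstrap_iterations: int = 10_000
    maf_min: float = 0.05
    top_coexpressed: int = 100
    top_eqtls: int = 10
    # analysis options
    covariates: tuple[str, ...] = ("purity", "sex", "age")
    phenotypes_tested: tuple[str, ...] = assoc.PHENOTYPES
    batch_adjust_eqtl: bool = True
    batch_in_association: bool = False
    moderation: bool = True
    p_floor: bool = True
    report_genes: tuple[str, ...] = tuple(HORMONE_SYMBOLS)
    enrichment_target: str = "INS"
    # per-stage seeds
    seed_simulate: int = 1
    seed_null: int = 2
    seed_enrich: int = 3
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        for name in ("min_reads", "cis_window", "n_pairs", "bootstrap_iterations",
                     "top_coexpressed", "top_eqtls"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("frac_nonzero", "frac_expressed"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        self.simulation.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        d["phenotypes_tested"] = list(self.phenotypes_tested)
        d["report_genes"] = list(self.report_genes)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        for key in ("covariates", "phenotypes_tested", "report_genes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2))


class PipelineRun:
    """Holds intermediate state and the output manifest during a run."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.files: list[Path] = []
        self.log: dict = {"package_version": isletview.__version__, "stages": {}}

    def register(self, path: Path) -> Path:
        self.files.append(path)
        return path

    def manifest(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "files": {str(p.relative_to(self.out)): _sha256(p) for p in sorted(self.files)},
            "log": self.log,
        }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the output manifest."""
    run = PipelineRun(config)
    out = run.out
    cfg = config
    stage = "simulate"
    try:
        # ---------------- inputs ----------------
        if cfg.counts:
            counts = read_counts(cfg.counts)
            metadata = read_phenotypes(cfg.phenotypes)
            annotation = read_annotation(cfg.annotation)
            genotypes = read_genotypes(cfg.genotypes, cfg.maf_min) if cfg.genotypes else None
            truth = None
        else:
            sim_cfg = cfg.simulation
            sim_cfg.seed = cfg.seed_simulate
            counts, metadata, annotation, genotypes, truth = simulate_cohort(sim_cfg)
            write_counts(counts, run.register(out / "counts.tsv"))
            write_phenotypes(metadata, run.register(out / "phenotypes.csv"))
            write_annotation(annotation, run.register(out / "annotation.tsv"))
            write_genotypes_vcf(genotypes, run.register(out / "genotypes.vcf"))
            _write_json(truth.to_dict(), run.register(out / "truth.json"))
        run.log["stages"]["simulate"] = {"n_genes": int(counts.shape[0]), "n_samples": int(counts.shape[1])}

        # ---------------- normalize ----------------
        stage = "normalize"
        lengths = pd.Series({a.gene_id: a.length for a in annotation})
        ds, norm_log = norm.normalize_dataset(
            counts, lengths, design=None,
            min_reads=cfg.min_reads, frac_nonzero=cfg.frac_nonzero, min_mean_fpkm=cfg.min_mean_fpkm,
        )
        filter_trace = {
            g: "filter_genes" for g in counts.index.difference(ds.counts.index)
        }
        run.log["stages"]["normalize"] = norm_log
        metadata = metadata.loc[ds.counts.columns]
        pd.Series(ds.counts.columns).to_csv(
            run.register(out / "retained_samples.txt"), index=False, header=False)
        pd.Series(ds.counts.index).to_csv(
            run.register(out / "retained_genes.txt"), index=False, header=False)
        ds.norm_factors.factors.to_csv(run.register(out / "factors.tsv"), sep="\t")
        ds.logcpm.round(6).to_csv(run.register(out / "logcpm.tsv"), sep="\t")
        purity_table = norm.purity_correlation(ds.logcpm, metadata["purity"])
        purity_table.to_csv(run.register(out / "purity_correlation.tsv"), sep="\t")

        # ---------------- associate ----------------
        stage = "associate"
        association_tables: dict[str, pd.DataFrame] = {}
        covariates = tuple(cfg.covariates) + (("batch",) if cfg.batch_in_association else ())
        for phen in cfg.phenotypes_tested:
            design = assoc.build_design(metadata, phen, covariates)
            weights = norm.precision_weights(
                ds.counts[design.samples], design.matrix, ds.norm_factors)
            res = assoc.fit_linear(
                ds.logcpm[design.samples], weights, design, moderation=cfg.moderation)
            association_tables[phen] = res
            res.round(10).to_csv(run.register(out / f"association_{phen}.tsv"), sep="\t")
        run.log["stages"]["associate"] = {
            phen: {"n_samples": int(len(assoc.build_design(metadata, phen, covariates).samples))}
            for phen in cfg.phenotypes_tested
        }

        # ---------------- coexpress ----------------
        stage = "coexpress"
        null = coexpr.build_null(ds.logcpm, n_pairs=cfg.n_pairs, seed=cfg.seed_null)
        null.save(out / "null.npy")
        run.register(out / "null.npy")
        run.register(out / "null.json")
        run.log["stages"]["coexpress"] = {"n_pairs": null.n_pairs, "seed": null.seed}

        symbol_to_id = {a.symbol: a.gene_id for a in annotation}
        # ---------------- eqtl ----------------
        stage = "eqtl"
        eqtl_summary = None
        eqtl_records = pd.DataFrame(columns=eqtl_mod.EQTL_COLUMNS)
        if genotypes is not None and genotypes.n_variants > 0:
            if cfg.batch_adjust_eqtl and metadata["batch"].nunique() > 1:
                expr = norm.batch_adjust(ds.logcpm, metadata["batch"])
            else:
                expr = ds.logcpm
            ann_kept = [a for a in annotation if a.gene_id in ds.counts.index]
            pairs = eqtl_mod.cis_pairs(ann_kept, genotypes, window=cfg.cis_window)
            eqtl_records = eqtl_mod.eqtl_scan(expr, genotypes, pairs)
            eqtl_summary = eqtl_mod.gene_summaries(eqtl_records, k=cfg.top_eqtls)
        eqtl_records.round(10).to_csv(run.register(out / "eqtl.tsv"), sep="\t", index=False)
        run.log["stages"]["eqtl"] = {"n_tests": int(len(eqtl_records))}

        # ---------------- enrich ----------------
        stage = "enrich"
        enrich_out: dict = {"skipped": True, "reason": "fewer than 2 eQTL genes"}
        if eqtl_summary:
            egenes = sorted(
                g for g, s in eqtl_summary.items() if s["lead"]["fdr"] <= 0.05
            )
            target_id = symbol_to_id.get(cfg.enrichment_target, cfg.enrichment_target)
            egenes = [g for g in egenes if g in ds.logcpm.index and g != target_id]
            if len(egenes) >= 2 and target_id in ds.logcpm.index:
                res = bootstrap_enrichment(
                    egenes, target_id, ds.logcpm, null,
                    B=cfg.bootstrap_iterations, seed=cfg.seed_enrich,
                )
                enrich_out = {
                    "target": cfg.enrichment_target,
                    "set_size": res.set_size,
                    "observed_stat": res.observed_stat,
                    "p_boot": res.p_boot,
                    "B": res.B,
                    "seed": res.seed,
                }
        _write_json(enrich_out, run.register(out / "enrichment.json"))
        run.log["stages"]["enrich"] = {"done": "p_boot" in enrich_out}

        # ---------------- report ----------------
        stage = "report"
        celltype = pd.read_csv(cfg.celltype_table, sep="\t") if cfg.celltype_table else None
        n_reports = 0
        for query in cfg.report_genes:
            try:
                gid = symbol_to_id.get(query, query)
                if gid not in ds.logcpm.index:
                    continue
                hormone = coexpr.hormone_panel(gid, ds.logcpm, null, symbol_to_id)
                top = coexpr.coexpressed_with(gid, ds.logcpm, null, k=cfg.top_coexpressed)
                rep = report_mod.build_gene_report(
                    query,
                    annotation,
                    ds.logcpm,
                    association=association_tables,
                    purity=purity_table,
                    hormone=hormone,
                    top_coexpressed=top,
                    eqtl_summary=eqtl_summary,
                    celltype=celltype,
                    filter_trace=filter_trace,
                )
            except NotFoundError as exc:
                logger.warning("report for %s skipped: %s", query, exc)
                continue
            path = run.register(out / f"report_{query}.json")
            path.write_text(report_mod.report_to_json(rep))
            n_reports += 1
        run.log["stages"]["report"] = {"n_reports": n_reports}
    except IsletViewError as exc:
        partial = PipelineRun.manifest(run)
        partial["failed_stage"] = stage
        _write_json(partial, out / "manifest.json")
        raise ConfigError(f"stage {stage!r} failed: {exc}") from exc

    manifest = run.manifest()
    _write_json(manifest, out / "manifest.json")
    return manifest
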