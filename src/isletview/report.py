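"""Per-gene report assembly and cross-tissue segment classification.

A gene report gathers, into one JSON-serializable document, the panels a
user of the islet resource sees for a gene: its annotation, cross-tissue
expression summary, relation to islet purity, expression rank, phenotype
associations (T2D status, HbA1c stratum, continuous HbA1c, BMI,
stimulatory index), coexpression with the six hormone genes, the top
coexpressed genes, the top cis-eQTLs, and an optional cell-type lookup.
Assembly only copies numbers from upstream result tables; nothing is
recomputed here.

Segments classify genes by the set of tissues calling them expressed:
A = islet only, B = islet+liver, C = islet+muscle, D = fat+islet,
E = fat+islet+liver, F = islet+liver+muscle, G = fat+islet+muscle,
H = all four.  Genes not expressed in islets carry no segment.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import stats

from isletview.errors import FormatError, NotFoundError
from isletview.io_formats import GeneAnnotation, resolve_gene

SCHEMA_VERSION = "1.0"

TISSUES = ["fat", "islet", "liver", "muscle"]

SEGMENTS = {
    frozenset({"islet"}): "A",
    frozenset({"islet", "liver"}): "B",
    frozenset({"islet", "muscle"}): "C",
    frozenset({"fat", "islet"}): "D",
    frozenset({"fat", "islet", "liver"}): "E",
    frozenset({"islet", "liver", "muscle"}): "F",
    frozenset({"fat", "islet", "muscle"}): "G",
    frozenset({"fat", "islet", "liver", "muscle"}): "H",
}


def rank_expression(gene: str, logcpm: pd.DataFrame, stat: str = "mean") -> float:
    """Percentile of the gene's average log2-CPM among all genes (descending).

    The highest-expressed of n genes is at 100/n percent ("top 0.5%" of
    200); ties take the average rank.  ``stat`` is ``mean`` (default) or
    ``median``.
    """
    if gene not in logcpm.index:
        raise NotFoundError(f"gene {gene!r} not in the expression universe")
    if stat == "mean":
        avg = logcpm.mean(axis=1)
    elif stat == "median":
        avg = logcpm.median(axis=1)
    else:
        raise FormatError(f"unknown rank statistic {stat!r}")
    ranks = stats.rankdata(-avg.to_numpy(), method="average")
    return float(100.0 * ranks[logcpm.index.get_loc(gene)] / len(avg))


def classify_segments(mask: pd.DataFrame, gene_set=None) -> pd.DataFrame:
    """Assign the tissue segment (A–H) of each gene from its expression calls.

    ``mask`` is the gene × tissue boolean frame from ``expressed_mask``
    (all four tissues required).  Returns gene_id, expressed_in
    (comma-joined tissue list) and segment (empty for genes not expressed
    in islets).
    """
    missing = [t for t in TISSUES if t not in mask.columns]
    if missing:
        raise FormatError(f"missing tissue masks: {missing}")
    genes = mask.index if gene_set is None else pd.Index([g for g in gene_set if g in mask.index])
    rows = []
    for g in genes:
        expressed = frozenset(t for t in TISSUES if bool(mask.at[g, t]))
        segment = SEGMENTS.get(expressed, "") if "islet" in expressed else ""
        rows.append(
            {
                "gene_id": g,
                "expressed_in": ",".join(sorted(expressed)),
                "segment": segment,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "expressed_in", "segment"])


def segment_counts(segments: pd.DataFrame) -> dict[str, int]:
    """Number of genes per segment label (A–H)."""
    with_segment = segments[segments["segment"] != ""]
    return {
        label: int((with_segment["segment"] == label).sum())
        for label in "ABCDEFGH"
    }


def tissue_expression_summary(logcpm: pd.DataFrame, tissue_labels: pd.Series) -> pd.DataFrame:
    """Median and IQR of log2-CPM per gene per tissue (long format)."""
    tissue_labels = tissue_labels.reindex(logcpm.columns)
    rows = []
    for tissue in sorted(tissue_labels.dropna().unique()):
        cols = tissue_labels.index[tissue_labels == tissue]
        sub = logcpm[cols]
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": logcpm.index,
                    "tissue": tissue,
                    "median": sub.median(axis=1),
                    "q25": sub.quantile(0.25, axis=1),
                    "q75": sub.quantile(0.75, axis=1),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _absent(reason: str) -> dict:
    return {"absent": True, "reason": reason}


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return round(v, ndigits) if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def build_gene_report(
    gene_query: str,
    annotation: list[GeneAnnotation],
    logcpm: pd.DataFrame,
    association: dict[str, pd.DataFrame] | None = None,
    purity: pd.DataFrame | None = None,
    hormone: pd.DataFrame | None = None,
    top_coexpressed: pd.DataFrame | None = None,
    eqtl_summary: dict | None = None,
    tissue_summary: pd.DataFrame | None = None,
    celltype: pd.DataFrame | None = None,
    filter_trace: dict[str, str] | None = None,
) -> dict:
    """Assemble the per-gene report as a JSON-serializable dict.

    Every panel is either populated from its upstream table or marked
    absent with a reason.  A gene that was removed by a QC filter raises
    :class:`NotFoundError` naming the filtering step (``filter_trace``
    maps removed gene ids to the step that removed them).
    """
    gene = resolve_gene(gene_query, annotation)
    gid = gene.gene_id
    if gid not in logcpm.index:
        step = (filter_trace or {}).get(gid, "unknown step")
        raise NotFoundError(f"gene {gene_query!r} ({gid}) was removed at {step}")

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "gene": {
            "gene_id": gid,
            "symbol": gene.symbol,
            "name": gene.name,
            "chrom": gene.chrom,
            "start": gene.start,
            "end": gene.end,
            "strand": gene.strand,
            "length": gene.length,
        },
        "rank_panel": {"percentile": rank_expression(gid, logcpm), "statistic": "mean"},
    }

    if tissue_summary is not None:
        sub = tissue_summary[tissue_summary["gene_id"] == gid]
        report["tissue_panel"] = (
            sub.drop(columns="gene_id").to_dict(orient="records")
            if not sub.empty
            else _absent("gene not in tissue panel")
        )
    else:
        report["tissue_panel"] = _absent("no tissue panel provided")

    if purity is not None and gid in purity.index:
        report["purity_panel"] = {
            "rho": float(purity.at[gid, "rho"]),
            "p": float(purity.at[gid, "p"]),
        }
    else:
        report["purity_panel"] = _absent("no purity correlation available")

    panels = {}
    for phen, table in (association or {}).items():
        if gid in table.index:
            row = table.loc[gid]
            panels[phen] = {
                k: (float(row[k]) if isinstance(row[k], (int, float, np.floating)) else row[k])
                for k in ("beta", "se", "t", "r2", "p", "fdr", "rank_pct")
                if k in row
            }
        else:
            panels[phen] = _absent("gene not in association table")
    report["phenotype_panels"] = panels or _absent("no association results provided")

    if hormone is not None:
        report["hormone_panels"] = hormone.to_dict(orient="records")
    else:
        report["hormone_panels"] = _absent("no hormone coexpression provided")

    if top_coexpressed is not None:
        report["top_coexpressed"] = top_coexpressed.head(100).to_dict(orient="records")
    else:
        report["top_coexpressed"] = _absent("no coexpression results provided")

    if eqtl_summary is not None:
        summary = eqtl_summary.get(gid)
        report["top_eqtls"] = summary["top"][:10] if summary else _absent("no cis pairs tested")
    else:
        report["top_eqtls"] = _absent("no eQTL results provided")

    if celltype is not None:
        key = "gene_id" if "gene_id" in celltype.columns else celltype.columns[0]
        sub = celltype[celltype[key].isin([gid, gene.symbol])]
        report["celltype_lookup"] = (
            sub.to_dict(orient="records") if not sub.empty else _absent("gene not in lookup table")
        )
    else:
        report["celltype_lookup"] = _absent("no cell-type table provided")
    return _round_floats(report)


def report_to_json(report: dict) -> str:
    """Deterministic JSON encoding (sorted keys, fixed float rounding)."""
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=False)
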