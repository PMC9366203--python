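"""Readers/writers for the formats the pipeline touches, and gene-id resolution.

Conventions
-----------
* Genomic coordinates are 1-based inclusive everywhere in memory (GTF
  convention); BED-style half-open input is converted on read.
* Counts travel as a gene × sample :class:`pandas.DataFrame` of
  non-negative integers.
* Phenotypes travel as a sample-indexed DataFrame with the columns of
  :data:`PHENOTYPE_COLUMNS`.
* Genotype dosages are alt-allele counts in [0, 2]; the VCF ``DS`` field
  is preferred over ``GT`` when both are present (imputed-data fidelity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from isletview.errors import AmbiguityError, FormatError, NotFoundError

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = [
    "donor_id",
    "tissue",
    "clinical_t2d",
    "hba1c",
    "bmi",
    "sex",
    "age",
    "purity",
    "stimulatory_index",
    "batch",
]

VALID_TISSUES = {"islet", "fat", "liver", "muscle"}


@dataclass(frozen=True)
class GeneAnnotation:
    """A single gene record: identifiers plus genomic coordinates.

    ``length`` is the merged exonic length in bp, used for FPKM; when no
    exon models are available it falls back to the gene span
    ``end - start + 1``.
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    length: int
    name: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if self.length < 1:
            raise FormatError(f"{self.gene_id}: length {self.length} < 1")


@dataclass
class GenotypeMatrix:
    """Variant × sample alt-allele dosage matrix with positions and MAF."""

    variant_id: np.ndarray  # str
    chrom: np.ndarray  # str
    pos: np.ndarray  # int, 1-based
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray  # float, shape (n_variants, n_samples), values in [0, 2]
    samples: list[str] = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return len(self.variant_id)

    @property
    def maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency from mean dosage."""
        p = self.dosage.mean(axis=1) / 2.0
        return np.minimum(p, 1.0 - p)

    def validate(self) -> None:
        if self.dosage.shape != (len(self.variant_id), len(self.samples)):
            raise FormatError("dosage shape does not match ids/samples")
        if np.any(self.dosage < 0) or np.any(self.dosage > 2):
            raise FormatError("dosages outside [0, 2]")
        if np.any(self.pos < 1):
            raise FormatError("variant positions must be >= 1")

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            variant_id=self.variant_id[mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            dosage=self.dosage[mask],
            samples=list(self.samples),
        )


# ---------------------------------------------------------------------------
# counts


def read_counts(path) -> pd.DataFrame:
    """Read a gene × sample count TSV (first column gene ids, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids: {dups[:5]}")
    if df.columns.has_duplicates:
        raise FormatError("duplicate sample ids in header")
    if df.isna().any().any():
        raise FormatError("missing cells in count matrix")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in count matrix: {exc}") from exc
    if np.any(values < 0):
        raise FormatError("negative counts")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# annotation


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by the union of 1-based inclusive intervals."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_s is not None:
        total += cur_e - cur_s + 1
    return total


def _parse_gtf_attributes(attr: str) -> dict:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, value = chunk.partition(" ")
            out[key] = value.strip().strip('"')
    return out


def read_annotation(path) -> list[GeneAnnotation]:
    """Read gene annotation from GTF (gene + exon features) or a BED-like TSV.

    TSV columns: gene_id, symbol, chrom, start, end, strand[, length[, name]]
    with 1-based inclusive coordinates.  In GTF mode the exonic length is
    the merged length of the gene's exon features, falling back to the gene
    span when no exons are present.
    """
    path = str(path)
    if path.endswith((".gtf", ".gtf.gz")):
        return _read_gtf(path)
    return _read_annotation_tsv(path)


def _read_gtf(path) -> list[GeneAnnotation]:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attr = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            attrs = _parse_gtf_attributes(attr)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            start, end = int(start), int(end)
            if feature == "gene":
                if gene_id in genes:
                    raise FormatError(f"duplicate gene id {gene_id}")
                genes[gene_id] = {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "symbol": attrs.get("gene_name", gene_id),
                    "name": attrs.get("gene_description", ""),
                }
            else:
                exons.setdefault(gene_id, []).append((start, end))
    out = []
    for gene_id, rec in genes.items():
        if gene_id in exons:
            length = _merged_length(exons[gene_id])
        else:
            length = rec["end"] - rec["start"] + 1
        out.append(
            GeneAnnotation(
                gene_id=gene_id,
                symbol=rec["symbol"],
                name=rec["name"],
                chrom=rec["chrom"],
                start=rec["start"],
                end=rec["end"],
                strand=rec["strand"],
                length=length,
            )
        )
    return out


def _read_annotation_tsv(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["gene_id", "symbol", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"annotation TSV missing columns: {missing}")
    if df["gene_id"].duplicated().any():
        raise FormatError("duplicate gene ids in annotation")
    out = []
    for _, row in df.iterrows():
        length = row.get("length")
        if length is None or pd.isna(length):
            length = int(row["end"]) - int(row["start"]) + 1
        name = row.get("name", "")
        out.append(
            GeneAnnotation(
                gene_id=str(row["gene_id"]),
                symbol=str(row["symbol"]),
                name="" if pd.isna(name) else str(name),
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row["strand"]),
                length=int(length),
            )
        )
    return out


def write_annotation(annotation: list[GeneAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "symbol": a.symbol,
                "chrom": a.chrom,
                "start": a.start,
                "end": a.end,
                "strand": a.strand,
                "length": a.length,
                "name": a.name,
            }
            for a in annotation
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path) -> pd.DataFrame:
    """Read the donor phenotype CSV into a donor-indexed DataFrame."""
    df = pd.read_csv(path, dtype={"donor_id": str, "batch": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype CSV missing columns: {missing}")
    if df.duplicated(subset=["donor_id", "tissue"]).any():
        raise FormatError("duplicate (donor_id, tissue) rows in phenotypes")
    bad = set(df["tissue"]) - VALID_TISSUES
    if bad:
        raise FormatError(f"unknown tissue labels: {sorted(bad)}")
    purity = df["purity"].dropna()
    if ((purity < 0) | (purity > 100)).any():
        raise FormatError("purity outside [0, 100]")
    if (df["hba1c"].dropna() <= 0).any():
        raise FormatError("non-positive HbA1c")
    if (df["stimulatory_index"].dropna() <= 0).any():
        raise FormatError("non-positive stimulatory index")
    df["clinical_t2d"] = df["clinical_t2d"].astype(bool)
    return df.set_index("donor_id", drop=False)


def write_phenotypes(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, maf_min: float = 0.05, samples: list[str] | None = None) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT and/or DS) or a dosage TSV.

    Dosages come from the ``DS`` FORMAT field when present, else from the
    alt-allele count of ``GT``.  Multi-allelic records are split into one
    record per alt allele.  Variants with minor-allele frequency below
    ``maf_min`` or zero variance are removed; removal counts are logged.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        gm = _read_vcf(path)
    else:
        gm = _read_dosage_tsv(path)
    gm.validate()
    if samples is not None:
        if not set(samples) & set(gm.samples):
            raise FormatError("genotype samples are disjoint from metadata samples")
    n0 = gm.n_variants
    var = gm.dosage.var(axis=1)
    keep = (gm.maf >= maf_min) & (var > 0)
    gm = gm.subset(keep)
    logger.info(
        "read_genotypes: %d variants read, %d removed (maf < %g or zero variance), %d retained",
        n0, n0 - gm.n_variants, maf_min, gm.n_variants,
    )
    return gm


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for i, variant in enumerate(vcf):
        try:
            n_alt = len(variant.ALT)
            try:
                ds = variant.format("DS") if "DS" in (variant.FORMAT or []) else None
            except KeyError:
                ds = None
            for ai in range(n_alt):
                if ds is not None:
                    dose = np.asarray(ds, dtype=float)[:, ai] if ds.ndim == 2 else np.asarray(ds, dtype=float)
                else:
                    gts = np.asarray(variant.genotypes, dtype=object)[:, :2].astype(int)
                    dose = (gts == ai + 1).sum(axis=1).astype(float)
                vid = variant.ID or f"{variant.CHROM}:{variant.POS}:{variant.REF}:{variant.ALT[ai]}"
                if n_alt > 1:
                    vid = f"{vid}_alt{ai + 1}"
                ids.append(vid)
                chroms.append(variant.CHROM)
                poss.append(variant.POS)
                refs.append(variant.REF)
                alts.append(variant.ALT[ai])
                rows.append(np.clip(dose, 0.0, 2.0))
        except (ValueError, TypeError, IndexError) as exc:
            raise FormatError(f"{path}: malformed VCF record #{i + 1}: {exc}") from exc
    if not rows:
        raise FormatError(f"{path}: no variants")
    return GenotypeMatrix(
        variant_id=np.array(ids),
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs),
        alt=np.array(alts),
        dosage=np.vstack(rows),
        samples=samples,
    )


def _read_dosage_tsv(path) -> GenotypeMatrix:
    """Dosage TSV: columns variant_id, chrom, pos, ref, alt, then one per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["variant_id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise FormatError(f"dosage TSV missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise FormatError("dosage TSV has no sample columns")
    dosage = df[sample_cols].to_numpy(dtype=float)
    return GenotypeMatrix(
        variant_id=df["variant_id"].to_numpy(dtype=str),
        chrom=df["chrom"].to_numpy(dtype=str),
        pos=df["pos"].to_numpy(dtype=np.int64),
        ref=df["ref"].to_numpy(dtype=str),
        alt=df["alt"].to_numpy(dtype=str),
        dosage=dosage,
        samples=sample_cols,
    )


def write_genotypes_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with a DS FORMAT field (plain text)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(set(gm.chrom)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=A,Type=Float,Description="Alt dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        order = np.lexsort((gm.pos, gm.chrom))
        for i in order:
            cells = []
            for d in gm.dosage[i]:
                n = int(round(d))
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(n, "./.")
                cells.append(f"{gt}:{d:g}")
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t{gm.variant_id[i]}\t{gm.ref[i]}\t{gm.alt[i]}"
                f"\t.\t.\t.\tGT:DS\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# gene resolution


def _levenshtein(a: str, b: str, cap: int = 3) -> int:
    if abs(len(a) - len(b)) > cap:
        return cap + 1
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        if min(cur) > cap:
            return cap + 1
        prev = cur
    return prev[-1]


def resolve_gene(query: str, annotation: list[GeneAnnotation]) -> GeneAnnotation:
    """Resolve a gene query by Ensembl id, then symbol, then full name.

    Symbol/name matching is case-insensitive.  An ambiguous symbol raises
    :class:`AmbiguityError` listing all candidate gene ids; no match raises
    :class:`NotFoundError` listing symbols within edit distance 2.
    """
    if not query:
        raise NotFoundError("empty gene query")
    by_id = [a for a in annotation if a.gene_id == query]
    if len(by_id) == 1:
        return by_id[0]
    q = query.casefold()
    for key in ("symbol", "name"):
        hits = [a for a in annotation if getattr(a, key) and getattr(a, key).casefold() == q]
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            ids = sorted(a.gene_id for a in hits)
            raise AmbiguityError(
                f"{key} {query!r} matches multiple genes: {ids}", candidates=ids
            )
    near = sorted(
        {a.symbol for a in annotation if _levenshtein(q, a.symbol.casefold(), 2) <= 2}
    )
    raise NotFoundError(
        f"gene {query!r} not found" + (f"; did you mean {near[:5]}?" if near else "")
    )
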