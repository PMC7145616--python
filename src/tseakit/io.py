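"""Readers and writers for every external format the pipeline touches.

GWAS summary statistics arrive in many column dialects; a caller-supplied
column map (internal field -> file column) normalises them to one internal
model. Gene annotation is accepted as BED (0-based half-open) or GFF
(1-based inclusive); internally all coordinates are 1-based inclusive and
only the BED reader converts. Chromosome labels are normalised by stripping
a leading ``chr`` and uppercasing.

Expression panels are plain gene x sample TSV matrices with a separate
sample->tissue label file. LD reference genotypes are read from VCF (via
cyvcf2) or from a plain dosage TSV.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError, FormatError

__all__ = [
    "SummaryStats",
    "GeneAnnotation",
    "ExpressionPanel",
    "GenotypeRef",
    "normalize_chrom",
    "sniff_column_map",
    "read_summary_stats",
    "write_summary_stats",
    "read_gene_annotation",
    "write_gene_annotation_bed",
    "read_expression_panel",
    "write_expression_panel",
    "read_genotypes",
    "write_genotypes_dosage",
    "file_sha256",
]

#: canonical internal field names for summary statistics
SUMSTAT_FIELDS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "maf", "effect", "se", "pvalue", "n",
)
MANDATORY_FIELDS = ("snp_id", "chrom", "pos", "pvalue")

#: common header spellings, used only by the optional sniffer
_ALIASES = {
    "snp_id": ["snp", "snpid", "rsid", "rs_id", "variant_id", "markername", "id"],
    "chrom": ["chr", "chrom", "chromosome"],
    "pos": ["pos", "bp", "position", "base_pair_location"],
    "effect_allele": ["effect_allele", "a1", "allele1", "ea", "alt"],
    "other_allele": ["other_allele", "a2", "allele2", "oa", "ref", "non_effect_allele"],
    "maf": ["maf", "eaf", "freq", "effect_allele_frequency", "af"],
    "effect": ["effect", "beta", "b", "or", "log_odds"],
    "se": ["se", "stderr", "standard_error"],
    "pvalue": ["p", "pval", "pvalue", "p_value", "p_bolt_lmm", "p-value"],
    "n": ["n", "nsamples", "sample_size", "n_total"],
}


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix and uppercase (``chr6`` -> ``6``, ``chrx`` -> ``X``)."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    return "MT" if s == "M" else s


@dataclass
class SummaryStats:
    """Per-variant GWAS association records for one study.

    ``records`` is a DataFrame with the canonical columns of
    :data:`SUMSTAT_FIELDS`; optional fields absent from the source file are
    NaN. ``drop_counts`` records how many raw rows each normalisation rule
    removed.
    """

    study_id: str
    records: pd.DataFrame
    drop_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # uniqueness is an invariant of the type (readers dedupe first);
        # missing-ID placeholders are exempt — QC removes them
        ids = self.records["snp_id"].astype("string")
        real = ids[~(ids.isna() | ids.str.strip().isin(["", ".", "NA", "na", "nan"]))]
        if real.duplicated().any():
            dup = real[real.duplicated()].iloc[0]
            raise FormatError(f"duplicate snp_id {dup!r} in study {self.study_id!r}")

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def subset(self, mask) -> "SummaryStats":
        return SummaryStats(self.study_id, self.records.loc[mask].reset_index(drop=True),
                            dict(self.drop_counts))


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene body; coordinates 1-based inclusive."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}")

    @property
    def is_autosomal(self) -> bool:
        return self.chrom.isdigit()

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ExpressionPanel:
    """A gene x sample expression matrix with sample->tissue labels.

    ``expr`` values are raw non-negative expression; scoring log-transforms
    internally. ``covariates`` (optional) is a sample x covariate frame
    aligned to ``expr``'s columns.
    """

    panel_id: str
    expr: pd.DataFrame
    sample_tissue: pd.Series
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.expr.index.duplicated().any():
            dup = self.expr.index[self.expr.index.duplicated()][0]
            raise FormatError(f"duplicate gene row {dup!r} in panel {self.panel_id!r}")
        missing = [s for s in self.expr.columns if s not in self.sample_tissue.index]
        if missing:
            raise ConfigurationError(
                f"samples without tissue label in panel {self.panel_id!r}: {missing[:5]}")
        self.sample_tissue = self.sample_tissue.loc[self.expr.columns]
        if (self.expr.to_numpy() < 0).any():
            raise FormatError(f"negative expression values in panel {self.panel_id!r}")
        if self.covariates is not None:
            missing = [s for s in self.expr.columns if s not in self.covariates.index]
            if missing:
                raise ConfigurationError(
                    f"samples without covariates in panel {self.panel_id!r}: {missing[:5]}")
            self.covariates = self.covariates.loc[self.expr.columns]

    @property
    def tissues(self) -> list[str]:
        return sorted(self.sample_tissue.unique())

    @property
    def n_samples_per_tissue(self) -> dict[str, int]:
        return self.sample_tissue.value_counts().to_dict()


@dataclass
class GenotypeRef:
    """Reference-panel dosages (SNP x sample, values in [0, 2]) for LD estimation."""

    samples: list[str]
    dosages: np.ndarray
    snp_ids: list[str]
    snp_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.snp_index:
            self.snp_index = {s: i for i, s in enumerate(self.snp_ids)}
        if self.dosages.shape != (len(self.snp_ids), len(self.samples)):
            raise ContractError("dosage matrix shape does not match snp/sample lists")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.snp_index

    def dosage_matrix(self, snp_ids: list[str]) -> np.ndarray:
        rows = [self.snp_index[s] for s in snp_ids]
        return self.dosages[rows]


# --------------------------------------------------------------------------
# summary statistics

def sniff_column_map(path: str | Path) -> dict[str, str]:
    """Guess a column map from common header spellings (convenience only)."""
    header = pd.read_csv(path, sep=None, engine="python", nrows=0).columns
    lower = {c.lower().strip(): c for c in header}
    cmap = {}
    for internal, aliases in _ALIASES.items():
        for a in (internal, *aliases):     # canonical names always recognised
            if a in lower:
                cmap[internal] = lower[a]
                break
    return cmap


def read_summary_stats(path: str | Path, column_map: dict[str, str] | None = None,
                       study_id: str | None = None) -> SummaryStats:
    """Read a whitespace/tab-separated summary-statistics file.

    Rows whose P-value is unparseable or outside (0, 1], or whose position
    is unparseable, are dropped and counted in ``drop_counts``. Allele
    frequencies above 0.5 are folded to minor-allele frequency. Exact
    duplicate rsIDs beyond the first occurrence are dropped with a count.
    """
    path = Path(path)
    if column_map is None:
        column_map = sniff_column_map(path)
    missing = [f for f in MANDATORY_FIELDS if f not in column_map]
    if missing:
        raise ConfigurationError(f"column_map lacks mandatory fields: {missing}")
    try:
        raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty summary-statistics file: {path}") from exc
    if raw.empty:
        raise FormatError(f"no data rows in summary-statistics file: {path}")
    absent = [col for col in column_map.values() if col not in raw.columns]
    if absent:
        raise ConfigurationError(f"mapped columns absent from {path.name}: {absent}")

    df = pd.DataFrame(index=raw.index)
    for internal in SUMSTAT_FIELDS:
        df[internal] = raw[column_map[internal]] if internal in column_map else np.nan

    drops: dict[str, int] = {}
    n0 = len(df)
    df["pvalue"] = pd.to_numeric(df["pvalue"], errors="coerce")
    keep = df["pvalue"].notna() & (df["pvalue"] > 0) & (df["pvalue"] <= 1)
    drops["bad_pvalue"] = int(n0 - keep.sum())
    df = df[keep]
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    keep = df["pos"].notna() & (df["pos"] >= 1)
    drops["bad_pos"] = int(len(df) - keep.sum())
    df = df[keep].copy()
    df["pos"] = df["pos"].astype(np.int64)
    df["chrom"] = df["chrom"].map(normalize_chrom)
    for col in ("maf", "effect", "se"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    # fold allele frequency to MAF
    fold = df["maf"].notna() & (df["maf"] > 0.5)
    df.loc[fold, "maf"] = 1.0 - df.loc[fold, "maf"]
    dup = df["snp_id"].duplicated()
    drops["duplicate_snp_id"] = int(dup.sum())
    df = df[~dup].reset_index(drop=True)

    return SummaryStats(study_id or path.stem, df, drops)


def write_summary_stats(ss: SummaryStats, path: str | Path, sidecar: bool = True) -> None:
    """Write canonical TSV plus a JSON sidecar with drop counts and provenance."""
    path = Path(path)
    ss.records.to_csv(path, sep="\t", index=False, na_rep="NA")
    if sidecar:
        meta = {
            "study_id": ss.study_id,
            "n_records": int(ss.n_variants),
            "drop_counts": ss.drop_counts,
            "sha256": file_sha256(path),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


# --------------------------------------------------------------------------
# gene annotation

def read_gene_annotation(path: str | Path, format: str | None = None) -> list[GeneAnnotation]:
    """Read gene bodies from BED (converted 0-based half-open -> 1-based
    inclusive) or GFF/GTF (kept 1-based inclusive).

    Non-autosomal features are retained; downstream stages filter them."""
    path = Path(path)
    if format is None:
        format = "gff" if path.suffix.lower() in {".gff", ".gff3", ".gtf"} else "bed"
    if format == "bed":
        return _read_bed(path)
    if format == "gff":
        return _read_gff(path)
    raise ConfigurationError(f"unknown annotation format {format!r}")


def _read_bed(path: Path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = re.split(r"\s+", line)
            if len(parts) < 4:
                raise FormatError(f"{path.name}:{ln}: BED needs >= 4 columns")
            chrom, start0, end, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 else "+"
            genes.append(GeneAnnotation(
                gene_id=name, symbol=name, chrom=normalize_chrom(chrom),
                start=int(start0) + 1, end=int(end), strand=strand))
    if not genes:
        raise FormatError(f"no gene records in {path}")
    return genes


def _read_gff(path: Path) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes = []
    for feat in db.features_of_type("gene"):
        symbol = feat.attributes.get("gene_name", feat.attributes.get("Name", [feat.id]))[0]
        genes.append(GeneAnnotation(
            gene_id=feat.id, symbol=symbol, chrom=normalize_chrom(feat.seqid),
            start=feat.start, end=feat.end, strand=feat.strand if feat.strand in "+-" else "+"))
    if not genes:
        raise FormatError(f"no gene features in {path}")
    return genes


def write_gene_annotation_bed(genes: list[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# --------------------------------------------------------------------------
# expression panel

def read_expression_panel(path: str | Path, label_path: str | Path,
                          covariate_path: str | Path | None = None,
                          panel_id: str | None = None) -> ExpressionPanel:
    """Read a gene x sample TSV matrix and a two-column sample->tissue label file."""
    path = Path(path)
    expr = pd.read_csv(path, sep="\t", index_col=0)
    labels = pd.read_csv(label_path, sep="\t")
    if labels.shape[1] < 2:
        raise FormatError(f"label file {label_path} needs two columns (sample, tissue)")
    sample_tissue = pd.Series(labels.iloc[:, 1].values, index=labels.iloc[:, 0].astype(str))
    covariates = None
    if covariate_path is not None:
        covariates = pd.read_csv(covariate_path, sep="\t", index_col=0)
        covariates.index = covariates.index.astype(str)
    expr.columns = expr.columns.astype(str)
    return ExpressionPanel(panel_id or path.stem, expr, sample_tissue, covariates)


def write_expression_panel(panel: ExpressionPanel, expr_path: str | Path,
                           label_path: str | Path) -> None:
    panel.expr.to_csv(expr_path, sep="\t")
    pd.DataFrame({"sample": panel.sample_tissue.index,
                  "tissue": panel.sample_tissue.values}).to_csv(
        label_path, sep="\t", index=False)


# --------------------------------------------------------------------------
# genotypes

def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeRef:
    """Read reference genotypes from VCF (ALT-allele dosage) or a dosage TSV
    whose first column is the SNP id and remaining columns are samples."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in {".vcf", ".bcf", ".gz"} else "dosage"
    if format == "vcf":
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    dos = df.to_numpy(dtype=float)
    if dos.size and (dos.min() < 0 or dos.max() > 2):
        raise FormatError(f"dosages outside [0, 2] in {path}")
    return GenotypeRef(samples=[str(c) for c in df.columns], dosages=dos,
                       snp_ids=[str(i) for i in df.index])


def _read_vcf(path: Path) -> GenotypeRef:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    snp_ids, rows = [], []
    for i, var in enumerate(vcf):
        gt = np.asarray(var.genotypes, dtype=int)[:, :2]
        dose = (gt > 0).sum(axis=1).astype(float)
        dose[(gt < 0).any(axis=1)] = np.nan
        snp_ids.append(var.ID or f"{normalize_chrom(var.CHROM)}:{var.POS}")
        rows.append(dose)
    if not rows:
        raise FormatError(f"no variant records in {path}")
    dos = np.vstack(rows)
    # mean-impute missing genotypes per SNP
    for r in dos:
        if np.isnan(r).any():
            r[np.isnan(r)] = np.nanmean(r)
    return GenotypeRef(samples=list(vcf.samples), dosages=dos, snp_ids=snp_ids)


def write_genotypes_dosage(geno: GenotypeRef, path: str | Path) -> None:
    pd.DataFrame(geno.dosages, index=geno.snp_ids, columns=geno.samples).to_csv(
        path, sep="\t", index_label="snp_id")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
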