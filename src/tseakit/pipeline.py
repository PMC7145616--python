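"""End-to-end orchestration of one study: QC -> gene scores -> TAG sets ->
tissue enrichment -> GSEA validation -> report.

A study failing QC, gene-score qualification or TAG qualification still
produces a report; it simply carries ``passed``/``study_qualified`` flags
and no enrichment section.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrich import (DEFAULT_TAG_THRESHOLDS, gsea_validate, make_tag_sets,
                     run_tsea, select_top_tissues)
from .errors import TseaError
from .genescore import GeneScoreConfig, GeneScoreTable, score_study
from .io import (ExpressionPanel, GeneAnnotation, SummaryStats, file_sha256,
                 read_gene_annotation, read_genotypes, read_summary_stats,
                 read_expression_panel, sniff_column_map)
from .qc import QCConfig, apply_study_qc
from .report import StudyReport
from .specificity import specificity_scores, top_fraction_sets

__all__ = ["PipelineConfig", "run_study", "run_study_objects", "export_manhattan_data"]


@dataclass
class PipelineConfig:
    """Every threshold of the pipeline in one place, with the defaults the
    method prescribes."""

    qc: QCConfig = field(default_factory=QCConfig)
    genescore: GeneScoreConfig = field(default_factory=GeneScoreConfig)
    tag_thresholds: tuple = DEFAULT_TAG_THRESHOLDS
    tissue_fraction: float = 0.05
    score_kind: str = "auto"
    covariate_names: list = field(default_factory=list)
    n_top_tissues: int = 3
    n_perm: int = 10_000
    seed: int = 0
    column_map: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "qc" in data:
            cfg.qc = QCConfig(**data["qc"])
        if "genescore" in data:
            cfg.genescore = GeneScoreConfig(**data["genescore"])
        for key in ("tag_thresholds", "tissue_fraction", "score_kind",
                    "covariate_names", "n_top_tissues", "n_perm", "seed",
                    "column_map"):
            if key in data:
                setattr(cfg, key, data[key])
        return cfg


def _stage(name):
    """Attach the failing stage name to propagated errors."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise TseaError(f"stage {name!r}: {exc}") from exc
    return _Ctx()


def run_study_objects(ss: SummaryStats, genes: list[GeneAnnotation], geno,
                      panels: list[ExpressionPanel],
                      cfg: PipelineConfig | None = None,
                      provenance: dict | None = None) -> StudyReport:
    """Run the pipeline on already-loaded objects (the file-path front end
    ``run_study`` delegates here)."""
    cfg = cfg or PipelineConfig()
    with _stage("qc"):
        ss_qc, qc_report = apply_study_qc(ss, cfg.qc)
    report = StudyReport(study_id=ss.study_id, qc=qc_report.to_dict(),
                         provenance={"version": __version__, "seed": cfg.seed,
                                     **(provenance or {})})
    if not qc_report.passed:
        return report

    with _stage("genescore"):
        gs: GeneScoreTable = score_study(ss_qc, genes, geno, cfg.genescore)
    report.n_genes_scored = gs.n_success
    report.study_qualified = gs.qualified
    if not gs.qualified:
        return report

    with _stage("tag"):
        tags = make_tag_sets(gs, cfg.tag_thresholds)
    report.tag_summary = {
        str(t): {"size": len(tags.sets[t]["genes"]),
                 "qualified": tags.sets[t]["qualified"]}
        for t in tags.thresholds}
    if tags.excluded:
        report.study_qualified = False
        return report

    scored = set(gs.ok_pvalues().index)
    for panel in panels:
        with _stage(f"tsea[{panel.panel_id}]"):
            spec = specificity_scores(panel, cfg.score_kind, cfg.covariate_names)
            tsets = top_fraction_sets(spec, cfg.tissue_fraction)
            universe = scored & set(spec.scores.index)
            res = run_tsea(tags, tsets, universe)
        rows = [{"tissue": t, "threshold": float(thr),
                 "pvalue": float(res.pvalues.loc[t, thr]),
                 "overlap": res.counts[(t, float(thr))]["overlap"],
                 "expected": res.counts[(t, float(thr))]["expected"]}
                for t in res.pvalues.index
                for thr in res.pvalues.columns
                if np.isfinite(res.pvalues.loc[t, thr])]
        report.tsea[panel.panel_id] = rows

        with _stage(f"gsea[{panel.panel_id}]"):
            top = select_top_tissues(res, cfg.n_top_tissues)
            gsea_rows = []
            for tissue in top:
                row = res.pvalues.loc[tissue].dropna()
                best_thr = float(row.idxmin())
                tag_genes = tags.sets[best_thr]["genes"] & universe
                col = spec.scores.loc[sorted(universe), tissue]
                g = gsea_validate(col, tag_genes, n_perm=cfg.n_perm,
                                  seed=cfg.seed, study_id=ss.study_id,
                                  tissue=str(tissue), threshold=best_thr)
                gsea_rows.append(g.to_dict())
        report.top_tissues[panel.panel_id] = gsea_rows
    return report


def run_study(gwas_path, genes_path, geno_path, panel_paths,
              cfg: PipelineConfig | None = None) -> StudyReport:
    """Read every input file, run all stages, and return the study report.

    ``panel_paths`` is a list of (expr_path, label_path) pairs; at least one
    panel is required."""
    cfg = cfg or PipelineConfig()
    if not panel_paths:
        raise TseaError("at least one expression panel is required")
    cmap = cfg.column_map or sniff_column_map(gwas_path)
    ss = read_summary_stats(gwas_path, cmap)
    genes = read_gene_annotation(genes_path)
    geno = read_genotypes(geno_path)
    panels = [read_expression_panel(e, l) for e, l in panel_paths]
    prov = {"gwas_sha256": file_sha256(gwas_path),
            "genes_sha256": file_sha256(genes_path),
            "geno_sha256": file_sha256(geno_path)}
    return run_study_objects(ss, genes, geno, panels, cfg, prov)


def export_manhattan_data(ss: SummaryStats, gs: GeneScoreTable,
                          genes: list[GeneAnnotation]
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP- and gene-level (chrom, pos, -log10 P) tables for Manhattan plots.

    Only autosomes are exported; the gene position is the gene-body
    midpoint; both tables are sorted by (chrom, pos)."""
    df = ss.records
    auto = df["chrom"].map(lambda c: str(c).isdigit())
    snp = pd.DataFrame({
        "chrom": df.loc[auto, "chrom"].astype(int),
        "pos": df.loc[auto, "pos"],
        "neglog10_p": -np.log10(df.loc[auto, "pvalue"]),
    }).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    pos_map = {g.gene_id: g for g in genes}
    ok = gs.table[gs.table["status"] == "ok"]
    rows = []
    for gid, row in ok.iterrows():
        g = pos_map.get(gid)
        if g is None or not g.is_autosomal:
            continue
        rows.append({"chrom": int(g.chrom), "pos": g.midpoint,
                     "neglog10_p": -np.log10(row["pvalue"]), "gene_id": gid})
    gene = pd.DataFrame(rows, columns=["chrom", "pos", "neglog10_p", "gene_id"]
                        ).sort_values(["chrom", "pos"], kind="mergesort"
                                      ).reset_index(drop=True)
    return snp, gene
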