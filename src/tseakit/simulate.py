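"""Seeded synthetic inputs with known ground truth.

The generators emulate the statistical structure the pipeline assumes: an
expression panel with planted tissue-specific genes, LD-structured
reference genotypes in gene-sized blocks, and GWAS summary statistics with
association signal planted in the blocks of genes specific to one target
tissue. Summary statistics are simulated directly at the z-score level
(multivariate normal with the block LD as covariance) rather than through
individual-level phenotypes.

All generators derive their randomness from ``SimConfig.seed`` through
deterministically spawned per-component streams, so the same configuration
always yields byte-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .io import ExpressionPanel, GeneAnnotation, GenotypeRef, SummaryStats

__all__ = ["SimConfig", "gen_gene_annotation", "gen_expression_panel",
           "gen_genotypes", "gen_summary_stats", "simulate_study"]

#: gene bodies are spaced so that 50kb windows of adjacent genes never touch
GENE_SPACING = 200_000
GENE_LENGTH = 1_000


@dataclass
class SimConfig:
    """Ground-truth parameters for one synthetic study.

    ``specificity_effect`` is the mean log2-expression shift a planted gene
    receives in its tissue. ``noncentrality`` is the mean per-SNP z-score
    shift inside a causal gene's LD block, with per-SNP spread
    ``effect_sd``. ``n_causal_genes`` genes are planted per tissue in the
    expression panel; the GWAS signal lands on the ``causal_tissue`` set.

    The default genome (400 genes, 20 causal) is sized so the loosest TAG
    set (~20 causal + ~5% null genes) clears the 20-gene qualification
    floor and the planted genes exactly fill a tissue's top-5% set.
    """

    seed: int = 0
    n_genes: int = 400
    n_tissues: int = 5
    n_samples_per_tissue: int = 30
    specificity_effect: float = 4.0
    n_snps_per_gene: int = 5
    ld_block_rho: float = 0.5
    n_causal_genes: int = 20
    causal_tissue: str = "tissue_0"
    gwas_n: int = 50_000
    effect_sd: float = 1.0
    noncentrality: float = 5.0
    n_ref_samples: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_block_rho < 1.0:
            raise ConfigurationError("ld_block_rho must lie in [0, 1)")
        if self.n_causal_genes > int(0.05 * self.n_genes):
            raise ConfigurationError(
                "n_causal_genes must not exceed floor(0.05 * n_genes) so planted "
                "genes can all sit in the top-5% tissue-specific set")

    def rng(self, component: str) -> np.random.Generator:
        """Deterministic per-component stream derived from the master seed."""
        idx = {"panel": 0, "genotypes": 1, "gwas": 2}[component]
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(3)[idx])

    @property
    def tissues(self) -> list[str]:
        return [f"tissue_{i}" for i in range(self.n_tissues)]

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]


def gen_gene_annotation(cfg: SimConfig) -> list[GeneAnnotation]:
    """Synthetic autosomal gene bodies, round-robin over chromosomes 1..22,
    spaced so that adjacent 50kb windows never overlap."""
    genes = []
    per_chrom: dict[str, int] = {}
    for i, gid in enumerate(cfg.gene_ids):
        chrom = str(i % 22 + 1)
        slot = per_chrom.get(chrom, 0)
        per_chrom[chrom] = slot + 1
        start = slot * GENE_SPACING + 100_001
        genes.append(GeneAnnotation(gene_id=gid, symbol=gid, chrom=chrom,
                                    start=start, end=start + GENE_LENGTH - 1))
    return genes


def _planted_genes(cfg: SimConfig) -> dict[str, list[str]]:
    gene_ids = cfg.gene_ids
    truth: dict[str, list[str]] = {}
    k = cfg.n_causal_genes
    for i, tissue in enumerate(cfg.tissues):
        truth[tissue] = gene_ids[i * k:(i + 1) * k]
    return truth


def gen_expression_panel(cfg: SimConfig) -> tuple[ExpressionPanel, dict[str, list[str]]]:
    """Expression panel with planted tissue-specific genes.

    Baseline log2-expression is i.i.d. normal(5, 1); each planted gene gets
    ``specificity_effect`` added in its tissue. Values are returned on the
    raw scale (2**log - 1) so downstream log2(x+1) recovers the simulated
    log-expression exactly."""
    rng = cfg.rng("panel")
    tissues = cfg.tissues
    samples = [f"{t}_s{j}" for t in tissues for j in range(cfg.n_samples_per_tissue)]
    labels = np.repeat(tissues, cfg.n_samples_per_tissue)
    log_expr = rng.normal(5.0, 1.0, size=(cfg.n_genes, len(samples)))
    truth = _planted_genes(cfg)
    gene_row = {g: i for i, g in enumerate(cfg.gene_ids)}
    for tissue, genes in truth.items():
        cols = np.flatnonzero(labels == tissue)
        for g in genes:
            log_expr[gene_row[g], cols] += cfg.specificity_effect
    expr = pd.DataFrame(np.maximum(2.0 ** log_expr - 1.0, 0.0),
                        index=cfg.gene_ids, columns=samples)
    panel = ExpressionPanel(f"sim_panel_seed{cfg.seed}", expr,
                            pd.Series(labels, index=samples))
    return panel, truth


def gen_genotypes(cfg: SimConfig) -> GenotypeRef:
    """LD-structured reference dosages: one block per gene.

    Within a block, two latent Gaussian haplotypes per sample share an
    equicorrelation ``ld_block_rho``; each is thresholded at the normal
    quantile of a MAF drawn uniform(0.06, 0.5), and the dosage is the sum.
    Blocks are independent, so cross-block LD is ~0."""
    rng = cfg.rng("genotypes")
    k, n = cfg.n_snps_per_gene, cfg.n_ref_samples
    rho = cfg.ld_block_rho
    chol = np.linalg.cholesky(np.full((k, k), rho) + np.eye(k) * (1.0 - rho))
    all_dose, snp_ids = [], []
    for gi, gid in enumerate(cfg.gene_ids):
        mafs = rng.uniform(0.06, 0.5, size=k)
        thresh = stats.norm.ppf(mafs)[:, None]
        hap1 = chol @ rng.standard_normal((k, n))
        hap2 = chol @ rng.standard_normal((k, n))
        dose = (hap1 < thresh).astype(float) + (hap2 < thresh).astype(float)
        all_dose.append(dose)
        snp_ids.extend(f"rs{gi}_{j}" for j in range(k))
    return GenotypeRef(samples=[f"ref{j}" for j in range(n)],
                       dosages=np.vstack(all_dose), snp_ids=snp_ids)


def gen_summary_stats(cfg: SimConfig, geno: GenotypeRef,
                      genes: list[GeneAnnotation],
                      truth: dict[str, list[str]]) -> SummaryStats:
    """GWAS summary statistics with signal planted in the causal tissue's genes.

    Per gene block, SNP z-scores are drawn from MVN(mean, R) where R is the
    empirical block LD from ``geno``. Non-causal blocks have mean 0; in the
    blocks of the first ``n_causal_genes`` genes planted for
    ``causal_tissue``, the mean is R @ delta with per-SNP non-centrality
    delta ~ normal(noncentrality, effect_sd). z converts to a two-sided P
    and to effect = z / sqrt(gwas_n), se = 1 / sqrt(gwas_n)."""
    if cfg.causal_tissue not in truth:
        raise ConfigurationError(f"causal tissue {cfg.causal_tissue!r} not in truth map")
    causal = set(truth[cfg.causal_tissue][: cfg.n_causal_genes])
    rng = cfg.rng("gwas")
    k = cfg.n_snps_per_gene
    gene_pos = {g.gene_id: g for g in genes}
    rows = []
    for gi, gid in enumerate(cfg.gene_ids):
        block = geno.dosages[gi * k:(gi + 1) * k]
        r = np.corrcoef(block) if k > 1 else np.ones((1, 1))
        # clip eigenvalues for a valid sampling covariance
        w, v = np.linalg.eigh((r + r.T) / 2.0)
        w = np.clip(w, 0.0, None)
        root = v * np.sqrt(w)
        mean = np.zeros(k)
        if gid in causal:
            delta = rng.normal(cfg.noncentrality, cfg.effect_sd, size=k)
            mean = r @ delta
        z = mean + root @ rng.standard_normal(k)
        pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
        g = gene_pos[gid]
        maf = geno.dosages[gi * k:(gi + 1) * k].mean(axis=1) / 2.0
        maf = np.minimum(maf, 1.0 - maf)
        for j in range(k):
            pos = g.start + int(round((j + 0.5) * GENE_LENGTH / k))
            rows.append({"snp_id": f"rs{gi}_{j}", "chrom": g.chrom, "pos": pos,
                         "effect_allele": "A", "other_allele": "G",
                         "maf": maf[j], "effect": z[j] / np.sqrt(cfg.gwas_n),
                         "se": 1.0 / np.sqrt(cfg.gwas_n), "pvalue": pvals[j],
                         "n": cfg.gwas_n})
    df = pd.DataFrame(rows)
    return SummaryStats(f"sim_study_seed{cfg.seed}", df)


def simulate_study(cfg: SimConfig):
    """Generate one complete synthetic study.

    Returns (summary_stats, genes, genotypes, panel, truth)."""
    panel, truth = gen_expression_panel(cfg)
    genes = gen_gene_annotation(cfg)
    geno = gen_genotypes(cfg)
    ss = gen_summary_stats(cfg, geno, genes, truth)
    return ss, genes, geno, panel, truth


def recover_top_tissue(cfg: SimConfig) -> tuple[str, object]:
    """End-to-end ground-truth check for one synthetic study.

    Runs QC -> gene scores -> TAG sets -> tissue enrichment on a freshly
    generated study and returns (top-ranked tissue, TSEAResult); with a
    planted signal the top tissue should be ``cfg.causal_tissue``."""
    from .enrich import make_tag_sets, run_tsea, select_top_tissues
    from .genescore import GeneScoreConfig, score_study
    from .qc import QCConfig, apply_study_qc
    from .specificity import specificity_scores, top_fraction_sets

    ss, genes, geno, panel, _ = simulate_study(cfg)
    ss_qc, _ = apply_study_qc(ss, QCConfig(min_variants=1))
    gs = score_study(ss_qc, genes, geno, GeneScoreConfig(min_genes=1))
    tags = make_tag_sets(gs)
    spec = specificity_scores(panel)
    sets = top_fraction_sets(spec)
    universe = set(gs.ok_pvalues().index) & set(spec.scores.index)
    res = run_tsea(tags, sets, universe)
    return select_top_tissues(res, 1)[0], res
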