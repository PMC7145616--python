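"""LD-aware gene-based association scores from GWAS summary statistics.

Each SNP's two-sided P-value is converted to a 1-df chi-square statistic
q_i = F^{-1}_{chi2_1}(1 - p_i) (the effect sign is ignored). The gene
statistic is the sum T = sum_i q_i. Under the null, with R the SNP-SNP
correlation (LD) matrix estimated from a reference genotype panel, T is
distributed as sum_j lambda_j Z_j^2 where lambda_j are the eigenvalues of R
and Z_j are i.i.d. standard normals. The gene P-value is the upper-tail
probability of that weighted chi-square law at T, computed by Imhof-type
numerical inversion of the characteristic function, with closed forms when
all eigenvalues coincide and a Monte-Carlo fallback when the integration
does not converge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .errors import ContractError
from .io import GeneAnnotation, GenotypeRef, SummaryStats

__all__ = [
    "LDMatrix", "GeneScoreTable", "GeneScoreConfig",
    "map_snps_to_genes", "ld_matrix", "weighted_chi2_sf", "gene_pvalue_sum",
    "score_study",
]

#: eigenvalues below this fraction of the largest are dropped before inversion
EIG_DROP_REL = 1e-8


@dataclass
class LDMatrix:
    """Pairwise Pearson correlations of reference dosages for an ordered SNP list."""

    snp_ids: list[str]
    corr: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.snp_ids)
        if self.corr.shape != (k, k):
            raise ContractError("LD matrix shape does not match SNP list")

    @property
    def dim(self) -> int:
        return len(self.snp_ids)

    def eigenvalues(self, drop_rel: float = EIG_DROP_REL) -> np.ndarray:
        """Eigenvalues clipped to >= 0, with near-zero ones (relative to the
        largest) dropped for numerical stability of the tail inversion."""
        lam = np.linalg.eigvalsh((self.corr + self.corr.T) / 2.0)
        if lam.min() < -1e-8 * max(1.0, abs(lam.max())):
            warnings.warn("LD matrix had sizeable negative eigenvalues; clipped to 0")
        lam = np.clip(lam, 0.0, None)
        return lam[lam > drop_rel * lam.max()] if lam.max() > 0 else lam[:0]


@dataclass
class GeneScoreConfig:
    window: int = 50_000
    min_genes: int = 18_000       # study qualification floor on successful genes
    max_snps: int = 5_000         # guard against pathological gene windows
    mc_draws: int = 1_000_000
    mc_seed: int = 0


@dataclass
class GeneScoreTable:
    """Per-gene aggregated association P-values for one study."""

    study_id: str
    table: "object"               # DataFrame: index gene_id; pvalue, n_snps, status
    min_genes: int = 18_000
    meta: dict = field(default_factory=dict)

    @property
    def n_success(self) -> int:
        return int((self.table["status"] == "ok").sum())

    @property
    def qualified(self) -> bool:
        return self.n_success >= self.min_genes

    def ok_pvalues(self):
        """Series of gene P-values restricted to successfully scored genes."""
        ok = self.table[self.table["status"] == "ok"]
        return ok["pvalue"]


def map_snps_to_genes(ss: SummaryStats, genes: list[GeneAnnotation],
                      window: int = 50_000) -> dict[str, list[str]]:
    """Assign each SNP to every autosomal gene whose body +/- ``window`` bp
    contains it (boundaries inclusive). Genes without SNPs are absent."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    df = ss.records
    for chrom, sub in df.groupby("chrom"):
        order = np.argsort(sub["pos"].to_numpy())
        by_chrom[str(chrom)] = (sub["pos"].to_numpy()[order],
                                sub["snp_id"].to_numpy()[order])
    mapping: dict[str, list[str]] = {}
    for g in genes:
        if not g.is_autosomal or g.chrom not in by_chrom:
            continue
        pos, ids = by_chrom[g.chrom]
        lo = np.searchsorted(pos, g.start - window, side="left")
        hi = np.searchsorted(pos, g.end + window, side="right")
        if hi > lo:
            mapping[g.gene_id] = list(ids[lo:hi])
    return mapping


def ld_matrix(geno: GenotypeRef, snps: list[str]) -> LDMatrix:
    """Pearson correlation of reference dosage vectors for ``snps``.

    Zero-variance SNPs are dropped with a warning and the matrix is built on
    the remainder; an empty remainder is a contract error."""
    missing = [s for s in snps if s not in geno]
    if missing:
        raise ContractError(f"SNPs absent from genotype reference: {missing[:5]}")
    dose = geno.dosage_matrix(snps)
    var = dose.var(axis=1)
    keep = var > 0
    if not keep.all():
        dropped = [s for s, k in zip(snps, keep) if not k]
        warnings.warn(f"dropping zero-variance SNPs from LD matrix: {dropped[:5]}")
        snps = [s for s, k in zip(snps, keep) if k]
        dose = dose[keep]
    if len(snps) == 0:
        raise ContractError("no SNPs with nonzero dosage variance")
    if len(snps) == 1:
        return LDMatrix(snps, np.array([[1.0]]))
    corr = np.corrcoef(dose)
    np.fill_diagonal(corr, 1.0)
    return LDMatrix(snps, corr)


def _make_imhof_callable():
    """Compiled Imhof integrand (numba LowLevelCallable) when available.

    quad passes (n, xx) with xx = [u, x, lam_1, ..., lam_k]."""
    try:
        from numba import cfunc, types
        from numba.types import CPointer, float64, intc
        from scipy import LowLevelCallable
        import math

        @cfunc(float64(intc, CPointer(float64)))
        def integrand(n, xx):
            u = xx[0]
            theta = -0.5 * xx[1] * u
            log_rho = 0.0
            for i in range(2, n):
                lu = xx[i] * u
                theta += 0.5 * math.atan(lu)
                log_rho += 0.25 * math.log1p(lu * lu)
            return math.sin(theta) / (u * math.exp(log_rho))

        return LowLevelCallable(integrand.ctypes)
    except Exception:                                    # pragma: no cover
        return None


_IMHOF_CALLABLE = _make_imhof_callable()


def _imhof_sf(x: float, lam: np.ndarray) -> tuple[float, float]:
    """Upper tail of sum_j lam_j Z_j^2 at x by Imhof's inversion integral.

    The oscillatory integrand is handled by scipy's adaptive infinite-range
    quadrature (QAGI, with extrapolation); the routine's own error estimate
    is returned so callers can fall back to Monte Carlo when it is poor."""

    def py_integrand(u, *_):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * x * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return np.sin(theta) / (u * rho)

    func = _IMHOF_CALLABLE or py_integrand
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(func, 0.0, np.inf, args=(x, *lam),
                                  limit=1000, epsabs=1e-9, epsrel=1e-9)
    return 0.5 + val / np.pi, err / np.pi


def _chernoff_bound(x: float, lam: np.ndarray) -> float:
    """Chernoff upper bound on P(sum lam_j Z_j^2 > x): caps the inversion
    result deep in the tail where quadrature noise dominates."""
    lmax = lam.max()
    if x <= lam.sum():
        return 1.0
    lo, hi = 0.0, 0.5 / lmax
    for _ in range(80):                      # bisection on the saddlepoint
        t = 0.5 * (lo + hi)
        if np.sum(lam / (1.0 - 2.0 * t * lam)) < x:
            lo = t
        else:
            hi = t
    t = lo
    log_mgf = -0.5 * np.sum(np.log1p(-2.0 * t * lam))
    return float(np.exp(min(-t * x + log_mgf, 0.0)))


def _mc_sf(x: float, lam: np.ndarray, draws: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    tail = 0
    chunk = 200_000
    done = 0
    while done < draws:
        m = min(chunk, draws - done)
        q = rng.chisquare(1.0, size=(m, lam.size)) @ lam
        tail += int((q > x).sum())
        done += m
    return (tail + 1) / (draws + 1)


def weighted_chi2_sf(x: float, weights, mc_draws: int = 1_000_000,
                     mc_seed: int = 0) -> float:
    """P(sum_j w_j Z_j^2 > x) for non-negative weights.

    Equal weights reduce to a scaled chi-square closed form; otherwise
    Imhof inversion, falling back to Monte Carlo when the quadrature fails
    to converge."""
    lam = np.asarray(weights, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0 or x <= 0:
        return 1.0
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        return float(stats.chi2.sf(x / lam[0], df=lam.size))
    bound = _chernoff_bound(x, lam)
    if bound < 1e-12:          # quadrature noise would swamp so small a tail
        return bound
    val, err = _imhof_sf(x, lam)
    if not np.isfinite(val) or err > 1e-4 or not (-1e-4 <= val <= 1 + 1e-4):
        val = _mc_sf(x, lam, mc_draws, mc_seed)
    return float(min(max(val, 0.0), bound, 1.0))


def gene_pvalue_sum(snp_pvalues, ld: LDMatrix, mc_draws: int = 1_000_000,
                    mc_seed: int = 0) -> float:
    """Gene-based P-value of the LD-aware sum-of-chi-squares statistic.

    ``snp_pvalues`` must align with ``ld.snp_ids``; each must lie in (0, 1].
    The result is clipped to (1e-300, 1]."""
    p = np.asarray(snp_pvalues, dtype=float)
    if p.size != ld.dim:
        raise ContractError(f"{p.size} P-values for a {ld.dim}-SNP LD matrix")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ContractError("SNP P-values must lie in (0, 1]")
    t_stat = float(stats.chi2.isf(p, df=1).sum())
    tail = weighted_chi2_sf(t_stat, ld.eigenvalues(), mc_draws, mc_seed)
    return float(min(max(tail, 1e-300), 1.0))


def score_study(ss: SummaryStats, genes: list[GeneAnnotation], geno: GenotypeRef,
                cfg: GeneScoreConfig | None = None) -> GeneScoreTable:
    """Score every autosomal gene with mapped SNPs; genes whose SNPs all lack
    LD-reference coverage get status ``failed``. The study qualifies when the
    number of successful genes reaches ``cfg.min_genes``."""
    import pandas as pd

    cfg = cfg or GeneScoreConfig()
    mapping = map_snps_to_genes(ss, genes, cfg.window)
    pmap = dict(zip(ss.records["snp_id"], ss.records["pvalue"]))
    rows = []
    for gene_id, snps in mapping.items():
        covered = [s for s in snps if s in geno]
        if not covered:
            rows.append((gene_id, np.nan, 0, "failed"))
            continue
        if len(covered) > cfg.max_snps:
            var = geno.dosage_matrix(covered).var(axis=1)
            order = np.argsort(var)[::-1][:cfg.max_snps]
            covered = [covered[i] for i in sorted(order)]
            warnings.warn(f"gene {gene_id}: truncated to {cfg.max_snps} top-variance SNPs")
        try:
            ld = ld_matrix(geno, covered)
        except ContractError:
            rows.append((gene_id, np.nan, len(covered), "failed"))
            continue
        pvals = [pmap[s] for s in ld.snp_ids]
        gp = gene_pvalue_sum(pvals, ld, cfg.mc_draws, cfg.mc_seed)
        rows.append((gene_id, gp, ld.dim, "ok"))
    table = pd.DataFrame(rows, columns=["gene_id", "pvalue", "n_snps", "status"]
                         ).set_index("gene_id")
    return GeneScoreTable(ss.study_id, table, min_genes=cfg.min_genes)
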