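"""Trait-associated gene sets and tissue-specific enrichment testing.

A trait-associated gene (TAG) set collects the genes whose gene-based
P-value falls strictly below a threshold; five thresholds (0.05, 0.01,
1e-3, 1e-4, 1e-5) give nested sets, and a set qualifies for testing only
when it holds between 20 and 3000 genes. Each qualified TAG set is tested
against every tissue's top-fraction specific genes with a one-sided
2x2 Pearson chi-square (overrepresentation direction); the top tissues are
then validated by preranked gene-set enrichment (GSEA) with gene-label
permutations and a normalised enrichment score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .genescore import GeneScoreTable
from .specificity import TissueSpecificSets

__all__ = [
    "TAGSetCollection", "TSEAResult", "GSEAResult",
    "DEFAULT_TAG_THRESHOLDS", "TAG_MIN_GENES", "TAG_MAX_GENES",
    "make_tag_sets", "chi2_enrichment", "run_tsea", "gsea_validate",
    "select_top_tissues",
]

DEFAULT_TAG_THRESHOLDS = (0.05, 0.01, 1e-3, 1e-4, 1e-5)
TAG_MIN_GENES = 20
TAG_MAX_GENES = 3000


@dataclass
class TAGSetCollection:
    """Thresholded trait-associated gene sets with qualification flags.

    Sets are nested: a stricter threshold's genes are a subset of any looser
    threshold's. A set qualifies iff 20 <= size <= 3000; a study with zero
    qualified sets is excluded from enrichment."""

    study_id: str
    thresholds: list[float]
    sets: dict[float, dict] = field(default_factory=dict)  # thr -> {genes, qualified}

    @property
    def qualified_thresholds(self) -> list[float]:
        return [t for t in self.thresholds if self.sets[t]["qualified"]]

    @property
    def excluded(self) -> bool:
        return not self.qualified_thresholds


@dataclass
class TSEAResult:
    """Tissue x TAG-threshold matrix of one-sided enrichment P-values."""

    study_id: str
    panel_id: str
    pvalues: pd.DataFrame                       # tissues x thresholds; NaN = unqualified
    counts: dict[tuple[str, float], dict] = field(default_factory=dict)

    @property
    def tissues(self) -> list[str]:
        return list(self.pvalues.index)


@dataclass
class GSEAResult:
    study_id: str
    tissue: str
    es: float
    nes: float
    perm_p: float
    n_perm: int
    threshold: float
    leading_edge: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"study_id": self.study_id, "tissue": self.tissue, "es": self.es,
                "nes": self.nes, "perm_p": self.perm_p, "n_perm": self.n_perm,
                "threshold": self.threshold, "leading_edge": self.leading_edge}


def make_tag_sets(gs: GeneScoreTable,
                  thresholds=DEFAULT_TAG_THRESHOLDS) -> TAGSetCollection:
    """Build TAG sets by strict P < threshold over successfully scored genes."""
    pvals = gs.ok_pvalues()
    thresholds = sorted(thresholds, reverse=True)
    sets = {}
    for thr in thresholds:
        genes = set(pvals.index[pvals < thr])
        sets[thr] = {"genes": genes,
                     "qualified": TAG_MIN_GENES <= len(genes) <= TAG_MAX_GENES}
    return TAGSetCollection(gs.study_id, thresholds, sets)


def chi2_enrichment(tag: set, tissue_set: set, universe: set) -> dict:
    """One-sided 2x2 Pearson chi-square test for overrepresentation of
    ``tag`` genes inside ``tissue_set``, both intersected with ``universe``.

    Returns pvalue, statistic, overlap, expected and the table margins. The
    one-sided P is half the upper chi2_1 tail when the overlap exceeds its
    expectation, 1 minus that half otherwise, and exactly 0.5 at equality.
    """
    if not universe:
        raise ContractError("empty universe")
    tag = set(tag) & set(universe)
    if not tag:
        raise ContractError("TAG set empty after intersection with universe")
    tissue_set = set(tissue_set) & set(universe)
    n = len(universe)
    a = len(tag & tissue_set)
    b = len(tag) - a
    c = len(tissue_set) - a
    d = n - a - b - c
    expected = len(tag) * len(tissue_set) / n
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        x2 = 0.0
    else:
        x2 = n * (a * d - b * c) ** 2 / margins
    half_tail = stats.chi2.sf(x2, df=1) / 2.0
    if a > expected:
        pvalue = half_tail
    elif a < expected:
        pvalue = 1.0 - half_tail
    else:
        pvalue = 0.5
    return {"pvalue": float(min(max(pvalue, 1e-300), 1.0)), "statistic": float(x2),
            "overlap": a, "expected": float(expected), "tag_size": len(tag),
            "tissue_set_size": len(tissue_set), "universe_size": n}


def run_tsea(tags: TAGSetCollection, sets: TissueSpecificSets,
             universe: set) -> TSEAResult:
    """Chi-square enrichment of every qualified TAG set in every tissue's
    specific genes, against a shared gene universe."""
    tissues = sets.tissues
    pmat = pd.DataFrame(np.nan, index=tissues,
                        columns=[float(t) for t in tags.thresholds])
    counts: dict[tuple[str, float], dict] = {}
    for thr in tags.qualified_thresholds:
        tag = tags.sets[thr]["genes"]
        for tissue in tissues:
            res = chi2_enrichment(tag, sets.sets[tissue], universe)
            pmat.loc[tissue, float(thr)] = res["pvalue"]
            counts[(tissue, float(thr))] = res
    return TSEAResult(tags.study_id, sets.panel_id, pmat, counts)


def _running_extremum(hit_w: np.ndarray, hit_pos: np.ndarray, total_w: float,
                      n: int, n_miss: int) -> tuple[float, int]:
    """Extremum of the GSEA running sum from hit weights and 0-based hit ranks.

    The running sum only attains candidate extrema immediately after a hit
    (local maxima) or immediately before one (local minima)."""
    inc = np.cumsum(hit_w) / total_w
    miss_step = 1.0 / n_miss if n_miss > 0 else 0.0
    # value just after the j-th hit and just before it
    after = inc - (hit_pos + 1 - np.arange(1, hit_pos.size + 1)) * miss_step
    before = after - hit_w / total_w
    hi, lo = after.max(), before.min()
    # the trailing tail returns to 0; no extra candidates
    if hi >= -lo:
        return float(hi), int(hit_pos[int(after.argmax())])
    return float(lo), int(hit_pos[int(before.argmin())])


def gsea_validate(spec_column: pd.Series, tag: set, n_perm: int = 10_000,
                  seed: int = 0, study_id: str = "", tissue: str = "",
                  threshold: float = float("nan")) -> GSEAResult:
    """Preranked GSEA of ``tag`` against genes ranked by decreasing score.

    The enrichment score is the classic weighted running-sum extremum
    (weight exponent 1 on |score|); the null re-draws |tag| gene labels
    uniformly without replacement ``n_perm`` times. NES divides ES by the
    mean same-sign permutation ES, and the permutation P adds one to both
    numerator and denominator."""
    col = spec_column.sort_values(ascending=False, kind="mergesort")
    # deterministic tie order by gene id within equal scores
    col = col.iloc[np.lexsort((col.index.to_numpy(), -col.to_numpy()))]
    genes = col.index.to_numpy()
    w = np.abs(col.to_numpy(dtype=float))
    n = genes.size
    tag = set(tag)
    if len(tag) > n:
        raise ContractError("TAG set larger than the ranked gene list")
    hit = np.isin(genes, list(tag))
    m = int(hit.sum())
    if m == 0:
        raise ContractError("TAG set does not intersect the ranked gene list")
    n_miss = n - m

    def es_at(pos: np.ndarray) -> tuple[float, int]:
        hw = w[pos]
        tw = hw.sum()
        if tw == 0:
            hw = np.ones_like(hw)
            tw = float(m)
        return _running_extremum(hw, pos, tw, n, n_miss)

    obs_pos = np.flatnonzero(hit)
    es, ext_pos = es_at(obs_pos)

    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=m, replace=False))
        perm_es[i], _ = es_at(pos)

    same = perm_es > 0 if es > 0 else perm_es < 0
    if same.any():
        nes = es / abs(perm_es[same].mean())
    else:
        nes = es / max(np.abs(perm_es).mean(), 1e-12)
    perm_p = (1 + int((same & (np.abs(perm_es) >= abs(es))).sum())) / (n_perm + 1)

    if es >= 0:
        lead = [g for g in genes[: ext_pos + 1] if g in tag]
    else:
        lead = [g for g in genes[ext_pos:] if g in tag]
    return GSEAResult(study_id=study_id, tissue=tissue, es=float(es),
                      nes=float(nes), perm_p=float(perm_p), n_perm=n_perm,
                      threshold=threshold, leading_edge=lead)


def select_top_tissues(res: TSEAResult, k: int = 3) -> list[str]:
    """Tissues ranked by their minimum enrichment P across qualified
    thresholds; ties break by larger overlap at the best cell, then name."""
    if res.pvalues.empty or res.pvalues.isna().all().all():
        raise ContractError("TSEA result holds no qualified enrichment P-values")
    ranking = []
    for tissue in res.pvalues.index:
        row = res.pvalues.loc[tissue].dropna()
        best_thr = float(row.idxmin())
        best_p = float(row.min())
        overlap = res.counts[(tissue, best_thr)]["overlap"]
        ranking.append((best_p, -overlap, str(tissue)))
    ranking.sort()
    return [t for _, _, t in ranking[:k]]
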