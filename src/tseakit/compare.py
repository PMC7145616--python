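"""Study-level comparisons: duplicate detection, cross-study enrichment
tables, and tissue-centric trait-overlap statistics.

Duplicated GWAS data sets (the same cohort deposited twice) are flagged by
the Pearson correlation of their gene-based P-values: a pair with
PCC > 0.99 is a duplicate, while merely similar studies (e.g. PCC 0.98)
are retained as distinct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .enrich import TSEAResult
from .genescore import GeneScoreTable

__all__ = [
    "StudySimilarity", "OverlapStat",
    "pairwise_pcc", "tissue_trait_overlap", "comparison_matrix",
]

PCC_DUPLICATE_THRESHOLD = 0.99
MIN_COMMON_GENES = 100


@dataclass
class StudySimilarity:
    pairs: list[dict] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


@dataclass
class OverlapStat:
    tissue_pair: tuple[str, str]
    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    fisher_p: float

    @property
    def pct_of_a(self) -> float:
        return round(100.0 * self.n_overlap / self.n_a, 1)

    @property
    def pct_of_b(self) -> float:
        return round(100.0 * self.n_overlap / self.n_b, 1)


def pairwise_pcc(tables: list[GeneScoreTable],
                 threshold: float = PCC_DUPLICATE_THRESHOLD,
                 log10: bool = False,
                 rng: np.random.Generator | None = None) -> StudySimilarity:
    """Pairwise Pearson correlation of gene-based P-values over each pair's
    common successfully-scored genes.

    Pairs with fewer than 100 common genes are skipped with a warning.
    Within each connected group of duplicate pairs one study is retained:
    the first by study_id, or a seeded random choice when ``rng`` is given.
    Set ``log10`` to correlate -log10 P instead of raw P."""
    if len(tables) < 2:
        raise ContractError("pairwise_pcc needs at least two score tables")
    pv = {t.study_id: t.ok_pvalues() for t in tables}
    sim = StudySimilarity()
    dup_edges = []
    for a, b in combinations(sorted(pv), 2):
        common = pv[a].index.intersection(pv[b].index)
        if len(common) < MIN_COMMON_GENES:
            warnings.warn(f"pair ({a}, {b}): only {len(common)} common genes; skipped")
            continue
        xa, xb = pv[a].loc[common].to_numpy(), pv[b].loc[common].to_numpy()
        if log10:
            xa, xb = -np.log10(xa), -np.log10(xb)
        pcc = float(np.corrcoef(xa, xb)[0, 1])
        dup = pcc > threshold
        sim.pairs.append({"study_a": a, "study_b": b, "pcc": pcc,
                          "n_common_genes": int(len(common)), "duplicate": dup})
        if dup:
            dup_edges.append((a, b))

    # connected components over duplicate edges; keep one study per group
    parent = {s: s for s in pv}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in dup_edges:
        parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for s in pv:
        groups.setdefault(find(s), []).append(s)
    for members in groups.values():
        members = sorted(members)
        keep = members[0] if rng is None else members[int(rng.integers(len(members)))]
        sim.retained.append(keep)
        sim.dropped.extend(m for m in members if m != keep)
    sim.retained.sort()
    sim.dropped.sort()
    return sim


def tissue_trait_overlap(assoc_a: set, assoc_b: set, universe_n: int,
                         tissue_pair: tuple[str, str] = ("A", "B")) -> OverlapStat:
    """Overlap of the study sets associated with two tissues, with one-sided
    Fisher exact P for more sharing than expected by chance."""
    assoc_a, assoc_b = set(assoc_a), set(assoc_b)
    union = assoc_a | assoc_b
    if universe_n < len(union):
        raise ContractError(
            f"universe_n={universe_n} smaller than the union of the sets ({len(union)})")
    n_ov = len(assoc_a & assoc_b)
    table = [[n_ov, len(assoc_a) - n_ov],
             [len(assoc_b) - n_ov, universe_n - len(union)]]
    _, fisher_p = stats.fisher_exact(table, alternative="greater")
    return OverlapStat(tissue_pair=tissue_pair, n_a=len(assoc_a), n_b=len(assoc_b),
                       n_overlap=n_ov, n_universe=universe_n, fisher_p=float(fisher_p))


def comparison_matrix(results: list[TSEAResult], max_studies: int = 10) -> pd.DataFrame:
    """Long-format (study, tissue, threshold, neglog10_p) table across studies
    from the same panel; unqualified cells stay missing, never imputed."""
    if len(results) > max_studies:
        raise ContractError(
            f"{len(results)} studies exceed the comparison cap of {max_studies}")
    panels = {r.panel_id for r in results}
    if len(panels) > 1:
        raise ContractError(f"results mix panels: {sorted(panels)}")
    rows = []
    for r in results:
        for tissue in r.pvalues.index:
            for thr in r.pvalues.columns:
                p = r.pvalues.loc[tissue, thr]
                rows.append({"study": r.study_id, "tissue": tissue,
                             "threshold": float(thr),
                             "neglog10_p": -np.log10(p) if np.isfinite(p) else np.nan})
    return pd.DataFrame(rows, columns=["study", "tissue", "threshold", "neglog10_p"])
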