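"""Tissue-specificity scoring of expression panels and top-fraction gene sets.

Two scores, chosen by panel size:

* **t-score** (large panels, >= ~30 samples per tissue): for each gene and
  tissue, regress log2(x+1) expression on a one-vs-rest tissue indicator
  plus optional covariates; the score is the indicator's t-statistic.
* **z-score** (small panels): per gene, standardise the tissue means of
  log-expression across tissues (population sd).

The top ``fraction`` (default 5%) of genes per tissue, ranked by score,
define that tissue's tissue-specific gene set; cutoff ties break by
lexicographic gene ID so sets are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError
from .io import ExpressionPanel

__all__ = [
    "SpecificityMatrix", "TissueSpecificSets",
    "tissue_t_scores", "tissue_z_scores", "specificity_scores",
    "top_fraction_sets",
]

#: per-tissue sample-size floor above which t-scores are the default
T_SCORE_MIN_SAMPLES = 30


@dataclass
class SpecificityMatrix:
    """Gene x tissue specificity scores (kind ``t`` or ``z``)."""

    panel_id: str
    score_kind: str
    scores: pd.DataFrame          # genes x tissues, no missing values
    n_samples: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.score_kind not in {"t", "z"}:
            raise ConfigurationError(f"score_kind must be 't' or 'z', got {self.score_kind!r}")
        if self.scores.isna().any().any():
            raise ContractError("specificity matrix contains missing values")
        if self.scores.columns.duplicated().any():
            raise ContractError("duplicate tissue names in specificity matrix")


@dataclass
class TissueSpecificSets:
    """Top-fraction tissue-specific gene sets derived from a SpecificityMatrix."""

    panel_id: str
    fraction: float
    sets: dict[str, set] = field(default_factory=dict)

    @property
    def tissues(self) -> list[str]:
        return sorted(self.sets)


def _log2p1(panel: ExpressionPanel) -> np.ndarray:
    return np.log2(panel.expr.to_numpy(dtype=float) + 1.0)


def tissue_t_scores(panel: ExpressionPanel,
                    covariate_names: list[str] | None = None) -> SpecificityMatrix:
    """One-vs-rest regression t-statistics of log2(x+1) expression.

    For tissue T the design is [intercept, 1{sample in T}, covariates]; the
    score of gene g in T is beta_indicator / se(beta_indicator). Genes with
    zero residual variance (flat expression) score 0.
    """
    covariate_names = covariate_names or []
    counts = panel.n_samples_per_tissue
    too_small = [t for t, c in counts.items() if c < 2]
    if too_small:
        raise ConfigurationError(f"t-scores need >= 2 samples per tissue; too few in {too_small}")
    if covariate_names:
        if panel.covariates is None:
            raise ConfigurationError("panel has no covariates")
        absent = [c for c in covariate_names if c not in panel.covariates.columns]
        if absent:
            raise ConfigurationError(f"covariates absent from panel: {absent}")
        cov = panel.covariates[covariate_names].to_numpy(dtype=float)
    else:
        cov = np.empty((len(panel.expr.columns), 0))

    y = _log2p1(panel)                       # genes x samples
    n = y.shape[1]
    tissues = panel.tissues
    out = np.zeros((y.shape[0], len(tissues)))
    for j, tissue in enumerate(tissues):
        ind = (panel.sample_tissue.to_numpy() == tissue).astype(float)
        x = np.column_stack([np.ones(n), ind, cov])
        p = x.shape[1]
        if n - p <= 0:
            raise ConfigurationError("not enough samples for the covariate design")
        xtx_inv = np.linalg.pinv(x.T @ x)
        beta = y @ x @ xtx_inv.T             # genes x p
        resid = y - beta @ x.T
        sigma2 = (resid ** 2).sum(axis=1) / (n - p)
        # genes fitted exactly (e.g. flat expression) have only rounding
        # noise left; their coefficient and t are 0 by definition
        exact = sigma2 <= 1e-20 * (1.0 + (y ** 2).mean(axis=1))
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(~exact & (se > 0), beta[:, 1] / np.where(se > 0, se, 1.0), 0.0)
        out[:, j] = t
    scores = pd.DataFrame(out, index=panel.expr.index, columns=tissues)
    return SpecificityMatrix(panel.panel_id, "t", scores, counts)


def tissue_z_scores(panel: ExpressionPanel) -> SpecificityMatrix:
    """Across-tissue z-scores of per-tissue mean log2(x+1) expression.

    z_gT = (m_gT - mean_T' m_gT') / sd_T' m_gT' with population sd; a gene
    with equal tissue means scores 0 everywhere."""
    tissues = panel.tissues
    if len(tissues) < 2:
        raise ConfigurationError("z-scores need at least two tissues")
    y = _log2p1(panel)
    labels = panel.sample_tissue.to_numpy()
    means = np.column_stack([y[:, labels == t].mean(axis=1) for t in tissues])
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (means - mu) / sd, 0.0)
    scores = pd.DataFrame(z, index=panel.expr.index, columns=tissues)
    return SpecificityMatrix(panel.panel_id, "z", scores, panel.n_samples_per_tissue)


def specificity_scores(panel: ExpressionPanel, kind: str = "auto",
                       covariate_names: list[str] | None = None) -> SpecificityMatrix:
    """Score a panel, choosing t vs z by per-tissue sample size when ``auto``."""
    if kind == "auto":
        kind = "t" if min(panel.n_samples_per_tissue.values()) >= T_SCORE_MIN_SAMPLES else "z"
    if kind == "t":
        return tissue_t_scores(panel, covariate_names)
    if kind == "z":
        return tissue_z_scores(panel)
    raise ConfigurationError(f"unknown score kind {kind!r}")


def top_fraction_sets(spec: SpecificityMatrix, fraction: float = 0.05) -> TissueSpecificSets:
    """Per tissue, the floor(fraction * G) highest-scoring genes.

    Ties at the cutoff break by lexicographic gene ID."""
    if not 0.0 < fraction <= 0.5:
        raise ContractError(f"fraction must lie in (0, 0.5], got {fraction}")
    n_top = int(np.floor(fraction * len(spec.scores)))
    if n_top < 1:
        raise ContractError(
            f"fraction {fraction} yields an empty set for {len(spec.scores)} genes")
    sets = {}
    for tissue in spec.scores.columns:
        col = spec.scores[tissue]
        order = sorted(col.index, key=lambda g: (-col[g], g))
        sets[str(tissue)] = set(order[:n_top])
    return TissueSpecificSets(spec.panel_id, fraction, sets)
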