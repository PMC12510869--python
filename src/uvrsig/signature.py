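"""Tumor-specific UV-response signature derivation from single-cell data.

The derivation runs per dataset and combines across datasets:

1. *Correlation screen (Gx)* — genes whose expression across malignant
   cells is positively Spearman-correlated with a per-cell enrichment
   score of the seed UV-response gene set (r > 0.3, p < 0.05; strict
   inequalities).
2. *Malignant DEGs (Gy)* — genes upregulated in malignant versus
   non-malignant cells by Wilcoxon rank-sum with BH correction
   (log2 fold change >= 0.30 and q < 1e-5 by default).
3. *Per-dataset signature (Gn)* — the intersection Gx ∩ Gy.
4. *Combined signature* — the deduplicated union of the Gn sets over all
   datasets, with per-gene provenance (which datasets supported it).

Fold changes are computed in log2 on linear-scale expression with a
1e-9 pseudocount.  The default restricts to genes *up* in malignant
cells; an absolute-fold-change mode is available for sensitivity
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    ExpressionMatrix,
    GeneSet,
    bh_adjust,
    spearman_matrix,
)

__all__ = [
    "DatasetDerivation",
    "correlated_genes",
    "malignant_degs",
    "dataset_signature",
    "combine_signatures",
    "derive_dataset",
]

R_MIN_DEFAULT = 0.3
P_MAX_DEFAULT = 0.05
LOGFC_MIN_DEFAULT = 0.30
Q_MAX_DEFAULT = 1e-5


@dataclass
class DatasetDerivation:
    """All intermediate products of one dataset's signature derivation."""

    dataset_id: str
    gx: pd.DataFrame  # index gene, columns r, p (selected genes only)
    gy: pd.DataFrame  # index gene, columns logfc, p, q (selected genes only)
    gn: frozenset[str]
    thresholds: dict

    def __post_init__(self) -> None:
        assert self.gn == frozenset(self.gx.index) & frozenset(self.gy.index)


def correlated_genes(
    matrix: ExpressionMatrix,
    activity: pd.Series,
    r_min: float = R_MIN_DEFAULT,
    p_max: float = P_MAX_DEFAULT,
) -> pd.DataFrame:
    """Genes positively correlated with the per-cell activity score.

    ``activity`` must be indexed by exactly the matrix sample (cell)
    ids.  Selection is strict: ``r > r_min`` and ``p < p_max``.  Returns
    a DataFrame (index gene, columns ``r``, ``p``) of selected genes.
    """
    if set(activity.index) != set(matrix.sample_ids):
        bad = sorted(set(activity.index) ^ set(matrix.sample_ids))
        raise ValueError(f"activity ids misaligned with matrix: {bad[:5]}")
    if matrix.n_samples < 10:
        raise ValueError("need at least 10 cells for the correlation screen")
    act = activity.loc[matrix.sample_ids].to_numpy(dtype=float)
    r, p = spearman_matrix(matrix.values, act)
    sel = (r > r_min) & (p < p_max)
    return pd.DataFrame(
        {"r": r[sel], "p": p[sel]},
        index=pd.Index(np.array(matrix.gene_ids)[sel], name="gene"),
    ).sort_index()


def malignant_degs(
    matrix: ExpressionMatrix,
    malignant: pd.Series,
    logfc_min: float = LOGFC_MIN_DEFAULT,
    q_max: float = Q_MAX_DEFAULT,
    absolute: bool = False,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Genes upregulated in malignant cells vs the rest.

    Per gene: two-sided Wilcoxon rank-sum malignant vs rest, BH q over
    all tested genes, and ``logfc = log2((mean_mal + eps)/(mean_rest + eps))``
    on linear-scale expression.  Selection: ``logfc >= logfc_min``
    (or ``|logfc| >= logfc_min`` with ``absolute=True``) and ``q < q_max``.
    """
    flags = malignant.loc[matrix.sample_ids].to_numpy()
    mal_cols = np.asarray(flags, dtype=bool)
    if mal_cols.sum() < 3 or (~mal_cols).sum() < 3:
        raise ValueError("need at least 3 cells per group")
    lin = matrix.linear_values()
    # negative linear means can only arise from already-centred input;
    # clamp at zero so the fold change stays defined
    mean_mal = np.clip(lin[:, mal_cols].mean(axis=1), 0.0, None)
    mean_rest = np.clip(lin[:, ~mal_cols].mean(axis=1), 0.0, None)
    logfc = np.log2((mean_mal + eps) / (mean_rest + eps))
    res = sps.mannwhitneyu(
        matrix.values[:, mal_cols],
        matrix.values[:, ~mal_cols],
        axis=1,
        alternative="two-sided",
        method="asymptotic",
        use_continuity=True,
    )
    q = bh_adjust(res.pvalue)
    passed = np.abs(logfc) >= logfc_min if absolute else logfc >= logfc_min
    sel = passed & (q < q_max)
    return pd.DataFrame(
        {"logfc": logfc[sel], "p": res.pvalue[sel], "q": q[sel]},
        index=pd.Index(np.array(matrix.gene_ids)[sel], name="gene"),
    ).sort_index()


def dataset_signature(gx: pd.DataFrame, gy: pd.DataFrame) -> frozenset[str]:
    """Gn = Gx ∩ Gy; an empty intersection is a valid outcome."""
    return frozenset(gx.index) & frozenset(gy.index)


def derive_dataset(
    matrix: ExpressionMatrix,
    malignant: pd.Series,
    activity: pd.Series,
    dataset_id: str = "dataset",
    r_min: float = R_MIN_DEFAULT,
    p_max: float = P_MAX_DEFAULT,
    logfc_min: float = LOGFC_MIN_DEFAULT,
    q_max: float = Q_MAX_DEFAULT,
    correlate_all_cells: bool = False,
) -> DatasetDerivation:
    """Run the full per-dataset derivation (Gx, Gy, Gn).

    The correlation screen runs on malignant cells only unless
    ``correlate_all_cells`` is set.
    """
    mal_ids = [s for s, f in zip(matrix.sample_ids, malignant.loc[matrix.sample_ids])
               if bool(f)]
    if correlate_all_cells:
        corr_matrix, corr_activity = matrix, activity
    else:
        corr_matrix = matrix.subset_samples(mal_ids)
        corr_activity = activity.loc[mal_ids]
    gx = correlated_genes(corr_matrix, corr_activity, r_min, p_max)
    gy = malignant_degs(matrix, malignant, logfc_min, q_max)
    return DatasetDerivation(
        dataset_id=dataset_id,
        gx=gx,
        gy=gy,
        gn=dataset_signature(gx, gy),
        thresholds={
            "r_min": r_min, "p_max": p_max,
            "logfc_min": logfc_min, "q_max": q_max,
        },
    )


def combine_signatures(per_dataset: dict[str, frozenset[str]] | list):
    """Union of per-dataset signatures with per-gene provenance.

    Accepts ``{dataset_id: genes}`` or a list of gene sets (auto-named).
    Returns ``(GeneSet, provenance)`` where provenance is a DataFrame
    indexed by gene (alphabetical) with columns ``n_datasets`` and
    ``datasets`` (comma-joined ids).
    """
    if isinstance(per_dataset, list):
        per_dataset = {f"dataset{i}": frozenset(s) for i, s in enumerate(per_dataset)}
    if not per_dataset:
        raise ValueError("no per-dataset signatures to combine")
    support: dict[str, list[str]] = {}
    for ds, genes in per_dataset.items():
        for g in genes:
            support.setdefault(g, []).append(ds)
    genes = sorted(support)
    if not genes:
        raise ValueError("all per-dataset signatures are empty")
    prov = pd.DataFrame(
        {
            "n_datasets": [len(support[g]) for g in genes],
            "datasets": [",".join(sorted(support[g])) for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return GeneSet("combined_signature", frozenset(genes)), prov
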