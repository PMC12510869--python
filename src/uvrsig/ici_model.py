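"""Nearest-centroid modelling of immune-checkpoint-inhibitor response.

Cohorts of expression profiles with binary response labels (R =
complete/partial response, NR = stable/progressive disease) are merged
on their common gene universe, batch-corrected with parametric
empirical-Bayes ComBat, and split 80/20 into training and validation.

The reference classifier is a nearest-centroid model in the spirit of
the cancerclass family: per-class gene-wise mean centroids on the
signature genes, with a continuous score

    score(x) = d(x, centroid_R) - d(x, centroid_NR)

under Pearson-correlation distance (``1 - r``) or Euclidean distance.
Higher scores predict non-response — the orientation used throughout the
package, matching the negative association between the UV-response
program and ICI efficacy.  AUC is the Mann–Whitney probability that an
NR sample scores above an R sample, ties counted one half.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .core import ExpressionMatrix, GeneSet, SignatureCollection

logger = logging.getLogger("uvrsig")

__all__ = [
    "ResponseCohort",
    "CentroidModel",
    "merge_cohorts",
    "combat_adjust",
    "split_cohort",
    "fit_centroid_model",
    "predict_scores",
    "roc_auc",
    "cross_validate",
    "benchmark_signatures",
]


@dataclass
class ResponseCohort:
    """Expression matrix plus per-sample response / batch / cohort labels."""

    matrix: ExpressionMatrix
    response: list[str]  # "R" / "NR"
    batch: list[str] = field(default_factory=list)
    cohort: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.matrix.n_samples
        if len(self.response) != n:
            raise ValueError("response length must match sample count")
        bad = set(self.response) - {"R", "NR"}
        if bad:
            raise ValueError(f"response labels must be R/NR, got {sorted(bad)}")
        if not self.batch:
            self.batch = ["batch0"] * n
        if not self.cohort:
            self.cohort = ["cohort0"] * n
        if len(self.batch) != n or len(self.cohort) != n:
            raise ValueError("batch/cohort length must match sample count")

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples

    def labels(self) -> np.ndarray:
        """1 for NR (positive class of the score orientation), 0 for R."""
        return np.array([1 if r == "NR" else 0 for r in self.response])

    def subset(self, idx) -> "ResponseCohort":
        samples = [self.matrix.sample_ids[i] for i in idx]
        return ResponseCohort(
            self.matrix.subset_samples(samples),
            [self.response[i] for i in idx],
            [self.batch[i] for i in idx],
            [self.cohort[i] for i in idx],
        )


@dataclass
class CentroidModel:
    signature: GeneSet
    genes: list[str]  # signature genes present in the training universe
    centroid_r: np.ndarray
    centroid_nr: np.ndarray
    distance: str = "pearson"

    def __post_init__(self) -> None:
        if self.distance not in ("pearson", "euclidean"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if not (len(self.genes) == self.centroid_r.size == self.centroid_nr.size):
            raise ValueError("centroids must align with the gene list")


def merge_cohorts(cohorts: list[ResponseCohort]) -> ResponseCohort:
    """Concatenate cohorts on the intersection of their gene universes.

    The per-sample cohort label is carried over as the batch label of
    the merged cohort, ready for batch correction.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    common = [g for g in cohorts[0].matrix.gene_ids
              if all(g in set(c.matrix.gene_ids) for c in cohorts[1:])]
    if not common:
        raise ValueError("empty gene intersection across cohorts")
    mats = [c.matrix.subset_genes(common) for c in cohorts]
    values = np.concatenate([m.values for m in mats], axis=1)
    samples = [s for m in mats for s in m.sample_ids]
    matrix = ExpressionMatrix(common, samples, values, cohorts[0].matrix.scale)
    return ResponseCohort(
        matrix,
        [r for c in cohorts for r in c.response],
        [b for c in cohorts for b in c.cohort],  # cohort becomes batch
        [b for c in cohorts for b in c.cohort],
    )


def combat_adjust(
    matrix: ExpressionMatrix, batch: list[str], allow_singleton: bool = False
) -> ExpressionMatrix:
    """Parametric empirical-Bayes (ComBat) batch correction.

    Gene-wise standardization, per-batch additive and multiplicative
    effect estimation with EB shrinkage, back-transformation.  With a
    single batch the input is returned unchanged.  After adjustment each
    gene is re-centred to its original grand mean, so correction never
    moves the overall expression level.
    """
    counts = pd.Series(batch).value_counts()
    if len(counts) == 1:
        return matrix
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        if not allow_singleton:
            raise ValueError(f"batches with a single sample: {small}")
        logger.warning("singleton batches passed through uncorrected: %s", small)
        return matrix

    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(
        X=matrix.values.T.copy(),
        obs=pd.DataFrame({"batch": pd.Categorical(batch)},
                         index=matrix.sample_ids),
        var=pd.DataFrame(index=matrix.gene_ids),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.combat(adata, key="batch")
    corrected = np.asarray(adata.X).T
    # re-centring contract: per-gene grand means preserved exactly
    corrected += (matrix.values.mean(axis=1) - corrected.mean(axis=1))[:, None]
    return ExpressionMatrix(
        matrix.gene_ids, matrix.sample_ids, corrected, matrix.scale
    )


def split_cohort(
    cohort: ResponseCohort, train_frac: float = 0.8, seed: int = 0
) -> tuple[ResponseCohort, ResponseCohort]:
    """Random train/validation split; train size rounds half away from zero.

    Redraws (up to 100 times) if the training partition would lose a
    response class entirely.
    """
    n = cohort.n_samples
    n_train = int(np.floor(train_frac * n + 0.5))
    if not (0 < n_train < n):
        raise ValueError("train fraction leaves an empty partition")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        val_idx = np.sort(perm[n_train:])
        train_classes = {cohort.response[i] for i in train_idx}
        if train_classes == {"R", "NR"}:
            return cohort.subset(train_idx), cohort.subset(val_idx)
    raise ValueError("could not draw a training set containing both classes")


def fit_centroid_model(
    train: ResponseCohort, signature: GeneSet, distance: str = "pearson"
) -> CentroidModel:
    """Per-class gene-wise mean centroids on the signature genes."""
    y = train.labels()
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise ValueError("need at least 3 samples per class")
    genes = [g for g in train.matrix.gene_ids if g in signature.genes]
    if len(genes) < 2:
        raise ValueError("fewer than 2 signature genes in the training universe")
    sub = train.matrix.subset_genes(genes)
    centroid_r = sub.values[:, y == 0].mean(axis=1)
    centroid_nr = sub.values[:, y == 1].mean(axis=1)
    return CentroidModel(signature, genes, centroid_r, centroid_nr, distance)


def _distances(model: CentroidModel, values: np.ndarray) -> np.ndarray:
    """Per-sample d(x, centroid_R) - d(x, centroid_NR)."""
    if model.distance == "euclidean":
        d_r = np.linalg.norm(values - model.centroid_r[:, None], axis=0)
        d_nr = np.linalg.norm(values - model.centroid_nr[:, None], axis=0)
        return d_r - d_nr
    # pearson distance 1 - r; constant samples fall back to euclidean
    out = np.empty(values.shape[1])
    sd = values.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance sample(s): euclidean fallback", int(degenerate.sum())
        )
    for j in range(values.shape[1]):
        x = values[:, j]
        if degenerate[j]:
            out[j] = np.linalg.norm(x - model.centroid_r) - np.linalg.norm(
                x - model.centroid_nr
            )
        else:
            r_r = np.corrcoef(x, model.centroid_r)[0, 1]
            r_nr = np.corrcoef(x, model.centroid_nr)[0, 1]
            out[j] = (1 - r_r) - (1 - r_nr)
    return out


def predict_scores(model: CentroidModel, samples: ExpressionMatrix) -> pd.Series:
    """Continuous response score per sample; higher predicts NR."""
    missing = [g for g in model.genes if g not in set(samples.gene_ids)]
    if missing:
        raise ValueError(f"model genes missing from matrix: {missing[:5]}")
    sub = samples.subset_genes(model.genes)
    # subset_genes preserves matrix order; realign to model gene order
    order = [sub.gene_ids.index(g) for g in model.genes]
    scores = _distances(model, sub.values[order, :])
    return pd.Series(scores, index=samples.sample_ids, name="score")


def roc_auc(scores, labels) -> float:
    """AUC of scores for the positive (NR = 1) class; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def cross_validate(
    cohort: ResponseCohort,
    signature: GeneSet,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    distance: str = "pearson",
) -> tuple[float, float]:
    """Repeated stratified k-fold AUC of the centroid model.

    Returns (mean, SD) over all repeats × folds.  If the minority class
    has fewer members than k, k is reduced with a warning.
    """
    y = cohort.labels()
    min_class = min((y == 1).sum(), (y == 0).sum())
    if min_class < k:
        logger.warning("reducing k from %d to %d (minority class size)", k, min_class)
        k = int(min_class)
    if k < 2:
        raise ValueError("not enough samples per class for cross-validation")
    aucs = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for train_idx, test_idx in skf.split(np.zeros(cohort.n_samples), y):
            model = fit_centroid_model(cohort.subset(train_idx), signature, distance)
            test = cohort.subset(test_idx)
            scores = predict_scores(model, test.matrix)
            aucs.append(roc_auc(scores.to_numpy(), test.labels()))
    return float(np.mean(aucs)), float(np.std(aucs))


def benchmark_signatures(
    cohorts: dict[str, ResponseCohort],
    signatures: SignatureCollection,
    train_cohort: str,
    distance: str = "pearson",
) -> pd.DataFrame:
    """AUC heat-table: one row per signature, one column per cohort.

    Each signature's centroid model is refit on the training cohort and
    evaluated on every cohort; a ``mean_auc`` column (over evaluation
    cohorts) is appended.  Signatures with < 2 genes in a cohort's
    universe get NaN for that cell.
    """
    if train_cohort not in cohorts:
        raise ValueError(f"unknown training cohort {train_cohort!r}")
    rows = {}
    for gs in signatures:
        row = {}
        try:
            model = fit_centroid_model(cohorts[train_cohort], gs, distance)
        except ValueError:
            rows[gs.name] = {name: np.nan for name in cohorts}
            continue
        for name, cohort in cohorts.items():
            try:
                scores = predict_scores(model, cohort.matrix)
                row[name] = roc_auc(scores.to_numpy(), cohort.labels())
            except ValueError:
                row[name] = np.nan
        rows[gs.name] = row
    report = pd.DataFrame(rows).T
    report["mean_auc"] = report.mean(axis=1)
    return report
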