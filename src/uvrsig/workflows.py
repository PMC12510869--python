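"""End-to-end workflow helpers tying the pipeline stages together.

Each function runs one complete experiment on synthetic data with
planted ground truth and returns the recovery metrics: these are the
package's own self-checks (signature recovery, response-model AUC,
CRISPR ranking recovery, Cox coverage, subtype recovery, deconvolution
error), and they back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import synthdata
from .core import ExpressionMatrix, GeneSet, SignatureCollection
from .crispr import ScreenTable, average_and_rank, signature_top_coverage, zscore_normalize
from .enrichment import ssgsea_score
from .ici_model import fit_centroid_model, predict_scores, roc_auc, split_cohort
from .prognosis import SurvivalTable, fit_cox
from .signature import derive_dataset
from .subtyping import consensus_cluster, svr_deconvolve

__all__ = [
    "signature_recovery",
    "ici_auc_experiment",
    "crispr_recovery",
    "cox_coverage",
    "subtype_recovery",
    "deconvolution_error",
]


def signature_recovery(seed: int, **scrna_kwargs) -> dict:
    """Derive a signature from one simulated single-cell dataset.

    Runs enrichment scoring of the planted program set, the correlation
    screen, the malignant DEG test and their intersection, then scores
    the result against the planted signature.  Returns precision,
    recall and F1.
    """
    matrix, truth = synthdata.make_scrna(seed=seed, **scrna_kwargs)
    mal = pd.Series(
        [c == "malignant" for c in truth.cell_labels], index=matrix.sample_ids
    )
    coll = SignatureCollection()
    coll.add(truth.program_genes)
    activity = ssgsea_score(matrix, coll).frame.iloc[0]
    derivation = derive_dataset(matrix, mal, activity, dataset_id=f"seed{seed}")
    tp = len(derivation.gn & truth.planted_signature)
    precision = tp / len(derivation.gn) if derivation.gn else 0.0
    recall = tp / len(truth.planted_signature)
    f1 = (
        2 * tp / (len(derivation.gn) + len(truth.planted_signature))
        if derivation.gn or truth.planted_signature
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_derived": len(derivation.gn)}


def ici_auc_experiment(
    seed: int,
    effect_size: float,
    n_samples: int = 100,
    n_genes: int = 500,
    distance: str = "pearson",
) -> float:
    """Train/validate the centroid model on one simulated cohort; return AUC."""
    cohort, truth = synthdata.make_ici_cohort(
        n_samples=n_samples, n_genes=n_genes, effect_size=effect_size, seed=seed
    )
    train, val = split_cohort(cohort, 0.8, seed=seed)
    model = fit_centroid_model(train, truth.effect_genes, distance)
    scores = predict_scores(model, val.matrix)
    return roc_auc(scores.to_numpy(), val.labels())


def crispr_recovery(seed: int, frac: float = 0.02, **screen_kwargs) -> float:
    """Fraction (%) of planted resistance genes inside the top ``frac``."""
    frame, truth = synthdata.make_screens(seed=seed, **screen_kwargs)
    ranked = average_and_rank(zscore_normalize(ScreenTable(frame)))
    cov = signature_top_coverage(truth.resistance_genes, ranked, [frac])
    return float(cov.loc[frac, "coverage_pct"])


def cox_coverage(
    n_seeds: int = 50,
    n_samples: int = 500,
    betas=(0.8, -0.5),
    censor_rate: float = 0.3,
    seed: int = 0,
) -> float:
    """Per-coefficient 95% CI coverage rate over repeated simulations."""
    betas = np.asarray(betas, dtype=float)
    covered = 0
    total = 0
    for s in range(n_seeds):
        matrix, surv, truth_betas = synthdata.make_survival_cohort(
            n_samples=n_samples, betas=betas, censor_rate=censor_rate,
            seed=seed * 100003 + s,
        )
        model = fit_cox(
            matrix,
            SurvivalTable(surv.sample_ids, surv.time, surv.event),
            GeneSet("risk", frozenset(matrix.gene_ids)),
        )
        coef = pd.Series(model.coef, index=model.genes)[matrix.gene_ids].to_numpy()
        se = pd.Series(model.se, index=model.genes)[matrix.gene_ids].to_numpy()
        lo, hi = coef - 1.96 * se, coef + 1.96 * se
        hit = (truth_betas >= lo) & (truth_betas <= hi)
        covered += int(hit.sum())
        total += hit.size
    return covered / total


def subtype_recovery(
    seed: int,
    n_samples: int = 300,
    shift: float = 3.0,
    n_resamples: int = 100,
) -> dict:
    """Consensus-cluster a planted 2-subtype cohort; return ARI and consensus."""
    matrix, labels, _ = synthdata.make_subtype_cohort(
        n_samples=n_samples, k=2, shift=shift, seed=seed
    )
    res = consensus_cluster(matrix, range(2, 7), n_resamples=n_resamples, seed=seed)
    return {
        "ari": float(adjusted_rand_score(labels, res.labels[2])),
        "result": res,
    }


def deconvolution_error(
    seed: int, n_types: int = 5, n_markers: int = 60, n_samples: int = 20,
    noise_sd: float = 0.1,
) -> float:
    """Mean absolute error of SVR deconvolution against planted fractions."""
    rng = synthdata.substream(seed, "deconv-basis")
    basis = ExpressionMatrix(
        [f"M{i:03d}" for i in range(n_markers)],
        [f"T{j}" for j in range(n_types)],
        rng.uniform(0, 10, (n_markers, n_types)),
    )
    proportions = rng.dirichlet(np.ones(n_types), size=n_samples)
    mix = synthdata.make_mixtures(basis, proportions, noise_sd=noise_sd, seed=seed)
    res = svr_deconvolve(mix, basis)
    return float(np.abs(res.fractions.to_numpy() - proportions).mean())
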