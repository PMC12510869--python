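"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be simulated here: annotated
single-cell matrices carrying a latent transcriptional program,
bulk immunotherapy cohorts with batch structure and a planted response
signature, multi-dataset CRISPR knockout log-fold-change tables with
planted resistance genes, survival cohorts with known Cox coefficients,
two-subtype cohorts, and cell-type mixtures for deconvolution.

Each generator returns the data **and** a truth object sufficient to
score recovery without re-reading the configuration.  A single global
integer seed expands into independent per-generator substreams by a
stable hash of the generator name, so the same seed and configuration
always reproduce bit-identical output.

Design of the single-cell generator: baseline log-expression is Gaussian
around gene-specific means (so linear expression is log-normal);
malignant cells get a constant mean shift on a set of malignant-marker
genes; the latent program activity ``a ~ Uniform(0, 1)`` of each
malignant cell adds a *centred* contribution ``(a - 1/2) * beta`` to the
program genes.  Centring keeps program membership orthogonal to the
malignant-versus-rest mean contrast, so the planted signature is exactly
the overlap of the program genes with the malignant-marker genes — the
quantity the derivation stage is supposed to recover.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .core import ExpressionMatrix, GeneSet
from .ici_model import ResponseCohort

__all__ = [
    "ScrnaTruth",
    "CohortTruth",
    "ScreenTruth",
    "SurvivalData",
    "make_scrna",
    "make_ici_cohort",
    "make_screens",
    "make_survival_cohort",
    "make_subtype_cohort",
    "make_mixtures",
    "substream",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG substream for ``name`` derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------


@dataclass
class ScrnaTruth:
    program_genes: GeneSet
    malignant_up_genes: GeneSet
    planted_signature: frozenset[str]
    cell_labels: list[str]  # per cell: malignant / immune / stromal
    latent_activity: np.ndarray  # per cell; 0 for non-malignant cells


@dataclass
class CohortTruth:
    effect_genes: GeneSet
    effect_size: float
    batch_offsets: dict[str, tuple[np.ndarray, np.ndarray]]  # batch -> (loc, scale)
    response_rate: float


@dataclass
class ScreenTruth:
    resistance_genes: GeneSet
    shift: float
    missing_rate: float


@dataclass
class SurvivalData:
    sample_ids: list[str]
    time: np.ndarray  # days, > 0
    event: np.ndarray  # 1 death, 0 censored


# ---------------------------------------------------------------------------
# Single-cell matrix with a planted program
# ---------------------------------------------------------------------------


def make_scrna(
    n_genes: int = 2000,
    n_cells: int = 1500,
    frac_malignant: float = 0.4,
    n_program: int = 100,
    n_malignant_up: int = 150,
    overlap: int = 40,
    malignant_shift: float = 1.0,
    beta: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ScrnaTruth]:
    """Simulate an annotated tumor single-cell expression matrix.

    ``overlap`` genes are shared between the latent-program drivers and
    the malignant-marker set; that intersection is the planted signature.
    ``beta`` scales the centred activity contribution and is chosen so a
    program gene's Spearman correlation with a set-level enrichment score
    comfortably exceeds the 0.3 screening threshold in expectation.
    """
    if overlap > min(n_program, n_malignant_up):
        raise ValueError("overlap cannot exceed either gene-set size")
    if n_cells < 50:
        raise ValueError("need at least 50 cells")
    if n_program + n_malignant_up - overlap > n_genes:
        raise ValueError("gene universe too small for requested sets")
    rng = substream(seed, "scrna")

    genes = [f"G{i:05d}" for i in range(n_genes)]
    perm = rng.permutation(n_genes)
    program_idx = perm[:n_program]
    # overlap genes are the first `overlap` of the program block
    mal_only = perm[n_program : n_program + n_malignant_up - overlap]
    mal_idx = np.concatenate([program_idx[:overlap], mal_only])

    n_mal = int(round(frac_malignant * n_cells))
    labels = ["malignant"] * n_mal + [
        "immune" if rng.random() < 0.7 else "stromal" for _ in range(n_cells - n_mal)
    ]
    cells = [f"C{i:05d}" for i in range(n_cells)]

    base = rng.uniform(1.0, 4.0, size=n_genes)
    X = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_cells))

    X[np.ix_(mal_idx, np.arange(n_mal))] += malignant_shift
    activity = np.zeros(n_cells)
    activity[:n_mal] = rng.uniform(0.0, 1.0, size=n_mal)
    X[np.ix_(program_idx, np.arange(n_mal))] += (
        (activity[:n_mal] - 0.5)[None, :] * beta
    )
    X = np.clip(X, 0.0, None)

    truth = ScrnaTruth(
        program_genes=GeneSet("program", frozenset(genes[i] for i in program_idx)),
        malignant_up_genes=GeneSet(
            "malignant_up", frozenset(genes[i] for i in mal_idx)
        ),
        planted_signature=frozenset(genes[i] for i in program_idx[:overlap]),
        cell_labels=labels,
        latent_activity=activity,
    )
    return ExpressionMatrix(genes, cells, X, "log_normalized"), truth


# ---------------------------------------------------------------------------
# Bulk ICI cohorts
# ---------------------------------------------------------------------------


def make_ici_cohort(
    n_samples: int = 100,
    n_genes: int = 500,
    n_effect: int = 30,
    effect_genes: frozenset[str] | None = None,
    effect_size: float = 1.0,
    n_batches: int = 1,
    batch_sd: float = 0.0,
    response_rate: float = 0.4,
    cohort_name: str = "cohort1",
    seed: int = 0,
) -> tuple[ResponseCohort, CohortTruth]:
    """Simulate a bulk cohort with binary immunotherapy response.

    Responders are shifted down on the effect genes by per-gene amounts
    ``effect_size * Uniform(0.5, 1.5)`` (mean ``effect_size``), so a
    high signature score predicts non-response — the score orientation
    used pipeline-wide.  The heterogeneous per-gene magnitudes mirror
    real signatures, whose member genes respond with different
    strengths; a spatially uniform shift would be a degenerate special
    case invisible to correlation-based classifiers.  Gene baselines
    differ (``Normal(0, 1)`` per-gene means).  Batches add per-gene
    location/scale noise; response labels are balanced across batches
    to within one sample.
    """
    if n_samples < 20:
        raise ValueError("need at least 20 samples")
    rng = substream(seed, f"ici:{cohort_name}")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    if effect_genes is None:
        effect_idx = rng.permutation(n_genes)[:n_effect]
        effect_genes = frozenset(genes[i] for i in effect_idx)
    else:
        missing = set(effect_genes) - set(genes)
        if missing:
            raise ValueError(f"effect genes outside universe: {sorted(missing)[:5]}")
        effect_idx = np.array([genes.index(g) for g in sorted(effect_genes)])

    samples = [f"{cohort_name}_S{i:04d}" for i in range(n_samples)]
    batches = [f"batch{i % n_batches}" for i in range(n_samples)]
    # responders balanced per batch to within 1
    n_resp = int(round(response_rate * n_samples))
    response = _balance_labels(batches, n_resp, rng)

    gene_means = rng.normal(0.0, 1.0, size=n_genes)
    X = gene_means[:, None] + rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    is_resp = np.array([r == "R" for r in response])
    gene_effect = effect_size * rng.uniform(0.5, 1.5, size=effect_idx.size)
    X[np.ix_(effect_idx, np.where(is_resp)[0])] -= gene_effect[:, None]

    batch_offsets: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for b in sorted(set(batches)):
        loc = rng.normal(0.0, batch_sd, size=n_genes)
        scale = np.exp(rng.normal(0.0, 0.1 * batch_sd, size=n_genes))
        batch_offsets[b] = (loc, scale)
        cols = [i for i, bb in enumerate(batches) if bb == b]
        X[:, cols] = X[:, cols] * scale[:, None] + loc[:, None]

    data = ResponseCohort(
        matrix=ExpressionMatrix(genes, samples, X, "log_normalized"),
        response=response,
        batch=batches,
        cohort=[cohort_name] * n_samples,
    )
    truth = CohortTruth(
        effect_genes=GeneSet("effect", effect_genes),
        effect_size=effect_size,
        batch_offsets=batch_offsets,
        response_rate=response_rate,
    )
    return data, truth


def _balance_labels(batches: list[str], n_resp: int, rng) -> list[str]:
    """Distribute ``n_resp`` responder labels evenly across batches."""
    n = len(batches)
    by_batch: dict[str, list[int]] = {}
    for i, b in enumerate(batches):
        by_batch.setdefault(b, []).append(i)
    response = ["NR"] * n
    remaining = n_resp
    batch_names = sorted(by_batch)
    quota = {b: int(n_resp * len(by_batch[b]) / n) for b in batch_names}
    leftover = n_resp - sum(quota.values())
    for b in batch_names:
        if leftover <= 0:
            break
        quota[b] += 1
        leftover -= 1
    for b in batch_names:
        idx = by_batch[b]
        chosen = rng.permutation(len(idx))[: quota[b]]
        for c in chosen:
            response[idx[c]] = "R"
        remaining -= quota[b]
    return response


# ---------------------------------------------------------------------------
# CRISPR screens
# ---------------------------------------------------------------------------


def make_screens(
    n_genes: int = 5000,
    n_datasets: int = 17,
    n_resistance: int = 50,
    shift: float = 2.0,
    missing_rate: float = 0.1,
    seed: int = 0,
):
    """Simulate gene × dataset CRISPR logFC tables with planted resistance genes.

    Each dataset has its own location and scale (exercising the z-score
    normalization); resistance genes are shifted down by ``shift`` in the
    dataset's own standardized units.  Returns ``(frame, truth)`` where
    ``frame`` is a pandas DataFrame with NaN for missing cells.
    """
    import pandas as pd

    if n_resistance >= n_genes:
        raise ValueError("n_resistance must be < n_genes")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = substream(seed, "screens")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    res_idx = rng.permutation(n_genes)[:n_resistance]
    is_res = np.zeros(n_genes, dtype=bool)
    is_res[res_idx] = True

    cols = {}
    for d in range(n_datasets):
        loc = rng.normal(0.0, 2.0)
        scale = rng.uniform(0.5, 2.0)
        z = rng.normal(0.0, 1.0, size=n_genes)
        z[is_res] -= shift
        col = loc + scale * z
        mask = rng.random(n_genes) < missing_rate
        col[mask] = np.nan
        cols[f"screen{d:02d}"] = col
    frame = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    truth = ScreenTruth(
        resistance_genes=GeneSet("resistance", frozenset(genes[i] for i in res_idx)),
        shift=shift,
        missing_rate=missing_rate,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------


def make_survival_cohort(
    n_samples: int = 500,
    genes: list[str] | None = None,
    betas=(0.8, -0.5),
    baseline_hazard: float = 1.0 / 365.0,
    censor_rate: float = 0.3,
    seed: int = 0,
):
    """Simulate expression + survival with exponential hazards.

    Event times are exponential with rate ``h0 * exp(x'beta)``; an
    independent exponential censoring time is tuned by bisection so the
    expected censored fraction matches ``censor_rate``.  Returns
    ``(ExpressionMatrix, SurvivalData, betas)``.
    """
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    betas = np.asarray(betas, dtype=float)
    if genes is None:
        genes = [f"G{i:05d}" for i in range(betas.size)]
    if len(genes) != betas.size:
        raise ValueError("genes and betas must align")
    rng = substream(seed, "survival")
    samples = [f"S{i:04d}" for i in range(n_samples)]
    X = rng.normal(0.0, 1.0, size=(len(genes), n_samples))
    rate = baseline_hazard * np.exp(betas @ X)
    t_event = rng.exponential(1.0 / rate)

    if censor_rate == 0:
        time = t_event
        event = np.ones(n_samples, dtype=int)
    else:
        c_rate = _tune_censor_rate(rate, censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n_samples)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)
    surv = SurvivalData(samples, time, event)
    return ExpressionMatrix(genes, samples, X, "log_normalized"), surv, betas


def _tune_censor_rate(event_rates: np.ndarray, target: float) -> float:
    """Bisection on the censoring hazard c so mean(c / (c + rate)) = target."""
    lo, hi = 1e-12, float(event_rates.max() * 1e6)
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        frac = float(np.mean(mid / (mid + event_rates)))
        if frac < target:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


# ---------------------------------------------------------------------------
# Subtype cohorts and mixtures
# ---------------------------------------------------------------------------


def make_subtype_cohort(
    n_samples: int = 300,
    n_genes: int = 200,
    k: int = 2,
    shift: float = 3.0,
    n_markers: int = 50,
    score_shift: float = 1.0,
    seed: int = 0,
):
    """Simulate a cohort of ``k`` expression subtypes plus auxiliary scores.

    Clusters are separated by ``shift`` on ``n_markers`` marker genes
    (signs alternating per cluster); auxiliary per-sample scores
    (TIDE-like, TMB-like, MSI-like) have cluster means differing by
    ``score_shift`` standard deviations.  Returns
    ``(ExpressionMatrix, labels, score_frame)``.
    """
    import pandas as pd

    if n_markers > n_genes:
        raise ValueError("n_markers cannot exceed n_genes")
    rng = substream(seed, "subtype")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    labels = np.array([i % k for i in range(n_samples)])
    labels = labels[rng.permutation(n_samples)]

    X = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    marker_idx = rng.permutation(n_genes)[:n_markers]
    signs = rng.choice([-1.0, 1.0], size=n_markers)
    for c in range(k):
        cols = np.where(labels == c)[0]
        # each cluster sits at a distinct multiple of the shift direction
        X[np.ix_(marker_idx, cols)] += signs[:, None] * shift * c
    score_names = ["TIDE", "TMB", "MSI"]
    scores = {}
    for j, name in enumerate(score_names):
        mu = np.array([score_shift * ((c + j) % k) for c in range(k)])
        scores[name] = rng.normal(mu[labels], 1.0)
    score_frame = pd.DataFrame(scores, index=samples)
    return (
        ExpressionMatrix(genes, samples, X, "log_normalized"),
        labels,
        score_frame,
    )


def make_mixtures(
    basis: ExpressionMatrix,
    proportions: np.ndarray,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> ExpressionMatrix:
    """Mix cell-type expression profiles into bulk samples.

    ``basis`` is genes × cell types; ``proportions`` is samples × cell
    types with non-negative rows summing to 1.  The mixture is
    ``basis @ proportions.T`` plus Gaussian noise.
    """
    P = np.asarray(proportions, dtype=float)
    if P.ndim != 2 or P.shape[1] != basis.n_samples:
        raise ValueError("proportions must be samples x cell-types")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("proportion rows must be non-negative and sum to 1")
    rng = substream(seed, "mixtures")
    M = basis.values @ P.T + rng.normal(0.0, noise_sd, size=(basis.n_genes, P.shape[0]))
    samples = [f"MIX{i:03d}" for i in range(P.shape[0])]
    return ExpressionMatrix(basis.gene_ids, samples, M, basis.scale)
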