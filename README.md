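# uvrsig

Tools for deriving a tumor-specific **ultraviolet-response (UVR)
expression signature** from single-cell data and putting it to work
downstream: predicting immune-checkpoint-inhibitor (ICI) response,
meta-ranking CRISPR immune-resistance screens, selecting hub genes,
building Cox/Kaplan–Meier risk models, and consensus-clustering
molecular subtypes. It is aimed at computational-oncology analysts who
want the full workflow as tested, scriptable Python rather than a chain
of one-off notebook steps, and every stage can be exercised offline on
synthetic cohorts with planted ground truth.

## The model in brief

For each single-cell dataset with expression matrix X (genes × cells)
and malignant-cell annotation, with per-cell ssGSEA enrichment score
s(c) of a seed UV-response gene set:

- **Gx** = { g : Spearman ρ(X_g, s) > 0.3, p < 0.05 } over malignant cells
- **Gy** = { g : log₂FC(malignant vs rest) ≥ 0.30, BH q < 10⁻⁵ } (Wilcoxon)
- **Gn** = Gx ∩ Gy, and the signature is ⋃ₙ Gn, deduplicated with
  per-gene dataset provenance.

The packaged reference signature (`uvrsig.load_uvr_sig()`) has 38 genes;
its 7-gene hub subset (`load_hub_sig()`) is the ≥4-of-6 consensus of six
feature selectors. The ICI classifier is a nearest-centroid model with
continuous score d(x, μ_R) − d(x, μ_NR) (Pearson distance by default);
higher scores predict non-response. CRISPR screens are z-normalized per
dataset and genes ranked by missing-aware average z (lowest = strongest
immune-resistance candidate). Risk scores are Cox linear predictors
Σβ·x dichotomized at the log-rank-optimal cutoff. See
`docs/methods.md` for the full treatment.

## Worked example

```python
import pandas as pd
from uvrsig import core, enrichment, signature, synthdata, workflows

# simulate an annotated tumor single-cell dataset with a planted program
matrix, truth = synthdata.make_scrna(seed=1)   # 2000 genes x 1500 cells
malignant = pd.Series([c == "malignant" for c in truth.cell_labels],
                      index=matrix.sample_ids)

# per-cell activity of the seed UV gene set, then the derivation
sets = core.SignatureCollection(); sets.add(truth.program_genes)
activity = enrichment.ssgsea_score(matrix, sets).frame.iloc[0]
d = signature.derive_dataset(matrix, malignant, activity, dataset_id="sim")
print(f"|Gx|={len(d.gx)}  |Gy|={len(d.gy)}  |Gn|={len(d.gn)}")

print(workflows.signature_recovery(seed=1))
print("validation AUC:", round(workflows.ici_auc_experiment(seed=1,
                                                            effect_size=2.0), 3))
```

prints

```
|Gx|=100  |Gy|=150  |Gn|=40
{'precision': 1.0, 'recall': 1.0, 'f1': 1.0, 'n_derived': 40}
validation AUC: 0.973
```

— the correlation screen recovered the 100 planted program genes, the
DEG test the 150 malignant markers, and their intersection exactly the
40-gene planted signature (F1 = 1.0); a centroid model trained on a
simulated cohort with a planted response effect separates responders
from non-responders on held-out samples with AUC 0.97.

The same stages are available from the shell:

```sh
uvrsig --seed 1 simulate scrna --out-dir sim/
uvrsig derive --matrix sim/expr.tsv --cells sim/cells.tsv \
       --uvset sim/uv_set.gmt --out sig.gmt --report provenance.tsv
uvrsig score --matrix sim/expr.tsv --sets sig.gmt --out scores.tsv
uvrsig crispr rank --logfc screens.tsv --out ranked.tsv
```

## Layout

- `uvrsig.core` — data model (ExpressionMatrix, GeneSet), GMT/TSV/MTX
  I/O, Spearman / Wilcoxon / BH primitives
- `uvrsig.synthdata` — generators with planted ground truth
- `uvrsig.enrichment` — ssGSEA, ECDF scoring, marker abundance,
  correlation panels
- `uvrsig.signature` — Gx/Gy/Gn derivation and cross-dataset union
- `uvrsig.ici_model` — cohort merge, ComBat, split, centroid model,
  AUC benchmarking
- `uvrsig.crispr` — z-score meta-ranking and top-fraction coverage
- `uvrsig.prognosis` — selector registry, consensus hub, Cox, optimal
  cutoff, KM/log-rank
- `uvrsig.subtyping` — consensus clustering, subtype score tests,
  SVR deconvolution
- `uvrsig.workflows` — end-to-end recovery experiments
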