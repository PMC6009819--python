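# tagdnl — plasma TAG clusters and de novo lipogenesis

Blood-plasma triacylglycerols (TAGs) are usually reported as a single total,
but direct-infusion mass spectrometry (DI-MS) resolves dozens of species,
annotated `TAG(total carbons : total double bonds)`. Those species are not
independent: they fall into co-regulated clusters, and the cluster of TAGs
built from saturated and monounsaturated 16–18-carbon fatty acids (≈46–52
total carbons, 0–2 double bonds) behaves as a signature of hepatic de novo
lipogenesis (DNL) and of fatty liver. `tagdnl` implements the full inference
chain behind that claim, for lipidomics analysts and metabolic-disease
researchers:

* **Preprocessing** — `Class(C:DB)` annotation parsing, pooled-QC plate
  normalization (per-plate factor = grand-mean QC total / plate QC total),
  CV diagnostics, TAG-percent normalization, centring/Pareto scaling.
* **Cluster structure** — Hopkins clustering-tendency statistic
  H = Σu/(Σu+Σw) with the H > 0.6799 decision rule, per lipid class;
  complete-linkage HCA and k-means references.
* **Bayesian hierarchical clustering** — greedy agglomeration under a
  Dirichlet-process prior: d_k = αΓ(n_k) + d_i d_j, π_k = αΓ(n_k)/d_k,
  merge posterior r_k = π_k p(D|H1)/p(D|T); Normal-Inverse-Wishart marginal
  likelihoods in log space; trees cut at r < 0.5; cluster intensity shares
  and composition summaries.
* **OPLS-DA** — Trygg–Wold orthogonal filtering with R²X/R²Y, k-fold Q²,
  S-plots, label-permutation validation, CV-ANOVA, train→test ROC/AUC, and
  PLS-DA with VIP for multi-class problems.
* **Clinical indices** — fatty liver index (Bedogni logistic, FLI ≥ 60 =
  steatosis), HOMA-IR, ultrasound-score labels, group summary tables.
* **DNL kinetics** — fractional synthesis from deuterium enrichment
  (enrichment / (body-water enrichment × 22)), FSR as the 1–4 h OLS slope in
  %/h, de novo palmitate mass, and TAG-cluster-vs-DNL regression.
* **Association scans** — proportional-odds (ordinal) and linear
  regressions of TAG markers with steatosis across adjustment batteries,
  with attenuation reporting.
* **Synthetic cohort generator** — seeded, tested, with planted TAG
  clusters, steatosis effects, batch structure and tracer kinetics; it
  defines the conditions under which every recovery property is verified.

See `docs/methods.md` for models, parameters and design decisions.

## Worked example

```python
from tagdnl.synthetic import CohortSpec, generate_cohort
from tagdnl.preprocess import qc_normalize, tag_percent_normalize, Scaler
from tagdnl.bhc import bhc_fit, bhc_cut, cluster_share, cluster_composition

table, subjects = generate_cohort(CohortSpec(seed=1))
normed, report = qc_normalize(table)
print(f"mean QC CV: {report.mean_cv_before:.3f} -> {report.mean_cv_after:.3f}")

tagpct = tag_percent_normalize(normed.subjects())
Z = Scaler("pareto").fit_transform(tagpct.intensities.to_numpy())
tree = bhc_fit(Z.T, alpha=1.0, labels=tagpct.feature_labels)
assign = bhc_cut(tree, r_threshold=0.5)
print(assign.n_clusters, cluster_share(assign, normed).round(3).to_dict())
```

prints

```
mean QC CV: 0.170 -> 0.109
3 {1: 0.309, 2: 0.457, 3: 0.234}
```

QC-pool normalization lowers the mean per-lipid QC coefficient of variation
from 17% to ~11%, and cutting the Bayesian merge tree at r < 0.5 yields
three TAG clusters: cluster 1 (11 saturated/monounsaturated 46–52-carbon
species — the DNL cluster) carries ~31% of the total TAG signal, the
polyunsaturated cluster ~46% and the short-chain cluster ~23%.

The numbered scripts under `analysis/` run the whole study narrative —
simulate, normalize, test clustering tendency (only the TAG class exceeds
the 0.6799 Hopkins threshold), cluster, discriminate steatosis by OPLS-DA
(FLI-trained model predicts ultrasound status with AUC ≈ 0.88), compute
indices, estimate FSR (≈ 4.4 %/h against a planted 4.41) and the
cluster–DNL regression (R² ≈ 0.8–0.9), and scan marker associations:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_qc_normalization.py
# ... through analysis/08_tag_association_scan.py
```

Outputs land under `results/`. A thin CLI mirrors the same stages
(`tagdnl simulate|normalize|tendency|bhc|opls|indices|dnl|associate|run-all`);
`tagdnl run-all --config configs/demo.yaml` runs a reduced end-to-end
pipeline with a manifest and a bit-reproducible report.

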