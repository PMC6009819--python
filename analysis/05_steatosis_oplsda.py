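"""OPLS-DA of hepatic steatosis from the plasma lipidome.

Fits OPLS-DA against the fatty-liver-index label (FLI >= 60) and against the
ultrasound label, validates by label permutation and CV-ANOVA, reads the
discriminatory lipids from the S-plot, and tests predictive transfer: a
model trained on FLI-labelled subjects predicts the ultrasound status of
held-out subjects (ROC AUC).
"""

import json
from pathlib import Path

import pandas as pd

from tagdnl.clinical import steatosis_labels
from tagdnl.containers import FeatureTable
from tagdnl.opls import cv_anova, oplsda_fit, permutation_test, predict_and_roc, splot

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def fit_and_report(X, y, name, out):
    model = oplsda_fit(X, y, seed=SEED)
    F, df1, df2, p = cv_anova(model)
    perm = permutation_test(X.to_numpy(), y, n_perm=200, seed=SEED, n_ortho=model.n_ortho)
    sp = splot(model, model.scaler.transform(X.to_numpy()))
    sp.to_csv(out / f"splot_{name}.tsv", sep="\t")
    print(f"{name}: R2X={model.r2x:.2f} R2Y={model.r2y:.2f} Q2={model.q2:.2f} "
          f"(n_ortho={model.n_ortho}); CV-ANOVA p={p:.2e}; permutation "
          f"{'passed' if perm.passed else 'FAILED'}")
    top = sp["p_corr"].abs().sort_values(ascending=False).head(5).index.tolist()
    print(f"  top discriminators: {', '.join(top)}")
    return {"model": model.summary(), "cv_anova_p": p, "permutation": perm.to_dict(),
            "top_splot": top}


def main() -> None:
    data = ROOT / "results" / "data"
    out = ROOT / "results"
    table = FeatureTable.from_tsv(data / "normalized_features.tsv").subjects()
    meta = pd.read_csv(data / "subjects.tsv", sep="\t", index_col="sample_id")
    X = table.intensities
    meta = meta.loc[X.index]

    summary = {}
    summary["fli"] = fit_and_report(X, steatosis_labels(meta, "fli60").to_numpy(), "fli", out)
    summary["ultrasound"] = fit_and_report(
        X, steatosis_labels(meta, "ultrasound").to_numpy(), "ultrasound", out
    )

    n_train = int(0.6 * len(X))
    train, test = X.index[:n_train], X.index[n_train:]
    m = oplsda_fit(X.loc[train], steatosis_labels(meta.loc[train], "fli60").to_numpy(), seed=SEED)
    y_us = steatosis_labels(meta.loc[test], "ultrasound").to_numpy()
    _, _, roc, auc = predict_and_roc(m, X.loc[test], y_us)
    roc.to_csv(out / "roc_fli_to_ultrasound.tsv", sep="\t", index=False)
    summary["transfer_auc"] = auc
    print(f"FLI-trained model predicting ultrasound status of {len(test)} "
          f"held-out subjects: AUC = {auc:.3f}")
    (out / "opls_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
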