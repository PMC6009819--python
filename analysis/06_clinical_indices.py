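"""Clinical indices and the group-comparison table.

Computes the fatty liver index and HOMA-IR for every subject, labels
steatosis by both schemes (FLI >= 60; ultrasound score 5-10), and writes a
comparison-of-groups table (mean ± SD, Welch t-test) in the style of a
cohort-description table.
"""

from pathlib import Path

import pandas as pd

from tagdnl.clinical import fatty_liver_index, group_summary, homa_ir, steatosis_labels

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "results" / "data"
    out = ROOT / "results"
    meta = pd.read_csv(data / "subjects.tsv", sep="\t", index_col="sample_id")
    meta["homa_ir"] = homa_ir(meta["glucose_mmol_l"], meta["insulin_pmol_l"])
    meta["fli"] = fatty_liver_index(
        meta["tag_mmol_l"], meta["bmi"], meta["ggt_u_l"], meta["waist_cm"]
    )
    worked = fatty_liver_index(tg_mg_dl=150.0, bmi=30.0, ggt_u_l=50.0, waist_cm=100.0)
    print(f"worked example: TG 150 mg/dL, BMI 30, GGT 50 U/L, waist 100 cm "
          f"-> FLI = {worked:.2f}")

    for scheme in ("fli60", "ultrasound"):
        labels = steatosis_labels(meta, scheme=scheme)
        print(f"steatosis prevalence ({scheme}): {labels.mean():.1%}")
    labels = steatosis_labels(meta, scheme="ultrasound")
    summary = group_summary(meta, labels)
    summary.to_csv(out / "group_summary.tsv", sep="\t")
    show = summary.loc[["n", "women_pct", "bmi", "tag_mmol_l", "homa_ir", "fli"]]
    print(show.round(2).to_string())


if __name__ == "__main__":
    main()
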