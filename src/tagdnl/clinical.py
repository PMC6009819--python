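"""Clinical indices of hepatic steatosis and insulin resistance.

The fatty liver index (FLI) is the Bedogni logistic score on BMI, waist
circumference, fasting triglycerides and GGT:

    L = 0.953 ln(TG mg/dL) + 0.139 BMI + 0.718 ln(GGT U/L)
        + 0.053 waist_cm - 15.745
    FLI = 100 * e^L / (1 + e^L)            (0-100; >= 60 indicates steatosis)

Triglycerides given in mmol/L are converted with 88.57 mg/dL per mmol/L.
HOMA-IR is the classic HOMA1 index glucose(mmol/L) x insulin(mU/L) / 22.5,
with insulin in pmol/L divided by 6.945. (The calculator-based HOMA2 variant
is not computed.)
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TG_MGDL_PER_MMOL",
    "fatty_liver_index",
    "homa_ir",
    "steatosis_labels",
    "group_summary",
    "validate_records",
]

TG_MGDL_PER_MMOL = 88.57
INSULIN_PMOL_PER_MU = 6.945
FLI_STEATOSIS_CUTOFF = 60.0

_RANGES = {"bmi": (10, 80), "waist_cm": (40, 200)}


def _positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} must be positive and finite")
    return arr


def fatty_liver_index(tag_mmol_l=None, bmi=None, ggt_u_l=None, waist_cm=None, tg_mg_dl=None):
    """Fatty liver index in [0, 100]. Provide triglycerides either as
    ``tag_mmol_l`` (converted internally) or directly as ``tg_mg_dl``."""
    if (tag_mmol_l is None) == (tg_mg_dl is None):
        raise ValueError("provide exactly one of tag_mmol_l or tg_mg_dl")
    tg = _positive("tg_mg_dl", tg_mg_dl) if tg_mg_dl is not None else (
        _positive("tag_mmol_l", tag_mmol_l) * TG_MGDL_PER_MMOL
    )
    bmi = _positive("bmi", bmi)
    ggt = _positive("ggt_u_l", ggt_u_l)
    waist = _positive("waist_cm", waist_cm)
    lp = 0.953 * np.log(tg) + 0.139 * bmi + 0.718 * np.log(ggt) + 0.053 * waist - 15.745
    fli = 100.0 / (1.0 + np.exp(-lp))
    return float(fli) if np.ndim(fli) == 0 else fli


def homa_ir(glucose_mmol_l, insulin_pmol_l):
    """HOMA1-IR: glucose (mmol/L) x insulin (mU/L) / 22.5."""
    glucose = np.asarray(glucose_mmol_l, dtype=float)
    insulin = np.asarray(insulin_pmol_l, dtype=float)
    if np.any(glucose < 0) or np.any(insulin < 0):
        raise ValueError("glucose and insulin must be >= 0")
    out = glucose * (insulin / INSULIN_PMOL_PER_MU) / 22.5
    return float(out) if np.ndim(out) == 0 else out


def validate_records(records: pd.DataFrame) -> None:
    """Physiological-range checks on a subject table."""
    for col, (lo, hi) in _RANGES.items():
        if col in records:
            bad = records.index[(records[col] < lo) | (records[col] > hi)].tolist()
            if bad:
                raise ValueError(f"{col} outside [{lo}, {hi}] for {bad[:5]}")
    for col in ("tag_mmol_l", "ggt_u_l"):
        if col in records and (records[col] <= 0).any():
            raise ValueError(f"{col} must be positive")


def steatosis_labels(records: pd.DataFrame, scheme: str = "fli60") -> pd.Series:
    """Binary steatosis labels.

    ``fli60``: FLI >= 60 (FLI computed from the table if not present);
    ``ultrasound``: liver score 5-10 vs 3-4 (scores outside 3-10 are an
    error).
    """
    if scheme == "fli60":
        if "fli" in records:
            fli = records["fli"]
        else:
            needed = ["tag_mmol_l", "bmi", "ggt_u_l", "waist_cm"]
            missing = [c for c in needed if c not in records]
            if missing:
                raise ValueError(f"fli60 scheme requires column(s) {missing}")
            fli = fatty_liver_index(
                records["tag_mmol_l"], records["bmi"], records["ggt_u_l"], records["waist_cm"]
            )
        return pd.Series((np.asarray(fli) >= FLI_STEATOSIS_CUTOFF).astype(int),
                         index=records.index, name="steatosis")
    if scheme == "ultrasound":
        if "liver_score" not in records:
            raise ValueError("ultrasound scheme requires column 'liver_score'")
        score = records["liver_score"].astype(int)
        if ((score < 3) | (score > 10)).any():
            bad = records.index[(score < 3) | (score > 10)].tolist()
            raise ValueError(f"liver score outside 3-10 for {bad[:5]}")
        return pd.Series((score >= 5).astype(int), index=records.index, name="steatosis")
    raise ValueError(f"unknown labelling scheme {scheme!r}")


def group_summary(records: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Comparison-of-groups table: n, % women, mean ± SD and Welch t-test p.

    One row per continuous variable plus count rows; the p-value column is
    the two-sided Welch (unequal-variance) t-test between the label groups.
    """
    labels = labels.reindex(records.index)
    g0 = records.loc[labels == 0]
    g1 = records.loc[labels == 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both label groups must be non-empty")
    rows = [{"variable": "n", "group0": float(len(g0)), "group1": float(len(g1)),
             "sd0": np.nan, "sd1": np.nan, "p": np.nan}]
    if "sex" in records:
        w0 = 100.0 * (g0["sex"] == "F").mean()
        w1 = 100.0 * (g1["sex"] == "F").mean()
        rows.append({"variable": "women_pct", "group0": w0, "group1": w1,
                     "sd0": np.nan, "sd1": np.nan, "p": np.nan})
    numeric = records.select_dtypes(include=[np.number]).columns
    for col in numeric:
        a, b = g0[col].dropna(), g1[col].dropna()
        if a.nunique() <= 1 and b.nunique() <= 1 and a.mean() == b.mean():
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append({"variable": col, "group0": float(a.mean()), "group1": float(b.mean()),
                     "sd0": float(a.std(ddof=1)), "sd1": float(b.std(ddof=1)), "p": p})
    return pd.DataFrame(rows).set_index("variable")
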