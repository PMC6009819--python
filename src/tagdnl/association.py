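"""Covariate-adjusted association scans of TAG markers with steatosis.

Individual TAG species are tested against the ordinal ultrasound liver score
(proportional-odds / cumulative-logit regression) or against the continuous
fatty liver index (OLS), across a battery of adjustment sets. Every set
extends the base adjustment (analysis batch entered as a fixed categorical
plus total TAG); markers are standardized to SD units inside each model so
estimates are per-SD log-odds (or betas). Attenuation relative to the base
set localizes which covariates mediate an association. Nominal p-values are
reported with a Benjamini-Hochberg column alongside for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable

__all__ = [
    "AdjustmentSet",
    "OrdinalFit",
    "ordinal_logistic",
    "association_scan",
    "attenuation_report",
]

BASE_COVARIATES = ("batch", "total_tag")


@dataclass
class AdjustmentSet:
    """A named list of subject-table columns added on top of the base set."""

    name: str
    covariates: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)


@dataclass
class OrdinalFit:
    params: pd.Series       # slopes for the design columns
    cutpoints: np.ndarray   # K-1 ordered thresholds
    bse: pd.Series
    llf: float
    converged: bool
    separation_flag: bool
    result: object = field(repr=False, default=None)


def ordinal_logistic(y, X, maxiter: int = 500) -> OrdinalFit:
    """Proportional-odds (cumulative logit) regression by maximum likelihood.

    ``y`` holds ordered categories (any orderable codes), ``X`` the design
    matrix without intercept (cutpoints play that role). Suspected complete
    separation (huge slopes or standard errors) is flagged, not fatal.
    """
    y = pd.Series(np.asarray(y), name="y")
    X = pd.DataFrame(X)
    cats = np.sort(y.unique())
    if cats.size < 2:
        raise ValueError("need >= 2 outcome categories")
    if (y.value_counts() < 1).any():
        raise ValueError("every category must be non-empty")
    y_ord = pd.Categorical(y, categories=cats, ordered=True)
    model = OrderedModel(y_ord, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=maxiter, disp=False, gtol=1e-8)
    k_slope = X.shape[1]
    params = pd.Series(res.params[:k_slope].to_numpy(), index=X.columns)
    bse = pd.Series(res.bse[:k_slope].to_numpy(), index=X.columns)
    # transformed threshold params -> ordered cutpoints
    cut = model.transform_threshold_params(res.params)[1:-1]
    sep = bool((params.abs() > 15).any() or (bse > 50).any() or not np.isfinite(res.llf))
    if sep:
        warnings.warn("possible separation: extreme ordinal-logistic estimates")
    return OrdinalFit(
        params=params,
        cutpoints=np.asarray(cut, dtype=float),
        bse=bse,
        llf=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation_flag=sep,
        result=res,
    )


def _design(
    subjects: pd.DataFrame,
    marker: pd.Series,
    covariates: tuple[str, ...],
    batch: pd.Series,
    total_tag: pd.Series,
) -> pd.DataFrame:
    cols = {"marker": (marker - marker.mean()) / marker.std(ddof=1)}
    dummies = pd.get_dummies(batch.astype(str), prefix="batch", drop_first=True, dtype=float)
    for c in dummies.columns:
        cols[c] = dummies[c]
    cols["total_tag"] = (total_tag - total_tag.mean()) / total_tag.std(ddof=1)
    for cov in covariates:
        if cov not in subjects.columns:
            raise ValueError(f"covariate {cov!r} not in subject table")
        v = subjects[cov]
        if v.dtype == object:
            d = pd.get_dummies(v.astype(str), prefix=cov, drop_first=True, dtype=float)
            for c in d.columns:
                cols[c] = d[c]
        else:
            v = v.astype(float)
            sd = v.std(ddof=1)
            cols[cov] = (v - v.mean()) / sd if sd > 0 else v - v.mean()
    return pd.DataFrame(cols, index=subjects.index)


def association_scan(
    table: FeatureTable,
    subjects: pd.DataFrame,
    markers: list[str],
    outcome: str,
    sets: list[AdjustmentSet],
) -> pd.DataFrame:
    """One adjusted association per marker x adjustment set.

    ``outcome`` is ``"ultrasound_ordinal"`` (liver score, proportional odds)
    or ``"fli_linear"`` (fatty liver index, OLS). The base adjustment (batch
    + total TAG) is always included; failed or non-converged fits are
    flagged per cell rather than fatal.
    """
    if outcome not in ("ultrasound_ordinal", "fli_linear"):
        raise ValueError(f"unknown outcome {outcome!r}")
    subj_tab = table.subjects()
    common = subjects.index.intersection(subj_tab.intensities.index)
    subjects = subjects.loc[common]
    intens = subj_tab.intensities.loc[common]
    batch = subj_tab.plate.loc[common]
    missing = [m for m in markers if m not in intens.columns]
    if missing:
        raise ValueError(f"marker(s) not in feature table: {missing}")
    total_tag = subjects["tag_mmol_l"].astype(float)

    if outcome == "ultrasound_ordinal":
        yvals = subjects["liver_score"].astype(int)
    else:
        from .clinical import fatty_liver_index

        yvals = pd.Series(
            fatty_liver_index(
                subjects["tag_mmol_l"], subjects["bmi"], subjects["ggt_u_l"],
                subjects["waist_cm"],
            ),
            index=subjects.index,
        )

    if not any(s.name == "base" for s in sets):
        sets = [AdjustmentSet("base", ())] + list(sets)

    rows = []
    for marker in markers:
        mk = np.log(intens[marker])  # log intensities: right-skewed ion counts
        for aset in sets:
            X = _design(subjects, mk, aset.covariates, batch, total_tag)
            est = se = p = np.nan
            converged = False
            try:
                if outcome == "ultrasound_ordinal":
                    fit = ordinal_logistic(yvals, X)
                    est, se = float(fit.params["marker"]), float(fit.bse["marker"])
                    z = est / se
                    from scipy import stats as _st

                    p = float(2 * _st.norm.sf(abs(z)))
                    converged = fit.converged and not fit.separation_flag
                else:
                    res = sm.OLS(yvals.to_numpy(), sm.add_constant(X)).fit()
                    est, se = float(res.params["marker"]), float(res.bse["marker"])
                    p = float(res.pvalues["marker"])
                    converged = True
            except Exception as exc:  # noqa: BLE001 - flagged per cell
                warnings.warn(f"fit failed for {marker} / {aset.name}: {exc}")
            ci = 1.959963984540054 * se
            rows.append(
                {
                    "marker": marker,
                    "outcome": outcome,
                    "set": aset.name,
                    "estimate": est,
                    "se": se,
                    "or": np.exp(est) if outcome == "ultrasound_ordinal" else np.nan,
                    "ci_lo": est - ci,
                    "ci_hi": est + ci,
                    "p": p,
                    "converged": converged,
                }
            )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_bh"] = np.nan
    if ok.any():
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def attenuation_report(results: pd.DataFrame) -> pd.DataFrame:
    """Per-marker estimates across adjustment sets with % change vs base.

    pct_change = (beta_adj - beta_base) / |beta_base| * 100.
    """
    if "base" not in set(results["set"]):
        raise ValueError("results must include the base adjustment set")
    rows = []
    for marker, grp in results.groupby("marker", sort=False):
        base = grp.loc[grp["set"] == "base", "estimate"].iloc[0]
        for _, r in grp.iterrows():
            rows.append(
                {
                    "marker": marker,
                    "set": r["set"],
                    "estimate": r["estimate"],
                    "pct_change_vs_base": (r["estimate"] - base) / abs(base) * 100.0
                    if base != 0
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)
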