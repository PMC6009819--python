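"""QC-pool batch normalization, CV diagnostics, TAG-percent and matrix scaling.

Plate-to-plate drift in direct-infusion lipidomics is corrected by a simple
total-intensity normalization against the pooled QC injections: every sample
on a plate is multiplied by ``grand mean QC total / plate mean QC total``.
Within-plate intensity ratios are preserved exactly and the procedure is
idempotent. Analytical precision is summarized as the per-feature coefficient
of variation over QC rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable

__all__ = [
    "NormalizationReport",
    "qc_normalize",
    "qc_cv",
    "tag_percent_normalize",
    "Scaler",
    "scale_matrix",
]


@dataclass
class NormalizationReport:
    """Per-plate factors and QC CV before/after normalization."""

    plate_factors: dict
    cv_before: pd.Series
    cv_after: pd.Series
    reference: str = "grand_mean_qc"

    @property
    def mean_cv_before(self) -> float:
        return float(self.cv_before.mean())

    @property
    def mean_cv_after(self) -> float:
        return float(self.cv_after.mean())

    def to_json(self, path=None) -> str:
        payload = {
            "reference": self.reference,
            "plate_factors": {str(k): float(v) for k, v in self.plate_factors.items()},
            "mean_cv_before": self.mean_cv_before,
            "mean_cv_after": self.mean_cv_after,
            "cv_before": {k: _jsonable(v) for k, v in self.cv_before.items()},
            "cv_after": {k: _jsonable(v) for k, v in self.cv_after.items()},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(v):
    return None if (v is None or (isinstance(v, float) and np.isnan(v))) else float(v)


def qc_cv(table: FeatureTable) -> tuple[pd.Series, float]:
    """Per-feature CV (sample SD / mean) over QC rows, and the mean CV.

    Features whose QC mean is zero have undefined CV and are reported as NaN;
    the mean CV skips them.
    """
    qc = table.intensities.loc[table.is_qc]
    if qc.shape[0] < 2:
        raise ValueError("qc_cv requires at least 2 QC samples")
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv = cv.where(mean != 0, np.nan)
    n_undef = int(cv.isna().sum())
    if n_undef:
        warnings.warn(f"{n_undef} feature(s) have zero QC mean; CV undefined")
    return cv, float(cv.mean(skipna=True))


def qc_normalize(
    table: FeatureTable, reference: str = "grand_mean_qc"
) -> tuple[FeatureTable, NormalizationReport]:
    """Scale each plate so its QC total intensity matches the grand QC mean.

    The scale factor for a plate is the grand mean (over all plates) of the
    per-injection QC total intensity divided by the mean QC total on that
    plate; all samples on the plate (QC included) are multiplied by it.
    """
    if reference != "grand_mean_qc":
        raise ValueError(f"unknown reference {reference!r}")
    qc_mask = table.is_qc.to_numpy()
    if not qc_mask.any():
        raise ValueError("table contains no QC samples")
    totals = table.intensities.sum(axis=1)
    plates = pd.unique(table.plate)
    empty = [str(p) for p in plates if not (qc_mask & (table.plate == p).to_numpy()).any()]
    if empty:
        raise ValueError(f"plate(s) without QC samples: {empty}")

    cv_before, _ = qc_cv(table)
    grand = totals[table.is_qc].mean()
    factors = {}
    out = table.intensities.copy()
    for p in plates:
        on_plate = (table.plate == p).to_numpy()
        plate_qc_mean = totals[on_plate & qc_mask].mean()
        f = grand / plate_qc_mean
        factors[p] = float(f)
        out.loc[on_plate] = out.loc[on_plate] * f
    normed = FeatureTable(out, table.plate.copy(), table.is_qc.copy(), list(table.species))
    cv_after, _ = qc_cv(normed)
    return normed, NormalizationReport(factors, cv_before, cv_after, reference)


def tag_percent_normalize(table: FeatureTable) -> FeatureTable:
    """Express each TAG as a percentage of the sample's total TAG intensity.

    The output is restricted to TAG features and every row sums to 100.
    """
    tags = table.select_class("TAG")
    if tags.n_features == 0:
        raise ValueError("no TAG features in table")
    totals = tags.intensities.sum(axis=1)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with zero TAG signal: {zero}")
    pct = tags.intensities.div(totals, axis=0) * 100.0
    return FeatureTable(pct, tags.plate, tags.is_qc, list(tags.species))


@dataclass
class Scaler:
    """Column scaling with stored parameters for held-out data.

    ``center``: x - mean; ``pareto``: (x - mean)/sqrt(sd);
    ``unit_variance``: (x - mean)/sd. Zero-variance columns are dropped under
    pareto / unit_variance (with a warning) to keep downstream NIPALS
    well-posed.
    """

    method: str = "pareto"
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None
    keep_: np.ndarray | None = None
    columns: list | None = field(default=None)

    _METHODS = ("center", "pareto", "unit_variance")

    def fit(self, X, columns=None) -> "Scaler":
        if self.method not in self._METHODS:
            raise ValueError(f"unknown scaling method {self.method!r}")
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("scaling requires at least 2 samples")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if self.method == "center":
            keep = np.ones(X.shape[1], dtype=bool)
            scale = np.ones_like(sd)
        else:
            keep = sd > 0
            if not keep.all():
                warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s) under {self.method} scaling")
            scale = np.where(keep, np.sqrt(sd) if self.method == "pareto" else sd, 1.0)
        self.mean_, self.scale_, self.keep_ = mean, scale, keep
        if columns is not None:
            self.columns = [c for c, k in zip(columns, keep) if k]
        return self

    def transform(self, X) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("Scaler not fitted")
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        return Z[:, self.keep_]

    def fit_transform(self, X, columns=None) -> np.ndarray:
        return self.fit(X, columns=columns).transform(X)


def scale_matrix(X, method: str = "pareto", columns=None) -> tuple[np.ndarray, Scaler]:
    """Scale a samples x features matrix, returning the matrix and parameters."""
    scaler = Scaler(method=method)
    return scaler.fit_transform(X, columns=columns), scaler
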