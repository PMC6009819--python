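"""De novo lipogenesis quantification from deuterium enrichment.

During D2O labelling at steady body-water enrichment, newly synthesized
palmitate incorporates deuterium at up to ``n_exchangeable_H`` positions
(22 for C16:0 by the standard mass-isotopomer convention). The
precursor-product simplification then gives the fraction of the palmitate
pool that is de novo at each timepoint as

    fractional_synthesis(t) = palmitate_enrichment(t)
                              / (body_water_enrichment * n_exchangeable_H)

and the fractional synthetic rate (FSR, %/h) as the OLS slope of that
fraction against time over the window where incorporation is linear
(1-4 h after baseline in the feeding protocol emulated here), times 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentTimecourse",
    "DnlEstimate",
    "fractional_synthesis",
    "fsr_linear",
    "de_novo_palmitate",
    "cluster_dnl_regression",
    "RegressionResult",
]

N_EXCHANGEABLE_H_PALMITATE = 22


@dataclass
class EnrichmentTimecourse:
    """Deuterium enrichment of palmitate (and body water) over time.

    ``times`` in hours, strictly increasing; enrichments are molar fractions
    in [0, 1]. ``body_water_enrichment`` may be a scalar (steady state) or a
    per-timepoint array.
    """

    times: np.ndarray
    palmitate_enrichment: np.ndarray
    body_water_enrichment: float | np.ndarray
    n_exchangeable_H: int = N_EXCHANGEABLE_H_PALMITATE

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.palmitate_enrichment = np.asarray(self.palmitate_enrichment, dtype=float)
        if self.times.shape != self.palmitate_enrichment.shape:
            raise ValueError("times and palmitate_enrichment must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        bw = np.asarray(self.body_water_enrichment, dtype=float)
        for name, arr in (("palmitate", self.palmitate_enrichment), ("body water", bw)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} enrichment must lie in [0, 1]")
        if self.n_exchangeable_H < 1:
            raise ValueError("n_exchangeable_H must be >= 1")

    def body_water_at(self, _t=None) -> np.ndarray:
        bw = np.asarray(self.body_water_enrichment, dtype=float)
        return np.broadcast_to(bw, self.times.shape)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "time_h": self.times,
                "palmitate_enrichment": self.palmitate_enrichment,
                "body_water_enrichment": self.body_water_at(),
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, n_exchangeable_H: int = N_EXCHANGEABLE_H_PALMITATE):
        df = pd.read_csv(path, sep="\t")
        bw = df["body_water_enrichment"].to_numpy()
        bw_val = float(bw[0]) if np.allclose(bw, bw[0]) else bw
        return cls(
            df["time_h"].to_numpy(),
            df["palmitate_enrichment"].to_numpy(),
            bw_val,
            n_exchangeable_H,
        )


@dataclass
class DnlEstimate:
    """FSR estimate (%/h) with OLS diagnostics."""

    fsr: float
    se: float
    r2: float
    intercept: float
    n_points: int
    window: tuple[float, float]
    negative: bool = field(default=False)

    def to_dict(self) -> dict:
        return {
            "fsr_pct_per_h": self.fsr,
            "se": self.se,
            "r2": self.r2,
            "intercept": self.intercept,
            "n_points": self.n_points,
            "window_h": list(self.window),
            "negative_estimate": self.negative,
        }


def fractional_synthesis(tc: EnrichmentTimecourse) -> np.ndarray:
    """Fraction of the palmitate pool that is de novo, per timepoint."""
    bw = tc.body_water_at()
    if np.any(bw <= 0):
        raise ValueError("body_water_enrichment must be positive")
    return tc.palmitate_enrichment / (bw * tc.n_exchangeable_H)


def fsr_linear(tc: EnrichmentTimecourse, window: tuple[float, float] = (1.0, 4.0)) -> DnlEstimate:
    """FSR in %/h: OLS slope of fractional synthesis vs time over ``window``."""
    t0, t1 = window
    mask = (tc.times >= t0) & (tc.times <= t1)
    if mask.sum() < 2:
        raise ValueError(f"need >= 2 timepoints in window {window}, have {int(mask.sum())}")
    t = tc.times[mask]
    frac = fractional_synthesis(tc)[mask]
    fit = stats.linregress(t, frac)
    fsr = float(fit.slope * 100.0)
    return DnlEstimate(
        fsr=fsr,
        se=float(fit.stderr * 100.0) if np.isfinite(fit.stderr) else float("nan"),
        r2=float(fit.rvalue**2),
        intercept=float(fit.intercept * 100.0),
        n_points=int(mask.sum()),
        window=(float(t0), float(t1)),
        negative=fsr < 0,
    )


def de_novo_palmitate(fraction, palmitate_pool):
    """Mass of de novo palmitate: fraction x pool size (units of the pool)."""
    fraction = np.asarray(fraction, dtype=float)
    pool = np.asarray(palmitate_pool, dtype=float)
    if np.any(pool < 0):
        raise ValueError("palmitate pool must be >= 0")
    return fraction * pool


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    se: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "p": self.p,
            "se": self.se,
            "n": self.n,
        }


def cluster_dnl_regression(cluster_signal, dnl) -> RegressionResult:
    """Simple OLS of summed TAG-cluster signal on a DNL measure.

    Two-sided slope test; raises on a zero-variance predictor.
    """
    y = np.asarray(cluster_signal, dtype=float)
    x = np.asarray(dnl, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("cluster_signal and dnl must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance DNL predictor")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p=float(fit.pvalue),
        se=float(fit.stderr),
        n=int(x.size),
    )
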