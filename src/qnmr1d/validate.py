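"""Method-validation statistics under intermediate precision conditions
(OIV-OENO 418-2013 style).

Covers: correction-factor regression, intra-laboratory reproducibility

    S_RW = sqrt(s_xbar^2 + (1 - 1/p) * s_r^2),   CV%_{k=2} = 2*100*S_RW/xbar,

bias uncertainty u_bias = sqrt(u_MTD^2 + sum(u_ref_i^2)/p), the linear
combined model u(x) = sqrt(u_bias^2 + u_prec^2) with expanded uncertainty
U_{k=2} = 2 u(x), trueness compliance against the maximum allowable
deviation (MAD), Thompson's dynamic uncertainty model
U(x) = sqrt(alpha^2/x^2 + beta^2), and limits of quantification (LOQ) by
the 60%-uncertainty rule or by signal-to-noise scaling.

Unit conventions: the precision/bias/linear-uncertainty quantities operate
in percent; the dynamic model and its LOQ operate in fractional units with
threshold 0.60 (the convention under which published alpha/beta pairs
reproduce their printed LOQs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "PrecisionResult",
    "BiasInputs",
    "UncertaintyLinear",
    "DynamicModel",
    "TruenessResult",
    "fit_cf",
    "precision",
    "bias_u",
    "combined_u",
    "trueness",
    "fit_dynamic",
    "propose_inflection_pair",
    "loq_dynamic",
    "loq_snr",
    "accuracy_profile",
    "u_mtd_from_mad",
    "round_to_step",
    "reference_validation_table",
    "LOQ_UNCERTAINTY_THRESHOLD",
    "LOQ_SNR_TARGET",
]

#: relative expanded uncertainty (fraction) defining the LOQ
LOQ_UNCERTAINTY_THRESHOLD = 0.60
#: signal-to-noise ratio defining the alternative LOQ
LOQ_SNR_TARGET = 10.0
#: reporting granularity for dynamic-model LOQs (mg/L)
LOQ_ROUND_STEP = 5.0


@dataclass
class PrecisionResult:
    s_xbar: float   # SD of series means, mg/L
    s_r: float      # repeatability SD, mg/L
    s_rw: float     # intra-laboratory reproducibility SD, mg/L
    xbar: float     # grand mean, mg/L
    u_prec: float   # 100 * S_RW / xbar, %
    cv_k2: float    # 2 * u_prec, %
    p: int
    n_series: int


@dataclass
class BiasInputs:
    u_mtd: float                      # %, standard uncertainty of the MAD
    u_ref: Sequence[float] = field(default_factory=list)  # % per material
    p: int = 1

    def __post_init__(self) -> None:
        if self.u_mtd < 0 or any(u < 0 for u in self.u_ref) or self.p < 1:
            raise ValueError("bias inputs must be non-negative, p >= 1")


@dataclass
class UncertaintyLinear:
    u_bias: float
    u_prec: float
    u: float
    u_k2: float


@dataclass
class DynamicModel:
    """Thompson's dynamic uncertainty model U(x) = sqrt(a^2/x^2 + b^2)
    (fractional units)."""

    alpha: float
    beta: float
    x1: float = float("nan")
    x2: float = float("nan")
    y1: float = float("nan")
    y2: float = float("nan")

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not 0.0 <= self.beta < LOQ_UNCERTAINTY_THRESHOLD:
            raise ValueError("beta must lie in [0, 0.6)")

    def u(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = np.sqrt(self.alpha ** 2 / x ** 2 + self.beta ** 2)
        return float(out) if out.ndim == 0 else out


@dataclass
class TruenessResult:
    b: float        # relative bias, %
    cv_k2: float    # %
    mad: float      # %
    passed: bool


# ---------------------------------------------------------------------------
# Correction factor
# ---------------------------------------------------------------------------

def fit_cf(measured: Sequence[float], spiked: Sequence[float]) -> dict:
    """Correction factor from the standard-addition design: ordinary
    least-squares regression predicting spiked (true) concentrations from
    measured ones; the slope is the CF."""
    measured = np.asarray(measured, dtype=float)
    spiked = np.asarray(spiked, dtype=float)
    if measured.size < 3 or measured.size != spiked.size:
        raise ValueError("need >= 3 paired points")
    if np.ptp(measured) == 0:
        raise ValueError("measured values have zero variance")
    res = linregress(measured, spiked)
    return {"CF": float(res.slope), "intercept": float(res.intercept),
            "R2": float(res.rvalue ** 2)}


# ---------------------------------------------------------------------------
# Precision / bias / combined uncertainty
# ---------------------------------------------------------------------------

def precision(measured: np.ndarray) -> PrecisionResult:
    """Intermediate-precision statistics for one concentration level.

    ``measured`` has shape (n_series, p): n independent series of p
    replicates (balanced design).  s_xbar is the SD of the series means,
    s_r^2 the mean within-series variance.
    """
    m = np.asarray(measured, dtype=float)
    if m.ndim != 2:
        raise ValueError("measured must be (n_series, p)")
    n, p = m.shape
    if n < 2 or p < 1:
        raise ValueError("need >= 2 series with >= 1 replicate")
    means = m.mean(axis=1)
    s_xbar = float(np.std(means, ddof=1))
    s_r2 = float(np.mean(np.var(m, axis=1, ddof=1))) if p >= 2 else 0.0
    s_rw = math.sqrt(s_xbar ** 2 + (1.0 - 1.0 / p) * s_r2)
    xbar = float(m.mean())
    u_prec = 100.0 * s_rw / xbar
    return PrecisionResult(s_xbar=s_xbar, s_r=math.sqrt(s_r2), s_rw=s_rw,
                           xbar=xbar, u_prec=u_prec, cv_k2=2.0 * u_prec,
                           p=p, n_series=n)


def bias_u(inputs: BiasInputs) -> float:
    """u_bias = sqrt(u_MTD^2 + sum(u_ref_i^2)/p), in percent."""
    return math.sqrt(inputs.u_mtd ** 2 +
                     sum(u ** 2 for u in inputs.u_ref) / inputs.p)


def combined_u(u_bias: float, u_prec: float) -> UncertaintyLinear:
    """Linear uncertainty model: u = sqrt(u_bias^2 + u_prec^2),
    U_{k=2} = 2u (percent)."""
    if u_bias < 0 or u_prec < 0:
        raise ValueError("uncertainty components must be non-negative")
    u = math.sqrt(u_bias ** 2 + u_prec ** 2)
    return UncertaintyLinear(u_bias=u_bias, u_prec=u_prec, u=u, u_k2=2.0 * u)


def u_mtd_from_mad(mad_pct: float) -> float:
    """Standard uncertainty of the maximum tolerated deviation under a
    rectangular-distribution reading: MAD / sqrt(3).  An interpretation,
    offered as a helper."""
    return mad_pct / math.sqrt(3.0)


def trueness(b: float, cv_k2: float, mad: float) -> TruenessResult:
    """Trueness compliance: +MAD > b + CV% and -MAD < b - CV%, both
    strict."""
    if mad <= 0:
        raise ValueError("MAD must be positive")
    passed = (mad > b + cv_k2) and (-mad < b - cv_k2)
    return TruenessResult(b=b, cv_k2=cv_k2, mad=mad, passed=passed)


# ---------------------------------------------------------------------------
# Dynamic uncertainty model and LOQ
# ---------------------------------------------------------------------------

def propose_inflection_pair(points: Sequence[tuple[float, float]]) -> tuple[int, int]:
    """Suggest the two lowest-x points with decreasing CV as the inflection
    pair for :func:`fit_dynamic`."""
    order = sorted(range(len(points)), key=lambda i: points[i][0])
    for a, b in zip(order, order[1:]):
        if points[a][1] > points[b][1]:
            return a, b
    raise ValueError("no decreasing CV pair found at low concentration")


def fit_dynamic(
    points: Sequence[tuple[float, float]],
    inflection_pair: tuple[int, int],
    stabilized: Sequence[int],
) -> DynamicModel:
    """Fit Thompson's model from (concentration, CV%_{k=2} as fraction)
    points.

    alpha comes from the two points (x1 < x2) at the inflection of the
    low-concentration rise, alpha = x1*x2*sqrt((y1^2-y2^2)/(x2^2-x1^2));
    beta is the mean CV over the explicitly designated stabilised
    high-concentration subset.
    """
    i, j = inflection_pair
    (x1, y1), (x2, y2) = points[i], points[j]
    if x1 > x2:
        (x1, y1), (x2, y2) = (x2, y2), (x1, y1)
    if y1 <= y2:
        raise ValueError(
            "CV must decrease between the two inflection points (y1 > y2)"
        )
    if not stabilized:
        raise ValueError("the stabilised subset must be designated explicitly")
    alpha = x1 * x2 * math.sqrt((y1 ** 2 - y2 ** 2) / (x2 ** 2 - x1 ** 2))
    beta = float(np.mean([points[k][1] for k in stabilized]))
    return DynamicModel(alpha=alpha, beta=beta, x1=x1, x2=x2, y1=y1, y2=y2)


def round_to_step(x: float, step: float = LOQ_ROUND_STEP) -> float:
    return step * math.floor(x / step + 0.5)


def loq_dynamic(
    model: DynamicModel,
    threshold: float = LOQ_UNCERTAINTY_THRESHOLD,
) -> dict:
    """Concentration at which U(x) reaches the threshold (default 60%):
    x = alpha / sqrt(threshold^2 - beta^2).  Returns the raw value and the
    value rounded to the nearest 5 mg/L."""
    if model.beta >= threshold:
        raise ValueError("beta >= threshold: U(x) never falls to the threshold")
    raw = model.alpha / math.sqrt(threshold ** 2 - model.beta ** 2)
    return {"raw_mgL": raw, "rounded_mgL": round_to_step(raw)}


def loq_snr(
    snr_observed: float,
    conc_observed_mgL: float,
    target_snr: float = LOQ_SNR_TARGET,
) -> float:
    """LOQ from an observed signal-to-noise ratio at a known concentration,
    assuming linear signal-concentration scaling: the concentration at
    which S/N would equal ``target_snr`` (default 10)."""
    if snr_observed <= 0:
        raise ValueError("snr_observed must be positive")
    return conc_observed_mgL * target_snr / snr_observed


# ---------------------------------------------------------------------------
# Accuracy profile
# ---------------------------------------------------------------------------

def accuracy_profile(
    data: pd.DataFrame,
    mad_pct: dict,
    linear_model: Optional[UncertaintyLinear] = None,
    dynamic_model: Optional[DynamicModel] = None,
) -> pd.DataFrame:
    """Tidy accuracy-profile table for one compound.

    ``data`` needs columns level_mgL, series, replicate, measured_mgL;
    ``mad_pct`` maps each level to its MAD (percent).  The output holds one
    ``series_bias`` row per (level, series) -- the mean relative deviation
    of that series, annotated with the level's overall bias b, CV%_{k=2}
    and MAD bounds -- plus one row per supplied uncertainty model per level
    sampling its expanded-uncertainty curve.  Row count:
    levels x series + levels x models.
    """
    rows = []
    for level, grp in data.groupby("level_mgL"):
        pivot = grp.pivot_table(index="series", columns="replicate",
                                values="measured_mgL")
        m = pivot.to_numpy()
        prec = precision(m)
        b = 100.0 * (prec.xbar - level) / level
        mad = float(mad_pct[level])
        for series, series_grp in grp.groupby("series"):
            dev = 100.0 * (series_grp["measured_mgL"].mean() - level) / level
            rows.append({
                "kind": "series_bias", "level_mgL": level, "series": series,
                "value_pct": dev, "b_pct": b, "cv_k2_pct": prec.cv_k2,
                "mad_pct": mad,
            })
        if linear_model is not None:
            rows.append({"kind": "linear_U", "level_mgL": level,
                         "series": None, "value_pct": linear_model.u_k2,
                         "b_pct": b, "cv_k2_pct": prec.cv_k2, "mad_pct": mad})
        if dynamic_model is not None:
            rows.append({"kind": "dynamic_U", "level_mgL": level,
                         "series": None,
                         "value_pct": 100.0 * float(dynamic_model.u(level)),
                         "b_pct": b, "cv_k2_pct": prec.cv_k2, "mad_pct": mad})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference parameter set
# ---------------------------------------------------------------------------

#: Validation parameters established for the 21 target signals on the
#: reference red-wine material (500 MHz instrument): per-signal correction
#: factor CF with calibration R^2, mean relative bias mu(b) %, mean
#: precision uncertainty mu(u_prec) %, bias uncertainty u_bias %, expanded
#: linear uncertainty U_{k=2} %, dynamic-model parameters (alpha mg/L,
#: beta fraction) where applicable, and the reported LOQ in mg/L
#: (loq_method "dynamic": 60%-uncertainty rule; "snr": S/N = 10).
_REFERENCE_ROWS = [
    # compound, CF, R2, mu_b, mu_uprec, u_bias, U_k2, alpha, beta, LOQ, method
    ("3-methylbutan-1-ol", 0.75, 0.998, -15.86, 3.42, 15.30, 31.36, None, None, 10, "snr"),
    ("acetic acid",        0.55, 0.979, -23.10, 2.25, 20.22, 40.69, None, None, 1, "snr"),
    ("glucose (alpha signal)", 2.30, 0.992, 5.03, 4.40, 10.44, 22.66, None, None, 40, "snr"),
    ("glucose (beta signal)",  1.25, 0.967, -0.27, 3.57, 10.44, 22.07, None, None, 15, "snr"),
    ("glucose (alpha+beta)",   0.80, 0.983, -0.35, 3.47, 12.85, 26.62, None, None, None, None),
    ("caffeic acid",       0.80, 0.950, -19.68, 18.93, 10.44, 43.24, 6.5039, 0.0757, 10, "dynamic"),
    ("catechin",           0.90, 0.999, 2.13, 4.34, 8.08, 18.34, 8.5548, 0.0430, 15, "dynamic"),
    ("epicatechin",        0.75, 0.998, -6.83, 9.99, 10.44, 28.90, 11.5328, 0.0873, 20, "dynamic"),
    ("ethyl acetate",      0.95, 0.982, -31.19, 13.86, 30.15, 66.37, 24.9662, 0.1991, 45, "dynamic"),
    ("ethyl lactate",      0.90, 0.955, -9.06, 11.60, 22.70, 50.98, None, None, 5, "snr"),
    ("formic acid",        0.75, 1.000, -4.19, 5.93, 10.44, 24.01, 0.6999, 0.0465, 1, "dynamic"),
    ("fructose",           2.20, 0.997, -3.91, 2.36, 10.44, 21.41, None, None, 20, "snr"),
    ("fumaric acid",       0.80, 0.997, 8.37, 6.99, 10.44, 25.13, 1.4600, 0.0800, 5, "dynamic"),
    ("galacturonic acid",  1.95, 0.998, -2.47, 1.62, 8.08, 16.48, None, None, 50, "snr"),
    ("gallic acid",        0.75, 0.994, -10.24, 6.83, 17.76, 38.06, None, None, 1, "snr"),
    ("malic acid",         1.10, 0.988, -0.19, 8.86, 20.22, 44.15, 5.8189, 0.1091, 10, "dynamic"),
    ("shikimic acid",      0.75, 0.999, 6.98, 4.63, 5.83, 14.89, 4.6924, 0.0419, 10, "dynamic"),
    ("sorbic acid",        0.90, 0.999, 8.08, 6.69, 10.44, 24.80, 5.9122, 0.0902, 10, "dynamic"),
    ("succinic acid",      1.05, 0.955, 3.25, 4.67, 15.30, 31.99, None, None, 1, "snr"),
    ("trigonelline",       0.90, 0.975, -0.03, 3.80, 5.83, 13.92, 3.0739, 0.0280, 5, "dynamic"),
    ("glycerol",           1.25, 0.990, 39.27, 2.46, 25.18, 50.60, None, None, 1, "snr"),
    ("methanol",           0.60, 0.997, -34.55, 2.58, 25.18, 50.62, None, None, 15, "snr"),
]


def reference_validation_table() -> pd.DataFrame:
    """Reference validation parameter set for the wine workflow (see module
    docstring of the row constant for column meanings)."""
    cols = ["compound", "cf", "r2", "mu_b_pct", "mu_uprec_pct", "u_bias_pct",
            "u_k2_pct", "alpha", "beta", "loq_mgL", "loq_method"]
    return pd.DataFrame(_REFERENCE_ROWS, columns=cols)
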