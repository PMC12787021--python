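"""PULCON external-standard calibration and compound quantification.

PULCON (pulse length-based concentration determination) relates absolute
integrals across spectra acquired on the same instrument.  A quantification
reference sample (QR) of exactly known composition defines the spectrometer
response per proton,

    f_PULCON = I_ref * K * MW_ref / (NH_ref * MC_ref),   K = SW_ref / SI_ref,

where I_ref is the absolute integral (point-sum) of a reference resonance,
SW the spectral width in Hz, and SI the real spectrum size.  The factor is
verified by two gates: the per-standard factors (citrate vs DMMA) must agree
to better than 5% (QR consistency), and an independently prepared quality
control sample (QC) must be recovered within +-8% of its nominal
concentrations.  Wine concentrations then follow from

    C_x = I_x*SW_x*MW_x*NS_ref*P1_x / (SI_x*f_PULCON*NH_x*NS_x*P1_ref)
          / f_dil * CF,

with f_dil the wine volume fraction in the tube (0.8 for the 800 uL wine +
200 uL additions preparation) and CF the empirical correction factor
absorbing relaxation/suppression losses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .peakproc import baseline_airpls, estimate_noise, fit_peaks, pick_peaks, \
    denoise_wavelet, NOISE_WINDOW_DEFAULT
from .preprocess import Spectrum
from .profilematch import MatchResult, QuantProfile, extract_areas, process_rois

__all__ = [
    "CalibRow",
    "PulconFactor",
    "QuantResult",
    "CalibrationError",
    "load_calibration",
    "default_calibration",
    "roi_integral",
    "pulcon_factor",
    "pulcon_factor_value",
    "check_qr",
    "qr_ok",
    "check_qc",
    "qc_recovery_ok",
    "quantify",
    "quantify_spectrum",
    "F_DIL_DEFAULT",
    "QR_REL_DIFF_LIMIT",
    "QC_RECOVERY_TOL",
]

#: wine volume fraction in the measurement tube (800 uL wine / 1000 uL total)
F_DIL_DEFAULT = 0.8
#: QR gate: relative difference between per-standard PULCON factors, strict.
QR_REL_DIFF_LIMIT = 0.05
#: QC gate: recovery tolerance, inclusive at the boundary.
QC_RECOVERY_TOL = 0.08


class CalibrationError(RuntimeError):
    pass


class CalibRow(BaseModel):
    """One row of the external-standard calibration profile."""

    sample: Literal["QR", "QC"]
    compound: str
    mw: float = Field(gt=0)       # g/mol
    nh: int = Field(ge=1)         # protons contributing to the resonance
    mc: float = Field(gt=0)       # exact mass concentration, mg/L
    ppm1: float
    ppm2: float

    @model_validator(mode="after")
    def _check(self):
        if self.ppm1 >= self.ppm2:
            raise ValueError(f"{self.compound}: ppm1 must be < ppm2")
        return self

    @property
    def standard(self) -> str:
        """Standard identity with any trailing ROI index stripped
        (Citrate1/Citrate2 are two halves of one citrate AB system)."""
        return re.sub(r"\d+$", "", self.compound)


@dataclass
class PulconFactor:
    """Spectrometer response per proton per unit mass concentration."""

    value: float
    k: float                         # SW_ref / SI_ref
    per_standard: dict = field(default_factory=dict)
    ns_ref: float = 1.0
    p1_ref_us: float = 10.0
    rg_ref: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0 or self.k <= 0:
            raise ValueError("PULCON factor and K must be positive")


@dataclass
class QuantResult:
    compound: str
    raw_tube_mgL: float
    cf: float
    f_dil: float
    conc_mgL: float
    flags: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# Calibration profile
# ---------------------------------------------------------------------------

#: external-standard composition used by the reference wine workflow
_DEFAULT_CALIB = [
    ("QC", "DMMA", 132.11, 6, 999.437, 1.300, 1.500),
    ("QC", "Succinate", 118.09, 4, 501.395, 2.600, 2.735),
    ("QC", "Citrate1", 210.14, 2, 2811.870, 2.735, 2.910),
    ("QC", "Citrate2", 210.14, 2, 2811.870, 2.910, 3.100),
    ("QR", "DMMA", 132.11, 6, 999.437, 1.300, 1.500),
    ("QR", "Citrate1", 210.14, 2, 3514.838, 2.735, 2.910),
    ("QR", "Citrate2", 210.14, 2, 3514.838, 2.910, 3.100),
]


def default_calibration() -> list[CalibRow]:
    """Bundled calibration profile: QR (citrate + DMMA) and QC (citrate +
    DMMA + succinate) standard compositions."""
    cols = ("sample", "compound", "mw", "nh", "mc", "ppm1", "ppm2")
    return [CalibRow(**dict(zip(cols, row))) for row in _DEFAULT_CALIB]


def load_calibration(path: str | Path) -> list[CalibRow]:
    """Read a calibration profile CSV (columns: sample, compound, MW, NH,
    MC, ppm1, ppm2; case-insensitive)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return [CalibRow(**{k: row[k] for k in
                        ("sample", "compound", "mw", "nh", "mc", "ppm1", "ppm2")})
            for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# PULCON factor
# ---------------------------------------------------------------------------

def roi_integral(
    spectrum: Spectrum,
    ppm1: float,
    ppm2: float,
    noise_sd: Optional[float] = None,
    airpls_lambda: float = 1e5,
) -> float:
    """Absolute integral (point-sum convention, intensity units) of all
    deconvolved peaks in [ppm1, ppm2]."""
    if noise_sd is None:
        noise_sd = estimate_noise(spectrum, NOISE_WINDOW_DEFAULT)
    idx = spectrum.window(ppm1, ppm2)
    if idx.size < 10:
        raise CalibrationError(f"ROI {ppm1}-{ppm2} ppm outside the spectrum")
    y = np.real(spectrum.intensity[idx])
    x = spectrum.ppm[idx]
    _, corrected = baseline_airpls(y, lam=airpls_lambda, noise_sd=noise_sd)
    cand = pick_peaks(denoise_wavelet(corrected), noise_sd)
    if cand.size == 0:
        raise CalibrationError(f"no signal found in ROI {ppm1}-{ppm2} ppm")
    freq = float(spectrum.meta["spectrometer_freq"])
    report = fit_peaks(x, corrected, cand, freq, fit_asym=False)
    area_hz = sum(p.area for p in report.peaks)
    return area_hz * spectrum.si / spectrum.sw_hz


def pulcon_factor_value(i_ref: float, k: float, mw: float, nh: float,
                        mc: float) -> float:
    """f_PULCON = I_ref * K * MW_ref / (NH_ref * MC_ref)."""
    return i_ref * k * mw / (nh * mc)


def pulcon_factor(
    qr_spectrum: Spectrum,
    rows: list[CalibRow],
) -> PulconFactor:
    """Compute the PULCON factor from a processed QR spectrum.

    Each standard's ROIs are deconvolved; rows belonging to one standard
    (e.g. Citrate1/Citrate2) have their integrals and proton counts summed
    before the factor formula.  Per-standard factors are combined by
    arithmetic mean (check with :func:`check_qr` first).
    """
    qr_rows = [r for r in rows if r.sample == "QR"]
    if not qr_rows:
        raise CalibrationError("no QR rows in the calibration profile")
    k = qr_spectrum.sw_hz / qr_spectrum.si
    noise_sd = estimate_noise(qr_spectrum, NOISE_WINDOW_DEFAULT)
    grouped: dict[str, dict] = {}
    for r in qr_rows:
        g = grouped.setdefault(r.standard, {"I": 0.0, "nh": 0, "mw": r.mw,
                                            "mc": r.mc})
        g["I"] += roi_integral(qr_spectrum, r.ppm1, r.ppm2, noise_sd)
        g["nh"] += r.nh
    per_standard = {
        name: pulcon_factor_value(g["I"], k, g["mw"], g["nh"], g["mc"])
        for name, g in grouped.items()
    }
    meta = qr_spectrum.meta
    return PulconFactor(
        value=float(np.mean(list(per_standard.values()))),
        k=k,
        per_standard=per_standard,
        ns_ref=float(meta.get("NS", 1)),
        p1_ref_us=float(meta.get("P1_us", 10.0)),
        rg_ref=float(meta.get("RG", 1)),
        source=str(meta.get("source", "")),
    )


def qr_ok(rel_diff: float) -> bool:
    """QR consistency rule: the citrate/DMMA factor difference must remain
    strictly below 5%."""
    return rel_diff < QR_REL_DIFF_LIMIT


def check_qr(per_standard: dict) -> dict:
    """Relative difference between per-standard PULCON factors (symmetric:
    |f1 - f2| / mean; max pairwise for >2 standards)."""
    vals = list(per_standard.values())
    if len(vals) < 2:
        raise ValueError("QR check requires at least two per-standard factors")
    mean = float(np.mean(vals))
    rel_diff = (max(vals) - min(vals)) / mean
    return {"rel_diff": rel_diff, "passed": qr_ok(rel_diff)}


def qc_recovery_ok(recovery: float) -> bool:
    """QC rule: measured/nominal within +-8%, inclusive at the boundary
    (exactly 8% passes; the epsilon keeps the inclusive boundary robust to
    floating-point representation)."""
    return abs(recovery - 1.0) <= QC_RECOVERY_TOL + 1e-12


def check_qc(qc_measured: dict, rows: list[CalibRow]) -> dict:
    """Compare QC concentrations quantified with the current factor against
    their nominal preparation values."""
    nominal: dict[str, float] = {}
    for r in rows:
        if r.sample == "QC":
            nominal[r.standard] = r.mc
    recoveries: dict[str, float] = {}
    reasons = []
    for name, mc in nominal.items():
        if name not in qc_measured:
            reasons.append(f"QC compound {name} not quantified")
            continue
        recoveries[name] = qc_measured[name] / mc
    passed = not reasons and all(qc_recovery_ok(r) for r in recoveries.values())
    return {"recovery": recoveries, "passed": passed,
            "reason": "; ".join(reasons) or None}


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def quantify(
    match: MatchResult,
    sample_meta: dict,
    factor: PulconFactor,
    mw: float,
    sw_hz: float,
    si: int,
    cf: Optional[float] = None,
    f_dil: float = F_DIL_DEFAULT,
    rg_override_ratio: Optional[float] = None,
) -> QuantResult:
    """Concentration of one matched compound in the original wine (mg/L).

    ``match`` supplies the absolute integral I_x (per-proton area times the
    matched proton weight) and NH_x (the matched weight); NS/P1 normalise
    for scans and pulse length against the reference acquisition.  CF
    multiplies; the dilution factor f_dil (wine volume fraction, in (0, 1])
    divides, restoring the concentration in the undiluted wine.  A missing
    CF is treated as 1 and flagged ``uncorrected``.  Quantification across
    different receiver gains is refused unless an explicit override ratio
    (RG_ref / RG_x) is supplied.
    """
    if not (0.0 < f_dil <= 1.0):
        raise ValueError("f_dil must lie in (0, 1]")
    if not match.matched:
        raise ValueError(f"{match.compound}: no matched area to quantify")
    flags = set(match.flags)
    if cf is None:
        cf = 1.0
        flags.add("uncorrected")

    rg_x = float(sample_meta.get("RG", factor.rg_ref))
    rg_ratio = 1.0
    if rg_x != factor.rg_ref:
        if rg_override_ratio is None:
            raise ValueError(
                "receiver gain differs between sample and reference; "
                "supply rg_override_ratio to quantify anyway"
            )
        rg_ratio = rg_override_ratio

    area_hz = match.per_proton_area * match.matched_weight
    i_x = area_hz * si / sw_hz  # point-sum absolute integral
    ns_x = float(sample_meta.get("NS", 1))
    p1_x = float(sample_meta.get("P1_us", factor.p1_ref_us))
    raw = (i_x * sw_hz * mw * factor.ns_ref * p1_x * rg_ratio
           / (si * factor.value * match.matched_weight * ns_x
              * factor.p1_ref_us))
    conc = raw / f_dil * cf
    return QuantResult(compound=match.compound, raw_tube_mgL=raw, cf=cf,
                       f_dil=f_dil, conc_mgL=conc, flags=flags)


def quantify_spectrum(
    spectrum: Spectrum,
    profile: QuantProfile,
    factor: PulconFactor,
    f_dil: float = F_DIL_DEFAULT,
    pulse_program: Optional[str] = None,
    fit_asym: bool = True,
    apply_cf: bool = True,
) -> list[QuantResult]:
    """Full quantification of one processed spectrum: ROI processing,
    pattern matching, and PULCON conversion with the profile's correction
    factors."""
    pp = pulse_program or spectrum.meta.get("pulse_program", "")
    fits = process_rois(spectrum, profile, pulse_program=pp, fit_asym=fit_asym)
    freq = float(spectrum.meta["spectrometer_freq"])
    matches = extract_areas(fits, profile, freq, pulse_program=pp)
    mw_by_compound = {p.compound: p.mw for p in profile.patterns}
    for comb in profile.combinations:
        mws = {mw_by_compound[c] for c in comb["components"]
               if c in mw_by_compound}
        if len(mws) == 1:
            mw_by_compound[comb["name"]] = mws.pop()
    out = []
    for m in matches:
        if not m.matched:
            continue
        cf = profile.correction_factors.get(m.compound) if apply_cf else 1.0
        out.append(quantify(
            m, spectrum.meta, factor, mw=mw_by_compound[m.compound],
            sw_hz=spectrum.sw_hz, si=spectrum.si, cf=cf, f_dil=f_dil,
        ))
    return out
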