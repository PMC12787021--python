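"""Synthetic FIDs, spectra, and validation datasets with known ground truth.

Everything downstream (preprocessing, peak processing, pattern matching,
PULCON quantification, validation statistics) is testable against spectra
rendered here: first-order multiplets at Table-style chemical shifts with
pseudo-Voigt lineshapes, polynomial baseline drift, seeded Gaussian noise,
and intermediate-precision validation sets with prescribed bias and
between-/within-series variance components.

Signal scale convention: a compound at mass concentration ``MC`` (mg/L)
with molecular weight ``MW`` (g/mol) contributes a per-proton line area of
``response * MC / MW`` (intensity * Hz), i.e. the area is proportional to
the molar concentration and the proton count -- the proportionality the
PULCON method relies on.  ``response`` plays the role of the spectrometer
response per proton and cancels between reference and sample.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .peakproc import PeakModel, peak_area, pseudo_voigt
from .preprocess import Fid, Spectrum
from .profilematch import PatternSpec, multiplet_lines

__all__ = [
    "LineshapeSpec",
    "AxisSpec",
    "SimPattern",
    "SimSpec",
    "ValidationDesign",
    "render_multiplet",
    "render_spectrum",
    "synth_fid",
    "make_validation_dataset",
    "write_bruker",
    "tmsp_pattern",
    "DEFAULT_RESPONSE",
    "SPECTROMETER_FREQ_MHZ",
    "SW_PPM",
]

#: 1H frequency of the acquisition setup emulated by default (MHz).
SPECTROMETER_FREQ_MHZ = 500.23
#: Default spectral width (ppm).
SW_PPM = 16.0182
#: Arbitrary spectrometer response: line area (intensity*Hz) per proton per
#: mmol/L.  Cancels in PULCON quantification.
DEFAULT_RESPONSE = 1000.0

#: TMSP reference: 9 equivalent methyl protons at 0.0 ppm; MW of the sodium
#: salt in g/mol.
TMSP_MW = 172.27
TMSP_NH = 9.0


class LineshapeSpec(BaseModel):
    """Pseudo-Voigt lineshape parameters shared by all rendered lines."""

    fwhm_hz: float = Field(1.0, gt=0)
    lorentz_fraction: float = Field(0.7, ge=0.0, le=1.0)
    asymmetry: float = 0.0


class AxisSpec(BaseModel):
    ppm_min: float = -1.0
    ppm_max: float = 15.0182
    points: int = Field(65536, ge=2)

    @model_validator(mode="after")
    def _check(self):
        if self.ppm_min >= self.ppm_max:
            raise ValueError("ppm range must be non-empty")
        return self


class SimPattern(BaseModel):
    pattern: PatternSpec
    concentration_mgL: float = Field(gt=0)


class SimSpec(BaseModel):
    """Full description of one synthetic spectrum."""

    patterns: list[SimPattern] = Field(default_factory=list)
    lineshape: LineshapeSpec = Field(default_factory=LineshapeSpec)
    noise_sd: float = Field(0.0, ge=0)
    #: baseline polynomial coefficients (ascending powers of ppm - centre)
    baseline: list[float] = Field(default_factory=lambda: [0.0])
    axis: AxisSpec = Field(default_factory=AxisSpec)
    spectrometer_freq: float = Field(SPECTROMETER_FREQ_MHZ, gt=0)
    response: float = Field(DEFAULT_RESPONSE, gt=0)
    seed: int = 0
    ns: int = 64
    ds: int = 8
    rg: float = 64.0
    p1_us: float = 10.0
    pulse_program: str = "noesygpps1d"


class ValidationDesign(BaseModel):
    """Intermediate-precision validation design: ``n_series`` independent
    series of ``p_reps`` replicates at each nominal level, with relative
    bias and between-/within-series variance components (as fractions of
    nominal)."""

    levels: list[float]
    n_series: int = Field(5, ge=2)
    p_reps: int = Field(3, ge=1)
    rel_bias: float = 0.0
    between_sd: float = Field(0.0, ge=0)
    within_sd: float = Field(0.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not self.levels or any(x <= 0 for x in self.levels):
            raise ValueError("all nominal levels must be positive")
        return self


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_multiplet(
    pattern: PatternSpec,
    per_proton_area: float,
    freq_mhz: float,
) -> list[tuple[float, float]]:
    """Expand a signature into (line position ppm, line area) pairs.

    Line positions follow first-order splitting; total area equals
    ``per_proton_area`` times the pattern's proton weight.
    """
    if per_proton_area <= 0:
        raise ValueError("per_proton_area must be positive")
    out = []
    for sub in pattern.sub_signals:
        sub_area = per_proton_area * sub.proton_weight
        for ppm, frac in multiplet_lines(sub, freq_mhz):
            out.append((ppm, sub_area * frac))
    return out


def _lines_for(spec: SimSpec) -> list[tuple[float, float]]:
    lines = []
    for sp in spec.patterns:
        ppa = spec.response * sp.concentration_mgL / sp.pattern.mw
        lines.extend(render_multiplet(sp.pattern, ppa, spec.spectrometer_freq))
    return lines


def render_spectrum(spec: SimSpec) -> Spectrum:
    """Render a frequency-domain spectrum directly: sum of pseudo-Voigt
    lines + baseline polynomial + seeded white Gaussian noise."""
    ax = spec.axis
    ppm = np.linspace(ax.ppm_max, ax.ppm_min, ax.points)  # descending
    x_hz = ppm * spec.spectrometer_freq
    sw_hz = (ax.ppm_max - ax.ppm_min) * spec.spectrometer_freq
    ls = spec.lineshape
    unit = PeakModel(center_ppm=0.0, amplitude=1.0, fwhm_hz=ls.fwhm_hz,
                     eta=ls.lorentz_fraction, asym=ls.asymmetry)
    unit_area = peak_area(unit)
    y = np.zeros_like(ppm)
    for line_ppm, line_area in _lines_for(spec):
        amp = line_area / unit_area
        y += pseudo_voigt(x_hz, amp, line_ppm * spec.spectrometer_freq,
                          ls.fwhm_hz, ls.lorentz_fraction, ls.asymmetry)
    centre = 0.5 * (ax.ppm_max + ax.ppm_min)
    y += np.polynomial.polynomial.polyval(ppm - centre, spec.baseline)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    meta = {
        "NS": spec.ns, "DS": spec.ds, "RG": spec.rg, "P1_us": spec.p1_us,
        "spectrometer_freq": spec.spectrometer_freq,
        "pulse_program": spec.pulse_program, "SW_ppm": ax.ppm_max - ax.ppm_min,
        "source": "simulated",
    }
    return Spectrum(intensity=y, ppm=ppm, sw_hz=sw_hz, meta=meta)


def synth_fid(spec: SimSpec) -> Fid:
    """Synthesize a complex time-domain FID of decaying oscillators.

    Only pure Lorentzian symmetric lineshapes (eta = 1, no asymmetry) have
    an exact exponential time-domain counterpart; other requests are
    rejected.  The FID holds ``axis.points / 2`` complex samples so that a
    single zero-fill in :func:`qnmr1d.preprocess.transform` reproduces the
    requested axis.  ``noise_sd`` is scaled so the post-FT real-part noise
    has approximately that standard deviation.
    """
    ls = spec.lineshape
    if ls.lorentz_fraction != 1.0 or ls.asymmetry != 0.0:
        raise ValueError(
            "synth_fid supports only symmetric Lorentzian lineshapes (eta=1)"
        )
    ax = spec.axis
    n_complex = ax.points // 2
    if n_complex < 2:
        raise ValueError("axis too short for a time-domain signal")
    sw_hz = (ax.ppm_max - ax.ppm_min) * spec.spectrometer_freq
    o1_ppm = 0.5 * (ax.ppm_max + ax.ppm_min)
    dt = 1.0 / sw_hz
    t = np.arange(n_complex) * dt
    r2 = math.pi * ls.fwhm_hz
    data = np.zeros(n_complex, dtype=complex)
    for line_ppm, line_area in _lines_for(spec):
        f_hz = (line_ppm - o1_ppm) * spec.spectrometer_freq
        # factor 2: the one-sided FT of a causal oscillator puts half the
        # amplitude into the absorption part, so the post-FT line area in Hz
        # equals the requested area only with this compensation
        data += 2.0 * line_area * np.exp((2j * math.pi * f_hz - r2) * t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        sigma_t = spec.noise_sd / (dt * math.sqrt(ax.points))
        data = data + sigma_t * (rng.standard_normal(n_complex)
                                 + 1j * rng.standard_normal(n_complex))
    meta = {
        "NS": spec.ns, "DS": spec.ds, "RG": spec.rg, "P1_us": spec.p1_us,
        "pulse_program": spec.pulse_program, "GRPDLY": 0,
    }
    return Fid(data=data, sw_hz=sw_hz, spectrometer_freq=spec.spectrometer_freq,
               o1_ppm=o1_ppm, meta=meta)


def tmsp_pattern(concentration_mgL: float = 700.0) -> "SimPattern":
    """TMSP chemical-shift reference as a simulation ingredient (9H singlet
    at 0.0 ppm)."""
    pat = PatternSpec(
        compound="tmsp", mw=TMSP_MW,
        sub_signals=[{"multiplicity": "s", "center_ppm": 0.0,
                      "proton_weight": TMSP_NH}],
    )
    return SimPattern(pattern=pat, concentration_mgL=concentration_mgL)


# ---------------------------------------------------------------------------
# Validation datasets
# ---------------------------------------------------------------------------

def make_validation_dataset(design: ValidationDesign) -> pd.DataFrame:
    """Simulate an intermediate-precision validation set.

    measured[level, series, rep] = nominal * (1 + rel_bias + B_i + W_ij)
    with B_i ~ N(0, between_sd^2) per series and W_ij ~ N(0, within_sd^2)
    per replicate.  Sub-streams are derived deterministically per
    (level, series) from the design seed; ground-truth components are
    stored alongside.
    """
    rows = []
    for li, nominal in enumerate(design.levels):
        for si in range(design.n_series):
            rng = np.random.default_rng([design.seed, li, si])
            b = rng.normal(0.0, design.between_sd) if design.between_sd > 0 else 0.0
            w = (rng.normal(0.0, design.within_sd, size=design.p_reps)
                 if design.within_sd > 0 else np.zeros(design.p_reps))
            for ri in range(design.p_reps):
                rows.append({
                    "level_mgL": nominal, "series": si + 1, "replicate": ri + 1,
                    "measured_mgL": nominal * (1.0 + design.rel_bias + b + w[ri]),
                    "true_rel_bias": design.rel_bias,
                    "true_b_series": b, "true_w_rep": float(w[ri]),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bruker-compatible writer
# ---------------------------------------------------------------------------

def write_bruker(fid: Fid, dir_path: str | Path) -> None:
    """Write a minimal Bruker-compatible experiment directory: int32
    interleaved real/imag ``fid`` plus a flat-text ``acqus``.

    The int32 scaling exponent is stored as ``##$NC=`` so relative
    amplitudes survive the integer round trip.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    inter = np.empty(2 * len(fid.data))
    inter[0::2] = np.real(fid.data)
    inter[1::2] = np.imag(fid.data)
    peak = float(np.max(np.abs(inter), initial=0.0))
    nc = 0 if peak == 0 else max(int(math.ceil(math.log2(peak / 2 ** 28))), -48)
    (inter * 2.0 ** (-nc)).astype("<i4").tofile(dir_path / "fid")

    m = fid.meta
    lines = [
        "##TITLE= minimal acqus",
        f"##$TD= {fid.td}",
        f"##$SW_h= {fid.sw_hz!r}",
        f"##$SFO1= {fid.spectrometer_freq!r}",
        f"##$O1= {fid.o1_ppm * fid.spectrometer_freq!r}",
        f"##$NS= {m.get('NS', 1)}",
        f"##$DS= {m.get('DS', 0)}",
        f"##$RG= {m.get('RG', 1)}",
        f"##$P1= {m.get('P1_us', 10.0)!r}",
        f"##$NC= {nc}",
        f"##$GRPDLY= {m.get('GRPDLY', 0)}",
        "##$BYTORDA= 0",
        f"##$PULPROG= <{m.get('pulse_program', '')}>",
        "##END=",
    ]
    if m.get("d1_s") is not None:
        lines.insert(-1, f"##$D1= {m['d1_s']!r}")
    (dir_path / "acqus").write_text("\n".join(lines) + "\n")


def write_validation_csv(df: pd.DataFrame, path: str | Path,
                         compound: str = "") -> None:
    out = df.copy()
    if compound:
        out.insert(0, "compound", compound)
    out.to_csv(path, index=False)


def write_simspec_json(spec: SimSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec.model_dump(), indent=1))


def load_simspec_json(path: str | Path) -> SimSpec:
    return SimSpec.model_validate(json.loads(Path(path).read_text()))
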