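"""Raw FID handling and spectral preprocessing.

Converts a complex time-domain NMR signal (free induction decay, FID) into a
phased, chemical-shift-calibrated real spectrum:

    read -> apodize (exponential line broadening) -> zero-fill + FFT
         -> automatic zero-order phasing (with TMSP refinement)
         -> ppm calibration on a reference peak

The ppm axis is stored in descending order (NMR display convention).
Spectral intensities carry the discrete-FT scaling ``dt * FFT`` so that the
numeric integral of an absorption line over frequency (in Hz) equals the
initial amplitude of the corresponding time-domain oscillator.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "Fid",
    "Spectrum",
    "read_bruker",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "apodize",
    "transform",
    "autophase",
    "calibrate_ppm",
    "preprocess_fid",
    "DEFAULT_SI",
    "DEFAULT_LB_HZ",
    "DEFAULT_CALIBRATION_TARGET_PPM",
]

#: Real spectrum size after one zero-fill ("128 k").
DEFAULT_SI = 131072
#: Exponential line broadening in Hz applied before the FT.
DEFAULT_LB_HZ = 0.25
#: Central peak of the ethanol triplet's 13C satellite, used for global
#: ppm calibration in wine spectra.
DEFAULT_CALIBRATION_TARGET_PPM = 1.046
DEFAULT_CALIBRATION_WINDOW = (1.02, 1.07)

#: Peak-free flanks around the TMSP resonance used for the zero-order phase
#: refinement, expressed relative to the TMSP window centre (ppm).
TMSP_FLANKS = ((-0.10, -0.03), (0.03, 0.10))

#: acqus keys that must be present to build a Fid.
REQUIRED_ACQUS_KEYS = ("TD", "SW_h", "SFO1", "O1", "NS", "DS", "RG", "P1")


@dataclass
class Fid:
    """Complex time-domain NMR signal plus the acquisition metadata needed
    downstream (number of scans NS, 90-degree pulse length P1, receiver gain
    RG, ...)."""

    data: np.ndarray          # complex samples
    sw_hz: float              # spectral width in Hz
    spectrometer_freq: float  # MHz
    o1_ppm: float             # carrier offset in ppm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 1 or self.td < 2:
            raise ValueError("Fid needs at least one complex point")
        if self.sw_hz <= 0:
            raise ValueError("sw_hz must be positive")
        if self.spectrometer_freq <= 0:
            raise ValueError("spectrometer_freq must be positive")

    @property
    def td(self) -> int:
        """Bruker-style time-domain size: number of real points (2 per
        complex sample)."""
        return 2 * len(self.data)

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.sw_hz


@dataclass
class Spectrum:
    """Frequency-domain spectrum on a descending ppm axis.

    ``intensity`` is complex right after :func:`transform` and real after
    :func:`autophase`.  ``si`` is the post-zero-fill real spectrum size.
    """

    intensity: np.ndarray
    ppm: np.ndarray
    sw_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.intensity.shape != self.ppm.shape:
            raise ValueError("intensity and ppm axis must have equal length")
        if len(self.ppm) >= 2 and not np.all(np.diff(self.ppm) < 0):
            raise ValueError("ppm axis must be strictly decreasing")

    @property
    def si(self) -> int:
        return len(self.intensity)

    @property
    def ppm_step(self) -> float:
        return abs(float(self.ppm[0] - self.ppm[-1])) / max(self.si - 1, 1)

    def window(self, ppm_low: float, ppm_high: float) -> np.ndarray:
        """Indices of points with ppm in the closed interval [low, high]."""
        lo, hi = sorted((ppm_low, ppm_high))
        return np.nonzero((self.ppm >= lo) & (self.ppm <= hi))[0]


# ---------------------------------------------------------------------------
# I/O: minimal Bruker experiment directories and CSV+JSON spectra
# ---------------------------------------------------------------------------

def _parse_acqus(path: Path) -> dict:
    """Parse a flat-text acqus file (``##$KEY= value`` lines)."""
    params: dict = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line.startswith("##$"):
            continue
        key, _, value = line[3:].partition("=")
        value = value.strip()
        if value.startswith("<") and value.endswith(">"):
            params[key.strip()] = value[1:-1]
            continue
        try:
            num = float(value)
        except ValueError:
            params[key.strip()] = value
            continue
        params[key.strip()] = int(num) if num == int(num) else num
    return params


def read_bruker(dir_path: str | Path) -> Fid:
    """Read a (minimal) Bruker TopSpin experiment directory: binary ``fid``
    (int32, interleaved real/imag) plus flat-text ``acqus``.

    Raises
    ------
    FileNotFoundError
        if ``fid`` or ``acqus`` is missing.
    ValueError
        if required acqus parameters are absent or the fid is truncated.
    """
    dir_path = Path(dir_path)
    fid_path = dir_path / "fid"
    acqus_path = dir_path / "acqus"
    for p in (fid_path, acqus_path):
        if not p.exists():
            raise FileNotFoundError(f"missing Bruker file: {p}")
    params = _parse_acqus(acqus_path)
    missing = [k for k in REQUIRED_ACQUS_KEYS if k not in params]
    if missing:
        raise ValueError(
            "acqus is missing required parameters: " + ", ".join(missing)
        )
    byteorder = "<" if params.get("BYTORDA", 0) == 0 else ">"
    raw = np.fromfile(fid_path, dtype=np.dtype(byteorder + "i4"))
    if raw.size % 2:
        raise ValueError(f"truncated fid: odd number of points ({raw.size})")
    scale = 2.0 ** params.get("NC", 0)
    data = (raw[0::2] + 1j * raw[1::2]) * scale
    sfo1 = float(params["SFO1"])
    meta = {
        "NS": params["NS"],
        "DS": params["DS"],
        "RG": params["RG"],
        "P1_us": float(params["P1"]),
        "GRPDLY": params.get("GRPDLY", 0),
        "pulse_program": params.get("PULPROG", ""),
        "d1_s": params.get("D1", None),
    }
    return Fid(
        data=data,
        sw_hz=float(params["SW_h"]),
        spectrometer_freq=sfo1,
        o1_ppm=float(params["O1"]) / sfo1,
        meta=meta,
    )


def write_spectrum_csv(spectrum: Spectrum, prefix: str | Path) -> None:
    """Write ``<prefix>.csv`` (ppm,intensity) and ``<prefix>.json`` metadata
    sidecar."""
    prefix = Path(prefix)
    arr = np.column_stack([spectrum.ppm, np.real(spectrum.intensity)])
    np.savetxt(prefix.with_suffix(".csv"), arr, delimiter=",",
               header="ppm,intensity", comments="")
    meta = dict(spectrum.meta)
    meta["sw_hz"] = spectrum.sw_hz
    meta["si"] = spectrum.si
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_spectrum_csv(prefix: str | Path) -> Spectrum:
    prefix = Path(prefix)
    arr = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", skiprows=1)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    sw_hz = float(meta.pop("sw_hz"))
    meta.pop("si", None)
    ppm, intensity = arr[:, 0], arr[:, 1]
    if len(ppm) >= 2 and ppm[0] < ppm[-1]:  # enforce descending storage
        ppm, intensity = ppm[::-1], intensity[::-1]
    return Spectrum(intensity=intensity, ppm=ppm, sw_hz=sw_hz, meta=meta)


# ---------------------------------------------------------------------------
# Processing chain
# ---------------------------------------------------------------------------

def apodize(fid: Fid, lb_hz: float = DEFAULT_LB_HZ) -> Fid:
    """Exponential line broadening: multiply point k by exp(-pi*lb*t_k).

    Convolves each Lorentzian line with a Lorentzian of width ``lb_hz``,
    i.e. adds ``lb_hz`` to every linewidth while preserving integrals.
    """
    if lb_hz < 0:
        raise ValueError("lb_hz must be non-negative")
    t = np.arange(len(fid.data)) * fid.dwell_s
    return Fid(
        data=fid.data * np.exp(-math.pi * lb_hz * t),
        sw_hz=fid.sw_hz,
        spectrometer_freq=fid.spectrometer_freq,
        o1_ppm=fid.o1_ppm,
        meta=dict(fid.meta, LB_hz=lb_hz),
    )


def transform(fid: Fid, target_si: int = DEFAULT_SI) -> Spectrum:
    """Zero-fill to ``target_si`` complex points, FFT, and map the frequency
    axis to ppm.  Returns a complex spectrum (phase not yet applied)."""
    n_complex = len(fid.data)
    if target_si < n_complex:
        raise ValueError("target_si smaller than the acquired FID")
    if target_si & (target_si - 1):
        warnings.warn(f"target_si={target_si} is not a power of two")
    data = fid.data.copy()
    grpdly = int(round(fid.meta.get("GRPDLY", 0) or 0))
    if grpdly > 0:  # Bruker digital-filter group delay: drop leading points
        data = np.concatenate([data[grpdly:], np.zeros(grpdly, dtype=complex)])
    data[0] *= 0.5  # half first point: removes the DC baseline offset
    spec = np.fft.fftshift(np.fft.fft(data, n=target_si)) * fid.dwell_s
    freqs = np.fft.fftshift(np.fft.fftfreq(target_si, d=fid.dwell_s))
    ppm = fid.o1_ppm + freqs / fid.spectrometer_freq
    meta = {
        "NS": fid.meta.get("NS"),
        "DS": fid.meta.get("DS"),
        "RG": fid.meta.get("RG"),
        "P1_us": fid.meta.get("P1_us"),
        "pulse_program": fid.meta.get("pulse_program", ""),
        "spectrometer_freq": fid.spectrometer_freq,
        "LB_hz": fid.meta.get("LB_hz", 0.0),
    }
    # descending ppm axis
    return Spectrum(intensity=spec[::-1], ppm=ppm[::-1], sw_hz=fid.sw_hz,
                    meta=meta)


def _pure_neg_cost(real_part: np.ndarray) -> float:
    neg = np.minimum(real_part, 0.0)
    return float(neg @ neg)


def _neg_cost(real_part: np.ndarray) -> float:
    # squared negative intensities, with a tiny reward for positive ones:
    # breaks the tie between a pure-absorption solution and the 90-degree
    # rotation that zeroes the real part entirely
    neg = np.minimum(real_part, 0.0)
    pos = np.maximum(real_part, 0.0)
    return float(neg @ neg) - 1e-6 * float(pos @ pos)


def autophase(
    spectrum: Spectrum,
    tmsp_window: tuple[float, float] = (-0.05, 0.05),
) -> Spectrum:
    """Automatic zero-order phase correction.

    A coarse 2-degree grid minimising the squared negative intensities is
    refined by bounded scalar optimisation; the zero-order phase is then
    fine-tuned so that the mean real intensity in the peak-free flanks of the
    TMSP window is as close to zero as possible.
    """
    if not np.iscomplexobj(spectrum.intensity):
        raise ValueError("autophase requires a complex spectrum")
    lo, hi = sorted(tmsp_window)
    if hi < spectrum.ppm[-1] or lo > spectrum.ppm[0]:
        raise ValueError("tmsp_window lies outside the spectrum axis")
    z = spectrum.intensity

    grid = np.deg2rad(np.arange(-180.0, 180.0, 2.0))
    costs = [_neg_cost(np.real(z * np.exp(-1j * phi))) for phi in grid]
    best = grid[int(np.argmin(costs))]
    res = minimize_scalar(
        lambda phi: _neg_cost(np.real(z * np.exp(-1j * phi))),
        bounds=(best - np.deg2rad(2.5), best + np.deg2rad(2.5)),
        method="bounded",
        options={"xatol": 1e-7},
    )
    phi0 = float(res.x)

    # TMSP flank refinement: minimise |mean real intensity| next to the
    # peak.  The refinement is only kept when it does not materially raise
    # the negative-intensity cost: a non-zero flank mean can stem from the
    # reference peak's own Lorentzian tails, and "fixing" it with a phase
    # rotation would only trade the offset for dispersion leakage.
    centre = 0.5 * (lo + hi)
    flank_idx = np.concatenate([
        spectrum.window(centre + a, centre + b) for a, b in TMSP_FLANKS
    ])
    if flank_idx.size:
        zf = z[flank_idx]
        ref = minimize_scalar(
            lambda phi: abs(float(np.mean(np.real(zf * np.exp(-1j * phi))))),
            bounds=(phi0 - np.deg2rad(3.0), phi0 + np.deg2rad(3.0)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        neg0 = _pure_neg_cost(np.real(z * np.exp(-1j * phi0)))
        neg1 = _pure_neg_cost(np.real(z * np.exp(-1j * float(ref.x))))
        if neg1 <= 1.02 * neg0 + np.finfo(float).tiny:
            phi0 = float(ref.x)

    out = np.real(z * np.exp(-1j * phi0))
    meta = dict(spectrum.meta, phase0_deg=math.degrees(phi0))
    return Spectrum(intensity=out, ppm=spectrum.ppm.copy(),
                    sw_hz=spectrum.sw_hz, meta=meta)


def calibrate_ppm(
    spectrum: Spectrum,
    search_window: tuple[float, float] = DEFAULT_CALIBRATION_WINDOW,
    target_ppm: float = DEFAULT_CALIBRATION_TARGET_PPM,
) -> Spectrum:
    """Shift the ppm axis so the dominant peak in ``search_window`` sits at
    ``target_ppm``.

    The apex is located by a three-point parabolic interpolation around the
    maximum.  If no maximum rises above the local noise the spectrum is
    returned unshifted with ``meta['calibration_failed']`` set.
    """
    idx = spectrum.window(*search_window)
    if idx.size < 3:
        raise ValueError("search window outside the spectrum axis")
    y = np.real(spectrum.intensity[idx])
    med = float(np.median(y))
    mad = float(np.median(np.abs(y - med)))
    peak_rel = int(np.argmax(y))
    if y[peak_rel] <= med + 5.0 * 1.4826 * mad or mad == 0.0:
        meta = dict(spectrum.meta, calibration_failed=True)
        return Spectrum(intensity=spectrum.intensity.copy(),
                        ppm=spectrum.ppm.copy(), sw_hz=spectrum.sw_hz,
                        meta=meta)
    i = idx[peak_rel]
    apex = float(spectrum.ppm[i])
    if 0 < i < spectrum.si - 1:
        y0, y1, y2 = (float(np.real(spectrum.intensity[j]))
                      for j in (i - 1, i, i + 1))
        denom = y0 - 2.0 * y1 + y2
        if denom != 0.0:
            delta = 0.5 * (y0 - y2) / denom
            apex += np.clip(delta, -1, 1) * (spectrum.ppm[i + 1] - spectrum.ppm[i])
    shift = target_ppm - apex
    meta = dict(spectrum.meta)
    meta["ppm_shift"] = meta.get("ppm_shift", 0.0) + shift
    return Spectrum(intensity=spectrum.intensity.copy(),
                    ppm=spectrum.ppm + shift, sw_hz=spectrum.sw_hz, meta=meta)


def preprocess_fid(
    fid: Fid,
    target_si: int = DEFAULT_SI,
    lb_hz: float = DEFAULT_LB_HZ,
    tmsp_window: tuple[float, float] = (-0.05, 0.05),
    calibration_window: tuple[float, float] | None = DEFAULT_CALIBRATION_WINDOW,
    calibration_target: float = DEFAULT_CALIBRATION_TARGET_PPM,
) -> Spectrum:
    """Full preprocessing chain: apodize -> transform -> autophase ->
    (optional) ppm calibration."""
    spec = autophase(transform(apodize(fid, lb_hz), target_si), tmsp_window)
    if calibration_window is not None:
        spec = calibrate_ppm(spec, calibration_window, calibration_target)
    return spec
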