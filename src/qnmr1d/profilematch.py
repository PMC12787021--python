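"""Quantification profiles and multiplet pattern matching.

A *quantification profile* declaratively describes everything the pipeline
needs for one matrix (here: wine): preprocessing settings, the regions of
interest (ROIs), one multiplet signature per target signal (chemical shift,
multiplicity, coupling constants, proton weights), per-signal correction
factors, and signal combinations (e.g. total glucose from the two anomers).

Pattern matching assigns fitted peaks to the first-order multiplet line
positions of each signature, minimising a dimensionless score

    score = sum(|d_delta| / delta_tol) + sum(|d_J| / J_tol)

over all line assignments subject to every line lying within tolerance;
coupling constants are measured as fitted-centre differences converted to
Hz.  The optimal assignment is found by exhaustive enumeration (candidate
lists are short in a narrow ROI), so it provably equals the brute-force
optimum.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .peakproc import FitReport, PeakModel, RoiSpec, NOISE_WINDOW_DEFAULT

__all__ = [
    "SubSignal",
    "PatternSpec",
    "QuantProfile",
    "MatchResult",
    "multiplet_lines",
    "load_profile",
    "default_profile",
    "calibrate_roi",
    "match_pattern",
    "extract_areas",
    "process_rois",
]

DELTA_TOL_DEFAULT = 0.01  # ppm, after ROI calibration
J_TOL_DEFAULT = 0.3       # Hz

_J_COUNT = {"s": 0, "d": 1, "dd": 2, "q": 1, "m": 0}


class SubSignal(BaseModel):
    """One multiplet of a compound signature.

    ``m`` multiplets carry an explicit (approximate) line list instead of a
    first-order splitting rule.
    """

    multiplicity: Literal["s", "d", "dd", "q", "m"]
    center_ppm: float
    j_hz: list[float] = Field(default_factory=list)
    proton_weight: float = 1.0
    #: explicit lines for "m": [{"delta_ppm": ..., "rel_intensity": ...}]
    lines: Optional[list[dict]] = None
    approximate: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.proton_weight <= 0:
            raise ValueError("proton_weight must be positive")
        need = _J_COUNT[self.multiplicity]
        if len(self.j_hz) != need:
            raise ValueError(
                f"multiplicity {self.multiplicity!r} needs {need} J value(s), "
                f"got {len(self.j_hz)}"
            )
        if self.multiplicity == "m" and not self.lines:
            raise ValueError("'m' multiplets require an explicit line list")
        return self


class PatternSpec(BaseModel):
    """Declarative multiplet signature of one target signal."""

    compound: str
    chebi_id: Optional[int] = None
    mw: float = Field(gt=0)  # g/mol
    sub_signals: list[SubSignal]
    delta_tol_ppm: float = DELTA_TOL_DEFAULT
    j_tol_hz: float = J_TOL_DEFAULT
    applicability: Literal["any", "noesy", "zgpr"] = "any"

    @model_validator(mode="after")
    def _check(self):
        if not self.sub_signals:
            raise ValueError(f"{self.compound}: at least one sub-signal required")
        return self

    @property
    def proton_weight(self) -> float:
        return sum(s.proton_weight for s in self.sub_signals)


class QuantProfile(BaseModel):
    """Full processing + quantification configuration for one matrix."""

    name: str = "profile"
    version: str = "1"
    preprocessing: dict = Field(default_factory=lambda: {
        "si": 131072, "lb_hz": 0.25,
        "calibration": {"window": [1.02, 1.07], "target_ppm": 1.046},
    })
    rois: list[RoiSpec] = Field(default_factory=list)
    patterns: list[PatternSpec] = Field(default_factory=list)
    #: signal combinations, e.g. total glucose from the two anomer signals
    combinations: list[dict] = Field(default_factory=list)
    correction_factors: dict[str, float] = Field(default_factory=dict)
    noise_window: tuple[float, float] = NOISE_WINDOW_DEFAULT

    @model_validator(mode="after")
    def _check(self):
        names = [p.compound for p in self.patterns]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate compound ids: {dup}")
        for pat in self.patterns:
            for sub in pat.sub_signals:
                if not any(r.contains(sub.center_ppm) for r in self.rois):
                    raise ValueError(
                        f"{pat.compound}: sub-signal at {sub.center_ppm} ppm "
                        "falls outside every ROI"
                    )
        for comp, cf in self.correction_factors.items():
            if cf <= 0:
                raise ValueError(f"correction factor for {comp} must be > 0")
        return self

    def rois_for(self, pattern: PatternSpec) -> list[RoiSpec]:
        out = []
        for roi in self.rois:
            if any(roi.contains(s.center_ppm) for s in pattern.sub_signals):
                out.append(roi)
        return out


@dataclass
class MatchResult:
    """Outcome of matching one pattern against a fitted peak list."""

    compound: str
    matched_peaks: list[PeakModel] = field(default_factory=list)
    per_proton_area: Optional[float] = None  # intensity*Hz per proton
    matched_weight: float = 0.0
    score: float = float("inf")
    flags: set = field(default_factory=set)

    @property
    def matched(self) -> bool:
        return "unmatched" not in self.flags and self.per_proton_area is not None


# ---------------------------------------------------------------------------
# First-order multiplet line positions
# ---------------------------------------------------------------------------

def multiplet_lines(sub: SubSignal, freq_mhz: float) -> list[tuple[float, float]]:
    """Expand a sub-signal into (line position ppm, intensity fraction)
    pairs using first-order splitting rules; fractions sum to 1."""
    d = sub.center_ppm
    if sub.multiplicity == "s":
        return [(d, 1.0)]
    if sub.multiplicity == "d":
        j = sub.j_hz[0] / freq_mhz
        return [(d - j / 2, 0.5), (d + j / 2, 0.5)]
    if sub.multiplicity == "dd":
        j1, j2 = (j / freq_mhz for j in sub.j_hz)
        offs = sorted(s1 * j1 / 2 + s2 * j2 / 2
                      for s1 in (-1, 1) for s2 in (-1, 1))
        return [(d + o, 0.25) for o in offs]
    if sub.multiplicity == "q":
        j = sub.j_hz[0] / freq_mhz
        return [(d - 1.5 * j, 1 / 8), (d - 0.5 * j, 3 / 8),
                (d + 0.5 * j, 3 / 8), (d + 1.5 * j, 1 / 8)]
    if sub.multiplicity == "m":
        total = sum(l["rel_intensity"] for l in sub.lines)
        return [(l["delta_ppm"], l["rel_intensity"] / total) for l in sub.lines]
    raise ValueError(f"unsupported multiplicity: {sub.multiplicity!r}")


# ---------------------------------------------------------------------------
# Profile I/O and the bundled wine profile
# ---------------------------------------------------------------------------

def load_profile(path: str | Path) -> QuantProfile:
    """Load and validate a quantification profile from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return QuantProfile.model_validate(doc)


def save_profile(profile: QuantProfile, path: str | Path) -> None:
    Path(path).write_text(json.dumps(profile.model_dump(), indent=1))


def _wine_rois() -> list[dict]:
    rois = [
        ("trigonelline", 9.04, 9.24),
        ("formate", 8.17, 8.37),
        ("gallate", 7.06, 7.26),
        ("fumarate_shikimate", 6.70, 6.92),
        ("caffeate", 6.24, 6.42),
        ("flavanols", 5.94, 6.16),
        ("sorbate", 5.76, 5.88),
        ("anomeric", 5.16, 5.36),
        ("beta_glucose", 4.55, 4.71),
        ("ethyl_lactate", 4.13, 4.29),
        ("fructose", 3.94, 4.08),
        ("glycerol", 3.47, 3.63),
        ("methanol", 3.27, 3.43),
        ("malate", 2.82, 2.96),
        ("succinate", 2.58, 2.72),
        ("acetate", 2.00, 2.15),
        ("isoamyl", 1.58, 1.72),
    ]
    return [{"name": n, "ppm_low": lo, "ppm_high": hi} for n, lo, hi in rois]


def _sig(mult, ppm, j=(), w=1.0, lines=None, approximate=False):
    d = {"multiplicity": mult, "center_ppm": ppm, "j_hz": list(j),
         "proton_weight": w}
    if lines:
        d["lines"] = lines
        d["approximate"] = approximate
    return d


def _wine_patterns() -> list[dict]:
    """The 21 target signals of the 20 wine compounds.

    Malic acid is searched as two doublets of 0.5-proton intensity (2.871
    and 2.903 ppm, J = 4.5 Hz) rather than its nominal 1H dd: the two
    halves of the dd shift slightly in the wine matrix and are detected
    more robustly as independent doublets.  Catechin and epicatechin each
    combine two 1H doublets from different proton groups.  Glycerol and
    methanol sit close to the suppressed water/ethanol signals of the
    NOESY experiment and are quantified from zgpr spectra only.  The two
    unresolved multiplets (3-methylbutan-1-ol, shikimic acid) carry
    empirically chosen explicit line lists and are flagged approximate.
    """
    isoamyl_lines = [{"delta_ppm": 1.643, "rel_intensity": 0.25},
                     {"delta_ppm": 1.650, "rel_intensity": 0.50},
                     {"delta_ppm": 1.657, "rel_intensity": 0.25}]
    shikimate_lines = [{"delta_ppm": 6.814, "rel_intensity": 0.25},
                       {"delta_ppm": 6.820, "rel_intensity": 0.50},
                       {"delta_ppm": 6.826, "rel_intensity": 0.25}]
    return [
        {"compound": "3-methylbutan-1-ol", "chebi_id": 15837, "mw": 88.15,
         "sub_signals": [_sig("m", 1.65, w=1.0, lines=isoamyl_lines,
                              approximate=True)]},
        {"compound": "acetic acid", "chebi_id": 15366, "mw": 60.05,
         "sub_signals": [_sig("s", 2.08, w=3.0)]},
        {"compound": "alpha-glucose", "chebi_id": 17925, "mw": 180.16,
         "sub_signals": [_sig("d", 5.23, (3.6,), 1.0)]},
        {"compound": "beta-glucose", "chebi_id": 15903, "mw": 180.16,
         "sub_signals": [_sig("d", 4.63, (7.9,), 1.0)]},
        {"compound": "caffeic acid", "chebi_id": 16433, "mw": 180.16,
         "sub_signals": [_sig("d", 6.33, (16.0,), 1.0)]},
        {"compound": "catechin", "chebi_id": 23053, "mw": 290.27,
         "sub_signals": [_sig("d", 5.99, (2.0,), 1.0),
                         _sig("d", 6.09, (2.0,), 1.0)]},
        {"compound": "epicatechin", "chebi_id": 90, "mw": 290.27,
         "sub_signals": [_sig("d", 6.07, (2.0,), 1.0),
                         _sig("d", 6.10, (2.0,), 1.0)]},
        {"compound": "ethyl acetate", "chebi_id": 27750, "mw": 88.11,
         "sub_signals": [_sig("s", 2.07, w=3.0)]},
        {"compound": "ethyl lactate", "chebi_id": 78321, "mw": 118.13,
         "sub_signals": [_sig("q", 4.21, (7.1,), 2.0)]},
        {"compound": "formic acid", "chebi_id": 30751, "mw": 46.03,
         "sub_signals": [_sig("s", 8.27, w=1.0)]},
        {"compound": "fructose", "chebi_id": 28757, "mw": 180.16,
         "sub_signals": [_sig("dd", 4.01, (12.8, 1.2), 2.0)]},
        {"compound": "fumaric acid", "chebi_id": 18012, "mw": 116.07,
         "sub_signals": [_sig("s", 6.75, w=2.0)]},
        {"compound": "galacturonic acid", "chebi_id": 33830, "mw": 194.14,
         "sub_signals": [_sig("d", 5.30, (3.7,), 1.0)]},
        {"compound": "gallic acid", "chebi_id": 30778, "mw": 170.12,
         "sub_signals": [_sig("s", 7.16, w=2.0)]},
        {"compound": "malic acid", "chebi_id": 6650, "mw": 134.09,
         "sub_signals": [_sig("d", 2.871, (4.5,), 0.5),
                         _sig("d", 2.903, (4.5,), 0.5)]},
        {"compound": "shikimic acid", "chebi_id": 16119, "mw": 174.15,
         "sub_signals": [_sig("m", 6.82, w=1.0, lines=shikimate_lines,
                              approximate=True)]},
        {"compound": "sorbic acid", "chebi_id": 35962, "mw": 112.13,
         "sub_signals": [_sig("d", 5.82, (15.3,), 1.0)]},
        {"compound": "succinic acid", "chebi_id": 15741, "mw": 118.09,
         "sub_signals": [_sig("s", 2.65, w=4.0)]},
        {"compound": "trigonelline", "chebi_id": 229203, "mw": 137.14,
         "sub_signals": [_sig("s", 9.14, w=1.0)]},
        {"compound": "glycerol", "chebi_id": 17754, "mw": 92.09,
         "applicability": "zgpr",
         "sub_signals": [_sig("dd", 3.55, (11.8, 6.5), 2.0)]},
        {"compound": "methanol", "chebi_id": 17790, "mw": 32.04,
         "applicability": "zgpr",
         "sub_signals": [_sig("s", 3.35, w=3.0)]},
    ]


#: per-signal correction factors for the bundled wine profile
_WINE_CF = {
    "3-methylbutan-1-ol": 0.75, "acetic acid": 0.55, "alpha-glucose": 2.30,
    "beta-glucose": 1.25, "glucose": 0.80, "caffeic acid": 0.80,
    "catechin": 0.90, "epicatechin": 0.75, "ethyl acetate": 0.95,
    "ethyl lactate": 0.90, "formic acid": 0.75, "fructose": 2.20,
    "fumaric acid": 0.80, "galacturonic acid": 1.95, "gallic acid": 0.75,
    "malic acid": 1.10, "shikimic acid": 0.75, "sorbic acid": 0.90,
    "succinic acid": 1.05, "trigonelline": 0.90, "glycerol": 1.25,
    "methanol": 0.60,
}


def default_profile() -> QuantProfile:
    """The bundled wine quantification profile: 21 target signals of 20
    compounds, their ROIs, correction factors, and the total-glucose
    combination."""
    return QuantProfile(
        name="wine-default",
        version="1",
        rois=_wine_rois(),
        patterns=_wine_patterns(),
        combinations=[{"name": "glucose",
                       "components": ["alpha-glucose", "beta-glucose"]}],
        correction_factors=dict(_WINE_CF),
    )


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def calibrate_roi(
    peaks: list[PeakModel],
    window: tuple[float, float],
    center_ppm: float,
) -> tuple[list[PeakModel], float, bool]:
    """Shift all candidate peak centres by a constant so that the (largest)
    calibration peak found in ``window`` sits at ``center_ppm``.

    Returns ``(shifted_peaks, shift_ppm, found)``; when no peak lies in the
    window the input list is returned unshifted with ``found=False``.
    """
    lo, hi = sorted(window)
    in_win = [p for p in peaks if lo <= p.center_ppm <= hi]
    if not in_win:
        return list(peaks), 0.0, False
    ref = max(in_win, key=lambda p: p.amplitude)
    shift = center_ppm - ref.center_ppm
    shifted = [PeakModel(center_ppm=p.center_ppm + shift, amplitude=p.amplitude,
                         fwhm_hz=p.fwhm_hz, eta=p.eta, asym=p.asym, area=p.area)
               for p in peaks]
    return shifted, shift, True


def _measured_j_dev(sub: SubSignal, centers: list[float], freq: float) -> list[float]:
    """|measured - expected| coupling deviations in Hz for one assignment
    (centres ascending)."""
    if sub.multiplicity == "d":
        return [abs((centers[1] - centers[0]) * freq - sub.j_hz[0])]
    if sub.multiplicity == "q":
        sp = [(centers[i + 1] - centers[i]) * freq for i in range(3)]
        return [abs(sum(sp) / 3.0 - sub.j_hz[0])]
    if sub.multiplicity == "dd":
        j_big, j_small = sorted(sub.j_hz, reverse=True)
        small = ((centers[1] - centers[0]) + (centers[3] - centers[2])) / 2 * freq
        big = ((centers[2] + centers[3]) - (centers[0] + centers[1])) / 2 * freq
        return [abs(small - j_small), abs(big - j_big)]
    return []


def _sub_signal_options(
    sub: SubSignal, peaks: list[PeakModel], pattern: PatternSpec, freq: float
) -> list[tuple[float, tuple[int, ...], float]]:
    """All tolerance-satisfying assignments of one sub-signal's lines to
    peaks, as (score, peak index tuple, total area), exhaustively."""
    lines = sorted(multiplet_lines(sub, freq))
    tol = pattern.delta_tol_ppm
    cand = [[i for i, p in enumerate(peaks)
             if abs(p.center_ppm - ppm_e) <= tol] for ppm_e, _ in lines]
    options = []
    for combo in itertools.product(*cand):
        if len(set(combo)) != len(combo):
            continue
        centers = [peaks[i].center_ppm for i in combo]
        if any(centers[k] >= centers[k + 1] for k in range(len(centers) - 1)):
            continue  # line order must match peak order
        j_dev = _measured_j_dev(sub, centers, freq)
        if any(d > pattern.j_tol_hz for d in j_dev):
            continue
        score = sum(abs(c - ppm_e) / tol
                    for c, (ppm_e, _) in zip(centers, lines))
        score += sum(d / pattern.j_tol_hz for d in j_dev)
        area = sum(peaks[i].area for i in combo)
        options.append((score, combo, area))
    options.sort(key=lambda t: (t[0], -t[2]))
    return options


def match_pattern(
    peaks: list[PeakModel],
    pattern: PatternSpec,
    freq_mhz: float,
) -> MatchResult:
    """Find the peak subset best matching a multiplet signature.

    Sub-signals are assigned jointly (no peak may serve two sub-signals of
    the same pattern); the minimal-score combination wins, ties broken by
    larger total area.  Absence of a match is a result (flags), not an
    error.  Partial matches (some sub-signals found) are quantified over
    the matched proton weights only and flagged ``partial``.
    """
    result = MatchResult(compound=pattern.compound)
    per_sub = [_sub_signal_options(s, peaks, pattern, freq_mhz)
               for s in pattern.sub_signals]

    matched_idx = [i for i, opts in enumerate(per_sub) if opts]
    if not matched_idx:
        result.flags.add("unmatched")
        return result
    if len(matched_idx) < len(pattern.sub_signals):
        result.flags.add("partial")

    # joint, injective selection over the matched sub-signals
    option_lists = [per_sub[i][:32] for i in matched_idx]
    best = None
    valid_scores: list[float] = []
    for combo in itertools.product(*option_lists):
        used: set[int] = set()
        ok = True
        for _, idx, _ in combo:
            if used & set(idx):
                ok = False
                break
            used |= set(idx)
        if not ok:
            continue
        total_score = sum(c[0] for c in combo)
        total_area = sum(c[2] for c in combo)
        valid_scores.append(total_score)
        key = (total_score, -total_area)
        if best is None or key < best[0]:
            best = (key, combo)
    if best is None:
        result.flags.add("unmatched")
        return result
    valid_scores.sort()
    if (len(valid_scores) > 1
            and valid_scores[1] <= valid_scores[0] + max(0.1 * valid_scores[0], 0.05)):
        # a second distinct valid combination close in score
        result.flags.add("ambiguous")

    combo = best[1]
    idx_all = [i for _, idx, _ in combo for i in idx]
    result.matched_peaks = [peaks[i] for i in idx_all]
    result.matched_weight = sum(pattern.sub_signals[i].proton_weight
                                for i in matched_idx)
    total_area = sum(c[2] for c in combo)
    result.per_proton_area = total_area / result.matched_weight
    result.score = sum(c[0] for c in combo)
    return result


def process_rois(spectrum, profile: QuantProfile, pulse_program: str | None = None,
                 fit_asym: bool = True) -> dict[str, FitReport]:
    """Run per-ROI baseline/denoise/pick/fit for every ROI hosting at least
    one applicable pattern; returns ``{roi name: FitReport}``."""
    from .peakproc import estimate_noise, process_roi

    family = _pulse_family(pulse_program or spectrum.meta.get("pulse_program", ""))
    noise_sd = estimate_noise(spectrum, profile.noise_window)
    needed: dict[str, RoiSpec] = {}
    for pat in profile.patterns:
        if pat.applicability not in ("any", family):
            continue
        for roi in profile.rois_for(pat):
            needed[roi.name] = roi
    return {name: process_roi(spectrum, roi, noise_sd, fit_asym=fit_asym)
            for name, roi in needed.items()}


def _pulse_family(pulse_program: str) -> str:
    p = (pulse_program or "").lower()
    if "noesy" in p:
        return "noesy"
    if p.startswith("zg") or "zgpr" in p:
        return "zgpr"
    return p or "noesy"


def extract_areas(
    fits_by_roi: dict[str, FitReport],
    profile: QuantProfile,
    freq_mhz: float,
    pulse_program: str = "noesy",
) -> list[MatchResult]:
    """One MatchResult per applicable pattern, plus configured combinations
    (e.g. total glucose from the two anomer signals)."""
    family = _pulse_family(pulse_program)
    roi_by_name = {r.name: r for r in profile.rois}

    # ROI-local calibration applied once per ROI before matching
    peaks_by_roi: dict[str, list[PeakModel]] = {}
    for name, rep in fits_by_roi.items():
        peaks = list(rep.peaks)
        roi = roi_by_name.get(name)
        if roi is not None and roi.local_calibration:
            cal = roi.local_calibration
            peaks, _, _ = calibrate_roi(peaks, tuple(cal["window"]), cal["center"])
        peaks_by_roi[name] = peaks

    results: list[MatchResult] = []
    by_compound: dict[str, MatchResult] = {}
    for pat in profile.patterns:
        if pat.applicability not in ("any", family):
            continue
        peaks: list[PeakModel] = []
        for roi in profile.rois_for(pat):
            peaks.extend(peaks_by_roi.get(roi.name, []))
        res = match_pattern(peaks, pat, freq_mhz)
        results.append(res)
        by_compound[pat.compound] = res

    for comb in profile.combinations:
        parts = [by_compound.get(c) for c in comb["components"]]
        present = [p for p in parts if p is not None and p.matched]
        if not present:
            continue
        area = sum(p.per_proton_area * p.matched_weight for p in present)
        weight = sum(p.matched_weight for p in present)
        combined = MatchResult(
            compound=comb["name"],
            matched_peaks=[pk for p in present for pk in p.matched_peaks],
            per_proton_area=area / weight,
            matched_weight=weight,
            score=sum(p.score for p in present),
            flags=set().union(*(p.flags for p in present)),
        )
        if len(present) < len(parts):
            combined.flags.add("partial")
        results.append(combined)
    return results
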