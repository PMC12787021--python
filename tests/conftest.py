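import numpy as np
import pytest

from qnmr1d import PatternSpec
from qnmr1d import simulate as sim
from qnmr1d.profilematch import default_profile

FREQ = 500.23  # MHz


@pytest.fixture(scope="session")
def freq():
    return FREQ


@pytest.fixture(scope="session")
def wine_profile():
    return default_profile()


def singlet(name="trigonelline", ppm=9.14, protons=1.0, mw=137.14):
    return PatternSpec(
        compound=name, mw=mw,
        sub_signals=[{"multiplicity": "s", "center_ppm": ppm,
                      "proton_weight": protons}],
    )


def make_simspec(patterns_with_conc, fwhm_hz=1.0, eta=1.0, asym=0.0,
                 noise_sd=0.0, baseline=(0.0,), points=65536, seed=0,
                 ppm_min=-1.0, ppm_max=15.0182):
    return sim.SimSpec(
        patterns=[{"pattern": p, "concentration_mgL": c}
                  for p, c in patterns_with_conc],
        lineshape={"fwhm_hz": fwhm_hz, "lorentz_fraction": eta,
                   "asymmetry": asym},
        noise_sd=noise_sd, baseline=list(baseline),
        axis={"ppm_min": ppm_min, "ppm_max": ppm_max, "points": points},
        seed=seed,
    )


@pytest.fixture
def trig_spectrum():
    """Noiseless Lorentzian trigonelline singlet at 100 mg/L."""
    spec = make_simspec([(singlet(), 100.0)])
    return sim.render_spectrum(spec), spec


def expected_area(conc_mgL, mw, response=sim.DEFAULT_RESPONSE):
    """Per-proton line area the renderer should produce (intensity*Hz)."""
    return response * conc_mgL / mw
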