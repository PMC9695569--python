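"""Digital radiographic system profiles and acquisition settings.

A :class:`SystemProfile` collects the effective physical constants of
one PSP read-out chain: aluminium attenuation, dose rate, the
logarithmic gray-value response, additive read-out noise, and the time
constant of light-induced fading of the latent signal.  Two default
profiles ship in the package configuration: a wide-dynamic-range
"VistaScan-like" system and a narrower "Express-like" system whose
thinnest steps reach dark saturation at the longest X-ray exposures.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SystemProfile:
    """Effective read-out model of one PSP system.

    Attributes
    ----------
    name
        System label used throughout manifests and result tables.
    mu_al_per_mm
        Effective linear attenuation coefficient of aluminium (1/mm).
    dap_rate
        Dose-area product accumulated per second of X-ray exposure
        (mGy cm^2 / s); doubles as the latent-signal scale.
    response_gain
        Gray values per decade of latent signal (g > 0).
    response_offset
        Gray-value intercept of the logarithmic response (b0).
    signal_floor
        Positive regulariser added to the signal before the logarithm;
        sets the response roll-off at very low dose.
    noise_sigma_gv
        Standard deviation of additive Gaussian read-out noise, in gray
        values, applied before quantization.
    fade_tau_s
        Time constant (s) of mono-exponential latent-signal loss under
        ambient light.
    """

    name: str
    mu_al_per_mm: float
    dap_rate: float
    response_gain: float
    response_offset: float
    signal_floor: float
    noise_sigma_gv: float
    fade_tau_s: float

    def __post_init__(self) -> None:
        if self.mu_al_per_mm < 0:
            raise ValueError("mu_al_per_mm must be >= 0")
        if self.dap_rate <= 0:
            raise ValueError("dap_rate must be positive")
        if self.response_gain <= 0:
            raise ValueError("response_gain must be positive")
        if self.signal_floor <= 0:
            raise ValueError("signal_floor must be positive")
        if self.noise_sigma_gv < 0:
            raise ValueError("noise_sigma_gv must be >= 0")
        if self.fade_tau_s <= 0:
            raise ValueError("fade_tau_s must be positive")


@dataclass(frozen=True)
class AcquisitionSetting:
    """One simulated acquisition: system, exposures, seed, noise flag."""

    profile: SystemProfile
    exposure_time_s: float
    light_duration_s: float
    seed: int = 0
    noise_enabled: bool = True

    def __post_init__(self) -> None:
        if self.exposure_time_s <= 0:
            raise ValueError("exposure_time_s must be positive")
        if self.light_duration_s < 0:
            raise ValueError("light_duration_s must be >= 0")
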