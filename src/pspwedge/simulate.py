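"""Synthetic step-wedge radiograph renderer.

The forward model, per pixel:

1. dose: latent signal proportional to X-ray exposure time
   (``dap_rate * t``);
2. Beer-Lambert attenuation through the local aluminium thickness,
   ``exp(-mu * d)``;
3. on the light-exposed half only, mono-exponential fading of the
   latent signal, ``exp(-t_light / tau)``;
4. logarithmic, *inverted* read-out response
   ``b0 - g * log10(signal + s0)`` (more dose -> darker), so fading
   raises gray values;
5. optional additive zero-mean Gaussian noise on the gray-value scale;
6. quantization: round half away from zero, then clip to [0, 255].

With noise disabled and zero light duration the two lateral halves are
pixel-identical by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .geometry import PhantomGeometry
from .systems import AcquisitionSetting, SystemProfile

__all__ = [
    "Radiograph",
    "attenuated_signal",
    "fade_signal",
    "gray_value",
    "render_radiograph",
    "recover_fade_tau",
]


def _round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (ties at .5 move away from 0).

    numpy's default rounding is banker's rounding; results here must be
    bit-reproducible under the stated convention.
    """
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def attenuated_signal(dose, thickness_mm, mu):
    """Latent signal after Beer-Lambert attenuation.

    ``dose * exp(-mu * thickness_mm)``; monotone non-increasing in
    thickness.  Accepts scalars or arrays.
    """
    dose = np.asarray(dose, dtype=np.float64)
    thickness_mm = np.asarray(thickness_mm, dtype=np.float64)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    if np.any(thickness_mm < 0):
        raise ValueError("thickness_mm must be >= 0")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    out = dose * np.exp(-mu * thickness_mm)
    return out.item() if out.ndim == 0 else out


def fade_signal(signal, light_duration_s, tau_s):
    """Latent signal surviving ``light_duration_s`` of ambient light.

    Mono-exponential survival ``signal * exp(-t / tau)``: equal to the
    input at zero duration and strictly decreasing in duration for a
    positive signal.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    signal = np.asarray(signal, dtype=np.float64)
    if np.any(signal < 0):
        raise ValueError("signal must be >= 0")
    if light_duration_s < 0:
        raise ValueError("light_duration_s must be >= 0")
    out = signal * np.exp(-light_duration_s / tau_s)
    return out.item() if out.ndim == 0 else out


def gray_value(signal, profile: SystemProfile):
    """Quantized 8-bit gray value of a latent signal.

    ``clip(round(b0 - g * log10(signal + s0)), 0, 255)``.  The response
    is inverted (monotone non-increasing in signal): higher dose gives a
    darker pixel, hence light-induced fading *raises* gray values and
    can lift dark-saturated steps back onto the scale.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if np.any(signal < 0):
        raise ValueError("signal must be >= 0")
    analog = profile.response_offset - profile.response_gain * np.log10(
        signal + profile.signal_floor
    )
    out = np.clip(_round_half_away(analog), 0, 255)
    if out.ndim == 0:
        return int(out)
    return out.astype(np.uint8)


@dataclass(frozen=True)
class Radiograph:
    """8-bit grayscale image plus the geometry/setting that produced it."""

    pixels: np.ndarray
    geometry: PhantomGeometry
    setting: AcquisitionSetting

    def __post_init__(self) -> None:
        if self.pixels.shape != self.geometry.image_shape_px:
            raise GeometryError(
                f"pixel grid {self.pixels.shape} does not match geometry "
                f"{self.geometry.image_shape_px}"
            )
        if self.pixels.dtype != np.uint8:
            raise GeometryError("pixels must be 8-bit (uint8)")


def render_radiograph(setting: AcquisitionSetting,
                      geometry: PhantomGeometry) -> Radiograph:
    """Render one synthetic radiograph under the forward model.

    Fading applies only to the exposed half.  Noise, when enabled, is
    seeded from ``setting.seed``, making the output bit-reproducible
    for identical inputs.
    """
    profile = setting.profile
    dose = profile.dap_rate * setting.exposure_time_s
    signal = attenuated_signal(dose, geometry.thickness_map(), profile.mu_al_per_mm)

    c0, c1 = geometry.half_col_range("exposed")
    signal[:, c0:c1] = fade_signal(
        signal[:, c0:c1], setting.light_duration_s, profile.fade_tau_s
    )

    analog = profile.response_offset - profile.response_gain * np.log10(
        signal + profile.signal_floor
    )
    if setting.noise_enabled and profile.noise_sigma_gv > 0:
        rng = np.random.default_rng(setting.seed)
        analog = analog + rng.normal(0.0, profile.noise_sigma_gv, analog.shape)

    pixels = np.clip(_round_half_away(analog), 0, 255).astype(np.uint8)
    return Radiograph(pixels=pixels, geometry=geometry, setting=setting)


def _invert_gray(mgv: float, profile: SystemProfile) -> float:
    """Latent signal implied by a (possibly non-integer) gray value."""
    return 10.0 ** ((profile.response_offset - mgv) / profile.response_gain) \
        - profile.signal_floor


def recover_fade_tau(
    profile: SystemProfile,
    geometry: PhantomGeometry,
    exposure_time_s: float = 0.32,
    durations_s: np.ndarray | None = None,
) -> float:
    """Internal consistency oracle: re-estimate ``fade_tau_s`` from images.

    Renders noise-free radiographs over a grid of light durations,
    inverts the read-out response on each exposed-half step whose gray
    values stay strictly inside (1, 254) for every duration, regresses
    ``log(signal)`` on duration per step, and averages the per-step
    slopes.  Quantization is the only error source, so the estimate
    should land within ~1% of the profile's true time constant.
    """
    from .metrics import place_rois, roi_stats  # local import avoids a cycle

    if durations_s is None:
        durations_s = np.arange(0.0, 91.0, 3.0)
    durations_s = np.asarray(durations_s, dtype=np.float64)

    rois = [r for r in place_rois(geometry, margin_px=4) if r.half == "exposed"]
    mgv = np.empty((len(durations_s), len(rois)))
    for i, t_l in enumerate(durations_s):
        setting = AcquisitionSetting(
            profile=profile, exposure_time_s=exposure_time_s,
            light_duration_s=float(t_l), seed=0, noise_enabled=False,
        )
        rad = render_radiograph(setting, geometry)
        for j, roi in enumerate(rois):
            mgv[i, j] = roi_stats(rad, roi).mgv

    valid = np.all((mgv > 1.0) & (mgv < 254.0), axis=0)
    if not np.any(valid):
        raise ValueError("no step stays inside the invertible gray range")

    x = durations_s - durations_s.mean()
    slopes = []
    for j in np.flatnonzero(valid):
        y = np.log([_invert_gray(m, profile) for m in mgv[:, j]])
        slopes.append(np.dot(x, y - y.mean()) / np.dot(x, x))
    return -1.0 / float(np.mean(slopes))
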