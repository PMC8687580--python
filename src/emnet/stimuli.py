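"""Synthetic auditory-like stimuli and attenuation envelopes.

Input vectors emulate the response of a bank of ``M`` log-spaced frequency
channels (inner-hair-cell-like units) to mixtures of pure tones.  Each sample
is a sum of up to five Gaussian bumps on the channel axis — tone centers
uniform on the axis, widths folded-normal, log-amplitudes uniform — plus
per-channel uniform background noise.  A single global normalization factor,
fixed once from a calibration batch, rescales every sample into ``[0, 0.5]``.

Sensory deprivation (hearing loss) is modelled as a multiplicative
attenuation envelope ``a(k) in [0, 1]`` over the channel axis, either a
single sigmoid edge or a band built from two sigmoids.

Channel indices ``k`` are 1-based in all formulas, matching the convention
of the attenuation profiles (``k0 = 20`` means mid-band for ``M = 40``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit


class CalibrationError(RuntimeError):
    """Raised when samples are requested from an uncalibrated model."""


@dataclass(frozen=True)
class StimulusModel:
    """Generative parameters for the synthetic tone-mixture stimuli.

    Parameters
    ----------
    n_channels
        Number of input channels ``M`` (log-spaced frequencies).
    min_tones, max_tones
        The number of tones per sample is drawn uniformly from
        ``{min_tones, ..., max_tones}``.
    amp_range
        Uniform range of tone amplitudes (arbitrary units; these stand for
        log-amplitudes of natural sounds).
    width_scale
        Scale of the folded-normal tone widths, in channel units.  ``None``
        defaults to ``M / 2`` (half the input domain).
    width_floor
        Lower floor on tone widths, avoiding sub-channel spikes.
    noise_range
        Uniform range of the additive per-channel background noise.
    norm_scale
        Global divisor fixed by :func:`calibrate_normalization`; ``None``
        while uncalibrated.
    """

    n_channels: int = 40
    min_tones: int = 1
    max_tones: int = 5
    amp_range: tuple[float, float] = (7.0, 10.0)
    width_scale: Optional[float] = None
    width_floor: float = 0.25
    noise_range: tuple[float, float] = (0.0, 1.0)
    norm_scale: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 input channels")
        if not 0 <= self.min_tones <= self.max_tones:
            raise ValueError("require 0 <= min_tones <= max_tones")
        if self.norm_scale is not None and self.norm_scale <= 0:
            raise ValueError("norm_scale must be positive")

    @property
    def effective_width_scale(self) -> float:
        return self.n_channels / 2 if self.width_scale is None else self.width_scale

    @property
    def channels(self) -> np.ndarray:
        """1-based channel axis ``[1, ..., M]``."""
        return np.arange(1, self.n_channels + 1, dtype=float)


def raw_stimulus(model: StimulusModel, rng: np.random.Generator) -> np.ndarray:
    """Draw one un-normalized sample: tone mixture plus background noise."""
    k = model.channels
    x = rng.uniform(*model.noise_range, size=model.n_channels)
    n_tones = int(rng.integers(model.min_tones, model.max_tones + 1))
    for _ in range(n_tones):
        center = rng.uniform(1.0, model.n_channels)
        width = max(abs(rng.normal(0.0, model.effective_width_scale)), model.width_floor)
        amp = rng.uniform(*model.amp_range)
        x += amp * np.exp(-0.5 * ((k - center) / width) ** 2)
    return x


def calibrate_normalization(
    model: StimulusModel, n_calibration: int = 10_000, rng: Optional[np.random.Generator] = None
) -> StimulusModel:
    """Fix the global normalization from a calibration batch.

    ``norm_scale`` is set to twice the highest activation observed over
    ``n_calibration`` raw samples and all channels, so that normalized
    samples lie in ``[0, 0.5]``.
    """
    if n_calibration < 1:
        raise ValueError("n_calibration must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    peak = 0.0
    for _ in range(n_calibration):
        peak = max(peak, float(raw_stimulus(model, rng).max()))
    return replace(model, norm_scale=2.0 * peak)


def generate_stimulus(model: StimulusModel, rng: np.random.Generator) -> np.ndarray:
    """Draw one normalized sample in ``[0, 0.5]``.

    Rare samples exceeding the calibration maximum are clipped to 0.5.
    """
    if model.norm_scale is None:
        raise CalibrationError(
            "stimulus model is uncalibrated; run calibrate_normalization first"
        )
    return np.clip(raw_stimulus(model, rng) / model.norm_scale, 0.0, 0.5)


def stimulus_batch(model: StimulusModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stack ``n`` normalized samples into an ``(n, M)`` array."""
    return np.stack([generate_stimulus(model, rng) for _ in range(n)])


@dataclass(frozen=True)
class AttenuationProfile:
    """Per-channel multiplicative attenuation envelope, values in [0, 1]."""

    values: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("attenuation values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.size

    def at_channel(self, k) -> np.ndarray:
        """Envelope value at 1-based channel index/indices ``k``."""
        return self.values[np.asarray(k) - 1]


def sigmoid_attenuation(k0: float, beta: float, m: int) -> AttenuationProfile:
    """Single-edge envelope ``a(k) = 1 / (1 + exp(-beta (k0 - k)))``.

    With ``beta > 0`` this attenuates the high frequencies (``k > k0``);
    a negative ``beta`` mirrors the profile and attenuates the lows.
    """
    if m < 2:
        raise ValueError("need at least 2 channels")
    k = np.arange(1, m + 1, dtype=float)
    return AttenuationProfile(expit(beta * (k0 - k)), {"kind": "sigmoid", "k0": k0, "beta": beta})


def band_attenuation(k1: float, k2: float, beta: float, m: int) -> AttenuationProfile:
    """Band-stop envelope from two opposing sigmoid edges.

    ``a(k) = 1 - (1 - sigma(beta (k1 - k))) * (1 - sigma(beta (k - k2)))``
    attenuates the band ``[k1, k2]`` and leaves both flanks near 1.
    """
    if k1 >= k2:
        raise ValueError("require k1 < k2")
    k = np.arange(1, m + 1, dtype=float)
    vals = 1.0 - (1.0 - expit(beta * (k1 - k))) * (1.0 - expit(beta * (k - k2)))
    return AttenuationProfile(vals, {"kind": "band", "k1": k1, "k2": k2, "beta": beta})


def apply_attenuation(x: np.ndarray, profile: AttenuationProfile) -> np.ndarray:
    """Multiply a stimulus (or batch, last axis = channels) by the envelope."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(profile):
        raise ValueError(
            f"stimulus has {x.shape[-1]} channels but profile has {len(profile)}"
        )
    return x * profile.values


def pure_tone_probe(
    k: int, amplitude: float, m: int, width: Optional[float] = None
) -> np.ndarray:
    """Probe stimulus active only at frequency channel ``k`` (1-based).

    By default a single-channel delta of the given amplitude; with ``width``
    set, a narrow Gaussian tone centered on ``k`` instead.
    """
    if not 1 <= k <= m:
        raise ValueError(f"channel {k} out of range 1..{m}")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if width is None:
        x = np.zeros(m)
        x[k - 1] = amplitude
    else:
        axis = np.arange(1, m + 1, dtype=float)
        x = amplitude * np.exp(-0.5 * ((axis - k) / width) ** 2)
    return x
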