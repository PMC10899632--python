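"""Synthetic 1-D lane densitometry: turn a transcript-length distribution
into the kind of lane trace a phosphorimager scan produces, plus marker
lanes, so the quantification stage can be tested round-trip against known
truth.

Each transcript length contributes a Gaussian band centered at its mapped
pixel with area proportional to its fraction of molecules; the point-spread
sigma models diffusion/scan blur.  Mobility is linear in length by default
(matching a calibration by straight-line regression); a log-length mode is
provided because denaturing-gel mobility is classically log-linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .simulate import LengthDistribution

__all__ = ["MobilityModel", "LaneProfile", "lengths_to_profile", "marker_lane",
           "default_mobility"]


@dataclass(frozen=True)
class MobilityModel:
    """Map transcript length (nt) to lane pixel position.

    ``linear``: pixel = intercept + slope * length.
    ``log``:    pixel = intercept + slope * ln(length).
    Slope may be negative (long species migrate less far); the map must be
    strictly monotonic over the template's length range.
    """

    mode: str = "linear"
    intercept: float = 60.0
    slope: float = 12.0
    lane_length: int = 3000

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "log"):
            raise ValueError("mode must be 'linear' or 'log'")
        if self.slope == 0:
            raise ValueError("slope must be non-zero (monotonic mapping)")

    def pixel_of(self, length: np.ndarray | float) -> np.ndarray | float:
        x = np.log(length) if self.mode == "log" else np.asarray(length, dtype=float)
        return self.intercept + self.slope * x

    def check_domain(self, lengths: np.ndarray) -> None:
        px = np.atleast_1d(self.pixel_of(lengths))
        if np.any(px < 0) or np.any(px >= self.lane_length):
            raise ValueError("mapped band positions fall outside the lane")


def default_mobility() -> MobilityModel:
    """A ~30 cm lane scanned at 100 um/px: 12 px per nt, 3000 px."""
    return MobilityModel()


@dataclass(frozen=True)
class LaneProfile:
    """A 1-D densitometry trace: non-negative intensity per pixel."""

    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1:
            raise ValueError("intensities must be 1-D")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "intensities", arr)

    @property
    def pixel_count(self) -> int:
        return len(self.intensities)

    @property
    def total(self) -> float:
        return float(self.intensities.sum())


def _band_profile(
    centers: np.ndarray,
    areas: np.ndarray,
    psf_sigma: float,
    n_pixels: int,
) -> np.ndarray:
    """Sum of Gaussian bands integrated over pixel bins (area-exact)."""
    out = np.zeros(n_pixels)
    edges = np.arange(n_pixels + 1) - 0.5
    if psf_sigma == 0:
        # delta bands: all area in the nearest pixel
        px = np.clip(np.rint(centers).astype(int), 0, n_pixels - 1)
        np.add.at(out, px, areas)
        return out
    for c, a in zip(centers, areas):
        lo = max(int(np.floor(c - 6 * psf_sigma)), 0)
        hi = min(int(np.ceil(c + 6 * psf_sigma)) + 1, n_pixels)
        if hi <= lo:
            continue
        cdf = norm.cdf(edges[lo : hi + 1], loc=c, scale=psf_sigma)
        out[lo:hi] += a * np.diff(cdf)
    return out


def lengths_to_profile(
    dist: LengthDistribution,
    mobility: MobilityModel | None = None,
    psf_sigma: float = 1.5,
    gain: float = 1e5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LaneProfile:
    """Render a length distribution as a lane trace.

    Each length's band has area ``gain * fraction``; optional additive
    Gaussian noise is truncated at zero.  With noise off the trace integral
    equals ``gain`` up to the tail mass clipped at the lane ends.
    """
    mobility = mobility or default_mobility()
    if psf_sigma < 0:
        raise ValueError("psf_sigma must be non-negative")
    if gain <= 0:
        raise ValueError("gain must be positive")
    frac = dist.fractions
    support = frac > 0
    lengths = dist.lengths[support]
    mobility.check_domain(lengths)
    centers = np.atleast_1d(mobility.pixel_of(lengths))
    profile = _band_profile(centers, gain * frac[support], psf_sigma,
                            mobility.lane_length)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        profile = profile + rng.normal(0.0, noise_sd, size=profile.shape)
        profile = np.clip(profile, 0.0, None)
    return LaneProfile(profile, label=f"t={dist.time_s:g}s")


def marker_lane(
    marker_lengths: list[float],
    mobility: MobilityModel | None = None,
    psf_sigma: float = 1.5,
    gain: float = 1e5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LaneProfile:
    """Render a size-standard lane: one equal-area band per marker length."""
    mobility = mobility or default_mobility()
    if len(marker_lengths) == 0:
        return LaneProfile(np.zeros(mobility.lane_length), label="marker")
    lengths = np.asarray(sorted(marker_lengths), dtype=float)
    mobility.check_domain(lengths)
    centers = np.atleast_1d(mobility.pixel_of(lengths))
    areas = np.full(len(lengths), gain / len(lengths))
    profile = _band_profile(centers, areas, psf_sigma, mobility.lane_length)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        profile = np.clip(profile + rng.normal(0.0, noise_sd, profile.shape), 0, None)
    return LaneProfile(profile, label="marker")


DEFAULT_MARKERS: tuple[float, ...] = (60, 90, 120, 150, 180, 210)
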