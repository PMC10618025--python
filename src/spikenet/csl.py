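"""Circular Smooth Label (CSL) encoding of oriented-box angles.

Angle regression on a 180°-periodic axis suffers a discontinuity at the
wrap; CSL instead treats the angle as a classification over ``K`` bins and
softens the one-hot target with a Gaussian window wrapped circularly around
the true bin, so near-miss angle predictions are only mildly penalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CSLConfig", "encode", "decode", "bin_of", "circular_bin_distance"]


@dataclass(frozen=True)
class CSLConfig:
    """K angle bins over [0, 180); Gaussian window of radius ``beta`` bins
    and width ``sigma`` bins.  Defaults give 1° bins with a ±6-bin window
    whose edge value is exp(-beta²/(2 sigma²)) ≈ 0.011."""

    K: int = 180
    beta: int = 6
    sigma: float = 2.0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        if not (0 < self.beta < self.K / 2):
            raise ValueError(f"beta must be in (0, K/2), got {self.beta}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def bin_width_deg(self) -> float:
        return 180.0 / self.K


def bin_of(theta_deg: float, cfg: CSLConfig) -> int:
    """Nearest angle bin of ``theta_deg`` (normalized modulo 180)."""
    t = float(theta_deg) % 180.0
    return int(round(t * cfg.K / 180.0)) % cfg.K


def circular_bin_distance(bins: np.ndarray, center: int, K: int) -> np.ndarray:
    d = np.abs(np.asarray(bins) - center)
    return np.minimum(d, K - d)


def encode(theta_deg: float, cfg: CSLConfig) -> np.ndarray:
    """Length-K circular smooth label for an angle.

    Bin ``b`` receives ``exp(-d²/(2 sigma²))`` where ``d`` is the circular
    bin distance to the true bin, zeroed outside the window ``d <= beta``.
    The true bin always carries exactly 1.
    """
    b0 = bin_of(theta_deg, cfg)
    d = circular_bin_distance(np.arange(cfg.K), b0, cfg.K)
    vec = np.exp(-(d.astype(float) ** 2) / (2.0 * cfg.sigma**2))
    vec[d > cfg.beta] = 0.0
    return vec


def decode(scores, cfg: CSLConfig) -> float:
    """Angle (degrees in [0, 180)) from per-bin scores: argmax bin center.

    All-equal scores resolve to bin 0 (NumPy argmax takes the first maximum),
    which is the documented tie-break.
    """
    scores = np.asarray(scores)
    if scores.shape[-1] != cfg.K:
        raise ValueError(f"expected {cfg.K} scores, got {scores.shape[-1]}")
    b = int(np.argmax(scores, axis=-1))
    return (b * 180.0 / cfg.K) % 180.0
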