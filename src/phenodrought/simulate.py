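"""Synthetic pot trial and plant images with known ground truth.

The generator emulates an 18-genotype × 2-treatment (WW/WS) × 2-replicate
greenhouse screen: each line belongs to a tolerance class (low, moderate,
tolerant) whose class ratio profile fixes the expected WS/WW mean ratio
per trait; well-watered replicate values scatter multiplicatively around
published trait means, and water-stressed values around mean × ratio.
Class profiles follow the qualitative stress response of a vegetative
drought screen — shoot traits depressed (severely so for susceptible
lines), root length / tips / forks / lateral-root share increased in
tolerant lines, leaf osmotic potential roughly doubled in magnitude
(osmotic adjustment) — and their 17-term sums land each class inside its
TDRI band by construction.

Noise is multiplicative Gaussian, truncated at ±3σ so positive traits
stay positive and the (negative) osmotic potential stays negative.
Count traits are rounded to integers ≥ 1.  All randomness flows through
:class:`numpy.random.Generator` (PCG64), so identical seeds give
identical tables on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import OBS_COLUMNS, TDRI_TRAITS

__all__ = [
    "SyntheticTrialConfig",
    "InvalidProfileError",
    "DEFAULT_WW_MEANS",
    "DEFAULT_CLASS_PROFILES",
    "generate_trial",
    "generate_plant_image",
]

#: Well-watered trait means used as generator baselines (published
#: trial-wide WW means of the 17 index traits; LOP in MPa is negative).
DEFAULT_WW_MEANS: dict[str, float] = {
    "TN": 6.19, "PH": 44.6, "CC": 6.27, "LOP": -1.31, "LGA": 269.4,
    "RGR": 0.139, "SDW": 1.39, "RDW": 0.426, "RSR": 0.31, "RL": 1246.0,
    "CRN": 73.1, "CRPT": 12.74, "MRL": 24.8, "RAD": 0.20, "RTi": 10784.0,
    "RF": 8807.1, "PLR": 77.4,
}

#: Mean water uptake (kg) under stress, for the WS-only water traits.
DEFAULT_WU_WS_MEAN = 0.42

#: Traits generated as integer counts (≥ 1).
COUNT_TRAITS = frozenset({"TN", "CRN", "RTi", "RF"})

#: Target WS/WW ratios per tolerance class.  Sums: low 14.0 (≤ 15.05),
#: moderate 16.0 (15.05–17.05), tolerant 18.1 (> 17.05).
DEFAULT_CLASS_PROFILES: dict[str, dict[str, float]] = {
    "low": {
        "TN": 0.60, "PH": 0.60, "CC": 0.55, "LGA": 0.50, "RGR": 0.55,
        "SDW": 0.50, "RDW": 0.45, "RSR": 0.75, "RL": 1.10, "CRN": 0.50,
        "CRPT": 0.70, "MRL": 0.95, "RAD": 0.85, "RTi": 1.05, "RF": 1.30,
        "PLR": 1.05, "LOP": 2.00,
    },
    "moderate": {
        "TN": 0.75, "PH": 0.75, "CC": 0.70, "LGA": 0.65, "RGR": 0.70,
        "SDW": 0.65, "RDW": 0.55, "RSR": 0.80, "RL": 1.25, "CRN": 0.60,
        "CRPT": 0.80, "MRL": 1.00, "RAD": 0.90, "RTi": 1.15, "RF": 1.60,
        "PLR": 1.07, "LOP": 2.10,
    },
    "tolerant": {
        "TN": 0.90, "PH": 0.85, "CC": 0.80, "LGA": 0.75, "RGR": 0.80,
        "SDW": 0.80, "RDW": 0.70, "RSR": 0.85, "RL": 1.40, "CRN": 0.70,
        "CRPT": 0.85, "MRL": 1.05, "RAD": 0.95, "RTi": 1.30, "RF": 2.10,
        "PLR": 1.10, "LOP": 2.20,
    },
}

_BAND_INTERVALS = {
    "low": (-np.inf, 15.05),
    "moderate": (15.05, 17.05),
    "tolerant": (17.05, np.inf),
}


class InvalidProfileError(ValueError):
    """A class ratio profile's TDRI sum falls outside its tolerance band."""


@dataclass
class SyntheticTrialConfig:
    """Parameters of the simulated screen.

    Defaults reproduce the reference panel structure: 6 low, 3 moderate
    and 6 tolerant lines with 2 replicate pots per treatment and 8%
    multiplicative noise (a conservative between-pot CV for controlled
    greenhouse conditions).
    """

    n_low: int = 6
    n_moderate: int = 3
    n_tolerant: int = 6
    n_replicates: int = 2
    ww_trait_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WW_MEANS))
    class_ratio_profiles: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_PROFILES.items()})
    wu_ws_mean: float = DEFAULT_WU_WS_MEAN
    noise_cv: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_low, self.n_moderate, self.n_tolerant) < 0:
            raise ValueError("class sizes must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if not 0 <= self.noise_cv < 1 / 3:
            raise ValueError("noise_cv must lie in [0, 1/3) to preserve signs")
        missing = [t for t in TDRI_TRAITS if t not in self.ww_trait_means]
        if missing:
            raise ValueError(f"ww_trait_means lacks traits {missing}")
        for band, profile in self.class_ratio_profiles.items():
            if band not in _BAND_INTERVALS:
                raise InvalidProfileError(f"unknown tolerance band {band!r}")
            miss = [t for t in TDRI_TRAITS if t not in profile]
            if miss:
                raise InvalidProfileError(f"profile {band!r} lacks traits {miss}")
            total = sum(profile[t] for t in TDRI_TRAITS)
            lo, hi = _BAND_INTERVALS[band]
            if not lo < total <= hi:
                raise InvalidProfileError(
                    f"profile {band!r} sums to {total:.3f}, outside its band "
                    f"({lo}, {hi}]"
                )

    def expected_tdri(self, band: str) -> float:
        return float(sum(self.class_ratio_profiles[band][t] for t in TDRI_TRAITS))


def _noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative factors 1 + ε with ε ~ N(0, cv²) clipped at ±3σ."""
    if cv == 0:
        return np.ones(size)
    eps = np.clip(rng.normal(0.0, cv, size), -3 * cv, 3 * cv)
    return 1.0 + eps


def _finalize(trait: str, values: np.ndarray, integer_counts: bool) -> np.ndarray:
    # Count traits are integer measurements, but only in the noisy regime:
    # the noiseless mode keeps exact values so the generating TDRI is
    # recoverable to machine precision.
    if integer_counts and trait in COUNT_TRAITS:
        return np.maximum(np.rint(values), 1.0)
    return values


def generate_trial(
    cfg: SyntheticTrialConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full screen; returns (observations, ground truth).

    Observations are a canonical long table over the 17 index traits
    under both treatments plus water uptake (WU) under stress.  The
    truth table carries each line's generating band and the exact TDRI
    its profile encodes (recovered exactly at ``noise_cv = 0``).
    """
    cfg = cfg or SyntheticTrialConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    lines: list[tuple[str, str]] = []
    for band, n in (("low", cfg.n_low), ("moderate", cfg.n_moderate),
                    ("tolerant", cfg.n_tolerant)):
        for i in range(n):
            lines.append((f"SYN-{band[:3].upper()}-{i + 1:02d}", band))

    rows = []
    reps = cfg.n_replicates
    noisy = cfg.noise_cv > 0
    for line_id, band in lines:
        profile = cfg.class_ratio_profiles[band]
        for trait in TDRI_TRAITS:
            mean = cfg.ww_trait_means[trait]
            ww = _finalize(trait, mean * _noise(rng, cfg.noise_cv, reps), noisy)
            ws = _finalize(
                trait, mean * profile[trait] * _noise(rng, cfg.noise_cv, reps),
                noisy)
            for r in range(reps):
                rows.append((line_id, "WW", r + 1, trait, ww[r], 35))
                rows.append((line_id, "WS", r + 1, trait, ws[r], 35))
        wu = cfg.wu_ws_mean * _noise(rng, cfg.noise_cv, reps)
        for r in range(reps):
            rows.append((line_id, "WS", r + 1, "WU", wu[r], 35))

    obs = pd.DataFrame(rows, columns=list(OBS_COLUMNS))
    truth = pd.DataFrame(
        [(lid, band, cfg.expected_tdri(band)) for lid, band in lines],
        columns=["line_id", "band", "expected_tdri"],
    )
    return obs, truth


# ---------------------------------------------------------------------------
# Plant image generator
# ---------------------------------------------------------------------------

_CARD_BLUE = (30, 60, 200)
_LEAF_GREEN = (60, 140, 60)
_BACKGROUND = (255, 255, 255)


def generate_plant_image(
    leaf_area_cm2: float,
    card_area_cm2: float = 100.0,
    px_per_cm: float = 5.0,
    canvas: tuple[int, int] = (400, 600),
    seed: int = 0,
) -> tuple[np.ndarray, int, int]:
    """Paint a synthetic screening photo with exact known pixel counts.

    A blue calibration-card block of exactly ``round(card_area·ppcm²)``
    pixels sits on the left; green foliage blobs totalling exactly
    ``round(leaf_area·ppcm²)`` pixels fill the right, all on a white
    background and never overlapping.  Returns (image, green_count,
    blue_count) so the painted counts serve as a segmentation oracle.
    """
    if leaf_area_cm2 < 0 or card_area_cm2 <= 0 or px_per_cm <= 0:
        raise ValueError("areas and resolution must be positive")
    h, w = canvas
    ppc2 = px_per_cm ** 2
    n_blue = int(round(card_area_cm2 * ppc2))
    n_green = int(round(leaf_area_cm2 * ppc2))

    card_w = max(1, int(np.ceil(np.sqrt(n_blue))))
    card_h = int(np.ceil(n_blue / card_w))
    margin = 4
    leaf_x0 = margin + card_w + margin
    leaf_w = w - leaf_x0 - margin
    leaf_h = h - 2 * margin
    if card_h + 2 * margin > h or leaf_w < 1 or n_green > leaf_w * leaf_h:
        raise ValueError(
            f"canvas {canvas} too small for card {n_blue}px + foliage {n_green}px"
        )

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = _BACKGROUND

    flat = np.arange(n_blue)
    img[margin + flat // card_w, margin + flat % card_w] = _CARD_BLUE

    if n_green:
        rng = np.random.default_rng(seed)
        # a handful of blobs: row-major fills of shuffled row-bands, so the
        # canopy is fragmented but the total pixel count stays exact
        rows = rng.permutation(leaf_h)
        painted = 0
        for row in rows:
            take = min(leaf_w, n_green - painted)
            if take <= 0:
                break
            x0 = leaf_x0 + int(rng.integers(0, leaf_w - take + 1))
            img[margin + row, x0:x0 + take] = _LEAF_GREEN
            painted += take
    return img, n_green, n_blue
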