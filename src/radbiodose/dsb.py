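"""γH2AX-style DNA double-strand-break quantification from image pairs.

A measurement is a two-channel fluorescence image: a nuclear stain channel
(e.g. Hoechst) and a damage channel (phospho-H2AX).  Both channels are
segmented (Otsu by default), and the DSB burden is the damage area as a
percentage of the total nuclear morphology, where the nuclear morphology is
the union of the two masks (damaged area counts as nuclear area even where
the nuclear stain is displaced):

    %DSB = 100 · |damage| / |damage ∪ nuclei|

The %DSB–dose response over a treatment series is summarised by an ordinary
least-squares line with a free intercept (untreated controls show a nonzero
baseline), and the relative biological effectiveness of one radiation
quality against another is the ratio of fitted slopes — for linear
responses this equals the iso-effect dose ratio at any effect level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import (
    DegenerateThresholdError,
    DomainError,
    InsufficientDataError,
    NoCellsError,
)


@dataclass(frozen=True)
class ImagePair:
    """Aligned nuclei/damage intensity grids with a common pixel size (µm)."""

    nuclei_channel: np.ndarray
    damage_channel: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self):
        nuc = np.asarray(self.nuclei_channel)
        dmg = np.asarray(self.damage_channel)
        if nuc.shape != dmg.shape or nuc.ndim != 2:
            raise DomainError("channels must be 2-D grids of equal shape")
        for arr in (nuc, dmg):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise DomainError("intensities must be finite and non-negative")
        if self.pixel_size_um <= 0:
            raise DomainError("pixel size must be positive")


@dataclass(frozen=True)
class DSBMeasurement:
    dose_gy: float
    percent_dsb: float
    n_cells: int = 1

    def __post_init__(self):
        if not 0.0 <= self.percent_dsb <= 100.0:
            raise DomainError("percent_dsb must be in [0, 100]")
        if self.dose_gy < 0:
            raise DomainError("dose must be non-negative")
        if self.n_cells < 1:
            raise DomainError("n_cells must be positive")


@dataclass(frozen=True)
class LinearFit:
    slope: float  # %/Gy
    intercept: float  # %
    slope_se: float
    residual_sd: float


def segment_mask(channel, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Binary foreground mask of an intensity grid.

    ``method="otsu"`` uses Otsu's criterion (deterministic, seedless);
    ``method="fixed"`` thresholds at the supplied value.
    """
    arr = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("intensities must be finite")
    if method == "fixed":
        if threshold is None:
            raise DomainError("fixed thresholding requires a threshold value")
        return arr > threshold
    if method == "otsu":
        if np.ptp(arr) == 0:
            raise DegenerateThresholdError("Otsu threshold undefined for a constant image")
        return arr > threshold_otsu(arr)
    raise DomainError(f"unknown segmentation method {method!r}")


def percent_dsb(nuclear_mask, damage_mask) -> float:
    """100 × damage area / (damage ∪ nuclei) area."""
    nuc = np.asarray(nuclear_mask, dtype=bool)
    dmg = np.asarray(damage_mask, dtype=bool)
    if nuc.shape != dmg.shape:
        raise DomainError("masks must have equal shapes")
    union = int(np.count_nonzero(nuc | dmg))
    if union == 0:
        raise NoCellsError("no nuclear area in either mask; %DSB undefined")
    return 100.0 * np.count_nonzero(dmg) / union


def measure_image_pair(pair: ImagePair, method: str = "otsu") -> float:
    """Segment both channels and return the %DSB of the pair."""
    nuc = segment_mask(pair.nuclei_channel, method=method)
    dmg = segment_mask(pair.damage_channel, method=method)
    return percent_dsb(nuc, dmg)


def fit_linear_response(measurements) -> LinearFit:
    """OLS of %DSB on dose with a free intercept (needs ≥ 3 distinct doses)."""
    ms = list(measurements)
    doses = np.array([m.dose_gy for m in ms], dtype=float)
    y = np.array([m.percent_dsb for m in ms], dtype=float)
    if len(np.unique(doses)) < 3:
        raise InsufficientDataError("linear response fit needs >= 3 distinct doses")
    x = doses - doses.mean()
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * doses.mean())
    resid = y - (intercept + slope * doses)
    dof = max(1, len(ms) - 2)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    slope_se = residual_sd / math.sqrt(sxx)
    return LinearFit(slope=slope, intercept=intercept, slope_se=slope_se,
                     residual_sd=residual_sd)


def rbe_from_slopes(slope_test: float, slope_ref: float) -> float:
    """Iso-effect RBE of a linear response: test slope over reference slope."""
    if slope_test <= 0 or slope_ref <= 0:
        raise DomainError("RBE from slopes requires positive slopes")
    return slope_test / slope_ref
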