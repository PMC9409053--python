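"""Biodistribution-based tumour/organ dosimetry and tumour-growth summaries.

Organ kinetics are percent administered activity per gram (%AA/g) at a few
sampling times.  The time-integrated activity concentration ã (decays per
gram per MBq administered) is obtained either by

* ``trapezoid_physical_tail`` (default): linear rise from zero at injection
  to the first sample, trapezoids between samples, and an exponential tail
  beyond the last sample decaying at the faster of the fitted effective
  rate and the physical decay constant (activity cannot outlive physical
  decay); or
* ``monoexp_fit``: a single exponential through the samples integrated over
  (0, ∞).

The absorbed dose coefficient follows the MIRD-style product

    Gy/MBq = ã · Ē · 1.602e−16 J/keV · 1000 g/kg · φ · w

with Ē the emitted energy per decay (keV), φ the absorbed fraction
(1.0 for tumour self-dose here) and w an optional RBE weighting (1 by
default; 5 is the conventional value for targeted-alpha-therapy equivalent
dose).

Tumour growth series are day-indexed relative sizes (normalised to day 0);
``regrowth_day`` operationalises "regrowth" as the first measured day after
the series minimum that exceeds the minimum by a rebound fraction on two
consecutive measurements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError
from .nuclides import Nuclide

log = logging.getLogger(__name__)

#: 1 %AA/g of a 1 MBq administration = 1e6 Bq × 0.01 / g
BQ_PER_G_PER_PERCENT_AA_MBQ = 1.0e4
KEV_TO_J = 1.602176634e-16


@dataclass(frozen=True)
class BiodistributionRow:
    organ: str
    time_h: float
    value: float
    unit: str = "%AA/g"  # thyroid conventionally reported whole-organ as %AA
    n: int = 1
    sd: float = 0.0

    def __post_init__(self):
        if self.value < 0 or self.sd < 0:
            raise DomainError("biodistribution values and sd must be non-negative")
        if self.unit not in ("%AA/g", "%AA"):
            raise DomainError("unit must be %AA/g or %AA")


@dataclass(frozen=True)
class BiodistributionTable:
    rows: tuple[BiodistributionRow, ...]

    def organs(self) -> tuple[str, ...]:
        seen = {}
        for r in self.rows:
            seen.setdefault(r.organ, None)
        return tuple(seen)

    def samples(self, organ: str, per_gram_only: bool = True):
        """Sorted (time_h, value) pairs for one organ."""
        rows = [r for r in self.rows if r.organ == organ
                and (not per_gram_only or r.unit == "%AA/g")]
        return sorted((r.time_h, r.value) for r in rows)


@dataclass(frozen=True)
class TimeIntegratedActivity:
    organ: str
    a_tilde_bq_s_per_g_mbq: float  # decays per gram per MBq administered
    scheme: str


@dataclass(frozen=True)
class AbsorbedDoseCoefficient:
    organ: str
    gy_per_mbq: float
    absorbed_fraction: float = 1.0
    rbe_weight: float = 1.0


@dataclass(frozen=True)
class TumorGrowthSeries:
    group: str
    day: tuple[float, ...]
    relative_size: tuple[float, ...]
    relative_weight: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self):
        days = np.asarray(self.day, dtype=float)
        size = np.asarray(self.relative_size, dtype=float)
        if len(days) != len(size):
            raise DomainError("day and relative_size must have equal length")
        if len(days) and np.any(np.diff(days) <= 0):
            raise DomainError("days must be strictly increasing")
        if len(days) and days[0] == 0 and not math.isclose(size[0], 1.0, rel_tol=1e-9):
            raise DomainError("relative size must be 1 at day 0")
        if len(size) and np.any(size <= 0):
            raise DomainError("relative sizes must be positive")


def time_integrated_concentration(
    samples,
    nuclide: Nuclide,
    scheme: str = "trapezoid_physical_tail",
    organ: str = "tumour",
) -> TimeIntegratedActivity:
    """ã for one organ from (time h, %AA/g) samples, per MBq administered."""
    pts = sorted((float(t), float(c)) for t, c in samples)
    if len(pts) < 2:
        raise InsufficientDataError("time integration needs >= 2 timepoints")
    if any(t < 0 or c < 0 for t, c in pts):
        raise DomainError("times and concentrations must be non-negative")
    lam_h = nuclide.decay_constant_per_s * 3600.0
    times = np.array([p[0] for p in pts])
    conc = np.array([p[1] for p in pts])

    if scheme == "monoexp_fit":
        if np.all(conc == 0):
            integral_h = 0.0
        else:
            if np.any(conc <= 0):
                raise DomainError("monoexp_fit requires positive concentrations")
            slope, logc0 = np.polyfit(times, np.log(conc), 1)
            rate = -slope
            if rate < lam_h:
                if rate <= 0:
                    log.warning("non-physical rising kinetics; falling back to physical decay")
                rate = max(rate, lam_h) if rate > 0 else lam_h
            c0 = math.exp(logc0)
            integral_h = c0 / rate
    elif scheme == "trapezoid_physical_tail":
        # linear rise from 0 at t=0, trapezoids, exponential physical-floored tail
        integral_h = 0.5 * times[0] * conc[0]
        integral_h += float(np.trapezoid(conc, times))
        c_last = conc[-1]
        if c_last > 0:
            if len(pts) >= 2 and conc[-2] > 0 and conc[-1] < conc[-2]:
                rate = math.log(conc[-2] / conc[-1]) / (times[-1] - times[-2])
            else:
                log.warning("tail rate not estimable or rising; using physical decay constant")
                rate = lam_h
            rate = max(rate, lam_h)
            integral_h += c_last / rate
    else:
        raise DomainError(f"unknown integration scheme {scheme!r}")

    a_tilde = integral_h * 3600.0 * BQ_PER_G_PER_PERCENT_AA_MBQ
    return TimeIntegratedActivity(organ=organ, a_tilde_bq_s_per_g_mbq=a_tilde, scheme=scheme)


def absorbed_dose_per_mbq(
    a_tilde: TimeIntegratedActivity,
    nuclide: Nuclide,
    absorbed_fraction: float = 1.0,
    rbe_weight: float = 1.0,
) -> AbsorbedDoseCoefficient:
    """Dose coefficient Gy/MBq from ã and the emitted energy per decay."""
    if not 0.0 < absorbed_fraction <= 1.0:
        raise DomainError("absorbed fraction must be in (0, 1]")
    if rbe_weight <= 0:
        raise DomainError("RBE weight must be positive")
    if a_tilde.a_tilde_bq_s_per_g_mbq < 0:
        raise DomainError("time-integrated activity must be non-negative")
    gy = (a_tilde.a_tilde_bq_s_per_g_mbq * nuclide.energy_per_decay_kev
          * KEV_TO_J * 1000.0 * absorbed_fraction * rbe_weight)
    return AbsorbedDoseCoefficient(organ=a_tilde.organ, gy_per_mbq=gy,
                                   absorbed_fraction=absorbed_fraction,
                                   rbe_weight=rbe_weight)


def regrowth_day(series: TumorGrowthSeries, rebound_fraction: float = 0.2):
    """First measured day after the minimum with sustained regrowth, else None.

    Sustained means relative size ≥ (1 + rebound_fraction) × minimum on two
    consecutive measurements (the last point alone cannot qualify).
    """
    if len(series.day) < 3:
        raise InsufficientDataError("regrowth detection needs >= 3 timepoints")
    if rebound_fraction <= 0:
        raise DomainError("rebound fraction must be positive")
    size = np.asarray(series.relative_size)
    days = np.asarray(series.day)
    i_min = int(np.argmin(size))
    thresh = (1.0 + rebound_fraction) * size[i_min]
    for i in range(i_min + 1, len(size) - 1):
        if size[i] >= thresh and size[i + 1] >= thresh:
            return float(days[i])
    return None


def compare_groups_at_day(series_by_group: dict, day: float, correction: str = "bonferroni"):
    """Pairwise unpaired t-tests on relative size at a day, Bonferroni-corrected.

    ``series_by_group`` maps group name → list of per-animal
    :class:`TumorGrowthSeries`.  Returns {(group_a, group_b): corrected p}.
    """
    if correction != "bonferroni":
        raise DomainError("only Bonferroni correction is supported")
    values = {}
    for group, series_list in series_by_group.items():
        vals = []
        for s in series_list:
            match = [sz for d, sz in zip(s.day, s.relative_size) if d == day]
            if match:
                vals.append(match[0])
        if len(vals) < 2:
            raise InsufficientDataError(
                f"group {group!r} has < 2 animals measured at day {day}"
            )
        values[group] = vals
    groups = sorted(values)
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    m = len(pairs)
    out = {}
    for a, b in pairs:
        # classic unpaired (pooled-variance) t-test
        p = stats.ttest_ind(values[a], values[b], equal_var=True).pvalue
        if math.isnan(p):  # identical constant groups
            p = 1.0
        out[(a, b)] = min(1.0, p * m)
    return out
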