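"""Seeded synthetic-data generators for every analysis stage.

Each generator emulates the statistical structure its downstream estimator
assumes and returns its ground truth alongside the data, so the whole
pipeline is testable without external measurements:

* DSB image pairs: non-overlapping disk nuclei, a damage subregion whose
  pixel count is exactly the dose-proportional target fraction of the
  nuclear area, optional blur and Gaussian intensity noise;
* colony assays: Binomial(seeded, PE · exp(−αD − βD²)) colony counts;
* biodistribution: mono-exponential organ kinetics with log-normal
  between-animal noise (effective rate floored at physical decay);
* tumour growth: shrink–plateau–regrow curves normalised to day 0 with
  log-normal animal noise.

Identical parameters and seed give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import gaussian

from .dsb import ImagePair
from .errors import ParameterError
from .invivo import BiodistributionRow, BiodistributionTable, TumorGrowthSeries
from .nuclides import Nuclide
from .survival import ColonyAssayRecord


@dataclass(frozen=True)
class GeneratorSpec:
    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0


#: Default organ kinetics (name, %AA/g at 3 h, effective half-life h) for the
#: biodistribution generator: iodide clears quickly from NIS organs while
#: astatide is retained, so At-211 kinetics are dominated by physical decay.
DEFAULT_ORGAN_KINETICS = {
    "I-131": [("tumour", 6.0, 5.0), ("thyroid", 25.0, 40.0), ("stomach", 8.0, 6.0)],
    "At-211": [("tumour", 5.0, 7.214), ("thyroid", 30.0, 7.214), ("stomach", 10.0, 7.0)],
}

#: Default tumour-growth groups (name, growth rate /day, log-kill, regrowth
#: delay days): untreated xenografts double in ~6 days; treated groups show
#: dose-dependent regrowth delays on the scale seen in NIS-targeted therapy.
DEFAULT_GROWTH_GROUPS = [
    ("control", 0.12, 0.0, 0.0),
    ("low", 0.12, 1.2, 18.0),
    ("high", 0.12, 2.0, 46.0),
]


# ---------------------------------------------------------------------------
# DSB images


def generate_dsb_images(
    doses_gy,
    n_nuclei: int = 25,
    damage_area_per_gy: float = 0.06,
    baseline_fraction: float = 0.03,
    noise_sd: float = 0.05,
    seed: int = 0,
    image_shape=(256, 256),
    nucleus_radius_px: int = 10,
    blur_sigma: float = 1.0,
    pixel_size_um: float = 1.0,
):
    """One (ImagePair, ground-truth %DSB) per dose.

    The damaged subset of each nucleus is the innermost
    round(fraction × area) pixels, so the ground-truth mask ratio equals the
    requested fraction up to pixel rounding, exactly as counted on the masks.
    """
    doses = [float(d) for d in doses_gy]
    max_frac = baseline_fraction + damage_area_per_gy * max(doses, default=0.0)
    if not 0.0 <= baseline_fraction <= 1.0 or max_frac > 1.0 or damage_area_per_gy < 0:
        raise ParameterError(
            f"infeasible damage fraction: baseline {baseline_fraction} + slope×max dose "
            f"gives {max_frac:.3f} (must stay within [0, 1])"
        )
    rng = np.random.default_rng(seed)
    out = []
    h, w = image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    for dose in doses:
        frac = baseline_fraction + damage_area_per_gy * dose
        nuc_mask = np.zeros(image_shape, dtype=bool)
        dmg_mask = np.zeros(image_shape, dtype=bool)
        centers = []
        attempts = 0
        while len(centers) < n_nuclei and attempts < 50 * n_nuclei:
            attempts += 1
            cy = rng.integers(nucleus_radius_px, h - nucleus_radius_px)
            cx = rng.integers(nucleus_radius_px, w - nucleus_radius_px)
            if any((cy - oy) ** 2 + (cx - ox) ** 2 < (2 * nucleus_radius_px + 2) ** 2
                   for oy, ox in centers):
                continue
            centers.append((cy, cx))
            r2 = (yy - cy) ** 2 + (xx - cx) ** 2
            disk = r2 <= nucleus_radius_px**2
            nuc_mask |= disk
            n_px = int(np.count_nonzero(disk))
            n_dmg = int(round(frac * n_px))
            if n_dmg > 0:
                # innermost pixels by radial distance: a deterministic subset
                flat = np.argsort(r2[disk], kind="stable")[:n_dmg]
                idx = np.flatnonzero(disk.ravel())[flat]
                dmg_flat = dmg_mask.ravel()
                dmg_flat[idx] = True
                dmg_mask = dmg_flat.reshape(image_shape)
        if not centers:
            raise ParameterError("could not place any nucleus; image too small")
        truth = 100.0 * np.count_nonzero(dmg_mask) / np.count_nonzero(nuc_mask | dmg_mask)
        nuc_img = nuc_mask.astype(float)
        dmg_img = dmg_mask.astype(float)
        if blur_sigma > 0:
            nuc_img = gaussian(nuc_img, sigma=blur_sigma, preserve_range=True)
            dmg_img = gaussian(dmg_img, sigma=blur_sigma, preserve_range=True)
        if noise_sd > 0:
            nuc_img = nuc_img + rng.normal(0.0, noise_sd, image_shape)
            dmg_img = dmg_img + rng.normal(0.0, noise_sd, image_shape)
        nuc_img = np.clip(nuc_img, 0.0, None)
        dmg_img = np.clip(dmg_img, 0.0, None)
        out.append((ImagePair(nuc_img, dmg_img, pixel_size_um=pixel_size_um), truth))
    return out


# ---------------------------------------------------------------------------
# colony assay


def generate_colony_assay(
    alpha: float,
    beta: float,
    doses_gy,
    cells_seeded: int = 1000,
    plating_efficiency: float = 0.6,
    replicates: int = 3,
    seed: int = 0,
) -> list[ColonyAssayRecord]:
    """Binomial colony counts under LQ survival at each dose × replicate."""
    if alpha < 0 or beta < 0:
        raise ParameterError("alpha and beta must be non-negative")
    if not 0.0 < plating_efficiency <= 1.0:
        raise ParameterError("plating efficiency must be in (0, 1]")
    if cells_seeded <= 0 or replicates <= 0:
        raise ParameterError("cells_seeded and replicates must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for dose in doses_gy:
        if dose < 0:
            raise ParameterError("doses must be non-negative")
        p = plating_efficiency * math.exp(-alpha * dose - beta * dose * dose)
        for rep in range(replicates):
            colonies = int(rng.binomial(cells_seeded, p))
            records.append(ColonyAssayRecord(activity_bq=0.0, dose_gy=float(dose),
                                             colonies=colonies, cells_seeded=cells_seeded,
                                             replicate=f"r{rep + 1}"))
    return records


# ---------------------------------------------------------------------------
# biodistribution


def generate_biodistribution(
    organs,
    nuclide: Nuclide,
    timepoints_h=(3.0, 24.0),
    n_animals: int = 6,
    cv: float = 0.15,
    seed: int = 0,
):
    """(BiodistributionTable, truth) from per-organ mono-exponential kinetics.

    ``organs`` is a list of (name, uptake %AA/g at 3 h, effective half-life h);
    truth maps organ → (c0 at t=0, effective rate /h).  Per-animal values are
    log-normal around the kinetic mean with coefficient of variation ``cv``.
    """
    if cv < 0:
        raise ParameterError("cv must be non-negative")
    if n_animals < 1:
        raise ParameterError("n_animals must be positive")
    phys_half_life_h = nuclide.half_life_s / 3600.0
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    rows = []
    truth = {}
    for name, uptake_3h, t_eff_h in organs:
        if t_eff_h > phys_half_life_h * (1 + 1e-9):
            raise ParameterError(
                f"effective half-life {t_eff_h} h exceeds physical {phys_half_life_h:.3f} h"
            )
        if uptake_3h < 0 or t_eff_h <= 0:
            raise ParameterError("uptake and effective half-life must be positive")
        rate = math.log(2.0) / t_eff_h
        c0 = uptake_3h * math.exp(rate * 3.0)
        truth[name] = (c0, rate)
        for t in timepoints_h:
            mean_c = c0 * math.exp(-rate * t)
            if sigma > 0 and mean_c > 0:
                vals = mean_c * np.exp(rng.normal(-0.5 * sigma**2, sigma, n_animals))
            else:
                vals = np.full(n_animals, mean_c)
            rows.append(BiodistributionRow(organ=name, time_h=float(t),
                                           value=float(np.mean(vals)), unit="%AA/g",
                                           n=n_animals, sd=float(np.std(vals, ddof=1))
                                           if n_animals > 1 else 0.0))
    return BiodistributionTable(rows=tuple(rows)), truth


# ---------------------------------------------------------------------------
# tumour growth


def _growth_curve(t, growth_rate, kill_effect, delay_days):
    """Relative-size mean curve: exponential shrink, plateau, regrowth."""
    if kill_effect <= 0:
        return math.exp(growth_rate * t)
    t_dec = min(7.0, delay_days) if delay_days > 0 else 7.0
    nadir = math.exp(-kill_effect)
    if t < t_dec:
        return math.exp(-kill_effect * t / t_dec)
    if t < delay_days:
        return nadir
    return nadir * math.exp(growth_rate * (t - delay_days))


def generate_tumor_growth(
    groups,
    days,
    n_animals: int = 4,
    cv: float = 0.1,
    seed: int = 0,
):
    """(series_by_group, truth) of per-animal relative tumour sizes.

    ``groups`` is a list of (name, growth rate /day, kill effect (total
    log-kill), regrowth delay days); ``truth`` maps group → delay.  Day 0 is
    exactly 1 for every animal by normalisation.
    """
    days = [float(d) for d in days]
    if not days or days[0] != 0.0:
        raise ParameterError("days must start at 0")
    if cv < 0 or n_animals < 1:
        raise ParameterError("cv must be >= 0 and n_animals >= 1")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    series_by_group: dict[str, list[TumorGrowthSeries]] = {}
    truth = {}
    for name, growth_rate, kill_effect, delay_days in groups:
        if growth_rate < 0 or kill_effect < 0 or delay_days < 0:
            raise ParameterError("group parameters must be non-negative")
        truth[name] = delay_days
        animals = []
        for a in range(n_animals):
            mean = np.array([_growth_curve(t, growth_rate, kill_effect, delay_days)
                             for t in days])
            if sigma > 0:
                noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, len(days)))
            else:
                noise = np.ones(len(days))
            vals = mean * noise
            vals = vals / vals[0]  # day-0 normalisation is exact
            animals.append(TumorGrowthSeries(group=name, day=tuple(days),
                                             relative_size=tuple(float(v) for v in vals),
                                             relative_weight=()))
        series_by_group[name] = animals
    return series_by_group, truth
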