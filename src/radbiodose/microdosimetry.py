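"""Monte Carlo cellular S-values for a coaxial-cylinder dish geometry.

The in vitro treatment is modelled as three stacked coaxial cylinders of a
common diameter — culture dish wall (bottom), an adherent cell monolayer,
and the activity-containing solution above it — all water-equivalent at
unit density.  Decays are sampled uniformly in a source region (cells or
solution); alpha and beta tracks are transported in the continuous-
slowing-down approximation along straight rays using embedded stopping-
power tables, and the energy imparted to the cell layer per decay, divided
by the cell-layer mass, is the cellular S-value in Gy per decay
(equivalently Gy/(Bq·s)).

Simplifications (documented, switchable where noted):

* beta tracks are straight with an effective path shortened by a detour
  factor (default 0.9) standing in for multiple scattering;
* photons are tallied as escaped by default (their contribution to a
  micrometre-scale water target is sub-percent); a thin-target kerma
  approximation is available via ``gamma_mode="kerma"``;
* delta-ray energy is deposited locally on the track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._physics_tables import (
    ALPHA_WATER_KEV_PER_UM,
    ELECTRON_WATER_KEV_PER_UM,
    MU_EN_WATER_CM2_PER_G,
)
from .errors import DomainError, GeometryError
from .nuclides import Nuclide
from .spectra import beta_spectrum

KEV_TO_J = 1.602176634e-16

REGIONS = ("dish", "cells", "solution")
ESCAPED = "escaped"


# ---------------------------------------------------------------------------
# stopping-power machinery


class StoppingTable:
    """Log-log interpolated stopping power with a consistent CSDA range grid.

    ``stopping(E)`` interpolates the knot table; ``csda_range(E)`` integrates
    1/S on a dense internal grid; ``energy_from_range(r)`` inverts it.  The
    pair (range, inverse) is used for transport so that energy bookkeeping is
    exact by construction.
    """

    def __init__(self, knots, n_dense: int = 800):
        e = np.asarray([k[0] for k in knots], dtype=float)
        s = np.asarray([k[1] for k in knots], dtype=float)
        if np.any(e <= 0) or np.any(s <= 0) or np.any(np.diff(e) <= 0):
            raise DomainError("stopping-power knots must be positive with increasing energies")
        self.e_min = float(e[0])
        self.e_max = float(e[-1])
        self._log_e = np.log(e)
        self._log_s = np.log(s)
        grid = np.geomspace(self.e_min, self.e_max, n_dense)
        sg = np.exp(np.interp(np.log(grid), self._log_e, self._log_s))
        r = np.concatenate(
            [[0.0], np.cumsum(0.5 * (1.0 / sg[1:] + 1.0 / sg[:-1]) * np.diff(grid))]
        )
        # residual range below the table floor (constant-S extrapolation)
        self._r_floor = self.e_min / sg[0]
        self._grid_e = grid
        self._grid_r = r

    def stopping(self, energy_kev):
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < self.e_min) or np.any(e > self.e_max):
            raise DomainError(
                f"energy outside stopping-power table domain [{self.e_min}, {self.e_max}] keV"
            )
        return np.exp(np.interp(np.log(e), self._log_e, self._log_s))

    def csda_range(self, energy_kev: float) -> float:
        """Continuous-slowing-down range in µm (unit-density water)."""
        if energy_kev <= self.e_min:
            return self._r_floor * energy_kev / self.e_min
        return float(np.interp(energy_kev, self._grid_e, self._grid_r)) + self._r_floor

    def energy_from_range(self, range_um: float) -> float:
        """Inverse of :meth:`csda_range`; 0 below the table floor."""
        r = range_um - self._r_floor
        if r <= 0.0:
            return 0.0
        return float(np.interp(r, self._grid_r, self._grid_e))


def constant_stopping_table(let_kev_per_um: float, e_max: float = 1e4) -> StoppingTable:
    """An artificial constant-LET table (for validation against geometric oracles)."""
    return StoppingTable(((1e-3, let_kev_per_um), (e_max, let_kev_per_um)))


ALPHA_TABLE = StoppingTable(ALPHA_WATER_KEV_PER_UM)
ELECTRON_TABLE = StoppingTable(ELECTRON_WATER_KEV_PER_UM)

_MU_EN_LOG_E = np.log([k[0] for k in MU_EN_WATER_CM2_PER_G])
_MU_EN_LOG_V = np.log([k[1] for k in MU_EN_WATER_CM2_PER_G])


def alpha_stopping_power(energy_kev: float) -> float:
    """Alpha stopping power in unit-density water, keV/µm (1 keV – 10 MeV)."""
    return float(ALPHA_TABLE.stopping(energy_kev))


def mu_en_over_rho(energy_kev: float) -> float:
    """Photon mass energy-absorption coefficient for water, cm²/g (clamped ends)."""
    x = math.log(min(max(energy_kev, MU_EN_WATER_CM2_PER_G[0][0]), MU_EN_WATER_CM2_PER_G[-1][0]))
    return float(np.exp(np.interp(x, _MU_EN_LOG_E, _MU_EN_LOG_V)))


@dataclass(frozen=True)
class TransportPhysics:
    """Bundle of physics settings used by the transport step."""

    alpha_table: StoppingTable = ALPHA_TABLE
    electron_table: StoppingTable = ELECTRON_TABLE
    beta_detour_factor: float = 0.9
    gamma_mode: str = "escape"  # or "kerma"

    def __post_init__(self):
        if not 0.0 < self.beta_detour_factor <= 1.0:
            raise DomainError("beta detour factor must be in (0, 1]")
        if self.gamma_mode not in ("escape", "kerma"):
            raise DomainError("gamma_mode must be 'escape' or 'kerma'")


DEFAULT_PHYSICS = TransportPhysics()


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class CylindricalAssembly:
    """Dish / cell-monolayer / solution stack of coaxial cylinders.

    Heights in mm, stacked bottom-up along z starting at z=0 (dish bottom).
    """

    diameter_mm: float
    dish_height_mm: float = 1.0
    cell_height_mm: float = 0.003
    solution_height_mm: float = 3.3
    medium_density_g_cm3: float = 1.0

    def __post_init__(self):
        for name in ("diameter_mm", "dish_height_mm", "cell_height_mm",
                     "solution_height_mm", "medium_density_g_cm3"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")

    @property
    def radius_um(self) -> float:
        return self.diameter_mm * 500.0

    @property
    def z_bounds_um(self) -> dict[str, tuple[float, float]]:
        z1 = self.dish_height_mm * 1000.0
        z2 = z1 + self.cell_height_mm * 1000.0
        z3 = z2 + self.solution_height_mm * 1000.0
        return {"dish": (0.0, z1), "cells": (z1, z2), "solution": (z2, z3)}

    def height_um(self, region: str) -> float:
        lo, hi = self.z_bounds_um[region]
        return hi - lo

    def volume_cm3(self, region: str) -> float:
        r_cm = self.radius_um * 1e-4
        return math.pi * r_cm * r_cm * self.height_um(region) * 1e-4

    def mass_g(self, region: str) -> float:
        return self.volume_cm3(region) * self.medium_density_g_cm3

    def region_at(self, point) -> str:
        x, y, z = point
        if x * x + y * y > self.radius_um**2:
            raise GeometryError("point outside assembly (radially)")
        for region, (lo, hi) in self.z_bounds_um.items():
            if lo <= z < hi:
                return region
        raise GeometryError("point outside assembly (axially)")

    def distance_to_exit(self, point, direction, region: str):
        """Distance (µm) to leave ``region`` along ``direction`` and the next region.

        The next region is an adjacent slab or ``"escaped"`` (radial wall,
        top of solution, bottom of dish).
        """
        x, y, z = point
        ux, uy, uz = direction
        lo, hi = self.z_bounds_um[region]
        idx = REGIONS.index(region)
        t_axial = math.inf
        next_axial = ESCAPED
        if uz > 0.0:
            t_axial = (hi - z) / uz
            next_axial = REGIONS[idx + 1] if idx + 1 < len(REGIONS) else ESCAPED
        elif uz < 0.0:
            t_axial = (lo - z) / uz
            next_axial = REGIONS[idx - 1] if idx - 1 >= 0 else ESCAPED
        a = ux * ux + uy * uy
        t_radial = math.inf
        if a > 0.0:
            b = x * ux + y * uy
            c = x * x + y * y - self.radius_um**2
            disc = b * b - a * c
            if disc > 0.0:
                t_radial = (-b + math.sqrt(disc)) / a
                if t_radial < 0.0:
                    t_radial = math.inf
        if t_radial < t_axial:
            return t_radial, ESCAPED
        return t_axial, next_axial


GEOMETRY_PRESETS = {
    # DSB observation wells: diameter 11.1 mm, solution column 3.3 mm
    "dsb_well": CylindricalAssembly(diameter_mm=11.1, solution_height_mm=3.3),
    # colony-assay wells: diameter 34.6 mm, solution column 2.1 mm
    "colony_well": CylindricalAssembly(diameter_mm=34.6, solution_height_mm=2.1),
}


# ---------------------------------------------------------------------------
# decay sampling and transport


@dataclass(frozen=True)
class EnergyDeposit:
    region: str
    energy_kev: float


def _isotropic_direction(rng) -> tuple[float, float, float]:
    cos_t = 2.0 * rng.random() - 1.0
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = 2.0 * math.pi * rng.random()
    return sin_t * math.cos(phi), sin_t * math.sin(phi), cos_t


def sample_decay(nuclide: Nuclide, rng) -> list[tuple[str, float, tuple[float, float, float]]]:
    """Draw one decay: list of (kind, energy keV, isotropic unit direction).

    Yields may exceed 1 (several emissions per decay) and daughter-branch
    emissions are already folded into the inventory with their branch yields.
    Beta energies are drawn from the Fermi-shaped spectrum of the line.
    """
    out = []
    for line in nuclide.emissions:
        y = line.yield_per_decay
        n = int(y)
        if rng.random() < y - n:
            n += 1
        for _ in range(n):
            if line.kind == "beta":
                e = float(beta_spectrum(line.energy_kev, line.z_daughter).sample(rng.random()))
                if e <= 0.0:
                    continue
            else:
                e = line.energy_kev
            out.append((line.kind, e, _isotropic_direction(rng)))
    return out


def transport_particle(
    origin,
    direction,
    kind: str,
    energy_kev: float,
    geometry: CylindricalAssembly,
    physics: TransportPhysics = DEFAULT_PHYSICS,
) -> list[EnergyDeposit]:
    """Transport one particle; returns per-region deposits plus the escaped share.

    The deposits (including ``escaped``) sum to the initial energy exactly —
    the tally invariant every caller may rely on.
    """
    if energy_kev <= 0:
        raise DomainError("particle energy must be positive")
    region = geometry.region_at(origin)
    totals: dict[str, float] = {}

    if kind == "gamma":
        if physics.gamma_mode == "escape":
            return [EnergyDeposit(ESCAPED, energy_kev)]
        # thin-target kerma: deposit E·(µen/ρ)·ρ·l per region along the ray
        mu = mu_en_over_rho(energy_kev) * geometry.medium_density_g_cm3 * 1e-4  # per µm
        pos = list(origin)
        remaining = energy_kev
        while True:
            d, nxt = geometry.distance_to_exit(pos, direction, region)
            dep = min(remaining, energy_kev * mu * d)
            totals[region] = totals.get(region, 0.0) + dep
            remaining -= dep
            if nxt == ESCAPED or remaining <= 0.0:
                totals[ESCAPED] = totals.get(ESCAPED, 0.0) + remaining
                break
            pos = [pos[i] + d * direction[i] for i in range(3)]
            region = nxt
        return [EnergyDeposit(r, e) for r, e in totals.items() if e != 0.0 or r == ESCAPED]

    if kind == "alpha":
        table, detour = physics.alpha_table, 1.0
    elif kind == "beta":
        table, detour = physics.electron_table, physics.beta_detour_factor
    else:
        raise DomainError(f"unknown particle kind {kind!r}")

    pos = list(origin)
    e = min(energy_kev, table.e_max)
    totals[region] = 0.0
    if e < energy_kev:  # clip above table ceiling: excess deposited locally
        totals[region] += energy_kev - e
    while e > 0.0:
        r_csda = table.csda_range(e)
        d, nxt = geometry.distance_to_exit(pos, direction, region)
        if detour * r_csda <= d:
            totals[region] = totals.get(region, 0.0) + e
            break
        e_next = table.energy_from_range(r_csda - d / detour)
        totals[region] = totals.get(region, 0.0) + (e - e_next)
        e = e_next
        if nxt == ESCAPED:
            totals[ESCAPED] = totals.get(ESCAPED, 0.0) + e
            break
        pos = [pos[i] + d * direction[i] for i in range(3)]
        region = nxt
    return [EnergyDeposit(r, en) for r, en in totals.items()]


# ---------------------------------------------------------------------------
# S-value estimation


@dataclass(frozen=True)
class SValueResult:
    """Per-decay dose coefficients for the cell layer (Gy per decay ≡ Gy/(Bq·s))."""

    s_cell_from_cell: float | None
    s_cell_from_solution: float | None
    se_cell_from_cell: float | None
    se_cell_from_solution: float | None
    n_histories: int
    seed: int
    nuclide: str = ""
    geometry: CylindricalAssembly | None = None

    def as_pair(self) -> tuple[float, float]:
        if self.s_cell_from_cell is None or self.s_cell_from_solution is None:
            raise DomainError("SValueResult does not hold both source terms")
        return self.s_cell_from_cell, self.s_cell_from_solution


def _sample_position(geometry: CylindricalAssembly, region: str, rng):
    lo, hi = geometry.z_bounds_um[region]
    r = geometry.radius_um * math.sqrt(rng.random())
    phi = 2.0 * math.pi * rng.random()
    z = lo + (hi - lo) * rng.random()
    return (r * math.cos(phi), r * math.sin(phi), z)


def estimate_s_value(
    nuclide: Nuclide,
    geometry: CylindricalAssembly,
    source_region: str,
    n_histories: int = 100_000,
    seed: int = 0,
    physics: TransportPhysics = DEFAULT_PHYSICS,
    target_region: str = "cells",
):
    """Monte Carlo S(target ← source): mean energy per decay in the target / its mass.

    Returns ``(s_gy_per_decay, se_gy_per_decay)``; the standard error is the
    per-history sample standard deviation over √n.
    """
    if n_histories < 1:
        raise DomainError("n_histories must be >= 1")
    if source_region not in REGIONS or target_region not in REGIONS:
        raise GeometryError(f"regions must be one of {REGIONS}")
    rng = np.random.default_rng(seed)
    total = 0.0
    total_sq = 0.0
    for _ in range(n_histories):
        pos = _sample_position(geometry, source_region, rng)
        dep = 0.0
        for kind, e_kev, direction in sample_decay(nuclide, rng):
            for d in transport_particle(pos, direction, kind, e_kev, geometry, physics):
                if d.region == target_region:
                    dep += d.energy_kev
        total += dep
        total_sq += dep * dep
    mean = total / n_histories
    var = max(0.0, total_sq / n_histories - mean * mean)
    se = math.sqrt(var / n_histories)
    mass_kg = geometry.mass_g(target_region) * 1e-3
    scale = KEV_TO_J / mass_kg
    return mean * scale, se * scale


def estimate_s_values(
    nuclide: Nuclide,
    geometry: CylindricalAssembly,
    source_region: str | None = None,
    n_histories: int = 100_000,
    seed: int = 0,
    physics: TransportPhysics = DEFAULT_PHYSICS,
) -> SValueResult:
    """Cellular S-value pair (cells←cells, cells←solution) for one nuclide/geometry.

    With ``source_region`` given, only that term is computed (the other is
    None).  Results are reproducible bit-for-bit for a fixed seed.
    """
    kw = dict(n_histories=n_histories, physics=physics)
    s_cc = se_cc = s_sc = se_sc = None
    if source_region in (None, "cells"):
        s_cc, se_cc = estimate_s_value(nuclide, geometry, "cells", seed=seed, **kw)
    if source_region in (None, "solution"):
        s_sc, se_sc = estimate_s_value(nuclide, geometry, "solution", seed=seed + 1, **kw)
    return SValueResult(
        s_cell_from_cell=s_cc,
        s_cell_from_solution=s_sc,
        se_cell_from_cell=se_cc,
        se_cell_from_solution=se_sc,
        n_histories=n_histories,
        seed=seed,
        nuclide=nuclide.name,
        geometry=geometry,
    )


def with_cell_height(geometry: CylindricalAssembly, cell_height_mm: float) -> CylindricalAssembly:
    """Same assembly with a different cell-layer thickness (sensitivity studies)."""
    return replace(geometry, cell_height_mm=cell_height_mm)
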