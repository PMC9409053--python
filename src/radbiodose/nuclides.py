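"""Embedded decay data for At-211 and I-131, plus decay arithmetic.

The emission inventories are compact per-decay tables (standard decay-data
values).  At-211 is represented with its two alpha routes folded together:
the direct 41.8% branch (5.87 MeV) and the 58.2% electron-capture branch
whose 0.516 s Po-211 daughter is in secular equilibrium on every timescale
of interest here, contributing its 7.45 MeV alpha with the branch yield.

``energy_per_decay_kev`` is deliberately pinned to the reference constants
used throughout the downstream dosimetry (6927 keV/decay for At-211,
570 keV/decay for I-131) rather than recomputed from the inventory; a
consistency check (:func:`mean_energy_per_decay`) guards the table against
drifting more than a few percent from those constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError, UnsupportedNuclideError
from .spectra import beta_spectrum

ALLOWED_KINDS = ("alpha", "beta", "gamma")

# Overridable half-life constants (seconds).
HALF_LIFE_AT211_S = 7.214 * 3600.0
HALF_LIFE_I131_S = 8.0252 * 86400.0


@dataclass(frozen=True)
class EmissionLine:
    """One emission per decay: a discrete alpha/gamma line or a beta endpoint.

    ``energy_kev`` is the line energy for alpha and gamma; for beta it is the
    spectrum endpoint and ``z_daughter`` the daughter charge entering the
    Coulomb correction of the sampled spectrum.
    """

    kind: str
    yield_per_decay: float
    energy_kev: float
    z_daughter: int = 0

    def __post_init__(self):
        if self.kind not in ALLOWED_KINDS:
            raise DomainError(f"emission kind must be one of {ALLOWED_KINDS}, got {self.kind!r}")
        if self.energy_kev <= 0:
            raise DomainError("emission energy must be positive")
        if self.yield_per_decay < 0:
            raise DomainError("emission yield must be non-negative")

    @property
    def mean_energy_kev(self) -> float:
        """Mean emitted energy: the line energy, or the beta spectral mean."""
        if self.kind == "beta":
            return beta_spectrum(self.energy_kev, self.z_daughter).mean_kev
        return self.energy_kev


@dataclass(frozen=True)
class Nuclide:
    name: str
    half_life_s: float
    emissions: tuple[EmissionLine, ...]
    energy_per_decay_kev: float
    daughters: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.half_life_s <= 0:
            raise DomainError("half-life must be positive")
        if self.energy_per_decay_kev <= 0:
            raise DomainError("energy per decay must be positive")
        total_branching = sum(b for _, b in self.daughters)
        if any(not 0.0 <= b <= 1.0 for _, b in self.daughters) or total_branching > 1.0 + 1e-12:
            raise DomainError("branching fractions must lie in [0,1] and sum to at most 1")

    @property
    def decay_constant_per_s(self) -> float:
        return decay_constant(self.half_life_s)


def decay_constant(half_life_s: float) -> float:
    """λ = ln 2 / T½ in s⁻¹."""
    if half_life_s <= 0:
        raise DomainError("half-life must be positive")
    return math.log(2.0) / half_life_s


def decay_integral(lambda_p: float, t_s: float) -> float:
    """Number of decays per unit initial activity, ∫₀ᵗ e^{−λu} du = (1 − e^{−λt})/λ.

    Stable-nuclide limit λ→0 returns t (series expansion guards λt < 1e-8).
    Result is bounded by min(t, 1/λ).
    """
    if lambda_p < 0 or t_s < 0:
        raise DomainError("decay_integral requires lambda_p >= 0 and t >= 0")
    x = lambda_p * t_s
    if x < 1e-8:
        # (1 - e^{-x})/λ = t (1 - x/2 + x²/6 - ...)
        return t_s * (1.0 - x / 2.0 + x * x / 6.0)
    return -math.expm1(-x) / lambda_p


def mean_energy_per_decay(nuclide: Nuclide) -> float:
    """Σ yield × mean energy over the inventory (beta lines use spectral means)."""
    return sum(line.yield_per_decay * line.mean_energy_kev for line in nuclide.emissions)


_AT211 = Nuclide(
    name="At-211",
    half_life_s=HALF_LIFE_AT211_S,
    emissions=(
        # direct alpha branch to Bi-207
        EmissionLine("alpha", 0.4180, 5869.5),
        # EC branch: Po-211 (0.516 s) alpha in secular equilibrium
        EmissionLine("alpha", 0.5820, 7450.3),
        # Po K X-rays following electron capture (lumped line)
        EmissionLine("gamma", 0.4500, 28.5),
        # weak gammas (At-211 EC and Po-211 de-excitation)
        EmissionLine("gamma", 0.0025, 687.0),
        EmissionLine("gamma", 0.0030, 569.7),
        EmissionLine("gamma", 0.0029, 897.8),
    ),
    energy_per_decay_kev=6927.0,
    daughters=(("Po-211", 0.582), ("Bi-207", 0.418)),
)

_I131 = Nuclide(
    name="I-131",
    half_life_s=HALF_LIFE_I131_S,
    emissions=(
        EmissionLine("beta", 0.896, 606.3, z_daughter=54),
        EmissionLine("beta", 0.072, 333.8, z_daughter=54),
        EmissionLine("beta", 0.021, 248.0, z_daughter=54),
        EmissionLine("gamma", 0.8150, 364.489),
        EmissionLine("gamma", 0.0717, 636.989),
        EmissionLine("gamma", 0.0613, 284.305),
        EmissionLine("gamma", 0.0177, 722.911),
        EmissionLine("gamma", 0.0262, 80.185),
        EmissionLine("gamma", 0.0540, 29.7),
    ),
    energy_per_decay_kev=570.0,
    daughters=(("Xe-131", 1.0),),
)

_REGISTRY: dict[str, Nuclide] = {n.name: n for n in (_AT211, _I131)}


def get_nuclide(name: str) -> Nuclide:
    """Look up an embedded nuclide ("At-211" or "I-131")."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnsupportedNuclideError(
            f"unsupported nuclide {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def available_nuclides() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))
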