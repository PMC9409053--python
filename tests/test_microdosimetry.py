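"""Monte Carlo transport and S-value estimation."""

import math

import numpy as np
import pytest

from radbiodose.errors import DomainError, GeometryError
from radbiodose.microdosimetry import (
    ALPHA_TABLE,
    DEFAULT_PHYSICS,
    KEV_TO_J,
    CylindricalAssembly,
    TransportPhysics,
    alpha_stopping_power,
    constant_stopping_table,
    estimate_s_value,
    estimate_s_values,
    sample_decay,
    transport_particle,
    with_cell_height,
)
from radbiodose.nuclides import EmissionLine, Nuclide


class TestStoppingPower:
    def test_table_knot_exact(self):
        from radbiodose._physics_tables import ALPHA_WATER_KEV_PER_UM

        e, s = ALPHA_WATER_KEV_PER_UM[7]
        assert alpha_stopping_power(e) == pytest.approx(s, rel=1e-12)

    def test_out_of_range(self):
        with pytest.raises(DomainError):
            alpha_stopping_power(0.5)
        with pytest.raises(DomainError):
            alpha_stopping_power(2e4)

    def test_csda_range_5870kev(self):
        """CSDA range of the direct-branch alpha ≈ 47 µm in water (±15%)."""
        r_num = ALPHA_TABLE.csda_range(5870.0)
        assert r_num == pytest.approx(47.0, rel=0.15)
        # consistency with an independent trapezoid integral of 1/S(E)
        e = np.linspace(1.0, 5870.0, 20000)
        oracle = np.trapezoid(1.0 / ALPHA_TABLE.stopping(e), e)
        assert r_num == pytest.approx(oracle, rel=0.01)

    def test_range_inversion_roundtrip(self):
        for e in (10.0, 500.0, 5000.0, 7450.0):
            r = ALPHA_TABLE.csda_range(e)
            assert ALPHA_TABLE.energy_from_range(r) == pytest.approx(e, rel=1e-3)


class TestSampleDecay:
    def test_degenerate_inventory(self, mono_alpha_5mev, rng):
        for _ in range(50):
            emissions = sample_decay(mono_alpha_5mev, rng)
            assert len(emissions) == 1
            kind, e, u = emissions[0]
            assert kind == "alpha" and e == 5000.0
            assert math.isclose(sum(c * c for c in u), 1.0, rel_tol=1e-9)

    def test_at211_mean_alpha_energy(self, at211, rng):
        energies = []
        for _ in range(100_000):
            energies.extend(e for k, e, _ in sample_decay(at211, rng) if k == "alpha")
        expected = 0.418 * 5869.5 + 0.582 * 7450.3
        se = np.std(energies) / math.sqrt(len(energies))
        assert abs(np.mean(energies) - expected) < 3 * se

    def test_beta_energies_below_endpoint(self, i131, rng):
        endpoints = {e.energy_kev for e in i131.emissions if e.kind == "beta"}
        emax = max(endpoints)
        for _ in range(2000):
            for kind, e, _ in sample_decay(i131, rng):
                if kind == "beta":
                    assert 0.0 < e < emax


class TestGeometry:
    def test_region_lookup_and_masses(self, colony_geometry):
        g = colony_geometry
        assert g.region_at((0.0, 0.0, 500.0)) == "dish"
        assert g.region_at((0.0, 0.0, 1001.0)) == "cells"
        assert g.region_at((0.0, 0.0, 2000.0)) == "solution"
        r_cm = 34.6 / 2 * 0.1
        assert g.mass_g("cells") == pytest.approx(math.pi * r_cm**2 * 3e-4, rel=1e-9)
        with pytest.raises(GeometryError):
            g.region_at((0.0, 0.0, -1.0))
        with pytest.raises(GeometryError):
            g.region_at((1e6, 0.0, 500.0))

    def test_invalid_dimensions(self):
        with pytest.raises(GeometryError):
            CylindricalAssembly(diameter_mm=-1.0)


class TestTransport:
    def test_energy_conservation_per_history(self, at211, i131, colony_geometry, rng):
        """Deposits incl. escaped sum to the emitted energy to 1e-6 relative."""
        for nuc in (at211, i131):
            for _ in range(300):
                z = 1000.0 + 3.0 * rng.random()
                for kind, e, u in sample_decay(nuc, rng):
                    deps = transport_particle((0.0, 0.0, z), u, kind, e, colony_geometry)
                    assert sum(d.energy_kev for d in deps) == pytest.approx(e, rel=1e-6)

    def test_full_absorption_in_large_region(self, huge_cell_geometry):
        """Any alpha deep inside a region ≫ its range deposits everything there."""
        origin = (0.0, 0.0, 1000.0 + 25_000.0)  # mid-cell, 25 mm from each face
        deps = transport_particle(origin, (0.0, 0.0, 1.0), "alpha", 6000.0,
                                  huge_cell_geometry)
        by_region = {d.region: d.energy_kev for d in deps}
        assert by_region["cells"] == pytest.approx(6000.0, rel=1e-9)

    def test_planar_track_stays_in_thin_layer(self, colony_geometry):
        """In-plane alpha from the cell mid-plane never leaves the 3 µm layer."""
        z_mid = 1000.0 + 1.5
        deps = transport_particle((0.0, 0.0, z_mid), (1.0, 0.0, 0.0), "alpha",
                                  6000.0, colony_geometry)
        by_region = {d.region: d.energy_kev for d in deps}
        assert by_region["cells"] == pytest.approx(6000.0, rel=1e-9)

    def test_axial_alpha_from_cells_ends_in_solution(self, colony_geometry):
        """Upward alpha with range ≪ solution height deposits the rest in solution."""
        deps = transport_particle((0.0, 0.0, 1001.5), (0.0, 0.0, 1.0), "alpha",
                                  6000.0, colony_geometry)
        by_region = {d.region: d.energy_kev for d in deps}
        assert set(by_region) <= {"cells", "solution"}
        assert by_region["solution"] > 0.0
        assert sum(by_region.values()) == pytest.approx(6000.0, rel=1e-9)

    def test_gamma_escapes_by_default(self, colony_geometry):
        deps = transport_particle((0.0, 0.0, 1001.0), (0.0, 0.0, 1.0), "gamma",
                                  364.0, colony_geometry)
        assert [(d.region, d.energy_kev) for d in deps] == [("escaped", 364.0)]

    def test_gamma_kerma_mode_conserves_energy(self, colony_geometry):
        physics = TransportPhysics(gamma_mode="kerma")
        deps = transport_particle((0.0, 0.0, 1500.0), (0.0, 0.0, 1.0), "gamma",
                                  364.0, colony_geometry, physics)
        total = sum(d.energy_kev for d in deps)
        assert total == pytest.approx(364.0, rel=1e-9)
        in_matter = sum(d.energy_kev for d in deps if d.region != "escaped")
        assert 0.0 < in_matter < 10.0  # thin water column absorbs well under 3%

    def test_origin_outside_assembly(self, colony_geometry):
        with pytest.raises(GeometryError):
            transport_particle((0.0, 0.0, -5.0), (0.0, 0.0, 1.0), "alpha", 1000.0,
                               colony_geometry)


def _slab_oracle_mean_deposit(let, e0, thickness_um, n_grid=1500):
    """Brute-force mean in-slab deposit for a constant-LET alpha emitted
    uniformly/isotropically inside an infinite slab: integral over depth and
    direction cosine of LET × min(range, exit distance)."""
    r = e0 / let
    z = (np.arange(n_grid) + 0.5) / n_grid * thickness_um
    mu = (np.arange(n_grid) + 0.5) / n_grid * 2.0 - 1.0
    zz, mm = np.meshgrid(z, mu, indexing="ij")
    exit_dist = np.where(mm > 0, (thickness_um - zz) / mm,
                         np.where(mm < 0, -zz / mm, np.inf))
    dep = let * np.minimum(r, exit_dist)
    return float(dep.mean())


class TestSValues:
    def test_zero_yield_inventory(self, colony_geometry):
        nuc = Nuclide("Quiet", 1.0, (EmissionLine("alpha", 0.0, 5000.0),), 1.0)
        s, se = estimate_s_value(nuc, colony_geometry, "cells", n_histories=200, seed=3)
        assert s == 0.0 and se == 0.0

    def test_full_absorption_closed_form(self, mono_alpha_5mev, huge_cell_geometry):
        """S = E/m when the source region dwarfs the range."""
        s, se = estimate_s_value(mono_alpha_5mev, huge_cell_geometry, "cells",
                                 n_histories=4000, seed=7)
        expected = 5000.0 * KEV_TO_J / (huge_cell_geometry.mass_g("cells") * 1e-3)
        assert abs(s - expected) <= 3 * se + 1e-12 * expected

    def test_mass_scaling_in_full_absorption(self, mono_alpha_5mev, huge_cell_geometry):
        doubled = with_cell_height(huge_cell_geometry, 100.0)
        s1, _ = estimate_s_value(mono_alpha_5mev, huge_cell_geometry, "cells",
                                 n_histories=2000, seed=11)
        s2, _ = estimate_s_value(mono_alpha_5mev, doubled, "cells",
                                 n_histories=2000, seed=11)
        assert s2 == pytest.approx(s1 / 2.0, rel=5e-3)

    def test_thin_slab_constant_let_matches_oracle(self, colony_geometry):
        """MC with an artificial constant-LET alpha agrees with the geometric
        brute-force oracle for the 3 µm cell layer."""
        let, e0 = 100.0, 5000.0
        physics = TransportPhysics(alpha_table=constant_stopping_table(let))
        nuc = Nuclide("Flat", 1.0, (EmissionLine("alpha", 1.0, e0),), e0)
        s, se = estimate_s_value(nuc, colony_geometry, "cells",
                                 n_histories=40_000, seed=5, physics=physics)
        mean_dep = _slab_oracle_mean_deposit(let, e0, colony_geometry.height_um("cells"))
        expected = mean_dep * KEV_TO_J / (colony_geometry.mass_g("cells") * 1e-3)
        assert abs(s - expected) <= 3 * se

    def test_fixed_seed_bit_reproducible(self, at211, colony_geometry):
        a = estimate_s_values(at211, colony_geometry, n_histories=500, seed=42)
        b = estimate_s_values(at211, colony_geometry, n_histories=500, seed=42)
        assert a == b

    def test_solution_dose_below_self_dose_for_alphas(self, at211, colony_geometry,
                                                      dsb_geometry):
        for geom in (colony_geometry, dsb_geometry):
            res = estimate_s_values(at211, geom, n_histories=4000, seed=9)
            assert res.s_cell_from_solution < res.s_cell_from_cell

    def test_invalid_inputs(self, at211, colony_geometry):
        with pytest.raises(DomainError):
            estimate_s_value(at211, colony_geometry, "cells", n_histories=0)
        with pytest.raises(GeometryError):
            estimate_s_value(at211, colony_geometry, "air", n_histories=10)
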