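"""Compact charged-particle and photon interaction tables for liquid water.

Values follow the standard reference tabulations (ICRU-49-style alpha
stopping powers, ICRU-37-style electron collision stopping powers, and
mass energy-absorption coefficients) at unit density, condensed to a
log-log-interpolable set of knots.  Accuracy after interpolation is at the
few-percent level, which is well inside the systematic uncertainty budget
of the thin-layer dosimetry built on top of them.

Units: energy keV; stopping power keV/µm at 1 g/cm³; µ_en/ρ cm²/g.
"""

# Alpha particles in water: total stopping power (electronic + nuclear).
# Bragg peak near 0.7 MeV at ~226 keV/µm; CSDA ranges ≈ 47 µm at 5.87 MeV
# and ≈ 69 µm at 7.45 MeV follow by integration.
ALPHA_WATER_KEV_PER_UM = (
    (1.0, 18.0),
    (3.0, 30.0),
    (10.0, 45.0),
    (30.0, 75.0),
    (100.0, 118.0),
    (300.0, 180.0),
    (500.0, 215.0),
    (700.0, 226.0),
    (1000.0, 220.0),
    (1500.0, 198.0),
    (2000.0, 160.0),
    (3000.0, 125.0),
    (4000.0, 103.0),
    (5000.0, 89.0),
    (6000.0, 79.0),
    (7000.0, 71.0),
    (8000.0, 65.0),
    (10000.0, 55.0),
)

# Electrons in water: collision stopping power.
ELECTRON_WATER_KEV_PER_UM = (
    (1.0, 12.6),
    (2.0, 7.85),
    (5.0, 4.05),
    (10.0, 2.32),
    (20.0, 1.30),
    (30.0, 0.965),
    (50.0, 0.667),
    (100.0, 0.412),
    (200.0, 0.279),
    (300.0, 0.2355),
    (500.0, 0.2034),
    (700.0, 0.1916),
    (1000.0, 0.1849),
    (2000.0, 0.1840),
    (5000.0, 0.1910),
    (10000.0, 0.1980),
)

# Photons in water: mass energy-absorption coefficient µ_en/ρ.
MU_EN_WATER_CM2_PER_G = (
    (10.0, 4.944),
    (15.0, 1.374),
    (20.0, 0.5503),
    (30.0, 0.1557),
    (40.0, 0.0695),
    (50.0, 0.04223),
    (60.0, 0.03190),
    (80.0, 0.02597),
    (100.0, 0.02546),
    (150.0, 0.02764),
    (200.0, 0.02967),
    (300.0, 0.03192),
    (400.0, 0.03279),
    (500.0, 0.03299),
    (600.0, 0.03284),
    (800.0, 0.03206),
    (1000.0, 0.03103),
    (1500.0, 0.02833),
    (2000.0, 0.02608),
)
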