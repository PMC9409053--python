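# Methods

## Decay data

Two nuclides are embedded.  ²¹¹At (T½ = 7.214 h) decays through two routes
that both end in an alpha emission: a direct 41.8% branch (5.87 MeV) and a
58.2% electron-capture branch to ²¹¹Po, whose 0.516 s half-life is treated
as instant secular equilibrium (7.45 MeV alpha carried with the branch
yield).  ¹³¹I (T½ = 8.0252 d) carries three beta endpoints and the main
gamma lines.  Weak X-ray/gamma lines are lumped so the inventory's mean
emitted energy stays within a guarded 5% of the pinned energy-per-decay
constants, 6927 keV (²¹¹At) and 570 keV (¹³¹I), which are used directly by
the in vivo dose conversion.  Half-lives and the constants are module-level
values and can be overridden.

Beta energies are drawn from an allowed-shape spectrum
`w(E) ∝ F(Z,E)·p·E_tot·(Q−E)²` with the non-relativistic Coulomb factor
`F = x/(1−e^(−x))`, `x = 2πZα/β`, sampled by inverse-CDF lookup on a
1024-point grid.  The sampled mean for the 606 keV endpoint is ≈197 keV,
~3% above the evaluated mean — adequate for the thin-target dosimetry here.

In `sample_decay`, emission lines are drawn independently with their
per-decay yields rather than as mutually exclusive branches.  Expected
emission counts and energies are exact; only the (unused) correlation
between the two alpha branches within one history is approximated.

## Monte Carlo S-values

Geometry: three stacked coaxial cylinders of common diameter — dish wall
(1 mm), adherent cell monolayer (3 µm), activity solution (3.3 mm for the
DSB wells of 11.1 mm diameter; 2.1 mm for the colony wells of 34.6 mm
diameter).  All media are unit-density water; the dish material is not
specified by typical protocols and water-equivalence affects only
backscatter.

Charged-particle transport is straight-ray continuous slowing down against
embedded stopping-power tables (log-log interpolated; compact knot sets
matched to the standard reference tabulations, giving e.g. a 48 µm CSDA
range for the 5.87 MeV alpha).  A dense internal range grid and its inverse
are used for the energy bookkeeping, so per-history energy conservation is
exact by construction.  Electrons keep a straight path but consume CSDA
range at 1/detour per unit distance (detour factor default 0.9), a
stand-in for multiple scattering.  Delta-ray energy is local.  Photons are
tallied as escaped by default — for a 3 µm water target their contribution
is sub-percent, and this is a documented low bias of order the difference
seen for ¹³¹I below — with an optional thin-target kerma mode
(`gamma_mode="kerma"`).

S(target ← source) is the mean energy imparted to the target per decay,
divided by the target mass, with the standard error taken from the
per-history variance.  Decays are uniform in the source region; the RNG is
`numpy.random.default_rng(seed)` and results are bit-reproducible per seed.
Default 10⁵ histories gives ≈0.5% relative SE for the alpha self-dose term.

With the colony-well geometry this reproduces the reference coefficients
for ²¹¹At closely (33.7 vs 33.5 nGy/(Bq·s) self-dose; 0.254 vs
0.247 nGy/(Bq·s) from solution).  For ¹³¹I the estimates are ~0.65× the
reference pair (232 vs 355 pGy/(Bq·s)); the gap is consistent with the
neglected secondary-electron buildup and photon dose that a full
condensed-history code transports.  The reference pairs therefore remain
the authoritative inputs to the treatment-dose equation, and the Monte
Carlo estimate is reported alongside with its ratio, never blended.

## Treatment dose

`D_T = κ · (1−e^(−λ_p t_T))/λ_p · A₀ · (f·S_c→c + (1−f)·S_s→c)`, with f the
end-of-treatment uptake fraction (0.116 for astatide, 0.325 for iodide in
K1-NIS cells) and κ ∈ (0,1] a partition-averaging factor, default 0.5.
Rationale for κ: applying the end-of-treatment partition over the whole
interval double-counts the cell term during gradual uptake; averaging the
initial (all-in-solution) and final partitions halves the bracket, because
the solution term is orders of magnitude smaller.  κ = 1 recovers the
literal evaluation (14.09 Gy for the ²¹¹At benchmark instead of 7.04).
Both terms are reported separately and the full input set is attached as
provenance.

Increasing the assumed cell thickness from 3 to 5 µm lowers the computed
dose by ≈9% (the self-dose S-value falls faster than the layer mass grows,
as expected for a target much thinner than the alpha range) — same
direction, similar size to the ~15% quoted sensitivity of such setups.

## DSB quantification

Nuclear morphology is the union of the nuclei and damage masks (damaged
area counts as nuclear area even where the nuclear stain is displaced), so
`%DSB = 100·|damage|/|damage ∪ nuclei|` is bounded by [0, 100].
Segmentation defaults to per-channel Otsu — deterministic and seedless,
replacing manual region selection.  The dose response is OLS with a free
intercept (controls show a nonzero baseline); RBE of a linear response is
the slope ratio, which equals the iso-effect dose ratio at every level.

## Clonogenic survival

SF is normalised to the untreated-control plating efficiency.  Fits run in
−ln SF space through the origin against (D, D²) with α, β ≥ 0 enforced by
non-negative least squares.  When colony counts are available the weights
are inverse binomial variances of −ln SF (≈ (1−c/n)/c), and the covariance
is the known-variance (XᵀWX)⁻¹; otherwise the fit is unweighted and the
covariance is scaled by the residual variance.  Zero-SF points are dropped
with a warning; a dose cutoff (used for alpha-emitter data distorted by
heterogeneous uptake at high dose — 1 Gy and 5 Gy are both exercised in
tests) removes the high-dose tail and is recorded in the fit bookkeeping.
D10 uses the closed forms (−ln L/α, or the positive quadratic root);
RBE at a level is the dose ratio, with an optional seeded
residual-bootstrap CI.

## In vivo dosimetry

Two integration schemes for %AA/g kinetics, both stored in the result:
`trapezoid_physical_tail` (default — linear rise from zero at injection to
the first sample, trapezoids between samples, exponential tail at the
faster of the fitted effective rate and the physical decay constant) and
`monoexp_fit` (single exponential through the samples integrated over
(0,∞), rate floored at physical decay).  The floor encodes that activity
cannot outlive physical decay; a rising (negative-rate) tail falls back to
the physical constant with a warning.  Unit conversion: 1 %AA/g of 1 MBq
administered = 10⁴ Bq/g.  The dose coefficient is
`Gy/MBq = ã · Ē · 1.602·10⁻¹⁶ J/keV · 1000 g/kg · φ · w` with absorbed
fraction φ = 1 for tumour self-dose and RBE weight w = 1 by default (5 is
the convention for targeted-alpha equivalent dose).  Whole-organ %AA rows
(the thyroid convention) are excluded from per-gram dosimetry unless a
mass is supplied.

Regrowth is defined operationally: the first measured day after the series
minimum with relative size ≥ (1 + rebound fraction, default 0.2) × minimum
on two consecutive measurements.  On noisy per-animal series the sample
minimum is biased low and the rule can fire during the plateau, so summary
analyses (as in the acceptance script) score the group-mean curve, which is
also what growth figures plot.  Group comparisons use the classic
pooled-variance unpaired t-test with Bonferroni multiplication, capped at 1.

## Synthetic data

Noise models are choices, each a parameter: Binomial colony counts
(n seeded, p = PE·SF), log-normal between-animal organ values (cv default
0.15), Gaussian image noise (sd 0.05 on unit-intensity channels), log-normal
growth noise (cv 0.1).  Nuclei are non-overlapping disks and the damaged
subset is exactly round(fraction × area) innermost pixels, so the mask
ground truth equals the requested fraction up to pixel rounding; rendering
adds a 1 px Gaussian blur.  Defaults mirror the study designs these
generators emulate: 1000 cells seeded per well with three replicates over
eight dose levels; two biodistribution timepoints (3 h, 24 h) with n = 6;
growth sampled every 3 days with untreated doubling ≈ 6 days (rate
0.12/day) and regrowth delays of 0/18/46 days.  Organ kinetics encode fast
iodide washout (tumour effective T½ ≈ 5 h) versus retained astatide
(effective ≈ physical T½), which drives the order-of-magnitude gap between
the synthetic ¹³¹I and ²¹¹At tumour dose coefficients (≈0.24 vs
≈2.8 Gy/MBq at these settings).  What passing recovery tests shows is that
the estimators invert these generative models; real images (morphology,
illumination), inter-animal correlation, and multi-compartment kinetics are
outside the generators' scope.

## Problem sizes and numerics

Monte Carlo checks run at 10⁵ histories (≈0.5% SE) and sensitivity runs at
3·10⁴ per source term; recovery suites use 100–200 replicates.  Stopping
tables span 1 keV–10 MeV (alphas and electrons); below-floor energy is
deposited locally (sub-0.1 µm residual range).  The λ→0 limit of the decay
integral switches to a series below λt = 10⁻⁸.  Otsu on a constant image,
an empty mask union, non-positive slopes, zero plating efficiency and an
exhausted fit all raise typed errors rather than returning sentinel values.

## Known limitations

No condensed-history electron scattering or secondary-electron buildup
(the main reason the ¹³¹I S-values sit ~35% low); no photon transport
beyond optional thin-target kerma; no kinetic uptake model beyond κ; no
focus-level DSB counting; no compartmental pharmacokinetics; no
animal-survival analysis.
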