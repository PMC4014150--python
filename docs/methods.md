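# Methods

This note records the models behind `thyrodose`, the defaults and why they
were chosen, the numerical details that affect results, and what the
synthetic inputs can and cannot say about real reference-phantom dosimetry.

## Dose assembly

Organ doses per administered MBq are the source-region sum
D(r_T) = Σ_S Ã(r_S)·d_S(r_T), where d_S(r_T) is the Monte Carlo estimate of
the mean dose to target T per decay in region S (the S value, evaluated on
the fly rather than taken from a table).  Units: tallies are MeV/g per
emitted particle; multiplying by the particle kind's total yield per decay
gives MeV/g per decay; 1 MeV/g = 1.602 176 634×10⁻⁷ mGy and 1 MBq·s = 10⁶
decays, so D[mGy/MBq] = Σ_S Ã_S[s] · 10⁶ · d_S[MeV/g] · 1.602×10⁻⁷.
Photon and electron transport run separately, so every organ dose carries a
photon/electron split (summing to 100% by construction) and per-source
contribution percentages Ã_S·d_S/D (summing to 100%).  The "major source
organ" is the largest contributor, labelled "Self-dose" when the target organ
belongs to the winning region; a wall counts its own wall+contents region as
self.  Ties break toward the larger fraction, then lexicographic region id.

## Biokinetics

Retention in each source region is a sum of exponentials,
A(r_S, t) = F_S Σᵢ aᵢ e^−(λᵢ+λ_p)t, with uptake phases encoded as paired
±aᵢ terms; validation rejects parameter sets whose retention goes negative
anywhere on a dense time grid.  The cumulated activity uses the closed form
F_S Σᵢ aᵢ/(λᵢ+λ_p), cross-checked against adaptive quadrature in the tests.

The shipped coefficient sets are **illustrative**, not transcriptions of a
published compilation (none is reprinted in an open form suitable for
packaging).  They were fixed once, before any end-to-end runs, to the
structure a reference first-order iodide model implies:

* thyroid: F_S = u (the chosen uptake, 0–0.55), long organic retention
  (T_bio 80 d) entered through a 6 h uptake phase from the circulating pool;
* bladder contents (urine): F_S = 0.62(1−u) with a ~2.4 h voiding residence —
  residence falls as uptake rises;
* stomach (wall+contents), small intestine (wall+contents), kidneys: constant
  transit fractions (0.10 / 0.07 / 0.035) with hour-scale residences;
* remaining tissues: the circulating inorganic pool (0.85(1−u), T 6 h) plus
  organic iodine released from the thyroid (0.25u, T 12 d).

With these defaults the ¹³¹I 15%-uptake residence times come out at 36.6 h
(thyroid), 1.5 h (urine) and 9.7 h (remaining tissues).  Pertechnetate
scenarios follow the same pattern with a small thyroid trap (F_S = 0.02,
zero when a blocking agent is given, bladder raised in exchange) and, for
oral intake, a strong stomach-contents transit source with every systemic
fraction scaled by 0.8.  GI contents other than stomach and small-intestine
contents never act as sources.  Users holding a published coefficient set can
supply it as a JSON scenario fixture; the schema round-trips exactly.

## Emission spectra

Packaged CSV fixtures for I-131 (T½ = 8.02 d), I-123 (13.27 h) and Tc-99m
(6.0067 h) compile ENSDF-derived photon lines, beta branches (endpoint plus
daughter Z), conversion-electron lines and average-energy Auger groups.
Lines with yields ≤ 0.1% per decay are kept in the files but dropped on load
(with a logged count); for these nuclides the cut moves the per-decay mean
energies by well under 1%.  Beta continua use the allowed shape
F(Z,E)·p·W·(Emax−E)² with the nonrelativistic point-charge Coulomb factor
F = 2πη/(1−e^−2πη), η = +Zα/β; sampling is inverse-transform on a 2048-point
CDF grid (linear interpolation), so the sampling error is bounded by the grid
density and sequences are reproducible under a fixed generator.  Note that
the textbook "mean beta energy ≈ Emax/3" holds only in the nonrelativistic
limit; for the 606 keV branch the allowed-shape mean is 0.378·Emax without
the Coulomb factor and 0.326·Emax with Z = 54.

## Photon transport

Woodcock (delta) tracking against a global majorant Σ_maj(E) (the maximum
linear attenuation over the materials present, interpolated with the same
log-log scheme as the local coefficients so the majorant property holds
exactly between grid nodes).  Interactions: photoelectric absorption and
incoherent scattering with exact Klein–Nishina sampling (uniform-ε rejection
under the ε+1/ε envelope).  Coherent scattering and fluorescence are omitted —
a few-percent effect in soft tissue over the 27–723 keV emission range — and
secondary electrons are not transported, consistent with kerma scoring.
Photons terminate below 2 keV (residual deposited locally in collision mode)
or on leaving the grid; an optional periodic mode wraps positions for
escape-proof benchmark geometries.

Two scoring modes mirror the classic estimator pair:

* **track_length_kerma** (F6-analog): the kerma integral ∫E·μ_en dl is scored
  at every delta-tracking sample point — virtual or real — as
  E·μ_en,linear/Σ_maj.  Because sample points occur with density Σ_maj along
  the flight path, this is an unbiased realisation of the same track-length
  integral without ray-marching voxel boundaries (the price is somewhat
  higher variance per history).
* **collision_deposit** (*F8-analog): the energy transferred at each sampled
  real interaction is deposited there.

The packaged μ_en/ρ is built *self-consistently* as μ_pe + μ_inc·f(E), with
f(E) the Klein–Nishina mean energy-transfer fraction.  This makes the two
estimators agree in expectation and makes the infinite-medium equilibrium
identity (kerma per mass = emitted energy per mass) exact, which the tests
exploit; the values land within a few percent of standard compilations for
soft tissue over 30 keV–1 MeV.  Photoelectric mass attenuation is a per-
material power law anchored at 30 keV (soft tissue/lung 0.134, bone 0.700,
air 0.140 cm²/g; exponent 3.1); incoherent attenuation is Klein–Nishina times
the electron density (soft tissue/lung 3.31, bone 3.12, air 3.01 ×10²³ e/g).
Tables live on a 160-point log grid, 1 keV–3 MeV, interpolated log-log.

## Electron transport

Straight-line continuous-slowing-down stepping: fixed 0.05 cm (configurable)
sub-steps, ΔE = (S/ρ)·ρ·ℓ with the collision stopping power re-evaluated at
each step from a water-like base table (per-material scale factors 1.00 soft
tissue/lung, 0.925 bone, 0.975 air); CSDA ranges are obtained by integrating
1/S over the same table, so the 1-D slowing-down oracle and the kernel share
one data source.  Histories terminate below 10 keV with the residual
deposited locally; energy bookkeeping is exact when nothing escapes.  No
multiple scattering, straggling or bremsstrahlung is modelled: for organ-
scale energy bookkeeping in low-Z tissue at ≤0.8 MeV (ranges ≤0.35 g/cm²,
radiative losses ≲1%) the straight-line approximation mainly affects the
few-percent surface-escape correction of small organs and is the main
fidelity gap relative to condensed-history codes.

## Sources, tallies, dose maps, CLDs

Source regions are selected with probability proportional to their cumulated
activity; within a region a voxel is drawn uniformly and the emission point
uniformly inside that voxel (the per-source decomposition instead restricts
the distribution to one region at a time).  "Remaining tissues" is everything
source-capable not claimed by the scenario's named regions, minus the
excluded GI contents.  Tallies accumulate organ energies over 20 independent
batches; uncertainties are batch-mean standard errors (they shrink as 1/√n).
Dose maps score per-voxel energy on the phantom lattice itself, convert to
energy per volume per decay and derive the per-mass grid by dividing by each
voxel's density (zero outside the body); a mid-coronal slice helper supports
contour display.  Chord-length distributions sample, per pair, a uniform
voxel of each region and a uniform point in each voxel, and histogram the
Euclidean distances (default 0.5 cm bins from zero to the grid diagonal) with
mean and SD; the definition is symmetric in the two regions up to sampling
noise.

## Effective dose

E = Σ_T w_T·H_T with w_R = 1 (photons/electrons), so equivalent dose equals
absorbed dose.  The packaged ICRP-103 table carries 14 named tissues plus a
0.12 remainder entering as the arithmetic mean of the 13 remainder tissues
present (gonads = testes or ovaries; prostate/uterus in the remainder).
Applied to the packaged published organ-dose columns for the reference adult
voxel phantoms this reproduces the published effective-dose footers to 0.03%
(¹³¹I male/female), 0.7% (¹²³I male) and 2.7% (⁹⁹ᵐTc male; more organs
contribute materially there, so table rounding accumulates), and gives a
thyroid share of 97.8% for ¹³¹I — evidence that the footers used exactly this
remainder rule.  A gender-averaged mode averages per-tissue doses before
weighting.  For pipeline output on the synthetic phantom, tissues the phantom
does not model explicitly (breast, skin, marrow, lymph nodes, muscle, oral
mucosa, extrathoracic region) borrow the nearest modelled surrogate
(skeleton, residual soft tissue, salivary glands, trachea); that proxy map is
adequate for qualitative comparisons on the synthetic geometry and is not a
reference-phantom evaluation.

## Synthetic phantoms

The generator builds deterministic male/female anthropomorphic phantoms from
analytic solids: ~177 cm / 68 kg male at scale 1, female a 0.94 linear copy.
It reproduces the features the dosimetry actually depends on — a two-lobe
thyroid of ~20 g (male) / ~17 g (female) wrapped around the trachea with the
esophagus behind, lungs/heart/stomach/liver/spleen/pancreas/kidneys/adrenals
at plausible positions, wall/contents pairs for stomach, small intestine,
colon, gall bladder and bladder, gonads near the bladder, a homogeneous bone
skeleton proxy and residual soft tissue.  It does **not** reproduce
reference-phantom anatomy: no skin/breast/marrow substructure, simplified GI
topology, four materials only.  Consequently the pipeline's *relative*
quantities (photon/electron shares, self-dose fractions, uptake trends,
male/female ordering) transfer to real anatomy, while absolute organ doses
are phantom-specific and are out of scope — the synthetic thyroid dose for
¹³¹I at 15% uptake (~222 mGy/MBq) is in the right regime but is not a
reference value.  A generic raw+CSV loader accepts externally produced label
grids for users with licensed reference phantoms.

## Problem sizes and determinism

Default study conditions: 4 mm isotropic voxels; 2×10⁵ photon and 2×10⁵
electron histories per source region for the headline runs (thyroid-organ
uncertainties well below a percentage point; the paper-scale equivalent would
be 10⁷–10⁸ histories), smaller counts for property tests and sweeps where the
assertion is shared-tally monotonicity rather than absolute precision.
Uptake sweeps reuse one set of per-source tallies across uptake levels —
doses are linear in Ã, so uptake-to-uptake orderings carry no Monte Carlo
noise.  All randomness flows from numpy Generators seeded from one root seed
(per-region streams derived via SeedSequence); equal configurations reproduce
outputs byte for byte, and CLI outputs embed the seed and a hash of the
resolved configuration.

## Known limitations

Illustrative biokinetic coefficients (structure, not values, of a published
model); kerma-mode photon dosimetry without secondary-electron transport
(wall doses from contents sources at high energies are approximate at the
wall-thickness scale); straight-line electrons; no coherent scattering or
fluorescence; homogeneous skeleton without marrow/endosteum dosimetry;
four-material cross sections from compact parametrisations rather than a
full compilation; synthetic-phantom tissue proxies in the effective dose.
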