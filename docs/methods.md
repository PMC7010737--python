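# Methods

This note documents the physical model, the bundled data, the numerical
choices and the known limitations of `mammomc`.

## Phantom and geometry

Coordinates are right-handed: origin on the receptor plane directly under
the focal spot, z up toward the source, y into the breast; lengths in cm.

The compressed breast is a semicylinder of interior radius 8.5 cm with a
0.4 cm skin layer on the curved surface and on the top and bottom faces (not
on the chest-wall face).  The stated breast thickness (3–9 cm) is the
overall compressed thickness including both skin caps; the interior is split
into three equal-thickness horizontal layers, layer 1 on the x-ray entrance
side.  Each layer is a glandular/adipose mixture at 25, 50 or 75% glandular
**mass** fraction.  The phantom bottom sits 1.2 cm above the receptor; the
isotropic point source is 65 cm above the receptor, directly over the
midpoint of the chest-wall edge; a 30×20×40 cm³ soft-tissue torso box stands
behind the chest-wall face.  The default collimation rectangle is
18 cm (lateral) × 10 cm (chest-wall depth) on the receptor plane — the exact
clinical field is not critical because both MGD and kerma are normalized
"per photon emitted into the field", so the solid angle cancels in DgN.
For breasts thicker than ≈7 cm the projected default field does not quite
cover the outermost phantom rim at the entrance plane; this affects superior
and inferior distributions almost identically and is invisible in the DgN
ratios.

Glandular fraction is interpreted as a mass fraction and mean glandular
fraction as the plain average of the three layer values (the layers have
equal volumes; mass-averaging would differ by under 3% because the layer
densities differ by under 3%, and by exactly zero for uniform phantoms).

### Validation geometry

The AAPM TG-195 Case 3 arrangement is built as: interior semicylinder
r = 9.8 cm, 4.6 cm thick, homogeneous 20% glandular mixture; 2 mm skin
envelope; 14×26×0.2 cm³ PMMA compression and support paddles; source 59.3 cm
above the compression paddle; beam collimated to the 14×26 cm image receptor
at 66 cm SID (1.3 cm air gap under the support paddle); world filled with
dry air.  The tally is the energy deposited in the breast interior
(excluding skin) per photon emitted into the collimated field.  With 10⁷
histories the package obtains ≈4780 eV/photon (CV < 0.1%) against the
published reference of 4707 eV/photon (+1.6%), which is within the combined
uncertainty of the independently compiled cross-section tables.

## Materials

Breast mixtures are generated from pure glandular and adipose endpoint
tissues obtained by linear unmixing of the printed 25% and 75% reference
rows (compositions element-wise, densities reciprocally).  This reproduces
all three printed mixture densities (0.955 / 0.982 / 1.010 g/cm³) exactly
and keeps the package self-consistent with its one printed source of
composition data; the recovered endpoints (glandular ρ = 1.040, adipose
ρ = 0.930 g/cm³) match the classical Hammerstein values.  Breast tissues and
skin are H/C/N/O only, as printed; the skin row is stored exactly as printed
(its fractions sum to 99.3% because trace elements were dropped from the
source table) and compositions are renormalized inside coefficient lookups.
The torso is ICRU-44 soft tissue renormalized to H/C/N/O; air is dry air
(C/N/O/Ar, ρ = 1.205×10⁻³ g/cm³); paddles are PMMA (ρ = 1.19).

### Photon interaction data

No physics-constant library is assumed at run time; the tables under
`src/mammomc/data/` are compiled as follows and shipped as CSV:

* **incoherent**: numerical integral of the Klein–Nishina cross section
  weighted by an incoherent-scattering function S(x) (exact `1−F²` for H,
  tabulated curves for C/N/O, Thomas–Fermi scaling above);
* **coherent**: numerical Thomson×F² integral with Cromer–Mann atomic form
  factors, damped at mid momentum transfer — the damping was calibrated once
  so that mixture μen/ρ reproduces the published NIST water and dry-air
  tables within ≈0.5% over 10–30 keV;
* **photoelectric**: the residual of published NIST/XCOM *total* mass
  attenuation coefficients after subtracting the two scattering integrals,
  log-log interpolated between anchor energies (power-law continuation where
  photoabsorption falls below 5% of the total);
* **μen/ρ**: photoelectric plus the Klein–Nishina energy-transfer integral
  (fluorescence escape and radiative losses are negligible below 50 keV for
  these elements);
* totals are stored as pe+incoh+coh, so the partials are exactly consistent
  and equal the published totals at every anchor energy.

Rh and Ag (beam filters only — photons are never transported inside them)
use K-edge-anchored power laws accurate to a few percent; because every beam
is re-anchored to its half-value layer, filter-table errors only perturb the
spectral *shape*, a second-order effect (verified: ±15% scaling of the
filter tables leaves DgN unchanged to <0.1%).

Dry-air μen/ρ is additionally carried as a dense direct table anchored to
the NIST nodes, since air-kerma weighting is first order for both HVL and
DgN.

## X-ray spectra

Beams are specified by (kVp, filter material, target HVL in mm Al).  The
tungsten provider is a generalized Kramers shape
`Φ(E) ∝ (kVp/E − 1)^0.64 · E^−0.15` on a 0.25 keV grid from the 5 keV
transport cutoff to kVp, plus the W L-fluorescence lines (8.4–11.3 keV) at
3× the 10 keV continuum level.  The two shape exponents were fitted once to
a published mammography filter-thickness↔HVL grid (12 W/Al pairs at
26/30/36 kVp, rms 0.009 mm Al); inherent filtration and target
self-absorption are absorbed into the shape.  The solved Al thickness for a
26 kVp beam at HVL 0.423 mm Al is 750 μm — identical to the published
pairing.  HVL is computed in the mammography-QC convention: narrow-beam Al
attenuation weighted by fluence·E·(μen/ρ)_air, solved by bracketed root
finding to |K/K₀ − ½| < 10⁻⁶.  Monoenergetic and two-column-text-file
providers are also available.

DgN was found to vary by only ±1.5% across deliberately different provider
shapes recalibrated to the same HVL, which is the justification for
anchoring beams by HVL rather than by filter thickness.

## Transport

Analog photon transport, vectorized over photon arrays.  Histories sample
their energy from the spectrum (uniform within bin) and their direction
isotropically within the collimated solid angle by rejection from the
bounding cone — an accepted history *is* one photon emitted into the field,
the denominator of every per-photon quantity.  Free flight uses exponential
path lengths against the local linear attenuation with exact ray-surface
intersection distances (convex solids: boxes, semicylinders, cylinders;
surface-crossing epsilon 10⁻⁷ cm).  Interactions branch on the tabulated
partial cross sections:

* photoelectric: full local deposition, history ends (K-fluorescence of
  H/C/N/O is sub-cutoff);
* incoherent: Kahn's composition–rejection sampling of the Klein–Nishina
  distribution; electron energy deposits locally; an optional S(x)
  rejection adds binding suppression of forward scatter (off by default —
  free-electron Compton is the reference-case convention; enabling it
  changes the validation deposition by well under 1%);
* coherent: inverse-CDF sampling of x² from the material form factor with
  the (1+cos²θ)/2 Thomson rejection; elastic.

Photons below 5 keV deposit their remaining energy on the spot.  Electrons
are not transported (CSDA range < 20 μm at these energies).  The receptor
plane and the world boundary absorb.  Energy is conserved exactly:
emitted = deposited + escaped to floating-point precision, asserted in the
test suite.

Tallies accumulate per region the deposited energy and the G-weighted
deposited energy, with G evaluated at the photon energy at the moment of
interaction — the standard interpretation for polyenergetic beams, exact
for monoenergetic ones.  Runs are split into 20 equal batches with
independent RNG streams spawned from the master seed; the coefficient of
variation is the batch standard error over the batch mean.  Identical
(seed, history count) reproduce results bit for bit.

## Dosimetry

`MGD = Σᵢ Gᵢ(E)·Eᵢ / Σᵢ V·ρᵢ·f_g,ᵢ` over the three layers; skin
glandularity is excluded (f_g,skin = 0).  Air kerma uses a track-length
estimator in the pancake chamber: `K = Σ ℓ·E·(μen/ρ)_air / V_chamber` per
emitted photon, converted with 1 keV/g = 1.602×10⁻¹⁰ mGy.  A deterministic
bin-sum kerma (inverse-square fluence, optional air-column attenuation)
serves as an independent cross-check; simulation and bin-sum agree within
statistics in vacuum and differ by the expected ≈1.4% in-air scatter
buildup otherwise.

**Chamber placement.** The reference description — a chamber "at the
position of the phantom", breast and torso removed — does not fix the
height of the 2 mm disc.  Two readings differ only by inverse square: upper
face in the phantom *entrance plane* (classic entrance-kerma convention) or
chamber centred at the removed phantom's *mid-height*.  Compared against
the three published uniform-distribution DgN values, the entrance
convention sits a uniform ≈5% low while the centre convention matches the
4 cm flagship condition within noise (+1.2%) and drifts to +5…+7% at
6–8 cm; the two conventions bracket the published values.  The package
defaults to the centre placement (`build_kerma_setup(placement="centre")`),
with `"entrance"` available; distribution *ratios* — the quantities this
phantom family exists to measure — are exactly independent of the choice.
Laterally the chamber axis sits 2 cm in from the chest-wall field edge so
the disc is fully irradiated (< 0.1% inverse-square effect).

## Problem sizes

Default budgets, chosen so a full validation-plus-comparison campaign runs
in minutes on one CPU while keeping every CV below 1%: 2×10⁶ histories per
MGD run, 10⁶ per kerma run, 10⁷ for the validation case (CV < 0.1%).
CV scales as 1/√N (asserted by test), so the full-scale 5×10⁷-history
budget reaches CV ≈ 0.1–0.3% per condition.

## What the simulation does and does not emulate

The three-layer phantom captures the first-order effect of glandular
distribution along the beam axis — exponential attenuation weighting the
entrance-side tissue — under idealized conditions: sharp layer boundaries,
laterally homogeneous layers, a semicylindrical compressed shape, no
compression paddle in the dose runs, a perfectly absorbing receptor, no
anode heel effect or off-axis spectral variation.  Agreement with the
published phantom-level results therefore validates the dosimetry chain,
not the anatomical realism: real breasts have continuous, laterally varying
glandular maps (voxel-phantom studies report DgN deviations of the same
±25–40% magnitude), thinner skin (≈1.5 mm versus the 4 mm modelled here,
which is known to depress absolute DgN), and Cooper-ligament-scale
structure that layer models cannot represent.  Distribution-ratio
corrections transfer to other dosimetry systems more robustly than the
absolute coefficients.

## Known limitations

* Cross sections are compiled from published anchors plus analytic physics,
  not a maintained evaluated library; totals match NIST at anchors, μen/ρ
  of water/air to ≈0.5% (10–30 keV), and the Rh/Ag filter tables are only
  few-percent accurate (by design immaterial under HVL anchoring).
* Free-electron Compton by default; no Doppler broadening; independent-atom
  form factors (no molecular interference).
* Absolute DgN carries a ≈5% systematic envelope dominated by the kerma
  reference-point ambiguity and depth-dose amplification of cross-section
  uncertainty at 8–9 cm thickness; distribution ratios are accurate to
  ≈1 percentage point against the published comparisons.
* W anode only, 22–36 kVp; no Mo/Rh anodes, no tomosynthesis geometry.
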