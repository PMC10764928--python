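# Methods

This note documents the models implemented in `isodose`, the parameter
defaults and why they were chosen, what the synthetic data generator does and
does not emulate, and the numerical decisions that matter.

## Dose bookkeeping

All plan comparison happens on a single-fraction photon-equivalent scale.

**Units.** Every grid carries one of five tags: `Gy_absorbed` (physical
dose), `Gy_per_min` (absorbed dose rate, before irradiation-time scaling),
`Gy_IsoE_C12` (carbon-ion photon-equivalent total over a fractionated
course), `Gy_IsoE_C12_BED` (its single-fraction equivalent) and
`Gy_IsoE_BNCT` (BNCT photon-isoeffective dose; single-session by nature).
Arithmetic across mismatched units or lattices is rejected; this is the main
guard rail of the whole pipeline.

**BED / single-fraction conversion.** A scheme of `n` equal fractions
totalling `D` has `BED = D·(1 + (D/n)/(α/β))`; the single-fraction
equivalent is the positive root of `D_SF·(1 + D_SF/(α/β)) = BED` (closed
form, exactly inverse to BED at n = 1; round-trip verified to 1e−12).
Per-voxel conversion of a grid assumes each voxel receives all `n` fractions
at `D(x)/n` — the only scheme expressible from a single total-dose grid.
The two carbon-ion series (9 and 7 fractions) are therefore kept as two
separate grids, each converted with its own `n`, and combined in BED space;
the pipeline documents this as its conversion rule.  `α/β = 2 Gy` is the
clinical-practice default for carbon-ion and normal-tissue conversions;
`α/β = 10 Gy` is the convention the tumour-control model was built on.  Both
are configuration fields.

**Plan combination.** Sequential plans are summed voxelwise as
`D = SF(BED_A(x) + BED_B(x))` (commutative, associative to 1e−10,
dominates either addend).  As `α/β → ∞` this degenerates to the plain sum of
physical doses; the residual is exactly `2·D_A·D_B/(α/β)` per voxel, which
is why the limit check is asserted at *relative* 1e−4 at `α/β = 10⁶` —
an absolute 1e−4 is not attainable at 20–30 Gy voxel doses.  Healthy tissue
is assumed to recover completely between irradiations (the emulated
protocol's ~6-week gap), so normal-tissue *reporting* uses the linear sum of
single-fraction isoeffective doses instead.  Which rule applies to which ROI
is explicit in the pipeline, never implicit.

## TCP model

Uniform dose: `TCP(v, D) = exp(−c1·v^c2·S(D))` with `S(D) = exp(−αD − βD²)`,
`v` in cm³.  Defaults carry a published head-and-neck fit from ~100 SBRT
patients (doses converted to single fractions at α/β = 10):
`c1 = 2.4 [1.1, 3.7]`, `c2 = 0.12 [0, 0.26]`, `α = 0.022 [0.016, 0.028]` Gy⁻¹
(68% CIs).  `β` is not part of that printed fit; the default ties it to α by
the construction convention, `β = α/10 = 0.0022` Gy⁻², overridable.

Non-uniform dose (equivalent-subvolume model): the survival entering the
uniform formula is the exponent-1/c2 power mean of per-voxel survivals,
discretized as an equal-weight mean over ROI voxels (dose is scored on a
uniform lattice, dx/v = 1/n).

Numerics: with c2 ≈ 0.12 the exponent 1/c2 ≈ 8.3 makes `S^(1/c2)` underflow
catastrophically for doses beyond ~40 Gy, so the mean is formed from
`log S = −αD − βD²` via log-sum-exp; for `c2 < 1e−6` a dedicated branch
returns the analytic limit (the power mean tends to `max_x S(D(x))`: TCP is
cold-spot dominated).  Equivalence with an extended-precision naive sum is
maintained to 1e−9 on ≤100-voxel lists, and the small-c2 branch matches the
analytic limit to 1e−6 at c2 = 1e−8.

CI propagation: (c1, c2, α) are sampled independently and uniformly within
their 68% bounds (10 000 samples by default, seeded; β tied to α), and the
16th/84th percentiles of the sampled TCP are reported.  The published
analysis does not state its propagation scheme or parameter correlations;
independent-uniform sampling is declared, reproducible and conservative.
`c2 = 0` draws are evaluated on the limit branch.

## Mixed-field effect model and isoeffective dose

The four BNCT components are boron capture (∝ local ¹⁰B concentration for
fixed fluence), nitrogen-capture protons, fast-neutron hydrogen recoils, and
photons.  The effect model is component-additive — linear terms for the
high-LET components, full LQ for the photon-like component:

    E = a_B·D_B + a_N·D_N + a_f·D_f + α_R·D_ph + β_R·D_ph².

This is the simplest form in which high-LET damage is linear and the
reference radiation is LQ; the true clinical formalism uses first-order
repair-based synergy terms, so the form is isolated behind one function
(`mixed_effect`) to be swappable.  The isoeffective dose solves
`α_R·D_R + β_R·D_R² = E` by bracketed root finding (bracket
`[0, E/α_R + 1]`, tolerance 1e−10 Gy; pure-photon fields map to themselves).

Coefficient defaults are **synthetic placeholders** — the underlying
radiobiological fits are not public: `α_R = 0.022`, `β_R = 0.0022` (the
reference photon response on the tumour-model scale), boron
`a_B = 0.12 Gy⁻¹` in tumour context and `0.04` elsewhere (the 3:1 asymmetry
mirrors the compound biological effectiveness gap between tumour and normal
tissue for BPA-like carriers), `a_N = a_f = 0.07`.  All are configuration
inputs, including per-tissue boron overrides rasterized onto the lattice.

The traditional fixed-RBE/CBE comparator is a plain weighted sum of the four
absorbed components (defaults 3.8 / 3.2 / 3.2 / 1.0 — the standard
historical factors, also configuration).  Applications are summed linearly
(that formalism has no BED bookkeeping).  On the synthetic scenarios it
pushes the weighted GTV dose past ~60 Gy-Eq everywhere and the nominal TCP
above 0.999 — the "certain control" artefact the isoeffective formalism is
designed to avoid.

**Protocol constraint.** Each BNCT application is scaled in time so the
maximum *absorbed* dose over the mucosa compartment equals the limit
(default 6 Gy): `t = limit / max_mucosa(total rate)`.  Everything not
contoured as target, brain or nerve counts as mucosa — the worst-case
convention of the emulated protocol.  The optic-nerve isoeffective maximum is
checked per application against a placeholder tolerance (12 Gy (IsoE);
the authoritative constraint is the mucosa limit).

## Synthetic phantom and dose generators

The clinical voxel data are not deposited, so all scenario-level results run
on a procedural phantom.  What it emulates:

* **Geometry** (24³ lattice, 1 cm³ voxels — the scoring resolution of the
  emulated planning system): nested ellipsoidal targets realized by
  k-nearest-voxel growth around one centre, so GTV ⊂ PTV-HD ⊂ PTV-LD holds
  by construction and realized volumes match the configured 57.4 / 102.9 /
  263.5 cm³ to the voxel; a 1235 cm³ brain; two ~1 voxel optic nerves on the
  GTV flanks; a recurrence region wrapping one nerve inside PTV-LD; head
  surface and interior non-contoured tissue as mucosa.  Axes: beam `+z`
  enters at the low-z surface; the target sits off-centre towards the entry
  surfaces of the two default ports.
* **Boron uptake** (µg/g): tumour compartment 52.5, mucosa 30, skin 22.5,
  other tissues 15 — the BPA-infusion values of the emulated protocol; the
  tumour-to-normal ratio 3.5 holds exactly off contour overlaps.
* **CIRT plans**: prescription inside each PTV with multiplicative
  log-normal noise (σ = 0.035), Gaussian penumbra outside (1.2 cm), and an
  under-dosed wedge (45% depth, σ = 1.2 cm) centred just beyond the
  designated optic nerve — the organ-at-risk compromise that produced the
  recurrence.  The noise level is calibrated so the combined single-fraction
  GTV homogeneity index falls in the 0.05–0.15 band around the reference
  value 0.11.
* **BNCT fields**: per port, a thermal-fluence surrogate
  `(1 − e^(−d/4.6 cm))·e^(−d/9.5 cm)` (buildup then attenuation, peaking
  ~5 cm deep) times a Gaussian aperture (σ = 2 cm) aimed through the target
  centroid; boron component = rate constant × fluence × concentration map;
  nitrogen tracks the thermal fluence; fast dose decays from the entry
  surface (λ = 1.5 cm); photons decay slowly (λ = 8 cm).  Two applications
  with the same two-port geometry and independent noise.  Rate constants are
  set so a 6 Gy mucosa limit yields ~24–26 min sessions and GTV isoeffective
  doses in the low tens of Gy (IsoE), with the GTV homogeneity index in the
  0.25–0.40 band around the reference 0.31.  The recurrence scenario re-aims
  the aperture at the recurrence ROI with a lateral port pair.

What it does **not** emulate: anatomical realism, Monte Carlo neutron/photon
transport (the depth/aperture surrogate has no scatter, no lateral diffusion
beyond the aperture factor, plane-parallel entry surfaces per column),
contour geometry, organ motion, and any per-patient variability.  Passing
scenario tests therefore demonstrates that the *bookkeeping machinery*
reproduces the qualitative clinical findings (ordering of TCPs, homogeneity
contrast, recurrence under-dosing, mucosa-limited timing) under conditions
shaped like the published case — not that the generator predicts real
dosimetry.

All generators are pure functions of (spec, seed) using `numpy`'s seeded
`default_rng`; grids round-trip bit-exactly at float32 through the portable
format (JSON header + raw little-endian payload, x-fastest order, 0-based
indexing).

## Pipeline and reproducibility

One master seed drives phantom geometry, plan noise and CI propagation
through fixed offsets.  Reports consist of pandas tables (CSV on disk), DVH
CSVs, grids in the portable format and a JSON manifest carrying the config
hash; the report hash is a SHA-256 over the canonical JSON of all tables and
the manifest, and identical config + seed reproduce it byte-for-byte.  Every
table cell is recomputable from the stored grid and mask by the
corresponding statistics call (spot-checked in the test suite).

Statistics conventions: D_x uses the discrete at-least rule (the largest
sampled dose received by ≥ x% of voxels; no interpolation — at 1 cm³ voxels
the difference from interpolated percentiles is immaterial, but the choice
is recorded; an interpolated variant exists for figure work).  Quartiles use
the linear-interpolation (type-7) convention.  The homogeneity index is
computed at full precision and rounded to two decimals only for table
mirroring.

Problem sizes: scenarios run on the 24³ lattice with 10 000 TCP parameter
samples; the full three-scenario pipeline takes ~2 s on one CPU, and the
test suite ~5 s.

## Known limitations

* The mixed-field effect model is linear-additive; synergy between
  components and dose-rate effects within a session are not modelled.
* The per-voxel fraction conversion assumes every voxel sees every fraction;
  series-by-series conversion of printed totals therefore cannot reproduce
  published single-fraction tables cell-by-cell, and no numeric assertion is
  made against them.
* CI propagation ignores parameter correlations of the underlying fit
  (unavailable) and dose uncertainty.
* The optic-nerve/brain tolerance values are placeholders; only the mucosa
  constraint is authoritative in the emulated protocol.
* Masks are voxel sets, not contours; there is no resampling between
  lattices — co-registration is assumed.
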