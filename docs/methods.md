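# Methods

## The staggered-lattice model

One repetition unit of the fibril is abstracted as five collagen molecules
staggered axially by one d_M period and separated laterally by d_E, giving
an axial two-level electron density: an overlap band (five molecule
fractions) of width σ·d_M and a gap band (four fractions plus one gap) of
width (1−σ)·d_M.  Defaults are d_M = 65.5 nm, d_E = 1.514 nm, σ = 0.475,
233 residues per period (≈1050 residues in the unit, divided among ≈4.5
strand fractions), hence a helix rise of 65.5/233 ≈ 0.28 nm per residue.

The in-plane unit-cell area is modelled as k·d_E² with k calibrated once so
the swollen cell at d_E = 1.695 nm (the 90-day ribose endpoint) has area
21.9 nm²; the native cell is that area divided by the 26% swelling factor
(17.4 nm²).  The exact parallelogram geometry of the cell (angles, strand
offsets) is not part of this model — the quadratic surrogate preserves the
three anchors (21.9 nm², 17.4 nm², factor 1.26) without inventing angles.
The free in-plane fraction w = 1 − A_mol/A_cell is pinned by
w_nat = 0.255 at the native cell; the per-molecule share 0.051 times the
native area, in Å², defines the reference polar surface area
PSA_nat = 89 Å² used by the rate model.

Sugar constants (molar mass, electron count, topological polar surface
area) live in an editable CSV registry, not in code.  The shipped defaults
— ribose 150.13 g/mol, 80 e⁻, 90.2 Å²; glucose 180.16 g/mol, 96 e⁻,
110.0 Å² — agree with cheminformatics TPSA values for the cyclic forms to
within 0.4 Å² (cross-checked against rdkit in the test suite).

## Bragg analysis of 1D profiles

Meridional peaks are expected at q_n = 2πn/d_M.  Each order is searched
within ±30% of the spacing around its predicted position; the local
background is fit as a/q² + c over flanking windows and subtracted before
the maximum is located and refined by a 3-point parabolic fit.  The a/q² + c
form (rather than a straight line) matters at low q, where a chord under the
convex 1/q² diffuse background otherwise overestimates the background and
can swallow the first order entirely.  The peak amplitude is the square
root of the net integrated intensity — robust to instrumental broadening,
and only relative amplitudes are used downstream.  d_M is refit through the
origin by amplitude-weighted least squares of q_n on n; orders that show no
clear interior maximum under noise are then integrated at their predicted
positions in a second pass, since a small or zero net amplitude is itself a
valid measurement and dropping the order would desynchronize a
native/glycated pair of datasets.

The overlap fraction σ is fit from the amplitudes via the two-level model
|F_n| = scale·|sin(πnσ)|/(πn) (grid search plus bounded polish; the scale is
solved analytically at each σ).  σ and 1−σ produce identical moduli, so the
convention σ ≤ 0.5 is enforced.

The zero-order amplitude — hence the absolute average density — is not
measured; Δρ therefore enters the pipeline as tabulated input (or generator
ground truth), never from the amplitudes.

## Fourier-difference phasing

Stage 1 retrieves ρ_ini and ρ_fin jointly from their measured moduli
(orders 1..15 by default) by error-reduction alternating projections:
impose the measured moduli keeping current phases, then clip negative
density.  Unmeasured orders above the band are set to zero — between Bragg
peaks only diffuse background is observed — while order 0 is always left
free (the average density is unknown).  The spec-literal alternative of
leaving unmeasured orders untouched is available
(``zero_unmeasured=False``) but is not the default: from the step-like
start it is an immediate fixed point that keeps the step's spurious
harmonics, because positivity never binds when the running average sits
near 0.5.  Both trials start from a step (1 on half the period, 0
elsewhere) — the minimal unbiased prior for a gap/overlap structure — and
are replaced by their mean after each iteration for the first 90% of the
200 iterations, then evolve independently.

Stage 2 refines ρ_gl by the same projections with the targets set to the
absolute differences of the measured moduli, |F_fin,n| − |F_ini,n|; a
modulus must be nonnegative, so the sign of the difference is absorbed into
the retrieved phase.  Its starting profile is the positive part of
ρ_fin − ρ_ini from stage 1 (which, at stage-1 convergence, coincides with a
classic difference-Fourier synthesis under the native phases).  500
iterations are run per stage-2 pass.

The outer loop repeats both stages, reseeding stage 1 with the previous
ρ_ini and ρ_ini + ρ_gl.  At least 7 cycles run; by default the loop then
continues (to at most 30) until the relative change of ρ_gl per cycle drops
below 1e-4, since how many cycles convergence takes depends on the data —
synthetic scenarios typically need ~20.  A divergence guard aborts if the
modulus residual grows tenfold above its running minimum.  The algorithm is
fully deterministic: identical inputs give bit-identical outputs.

Because only moduli are constrained, any retrieved profile is defined up to
a cyclic shift and a mirror inversion; comparisons against absolutely
registered references always search both exhaustively (FFT
cross-correlation over all shifts, both orientations).

The two peak sets of a native/glycated pair carry one arbitrary intensity
scale each; both are divided by the *native* order-1 amplitude (the same
factor for the partner) so their difference is meaningful.  This rescaling
convention is an assumption; it is exact for the synthetic generator, which
shares one scale by construction.

With 15 orders at d_M ≈ 65 nm the resolution of ρ_gl is ≈ 4.3 nm.

## Residue proximity maps

Residue tables list (strand row, fractional axial coordinate, class) for
arginine and lysine/hydroxylysine.  Each residue is drawn as a 2-pixel
radius disk of unit total mass on a raster of 1930 pixels per period (one
pixel ≈ 1/1930 of d_M in both directions; strand rows are d_E apart in the
same pixel units), periodic in x.  Each class map is convolved with a
uniform disk whose *diameter* equals the experimental resolution (4.3 nm ≈
127 px; "width" is read as full extent, configurable), zero-padded in y
with a one-diameter margin so no mass is lost, periodic in x.  The
pointwise product of the two blurred maps peaks where both classes lie
within about one disk of each other; its column sums give the 1D proximity
profile D_arg–lys(x).  Correlation against a ρ_gl profile is plain Pearson
after linear resampling to the common grid; the CLI additionally aligns a
*phased* ρ_gl over shift/mirror before reporting r, echoing the shift.

Real linearized collagen coordinates are not shipped (no public table to
transcribe); the package provides the file format plus seeded synthetic
tables, including a paired mode that plants arg–lys proximity hot spots at
known positions.

## Period kinetics

The squared relative variations (d_Et/d_E0 − 1)² and (d_Mt/d_M0 − 1)² are
fit linearly in time by ordinary least squares *with* intercept —
through-origin fits are available but the with-intercept form reproduces
the tabulated slopes within their quoted uncertainties (1.63×10⁻⁴ day⁻¹
ribose d_E; 0.043×10⁻⁴ day⁻¹ glucose d_E; 3.1×10⁻⁶ day⁻¹ ribose d_M).
The squared quantity cannot carry a sign, so the d_M slope is reported
negative when the raw period shrinks over the series.  Fits are unweighted
(the tabulated uncertainties are nearly uniform); weighting is not applied
by default.  The ribose/glucose time-scale factor is the ratio of the two
d_E slopes, f ≈ 38.  The volume rate combines the signed slopes as
ΔV = (Δd_E + 1)(Δd_M + 1) − 1, dominated by the equatorial term; a
geometric alternative from period ratios at a chosen time is reported
separately when requested.

## Glycation kinetics model

Electron counting: a contrast increment Δρ_f − Δρ_i of 0.012 (ribose,
90 days, 40 mg/ml) times N_e = 160 000 electrons per collagen molecule
gives ≈1920 added electrons, i.e. ≈24 ribose molecules at 80 e⁻ each.
A detailed counting correction κ multiplies this rough count; κ defaults to
36.8/24 ≈ 1.533, anchored so the ribose 90-day count reproduces the
detailed estimate of 36.8 molecules.  The same κ applied to the glucose
increment (0.002 → 3.33 rough) yields 5.1, not the 8.2 reported from the
detailed treatment — a sugar-independent κ cannot reproduce both anchors;
the constant-κ choice is kept and only the ribose anchor is asserted.

Rates: each of the Np = 86 arginine–lysine/hydroxylysine pairs close enough
for crosslinking glycates at per-sugar rate R_AGE = c·(PSA_nat/TPSA)^5 —
sugars with larger polar surface area permeate the inter-molecular space
more slowly.  (The inverted orientation (TPSA/PSA_nat)^5 would make the
smaller-TPSA ribose slower than glucose, contradicting every observation
the model is built on, so the decreasing form is used.)  The per-site
probability is P(t) = min(R·t, 1) by default (an exponential
1 − e^(−Rt) is provided; both agree to first order and the linear form is
the simpler reading of a constant accumulation rate).  With N_s sugars
available, P_tot = 1 − (1 − P)^N_s (real-valued N_s allowed), and
N_glyc = Np·P_tot.

Sugar availability: N_s = N_sugar·w_sugar, where N_sugar is the molecule
count in a solution volume equal to one repetition unit (swollen cell area
× d_M; ≈230 for 40 mg/ml ribose) and w_sugar = 1 − (d_E0/d_Et)²(1 − w_nat)
is the free-space fraction of the (swollen) lattice, 0.255 native → 0.406
at the ribose endpoint.  Both terms are reconstructions of quantities whose
defining equations are in supplementary material not included here; each is
isolated behind its own function so alternates can be swapped in.

Calibration: c is the model's only free parameter, solved by bracketed
root-finding so that N_glyc(t_obs) matches one observed count (the
prediction is strictly increasing in c below saturation, so the root is
unique; round-trips invert to 1e-8 relative).  Under this package's
reconstruction, calibrating on 36.8 ribose molecules at 90 days / 40 mg/ml
gives c ≈ 0.026 yr⁻¹; literature-calibrated values near 0.069 yr⁻¹ rest on
the supplementary definitions of N_sugar and w_sugar and are *reported
against*, never asserted.  The relative volume curve is modelled as
ΔV(t) = ΔV_sat·P_tot(t) with saturation increments of 36% (ribose) and 10%
(glucose); the saturation *times* quoted elsewhere (0.64/2.27 yr) are not
reproducible under any reconstruction tried and are out of scope.

Rates are per-year internally; day inputs convert at 365 d/yr.

## Synthetic data and what passing tests show

The generator emulates the study conditions: two-level native density with
Δρ = 0.055 around a unit mean, planted Gaussian glycation sites, 15 Bragg
orders as unit-area Gaussian peaks of integrated intensity |F_n|² on a
1/q² background (coefficient 1e-4 — the background dominates the weakest
orders while leaving them locatable), Gaussian counting noise with
per-point σ = I/SNR (SNR 50 by default; the high-count synchrotron regime,
Poisson available in spirit via the same hook), and lattice time series
following the fitted linear laws with noise at the tabulated uncertainties
(0.1 nm d_M, 0.006 nm d_E, 0.001 Δρ), the t = 0 row exact so baselines are
well-defined.  All randomness derives from a single scenario seed with
per-output streams; every generator is bit-reproducible.

What the generator does *not* emulate: instrumental smearing beyond a
Gaussian peak width, inter-fibril disorder, drift between the native and
glycated measurements (the two synthetic profiles share one intensity
scale, which makes the order-1 rescaling convention exact), or real residue
coordinates.  Passing recovery tests therefore demonstrate the internal
consistency and numerical correctness of the pipeline under its own model
assumptions — not performance on measured tissue data.

## Numerical choices

* Phasing grid 1930 points (shared with the residue raster); results are
  grid-size-stable (tested at 960 and 3860).
* Zero-modulus phase convention: if a measured order's current modulus is
  exactly zero, its phase is set to 0 when the target is imposed.
* Positivity clips all negatives to zero; the tolerance field only widens
  the validity check, not the projector.
* Two-level σ fit: grid step ~1e-3 then bounded polish to 1e-7.
* Peak windows: ±30% of the spacing; background flanks span from the window
  edge to half the spacing.  These are documented defaults, not measured
  facts.
* Pearson correlations between profiles on different grids use periodic
  linear interpolation onto the finer grid.
* Calibration root-finding: Brent's method on [1e-6, 1e3] yr⁻¹ with
  xtol 1e-14.

## Known limitations

* Error-reduction projections (no feedback parameter) stagnate more easily
  than HIO-type algorithms; the outer refinement loop compensates but the
  recovered ρ_gl typically correlates ~0.88, not 1.0, with a planted truth
  at SNR 50 — the modulus-difference targets themselves differ from the
  true |F_gl,n| where native and glycation phases disagree.
* No uncertainty quantification on ρ_gl.
* The in-plane cell is a quadratic surrogate, not a real 2D lattice model.
* The kinetics model treats the sugar reservoir as constant (weekly solution
  refills) and ignores collagen turnover.
* The detailed-counting correction κ is sugar-independent by construction
  and is anchored on ribose only.
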