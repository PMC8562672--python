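# glycofibril

Analysis of non-enzymatic collagen glycation from small- and wide-angle
X-ray scattering (SAXS/WAXS) observables.

Type I collagen fibrils are built from ~306 nm triple-helix molecules packed
laterally at an equatorial spacing d_E ≈ 1.5 nm and staggered axially so that
the electron density repeats with a meridional period d_M ≈ 65 nm, split into
a dense *overlap* band of width σ·d_M (σ ≈ 0.475) and a sparser *gap* band.
When the tissue is incubated in a reducing-sugar solution, sugars attach to
lysine/hydroxylysine and arginine side chains (advanced glycation
end-products, e.g. glucosepane crosslinks), adding electron density at
specific axial positions and slowly swelling the lateral packing.  This
package turns the SAXS/WAXS observables of that process into quantitative
structure and kinetics:

* **Bragg analysis** — index the meridional orders of an azimuthally
  integrated 1D profile, extract d_M, the peak amplitudes |F_n|, the WAXS
  equatorial spacing d_E, and the overlap fraction σ from the two-level
  contrast model |F_n| ∝ |sin(πnσ)|/(πn).
* **Fourier-difference phasing** — recover the axial glycation density
  ρ_gl(x) = ρ_fin(x) − ρ_ini(x) from the native and glycated Bragg moduli by
  alternating projections (measured moduli in Fourier space, positivity in
  real space), two stages repeated in outer refinement cycles.  With 15
  measured orders the spatial resolution is d_M/15 ≈ 4.3 nm.
* **Residue proximity maps** — rasterize arginine and lysine/hydroxylysine
  positions over the 5-strand staggered unit, blur each class map to the
  experimental resolution with a uniform disk, and form
  D_arg–lys(x,y) = [D_arg ⊗ Disk_R]·[D_lys ⊗ Disk_R]; its y-integral
  D_arg–lys(x) is the structural model that ρ_gl is correlated against.
* **Period kinetics** — the squared relative variations
  (d_Et/d_E0 − 1)² and (d_Mt/d_M0 − 1)² grow linearly in incubation time;
  ordinary least squares gives the sugar-specific slopes, the
  ribose/glucose time-scale factor f ≈ 38, the contrast trend Δρ(t), and the
  fibril volume change ΔV = (Δd_E + 1)(Δd_M + 1) − 1.
* **Glycation-rate model** — electron counting converts the contrast
  increment into bound-molecule counts (Δρ increment × N_e electrons ÷
  electrons per sugar); the kinetics model predicts the glycated fraction of
  the Np = 86 candidate arg–lys pairs over years, with a per-site rate
  R_AGE = c·(PSA_nat/TPSA_sugar)^5 scaled by the sugar's topological polar
  surface area, P_tot(t) = 1 − (1 − P(t))^N_s for N_s available sugars, and
  a single rate constant c calibrated on one observed count.
* **Synthetic data** — seeded generators for every input (density pairs with
  planted glycation sites, SAXS/WAXS profiles with 1/q² background and
  counting noise, lattice time series, residue tables), so the full pipeline
  is testable end to end without any measured data.

The packaged observable tables (`glycofibril.data`) are per-timepoint
(t, d_M, d_E, Δρ) series for bovine-pericardium collagen in 40 mg/ml ribose
and glucose solutions over 0–90 days.

## Worked example

```text
$ glycofibril periods table1_ribose.csv --second table2_glucose.csv --out results
d_E slope 1.626e-04/day, d_M slope -3.125e-06/day, f = 37.8
```

The equatorial packing of the ribose series swells with a squared-relative
slope of 1.63×10⁻⁴ day⁻¹ while the axial period shrinks about two orders of
magnitude more slowly (−3.1×10⁻⁶ day⁻¹); glucose drives the same swelling
law a factor f ≈ 38 more slowly.

```text
$ glycofibril simulate --seed 1 --out sim
synthetic dataset written to sim
$ glycofibril phase sim/peaks_native.csv sim/peaks_glycated.csv --out results
rho_gl written (30 cycles, resolution 4.37 nm)
$ glycofibril map sim/residues.csv results/rho_gl.csv --out results
Pearson r(model, rho_gl) = 0.847 (shift 1726 px)
```

`simulate` plants glycation density at the arginine–lysine pair positions of
a random residue table and writes noisy (SNR 50) SAXS profiles for the
native and glycated states.  `phase` retrieves ρ_gl from the two indexed
peak sets at 4.37 nm resolution; `map` builds the proximity model from the
residue table and correlates it with the retrieved ρ_gl (r = 0.85 here; a
phased profile is defined only up to a cyclic shift and mirror, so the
reported r is after alignment, with the shift echoed).

```text
$ glycofibril kinetics --observed-n 36.8 --t-obs-days 90 --sugar ribose --concentration 40 --out results
c = 0.0259/yr, R_AGE = 0.0242/yr, fraction at 10 yr = 1.000
```

Calibrating the rate constant on 36.8 glycated ribose molecules after 90
days at 40 mg/ml gives c = 0.026 yr⁻¹ under this package's reconstruction of
the sugar-availability terms (see `docs/methods.md` for why this differs
from literature values), an effective ribose rate of 0.024 yr⁻¹, and a
ribose curve that saturates all 86 candidate pairs within 10 years at that
concentration.

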