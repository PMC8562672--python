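"""Synthetic data emulating meridional SAXS of glycating collagen.

Everything the pipeline ingests can be generated here under one seeded
scenario: native/glycated axial density pairs (two-level gap/overlap profile
plus planted Gaussian glycation sites), SAXS profiles with Bragg peaks on a
1/q² background and counting noise, lattice time series obeying the linear
squared-relative-variation laws, WAXS equatorial peaks, and residue tables
with optional planted arginine-lysine proximity hot spots.

Defaults mirror the bovine-pericardium study conditions: d_M = 65.5 nm,
d_E = 1.514 nm, sigma = 0.475, 15 measurable Bragg orders, contrast
delta_rho = 0.055, and per-timepoint noise at the printed measurement
uncertainties (0.1 nm in d_M, ~0.006 nm in d_E, 0.001 in delta_rho).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CollagenLattice
from .kinetics import LatticeTimeSeries
from .phasing import AxialDensityProfile
from .residue_map import ResidueTable
from .saxs import SAXSProfile

import pandas as pd

__all__ = [
    "SyntheticScenario",
    "gen_density_pair",
    "gen_saxs_profile",
    "gen_waxs_profile",
    "gen_timeseries",
    "gen_residue_table",
]


@dataclass
class SyntheticScenario:
    """One seeded set of ground-truth parameters for all generators.

    ``glycation_sites`` are (x_frac, amplitude, width_nm) Gaussians added to
    the native two-level profile; ``timeseries_slopes`` are the linear-law
    rates (d_E day⁻¹, signed d_M day⁻¹, delta_rho day⁻¹).
    """

    seed: int = 0
    lattice: CollagenLattice = field(default_factory=CollagenLattice)
    delta_rho_contrast: float = 0.055
    glycation_sites: tuple[tuple[float, float, float], ...] = (
        (0.20, 0.040, 3.2),
        (0.47, 0.030, 2.8),
        (0.78, 0.035, 3.6),
    )
    n_orders: int = 15
    grid_size: int = 1930
    background_amp: float = 1e-4
    noise_snr: float = 50.0
    peak_width_q: float = 0.004
    timeseries_slopes: tuple[float, float, float] = (1.63e-4, -3.1e-6, 1.26e-4)
    noise_d_M: float = 0.1
    noise_d_E: float = 0.006
    noise_delta_rho: float = 0.001
    n_residues: int = 30

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def gen_density_pair(scenario: SyntheticScenario
                     ) -> tuple[AxialDensityProfile, AxialDensityProfile, AxialDensityProfile]:
    """Native profile, glycated profile and planted glycation ground truth.

    The native profile is the two-level model around a unit average: overlap
    band at ``1 + (1-sigma)*delta_rho``, gap at ``1 - sigma*delta_rho``; the
    glycation density is a sum of periodic Gaussians at the planted sites;
    the glycated profile is their sum.  All three are nonnegative.
    """
    lat, n = scenario.lattice, scenario.grid_size
    x = np.arange(n) / n
    ini = np.where(x < lat.sigma,
                   1.0 + (1.0 - lat.sigma) * scenario.delta_rho_contrast,
                   1.0 - lat.sigma * scenario.delta_rho_contrast)
    gl = np.zeros(n)
    for x0, amp, width_nm in scenario.glycation_sites:
        if not 0 <= x0 < 1:
            raise ValueError(f"glycation site {x0} outside [0, 1)")
        if width_nm <= 0 or amp < 0:
            raise ValueError("site widths must be positive, amplitudes nonnegative")
        s = width_nm / lat.d_M  # Gaussian sigma in fractional units
        dx = (x - x0 + 0.5) % 1.0 - 0.5  # minimal periodic image distance
        gl += amp * np.exp(-0.5 * (dx / s) ** 2)
    fin = ini + gl
    return (AxialDensityProfile(ini, d_M=lat.d_M, role="rho_ini"),
            AxialDensityProfile(fin, d_M=lat.d_M, role="rho_fin"),
            AxialDensityProfile(gl, d_M=lat.d_M, role="rho_gl"))


def gen_saxs_profile(density: AxialDensityProfile, scenario: SyntheticScenario,
                     stream: int = 1, label: str = "synthetic") -> SAXSProfile:
    """SAXS curve of a density: Bragg peaks + 1/q² background + noise.

    Each order n carries integrated intensity |F_n|² (unit-area Gaussian of
    width ``peak_width_q``), so indexing recovers |F_n| as its amplitude.
    Gaussian noise with per-point sigma = intensity / SNR is drawn from the
    seeded stream; intensities are floored at zero.
    """
    lat = scenario.lattice
    d_M = density.d_M
    spec = np.fft.rfft(density.values) / density.grid_size
    q_max = 2 * np.pi * (scenario.n_orders + 0.7) / d_M
    q = np.linspace(0.03, q_max, 4096)
    intensity = scenario.background_amp / q**2
    w = scenario.peak_width_q
    for n in range(1, scenario.n_orders + 1):
        qn = 2 * np.pi * n / d_M
        f2 = np.abs(spec[n]) ** 2
        intensity = intensity + f2 / (w * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((q - qn) / w) ** 2)
    if np.isfinite(scenario.noise_snr):
        rng = scenario.rng(stream)
        intensity = intensity + rng.normal(0.0, intensity / scenario.noise_snr)
        intensity = np.maximum(intensity, 0.0)
    return SAXSProfile(q, intensity, label=label, kind="SAXS")


def gen_waxs_profile(d_E: float, scenario: SyntheticScenario,
                     stream: int = 2, label: str = "synthetic-waxs") -> SAXSProfile:
    """WAXS curve with one equatorial peak at q = 2*pi/d_E on a flat floor."""
    q = np.linspace(2.0, 6.0, 2048)
    q0 = 2 * np.pi / d_E
    intensity = 0.05 + np.exp(-0.5 * ((q - q0) / 0.05) ** 2)
    if np.isfinite(scenario.noise_snr):
        rng = scenario.rng(stream)
        intensity = np.maximum(
            intensity + rng.normal(0.0, intensity / scenario.noise_snr), 0.0)
    return SAXSProfile(q, intensity, label=label, kind="WAXS")


def gen_timeseries(scenario: SyntheticScenario, t_days,
                   sugar: str = "ribose", concentration: float = 40.0,
                   noisy: bool = True, stream: int = 3) -> LatticeTimeSeries:
    """Lattice observables over time obeying the linear squared-variation laws.

    ``d_E(t) = d_E0 (1 + sqrt(s_E t))``, ``d_M(t) = d_M0 (1 - sqrt(|s_M| t))``
    for a negative meridional slope (growing for positive), and a linear
    delta_rho trend; optional seeded Gaussian noise at the printed
    measurement uncertainties.  The t = 0 baseline row stays noise-free so it
    defines the reference periods exactly.
    """
    t = np.asarray(t_days, dtype=float)
    if t[0] != 0:
        raise ValueError("t grid must start at 0")
    s_E, s_M, s_rho = scenario.timeseries_slopes
    if s_E < 0:
        raise ValueError("equatorial slope must be nonnegative (d_E swells)")
    lat = scenario.lattice
    d_E = lat.d_E * (1.0 + np.sqrt(s_E * t))
    d_M = lat.d_M * (1.0 + np.sign(s_M) * np.sqrt(np.abs(s_M) * t))
    rho = scenario.delta_rho_contrast + s_rho * t
    if noisy:
        rng = scenario.rng(stream)
        keep = t == 0
        d_E = np.where(keep, d_E, d_E + rng.normal(0, scenario.noise_d_E, t.size))
        d_M = np.where(keep, d_M, d_M + rng.normal(0, scenario.noise_d_M, t.size))
        rho = np.where(keep, rho, rho + rng.normal(0, scenario.noise_delta_rho, t.size))
    df = pd.DataFrame({
        "t_days": t, "d_M": d_M, "d_M_err": scenario.noise_d_M,
        "d_E": d_E, "d_E_err": scenario.noise_d_E,
        "delta_rho": rho, "delta_rho_err": scenario.noise_delta_rho,
        "sugar": sugar, "concentration": concentration,
    })
    return LatticeTimeSeries(df, sugar=sugar, concentration=concentration)


def gen_residue_table(scenario: SyntheticScenario, paired: bool = False,
                      pair_x: float | None = None, pair_spread: float = 0.01,
                      stream: int = 4) -> ResidueTable:
    """Seeded residue positions for both classes.

    In ``paired`` mode every arginine is placed within ``pair_spread`` of a
    lysine/hydroxylysine partner (all pairs at ``pair_x`` when given),
    planting proximity hot spots at known axial positions; otherwise both
    classes are scattered independently.
    """
    rng = scenario.rng(stream)
    n, rows = scenario.n_residues, scenario.lattice.n_strands
    recs = []
    if paired:
        for _ in range(n):
            x = pair_x if pair_x is not None else rng.uniform(0, 1)
            strand = rng.integers(0, rows)
            recs.append((strand, x % 1.0, "LYS_HYL"))
            recs.append((strand, (x + rng.uniform(-pair_spread, pair_spread)) % 1.0, "ARG"))
    else:
        for cls in ("ARG", "LYS_HYL"):
            for _ in range(n):
                recs.append((rng.integers(0, rows), rng.uniform(0, 1), cls))
    df = pd.DataFrame(recs, columns=["strand_row", "x_frac", "residue_class"])
    return ResidueTable(df)
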