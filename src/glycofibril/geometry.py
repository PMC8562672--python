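"""Staggered-fibril lattice geometry of type I collagen.

The axial electron density of a collagen fibril repeats with the meridional
period ``d_M`` (~65 nm).  Five laterally staggered triple-helix molecules
(separated equatorially by ``d_E`` ~ 1.5 nm) form one repetition unit whose
period splits into a dense *overlap* band of width ``sigma * d_M`` (five
molecule fractions) and a complementary *gap* band of width
``(1 - sigma) * d_M`` (four fractions plus one gap).

This module holds the lattice record, the sugar registry, and the small
geometric derivations used downstream: band widths, the in-plane unit-cell
area, the free (inter-molecular) packing fraction, and the reference polar
surface area ``PSA_nat`` of the native packing.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "CollagenLattice",
    "SugarSpec",
    "load_sugar_registry",
    "get_sugar",
    "band_widths",
    "unit_cell_area",
    "packing_free_fraction",
    "psa_nat_estimate",
    "SWOLLEN_CELL_AREA_NM2",
    "SWELLING_FACTOR",
    "NATIVE_CELL_AREA_NM2",
    "REFERENCE_D_E_SWOLLEN",
    "W_NATIVE",
]

# Printed anchors of the in-plane packing model: the swollen unit cell is
# 21.9 nm^2 (evaluated at the 90-day ribose d_E = 1.695 nm) and is 26% larger
# than the native cell; the native free-space fraction is w_nat = 0.255.
SWOLLEN_CELL_AREA_NM2 = 21.9
SWELLING_FACTOR = 1.26
NATIVE_CELL_AREA_NM2 = 17.4
REFERENCE_D_E_SWOLLEN = 1.695
W_NATIVE = 0.255


@dataclass(frozen=True)
class CollagenLattice:
    """Geometry of the staggered collagen repetition unit.

    Parameters
    ----------
    d_M : float
        Meridional (axial) period in nm.
    d_E : float
        Equatorial center-to-center distance between molecules, nm.
    sigma : float
        Overlap fraction of the period (dimensionless, 0 < sigma < 1).
    n_strands : int
        Number of laterally staggered molecules per repetition unit.
    molecule_length : float
        Length of one triple-helix molecule, nm.
    residues_per_period : int
        Residue count per d_M period (~1050 residues / 4.5 strand fractions).
    """

    d_M: float = 65.5
    d_E: float = 1.514
    sigma: float = 0.475
    n_strands: int = 5
    molecule_length: float = 306.0
    residues_per_period: int = 233

    def __post_init__(self) -> None:
        if not self.d_M > 0:
            raise ValueError(f"d_M must be positive, got {self.d_M}")
        if not self.d_E > 0:
            raise ValueError(f"d_E must be positive, got {self.d_E}")
        if not 0.0 < self.sigma < 1.0:
            raise ValueError(f"sigma must lie in (0, 1), got {self.sigma}")
        if self.n_strands < 2:
            raise ValueError(f"n_strands must be >= 2, got {self.n_strands}")
        if self.residues_per_period < 1:
            raise ValueError("residues_per_period must be positive")

    @property
    def rise_per_residue(self) -> float:
        """Axial rise of the collagen helix per residue, nm (d_M / residues)."""
        return self.d_M / self.residues_per_period


@dataclass(frozen=True)
class SugarSpec:
    """One reducing sugar: identity, size and polar surface area.

    ``tpsa`` is the topological polar surface area in Å², the descriptor the
    rate model scales with; ``electrons`` is the total electron count per
    molecule, used to convert electron-density increments into molecule
    counts.
    """

    name: str
    molar_mass: float
    electrons: int
    tpsa: float

    def __post_init__(self) -> None:
        if self.molar_mass <= 0 or self.tpsa <= 0:
            raise ValueError(f"molar_mass and tpsa must be positive for {self.name}")
        if int(self.electrons) != self.electrons or self.electrons <= 0:
            raise ValueError(f"electrons must be a positive integer for {self.name}")


def load_sugar_registry(path: str | Path | None = None) -> dict[str, SugarSpec]:
    """Load the sugar registry (CSV: name,molar_mass,electrons,tpsa).

    Without ``path`` the packaged defaults (ribose, glucose) are returned.
    """
    if path is None:
        src = resources.files("glycofibril.data").joinpath("sugars.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"name", "molar_mass", "electrons", "tpsa"}
    if not required.issubset(df.columns):
        raise ValueError(f"sugar registry must have columns {sorted(required)}")
    return {
        str(r["name"]): SugarSpec(
            name=str(r["name"]),
            molar_mass=float(r["molar_mass"]),
            electrons=int(r["electrons"]),
            tpsa=float(r["tpsa"]),
        )
        for _, r in df.iterrows()
    }


def get_sugar(name: str, path: str | Path | None = None) -> SugarSpec:
    registry = load_sugar_registry(path)
    try:
        return registry[name]
    except KeyError:
        raise KeyError(f"unknown sugar {name!r}; registry has {sorted(registry)}") from None


def band_widths(lattice: CollagenLattice) -> tuple[float, float]:
    """Widths (nm) of the overlap and gap bands: (sigma*d_M, (1-sigma)*d_M).

    Their sum is exactly d_M.
    """
    overlap = lattice.sigma * lattice.d_M
    return overlap, lattice.d_M - overlap


def unit_cell_area(d_E: float, state: str = "swollen") -> float:
    """In-plane unit-cell area (nm²) for the n-strand repetition unit.

    The cell area is modelled as ``k * d_E**2`` with ``k`` calibrated once so
    that the swollen cell evaluated at the reference swollen spacing
    (d_E = 1.695 nm) has area 21.9 nm².  The native cell is the swollen cell
    divided by the 26% swelling factor at the same d_E.
    """
    if d_E <= 0:
        raise ValueError(f"d_E must be positive, got {d_E}")
    k = SWOLLEN_CELL_AREA_NM2 / REFERENCE_D_E_SWOLLEN**2
    area = k * d_E**2
    if state == "swollen":
        return area
    if state == "native":
        return area / SWELLING_FACTOR
    raise ValueError(f"state must be 'swollen' or 'native', got {state!r}")


#: total molecular cross-section in one cell, fixed by w_nat at the native cell
_A_MOLECULES_NM2 = (1.0 - W_NATIVE) * NATIVE_CELL_AREA_NM2


def packing_free_fraction(area_cell: float, state: str = "native") -> float:
    """Fraction of in-plane space not occupied by collagen molecules.

    Cylinder-packing picture: the total molecular cross-section per cell is a
    constant, fixed so that the native cell has a free fraction
    ``w_nat = 0.255``.  A swollen cell therefore frees more space:
    ``w = 1 - A_mol / area_cell``.  ``state`` is informational only (the
    molecular cross-section does not change on swelling).
    """
    if state not in ("native", "swollen"):
        raise ValueError(f"state must be 'swollen' or 'native', got {state!r}")
    if area_cell < _A_MOLECULES_NM2:
        raise ValueError(
            f"cell area {area_cell} nm² is below the total molecular "
            f"cross-section {_A_MOLECULES_NM2:.3f} nm²"
        )
    return 1.0 - _A_MOLECULES_NM2 / area_cell


def psa_nat_estimate(w_per_molecule: float, native_area_nm2: float) -> int:
    """Reference polar surface area of the native packing, Å² (rounded).

    The per-molecule free-space fraction times the native cell area gives the
    effective inter-molecular area available to a permeating sugar; expressed
    in Å² (1 nm² = 100 Å²) and rounded to the nearest integer.
    """
    if w_per_molecule <= 0 or native_area_nm2 <= 0:
        raise ValueError("inputs must be positive")
    return round(w_per_molecule * native_area_nm2 * 100.0)
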