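"""2D residue maps of the staggered repetition unit and proximity analysis.

Arginine and lysine/hydroxylysine positions along the five staggered strands
are rasterized onto a shared pixel grid (one pixel = 1/1930 of the d_M
period in both directions), blurred to the experimental resolution with a
uniform circular disk, and multiplied pointwise:

    D_arg-lys(x, y) = [D_arg ⊗ Disk_R] * [D_lys ⊗ Disk_R]

The product peaks where residues of *both* classes sit within ~R of each
other — candidate crosslink (glucosepane) sites.  Integrating over y gives a
1D profile D_arg-lys(x) directly comparable, via Pearson correlation, with
the glycation density retrieved by Fourier-difference phasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CollagenLattice
from .phasing import AxialDensityProfile

__all__ = [
    "ResidueTable",
    "ResidueMap2D",
    "read_residue_table",
    "write_residue_table",
    "rasterize",
    "disk_blur",
    "proximity_map",
    "project_axial",
    "correlate",
    "disk_diameter_px",
]

RESIDUE_CLASSES = ("ARG", "LYS_HYL")
DEFAULT_X_PIXELS = 1930
DEFAULT_BULLET_RADIUS_PX = 2
DEFAULT_RESOLUTION_NM = 4.3


@dataclass
class ResidueTable:
    """Residue positions: strand row, fractional axial coordinate, class."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"strand_row", "x_frac", "residue_class"}
        if not req.issubset(self.data.columns):
            raise ValueError(f"residue table must have columns {sorted(req)}")
        if len(self.data) == 0:
            raise ValueError("residue table is empty")
        x = self.data["x_frac"].to_numpy(dtype=float)
        if np.any(x < 0) or np.any(x >= 1):
            raise ValueError("x_frac must lie in [0, 1)")
        bad = set(self.data["residue_class"]) - set(RESIDUE_CLASSES)
        if bad:
            raise ValueError(f"unknown residue classes {sorted(bad)}")

    def subset(self, residue_class: str) -> pd.DataFrame:
        return self.data[self.data["residue_class"] == residue_class]


@dataclass
class ResidueMap2D:
    """A nonnegative raster over the repetition unit (shared pixel size)."""

    raster: np.ndarray
    x_pixels: int = DEFAULT_X_PIXELS
    y_margin_px: int = 0

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=float)
        if self.raster.ndim != 2 or self.raster.shape[1] != self.x_pixels:
            raise ValueError("raster must be 2D with x_pixels columns")
        if np.any(self.raster < 0):
            raise ValueError("raster must be nonnegative")

    @property
    def mass(self) -> float:
        return float(self.raster.sum())


def read_residue_table(path: str | Path) -> ResidueTable:
    return ResidueTable(pd.read_csv(path))


def write_residue_table(table: ResidueTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def disk_diameter_px(r_nm: float, lattice: CollagenLattice,
                     x_pixels: int = DEFAULT_X_PIXELS) -> int:
    """Disk diameter in pixels for a blur width R in nm, rounded to odd."""
    d = r_nm / lattice.d_M * x_pixels
    k = int(round(d))
    return k if k % 2 == 1 else k + 1


def _disk_kernel(diameter_px: int) -> np.ndarray:
    r = diameter_px / 2.0
    c = (diameter_px - 1) / 2.0
    yy, xx = np.mgrid[0:diameter_px, 0:diameter_px]
    kernel = ((xx - c) ** 2 + (yy - c) ** 2 <= r**2).astype(float)
    return kernel / kernel.sum()


def _stamp_disk(canvas: np.ndarray, cx: float, cy: float, radius_px: int) -> None:
    """Add one unit of mass as a disk, periodic in x, clipped in y."""
    ny, nx = canvas.shape
    ix, iy = int(round(cx)) % nx, int(round(cy))
    yy, xx = np.mgrid[-radius_px:radius_px + 1, -radius_px:radius_px + 1]
    inside = xx**2 + yy**2 <= radius_px**2
    npix = int(inside.sum())
    for dy, dx in zip(yy[inside], xx[inside]):
        y, x = iy + dy, (ix + dx) % nx
        if 0 <= y < ny:
            canvas[y, x] += 1.0 / npix


def rasterize(table: ResidueTable, lattice: CollagenLattice,
              x_pixels: int = DEFAULT_X_PIXELS,
              bullet_radius_px: int = DEFAULT_BULLET_RADIUS_PX,
              resolution_nm: float = DEFAULT_RESOLUTION_NM) -> tuple[ResidueMap2D, ResidueMap2D]:
    """Draw each residue as a unit-mass disk on a shared canvas pair.

    Strand rows are separated by d_E in pixel units (same pixel size on both
    axes); the canvas carries a y-margin of one blur-disk diameter on each
    side so the later disk blur loses no mass at the top/bottom edges.
    Periodic wrap applies in x.  Returns (arginine map, lysine map).
    """
    row_spacing = lattice.d_E / lattice.d_M * x_pixels
    margin = disk_diameter_px(resolution_nm, lattice, x_pixels)
    ny = int(np.ceil((lattice.n_strands - 1) * row_spacing)) + 2 * margin + 1

    maps = {}
    for cls in RESIDUE_CLASSES:
        canvas = np.zeros((ny, x_pixels))
        sub = table.subset(cls)
        for _, row in sub.iterrows():
            strand = int(row["strand_row"])
            if strand < 0 or strand >= lattice.n_strands:
                raise ValueError(f"strand_row {strand} outside 0..{lattice.n_strands - 1}")
            cx = float(row["x_frac"]) * x_pixels
            cy = margin + strand * row_spacing
            _stamp_disk(canvas, cx, cy, bullet_radius_px)
        maps[cls] = ResidueMap2D(canvas, x_pixels=x_pixels, y_margin_px=margin)
    return maps["ARG"], maps["LYS_HYL"]


def disk_blur(rmap: ResidueMap2D, r_nm: float, lattice: CollagenLattice) -> ResidueMap2D:
    """Convolve with a unit-integral uniform disk of diameter R (in nm).

    Periodic in x (the d_M period repeats), zero-padded in y.  Mass is
    conserved up to boundary loss in y, which the rasterization margin makes
    negligible.
    """
    if r_nm <= 0:
        raise ValueError("R must be positive")
    dia = disk_diameter_px(r_nm, lattice, rmap.x_pixels)
    ny, nx = rmap.raster.shape
    if dia > min(ny, nx):
        raise ValueError(f"disk diameter {dia}px exceeds canvas {rmap.raster.shape}")
    kernel = _disk_kernel(dia)
    pad = dia // 2
    # zero-pad y so the circular FFT convolution is linear in y; x stays periodic
    padded = np.zeros((ny + 2 * pad, nx))
    padded[pad:pad + ny] = rmap.raster
    kfull = np.zeros_like(padded)
    kfull[:dia, :dia] = kernel
    kfull = np.roll(kfull, (-pad, -pad), axis=(0, 1))
    out = np.fft.irfft2(np.fft.rfft2(padded) * np.fft.rfft2(kfull), s=padded.shape)
    out = out[pad:pad + ny]
    return ResidueMap2D(np.maximum(out, 0.0), x_pixels=rmap.x_pixels,
                        y_margin_px=rmap.y_margin_px)


def proximity_map(map_arg: ResidueMap2D, map_lys: ResidueMap2D,
                  r_nm: float, lattice: CollagenLattice) -> ResidueMap2D:
    """Pointwise product of the two resolution-blurred class maps.

    Maxima mark x,y locations where arginine and lysine/hydroxylysine lie
    within about one blur disk of each other.
    """
    if map_arg.raster.shape != map_lys.raster.shape:
        raise ValueError("maps must share one geometry")
    a = disk_blur(map_arg, r_nm, lattice)
    b = disk_blur(map_lys, r_nm, lattice)
    return ResidueMap2D(a.raster * b.raster, x_pixels=map_arg.x_pixels,
                        y_margin_px=map_arg.y_margin_px)


def project_axial(rmap: ResidueMap2D, d_M: float = 65.5) -> AxialDensityProfile:
    """Integrate over y: the 1D proximity profile D_arg-lys(x)."""
    return AxialDensityProfile(rmap.raster.sum(axis=0), d_M=d_M, role="rho_model")


def correlate(model: AxialDensityProfile, rho_gl: AxialDensityProfile
              ) -> tuple[float, np.ndarray, np.ndarray]:
    """Pearson correlation of a model profile with the retrieved rho_gl.

    The two profiles are linearly resampled onto the finer of the two grids
    (periodic in the fractional coordinate).  Also returns the pair
    normalized to a common (unit) integral, for plotting.
    """
    n = max(model.grid_size, rho_gl.grid_size)
    x = np.arange(n) / n

    def resample(p: AxialDensityProfile) -> np.ndarray:
        if p.grid_size == n:
            return p.values.astype(float)
        xp = np.arange(p.grid_size + 1) / p.grid_size
        fp = np.append(p.values, p.values[0])  # periodic closure
        return np.interp(x, xp, fp)

    a, b = resample(model), resample(rho_gl)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(a, b)[0, 1])

    def unit_integral(v: np.ndarray) -> np.ndarray:
        s = v.sum() / n
        return v / s if s != 0 else v

    return r, unit_integral(a), unit_integral(b)
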