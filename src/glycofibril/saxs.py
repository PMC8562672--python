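"""1D SAXS/WAXS profile handling and meridional Bragg analysis.

The fibril's axial periodicity produces equispaced meridional Bragg peaks at
``q_n = 2*pi*n / d_M`` riding on a large ``1/q^2`` background.  This module
reads azimuthally integrated two-column profiles, locates and integrates the
peaks net of a local ``a/q^2 + c`` background, refines ``d_M`` by a
through-origin fit of the peak positions, extracts the equatorial spacing
``d_E`` from the WAXS peak, and fits the two-level (gap/overlap) contrast
model whose order-n Fourier modulus is ``scale * |sin(pi*n*sigma)|/(pi*n)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "SAXSProfile",
    "PeakSet",
    "read_profile",
    "write_profile",
    "index_meridional_peaks",
    "fit_d_E",
    "fit_two_level_model",
    "two_level_moduli",
    "read_peakset",
    "write_peakset",
    "IndexingError",
]


class IndexingError(RuntimeError):
    """Raised when too few Bragg orders can be located."""


@dataclass
class SAXSProfile:
    """A measured 1D scattering curve I(q).

    q is in nm⁻¹ and strictly increasing; intensities are nonnegative.
    """

    q: np.ndarray
    intensity: np.ndarray
    label: str = ""
    kind: str = "SAXS"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape or self.q.ndim != 1:
            raise ValueError("q and intensity must be 1D arrays of equal length")
        if self.q.size < 16:
            raise ValueError(f"profile needs >= 16 points, got {self.q.size}")
        if not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")
        if self.kind not in ("SAXS", "WAXS"):
            raise ValueError(f"kind must be SAXS or WAXS, got {self.kind!r}")


@dataclass
class PeakSet:
    """Indexed meridional Bragg orders of one profile.

    ``amplitude`` is the square root of the background-subtracted integrated
    peak intensity (arbitrary units — only relative amplitudes matter).
    """

    orders: np.ndarray
    q_centers: np.ndarray
    amplitudes: np.ndarray
    d_M: float
    n_max: int
    label: str = ""

    def __post_init__(self) -> None:
        self.orders = np.asarray(self.orders, dtype=int)
        self.q_centers = np.asarray(self.q_centers, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(set(self.orders.tolist())) != self.orders.size or np.any(self.orders < 1):
            raise ValueError("orders must be distinct positive integers")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")

    def moduli(self) -> dict[int, float]:
        """Map order -> amplitude."""
        return {int(n): float(a) for n, a in zip(self.orders, self.amplitudes)}

    def rescaled(self, factor: float) -> "PeakSet":
        return PeakSet(self.orders.copy(), self.q_centers.copy(),
                       self.amplitudes * factor, self.d_M, self.n_max, self.label)


def read_profile(path: str | Path, kind: str = "SAXS", label: str | None = None) -> SAXSProfile:
    """Read a two-column (q, I) text profile.

    Lines starting with '#' are comments; a header line ``# units: A^-1``
    requests conversion of q from Å⁻¹ to nm⁻¹ (×10).  Columns may be
    whitespace- or comma-delimited.
    """
    path = Path(path)
    factor = 1.0
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "units:" in line and "A^-1" in line:
                    factor = 10.0
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed line {line!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError(f"{path}: empty profile file")
    arr = np.array(rows, dtype=float)
    return SAXSProfile(arr[:, 0] * factor, arr[:, 1],
                       label=label if label is not None else path.stem, kind=kind)


def write_profile(profile: SAXSProfile, path: str | Path) -> None:
    """Write a profile in the same two-column dialect read_profile accepts."""
    with open(path, "w") as fh:
        fh.write(f"# {profile.kind} profile: {profile.label}\n")
        fh.write("# q[nm^-1]  intensity\n")
        for q, i in zip(profile.q, profile.intensity):
            fh.write(f"{q:.8g} {i:.8g}\n")


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> float:
    """Vertex abscissa of the parabola through three points."""
    denom = (y[0] - 2 * y[1] + y[2])
    if denom == 0:
        return float(x[1])
    h = x[1] - x[0]
    return float(x[1] + 0.5 * h * (y[0] - y[2]) / denom)


def _integrate_peak(q: np.ndarray, i: np.ndarray, lo: float, hi: float,
                    flank: float) -> tuple[float, float] | None:
    """Integrate one peak over [lo, hi] after subtracting a local
    ``a/q^2 + c`` background estimated from flanking windows of width
    ``flank``.

    Returns (net_area, refined_center) or None if the window has no interior
    maximum.
    """
    sel = (q >= lo) & (q <= hi)
    if sel.sum() < 5:
        return None
    qs, isig = q[sel], i[sel]

    left = (q >= lo - flank) & (q < lo)
    right = (q > hi) & (q <= hi + flank)
    bg_q = np.concatenate([q[left], q[right]])
    bg_i = np.concatenate([i[left], i[right]])
    if bg_q.size >= 2:
        # local background a/q^2 + c: linear in 1/q^2, matching the diffuse
        # SAXS background shape (a straight line in q overshoots under the
        # convex 1/q^2 curve at low q and can swallow the first orders)
        design = np.column_stack([1.0 / bg_q**2, np.ones_like(bg_q)])
        coef, *_ = np.linalg.lstsq(design, bg_i, rcond=None)
        background = coef[0] / qs**2 + coef[1]
    else:
        background = np.full_like(qs, float(isig.min()))

    net_sig = isig - background  # center found net of background
    k = int(np.argmax(net_sig))
    if k == 0 or k == net_sig.size - 1:
        return None  # maximum at window edge: not a local peak
    center = _parabolic_vertex(qs[k - 1:k + 2], net_sig[k - 1:k + 2])
    net = np.trapezoid(net_sig, qs)
    return float(net), float(center)


def index_meridional_peaks(profile: SAXSProfile, d_M_guess: float,
                           n_max: int = 15, label: str | None = None) -> PeakSet:
    """Locate and integrate meridional Bragg orders 1..n_max.

    For each order the local maximum is searched within ±30% of the peak
    spacing around ``2*pi*n/d_M_guess``, refined by a 3-point parabolic fit;
    an ``a/q^2 + c`` background fit over the flanking windows is subtracted
    and the amplitude is the square root of the net integrated intensity.
    d_M is then refit by amplitude-weighted least squares of
    ``q_n = 2*pi*n/d_M`` through the origin.
    """
    if n_max < 3:
        raise ValueError("n_max must be >= 3")
    spacing = 2 * np.pi / d_M_guess
    half_window = 0.3 * spacing
    flank = 0.5 * spacing - half_window  # flanks stay clear of neighbours

    # pass 1: orders with a clear interior maximum anchor the period refit
    located: dict[int, tuple[float, float]] = {}
    in_range: list[int] = []
    for n in range(1, n_max + 1):
        q_pred = n * spacing
        if q_pred - half_window < profile.q[0] or q_pred + half_window > profile.q[-1]:
            continue
        in_range.append(n)
        res = _integrate_peak(profile.q, profile.intensity,
                              q_pred - half_window, q_pred + half_window, flank)
        if res is not None:
            net, center = res
            located[n] = (np.sqrt(max(0.0, net)), center)
    if len(located) < 3:
        raise IndexingError(
            f"only {len(located)} of {n_max} Bragg orders locatable "
            f"(d_M guess {d_M_guess} nm)")

    n_arr = np.array(sorted(located), dtype=float)
    q_arr = np.array([located[int(n)][1] for n in n_arr])
    w = np.array([located[int(n)][0] for n in n_arr])
    if not np.any(w > 0):
        w = np.ones_like(w)
    slope = np.sum(w * n_arr * q_arr) / np.sum(w * n_arr**2)  # q_n = slope * n
    d_M = 2 * np.pi / slope

    # pass 2: integrate weak orders (no interior maximum under noise) at the
    # positions predicted by the refined period — a small or zero net area is
    # still a valid amplitude measurement
    orders, centers, amps = [], [], []
    for n in in_range:
        if n in located:
            amp, center = located[n]
        else:
            q_pred = 2 * np.pi * n / d_M
            sel = (profile.q >= q_pred - half_window) & (profile.q <= q_pred + half_window)
            if sel.sum() < 5:
                continue
            left = (profile.q >= q_pred - half_window - flank) & (profile.q < q_pred - half_window)
            right = (profile.q > q_pred + half_window) & (profile.q <= q_pred + half_window + flank)
            bg_q = np.concatenate([profile.q[left], profile.q[right]])
            bg_i = np.concatenate([profile.intensity[left], profile.intensity[right]])
            qs, isig = profile.q[sel], profile.intensity[sel]
            if bg_q.size >= 2:
                design = np.column_stack([1.0 / bg_q**2, np.ones_like(bg_q)])
                coef, *_ = np.linalg.lstsq(design, bg_i, rcond=None)
                background = coef[0] / qs**2 + coef[1]
            else:
                background = np.full_like(qs, float(isig.min()))
            amp = np.sqrt(max(0.0, float(np.trapezoid(isig - background, qs))))
            center = q_pred
        orders.append(n)
        centers.append(center)
        amps.append(amp)
    return PeakSet(np.array(orders), np.array(centers), np.array(amps),
                   float(d_M), n_max,
                   label=label if label is not None else profile.label)


def fit_d_E(waxs_profile: SAXSProfile, q_window: tuple[float, float]) -> float:
    """Equatorial spacing d_E (nm) from the dominant WAXS peak in q_window.

    The peak center is refined by a 3-point parabolic fit; d_E = 2*pi/q_peak.
    """
    lo, hi = q_window
    sel = (waxs_profile.q >= lo) & (waxs_profile.q <= hi)
    if sel.sum() < 3:
        raise ValueError("q_window contains fewer than 3 points")
    qs, isig = waxs_profile.q[sel], waxs_profile.intensity[sel]
    k = int(np.argmax(isig))
    if k == 0 or k == isig.size - 1 or np.allclose(isig, isig[0]):
        raise ValueError("no interior maximum in q_window")
    center = _parabolic_vertex(qs[k - 1:k + 2], isig[k - 1:k + 2])
    return 2 * np.pi / center


def two_level_moduli(orders: np.ndarray, sigma: float, scale: float = 1.0) -> np.ndarray:
    """Fourier moduli of a two-level gap/overlap density: scale*|sin(pi n sigma)|/(pi n)."""
    n = np.asarray(orders, dtype=float)
    return scale * np.abs(np.sin(np.pi * n * sigma)) / (np.pi * n)


def fit_two_level_model(peaks: PeakSet) -> tuple[float, float]:
    """Fit (sigma, scale) of the two-level contrast model to peak amplitudes.

    Least squares of ``amplitude_n ~ scale * |sin(pi n sigma)|/(pi n)``; the
    sigma <-> 1-sigma modulus degeneracy is resolved to sigma <= 0.5.  The
    scale is solved analytically for each sigma; sigma by a grid search
    followed by a bounded polish.
    """
    mask = peaks.amplitudes > 0
    if mask.sum() < 4:
        raise ValueError("need >= 4 orders with positive amplitude")
    n = peaks.orders[mask].astype(float)
    a = peaks.amplitudes[mask]

    def sse(sigma: float) -> float:
        basis = np.abs(np.sin(np.pi * n * sigma)) / (np.pi * n)
        denom = np.dot(basis, basis)
        if denom == 0:
            return float(np.dot(a, a))
        scale = np.dot(a, basis) / denom
        resid = a - scale * basis
        return float(np.dot(resid, resid))

    grid = np.linspace(0.01, 0.5, 491)
    losses = [sse(s) for s in grid]
    s0 = grid[int(np.argmin(losses))]
    res = minimize_scalar(sse, bounds=(max(0.005, s0 - 0.01), min(0.5, s0 + 0.01)),
                          method="bounded", options={"xatol": 1e-7})
    sigma = float(res.x) if res.success else float(s0)
    if not np.isfinite(sigma):
        raise RuntimeError("two-level fit did not converge")
    sigma = min(sigma, 1.0 - sigma)
    basis = np.abs(np.sin(np.pi * n * sigma)) / (np.pi * n)
    scale = float(np.dot(a, basis) / np.dot(basis, basis))
    return sigma, scale


def paired_moduli(native: PeakSet, glycated: PeakSet,
                  require_orders: tuple[int, ...] | None = None
                  ) -> tuple[dict[int, float], dict[int, float]]:
    """Moduli of a native/glycated pair on their common orders, co-rescaled.

    The two measurements share one arbitrary intensity scale convention:
    both sets are divided by the native order-1 amplitude (the partner gets
    the *same* factor, so their difference stays meaningful).  Orders located
    in only one set are dropped; if ``require_orders`` is given, any of those
    orders missing from either set raises.
    """
    mn, mg = native.moduli(), glycated.moduli()
    common = sorted(set(mn) & set(mg))
    if require_orders is not None:
        missing = sorted(set(require_orders) - set(common))
        if missing:
            raise IndexingError(f"orders {missing} missing from one of the pair")
    if 1 not in mn or mn[1] <= 0:
        raise IndexingError("native order-1 amplitude unavailable for rescaling")
    f = 1.0 / mn[1]
    return ({n: mn[n] * f for n in common}, {n: mg[n] * f for n in common})


def write_peakset(peaks: PeakSet, path: str | Path) -> None:
    """Export as CSV with columns order,q_center,amplitude."""
    pd.DataFrame({"order": peaks.orders, "q_center": peaks.q_centers,
                  "amplitude": peaks.amplitudes}).to_csv(path, index=False)


def read_peakset(path: str | Path, d_M: float | None = None) -> PeakSet:
    """Read a PeakSet CSV (order,q_center,amplitude).

    If d_M is not given it is refit through the origin from the centers.
    """
    df = pd.read_csv(path)
    orders = df["order"].to_numpy(dtype=int)
    q = df["q_center"].to_numpy(dtype=float)
    a = df["amplitude"].to_numpy(dtype=float)
    if d_M is None:
        n = orders.astype(float)
        d_M = float(2 * np.pi * np.sum(n * n) / np.sum(n * q))
    return PeakSet(orders, q, a, float(d_M), int(orders.max()), label=Path(path).stem)
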