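"""Frequency-shift conversion and constant-height image stacks.

In frequency-modulation AFM the observable is the shift Δf of the
cantilever resonance. For a tip oscillating with amplitude A about a
closest-approach height z, the shift is the weighted average of the
vertical force over the oscillation cycle

    Δf(z) = -(f0 / (pi k A)) * ∫_{-1}^{1} F_z(z + A(1+u)) u / sqrt(1-u^2) du,

which reduces to the force-gradient formula Δf = -(f0/2k) dF_z/dz as
A -> 0. The integral is evaluated by Chebyshev-Gauss quadrature on a cubic
interpolation of the sampled force curve. A purely attractive force gives
Δf < 0 on approach.

Tip-sample distances ("heights") are measured between the probe's closest
oscillation turning point and the arithmetic mean of the atomic
z-coordinates of the molecule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy.interpolate import CubicSpline

from .forcefield import ForceFieldGrids
from .geometry import Molecule
from .relaxation import NM_PER_EV_A2, ForceCurve, ScanConfig, TipModel, relaxed_scan

__all__ = [
    "CantileverConfig",
    "ImageStack",
    "frequency_shift_curve",
    "frequency_shift_at",
    "tip_placement",
    "render_grayscale",
    "save_grayscale_png",
    "generate_stack",
]


@dataclass(frozen=True)
class CantileverConfig:
    """qPlus-style sensor parameters.

    Defaults f0 = 30300 Hz and k = 1800 N/m are typical qPlus values chosen
    by this package (configurable), not literature-fitted constants.
    """

    f0: float = 30300.0  # Hz
    k: float = 1800.0  # N/m
    A: float = 1.0  # A, oscillation amplitude

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.k <= 0 or self.A <= 0:
            raise ValueError("f0, k and A must all be > 0")

    @property
    def k_ev(self) -> float:
        """Cantilever stiffness in eV/A^2."""
        return self.k / NM_PER_EV_A2


_CHEB_NODES = 64


def _cheb_nodes(n: int = _CHEB_NODES) -> Tuple[np.ndarray, float]:
    """Chebyshev-Gauss nodes u_j and common weight pi/n for
    ∫ f(u)/sqrt(1-u^2) du."""
    j = np.arange(1, n + 1)
    u = np.cos((2 * j - 1) * np.pi / (2 * n))
    return u, np.pi / n


def frequency_shift_at(
    z_samples: np.ndarray,
    fz_samples: np.ndarray,
    z_eval: np.ndarray,
    cant: CantileverConfig,
) -> np.ndarray:
    """Δf (Hz) at closest-approach positions ``z_eval``.

    ``fz_samples`` may be 1D (one curve) or (nz, npoints); the quadrature
    then vectorizes over the trailing axis. Requires the oscillation span
    [z, z + 2A] to lie inside the sampled range.
    """
    z_samples = np.asarray(z_samples, dtype=float)
    z_eval = np.atleast_1d(np.asarray(z_eval, dtype=float))
    if np.any(z_eval < z_samples[0] - 1e-9) or np.any(
        z_eval + 2.0 * cant.A > z_samples[-1] + 1e-9
    ):
        raise ValueError(
            "oscillation span extends beyond the sampled force curve "
            f"([{z_samples[0]:.2f}, {z_samples[-1]:.2f}] A)"
        )
    spline = CubicSpline(z_samples, fz_samples, axis=0)
    u, w = _cheb_nodes()
    pref = -cant.f0 / (np.pi * cant.k_ev * cant.A)
    out_shape = (len(z_eval),) + np.shape(fz_samples)[1:]
    out = np.empty(out_shape)
    for i, z0 in enumerate(z_eval):
        znodes = z0 + cant.A * (1.0 + u)
        fvals = spline(znodes)  # (n_nodes, ...)
        out[i] = pref * w * np.tensordot(u, fvals, axes=(0, 0))
    return out


def frequency_shift_curve(curve: ForceCurve, cant: CantileverConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Convert a relaxed force curve to Δf(z).

    Returns (z, Δf) for every sampled z whose oscillation span fits inside
    the curve support.
    """
    z = curve.z
    ok = z + 2.0 * cant.A <= z[-1] + 1e-9
    z_eval = z[ok]
    df = frequency_shift_at(z, curve.fz, z_eval, cant)
    return z_eval, df


def tip_placement(height: float, A: float, molecule: Molecule) -> Tuple[float, float]:
    """Oscillation span for a tip-sample distance ``height``.

    The probe's closest approach sits at mean(atomic z) + height; the
    returned span (z_low, z_high) = (that z, that z + 2A) is the range of
    force-curve data the Δf quadrature consumes.
    """
    mean_z = float(molecule.coordinates[:, 2].mean())
    z0 = mean_z + height
    return z0, z0 + 2.0 * A


def render_grayscale(df_map: np.ndarray) -> np.ndarray:
    """Per-image linear min-max rendering to 8-bit grayscale.

    The most negative Δf maps to 0 (darkest), the maximum to 255; a
    constant map renders mid-gray (128).
    """
    m = np.asarray(df_map, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("Δf map contains non-finite values")
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.full(m.shape, 128, dtype=np.uint8)
    return np.round(255.0 * (m - lo) / (hi - lo)).astype(np.uint8)


def save_grayscale_png(img: np.ndarray, path) -> None:
    """Write an 8-bit grayscale array as PNG (row 0 at the top = max y)."""
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = np.round(np.clip(arr, 0, 255)).astype(np.uint8)
    Image.fromarray(np.flipud(arr.T), mode="L").save(Path(path))


@dataclass
class ImageStack:
    """Constant-height Δf maps of one molecule at one (A, kappa) setting."""

    molecule_id: int
    amplitude: float  # A
    kappa: float  # N/m
    heights: Tuple[float, ...]
    maps: List[np.ndarray]  # Δf in Hz, one per height
    rendered: List[np.ndarray]  # uint8, one per height
    f0: float
    k: float

    def __post_init__(self) -> None:
        if len(self.maps) != len(self.heights) or len(self.rendered) != len(self.heights):
            raise ValueError("one map and one rendered image required per height")
        shapes = {m.shape for m in self.maps} | {r.shape for r in self.rendered}
        if len(shapes) != 1:
            raise ValueError("all maps in a stack must share one pixel shape")

    @property
    def pixels(self) -> int:
        return self.maps[0].shape[0]

    def save(self, directory) -> List[Path]:
        """Write df_<i>.png (index 0 = farthest height) plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        order = np.argsort(self.heights)[::-1]  # index 0 = farthest
        for i, hidx in enumerate(order):
            p = directory / f"df_{i}.png"
            save_grayscale_png(self.rendered[hidx], p)
            paths.append(p)
        sidecar = {
            "cid": self.molecule_id,
            "amplitude_A": self.amplitude,
            "kappa_N_per_m": self.kappa,
            "heights_A": list(self.heights),
            "height_order": "df_0.png is the farthest height",
            "f0_Hz": self.f0,
            "k_N_per_m": self.k,
            "pixels": self.pixels,
        }
        (directory / "stack.json").write_text(json.dumps(sidecar, indent=2) + "\n")
        return paths

    def save_maps_hdf5(self, path) -> None:
        """Store the raw Δf maps (Hz, float) with their heights."""
        import h5py

        with h5py.File(Path(path), "w") as f:
            f.create_dataset("heights_A", data=np.asarray(self.heights))
            f.create_dataset("df_maps_Hz", data=np.stack(self.maps),
                             compression="gzip")
            f.attrs.update({
                "cid": self.molecule_id, "amplitude_A": self.amplitude,
                "kappa_N_per_m": self.kappa, "f0_Hz": self.f0, "k_N_per_m": self.k,
            })


def _pixel_force_curves(
    ff: ForceFieldGrids,
    tip: TipModel,
    cfg: ScanConfig,
    z_lo: float,
    z_hi: float,
):
    """Relaxed per-pixel force curves over the full cell raster.

    Returns (z (nz,), fz (nz, px*px)); the tip approaches far-to-near once
    and the curves are differentiated from the relaxed energies.
    """
    dz = cfg.dz
    nz = int(np.ceil((z_hi - z_lo) / dz - 1e-9)) + 1
    z = z_lo + dz * np.arange(nz)
    L = ff.E_total.lengths
    px = cfg.pixels
    xs = np.arange(px) * (L[0] / px)
    ys = np.arange(px) * (L[1] / px)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    xy = np.column_stack([X.ravel(), Y.ravel()])
    energies, _, _ = relaxed_scan(ff, tip, cfg, xy, z)
    fz = np.empty_like(energies)
    fz[1:-1] = -(energies[2:] - energies[:-2]) / (2.0 * dz)
    fz[0] = -(energies[1] - energies[0]) / dz
    fz[-1] = -(energies[-1] - energies[-2]) / dz
    return z, fz


def _render_maps(maps: List[np.ndarray], normalize: str, px: int) -> List[np.ndarray]:
    if normalize == "stack":
        lo = min(m.min() for m in maps)
        hi = max(m.max() for m in maps)
        if hi == lo:
            return [np.full((px, px), 128, dtype=np.uint8) for _ in maps]
        return [np.round(255.0 * (m - lo) / (hi - lo)).astype(np.uint8) for m in maps]
    if normalize == "image":
        return [render_grayscale(m) for m in maps]
    raise ValueError("normalize must be 'image' or 'stack'")


def generate_stacks(
    molecule: Molecule,
    ff: ForceFieldGrids,
    kappa: float,
    amplitudes: Sequence[float],
    cfg: Optional[ScanConfig] = None,
    cant: Optional[CantileverConfig] = None,
    normalize: str = "image",
) -> List[ImageStack]:
    """Image stacks of one molecule at one stiffness for several amplitudes.

    The expensive relaxed scan depends only on kappa, so a single per-pixel
    force-curve set covering the largest oscillation span is computed and
    reused for every amplitude and height. Returns one stack per amplitude,
    in input order. Fully deterministic.
    """
    if cfg is None:
        cfg = ScanConfig()
    base = cant or CantileverConfig()
    tip = TipModel(kappa=kappa)
    mean_z = float(molecule.coordinates[:, 2].mean())
    heights = cfg.heights
    z_lo = mean_z + min(heights) - cfg.dz
    z_hi = mean_z + max(heights) + 2.0 * max(amplitudes) + cfg.dz
    z, fz = _pixel_force_curves(ff, tip, cfg, z_lo, z_hi)
    px = cfg.pixels
    z_eval = np.array([mean_z + h for h in heights])
    stacks = []
    for A in amplitudes:
        this_cant = CantileverConfig(f0=base.f0, k=base.k, A=A)
        dfs = frequency_shift_at(z, fz, z_eval, this_cant)  # (n_heights, npix)
        maps = [dfs[i].reshape(px, px) for i in range(len(heights))]
        rendered = _render_maps(maps, normalize, px)
        stacks.append(
            ImageStack(
                molecule_id=molecule.id,
                amplitude=A,
                kappa=kappa,
                heights=tuple(heights),
                maps=maps,
                rendered=rendered,
                f0=base.f0,
                k=base.k,
            )
        )
    return stacks


def generate_stack(
    molecule: Molecule,
    ff: ForceFieldGrids,
    amplitude: float,
    kappa: float,
    cfg: Optional[ScanConfig] = None,
    cant: Optional[CantileverConfig] = None,
    normalize: str = "image",
) -> ImageStack:
    """Simulate the constant-height Δf image stack of one molecule.

    One relaxed approach curve is computed per pixel over the union of all
    oscillation spans and reused across heights; each height's Δf map comes
    from the large-amplitude quadrature at its closest-approach position.
    ``normalize`` is "image" (per-image min-max) or "stack" (shared range).
    Fully deterministic: identical inputs give bit-identical images.
    """
    return generate_stacks(
        molecule, ff, kappa, [amplitude], cfg=cfg, cant=cant, normalize=normalize
    )[0]
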