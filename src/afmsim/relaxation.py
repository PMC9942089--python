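"""CO-probe tilt relaxation and relaxed z-scans.

The probe particle (the O apex of the CO molecule) is attached to the tip
pivot by a rigid lever of length delta = 3.02 A and tilts on the sphere of
that radius against a harmonic torsional spring,

    E_tilt(theta) = 1/2 * kappa * (delta * theta)^2,

with kappa the lateral stiffness quoted in N/m (converted internally to
eV/A^2). For each tip position the total energy — the rigid-case
potential-energy surface evaluated at the tilted probe position plus the
spring term — is minimized over the tilt; the tip then steps toward the
sample in dz = 0.1 A increments, warm-starting each relaxation from the
previous step. Vertical forces follow by numerical differentiation of the
relaxed energy with respect to the tip z position.

The scan coordinate ``z`` throughout is the *nominal* (untilted) probe
height: the pivot sits at z + delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .forcefield import ForceFieldGrids, interpolate

__all__ = [
    "NM_PER_EV_A2",
    "TipModel",
    "ProbeState",
    "ScanConfig",
    "ForceCurve",
    "tilt_energy",
    "relax_probe",
    "z_scan",
    "scan_image",
    "relaxed_scan",
]

#: 1 eV/A^2 expressed in N/m.
NM_PER_EV_A2 = 16.02177


@dataclass(frozen=True)
class TipModel:
    """CO probe description: torsional stiffness and lever geometry."""

    kappa: float = 0.4  # N/m, lateral/torsional stiffness
    delta: float = 3.02  # A, lever arm (pivot atom to O probe)

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")

    @property
    def kappa_ev(self) -> float:
        """Stiffness in eV/A^2."""
        return self.kappa / NM_PER_EV_A2


@dataclass(frozen=True)
class ProbeState:
    """Relaxed probe configuration at one tip position."""

    pivot: np.ndarray  # A, tip anchor position
    theta: float  # rad, polar tilt from -z
    phi: float  # rad, azimuth (0 when theta == 0)
    probe_position: np.ndarray  # A, pivot + delta * tilted axis
    converged: bool = True
    capped: bool = False  # theta hit the small-angle cap

    def __post_init__(self) -> None:
        object.__setattr__(self, "pivot", np.asarray(self.pivot, dtype=float).reshape(3))
        object.__setattr__(
            self, "probe_position", np.asarray(self.probe_position, dtype=float).reshape(3)
        )
        if not (0.0 <= self.theta < np.pi / 2):
            raise ValueError("theta must lie in [0, pi/2)")


@dataclass(frozen=True)
class ScanConfig:
    """Relaxed-scan control parameters."""

    dz: float = 0.1  # A, tip step
    force_tol: float = 1e-6  # eV/A, convergence threshold on the residual force
    max_iter: int = 400
    heights: Tuple[float, ...] = (2.8, 2.9, 3.0, 3.1, 3.2, 3.3, 3.4, 3.5, 3.6, 3.7)
    pixels: int = 256
    theta_cap: float = 0.5  # rad, small-angle validity cap

    def __post_init__(self) -> None:
        if self.dz <= 0 or self.force_tol <= 0:
            raise ValueError("dz and force_tol must be > 0")
        hs = tuple(float(h) for h in self.heights)
        if any(b <= a for a, b in zip(hs, hs[1:])):
            raise ValueError("heights must be strictly increasing")
        object.__setattr__(self, "heights", hs)


@dataclass
class ForceCurve:
    """Relaxed force-distance data at one lateral position (or curve set).

    ``z`` ascends; ``energy`` and ``fz`` may be 1D (single curve) or
    (nz, npoints) arrays for batched scans. ``converged`` flags mirror the
    energy layout.
    """

    z: np.ndarray
    energy: np.ndarray
    fz: np.ndarray
    converged: np.ndarray

    def as_table(self) -> np.ndarray:
        """(nz, 3) array of (z, E, F_z) for a single curve."""
        return np.column_stack([self.z, self.energy, self.fz])

    def save_text(self, path) -> None:
        """Write the curve as a plain-text (z, E, F_z) table."""
        np.savetxt(path, self.as_table(),
                   header="z_A energy_eV fz_eV_per_A", fmt="%.10e")


def tilt_energy(theta: float | np.ndarray, tip: TipModel) -> float | np.ndarray:
    """Harmonic tilt energy 1/2 * kappa * (delta*theta)^2 in eV."""
    return 0.5 * tip.kappa_ev * (tip.delta * np.asarray(theta, dtype=float)) ** 2


# ---------------------------------------------------------------------------
# Core batched minimizer
#
# The tilt is parameterized by the lateral displacement s = (sx, sy) of the
# probe from the untilted axis; probe = pivot + (sx, sy, -sqrt(delta^2-|s|^2)),
# theta = asin(|s|/delta), with theta capped at the small-angle validity
# limit (capped probes converge on the cap circle and carry a warning flag).
#
# The relaxation drives the generalized force — the tangential interaction
# force (trilinear interpolation of the lattice-sampled force field, which
# is continuous) plus the spring restoring force — below cfg.force_tol by
# damped preconditioned descent: steps -R/h with a per-probe stiffness h
# (spring plus lever-curvature estimate initially, Barzilai-Borwein secant
# afterwards), a trust radius, and acceptance requiring the residual norm
# to decrease.


def _total_energy_residual(ff, tip: TipModel, pivots: np.ndarray, s: np.ndarray,
                           s_cap: float):
    """Energy (N,), generalized force residual (N, 2) and stiffness hint (N,)."""
    delta = tip.delta
    s2 = np.minimum((s ** 2).sum(axis=1), s_cap ** 2)
    drop = np.sqrt(delta * delta - s2)
    probe = pivots + np.column_stack([s[:, 0], s[:, 1], -drop])
    E_pes = interpolate(ff.E_total, probe)
    gfx, gfy, gfz = ff.force_grids()
    fx = interpolate(gfx, probe)
    fy = interpolate(gfy, probe)
    fz = interpolate(gfz, probe)
    # generalized PES gradient wrt s, chain rule d(probe_z)/ds = s/drop
    gs = np.column_stack([-fx, -fy]) + (-fz)[:, None] * (s / drop[:, None])
    snorm = np.sqrt(s2)
    theta = np.arcsin(snorm / delta)
    E_spring = tilt_energy(theta, tip)
    factor = np.where(
        snorm > 1e-12,
        tip.kappa_ev * tip.delta ** 2 * theta / (drop * np.maximum(snorm, 1e-12)),
        tip.kappa_ev * tip.delta / drop,  # small-s limit of delta*theta/|s| -> 1
    )
    gs += factor[:, None] * s
    # lever curvature -fz/drop stiffens or softens the tilt mode
    h_hint = np.maximum(tip.kappa_ev - fz / drop, 0.25 * tip.kappa_ev)
    return E_pes + E_spring, gs, h_hint


def _residual_norm(g: np.ndarray, s: np.ndarray, s_cap: float) -> np.ndarray:
    """Residual norm; on the cap circle with the force pulling outward only
    the tangential component counts (the cap is a binding constraint)."""
    res = np.linalg.norm(g, axis=1)
    snorm = np.linalg.norm(s, axis=1)
    on_cap = snorm >= s_cap - 1e-9
    if on_cap.any():
        shat = s[on_cap] / snorm[on_cap, None]
        radial = (g[on_cap] * shat).sum(axis=1)
        outward = radial < 0.0
        tang = g[on_cap] - radial[:, None] * shat
        res[on_cap] = np.where(outward, np.linalg.norm(tang, axis=1), res[on_cap])
    return res


def _project_capped(g: np.ndarray, s: np.ndarray, s_cap: float) -> np.ndarray:
    """Remove outward radial components of the step direction on the cap."""
    out = g.copy()
    snorm = np.linalg.norm(s, axis=1)
    on_cap = snorm >= s_cap - 1e-9
    if on_cap.any():
        rows = np.nonzero(on_cap)[0]
        shat = s[rows] / snorm[rows, None]
        radial = (out[rows] * shat).sum(axis=1)
        block = radial < 0.0
        out[rows[block]] -= radial[block, None] * shat[block]
    return out


def _relax_batch(
    ff: ForceFieldGrids,
    tip: TipModel,
    pivots: np.ndarray,
    s0: np.ndarray,
    cfg: ScanConfig,
):
    """Relax many probes at fixed pivots.

    Returns (s, energy, converged, capped). Deterministic; non-convergence
    within ``cfg.max_iter`` is reported in the flags, never silent.
    """
    s = s0.copy()
    n = len(s)
    s_cap = tip.delta * np.sin(cfg.theta_cap)
    E, g, h_hint = _total_energy_residual(ff, tip, pivots, s, s_cap)
    h = h_hint.copy()
    trust = np.full(n, 0.15)  # A
    res = _residual_norm(g, s, s_cap)
    converged = res < cfg.force_tol
    for _ in range(cfg.max_iter):
        active = ~converged
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        g_a = _project_capped(g[idx], s[idx], s_cap)
        step = g_a / h[idx, None]
        stepnorm = np.linalg.norm(step, axis=1)
        scale = np.minimum(1.0, trust[idx] / np.maximum(stepnorm, 1e-300))
        cand = s[idx] - scale[:, None] * step
        cn = np.linalg.norm(cand, axis=1)
        over = cn > s_cap
        if over.any():
            cand[over] *= (s_cap / cn[over])[:, None]
        E_c, g_c, hh_c = _total_energy_residual(ff, tip, pivots[idx], cand, s_cap)
        res_c = _residual_norm(g_c, cand, s_cap)
        improved = (res_c <= res[idx] * (1.0 - 1e-6)) | (E_c < E[idx] - 1e-14)
        ok = idx[improved]
        if ok.size:
            ds = cand[improved] - s[ok]
            dg = g_c[improved] - g[ok]
            num = (dg * ds).sum(axis=1)
            den = (ds * ds).sum(axis=1)
            bb = np.where(den > 0, num / np.maximum(den, 1e-300), h[ok])
            floor = 0.25 * tip.kappa_ev
            h[ok] = np.where(np.isfinite(bb) & (bb > floor), bb, hh_c[improved])
            s[ok] = cand[improved]
            E[ok] = E_c[improved]
            g[ok] = g_c[improved]
            res[ok] = res_c[improved]
            trust[ok] = np.minimum(trust[ok] * 1.4, 0.6)
        trust[idx[~improved]] *= 0.3
        converged[idx] = res[idx] < cfg.force_tol
    capped = np.linalg.norm(s, axis=1) >= s_cap - 1e-9
    return s, E, converged, capped


def _state_from_s(pivot: np.ndarray, s: np.ndarray, tip: TipModel,
                  converged: bool, capped: bool) -> ProbeState:
    snorm = float(np.linalg.norm(s))
    theta = float(np.arcsin(min(snorm / tip.delta, 1.0 - 1e-12)))
    phi = float(np.arctan2(s[1], s[0])) if snorm > 1e-12 else 0.0
    if phi < 0:
        phi += 2.0 * np.pi
    if theta < 1e-12:
        theta, phi = 0.0, 0.0
    probe = pivot + np.array([s[0], s[1], -np.sqrt(tip.delta ** 2 - snorm ** 2)])
    return ProbeState(
        pivot=pivot, theta=theta, phi=phi, probe_position=probe,
        converged=converged, capped=capped,
    )


def relax_probe(
    pivot,
    ff: ForceFieldGrids,
    tip: TipModel,
    cfg: Optional[ScanConfig] = None,
    s0: Optional[np.ndarray] = None,
) -> ProbeState:
    """Relax the probe tilt at a single tip pivot position.

    Deterministic: starts untilted (or from ``s0`` when warm-starting) and
    descends the total energy until the generalized force drops below
    ``cfg.force_tol``. Non-convergence is flagged on the returned state,
    never silent.
    """
    if cfg is None:
        cfg = ScanConfig()
    pivot = np.asarray(pivot, dtype=float).reshape(1, 3)
    s_init = np.zeros((1, 2)) if s0 is None else np.asarray(s0, dtype=float).reshape(1, 2)
    s, E, conv, capped = _relax_batch(ff, tip, pivot, s_init, cfg)
    return _state_from_s(pivot[0], s[0], tip, bool(conv[0]), bool(capped[0]))


def relaxed_scan(
    ff: ForceFieldGrids,
    tip: TipModel,
    cfg: ScanConfig,
    xy: np.ndarray,
    z_values: np.ndarray,
):
    """Relaxed energies over a descending approach for many lateral points.

    ``xy`` is (N, 2); ``z_values`` must be equally spaced ascending nominal
    probe heights. The tip approaches from the farthest z, warm-starting
    each relaxation from the previous step's tilt. Returns
    (energies (nz, N), converged (nz, N), capped (nz, N)) with rows ordered
    like ``z_values``.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    z_values = np.asarray(z_values, dtype=float)
    n = len(xy)
    nz = len(z_values)
    energies = np.empty((nz, n))
    conv = np.empty((nz, n), dtype=bool)
    capped = np.empty((nz, n), dtype=bool)
    s = np.zeros((n, 2))
    for i in range(nz - 1, -1, -1):  # far to near
        pivots = np.column_stack([xy, np.full(n, z_values[i] + tip.delta)])
        s, E, cv, cp = _relax_batch(ff, tip, pivots, s, cfg)
        energies[i] = E
        conv[i] = cv
        capped[i] = cp
    return energies, conv, capped


def _differentiate(z: np.ndarray, E: np.ndarray) -> np.ndarray:
    """F_z = -dE/dz, central differences inside, one-sided at the ends."""
    fz = np.empty_like(E)
    dz = z[1] - z[0]
    fz[1:-1] = -(E[2:] - E[:-2]) / (2.0 * dz)
    fz[0] = -(E[1] - E[0]) / dz
    fz[-1] = -(E[-1] - E[-2]) / dz
    return fz


def z_scan(
    xy,
    ff: ForceFieldGrids,
    tip: TipModel,
    cfg: Optional[ScanConfig] = None,
    z_min: Optional[float] = None,
    z_max: Optional[float] = None,
) -> ForceCurve:
    """Relaxed approach curve at one lateral position.

    Scans nominal probe heights from ``z_max`` down to ``z_min`` in steps of
    ``cfg.dz`` (defaults: the span of ``cfg.heights`` padded by one step on
    each side), relaxing at every step, and differentiates the relaxed
    energy to obtain F_z(z). Deterministic; rerunning reproduces the curve
    bit-exactly.
    """
    if cfg is None:
        cfg = ScanConfig()
    if z_min is None:
        z_min = min(cfg.heights) - cfg.dz
    if z_max is None:
        z_max = max(cfg.heights) + cfg.dz
    nz = int(round((z_max - z_min) / cfg.dz)) + 1
    z = z_min + cfg.dz * np.arange(nz)
    E, conv, _ = relaxed_scan(ff, tip, cfg, np.asarray(xy, dtype=float).reshape(1, 2), z)
    fz = _differentiate(z, E[:, 0])
    return ForceCurve(z=z, energy=E[:, 0], fz=fz, converged=conv[:, 0])


def scan_image(
    ff: ForceFieldGrids,
    tip: TipModel,
    cfg: ScanConfig,
    height: float,
) -> np.ndarray:
    """Constant-height F_z map over the cell (pixels x pixels raster).

    Pixel (i, j) sits at x = i*cell/px, y = j*cell/px (periodic in xy); the
    value is the relaxed F_z of the approach curve at that pixel, evaluated
    at the nominal probe height ``height``.
    """
    L = ff.E_total.lengths
    px = cfg.pixels
    xs = np.arange(px) * (L[0] / px)
    ys = np.arange(px) * (L[1] / px)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    xy = np.column_stack([X.ravel(), Y.ravel()])
    z = np.array([height - cfg.dz, height, height + cfg.dz])
    E, conv, _ = relaxed_scan(ff, tip, cfg, xy, z)
    fz = -(E[2] - E[0]) / (2.0 * cfg.dz)
    return fz.reshape(px, px)
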