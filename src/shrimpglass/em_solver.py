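"""Finite-difference time-domain solver for antenna cross-section scenes.

A from-scratch 2-D FDTD solver on a Yee grid computes broadband
reflectance and transmittance of scenes built from planar layers (the
chitin cuticle, lamellae stacks) and packed-sphere layers.  The plane of
simulation is x-z: x is lateral and periodic (mirroring the lateral
periodic boundaries of a plane-wave cell), z is axial and terminated by
convolutional perfectly-matched layers (CPML).  Spheres become disc
cross-sections of cylinders running along the out-of-plane axis; the two
scalar polarizations (E out of plane and H out of plane) are solved
separately and averaged for unpolarized illumination.

A single Gaussian-pulse plane-wave run yields the full 400-700 nm
spectrum through on-the-fly discrete Fourier transforms of the fields at
two flux monitors, one between source and structure (reflection, with
incident-field subtraction against an empty-scene reference run) and one
behind the structure (transmission).  Units: lengths in µm, c = 1, so
time is in µm and frequency in 1/µm.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numba import njit

from .geometry import LayerStack, SpherePacking
from .thin_films import Spectrum

__all__ = [
    "Scene",
    "SolverConfig",
    "run_fdtd",
    "energy_balance",
    "convergence_study",
    "load_scene_config",
    "clear_reference_cache",
]


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the time-domain solver.

    ``resolution_nm`` is the Yee cell size (default 10 nm in 2-D);
    stability requires a Courant factor below 1/sqrt(2) and a grid finer
    than λ_min / (10 n_max).  The run stops once residual field energy
    falls below ``decay_threshold`` of its peak, or at ``max_steps``
    (flagged in the output metadata).
    """

    resolution_nm: float = 10.0
    courant: float = 0.5
    pml_cells: int = 10
    decay_threshold: float = 1e-6
    max_steps: int = 60_000
    n_freqs: int = 31
    band_nm: tuple[float, float] = (400.0, 700.0)
    check_interval: int = 200
    subpixel: int = 4
    polarization: str = "avg"  # "s", "p" or "avg"

    def validate(self, n_max: float, dim: int = 2) -> None:
        if self.courant >= 1.0 / math.sqrt(dim):
            raise ValueError(
                f"Courant factor {self.courant} violates stability bound 1/sqrt({dim})"
            )
        limit = self.band_nm[0] / (10.0 * n_max)
        if self.resolution_nm > limit + 1e-9:
            raise ValueError(
                f"grid spacing {self.resolution_nm} nm exceeds λ_min/(10 n_max) = {limit:.2f} nm"
            )
        if self.pml_cells < 4:
            raise ValueError("need at least 4 PML cells")
        if self.polarization not in ("s", "p", "avg"):
            raise ValueError("polarization must be 's', 'p' or 'avg'")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.linspace(self.band_nm[0], self.band_nm[1], self.n_freqs)


@dataclass(frozen=True)
class Scene:
    """Geometry of one simulation cell.

    From the illuminated side downward: ambient matrix, then the planar
    ``layers`` (e.g. the 5 µm chitin cuticle), then the optional sphere
    ``packing`` (its box_z sets the layer thickness), then a semi-infinite
    substrate (defaults to the matrix).  The packing box must match the
    lateral extent so the periodic images tile correctly.
    """

    lateral_um: float
    matrix_n: float = 1.34
    layers: tuple[tuple[float, float], ...] = ()
    packing: SpherePacking | None = None
    substrate_n: float | None = None
    clearance_um: float = 0.4

    def __post_init__(self):
        if self.lateral_um <= 0:
            raise ValueError("lateral extent must be positive")
        if self.packing is not None and abs(self.packing.box[0] - self.lateral_um) > 1e-9:
            raise ValueError("packing box_x must equal the scene's lateral extent")

    @classmethod
    def from_stack(cls, stack: LayerStack, lateral_um: float = 0.5) -> "Scene":
        """Planar scene equivalent to a LayerStack (for TMM cross-checks)."""
        return cls(
            lateral_um=lateral_um,
            matrix_n=stack.ambient_n,
            layers=tuple(stack.layers),
            substrate_n=stack.substrate_n,
        )

    @property
    def structure_thickness_um(self) -> float:
        t = sum(t for t, _ in self.layers)
        if self.packing is not None:
            t += self.packing.box[2]
        return float(t)

    @property
    def n_max(self) -> float:
        candidates = [self.matrix_n, self.substrate_n or self.matrix_n]
        candidates += [n for _, n in self.layers]
        if self.packing is not None:
            candidates += [self.packing.n_sphere, self.packing.n_matrix]
        return float(max(candidates))


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------


@dataclass
class _Grid:
    Nx: int
    Nz: int
    dx: float  # µm
    k_src: int
    k_refl: int
    k_tran: int
    k_struct: int


def _build_grid(scene: Scene, config: SolverConfig) -> _Grid:
    dx = config.resolution_nm / 1000.0
    Nx = max(4, int(round(scene.lateral_um / dx)))
    npml = config.pml_cells
    gap = max(2, int(round(scene.clearance_um / dx)))
    pad = max(2, int(round(0.25 / dx)))
    n_struct = int(round(scene.structure_thickness_um / dx))
    k_src = npml + pad
    k_refl = k_src + gap
    k_struct = k_refl + gap
    k_tran = k_struct + n_struct + gap
    Nz = k_tran + pad + npml
    return _Grid(Nx, Nz, dx, k_src, k_refl, k_tran, k_struct)


def _eps_fine(scene: Scene, grid: _Grid, ss: int) -> np.ndarray:
    """Supersampled permittivity raster (subpixel smoothing source)."""
    Nxf, Nzf = grid.Nx * ss, grid.Nz * ss
    dxf = grid.dx / ss
    eps = np.full((Nxf, Nzf), scene.matrix_n**2, dtype=np.float64)
    zf = (np.arange(Nzf) + 0.5) * dxf
    z0 = grid.k_struct * grid.dx
    for t_um, n in scene.layers:
        sel = (zf >= z0) & (zf < z0 + t_um)
        eps[:, sel] = n**2
        z0 += t_um
    if scene.packing is not None:
        p = scene.packing
        xf = (np.arange(Nxf) + 0.5) * dxf
        box_x = p.box[0]
        for c, r in zip(p.centers, p.radii_um):
            if p.dim == 3:
                dy = c[1] - p.box[1] / 2.0
                r2 = r * r - dy * dy
                if r2 <= 0:
                    continue
                r_eff = math.sqrt(r2)
            else:
                r_eff = r
            cz = z0 + c[2]
            ksel = np.abs(zf - cz) <= r_eff
            if not np.any(ksel):
                continue
            for shift in (-box_x, 0.0, box_x):
                cx = c[0] + shift
                isel = np.abs(xf - cx) <= r_eff
                if not np.any(isel):
                    continue
                xs = xf[isel][:, None] - cx
                zs = zf[None, ksel] - cz
                mask = xs * xs + zs * zs <= r_eff * r_eff
                block = eps[np.ix_(isel, ksel)]
                block[mask] = p.n_sphere**2
                eps[np.ix_(isel, ksel)] = block
        z0 += p.box[2]
    sub_n = scene.substrate_n if scene.substrate_n is not None else scene.matrix_n
    eps[:, zf >= z0] = sub_n**2
    return eps


def _block_avg(eps_fine: np.ndarray, ss: int, off_x: int, off_z: int) -> np.ndarray:
    """Average ss x ss windows whose origin is shifted by (off_x, off_z)
    fine cells; periodic in x, edge-clamped in z."""
    shifted = np.roll(eps_fine, -off_x, axis=0)
    if off_z > 0:
        shifted = np.concatenate(
            [shifted[:, off_z:], np.repeat(shifted[:, -1:], off_z, axis=1)], axis=1
        )
    elif off_z < 0:
        shifted = np.concatenate(
            [np.repeat(shifted[:, :1], -off_z, axis=1), shifted[:, :off_z]], axis=1
        )
    Nx = eps_fine.shape[0] // ss
    Nz = eps_fine.shape[1] // ss
    return shifted.reshape(Nx, ss, Nz, ss).mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# CPML coefficient profiles
# ---------------------------------------------------------------------------


def _cpml_profiles(Nz: int, npml: int, dx: float, dt: float, n_top: float, n_bot: float):
    """b, a arrays for E (integer z) and H (half-integer z) positions."""
    m = 3.0
    alpha_max = 0.1

    def coeffs(depth_fraction: np.ndarray, n_medium: float):
        u = np.clip(depth_fraction, 0.0, 1.0)
        sigma_max = 0.8 * (m + 1.0) / (dx * n_medium)
        sigma = sigma_max * u**m
        alpha = alpha_max * (1.0 - u)
        b = np.exp(-(sigma + alpha) * dt)
        a = np.where(sigma + alpha > 0, sigma * (b - 1.0) / np.maximum(sigma + alpha, 1e-30), 0.0)
        a = np.where(u > 0, a, 0.0)
        return b, a

    k_idx = np.arange(Nz, dtype=float)
    be = np.ones(Nz)
    ae = np.zeros(Nz)
    bh = np.ones(Nz)
    ah = np.zeros(Nz)
    # top PML: interior interface at k = npml
    for karr, (bo, ao) in ((k_idx, (be, ae)), (k_idx + 0.5, (bh, ah))):
        u_top = (npml - karr) / npml
        b, a = coeffs(u_top, n_top)
        sel = u_top > 0
        bo[sel], ao[sel] = b[sel], a[sel]
        u_bot = (karr - (Nz - 1 - npml)) / npml
        b, a = coeffs(u_bot, n_bot)
        sel = u_bot > 0
        bo[sel], ao[sel] = b[sel], a[sel]
    return be, ae, bh, ah


# ---------------------------------------------------------------------------
# time-stepping kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _kernel_s(eps_inv, g, dt, dx, k_src, k_refl, k_tran, omegas,
              be, ae, bh, ah, check_every, decay_threshold, min_steps, max_steps):
    Nx, Nz = eps_inv.shape
    nf = omegas.shape[0]
    Ey = np.zeros((Nx, Nz))
    Hx = np.zeros((Nx, Nz))
    Hz = np.zeros((Nx, Nz))
    psi_h = np.zeros((Nx, Nz))
    psi_e = np.zeros((Nx, Nz))
    dE_r = np.zeros((nf, Nx), dtype=np.complex128)
    dH_r = np.zeros((nf, Nx), dtype=np.complex128)
    dE_t = np.zeros((nf, Nx), dtype=np.complex128)
    dH_t = np.zeros((nf, Nx), dtype=np.complex128)
    peak = 0.0
    energy = 0.0
    n_run = max_steps
    inv_dx = 1.0 / dx
    for n in range(max_steps):
        # H update at t = (n + 1/2) dt
        for i in range(Nx):
            ip = i + 1 if i < Nx - 1 else 0
            for k in range(Nz - 1):
                dEdz = (Ey[i, k + 1] - Ey[i, k]) * inv_dx
                psi_h[i, k] = bh[k] * psi_h[i, k] + ah[k] * dEdz
                Hx[i, k] += dt * (dEdz + psi_h[i, k])
            for k in range(Nz):
                Hz[i, k] -= dt * (Ey[ip, k] - Ey[i, k]) * inv_dx
        # E update at t = (n + 1) dt
        for i in range(Nx):
            im = i - 1 if i > 0 else Nx - 1
            for k in range(1, Nz - 1):
                dHdz = (Hx[i, k] - Hx[i, k - 1]) * inv_dx
                psi_e[i, k] = be[k] * psi_e[i, k] + ae[k] * dHdz
                curl = dHdz + psi_e[i, k] - (Hz[i, k] - Hz[im, k]) * inv_dx
                Ey[i, k] += dt * eps_inv[i, k] * curl
        src = g[n]
        if src != 0.0:
            for i in range(Nx):
                Ey[i, k_src] += src
        t_e = (n + 1.0) * dt
        t_h = (n + 0.5) * dt
        for f in range(nf):
            pe = np.exp(-1j * omegas[f] * t_e)
            ph = np.exp(-1j * omegas[f] * t_h)
            for i in range(Nx):
                dE_r[f, i] += Ey[i, k_refl] * pe
                dH_r[f, i] += 0.5 * (Hx[i, k_refl - 1] + Hx[i, k_refl]) * ph
                dE_t[f, i] += Ey[i, k_tran] * pe
                dH_t[f, i] += 0.5 * (Hx[i, k_tran - 1] + Hx[i, k_tran]) * ph
        if n % check_every == 0:
            energy = 0.0
            for i in range(Nx):
                for k in range(Nz):
                    energy += Ey[i, k] * Ey[i, k]
            if energy > peak:
                peak = energy
            if n > min_steps and peak > 0.0 and energy < decay_threshold * peak:
                n_run = n + 1
                break
    return dE_r, dH_r, dE_t, dH_t, n_run, peak, energy


@njit(cache=True)
def _kernel_p(eps_inv_x, eps_inv_z, g, dt, dx, k_src, k_refl, k_tran, omegas,
              be, ae, bh, ah, check_every, decay_threshold, min_steps, max_steps):
    Nx, Nz = eps_inv_x.shape
    nf = omegas.shape[0]
    Ex = np.zeros((Nx, Nz))
    Ez = np.zeros((Nx, Nz))
    Hy = np.zeros((Nx, Nz))
    psi_h = np.zeros((Nx, Nz))
    psi_e = np.zeros((Nx, Nz))
    dE_r = np.zeros((nf, Nx), dtype=np.complex128)
    dH_r = np.zeros((nf, Nx), dtype=np.complex128)
    dE_t = np.zeros((nf, Nx), dtype=np.complex128)
    dH_t = np.zeros((nf, Nx), dtype=np.complex128)
    peak = 0.0
    energy = 0.0
    n_run = max_steps
    inv_dx = 1.0 / dx
    for n in range(max_steps):
        # Hy at (i+1/2, k+1/2), t = (n + 1/2) dt
        for i in range(Nx):
            ip = i + 1 if i < Nx - 1 else 0
            for k in range(Nz - 1):
                dExdz = (Ex[i, k + 1] - Ex[i, k]) * inv_dx
                psi_h[i, k] = bh[k] * psi_h[i, k] + ah[k] * dExdz
                dEzdx = (Ez[ip, k] - Ez[i, k]) * inv_dx
                Hy[i, k] -= dt * (dExdz + psi_h[i, k] - dEzdx)
        # E update
        for i in range(Nx):
            im = i - 1 if i > 0 else Nx - 1
            for k in range(1, Nz - 1):
                dHdz = (Hy[i, k] - Hy[i, k - 1]) * inv_dx
                psi_e[i, k] = be[k] * psi_e[i, k] + ae[k] * dHdz
                Ex[i, k] -= dt * eps_inv_x[i, k] * (dHdz + psi_e[i, k])
            for k in range(Nz - 1):
                dHdx = (Hy[i, k] - Hy[im, k]) * inv_dx
                Ez[i, k] += dt * eps_inv_z[i, k] * dHdx
        src = g[n]
        if src != 0.0:
            for i in range(Nx):
                Ex[i, k_src] += src
        t_e = (n + 1.0) * dt
        t_h = (n + 0.5) * dt
        for f in range(nf):
            pe = np.exp(-1j * omegas[f] * t_e)
            ph = np.exp(-1j * omegas[f] * t_h)
            for i in range(Nx):
                dE_r[f, i] += Ex[i, k_refl] * pe
                dH_r[f, i] += 0.5 * (Hy[i, k_refl - 1] + Hy[i, k_refl]) * ph
                dE_t[f, i] += Ex[i, k_tran] * pe
                dH_t[f, i] += 0.5 * (Hy[i, k_tran - 1] + Hy[i, k_tran]) * ph
        if n % check_every == 0:
            energy = 0.0
            for i in range(Nx):
                for k in range(Nz):
                    energy += Ex[i, k] * Ex[i, k] + Ez[i, k] * Ez[i, k]
            if energy > peak:
                peak = energy
            if n > min_steps and peak > 0.0 and energy < decay_threshold * peak:
                n_run = n + 1
                break
    return dE_r, dH_r, dE_t, dH_t, n_run, peak, energy


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

_REFERENCE_CACHE: dict = {}


def clear_reference_cache() -> None:
    _REFERENCE_CACHE.clear()


def _source_waveform(config: SolverConfig, dt: float, max_steps: int):
    """Gaussian-modulated sinusoid spanning the target band."""
    f_lo = 1.0 / (config.band_nm[1] / 1000.0)
    f_hi = 1.0 / (config.band_nm[0] / 1000.0)
    f0 = 0.5 * (f_lo + f_hi)
    df = 0.5 * (f_hi - f_lo)
    sigma = math.sqrt(2.0 * math.log(5.0)) / (2.0 * math.pi * df)  # 20% edge amplitude
    t0 = 5.0 * sigma
    n_on = int(math.ceil(2.0 * t0 / dt))
    t = (np.arange(max_steps) + 1.0) * dt
    g = np.zeros(max_steps)
    env = np.exp(-((t[:n_on] - t0) ** 2) / (2.0 * sigma**2))
    g[:n_on] = env * np.sin(2.0 * np.pi * f0 * t[:n_on])
    return g, t0


def _flux(E_dft: np.ndarray, H_dft: np.ndarray, sign: float, dx: float) -> np.ndarray:
    """Time-averaged Poynting flux through the monitor per frequency."""
    return sign * 0.5 * np.real(np.sum(E_dft * np.conj(H_dft), axis=1)) * dx


def _run_one_pol(scene, config, grid, pol: str):
    dx = grid.dx
    dt = config.courant * dx / math.sqrt(2.0)
    ss = config.subpixel
    eps_fine = _eps_fine(scene, grid, ss)
    half = ss // 2
    if pol == "s":
        eps = _block_avg(eps_fine, ss, -half, -half)  # Ey at (i, k)
        eps_args = (1.0 / eps,)
        kernel = _kernel_s
        sign_E = -1.0  # S_z = -Re(Ey Hx*)
    else:
        eps_x = _block_avg(eps_fine, ss, 0, -half)    # Ex at (i+1/2, k)
        eps_z = _block_avg(eps_fine, ss, -half, 0)    # Ez at (i, k+1/2)
        eps_args = (1.0 / eps_x, 1.0 / eps_z)
        kernel = _kernel_p
        sign_E = 1.0   # S_z = +Re(Ex Hy*)

    n_top = math.sqrt(float(np.mean(eps_fine[:, 0])))
    n_bot = math.sqrt(float(np.mean(eps_fine[:, -1])))
    be, ae, bh, ah = _cpml_profiles(grid.Nz, config.pml_cells, dx, dt, n_top, n_bot)
    g, t0 = _source_waveform(config, dt, config.max_steps)
    wl_um = config.wavelengths_nm / 1000.0
    omegas = 2.0 * np.pi / wl_um
    Lz = grid.Nz * dx
    min_steps = int((2.0 * t0 + 2.0 * Lz * scene.n_max) / dt)
    out = kernel(
        *eps_args, g, dt, dx, grid.k_src, grid.k_refl, grid.k_tran, omegas,
        be, ae, bh, ah, config.check_interval, config.decay_threshold,
        min_steps, config.max_steps,
    )
    dE_r, dH_r, dE_t, dH_t, n_run, peak, energy = out
    return {
        "dE_r": dE_r, "dH_r": dH_r, "dE_t": dE_t, "dH_t": dH_t,
        "n_run": int(n_run), "peak": peak, "final": energy,
        "sign": sign_E, "dx": dx,
    }


def _reference(scene: Scene, config: SolverConfig, grid: _Grid, pol: str):
    key = (
        grid.Nx, grid.Nz, round(grid.dx, 9), grid.k_src, grid.k_refl, grid.k_tran,
        round(scene.matrix_n, 9), config.courant, config.pml_cells, config.n_freqs,
        config.band_nm, config.max_steps, config.decay_threshold, pol,
    )
    if key not in _REFERENCE_CACHE:
        empty = Scene(
            lateral_um=scene.lateral_um, matrix_n=scene.matrix_n,
            clearance_um=scene.clearance_um,
        )
        empty = replace(empty, layers=(), packing=None, substrate_n=scene.matrix_n)
        res = _run_one_pol(empty, config, grid, pol)
        P_inc_r = _flux(res["dE_r"], res["dH_r"], res["sign"], grid.dx)
        P_inc_t = _flux(res["dE_t"], res["dH_t"], res["sign"], grid.dx)
        _REFERENCE_CACHE[key] = {
            "E_inc": res["dE_r"], "H_inc": res["dH_r"],
            "P_inc_r": P_inc_r, "P_inc_t": P_inc_t,
        }
    return _REFERENCE_CACHE[key]


def run_fdtd(scene: Scene, config: SolverConfig | None = None) -> Spectrum:
    """Compute R(λ), T(λ) of a scene by a broadband pulsed FDTD run.

    Reflectance uses incident-field subtraction at the upstream monitor
    against a cached empty-scene reference run on the identical grid;
    transmittance is the downstream flux normalized by the incident flux.
    Unstable configurations are rejected before time-stepping; runs that
    hit the step budget before the fields decay are flagged via
    ``meta["converged"]``.
    """
    config = config or SolverConfig()
    config.validate(scene.n_max, dim=2)
    grid = _build_grid(scene, config)
    pols = ["s", "p"] if config.polarization == "avg" else [config.polarization]
    R_acc, T_acc = [], []
    meta: dict = {
        "grid": {"Nx": grid.Nx, "Nz": grid.Nz, "dx_um": grid.dx},
        "polarizations": pols,
        "steps": {},
        "converged": True,
    }
    start = time.perf_counter()
    for pol in pols:
        ref = _reference(scene, config, grid, pol)
        res = _run_one_pol(scene, config, grid, pol)
        E_sc = res["dE_r"] - ref["E_inc"]
        H_sc = res["dH_r"] - ref["H_inc"]
        P_refl = _flux(E_sc, H_sc, res["sign"], grid.dx)
        P_tran = _flux(res["dE_t"], res["dH_t"], res["sign"], grid.dx)
        R = -P_refl / ref["P_inc_r"]
        T = P_tran / ref["P_inc_t"]
        R_acc.append(R)
        T_acc.append(T)
        meta["steps"][pol] = res["n_run"]
        decayed = res["final"] <= config.decay_threshold * res["peak"] * 1.01
        if res["n_run"] >= config.max_steps and not decayed:
            meta["converged"] = False
    R = np.clip(np.mean(R_acc, axis=0), 0.0, 1.0)
    T = np.clip(np.mean(T_acc, axis=0), 0.0, 1.0)
    meta["wall_clock_s"] = time.perf_counter() - start
    spec = Spectrum(config.wavelengths_nm.copy(), R, T, meta=meta)
    meta["energy_imbalance"] = spec.energy_imbalance()
    return spec


def energy_balance(spectrum: Spectrum) -> float:
    """max over λ of |R + T - 1| for a non-absorbing scene (flag > 0.01)."""
    imbalance = spectrum.energy_imbalance()
    spectrum.meta["energy_flagged"] = bool(imbalance > 0.01)
    return imbalance


def convergence_study(scene: Scene, spacings_nm, config: SolverConfig | None = None):
    """Band-averaged R at a series of grid spacings (coarse to fine)."""
    import pandas as pd

    if len(spacings_nm) < 2:
        raise ValueError("need at least two grid spacings")
    config = config or SolverConfig()
    rows = []
    for h in spacings_nm:
        cfg = replace(config, resolution_nm=float(h))
        spec = run_fdtd(scene, cfg)
        R_bar, T_bar = spec.band_average()
        rows.append({
            "spacing_nm": float(h),
            "R_band": R_bar,
            "T_band": T_bar,
            "energy_imbalance": spec.energy_imbalance(),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------


def load_scene_config(path: str | Path) -> tuple[Scene, SolverConfig]:
    """Read a scene + solver configuration from YAML or JSON.

    Recognized keys: ``scene: {lateral_um, matrix_n, substrate_n, layers:
    [[t_um, n], ...], packing_csv}`` and ``solver: {resolution_nm,
    courant, pml_cells, decay_threshold, max_steps, n_freqs, band_nm,
    polarization}``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    s = data.get("scene", {})
    packing = None
    if s.get("packing_csv"):
        packing = SpherePacking.from_csv(path.parent / s["packing_csv"])
    scene = Scene(
        lateral_um=float(s["lateral_um"]),
        matrix_n=float(s.get("matrix_n", 1.34)),
        layers=tuple((float(t), float(n)) for t, n in s.get("layers", [])),
        packing=packing,
        substrate_n=s.get("substrate_n"),
    )
    cfg_kwargs = data.get("solver", {})
    if "band_nm" in cfg_kwargs:
        cfg_kwargs["band_nm"] = tuple(cfg_kwargs["band_nm"])
    config = SolverConfig(**cfg_kwargs)
    return scene, config
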