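"""Parameter sweeps over sphere refractive index, layer thickness and
sphere diameter, with the double-pass antenna correction.

Each sweep simulates a layer of packed spheres beneath a homogeneous
chitin cuticle (default 5 µm, n = 1.57) in a seawater matrix (n = 1.34),
averages several independent packing realizations per swept value, and
reports band-averaged (400-700 nm) reflectance both for the single layer
and with the antenna double-pass correction R + R T²: an antenna is a
thin cylinder, so most light that enters it meets the structured wall
twice, and the far-wall reflection re-crosses the near wall on the way
back out.

The default grids are coarsened relative to a production sweep (index
step 0.05 rather than 0.01, thickness step 1 µm rather than 0.3 µm,
diameter step 100 nm rather than 30 nm) so a full sweep runs on a single
desktop core; the printed endpoints of each grid are preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .em_solver import Scene, SolverConfig, run_fdtd
from .geometry import SpherePacking, generate_sphere_packing

__all__ = [
    "SweepTable",
    "PlateauResult",
    "antenna_double_pass",
    "sphere_layer_scene",
    "sweep_refractive_index",
    "sweep_layer_thickness",
    "sweep_sphere_diameter",
    "control_reflectance",
    "detect_plateau",
    "plot_sweep",
]

CUTICLE_UM = 5.0
CHITIN_N = 1.57
SEAWATER_N = 1.34
DEFAULT_FILL = 0.55

#: coarsened default grids (full-resolution grids available by argument)
RI_GRID_COARSE = tuple(np.round(np.arange(1.57, 1.97001, 0.05), 4)) + (2.00,)
RI_GRID_FULL = tuple(np.round(np.arange(1.57, 2.00001, 0.01), 4))
THICKNESS_GRID_COARSE_UM = tuple(np.arange(1.0, 10.0001, 1.0))
THICKNESS_GRID_FULL_UM = tuple(np.round(np.arange(1.0, 10.0001, 0.3), 4))
DIAMETER_GRID_COARSE_NM = tuple(np.arange(100.0, 1000.01, 100.0))
DIAMETER_GRID_FULL_NM = tuple(np.arange(100.0, 1000.01, 30.0))


def antenna_double_pass(R: float, T: float) -> float:
    """Antenna-level reflectance R + R T² of a single structured wall."""
    R = np.asarray(R, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(R < 0) or np.any(R > 1) or np.any(T < 0) or np.any(T > 1):
        raise ValueError("R and T must lie in [0, 1]")
    out = R + R * T * T
    return float(out) if out.ndim == 0 else out


@dataclass
class SweepTable:
    """Replicate-averaged sweep results.

    One row per swept value with columns ``value``, ``R`` and ``T``
    (replicate-mean single-layer band averages), ``R_antenna``
    (= R + R T² of the mean R, T), ``R_sd`` (replicate spread), ``n_rep``
    and ``failed`` (solver failures at that point).
    """

    param: str
    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = self.df["value"].to_numpy()
        if np.any(np.diff(v) <= 0):
            raise ValueError("swept values must be strictly increasing")

    def validate_double_pass(self, tol: float = 1e-12) -> None:
        recomputed = self.df["R"] + self.df["R"] * self.df["T"] ** 2
        if np.max(np.abs(recomputed - self.df["R_antenna"])) > tol:
            raise ValueError("stored antenna reflectance inconsistent with R, T")

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False)
        path.with_suffix(".json").write_text(json.dumps(self.meta, indent=1, default=str))

    @classmethod
    def from_csv(cls, path: str | Path, param: str) -> "SweepTable":
        path = Path(path)
        meta = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(param, pd.read_csv(path), meta)


def sphere_layer_scene(
    lateral_um: float,
    layer_um: float,
    diam_spec,
    n_sphere: float,
    seed: int,
    matrix_n: float = SEAWATER_N,
    cuticle: tuple[float, float] | None = (CUTICLE_UM, CHITIN_N),
    target_fill: float = DEFAULT_FILL,
) -> Scene:
    """Build the standard scene: cuticle above a packed disc layer."""
    packing = generate_sphere_packing(
        box=(lateral_um, 0.0, layer_um),
        diam_spec=diam_spec,
        target_fill=target_fill,
        seed=seed,
        n_sphere=n_sphere,
        n_matrix=matrix_n,
    )
    layers = (cuticle,) if cuticle else ()
    return Scene(lateral_um=lateral_um, matrix_n=matrix_n, layers=layers, packing=packing)


def control_reflectance(
    cuticle: tuple[float, float] = (CUTICLE_UM, CHITIN_N),
    matrix_n: float = SEAWATER_N,
    method: str = "tmm",
    config: SolverConfig | None = None,
    lateral_um: float = 2.0,
) -> dict:
    """Reflectance of the bare cuticle (no sphere layer).

    The planar control is computed by the transfer-matrix solver
    (authoritative for planar geometry) and optionally cross-checked by
    FDTD.  Returns band-averaged single-layer and double-pass values.
    """
    from .geometry import LayerStack
    from .thin_films import tmm_spectrum

    if method == "tmm":
        stack = LayerStack(matrix_n, (cuticle,), matrix_n)
        spec = tmm_spectrum(stack, np.arange(400.0, 700.0 + 0.5, 1.0))
    elif method == "fdtd":
        scene = Scene(lateral_um=lateral_um, matrix_n=matrix_n, layers=(cuticle,))
        spec = run_fdtd(scene, config)
    else:
        raise ValueError("method must be 'tmm' or 'fdtd'")
    R_bar, T_bar = spec.band_average()
    return {
        "R": R_bar,
        "T": T_bar,
        "R_antenna": antenna_double_pass(R_bar, T_bar),
        "method": method,
    }


def _replicate_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def _sweep(
    param_name: str,
    values,
    scene_for,
    replicates: int,
    seed: int,
    config: SolverConfig | None,
    meta_extra: dict,
) -> SweepTable:
    config = config or SolverConfig()
    seeds = _replicate_seeds(seed, replicates)
    rows = []
    for v in values:
        Rs, Ts, failures = [], [], 0
        for s in seeds:
            try:
                scene = scene_for(v, s)
                spec = run_fdtd(scene, config)
                R_bar, T_bar = spec.band_average()
                Rs.append(R_bar)
                Ts.append(T_bar)
            except Exception:  # solver failure at one point -> marked, sweep continues
                failures += 1
        if Rs:
            R_m, T_m = float(np.mean(Rs)), float(np.mean(Ts))
            rows.append({
                "value": float(v), "R": R_m, "T": T_m,
                "R_antenna": antenna_double_pass(R_m, T_m),
                "R_sd": float(np.std(Rs, ddof=1)) if len(Rs) > 1 else 0.0,
                "n_rep": len(Rs), "failed": failures,
            })
        else:
            rows.append({
                "value": float(v), "R": np.nan, "T": np.nan, "R_antenna": np.nan,
                "R_sd": np.nan, "n_rep": 0, "failed": failures,
            })
    meta = {"seed": seed, "replicate_seeds": seeds, "param": param_name,
            "config": {"resolution_nm": config.resolution_nm,
                       "n_freqs": config.n_freqs,
                       "max_steps": config.max_steps}}
    meta.update(meta_extra)
    return SweepTable(param_name, pd.DataFrame(rows), meta)


def sweep_refractive_index(
    ri_values=RI_GRID_COARSE,
    layer_um: float = 2.0,
    diam_spec=("uniform", 300.0, 400.0),
    cuticle: tuple[float, float] = (CUTICLE_UM, CHITIN_N),
    lateral_um: float = 2.0,
    replicates: int = 3,
    seed: int = 0,
    config: SolverConfig | None = None,
) -> SweepTable:
    """Band-averaged reflectance of a 2 µm sphere layer vs sphere index."""
    if replicates < 1:
        raise ValueError("need at least one replicate")

    def scene_for(n_sphere, s):
        return sphere_layer_scene(lateral_um, layer_um, diam_spec, float(n_sphere), s,
                                  cuticle=cuticle)

    return _sweep("refractive_index", ri_values, scene_for, replicates, seed, config,
                  {"layer_um": layer_um, "diam_spec": list(diam_spec)})


def sweep_layer_thickness(
    thickness_values_um=THICKNESS_GRID_COARSE_UM,
    n_sphere: float = 1.78,
    diam_spec=("uniform", 300.0, 400.0),
    cuticle: tuple[float, float] = (CUTICLE_UM, CHITIN_N),
    lateral_um: float = 2.0,
    replicates: int = 3,
    seed: int = 0,
    config: SolverConfig | None = None,
) -> SweepTable:
    """Band-averaged reflectance vs sphere-layer thickness at one index."""
    if replicates < 1:
        raise ValueError("need at least one replicate")

    def scene_for(t_um, s):
        return sphere_layer_scene(lateral_um, float(t_um), diam_spec, n_sphere, s,
                                  cuticle=cuticle)

    return _sweep("layer_thickness_um", thickness_values_um, scene_for, replicates, seed,
                  config, {"n_sphere": n_sphere, "diam_spec": list(diam_spec)})


def sweep_sphere_diameter(
    diameter_values_nm=DIAMETER_GRID_COARSE_NM,
    n_sphere: float = 1.78,
    layer_um: float = 2.0,
    diameter_jitter_nm: float = 5.0,
    cuticle: tuple[float, float] = (CUTICLE_UM, CHITIN_N),
    lateral_um: float = 2.0,
    replicates: int = 3,
    seed: int = 0,
    config: SolverConfig | None = None,
) -> SweepTable:
    """Band-averaged reflectance vs (near-monodisperse) sphere diameter.

    Within each simulation all spheres share the nominal diameter to
    within ``diameter_jitter_nm`` (drawn uniformly in ±jitter).
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")

    def scene_for(d_nm, s):
        spec = ("uniform", float(d_nm) - diameter_jitter_nm, float(d_nm) + diameter_jitter_nm)
        return sphere_layer_scene(lateral_um, layer_um, spec, n_sphere, s, cuticle=cuticle)

    return _sweep("diameter_nm", diameter_values_nm, scene_for, replicates, seed, config,
                  {"n_sphere": n_sphere, "layer_um": layer_um})


@dataclass(frozen=True)
class PlateauResult:
    value: float          # mean reflectance over the plateau window
    onset: float          # first swept value inside the window
    n_points: int


def detect_plateau(table, rel_tol: float = 0.15, column: str = "R_antenna") -> PlateauResult | None:
    """Find the maximal trailing window whose relative spread < rel_tol.

    The plateau value is the mean over the longest suffix of the sweep
    whose (max - min)/mean falls below ``rel_tol``; the onset is the
    first swept value inside that window.  Windows shorter than two
    points never qualify; returns ``None`` when no window qualifies.
    """
    if isinstance(table, SweepTable):
        params = table.df["value"].to_numpy(dtype=float)
        values = table.df[column].to_numpy(dtype=float)
    else:
        params = np.asarray(table[0], dtype=float)
        values = np.asarray(table[1], dtype=float)
    ok = np.isfinite(values)
    params, values = params[ok], values[ok]  # failed sweep points are skipped
    if len(values) < 4:
        raise ValueError("plateau detection needs at least 4 points")
    n = len(values)
    for j in range(0, n - 1):  # longest qualifying suffix wins; earlier onset on ties
        window = values[j:]
        mean = window.mean()
        if mean <= 0:
            continue
        if (window.max() - window.min()) / mean < rel_tol:
            return PlateauResult(float(mean), float(params[j]), n - j)
    return None


def plot_sweep(table: SweepTable, path: str | Path, title: str | None = None) -> None:
    """Save a reflectance-vs-parameter plot (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = {
        "refractive_index": "Sphere refractive index",
        "layer_thickness_um": "Sphere layer thickness (µm)",
        "diameter_nm": "Sphere diameter (nm)",
    }
    fig, ax = plt.subplots(figsize=(5, 3.5))
    df = table.df
    ax.errorbar(df["value"], 100 * df["R_antenna"], yerr=100 * df["R_sd"], marker="o",
                capsize=3, lw=1.2)
    ax.set_xlabel(labels.get(table.param, table.param))
    ax.set_ylabel("Antenna reflectance, R + RT² (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
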