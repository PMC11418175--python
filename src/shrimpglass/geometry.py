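"""Structural models of antennal ultrastructure.

Two geometries recur in reflective antennae: a disordered layer of
high-refractive-index spheres embedded in a watery matrix (a "photonic
glass"), and a regular stack of thin chitin lamellae.  This module
generates both: random close-ish packings of hard spheres (or discs, for
two-dimensional scenes) in a laterally periodic box, and alternating
high/low-index multilayer stacks.

Lengths are in micrometres except sphere diameters, which follow the
field convention of nanometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpherePacking",
    "LayerStack",
    "PackingError",
    "generate_sphere_packing",
    "packing_fraction",
    "build_multilayer_stack",
    "draw_diameters",
]

#: tolerance (nm) absorbed when checking pairwise overlaps
OVERLAP_EPS_NM = 1.0


class PackingError(ValueError):
    """Raised when a packing cannot reach the requested fill fraction."""

    def __init__(self, message: str, achieved_fill: float | None = None):
        super().__init__(message)
        self.achieved_fill = achieved_fill


@dataclass(frozen=True)
class SpherePacking:
    """Non-overlapping spheres in a box periodic in x (and y when 3-D).

    ``box = (box_x, box_y, box_z)`` in µm.  ``box_y == 0`` marks a
    two-dimensional disc packing in the x–z plane (discs are cross
    sections of cylinders running along y).  The z direction is bounded:
    every sphere lies entirely inside ``[0, box_z]``.
    """

    box: tuple[float, float, float]
    centers: np.ndarray          # (N, 3) µm
    diameters_nm: np.ndarray     # (N,)
    n_sphere: float
    n_matrix: float
    seed: int | None = None
    diam_bounds_nm: tuple[float, float] | None = None

    @property
    def dim(self) -> int:
        return 2 if self.box[1] == 0 else 3

    @property
    def n(self) -> int:
        return len(self.diameters_nm)

    @property
    def radii_um(self) -> np.ndarray:
        return self.diameters_nm / 2000.0

    def min_image_distances(self) -> np.ndarray:
        """Pairwise periodic minimum-image centre distances (condensed)."""
        return _pairwise_distances(self.centers, self.box, self.dim)

    def validate(self, eps_nm: float = OVERLAP_EPS_NM) -> None:
        """Check all structural invariants; raise ``ValueError`` on failure."""
        if self.n == 0:
            return
        c, r = self.centers, self.radii_um
        if np.any(c[:, 0] < 0) or np.any(c[:, 0] >= self.box[0]):
            raise ValueError("sphere centre outside box in x")
        if self.dim == 3 and (np.any(c[:, 1] < 0) or np.any(c[:, 1] >= self.box[1])):
            raise ValueError("sphere centre outside box in y")
        if np.any(c[:, 2] - r < -1e-9) or np.any(c[:, 2] + r > self.box[2] + 1e-9):
            raise ValueError("sphere crosses z boundary")
        if self.diam_bounds_nm is not None:
            lo, hi = self.diam_bounds_nm
            if np.any(self.diameters_nm < lo - 1e-9) or np.any(self.diameters_nm > hi + 1e-9):
                raise ValueError("diameter outside configured bounds")
        if self.n > 1:
            d = self.min_image_distances()
            i, j = np.triu_indices(self.n, k=1)
            required = (self.radii_um[i] + self.radii_um[j]) - eps_nm / 1000.0
            if np.any(d < required):
                worst = float(np.max(required - d))
                raise ValueError(f"overlapping spheres (worst penetration {worst * 1000:.3f} nm)")

    # -- serialization -------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write positions/diameters as CSV with a JSON sidecar."""
        path = Path(path)
        header = "x_um,y_um,z_um,d_nm"
        data = np.column_stack([self.centers, self.diameters_nm]) if self.n else np.empty((0, 4))
        np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.9f")
        sidecar = {
            "box_um": list(self.box),
            "n_sphere": self.n_sphere,
            "n_matrix": self.n_matrix,
            "seed": self.seed,
            "diam_bounds_nm": list(self.diam_bounds_nm) if self.diam_bounds_nm else None,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpherePacking":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        meta = json.loads(path.with_suffix(".json").read_text())
        bounds = meta.get("diam_bounds_nm")
        return cls(
            box=tuple(meta["box_um"]),
            centers=data[:, :3] if data.size else np.empty((0, 3)),
            diameters_nm=data[:, 3] if data.size else np.empty(0),
            n_sphere=meta["n_sphere"],
            n_matrix=meta["n_matrix"],
            seed=meta["seed"],
            diam_bounds_nm=tuple(bounds) if bounds else None,
        )


def _pairwise_distances(centers: np.ndarray, box, dim: int) -> np.ndarray:
    """Condensed periodic minimum-image distance matrix (upper triangle)."""
    n = len(centers)
    i, j = np.triu_indices(n, k=1)
    delta = centers[i] - centers[j]
    delta[:, 0] -= box[0] * np.round(delta[:, 0] / box[0])
    if dim == 3:
        delta[:, 1] -= box[1] * np.round(delta[:, 1] / box[1])
    else:
        delta[:, 1] = 0.0
    return np.sqrt((delta**2).sum(axis=1))


def draw_diameters(diam_spec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` diameters (nm) from a spec tuple.

    ``("uniform", lo, hi)`` draws i.i.d. uniform diameters;
    ``("fixed", d)`` returns ``d`` for every sphere.
    """
    kind = diam_spec[0]
    if kind == "uniform":
        lo, hi = float(diam_spec[1]), float(diam_spec[2])
        if not 0 < lo <= hi:
            raise ValueError("uniform diameter bounds must satisfy 0 < lo <= hi")
        return rng.uniform(lo, hi, size=n)
    if kind == "fixed":
        d = float(diam_spec[1])
        if d <= 0:
            raise ValueError("fixed diameter must be positive")
        return np.full(n, d)
    raise ValueError(f"unknown diameter spec kind {kind!r}")


def _diam_bounds(diam_spec) -> tuple[float, float]:
    if diam_spec[0] == "uniform":
        return float(diam_spec[1]), float(diam_spec[2])
    return float(diam_spec[1]), float(diam_spec[1])


def _mean_particle_measure(diam_spec, dim: int) -> float:
    """Expected per-particle volume (µm³) or area (µm²)."""
    lo, hi = _diam_bounds(diam_spec)
    lo_um, hi_um = lo / 1000.0, hi / 1000.0
    if dim == 3:
        # E[d^3] for uniform(lo, hi)
        if hi_um > lo_um:
            ed3 = (hi_um**4 - lo_um**4) / (4 * (hi_um - lo_um))
        else:
            ed3 = lo_um**3
        return np.pi / 6.0 * ed3
    if hi_um > lo_um:
        ed2 = (hi_um**3 - lo_um**3) / (3 * (hi_um - lo_um))
    else:
        ed2 = lo_um**2
    return np.pi / 4.0 * ed2


def generate_sphere_packing(
    box: tuple[float, float, float],
    diam_spec,
    target_fill: float,
    seed: int,
    n_sphere: float = 1.78,
    n_matrix: float = 1.34,
    relax_sweeps: int = 120,
    polish_sweeps: int = 5000,
) -> SpherePacking:
    """Generate a dense random packing of hard spheres (or discs).

    Particles are first placed by random sequential addition at a reduced
    scale, then grown toward full size while overlaps are relaxed by
    pushing offending pairs apart along their centre line (a simple
    Lubachevsky–Stillinger-style densification).  The box is periodic in
    x (and y for 3-D packings); z is bounded.

    ``target_fill`` is a volume fraction for 3-D boxes and an area
    fraction for 2-D (``box_y == 0``) boxes, at most 0.64.
    """
    if not 0 <= target_fill <= 0.64:
        raise ValueError("target_fill must lie in [0, 0.64]")
    dim = 2 if box[1] == 0 else 3
    bounds = _diam_bounds(diam_spec)
    max_r_um = bounds[1] / 2000.0
    if box[0] < 2 * max_r_um or box[2] < 2 * max_r_um or (dim == 3 and box[1] < 2 * max_r_um):
        raise PackingError("box smaller than a single sphere")

    rng = np.random.default_rng(seed)
    measure = box[0] * box[2] * (box[1] if dim == 3 else 1.0)
    if target_fill == 0:
        return SpherePacking(box, np.empty((0, 3)), np.empty(0), n_sphere, n_matrix, seed, bounds)

    # draw particles until their cumulative measure reaches the target,
    # so the achieved fill never undershoots through sampling variance
    n_guess = max(1, int(np.ceil(1.5 * target_fill * measure / _mean_particle_measure(diam_spec, dim))))
    batch = draw_diameters(diam_spec, n_guess + 8, rng)
    r_um = batch / 2000.0
    per = 4.0 / 3.0 * np.pi * r_um**3 if dim == 3 else np.pi * r_um**2
    cum = np.cumsum(per)
    n = int(np.searchsorted(cum, target_fill * measure) + 1)
    n = min(n, len(batch))
    diam = np.sort(batch[:n])[::-1].copy()
    radii = diam / 2000.0

    # initial RSA placement at reduced scale: easy to satisfy
    scale0 = 0.6
    centers = _rsa_place(box, radii * scale0, dim, rng)

    # grow toward full size, relaxing overlaps after each growth step,
    # then polish at full size until overlap-free
    n_grow = 25
    for step in range(1, n_grow + 1):
        scale = scale0 + (1.0 - scale0) * step / n_grow
        _relax(centers, radii * scale, box, dim, rng, relax_sweeps)
    ok = _relax(centers, radii, box, dim, rng, polish_sweeps)
    if not ok:
        achieved = packing_fraction(
            SpherePacking(box, centers, diam, n_sphere, n_matrix, seed, None)
        )
        raise PackingError(
            f"could not reach target fill {target_fill:.3f}; achieved {achieved:.3f}",
            achieved_fill=achieved,
        )

    packing = SpherePacking(box, centers, diam, n_sphere, n_matrix, seed, bounds)
    packing.validate()
    achieved = packing_fraction(packing)
    if achieved < 0.9 * target_fill:
        raise PackingError(
            f"achieved fill {achieved:.3f} below 0.9 x target {target_fill:.3f}",
            achieved_fill=achieved,
        )
    return packing


def _rsa_place(box, radii_um, dim, rng, max_tries: int = 4000) -> np.ndarray:
    """Random sequential addition; radii already scaled."""
    n = len(radii_um)
    centers = np.zeros((n, 3))
    for k in range(n):
        r = radii_um[k]
        placed = False
        for _ in range(max_tries):
            x = rng.uniform(0, box[0])
            y = rng.uniform(0, box[1]) if dim == 3 else 0.0
            z = rng.uniform(r, box[2] - r)
            cand = np.array([x, y, z])
            if k == 0 or _clear(cand, r, centers[:k], radii_um[:k], box, dim):
                centers[k] = cand
                placed = True
                break
        if not placed:
            raise PackingError(f"RSA stalled after placing {k} of {n} spheres")
    return centers


def _clear(cand, r, centers, radii, box, dim) -> bool:
    delta = centers - cand
    delta[:, 0] -= box[0] * np.round(delta[:, 0] / box[0])
    if dim == 3:
        delta[:, 1] -= box[1] * np.round(delta[:, 1] / box[1])
    d2 = (delta**2).sum(axis=1)
    return bool(np.all(d2 >= (radii + r) ** 2))


def _neighbor_pairs(centers, box, dim, cutoff) -> tuple[np.ndarray, np.ndarray]:
    """Candidate close pairs via a KD-tree, periodic in the lateral axes."""
    from scipy.spatial import cKDTree

    pts = centers.copy()
    pts[:, 0] %= box[0]
    big = max(box[2], 1.0) * 1e3
    boxsize = [box[0], box[1] if dim == 3 else big, big]
    pairs = cKDTree(pts, boxsize=boxsize).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return pairs[:, 0], pairs[:, 1]


def _relax(centers, radii_um, box, dim, rng, max_sweeps: int) -> bool:
    """Push overlapping pairs apart; returns True when overlap-free.

    Mutates ``centers`` in place.  The push threshold keeps a quarter of
    the 1 nm overlap tolerance as safety margin so floating-point drift
    cannot break the packing invariant afterwards.  Neighbor pairs come
    from a KD-tree with a skin distance, rebuilt periodically.
    """
    n = len(centers)
    if n < 2:
        return True
    margin = 0.25 * OVERLAP_EPS_NM / 1000.0   # pushes aim for positive clearance
    eps_ok = 0.5 * OVERLAP_EPS_NM / 1000.0    # residual penetration still valid
    skin = 0.04
    cutoff = 2.0 * float(np.max(radii_um)) + skin
    rebuild_every = 12
    stall = 0
    prev_worst = np.inf

    def worst_violation(ii, jj):
        if len(ii) == 0:
            return -np.inf, None, None
        delta = centers[ii] - centers[jj]
        delta[:, 0] -= box[0] * np.round(delta[:, 0] / box[0])
        if dim == 3:
            delta[:, 1] -= box[1] * np.round(delta[:, 1] / box[1])
        else:
            delta[:, 1] = 0.0
        dist = np.sqrt((delta**2).sum(axis=1))
        return radii_um[ii] + radii_um[jj] - dist, delta, dist

    i_idx = j_idx = np.empty(0, dtype=int)
    for sweep in range(max_sweeps):
        if sweep % rebuild_every == 0:
            i_idx, j_idx = _neighbor_pairs(centers, box, dim, cutoff)
        viol, delta, dist = worst_violation(i_idx, j_idx)
        if np.isscalar(viol) or len(i_idx) == 0:
            return True
        bad = viol > -margin
        if not np.any(bad) or viol.max() <= eps_ok:
            if np.max(viol) <= eps_ok and sweep % rebuild_every == 0:
                return True  # verified on a fresh neighbor list
            if not np.any(bad):
                i_idx, j_idx = _neighbor_pairs(centers, box, dim, cutoff)
                viol, delta, dist = worst_violation(i_idx, j_idx)
                if np.isscalar(viol) or np.max(viol) <= eps_ok:
                    return True
                bad = viol > -margin
        worst = float(viol.max())
        stall = stall + 1 if worst >= prev_worst - 1e-12 else 0
        prev_worst = worst
        moves = np.zeros_like(centers)
        d_bad = np.maximum(dist[bad], 1e-9)
        push = (0.55 * (viol[bad] + margin) / d_bad)[:, None] * delta[bad]
        np.add.at(moves, i_idx[bad], push)
        np.add.at(moves, j_idx[bad], -push)
        if stall > 25:  # jammed: kick the offending particles only
            stuck = np.unique(np.concatenate([i_idx[bad], j_idx[bad]]))
            kick = rng.normal(0.0, max(1e-3, 0.5 * worst), size=(len(stuck), 3))
            moves[stuck] += kick
            stall = 0
        if dim == 2:
            moves[:, 1] = 0.0
        centers += moves
        centers[:, 0] %= box[0]
        if dim == 3:
            centers[:, 1] %= box[1]
        np.clip(centers[:, 2], radii_um, box[2] - radii_um, out=centers[:, 2])
    i_idx, j_idx = _neighbor_pairs(centers, box, dim, cutoff)
    viol, _, _ = worst_violation(i_idx, j_idx)
    return bool(np.isscalar(viol) or np.max(viol) <= eps_ok)


def packing_fraction(p: SpherePacking) -> float:
    """Filled volume (or area, for disc packings) fraction of the box.

    Periodic wrapping in the lateral directions means every particle
    contributes its full measure; z-bounded placement keeps particles
    inside the box, so no clipping is required.
    """
    if p.n == 0:
        return 0.0
    r = p.radii_um
    if p.dim == 3:
        total = np.sum(4.0 / 3.0 * np.pi * r**3)
        vol = p.box[0] * p.box[1] * p.box[2]
    else:
        total = np.sum(np.pi * r**2)
        vol = p.box[0] * p.box[2]
    return float(total / vol)


# ---------------------------------------------------------------------------
# planar multilayers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerStack:
    """Ordered planar layers between two semi-infinite media.

    ``layers`` is a list of ``(thickness_um, refractive_index)`` in the
    order light encounters them from the ambient side.
    """

    ambient_n: float
    layers: tuple[tuple[float, float], ...]
    substrate_n: float

    def __post_init__(self):
        if self.ambient_n < 1 or self.substrate_n < 1:
            raise ValueError("refractive indices must be >= 1")
        for t, n in self.layers:
            if t <= 0:
                raise ValueError("layer thicknesses must be positive")
            if n < 1:
                raise ValueError("layer indices must be >= 1")

    @property
    def total_thickness(self) -> float:
        return float(sum(t for t, _ in self.layers))

    def reversed(self) -> "LayerStack":
        return LayerStack(self.substrate_n, tuple(self.layers[::-1]), self.ambient_n)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ambient_n": self.ambient_n,
            "layers": [[t, n] for t, n in self.layers],
            "substrate_n": self.substrate_n,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LayerStack":
        d = json.loads(Path(path).read_text())
        return cls(d["ambient_n"], tuple((t, n) for t, n in d["layers"]), d["substrate_n"])


def build_multilayer_stack(
    n_high_layers: int,
    t_high: float,
    t_low: float,
    n_high: float,
    n_low: float = 1.34,
    ambient_n: float = 1.34,
    substrate_n: float = 1.34,
) -> LayerStack:
    """Alternating high/low stack that begins and ends with a high layer.

    Models the regular chitin lamellae seen in some antennae: ``n`` high
    index layers of thickness ``t_high`` separated by ``n - 1`` low-index
    gaps of ``t_low``; total thickness ``n*t_high + (n-1)*t_low``.
    """
    if n_high_layers < 1:
        raise ValueError("need at least one high-index layer")
    if t_high <= 0 or (n_high_layers > 1 and t_low <= 0):
        raise ValueError("layer thicknesses must be positive")
    layers: list[tuple[float, float]] = []
    for k in range(n_high_layers):
        layers.append((t_high, n_high))
        if k < n_high_layers - 1:
            layers.append((t_low, n_low))
    return LayerStack(ambient_n, tuple(layers), substrate_n)
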