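"""Synthetic inputs with known ground truth.

Every input the analysis pipeline consumes can be generated here:
SEM-like cross-section images of the antennal sphere layer (for the
morphometry round trip), calibration photographs with five grey swatches
and antenna regions (for the photometry round trip), and per-individual
reflectance datasets drawn from the published species summaries (for the
group statistics).  All generators are seed-deterministic and carry
machine-readable ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import FOCAL_SPECIES

__all__ = [
    "SynthSEM",
    "SynthPhoto",
    "SPECIES_PARAMS",
    "synth_sem",
    "measure_circles",
    "synth_photo",
    "synth_reflectance_dataset",
]

#: species reflectance summaries (fractions) used as generator defaults.
#: A. pedersoni has two measured individuals (0.438, 0.389) and no
#: published s.d.; its generator uses their mean and half-range.
SPECIES_PARAMS = {
    "Ancylomenes pedersoni": {"mean": 0.4135, "sd": 0.0245, "n": 2},
    "Lysmata amboinensis": {"mean": 0.521, "sd": 0.040, "n": 3},
    "Lysmata debelius": {"mean": 0.481, "sd": 0.004, "n": 3},
    "Periclimenes yucatanicus": {"mean": 0.347, "sd": 0.016, "n": 3},
    "Lysmata boggessi": {"mean": 0.218, "sd": 0.023, "n": 3},
}


# ---------------------------------------------------------------------------
# SEM-like sphere-layer images
# ---------------------------------------------------------------------------


@dataclass
class SynthSEM:
    """Synthetic cross-section image of a sphere layer.

    Spheres are rendered as filled anti-aliased discs (3-D sectioning
    effects on apparent diameter are deliberately ignored).  Ground-truth
    centres are in pixels, diameters in nm.
    """

    image: np.ndarray          # uint8 grayscale
    px_scale_nm: float
    centers_px: np.ndarray     # (N, 2) row, col
    diameters_nm: np.ndarray
    seed: int

    def ground_truth(self) -> dict:
        return {
            "px_scale_nm": self.px_scale_nm,
            "centers_px": self.centers_px.tolist(),
            "diameters_nm": self.diameters_nm.tolist(),
            "seed": self.seed,
        }

    def to_files(self, stem: str | Path) -> None:
        from PIL import Image

        stem = Path(stem)
        Image.fromarray(self.image).save(stem.with_suffix(".png"))
        stem.with_suffix(".json").write_text(json.dumps(self.ground_truth(), indent=1))


def synth_sem(
    diam_mean_nm: float = 395.0,
    diam_sd_nm: float = 40.0,
    n_spheres: int = 207,
    px_scale_nm: float = 4.0,
    seed: int = 0,
    fg: int = 200,
    bg: int = 30,
    min_gap_px: float = 3.0,
) -> SynthSEM:
    """Render non-overlapping circle cross-sections with known truth.

    Diameters follow ``normal(diam_mean_nm, diam_sd_nm)`` truncated at
    ±3 s.d.; circles are placed by random sequential addition with a
    ``min_gap_px`` clearance so segmentation can separate them.
    """
    if diam_mean_nm - 3 * diam_sd_nm <= 2 * px_scale_nm:
        raise ValueError("diameter distribution not resolvable at this pixel scale")
    rng = np.random.default_rng(seed)
    diam = diam_mean_nm + diam_sd_nm * np.clip(rng.standard_normal(n_spheres), -3, 3)
    radii_px = diam / (2.0 * px_scale_nm)

    # image sized for ~25% fill so RSA placement stays easy
    area = np.sum(np.pi * radii_px**2) / 0.25
    side = int(np.ceil(np.sqrt(area))) + int(4 * radii_px.max())
    centers = np.zeros((n_spheres, 2))
    order = np.argsort(radii_px)[::-1]
    for k, idx in enumerate(order):
        r = radii_px[idx]
        for _ in range(20000):
            c = rng.uniform(r + 2, side - r - 2, size=2)
            if k == 0:
                break
            prev = order[:k]
            d = np.sqrt(((centers[prev] - c) ** 2).sum(axis=1))
            if np.all(d >= radii_px[prev] + r + min_gap_px):
                break
        else:
            raise ValueError("could not place all circles without overlap")
        centers[idx] = c

    image = np.full((side, side), float(bg))
    yy = np.arange(side)
    for (cy, cx), r in zip(centers, radii_px):
        y0, y1 = int(max(cy - r - 2, 0)), int(min(cy + r + 3, side))
        x0, x1 = int(max(cx - r - 2, 0)), int(min(cx + r + 3, side))
        ys = yy[y0:y1, None] - cy
        xs = yy[None, x0:x1] - cx
        dist = np.sqrt(ys**2 + xs**2)
        cov = np.clip(r + 0.5 - dist, 0.0, 1.0)  # anti-aliased edge
        patch = image[y0:y1, x0:x1]
        image[y0:y1, x0:x1] = patch + cov * (fg - bg)
    image = np.clip(image, 0, 255).astype(np.uint8)
    return SynthSEM(image, px_scale_nm, centers, diam, seed)


def measure_circles(image: np.ndarray, px_scale_nm: float, min_area_px: int = 12) -> dict:
    """Morphometry of a sphere-layer image: per-circle diameters.

    Otsu threshold -> connected components -> equivalent-circle diameter
    per component, scaled to nm.  Returns diameters plus mean ± s.d. and
    the count; a blank image yields an empty result rather than an error.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if img.max() == img.min():
        return {"diameters_nm": np.empty(0), "mean_nm": np.nan, "sd_nm": np.nan, "n": 0}
    mask = img > threshold_otsu(img)
    labels = label(mask)
    diams = [
        p.equivalent_diameter_area * px_scale_nm
        for p in regionprops(labels)
        if p.area >= min_area_px
    ]
    diams = np.asarray(diams)
    return {
        "diameters_nm": diams,
        "mean_nm": float(diams.mean()) if len(diams) else np.nan,
        "sd_nm": float(diams.std(ddof=1)) if len(diams) > 1 else np.nan,
        "n": int(len(diams)),
    }


# ---------------------------------------------------------------------------
# calibration photographs
# ---------------------------------------------------------------------------

DEFAULT_SWATCH_RS = (0.03, 0.10, 0.30, 0.60, 0.90)


@dataclass
class SynthPhoto:
    """Synthetic calibration photograph.

    The camera model is a power-law tone curve applied per channel,
    ``G = round(255 * R**(1/gamma)) + noise`` clipped to [0, 255]; the
    red and blue channels carry scaled copies of the green signal.
    Swatch and antenna regions are uniform up to the additive noise.
    """

    image: np.ndarray                 # uint8 RGB
    swatch_rois: list
    swatch_reflectances: tuple
    antenna_rois: list
    antenna_reflectance: float
    gamma: float
    noise_sd: float
    seed: int

    def ground_truth(self) -> dict:
        return {
            "swatch_reflectances": list(self.swatch_reflectances),
            "antenna_reflectance": self.antenna_reflectance,
            "gamma": self.gamma,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    def to_files(self, stem: str | Path) -> None:
        from PIL import Image

        stem = Path(stem)
        Image.fromarray(self.image).save(stem.with_suffix(".png"))
        payload = {
            "rois": self.antenna_rois,
            "swatch_rois": self.swatch_rois,
            "ground_truth": self.ground_truth(),
        }
        stem.with_suffix(".json").write_text(json.dumps(payload, indent=1))


def synth_photo(
    swatch_Rs=DEFAULT_SWATCH_RS,
    antenna_R: float = 0.45,
    gamma: float = 2.2,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_antenna_rois: int = 10,
) -> SynthPhoto:
    """Render a calibration photograph with known reflectances."""
    swatch_Rs = tuple(float(r) for r in swatch_Rs)
    if len(swatch_Rs) != 5 or np.any(np.diff(swatch_Rs) <= 0) or swatch_Rs[0] <= 0 or swatch_Rs[-1] > 1:
        raise ValueError("swatch reflectances must be 5 strictly increasing values in (0, 1]")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    rng = np.random.default_rng(seed)
    H, W = 300, 520
    R_map = np.full((H, W), 0.15)

    # antenna: a bright horizontal band across the top
    band = {"y0": 40, "y1": 80}
    R_map[band["y0"]:band["y1"], :] = antenna_R
    roi_w = W // n_antenna_rois
    antenna_rois = [
        {"type": "rect", "x": i * roi_w + 4, "y": band["y0"] + 5, "w": roi_w - 8, "h": 30}
        for i in range(n_antenna_rois)
    ]

    # five swatches along the bottom
    sw_w = W // 5
    swatch_rois = []
    for i, r in enumerate(swatch_Rs):
        x0 = i * sw_w
        R_map[180:280, x0 + 6:x0 + sw_w - 6] = r
        swatch_rois.append({"type": "rect", "x": x0 + 12, "y": 190, "w": sw_w - 24, "h": 80})

    G = np.round(255.0 * R_map ** (1.0 / gamma))
    if noise_sd > 0:
        G = G + rng.normal(0.0, noise_sd, size=G.shape)
    G = np.clip(G, 0, 255)
    image = np.stack([
        np.round(G * 0.95), G, np.round(G * 0.90)
    ], axis=-1).astype(np.uint8)
    return SynthPhoto(image, swatch_rois, swatch_Rs, antenna_rois, float(antenna_R),
                      float(gamma), float(noise_sd), seed)


# ---------------------------------------------------------------------------
# reflectance datasets
# ---------------------------------------------------------------------------


def synth_reflectance_dataset(
    species_params: dict | None = None,
    n_per_species: int | None = None,
    roi_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-ROI reflectance records drawn from species summaries.

    Individual means are drawn ``normal(mean, sd)`` truncated to [0, 1];
    each individual gets 4-10 ROIs whose values scatter around the
    individual mean with ``roi_sd`` (zero by default, so individual means
    are exact).  Status and ultrastructure labels follow the five focal
    species; sample sizes default to the published ones (2 for
    A. pedersoni, 3 elsewhere).
    """
    params = species_params or SPECIES_PARAMS
    rng = np.random.default_rng(seed)
    records = []
    for species, p in params.items():
        n_ind = n_per_species or p.get("n", 3)
        labels = FOCAL_SPECIES.get(species, {"status": p.get("status", "unknown"),
                                             "ultrastructure": p.get("ultrastructure", False)})
        for i in range(n_ind):
            value = float(np.clip(rng.normal(p["mean"], p["sd"]), 0.0, 1.0)) if p["sd"] > 0 else p["mean"]
            n_roi = int(rng.integers(4, 11))
            for r in range(n_roi):
                v = value + (rng.normal(0.0, roi_sd) if roi_sd > 0 else 0.0)
                records.append({
                    "species": species,
                    "status": labels["status"],
                    "ultrastructure": labels["ultrastructure"],
                    "individual": f"{species}_{i + 1}",
                    "roi": r + 1,
                    "reflectance": float(np.clip(v, 0.0, 1.0)),
                })
    return pd.DataFrame.from_records(records)
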