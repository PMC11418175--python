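"""Calibrated-photography reflectometry.

Reflectance of an antenna is measured from an ordinary sRGB photograph
that includes a standard of five grey swatches of known reflectance: the
green channel approximates brightness vision and matches the dominant
illuminant on a reef, an exponential calibration curve is fitted to the
swatch green values, and antenna regions of interest are converted to
fractional reflectance through that curve.  Values are then aggregated
ROIs -> individual -> species.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CalibrationStandard",
    "CalibrationCurve",
    "green_channel",
    "fit_calibration",
    "measure_standard",
    "roi_mask",
    "roi_reflectance",
    "aggregate",
    "load_rois",
]


def green_channel(image: np.ndarray) -> np.ndarray:
    """Extract the green channel of an 8-bit RGB raster, unrescaled."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image with 3 channels")
    if image.dtype != np.uint8:
        raise ValueError("expected an 8-bit image")
    return image[:, :, 1]


@dataclass(frozen=True)
class CalibrationStandard:
    """Five grey swatches: known reflectance vs measured mean green value."""

    reflectances: tuple[float, ...]
    green_values: tuple[float, ...]

    def __post_init__(self):
        if len(self.reflectances) != 5 or len(self.green_values) != 5:
            raise ValueError("a standard comprises exactly five swatches")
        g = np.asarray(self.green_values, dtype=float)
        r = np.asarray(self.reflectances, dtype=float)
        if np.any(g < 0) or np.any(g > 255):
            raise ValueError("green values must lie in [0, 255]")
        order = np.argsort(g)
        if np.any(np.diff(g[order]) <= 0):
            raise ValueError("degenerate standard: swatch green values must be distinct")
        if np.any(np.diff(r[order]) <= 0):
            raise ValueError("standard is not monotone: reflectance must increase with green value")


@dataclass(frozen=True)
class CalibrationCurve:
    """Exponential map from 0-255 green value to fractional reflectance.

    ``R(G) = a * exp(b * G) + c``; the offset term absorbs the camera's
    tone-curve curvature that a pure exponential cannot follow.  ``a`` and
    ``b`` are positive, so the curve is strictly increasing on [0, 255].
    """

    a: float
    b: float
    c: float = 0.0
    residuals: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("calibration curve must be strictly increasing (a > 0, b > 0)")

    def __call__(self, green):
        return self.a * np.exp(self.b * np.asarray(green, dtype=float)) + self.c


def fit_calibration(standard: CalibrationStandard, with_offset: bool = True) -> CalibrationCurve:
    """Least-squares exponential calibration from a five-swatch standard.

    A log-linear regression initializes the nonlinear fit.  On data that
    are exactly exponential (c = 0) the parameters are recovered to
    relative error far below 1e-6.
    """
    G = np.asarray(standard.green_values, dtype=float)
    R = np.asarray(standard.reflectances, dtype=float)
    b0, loga = np.polyfit(G, np.log(np.maximum(R, 1e-12)), 1)
    a0 = float(np.exp(loga))
    if b0 <= 0:
        raise ValueError("standard implies a non-increasing calibration")
    if with_offset:
        def model(g, a, b, c):
            return a * np.exp(b * g) + c

        popt, _ = curve_fit(model, G, R, p0=[a0, b0, 0.0], maxfev=20000)
        a, b, c = (float(v) for v in popt)
    else:
        def model(g, a, b):
            return a * np.exp(b * g)

        popt, _ = curve_fit(model, G, R, p0=[a0, b0], maxfev=20000)
        a, b = (float(v) for v in popt)
        c = 0.0
    resid = tuple(float(r) for r in (R - (a * np.exp(b * G) + c)))
    return CalibrationCurve(a, b, c, resid)


def two_point_calibration(g1: float, r1: float, g2: float, r2: float) -> CalibrationCurve:
    """Closed-form two-swatch exponential (minimum viable standard)."""
    if g1 == g2 or r1 <= 0 or r2 <= 0:
        raise ValueError("two-point calibration needs distinct green values and positive R")
    b = float(np.log(r2 / r1) / (g2 - g1))
    a = float(r1 / np.exp(b * g1))
    return CalibrationCurve(a, b, 0.0)


def measure_standard(image: np.ndarray, swatch_rois, known_reflectances) -> CalibrationStandard:
    """Measure the mean green value of each swatch region."""
    g = green_channel(image)
    means = [float(np.mean(g[roi_mask(r, g.shape)])) for r in swatch_rois]
    return CalibrationStandard(tuple(float(r) for r in known_reflectances), tuple(means))


def roi_mask(roi, shape) -> np.ndarray:
    """Boolean mask from a rectangle or polygon ROI description.

    Rectangles: ``{"type": "rect", "x":, "y":, "w":, "h":}`` (x = column,
    y = row); polygons: ``{"type": "polygon", "xy": [[x, y], ...]}``.
    """
    mask = np.zeros(shape, dtype=bool)
    if roi.get("type", "rect") == "rect":
        x, y, w, h = roi["x"], roi["y"], roi["w"], roi["h"]
        if w <= 0 or h <= 0 or y + h > shape[0] or x + w > shape[1] or x < 0 or y < 0:
            raise ValueError("rectangle ROI outside image or empty")
        mask[y:y + h, x:x + w] = True
    elif roi["type"] == "polygon":
        from skimage.draw import polygon

        xy = np.asarray(roi["xy"], dtype=float)
        rr, cc = polygon(xy[:, 1], xy[:, 0], shape)
        if len(rr) == 0:
            raise ValueError("polygon ROI empty or outside image")
        mask[rr, cc] = True
    else:
        raise ValueError(f"unknown ROI type {roi['type']!r}")
    return mask


def load_rois(path: str | Path) -> list[dict]:
    """Read a list of ROI descriptions from a JSON sidecar."""
    data = json.loads(Path(path).read_text())
    return data["rois"] if isinstance(data, dict) else data


def roi_reflectance(image: np.ndarray, rois, curve: CalibrationCurve) -> list[float]:
    """Convert the mean green value of each ROI to reflectance.

    Values above 1 indicate extrapolation beyond the brightest swatch;
    they are clipped to 1 with a warning.
    """
    g = green_channel(image)
    out = []
    for roi in rois:
        mask = roi_mask(roi, g.shape)
        if not mask.any():
            raise ValueError("empty ROI")
        r = float(curve(float(g[mask].mean())))
        if r > 1.0:
            warnings.warn("calibration extrapolated above R=1; clipping", stacklevel=2)
            r = 1.0
        out.append(max(r, 0.0))
    return out


def aggregate(dataset: pd.DataFrame) -> pd.DataFrame:
    """Two-stage aggregation: ROIs -> individual mean -> species mean ± s.d.

    ``dataset`` columns: species, status, individual, roi, reflectance.
    The species s.d. is across individual means (ddof=1); species with a
    single individual get s.d. NaN and are flagged.
    """
    required = {"species", "individual", "reflectance"}
    if not required.issubset(dataset.columns):
        raise ValueError(f"dataset must contain columns {sorted(required)}")
    indiv = (
        dataset.groupby(["species", "individual"], sort=False)["reflectance"]
        .mean()
        .reset_index()
    )
    def _sd(x):
        return x.std(ddof=1) if len(x) > 1 else np.nan

    species = indiv.groupby("species", sort=False)["reflectance"].agg(
        mean="mean", sd=_sd, n="count"
    ).reset_index()
    species["sd_defined"] = species["n"] > 1
    if "status" in dataset.columns:
        status = dataset.groupby("species", sort=False)["status"].first()
        species = species.merge(status, on="species")
    return species
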