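"""Per-seed feature extraction: 19 shape, color and binary variables.

The classifier downstream consumes one fixed-length vector per seed side.
The 19 variables fall in three groups:

* shape (7): area, perimeter, major-axis length, minor-axis width,
  length/width ratio, circularity ``4πA/P²``, compactness (area over
  convex-hull area);
* color (9): mean reflectance inside the footprint at six fixed bands
  (450, 525, 590, 660, 780, 940 nm) plus CIELab-style L*, a*, b* computed
  from the visible-band means under a fixed nominal illuminant;
* binary (3): interior-hole count of the pre-fill mask, damaged-area
  fraction (footprint pixels whose nCDA-transformed value exceeds the
  model's damage threshold), and damaged-patch count.

The variable order is frozen in ``FEATURE_NAMES`` — the contract that makes
scoring models portable across runs.  ``mean_spectrum`` builds the
per-class mean reflectance table over all footprint pixels, the standard
first look at class separability across the wavelength axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color as skcolor
from skimage.measure import label as sk_label
from skimage.measure import perimeter_crofton, regionprops

from .msi_io import SeedRegion, SpectralStack
from .ncda import NCDAModel, apply_ncda

__all__ = ["FEATURE_NAMES", "COLOR_BANDS_NM", "FeatureVector", "extract_features", "mean_spectrum"]

#: Bands (nm) whose footprint means are color features.
COLOR_BANDS_NM: tuple[float, ...] = (450, 525, 590, 660, 780, 940)

#: The frozen 19-variable order.
FEATURE_NAMES: tuple[str, ...] = (
    "area",
    "perimeter",
    "length",
    "width",
    "aspect_ratio",
    "circularity",
    "compactness",
    "mean_450",
    "mean_525",
    "mean_590",
    "mean_660",
    "mean_780",
    "mean_940",
    "cielab_l",
    "cielab_a",
    "cielab_b",
    "hole_count",
    "damaged_area_fraction",
    "damaged_patch_count",
)


@dataclass
class FeatureVector:
    """The 19 named variables for one seed side, in frozen order."""

    values: np.ndarray
    ncda_available: bool = True
    names: tuple[str, ...] = field(default=FEATURE_NAMES, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")
        d = self.as_dict()
        for name in ("area", "perimeter", "length", "width"):
            if d[name] <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < d["circularity"] <= 1.05:
            raise ValueError("circularity outside (0, 1.05]")
        for name in ("compactness", "damaged_area_fraction"):
            if not 0 <= d[name] <= 1:
                raise ValueError(f"{name} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def _nearest_band(wavelengths: np.ndarray, target: float) -> int:
    return int(np.argmin(np.abs(wavelengths - target)))


def _lab_from_band_means(stack_wl: np.ndarray, band_means: np.ndarray) -> np.ndarray:
    """CIELab-style triplet from visible band means.

    A nominal pseudo-RGB is assembled from broadband red/green/blue
    channels (each the mean of three neighbouring visible bands, which
    damps per-band noise) and converted with the standard sRGB→Lab
    transform (D65).  Exact colorimetry is not the goal — the triplet
    feeds a relative scoring model, so a fixed reproducible transform
    suffices.
    """
    channels = {"r": (630, 645, 660), "g": (505, 525, 570), "b": (435, 450, 470)}
    rgb_vals = [
        np.mean([band_means[_nearest_band(stack_wl, t)] for t in bands])
        for bands in (channels["r"], channels["g"], channels["b"])
    ]
    rgb = np.clip(np.array([[rgb_vals]], dtype=float) / 100.0, 0.0, 1.0)
    return skcolor.rgb2lab(rgb)[0, 0]


def extract_features(
    stack: SpectralStack,
    region: SeedRegion,
    ncda_model: NCDAModel | None = None,
) -> FeatureVector:
    """Extract the 19 variables for one segmented seed side.

    Without an nCDA model the two transform-derived binary features
    (damaged-area fraction, damaged-patch count) are 0 and the vector is
    flagged ``ncda_available=False``.
    """
    rows, cols = stack.resolution
    if region.mask.shape != (rows, cols):
        raise ValueError("region mask shape does not match stack")
    if region.area == 0:
        raise ValueError("empty region")
    r0, c0, r1, c1 = region.bbox
    if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
        raise ValueError("region outside stack bounds")

    # shape: all geometry from the cropped mask, so results are
    # translation-invariant by construction
    crop = region.mask[r0:r1, c0:c1]
    props = regionprops(crop.astype(np.uint8))[0]
    area = float(props.area)
    # Crofton (4 directions): near-unbiased on digitized smooth shapes,
    # so a rasterized disc scores circularity ≈ 1
    perimeter = float(perimeter_crofton(crop, directions=4))
    length = float(props.axis_major_length)
    width = float(props.axis_minor_length)
    if width <= 0 or perimeter <= 0:
        raise ValueError("degenerate region geometry")
    circularity = min(4 * np.pi * area / perimeter**2, 1.05)
    compactness = min(area / float(props.area_convex), 1.0)

    # color: footprint means per band
    per_band = stack.pixels[:, region.mask].mean(axis=1)
    color_means = [
        per_band[_nearest_band(stack.wavelengths, t)] for t in COLOR_BANDS_NM
    ]
    lab = _lab_from_band_means(stack.wavelengths, per_band)

    # binary: holes of the pre-fill mask (4-connected background pockets)
    holes = region.mask & ~region.mask_prefill
    _, hole_count = ndimage.label(holes, structure=ndimage.generate_binary_structure(2, 1))

    if ncda_model is not None:
        transformed = apply_ncda(ncda_model, stack)
        damaged = region.mask & (transformed > ncda_model.damage_threshold)
        damaged_fraction = float(damaged.sum()) / area
        patches = sk_label(damaged, connectivity=2)
        patch_count = float(patches.max())
    else:
        damaged_fraction = 0.0
        patch_count = 0.0

    values = np.array(
        [
            area,
            perimeter,
            length,
            width,
            length / width,
            circularity,
            compactness,
            *color_means,
            *lab,
            float(hole_count),
            damaged_fraction,
            patch_count,
        ]
    )
    return FeatureVector(values=values, ncda_available=ncda_model is not None)


def mean_spectrum(
    groups: dict[int, list[tuple[SpectralStack, SeedRegion]]],
) -> pd.DataFrame:
    """Per-class mean reflectance at each wavelength over footprint pixels.

    Rows are damage classes, columns wavelengths.  The mean is over the
    pooled pixels of all seeds in a class, i.e. an area-weighted mean of
    per-seed spectra.
    """
    if not groups:
        raise ValueError("no groups supplied")
    wavelengths: np.ndarray | None = None
    rows = {}
    for cls, members in groups.items():
        if not members:
            raise ValueError(f"empty group for class {cls}")
        total = None
        n_px = 0
        for stack, region in members:
            if wavelengths is None:
                wavelengths = stack.wavelengths
            elif not np.array_equal(wavelengths, stack.wavelengths):
                raise ValueError("inconsistent wavelength axes across stacks")
            px = stack.pixels[:, region.mask]
            total = px.sum(axis=1) if total is None else total + px.sum(axis=1)
            n_px += px.shape[1]
        rows[cls] = total / n_px
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(wavelengths))
    table.index.name = "damage_class"
    return table.sort_index()
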