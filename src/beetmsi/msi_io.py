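"""Reading, writing and segmenting multiband reflectance stacks.

A :class:`SpectralStack` is the in-memory form of one VideometerLab-style
acquisition: a ``(bands, rows, cols)`` array of percent reflectance together
with the wavelength (nm) of each band.  Stacks are stored on disk as
multi-page TIFFs (one page per band, ascending wavelength) with the
wavelength written both into each page description and into a plain-text
sidecar ``<stem>.wavelengths.txt``, so either source suffices to recover the
band axis.

Segmentation finds individual seeds lying on a uniform dark background:
Otsu's threshold on the band-mean image, 8-connected labelling, small-object
removal, and hole filling of each component's footprint.  The pre-fill mask
is kept alongside the filled one because interior holes are themselves a
damage signature used by the feature extractor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = ["SpectralStack", "SeedRegion", "read_stack", "write_stack", "segment_seeds"]

_WL_DESC_RE = re.compile(r"wavelength_nm\s*=\s*([0-9.]+)")


@dataclass
class SpectralStack:
    """A co-registered multiband reflectance image.

    Parameters
    ----------
    pixels
        ``(n_bands, rows, cols)`` float array of reflectance in percent,
        values in ``[0, 100]``.
    wavelengths
        One wavelength (nm) per band, ascending.
    """

    pixels: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if not np.issubdtype(self.pixels.dtype, np.floating):
            self.pixels = self.pixels.astype(np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (bands, rows, cols)")
        if self.pixels.shape[0] != self.wavelengths.shape[0]:
            raise ValueError(
                f"{self.pixels.shape[0]} bands but "
                f"{self.wavelengths.shape[0]} wavelengths"
            )
        if np.any(~np.isfinite(self.pixels)):
            raise ValueError("non-finite pixel data")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 100):
            raise ValueError("reflectance must lie in [0, 100] percent")

    @property
    def n_bands(self) -> int:
        return self.pixels.shape[0]

    @property
    def resolution(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    def band_mean_image(self) -> np.ndarray:
        """Mean reflectance over bands; the segmentation working image."""
        return self.pixels.mean(axis=0)


@dataclass
class SeedRegion:
    """One segmented seed footprint within a stack.

    ``mask`` is the hole-filled footprint; ``mask_prefill`` retains interior
    holes so binary features can count them.  The bounding box is the tight
    box of ``mask``, 0-based, half-open.
    """

    region_id: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    mask_prefill: np.ndarray | None = None
    area: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.area = int(self.mask.sum())
        if self.area == 0:
            raise ValueError("empty seed region")
        rows = np.any(self.mask, axis=1)
        cols = np.any(self.mask, axis=0)
        r0, r1 = np.flatnonzero(rows)[[0, -1]]
        c0, c1 = np.flatnonzero(cols)[[0, -1]]
        tight = (int(r0), int(c0), int(r1) + 1, int(c1) + 1)
        if tuple(self.bbox) != tight:
            raise ValueError(f"bbox {self.bbox} is not the tight box {tight}")
        if self.mask_prefill is None:
            self.mask_prefill = self.mask.copy()
        else:
            self.mask_prefill = np.asarray(self.mask_prefill, dtype=bool)


def write_stack(path: str | Path, stack: SpectralStack) -> Path:
    """Write a stack as a multi-page TIFF plus wavelength sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with tifffile.TiffWriter(path) as tw:
        for band, wl in zip(stack.pixels, stack.wavelengths):
            tw.write(
                band.astype(np.float32),
                description=f"wavelength_nm={wl:g}",
                contiguous=False,
            )
    sidecar = path.with_suffix(".wavelengths.txt")
    sidecar.write_text("".join(f"{wl:g}\n" for wl in stack.wavelengths))
    return path


def _read_sidecar(path: Path) -> np.ndarray | None:
    sidecar = path.with_suffix(".wavelengths.txt")
    if not sidecar.exists():
        return None
    vals = [float(line) for line in sidecar.read_text().split()]
    return np.asarray(vals, dtype=np.float64)


def read_stack(path: str | Path) -> SpectralStack:
    """Read a multi-page TIFF stack, returning bands in ascending wavelength.

    Wavelengths come from the per-page descriptions when present, otherwise
    from the sidecar (in on-disk page order).  Pages are re-sorted by
    wavelength, so a file whose pages were shuffled still reads back in
    canonical band order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages: list[np.ndarray] = []
    page_wls: list[float | None] = []
    with tifffile.TiffFile(path) as tf:
        for page in tf.pages:
            arr = np.asarray(page.asarray())
            if not np.issubdtype(arr.dtype, np.number):
                raise ValueError(f"non-numeric pixel data in {path}")
            pages.append(arr)
            desc = page.description or ""
            m = _WL_DESC_RE.search(desc)
            page_wls.append(float(m.group(1)) if m else None)

    if all(w is not None for w in page_wls) and page_wls:
        wavelengths = np.asarray(page_wls, dtype=np.float64)
    else:
        sidecar = _read_sidecar(path)
        if sidecar is None:
            raise ValueError(f"no wavelength metadata for {path}")
        if len(sidecar) != len(pages):
            raise ValueError(
                f"{len(pages)} pages but {len(sidecar)} wavelengths listed"
            )
        wavelengths = sidecar
    if len(wavelengths) != len(pages):
        raise ValueError(f"{len(pages)} pages but {len(wavelengths)} wavelengths")

    order = np.argsort(wavelengths, kind="stable")
    pixels = np.stack([pages[i] for i in order], axis=0)
    return SpectralStack(pixels=pixels, wavelengths=wavelengths[order])


def segment_seeds(stack: SpectralStack, min_area: int = 50) -> list[SeedRegion]:
    """Segment individual seeds from a stack.

    Thresholds the band-mean image by Otsu's criterion, labels 8-connected
    foreground components, discards components smaller than ``min_area``,
    and fills interior holes for the footprint mask (the pre-fill mask is
    kept on the region).  Regions are ordered by bounding-box (row0, col0).

    Returns an empty list when nothing survives — a blank image is not an
    error.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    mean_img = stack.band_mean_image()
    if np.ptp(mean_img) == 0:  # uniform image: no threshold exists
        return []
    thr = threshold_otsu(mean_img)
    fg = mean_img > thr
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    labels, n = ndimage.label(fg, structure=structure)
    regions: list[SeedRegion] = []
    for lab in range(1, n + 1):
        prefill = labels == lab
        if int(prefill.sum()) < min_area:
            continue
        filled = ndimage.binary_fill_holes(prefill)
        rows = np.any(filled, axis=1)
        cols = np.any(filled, axis=0)
        r0, r1 = np.flatnonzero(rows)[[0, -1]]
        c0, c1 = np.flatnonzero(cols)[[0, -1]]
        regions.append(
            SeedRegion(
                region_id=0,
                mask=filled,
                bbox=(int(r0), int(c0), int(r1) + 1, int(c1) + 1),
                mask_prefill=prefill,
            )
        )
    regions.sort(key=lambda r: (r.bbox[0], r.bbox[1]))
    for i, reg in enumerate(regions):
        reg.region_id = i
    return regions
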