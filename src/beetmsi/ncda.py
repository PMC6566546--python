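"""Pixel-level normalized canonical discriminant analysis (nCDA).

Learns the linear band combination maximizing the ratio of between-class to
within-class variance of labelled pixel spectra — the leading solution of
the generalized eigenproblem  S_B w = λ S_W w  — and applies it to a stack
to produce a single-band "damage" image.  The projection is normalized to
[0, 1] by an affine map of the 1st/99th percentiles of the projected
training pixels, which is robust to outlier pixels; a damage threshold on
that normalized scale (midpoint of the extreme class means) supports the
binary damaged-area features.

The model is serialized as a plain-text key-value (YAML) file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import linalg

from .msi_io import SpectralStack

__all__ = ["NCDAModel", "fit_ncda", "apply_ncda", "save_ncda", "load_ncda"]

#: ridge factor for the within-class scatter, scaled by trace/n_bands
RIDGE_EPS = 1e-6
MIN_PIXELS_PER_CLASS = 20


@dataclass(frozen=True)
class NCDAModel:
    """Fitted discriminant direction with its normalization constants."""

    weights: np.ndarray       # unit-norm, one coefficient per band
    band_means: np.ndarray    # per-band mean of training pixels
    norm_low: float           # 1st percentile of projected training pixels
    norm_high: float          # 99th percentile
    damage_threshold: float   # on the normalized [0, 1] scale

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(
            self, "band_means", np.asarray(self.band_means, dtype=float)
        )
        if not np.isclose(np.linalg.norm(w), 1.0, atol=1e-8):
            raise ValueError("weights must have unit Euclidean norm")
        if not self.norm_low < self.norm_high:
            raise ValueError("norm_low must be < norm_high")

    @property
    def n_bands(self) -> int:
        return self.weights.size


def fit_ncda(
    pixels: np.ndarray, labels: np.ndarray
) -> NCDAModel:
    """Fit the leading canonical discriminant direction on labelled pixels.

    Parameters
    ----------
    pixels
        ``(n_pixels, n_bands)`` reflectance vectors.
    labels
        One integer class label per pixel; at least two classes, at least
        20 pixels each.

    Notes
    -----
    The within-class scatter is regularized as
    ``S_W + eps * trace(S_W)/n_bands * I`` with ``eps = 1e-6`` so the
    generalized eigenproblem stays solvable for strongly correlated bands.
    The sign is fixed so the highest-labelled class has the highest mean
    projection (damage reads bright).
    """
    X = np.asarray(pixels, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("pixels must be (n_pixels, n_bands) matching labels")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("nCDA requires at least two pixel classes")
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < MIN_PIXELS_PER_CLASS]
    if small:
        raise ValueError(
            f"classes {small} have fewer than {MIN_PIXELS_PER_CLASS} pixels"
        )

    n_bands = X.shape[1]
    grand_mean = X.mean(axis=0)
    Xc = X - grand_mean
    S_W = np.zeros((n_bands, n_bands))
    S_B = np.zeros((n_bands, n_bands))
    for c in classes:
        Xk = Xc[y == c]
        mu_k = Xk.mean(axis=0)
        D = Xk - mu_k
        S_W += D.T @ D
        S_B += Xk.shape[0] * np.outer(mu_k, mu_k)
    tr = np.trace(S_W)
    if tr <= 0:
        raise ValueError("degenerate training pixels: zero within-class scatter")
    S_W_reg = S_W + RIDGE_EPS * tr / n_bands * np.eye(n_bands)

    eigvals, eigvecs = linalg.eigh(S_B, S_W_reg)
    w = eigvecs[:, np.argmax(eigvals)]
    w = w / np.linalg.norm(w)

    # sign convention: highest label projects highest
    proj_means = {c: float((Xc[y == c] @ w).mean()) for c in classes}
    if proj_means[classes.max()] < proj_means[classes.min()]:
        w = -w

    proj = Xc @ w
    norm_low, norm_high = np.percentile(proj, [1.0, 99.0])
    if norm_high <= norm_low:  # nearly constant projections
        raise ValueError("degenerate training pixels: constant projection")

    lo_mean = (proj_means[classes.min()] - norm_low) / (norm_high - norm_low)
    hi_mean = (proj_means[classes.max()] - norm_low) / (norm_high - norm_low)
    threshold = float((lo_mean + hi_mean) / 2.0)

    return NCDAModel(
        weights=w,
        band_means=grand_mean,
        norm_low=float(norm_low),
        norm_high=float(norm_high),
        damage_threshold=threshold,
    )


def apply_ncda(model: NCDAModel, stack: SpectralStack) -> np.ndarray:
    """Project a stack onto the discriminant direction, normalized to [0, 1].

    Each pixel's band vector is centered on the training means, projected on
    the weights, affinely mapped so ``norm_low → 0`` and ``norm_high → 1``,
    and clipped.  Output shape equals the stack's spatial shape.
    """
    if stack.n_bands != model.n_bands:
        raise ValueError(
            f"stack has {stack.n_bands} bands, model expects {model.n_bands}"
        )
    flat = stack.pixels.reshape(stack.n_bands, -1).T - model.band_means
    proj = flat @ model.weights
    out = (proj - model.norm_low) / (model.norm_high - model.norm_low)
    return np.clip(out, 0.0, 1.0).reshape(stack.resolution)


def save_ncda(model: NCDAModel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "weights": [float(v) for v in model.weights],
        "band_means": [float(v) for v in model.band_means],
        "norm_low": model.norm_low,
        "norm_high": model.norm_high,
        "damage_threshold": model.damage_threshold,
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def load_ncda(path: str | Path) -> NCDAModel:
    payload = yaml.safe_load(Path(path).read_text())
    return NCDAModel(
        weights=np.asarray(payload["weights"], dtype=float),
        band_means=np.asarray(payload["band_means"], dtype=float),
        norm_low=float(payload["norm_low"]),
        norm_high=float(payload["norm_high"]),
        damage_threshold=float(payload["damage_threshold"]),
    )
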