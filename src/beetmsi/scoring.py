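"""Factor-analytic scoring and score-range classification.

The calibration feature table is standardized (zero mean, unit SD per
variable), a principal-component factor extraction is run on its
correlation matrix, and the leading factor's loadings are rescaled into
*scoring coefficients* — weights that produce unit-variance scores on the
calibration set.  Validation seeds are scored by the same linear
combination of their standardized features.

Each damage class then gets a score range: mean ± sample SD of its
calibration scores, with a contiguity correction — classes are ordered by
ascending mean score, and where adjacent provisional ranges overlap or
leave a gap, the lower class's upper bound becomes the upper class's lower
bound, so the five ranges tile an interval.  A seed side is classified by
the range containing its score (outermost ranges extended to ±∞ so
classification is total); the seed's class is the more severe of its
ventral and dorsal side classes.  The severity-max rule makes class 1 —
the only class accepted for pelleting — deliberately conservative: a seed
is called undamaged only when *both* sides look undamaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FEATURE_NAMES

__all__ = [
    "ScoringModel",
    "ClassRange",
    "ClassificationResult",
    "fit_scoring_model",
    "score_seeds",
    "derive_class_ranges",
    "ranges_from_stats",
    "classify_side",
    "classify_pair",
    "save_scoring",
    "load_scoring",
]


@dataclass(frozen=True)
class ScoringModel:
    """Standardization constants plus leading-factor scoring coefficients."""

    feature_names: tuple[str, ...]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    scoring_coefficients: np.ndarray
    n_factors_retained: int  # eigenvalue > 1 count, diagnostics only

    def __post_init__(self) -> None:
        for attr in ("feature_means", "feature_sds", "scoring_coefficients"):
            object.__setattr__(
                self, attr, np.asarray(getattr(self, attr), dtype=float)
            )
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        k = len(self.feature_names)
        if not (
            self.feature_means.shape
            == self.feature_sds.shape
            == self.scoring_coefficients.shape
            == (k,)
        ):
            raise ValueError("inconsistent model vector lengths")
        if np.any(self.feature_sds <= 0):
            raise ValueError("feature SDs must all be > 0")


@dataclass(frozen=True)
class ClassRange:
    """Score interval [low, high) owned by one damage class (last class
    closed at the top; outermost bounds treated as ±∞ when classifying)."""

    damage_class: int
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 1 <= self.damage_class <= 5:
            raise ValueError("damage_class must be 1..5")
        if not self.low < self.high:
            raise ValueError("range must satisfy low < high")


@dataclass
class ClassificationResult:
    seed_id: int
    variety_id: int
    ventral_score: float
    dorsal_score: float
    predicted_class: int
    true_class: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.predicted_class <= 5:
            raise ValueError("predicted_class must be 1..5")


def _feature_matrix(table: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    missing = [n for n in names if n not in table.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    return table.loc[:, list(names)].to_numpy(dtype=float)


def fit_scoring_model(
    calibration: pd.DataFrame,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    class_column: str = "true_class",
) -> ScoringModel:
    """Fit standardization constants and scoring coefficients.

    Factor extraction is the principal-component method on the correlation
    matrix of the standardized calibration features; the leading factor's
    eigenvector ``v1`` with eigenvalue ``λ1`` gives scoring coefficients
    ``v1 / sqrt(λ1)``, so calibration scores ``Z @ v1/sqrt(λ1)`` have
    variance exactly 1 ("united variance").  The sign is fixed so the
    class-5 calibration mean score exceeds the class-1 mean (damage scores
    high); without class labels the convention falls back to a positive
    coefficient sum.
    """
    X = _feature_matrix(calibration, feature_names)
    n = X.shape[0]
    if n < 2:
        raise ValueError("calibration needs at least 2 seeds")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dead = [name for name, s in zip(feature_names, sds) if s <= 0]
    if dead:
        raise ValueError(f"zero-variance feature(s): {dead}")
    Z = (X - means) / sds

    corr = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    lam1 = eigvals[0]
    if lam1 <= 0:
        raise ValueError("degenerate correlation matrix")
    coeffs = eigvecs[:, 0] / np.sqrt(lam1)
    n_retained = int((eigvals > 1.0).sum())

    scores = Z @ coeffs
    if class_column in calibration.columns:
        cls = calibration[class_column].to_numpy()
        if (cls == 5).any() and (cls == 1).any():
            if scores[cls == 5].mean() < scores[cls == 1].mean():
                coeffs = -coeffs
    elif coeffs.sum() < 0:
        coeffs = -coeffs

    return ScoringModel(
        feature_names=tuple(feature_names),
        feature_means=means,
        feature_sds=sds,
        scoring_coefficients=coeffs,
        n_factors_retained=n_retained,
    )


def score_seeds(model: ScoringModel, features: pd.DataFrame) -> pd.DataFrame:
    """Score seed sides: Σ coeff · (feature − calib mean)/calib SD.

    Returns the identifying columns present in the input (seed_id,
    variety_id, side, true_class) plus a ``score`` column.  Extra feature
    columns beyond the model's set are an error, as is any missing one.
    """
    id_cols = [c for c in ("seed_id", "variety_id", "side", "true_class") if c in features.columns]
    extra = [
        c
        for c in features.columns
        if c not in model.feature_names and c not in id_cols
    ]
    if extra:
        raise ValueError(f"unexpected feature columns: {extra}")
    X = _feature_matrix(features, model.feature_names)
    Z = (X - model.feature_means) / model.feature_sds
    out = features.loc[:, id_cols].copy()
    out["score"] = Z @ model.scoring_coefficients
    return out


def derive_class_ranges(
    scores: np.ndarray | list[float], classes: np.ndarray | list[int]
) -> list[ClassRange]:
    """Per-class score ranges: mean ± sample SD, with contiguity correction.

    Classes are ordered by ascending mean score; each class's provisional
    range is [mean − SD, mean + SD] (SD with n−1 denominator).  Overlaps or
    gaps between adjacent ranges are corrected by setting the upper class's
    lower bound to the lower class's upper bound, so the returned ranges
    tile an interval.  Requires all five classes, each with ≥ 2 seeds;
    tied class means are an error (no defensible order exists).
    """
    s = np.asarray(scores, dtype=float)
    c = np.asarray(classes, dtype=int)
    if s.shape != c.shape:
        raise ValueError("scores and classes must align")
    present = sorted(set(c.tolist()))
    if present != [1, 2, 3, 4, 5]:
        raise ValueError(f"need all 5 classes, got {present}")
    stats = {}
    for cls in present:
        vals = s[c == cls]
        if vals.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 seeds")
        stats[cls] = (float(vals.mean()), float(vals.std(ddof=1)))
    return ranges_from_stats(stats)


def ranges_from_stats(stats: dict[int, tuple[float, float]]) -> list[ClassRange]:
    """Apply the mean ± SD rule plus contiguity correction to per-class
    (mean, SD) statistics.  Exposed separately so the correction rule can
    be exercised on hand-built two-class cases."""
    ordered = sorted(stats, key=lambda k: stats[k][0])
    means = [stats[k][0] for k in ordered]
    if len(set(means)) != len(means):
        raise ValueError("tied class mean scores: ordering is ambiguous")

    ranges: list[ClassRange] = []
    prev_high: float | None = None
    for cls in ordered:
        m, sd = stats[cls]
        low, high = m - sd, m + sd
        if prev_high is not None:
            low = prev_high  # contiguity correction (gap or overlap)
        if not low < high:
            raise ValueError(
                f"class {cls} range collapsed after contiguity correction"
            )
        ranges.append(ClassRange(damage_class=cls, low=low, high=high))
        prev_high = high
    return ranges


def classify_side(
    ranges: list[ClassRange], score: float, *, extend: bool = True
) -> int | None:
    """Map one side score to a damage class by its range.

    With ``extend`` (default) the outermost ranges act as if extended to
    ±∞ so every score classifies; otherwise out-of-range scores are
    rejected (``None``).
    """
    if not ranges:
        raise ValueError("no ranges")
    if score < ranges[0].low:
        return ranges[0].damage_class if extend else None
    for r in ranges[:-1]:
        if r.low <= score < r.high:
            return r.damage_class
    last = ranges[-1]
    if last.low <= score <= last.high:
        return last.damage_class
    return last.damage_class if extend else None


def classify_pair(
    ranges: list[ClassRange],
    ventral_score: float,
    dorsal_score: float,
    *,
    extend: bool = True,
) -> int | None:
    """Classify a seed from its two side scores.

    Each side maps to a class; the seed takes the more severe (numerically
    larger) side class, so class 1 is assigned only when both sides fall in
    the class-1 range.  Returns None only in reject mode when either side
    is out of range.
    """
    v = classify_side(ranges, ventral_score, extend=extend)
    d = classify_side(ranges, dorsal_score, extend=extend)
    if v is None or d is None:
        return None
    return max(v, d)


def save_scoring(
    model: ScoringModel, ranges: list[ClassRange], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "feature_names": list(model.feature_names),
        "feature_means": [float(v) for v in model.feature_means],
        "feature_sds": [float(v) for v in model.feature_sds],
        "scoring_coefficients": [float(v) for v in model.scoring_coefficients],
        "n_factors_retained": model.n_factors_retained,
        "class_ranges": [
            {"damage_class": r.damage_class, "low": r.low, "high": r.high}
            for r in ranges
        ],
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def load_scoring(path: str | Path) -> tuple[ScoringModel, list[ClassRange]]:
    payload = yaml.safe_load(Path(path).read_text())
    model = ScoringModel(
        feature_names=tuple(payload["feature_names"]),
        feature_means=payload["feature_means"],
        feature_sds=payload["feature_sds"],
        scoring_coefficients=payload["scoring_coefficients"],
        n_factors_retained=int(payload["n_factors_retained"]),
    )
    ranges = [
        ClassRange(int(r["damage_class"]), float(r["low"]), float(r["high"]))
        for r in payload["class_ranges"]
    ]
    return model, ranges
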