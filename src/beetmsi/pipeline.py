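"""End-to-end pipeline: simulate → transform → features → train → classify
→ evaluate, with every stage boundary a file on disk.

Each stage reads only on-disk intermediates and writes its own outputs, so
any stage can be re-run in isolation and reproduces the full-run results
bit for bit.  The working directory after a full run contains::

    calibration/ , validation/   stacks (TIFF), masks, tissue maps,
                                 ground_truth.csv
    ncda.yaml                    pixel discriminant model
    features_calibration.csv     19 variables + ids per seed side
    features_validation.csv
    scoring.yaml                 scoring model + class score ranges
    scores_calibration.csv
    results.csv                  per-seed classification
    report.txt / report.csv      misclassification table and rates

Randomness: one integer seed in the config; the calibration and validation
sets, the pixel subsample for the discriminant fit, and all rendering noise
derive from it through independent seed-sequence spawns.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import msi_io, ncda, scoring, synthetic_seeds
from .evaluation import EvaluationReport, evaluate
from .features import FEATURE_NAMES, extract_features
from .msi_io import SeedRegion, read_stack, segment_seeds, write_stack
from .scoring import ClassificationResult
from .synthetic_seeds import (
    TISSUE_CODES,
    SimulationConfig,
    make_default_profiles,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "stage_simulate",
    "stage_ncda",
    "stage_features",
    "stage_train",
    "stage_classify",
    "stage_evaluate",
]

log = logging.getLogger("beetmsi.pipeline")

#: tissue roles whose pixels count as intact surface vs damage-exposed
#: interior when training the pixel discriminant
_INTACT_ROLES = ("pericarp", "outer_testa")
_EXPOSED_ROLES = ("inner_testa", "embryo")


@dataclass(frozen=True)
class PipelineConfig:
    """One config drives a full run; every output header records rng_seed."""

    workdir: str | Path = "pipeline_run"
    n_calibration_per_class: int = 60
    n_validation_per_class: int = 40
    n_varieties: int = 18
    noise_sd: float = 1.0
    variety_color_shift_sd: float = 0.15
    image_size: tuple[int, int] = (72, 72)
    min_area: int = 50
    pixels_per_stack: int = 150   # nCDA training subsample per stack
    reject_out_of_range: bool = False
    rng_seed: int = 0

    def sim_config(self, role: str) -> SimulationConfig:
        """Simulation conditions for the calibration or validation set."""
        if role == "calibration":
            n, offset = self.n_calibration_per_class, 1
        elif role == "validation":
            n, offset = self.n_validation_per_class, 2
        else:
            raise ValueError(role)
        sub_seed = int(
            np.random.SeedSequence(
                entropy=self.rng_seed, spawn_key=(offset,)
            ).generate_state(1)[0] % (2**31)
        )
        return SimulationConfig(
            n_seeds_per_class=n,
            n_varieties=self.n_varieties,
            image_size=self.image_size,
            noise_sd=self.noise_sd,
            variety_color_shift_sd=self.variety_color_shift_sd,
            rng_seed=sub_seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "image_size" in payload:
            payload["image_size"] = tuple(payload["image_size"])
        return cls(**payload)


def _workdir(config: PipelineConfig) -> Path:
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    return wd


def _stamp(config: PipelineConfig) -> str:
    return f"# rng_seed={config.rng_seed}\n"


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        df.to_csv(fh, index=False)


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def stage_simulate(config: PipelineConfig) -> None:
    """Render calibration and validation sets to disk.

    The same class spectral profiles underlie both sets (they are the
    "true" tissue optics); the two sets differ in seeds, noise draws and
    variety color shifts.
    """
    wd = _workdir(config)
    profiles = make_default_profiles(config.rng_seed)
    for role in ("calibration", "validation"):
        sim = config.sim_config(role)
        out = wd / role
        out.mkdir(parents=True, exist_ok=True)
        stacks, records = synthetic_seeds.generate_dataset(sim, profiles)
        rows = []
        for stack, rec in zip(stacks, records):
            stem = f"seed{rec.seed_id:04d}_{rec.side}"
            write_stack(out / f"{stem}.tif", stack)
            tifffile.imwrite(out / f"{stem}_mask.tif", rec.mask.astype(np.uint8))
            tifffile.imwrite(
                out / f"{stem}_tissue.tif", rec.tissue_map.astype(np.int8)
            )
            rows.append(
                {
                    "seed_id": rec.seed_id,
                    "variety_id": rec.variety_id,
                    "side": rec.side,
                    "true_class": rec.true_class,
                    "stack": f"{stem}.tif",
                }
            )
        _write_table(pd.DataFrame(rows), out / "ground_truth.csv", config)
        log.info("simulated %s: %d stacks", role, len(rows))


def stage_ncda(config: PipelineConfig) -> ncda.NCDAModel:
    """Fit the pixel discriminant from calibration tissue maps.

    Pixels are labelled intact surface (pericarp, outer testa) vs
    damage-exposed interior (inner testa, embryo); a fixed-size subsample
    per stack keeps the fit fast.  The damage threshold stored with the
    model is the midpoint between the per-damage-class mean transformed
    footprint values of the extreme calibration classes.
    """
    wd = _workdir(config)
    cal = wd / "calibration"
    gt = _read_table(cal / "ground_truth.csv")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(3,))
    )
    intact_codes = [TISSUE_CODES[r] for r in _INTACT_ROLES]
    exposed_codes = [TISSUE_CODES[r] for r in _EXPOSED_ROLES]
    pixels, labels = [], []
    for row in gt.itertuples():
        stack = read_stack(cal / row.stack)
        tissue = tifffile.imread(cal / f"{Path(row.stack).stem}_tissue.tif")
        flat = stack.pixels.reshape(stack.n_bands, -1).T
        tflat = np.asarray(tissue).ravel()
        for codes, lab in ((intact_codes, 0), (exposed_codes, 1)):
            idx = np.flatnonzero(np.isin(tflat, codes))
            if idx.size == 0:
                continue
            take = min(config.pixels_per_stack, idx.size)
            chosen = rng.choice(idx, size=take, replace=False)
            pixels.append(flat[chosen])
            labels.append(np.full(take, lab))
    X = np.concatenate(pixels)
    y = np.concatenate(labels)
    model = ncda.fit_ncda(X, y)

    # damage threshold: midpoint between the two lowest per-class mean
    # transformed footprint values — i.e. between the least-damaged
    # calibration class and its nearest neighbour, so "damaged" means any
    # surface beyond class-1-typical abrasion
    class_means: dict[int, list[float]] = {}
    for row in gt.itertuples():
        stack = read_stack(cal / row.stack)
        mask = tifffile.imread(cal / f"{Path(row.stack).stem}_mask.tif").astype(bool)
        img = ncda.apply_ncda(model, stack)
        class_means.setdefault(row.true_class, []).append(float(img[mask].mean()))
    per_class = sorted(float(np.mean(v)) for v in class_means.values())
    model = dataclasses.replace(
        model, damage_threshold=(per_class[0] + per_class[1]) / 2.0
    )

    ncda.save_ncda(model, wd / "ncda.yaml")
    log.info(
        "nCDA fitted on %d pixels; damage threshold %.3f", len(y), model.damage_threshold
    )
    return model


def _segment_one(stack, min_area: int) -> SeedRegion:
    regions = segment_seeds(stack, min_area=min_area)
    if not regions:
        raise RuntimeError("no seed found in stack")
    return max(regions, key=lambda r: r.area)


def stage_features(config: PipelineConfig, role: str) -> pd.DataFrame:
    """Segment each stack and extract the 19 variables per seed side."""
    wd = _workdir(config)
    sub = wd / role
    gt = _read_table(sub / "ground_truth.csv")
    model = ncda.load_ncda(wd / "ncda.yaml")
    rows = []
    for row in gt.itertuples():
        stack = read_stack(sub / row.stack)
        region = _segment_one(stack, config.min_area)
        fv = extract_features(stack, region, model)
        rec = {
            "seed_id": row.seed_id,
            "variety_id": row.variety_id,
            "side": row.side,
            "true_class": row.true_class,
        }
        rec.update(fv.as_dict())
        rows.append(rec)
    table = pd.DataFrame(rows)
    _write_table(table, wd / f"features_{role}.csv", config)
    log.info("extracted features for %d %s seed sides", len(rows), role)
    return table


def stage_train(config: PipelineConfig) -> tuple[scoring.ScoringModel, list[scoring.ClassRange]]:
    """Fit the scoring model and per-class score ranges on calibration."""
    wd = _workdir(config)
    table = _read_table(wd / "features_calibration.csv")
    model = scoring.fit_scoring_model(table)
    scored = scoring.score_seeds(model, table)
    ranges = scoring.derive_class_ranges(
        scored["score"].to_numpy(), scored["true_class"].to_numpy()
    )
    scoring.save_scoring(model, ranges, wd / "scoring.yaml")
    _write_table(scored, wd / "scores_calibration.csv", config)
    log.info(
        "scoring model trained; class ranges %s",
        [(r.damage_class, round(r.low, 2), round(r.high, 2)) for r in ranges],
    )
    return model, ranges


def stage_classify(config: PipelineConfig) -> pd.DataFrame:
    """Score validation seed sides and classify each ventral/dorsal pair."""
    wd = _workdir(config)
    model, ranges = scoring.load_scoring(wd / "scoring.yaml")
    table = _read_table(wd / "features_validation.csv")
    scored = scoring.score_seeds(model, table)
    wide = scored.pivot_table(
        index=["seed_id", "variety_id", "true_class"],
        columns="side",
        values="score",
    ).reset_index()
    rows = []
    for row in wide.itertuples():
        pred = scoring.classify_pair(
            ranges,
            row.ventral,
            row.dorsal,
            extend=not config.reject_out_of_range,
        )
        rows.append(
            {
                "seed_id": row.seed_id,
                "variety_id": row.variety_id,
                "ventral_score": row.ventral,
                "dorsal_score": row.dorsal,
                "predicted_class": pred,
                "true_class": row.true_class,
            }
        )
    results = pd.DataFrame(rows)
    _write_table(results, wd / "results.csv", config)
    log.info("classified %d seeds", len(results))
    return results


def stage_evaluate(config: PipelineConfig) -> EvaluationReport:
    """Cross-tabulate results into the misclassification report."""
    wd = _workdir(config)
    table = _read_table(wd / "results.csv")
    results = [
        ClassificationResult(
            seed_id=int(r.seed_id),
            variety_id=int(r.variety_id),
            ventral_score=float(r.ventral_score),
            dorsal_score=float(r.dorsal_score),
            predicted_class=int(r.predicted_class),
            true_class=int(r.true_class),
        )
        for r in table.itertuples()
    ]
    report = evaluate(results)
    (wd / "report.txt").write_text(_stamp(config) + report.render() + "\n")
    with open(wd / "report.csv", "w") as fh:
        fh.write(_stamp(config))
        report.to_frame().to_csv(fh)
    log.info("overall accuracy %.1f%%", float(report.overall_accuracy))
    return report


_STAGES = (
    ("simulate", stage_simulate),
    ("ncda", stage_ncda),
    ("features_calibration", lambda c: stage_features(c, "calibration")),
    ("features_validation", lambda c: stage_features(c, "validation")),
    ("train", stage_train),
    ("classify", stage_classify),
    ("evaluate", stage_evaluate),
)


def run_pipeline(config: PipelineConfig) -> EvaluationReport:
    """Run all stages in order; deterministic given ``config.rng_seed``."""
    report = None
    for name, fn in _STAGES:
        t0 = time.perf_counter()
        try:
            out = fn(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
        if name == "evaluate":
            report = out
    assert report is not None
    return report
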