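"""Synthetic multispectral sugar-beet seed imagery with known damage class.

Polished monogerm beet seeds are classified into five mechanical-damage
classes by what the abrasive polishing step exposed:

1. pericarp / outer testa partially broken, inner testa intact;
2. pericarp and outer testa completely broken, intact inner testa exposed
   over (nearly) the whole surface;
3. fractured pericarp and outer testa, inner testa partially crushed,
   embryo sound;
4. partially broken pericarp / outer testa with a damaged inner testa,
   embryo intact;
5. embryo severely damaged or absent.

The generator renders each seed side as an ellipse of pericarp in which
angular sectors of deeper tissue are exposed, with per-tissue reflectance
spectra over the 19 instrument wavelengths (375–970 nm).  Spectra are
designed with little between-tissue contrast in the visible region and most
of the contrast in the NIR, the structure observed in real beet-seed
multispectral data.  Each seed has a ventral and a dorsal rendering; seeds
belong to varieties that carry a small constant per-band color shift.

Everything is deterministic given the configured RNG seed, so every
downstream stage (segmentation, discriminant transform, feature scoring,
classification) can be tested against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .msi_io import SpectralStack

__all__ = [
    "DEFAULT_WAVELENGTHS",
    "TISSUE_CODES",
    "DamageGeometry",
    "ClassSpectralProfile",
    "SimulationConfig",
    "GroundTruthRecord",
    "make_default_profiles",
    "render_seed",
    "generate_dataset",
]

#: The 19 LED wavelengths (nm) of the imaging instrument, ascending.
DEFAULT_WAVELENGTHS: tuple[float, ...] = (
    375, 405, 435, 450, 470, 505, 525, 570, 590, 630,
    645, 660, 700, 780, 850, 870, 890, 940, 970,
)

#: Integer codes used in tissue maps.
TISSUE_CODES: dict[str, int] = {
    "background": 0,
    "pericarp": 1,
    "outer_testa": 2,
    "inner_testa": 3,
    "embryo": 4,
}

_CODE_TO_TISSUE = {v: k for k, v in TISSUE_CODES.items()}

#: NIR spectral ramp: fraction of the visible→NIR transition completed at
#: each wavelength.  The rise happens between 660 and 940 nm, so bands at
#: 780 nm and above carry most of the between-tissue contrast.
def _nir_ramp(wavelengths: np.ndarray) -> np.ndarray:
    return np.clip((wavelengths - 660.0) / (940.0 - 660.0), 0.0, 1.0)


@dataclass(frozen=True)
class DamageGeometry:
    """How much of each layer the polishing damage removed or crushed.

    ``pericarp_removed_frac`` of the seed footprint exposes deeper tissue;
    within it, ``inner_testa_crushed_frac`` of the footprint is crushed
    through to the embryo (or to the collapsed interior when the embryo is
    absent).  ``exposure_role`` names the tissue visible where only the
    pericarp was rubbed off: ``outer_testa`` for mild class-1 abrasion,
    ``inner_testa`` once the outer testa is broken through.
    """

    pericarp_removed_frac: float
    inner_testa_crushed_frac: float
    embryo_present: bool
    embryo_damage_frac: float
    exposure_role: str = "inner_testa"
    #: fractured-edge chips and deep fracture pits; counts grow with
    #: severity, making damaged seeds visibly misshapen and pitted
    n_edge_chips: int = 0
    n_pits: int = 0
    #: the exposed area fragments into this many disjoint patches
    n_damage_sectors: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.pericarp_removed_frac <= 1.0:
            raise ValueError("pericarp_removed_frac outside [0, 1]")
        if not 0.0 <= self.inner_testa_crushed_frac <= 1.0:
            raise ValueError("inner_testa_crushed_frac outside [0, 1]")
        if self.inner_testa_crushed_frac > self.pericarp_removed_frac + 1e-12:
            raise ValueError("crushed fraction cannot exceed removed fraction")
        if self.exposure_role not in ("outer_testa", "inner_testa"):
            raise ValueError(f"unknown exposure_role {self.exposure_role!r}")


@dataclass(frozen=True)
class ClassSpectralProfile:
    """Per-class tissue spectra plus damage-geometry parameters."""

    damage_class: int
    tissue_spectra: dict[str, np.ndarray]
    damage_geometry: DamageGeometry
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_WAVELENGTHS, dtype=float)
    )

    def __post_init__(self) -> None:
        if not 1 <= self.damage_class <= 5:
            raise ValueError("damage_class must be 1..5")
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        spectra = {}
        for role in TISSUE_CODES:
            if role not in self.tissue_spectra:
                raise ValueError(f"missing tissue spectrum for {role!r}")
            s = np.asarray(self.tissue_spectra[role], dtype=float)
            if s.shape != wl.shape:
                raise ValueError(f"{role} spectrum length != wavelength count")
            if s.min() < 0 or s.max() > 100:
                raise ValueError(f"{role} reflectance outside [0, 100]")
            spectra[role] = s
        object.__setattr__(self, "tissue_spectra", spectra)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the study layout: 60 seeds per class (300 seeds,
    600 stacks counting both sides), 18 varieties, additive Gaussian
    reflectance noise of 1 % SD, and a per-variety pericarp color shift of
    0.15 % SD.  The pixel scale is 10 px/mm, giving elliptical seeds of
    3.5–4.75 mm equivalent diameter inside a 72×72 px frame.
    """

    n_seeds_per_class: int = 60
    n_varieties: int = 18
    image_size: tuple[int, int] = (72, 72)
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
    noise_sd: float = 1.0
    variety_color_shift_sd: float = 0.15
    damage_jitter_sd: float = 0.01
    px_per_mm: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        wl = tuple(float(w) for w in self.wavelengths)
        object.__setattr__(self, "wavelengths", wl)
        if len(wl) < 2 or any(b <= a for a, b in zip(wl, wl[1:])):
            raise ValueError("wavelengths must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_seeds_per_class < 1 or self.n_varieties < 1:
            raise ValueError("counts must be positive")


@dataclass
class GroundTruthRecord:
    """Exact per-pixel truth for one rendered seed side."""

    seed_id: int
    variety_id: int
    side: str
    true_class: int
    mask: np.ndarray
    tissue_map: np.ndarray

    def __post_init__(self) -> None:
        if self.side not in ("ventral", "dorsal"):
            raise ValueError("side must be ventral or dorsal")
        self.mask = np.asarray(self.mask, dtype=bool)
        self.tissue_map = np.asarray(self.tissue_map, dtype=np.int8)
        fg = self.tissue_map != TISSUE_CODES["background"]
        if not np.array_equal(self.mask, fg):
            raise ValueError("mask must equal the non-background tissue pixels")


def _build_spectrum(
    vis: float, nir: float, wavelengths: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """A tissue reflectance curve: a nearly flat visible region with a small
    upward tilt, rising along the NIR ramp to the tissue's NIR plateau, plus
    a tiny fixed per-band texture so curves are not perfectly smooth."""
    ramp = _nir_ramp(wavelengths)
    tilt = 1.2 * np.clip((wavelengths - 375.0) / (660.0 - 375.0), 0.0, 1.0)
    spectrum = vis + tilt * (1.0 - ramp) + (nir - vis) * ramp
    spectrum = spectrum + rng.normal(0.0, 0.12, size=wavelengths.shape)
    return np.clip(spectrum, 0.0, 100.0)


# (visible level %, NIR plateau %) per tissue.  The corky pericarp is
# bright in the visible; exposed interior tissues are slightly darker in
# the visible but strongly reflective in the NIR, so the damage ladder
# lives almost entirely above 700 nm (little visible diversity) and the
# band-mean image stays nearly uniform across the seed — which keeps
# global-threshold segmentation robust.
_BASE_LEVELS = {
    "background": (3.0, 3.0),
    "pericarp": (32.0, 40.0),
    "outer_testa": (30.0, 46.0),
    "inner_testa": (29.5, 50.0),
    "embryo": (30.0, 60.0),
}

# Exposed interior tissue reads progressively brighter in NIR with damage
# severity; per-class overrides of the inner-testa / embryo levels encode
# that (crushed or collapsed tissue compacts and brightens).
_CLASS_TISSUE_OVERRIDES: dict[int, dict[str, tuple[float, float]]] = {
    3: {"inner_testa": (27.5, 66.0)},
    4: {"inner_testa": (24.0, 90.0), "embryo": (28.0, 78.0)},
    5: {"inner_testa": (27.0, 88.0)},
}

# Damage-geometry parameters per class: (removed, crushed, embryo_present,
# embryo_damage, exposure_role, edge chips, pits, damage sectors).
# Classes 2/3 and 3/4 sit close together on purpose — real class-2 vs
# class-3 damage differs by very small surface fractures.
_CLASS_GEOMETRY = {
    1: (0.10, 0.00, True, 0.0, "outer_testa", 0, 0, 1),
    2: (0.97, 0.00, True, 0.0, "inner_testa", 1, 1, 1),
    3: (0.85, 0.35, True, 0.0, "inner_testa", 2, 2, 2),
    4: (0.80, 0.70, True, 0.0, "inner_testa", 4, 4, 3),
    5: (0.95, 0.85, False, 1.0, "inner_testa", 6, 6, 4),
}


def make_default_profiles(rng_seed: int = 0) -> list[ClassSpectralProfile]:
    """Build the five default class profiles.

    Class 5 is the embryo-absent variant: its interior collapsed during
    polishing, so crushed regions expose bright desiccated inner-testa
    material (rendered under the ``inner_testa`` role with an elevated
    spectrum) and no embryo tissue appears at all.
    """
    rng = np.random.default_rng(rng_seed)
    wl = np.asarray(DEFAULT_WAVELENGTHS, dtype=float)
    profiles = []
    for cls in range(1, 6):
        (
            removed,
            crushed,
            embryo_present,
            embryo_damage,
            role,
            chips,
            pits,
            sectors,
        ) = _CLASS_GEOMETRY[cls]
        levels = dict(_BASE_LEVELS)
        levels.update(_CLASS_TISSUE_OVERRIDES.get(cls, {}))
        spectra = {
            name: _build_spectrum(v, n, wl, rng) for name, (v, n) in levels.items()
        }
        profiles.append(
            ClassSpectralProfile(
                damage_class=cls,
                tissue_spectra=spectra,
                damage_geometry=DamageGeometry(
                    pericarp_removed_frac=removed,
                    inner_testa_crushed_frac=crushed,
                    embryo_present=embryo_present,
                    embryo_damage_frac=embryo_damage,
                    exposure_role=role,
                    n_edge_chips=chips,
                    n_pits=pits,
                    n_damage_sectors=sectors,
                ),
                wavelengths=wl,
            )
        )
    return profiles


def _ellipse_params(rng: np.random.Generator, config: SimulationConfig):
    """Seed footprint: an ellipse drawn from a sieve-graded commercial
    size window (4.0–4.5 mm equivalent diameter, within the 3.5–4.75 mm
    range of polished monogerm seed)."""
    d_mm = rng.uniform(4.0, 4.5)
    a = d_mm * config.px_per_mm / 2.0
    b = a * rng.uniform(0.80, 0.90)
    theta = rng.uniform(0.0, np.pi)
    return a, b, theta


def render_seed(
    profile: ClassSpectralProfile,
    side: str,
    variety_shift: np.ndarray,
    config: SimulationConfig,
    seed_id: int,
    rng: np.random.Generator,
    *,
    variety_id: int = 0,
    axes: tuple[float, float, float] | None = None,
) -> tuple[SpectralStack, GroundTruthRecord]:
    """Render one seed side as a spectral stack plus exact ground truth.

    The damage geometry is drawn as angular sectors of the ellipse (sector
    area is exactly proportional to parametric angle, so exposed-area
    fractions are honoured): a crushed core sector exposing embryo (or the
    collapsed interior), a surrounding sector of exposed testa, pericarp
    elsewhere.  Severity fractions are jittered per side by
    ``damage_jitter_sd``.  Fracture pits — tiny background-dark spots inside
    the damaged area — appear for classes with crushed or fully broken
    surfaces and become interior holes after segmentation.
    """
    rows, cols = config.image_size
    wl = np.asarray(config.wavelengths, dtype=float)
    if wl.shape != profile.wavelengths.shape or not np.allclose(
        wl, profile.wavelengths
    ):
        raise ValueError("config wavelengths do not match profile")

    if axes is None:
        a, b, theta = _ellipse_params(rng, config)
    else:
        a, b, theta = axes
    if 2 * a + 4 > min(rows, cols):
        raise ValueError(
            f"image_size {config.image_size} too small for a seed of "
            f"major axis {2 * a:.0f} px"
        )

    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    yy, xx = np.mgrid[0:rows, 0:cols]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a   # ellipse frame, unit circle coords
    v = (-dx * st + dy * ct) / b
    rho2 = u**2 + v**2
    footprint = rho2 <= 1.0

    geom = profile.damage_geometry

    # fractured-edge chips: shallow angular bites out of the rim, so
    # heavily damaged seeds are visibly misshapen
    t_all = np.mod(np.arctan2(v, u), 2 * np.pi)
    for _ in range(geom.n_edge_chips):
        t_chip = rng.uniform(0.0, 2 * np.pi)
        half_w = rng.uniform(0.18, 0.24)
        depth = rng.uniform(0.07, 0.10)
        ang = np.abs(np.mod(t_all - t_chip + np.pi, 2 * np.pi) - np.pi)
        footprint &= ~((ang < half_w) & (rho2 > (1.0 - depth) ** 2))
    jit = rng.normal(0.0, config.damage_jitter_sd, size=2)
    removed = float(np.clip(geom.pericarp_removed_frac + jit[0], 0.0, 1.0))
    crushed = float(np.clip(geom.inner_testa_crushed_frac + jit[1], 0.0, removed))

    # parametric angle: an angular interval of width 2π·f covers exactly
    # the area fraction f of the ellipse.  The exposed area is split over
    # n_damage_sectors disjoint sectors separated by intact gaps, so the
    # damaged surface fragments into a class-typical number of patches.
    t = np.mod(np.arctan2(v, u), 2 * np.pi)
    t0 = rng.uniform(0.0, 2 * np.pi)
    frac = np.mod(t - t0, 2 * np.pi) / (2 * np.pi)

    k = max(1, geom.n_damage_sectors)
    sector_w = removed * rng.dirichlet(np.ones(k))
    gap_w = (1.0 - removed) * rng.dirichlet(np.ones(k))
    widths = np.empty(2 * k)
    widths[0::2], widths[1::2] = sector_w, gap_w
    edges = np.concatenate([[0.0], np.cumsum(widths)])
    idx = np.clip(np.searchsorted(edges, frac, side="right") - 1, 0, 2 * k - 1)

    tissue_map = np.zeros((rows, cols), dtype=np.int8)
    tissue_map[footprint] = TISSUE_CODES["pericarp"]
    exposed = footprint & (idx % 2 == 0) & (removed > 0)
    tissue_map[exposed] = TISSUE_CODES[geom.exposure_role]
    # crushed: the leading portion of each sector, totalling the crushed
    # fraction exactly
    crush_share = crushed / removed if removed > 0 else 0.0
    rel = frac - edges[idx]
    crushed_px = exposed & (rel < crush_share * widths[idx])
    crush_role = "embryo" if geom.embryo_present else "inner_testa"
    tissue_map[crushed_px] = TISSUE_CODES[crush_role]
    # severely damaged (but present) embryo: the innermost portion of each
    # crushed sector reads brighter than sound embryo tissue
    damaged_embryo = (
        crushed_px & (rel < crush_share * geom.embryo_damage_frac * widths[idx])
        if geom.embryo_present and geom.embryo_damage_frac > 0
        else np.zeros_like(footprint)
    )

    # deep fracture pits: small background-dark spots strictly inside the
    # damaged area, so they read as interior holes (never boundary
    # notches) after segmentation; count grows with damage severity
    n_pits = geom.n_pits + (int(rng.integers(0, 2)) if geom.n_pits else 0)
    if n_pits and exposed.any():
        interior = exposed & (rho2 <= 0.7**2)
        er, ec = np.nonzero(interior)
        placed: list[tuple[int, int]] = []
        for _ in range(n_pits):
            if er.size == 0:
                break
            for _try in range(10):  # keep pits apart so holes stay distinct
                k = rng.integers(0, er.size)
                pr, pc = int(er[k]), int(ec[k])
                if all((pr - q) ** 2 + (pc - r) ** 2 > 36 for q, r in placed):
                    break
            placed.append((pr, pc))
            rad = rng.uniform(1.0, 1.6)
            pit = (yy - pr) ** 2 + (xx - pc) ** 2 <= rad**2
            tissue_map[pit & footprint] = TISSUE_CODES["background"]

    mask = tissue_map != TISSUE_CODES["background"]

    pixels = np.empty((wl.size, rows, cols), dtype=np.float64)
    shift = np.asarray(variety_shift, dtype=float).reshape(-1)
    if shift.size != wl.size:
        raise ValueError("variety_shift length must equal band count")
    for code, role in _CODE_TO_TISSUE.items():
        sel = tissue_map == code
        if not sel.any():
            continue
        spec = profile.tissue_spectra[role].copy()
        if role != "background":
            spec = spec + shift
        pixels[:, sel] = np.clip(spec, 0.0, 100.0)[:, None]
    if damaged_embryo.any():
        spec = profile.tissue_spectra["embryo"] * 1.15 + shift
        pixels[:, damaged_embryo] = np.clip(spec, 0.0, 100.0)[:, None]
    if config.noise_sd > 0:
        pixels += rng.normal(0.0, config.noise_sd, size=pixels.shape)
    # float32 is the canonical on-disk precision; quantize here so a
    # write/read cycle is the exact identity
    pixels = np.clip(pixels, 0.0, 100.0).astype(np.float32)

    stack = SpectralStack(pixels=pixels, wavelengths=wl)
    record = GroundTruthRecord(
        seed_id=seed_id,
        variety_id=variety_id,
        side=side,
        true_class=profile.damage_class,
        mask=mask,
        tissue_map=tissue_map,
    )
    return stack, record


def generate_dataset(
    config: SimulationConfig,
    profiles: list[ClassSpectralProfile] | None = None,
) -> tuple[list[SpectralStack], list[GroundTruthRecord]]:
    """Generate ``n_seeds_per_class × 5`` seeds, two sides each.

    Seeds are assigned round-robin to varieties; each variety carries a
    fixed per-band color shift drawn with SD ``variety_color_shift_sd``.
    Output order is by seed id, ventral before dorsal.  Fully reproducible
    from ``config.rng_seed``.
    """
    if profiles is None:
        profiles = make_default_profiles(config.rng_seed)
    by_class = {p.damage_class: p for p in profiles}
    master = np.random.SeedSequence(config.rng_seed)
    shift_rng = np.random.default_rng(master.spawn(1)[0])
    n_bands = len(config.wavelengths)
    shifts = shift_rng.normal(
        0.0, config.variety_color_shift_sd, size=(config.n_varieties, n_bands)
    )

    stacks: list[SpectralStack] = []
    records: list[GroundTruthRecord] = []
    seed_id = 0
    for cls in sorted(by_class):
        profile = by_class[cls]
        for _ in range(config.n_seeds_per_class):
            variety = seed_id % config.n_varieties
            seed_rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=config.rng_seed, spawn_key=(1, seed_id)
                )
            )
            axes = _ellipse_params(seed_rng, config)  # shared by both sides
            for side in ("ventral", "dorsal"):
                stack, rec = render_seed(
                    profile,
                    side,
                    shifts[variety],
                    config,
                    seed_id,
                    seed_rng,
                    variety_id=variety,
                    axes=axes,
                )
                stacks.append(stack)
                records.append(rec)
            seed_id += 1
    return stacks, records
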