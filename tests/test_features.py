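"""The 19-variable extractor and per-class mean spectra."""

import numpy as np
import pytest

from beetmsi.features import (
    FEATURE_NAMES,
    extract_features,
    mean_spectrum,
)
from beetmsi.msi_io import SeedRegion, SpectralStack, segment_seeds
from beetmsi.ncda import fit_ncda
from beetmsi.synthetic_seeds import TISSUE_CODES

from conftest import render_single


def disc_stack(radius=50, pad=10, value=60.0, n_bands=3):
    size = 2 * (radius + pad)
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2
    pixels = np.full((n_bands, size, size), 5.0)
    pixels[:, mask] = value
    stack = SpectralStack(pixels=pixels, wavelengths=list(range(400, 400 + n_bands)))
    return stack, mask


def region_from_mask(mask, prefill=None):
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return SeedRegion(
        region_id=0,
        mask=mask,
        bbox=(int(r0), int(c0), int(r1) + 1, int(c1) + 1),
        mask_prefill=prefill,
    )


class TestExtractFeatures:
    def test_has_all_19_named_values(self, small_dataset):
        stacks, records = small_dataset
        fv = extract_features(stacks[0], region_from_mask(records[0].mask))
        assert len(FEATURE_NAMES) == 19
        assert tuple(fv.as_series().index) == FEATURE_NAMES

    def test_disc_geometry(self):
        stack, mask = disc_stack(radius=50)
        fv = extract_features(stack, region_from_mask(mask)).as_dict()
        assert fv["circularity"] == pytest.approx(1.0, rel=0.02)
        assert fv["aspect_ratio"] == pytest.approx(1.0, rel=0.02)
        assert fv["area"] == pytest.approx(np.pi * 50**2, rel=0.02)

    def test_hole_count_from_prefill_mask(self):
        stack, mask = disc_stack(radius=20, pad=5)
        prefill = mask.copy()
        prefill[24:27, 24:27] = False  # one interior hole
        fv = extract_features(stack, region_from_mask(mask, prefill)).as_dict()
        assert fv["hole_count"] == 1

    def test_translation_invariance(self):
        pixels = np.full((3, 60, 60), 4.0)
        pixels[:, 10:30, 8:26] = 55.0
        stack_a = SpectralStack(pixels=pixels, wavelengths=[400, 500, 600])
        shifted = np.full((3, 60, 60), 4.0)
        shifted[:, 30:50, 30:48] = 55.0
        stack_b = SpectralStack(pixels=shifted, wavelengths=[400, 500, 600])
        fa = extract_features(stack_a, region_from_mask(pixels[0] > 10))
        fb = extract_features(stack_b, region_from_mask(shifted[0] > 10))
        np.testing.assert_allclose(fa.values, fb.values, rtol=1e-12)

    def test_area_perimeter_scaling(self):
        """Integer upscaling by s multiplies area by s² and perimeter by s
        within discretization tolerance (rectangle: upscaling is exact
        geometry, so only estimator discretization error remains)."""
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:20, 8:26] = True
        pixels = np.full((3, 30, 30), 5.0)
        pixels[:, mask] = 60.0
        stack = SpectralStack(pixels=pixels, wavelengths=[400, 500, 600])
        fv1 = extract_features(stack, region_from_mask(mask)).as_dict()
        s = 3
        big = np.kron(mask, np.ones((s, s), dtype=bool))
        pixels_b = np.full((3, *big.shape), 5.0)
        pixels_b[:, big] = 60.0
        stack_b = SpectralStack(pixels=pixels_b, wavelengths=[400, 500, 600])
        fv2 = extract_features(stack_b, region_from_mask(big)).as_dict()
        assert fv2["area"] == pytest.approx(fv1["area"] * s**2, rel=0.05)
        assert fv2["perimeter"] == pytest.approx(fv1["perimeter"] * s, rel=0.05)

    def test_without_ncda_model_binary_features_zero(self):
        stack, mask = disc_stack()
        fv = extract_features(stack, region_from_mask(mask))
        assert not fv.ncda_available
        d = fv.as_dict()
        assert d["damaged_area_fraction"] == 0.0
        assert d["damaged_patch_count"] == 0.0

    def test_class2_damaged_fraction_exceeds_class1(self, profiles):
        """Class 2 ('completely broken' pericarp) shows a strictly larger
        damaged-area fraction than class 1 under the fitted transform."""
        s1, r1 = render_single(profiles[0], rng_seed=31)
        s2, r2 = render_single(profiles[1], rng_seed=32)
        X, y = [], []
        for stack, rec in ((s1, r1), (s2, r2)):
            flat = stack.pixels.reshape(stack.n_bands, -1).T
            tis = rec.tissue_map.ravel()
            intact = np.isin(tis, [TISSUE_CODES["pericarp"], TISSUE_CODES["outer_testa"]])
            exposed = np.isin(tis, [TISSUE_CODES["inner_testa"], TISSUE_CODES["embryo"]])
            X.extend([flat[intact], flat[exposed]])
            y.extend([np.zeros(intact.sum()), np.ones(exposed.sum())])
        model = fit_ncda(np.vstack(X), np.concatenate(y))
        f1 = extract_features(s1, region_from_mask(r1.mask), model).as_dict()
        f2 = extract_features(s2, region_from_mask(r2.mask), model).as_dict()
        assert f2["damaged_area_fraction"] > f1["damaged_area_fraction"]

    def test_empty_region_raises(self):
        stack, mask = disc_stack(radius=10, pad=4)
        with pytest.raises(ValueError, match="empty"):
            SeedRegion(region_id=0, mask=np.zeros_like(mask), bbox=(0, 0, 0, 0))

    def test_region_outside_stack_raises(self):
        stack, mask = disc_stack(radius=10, pad=4)
        region = region_from_mask(mask)
        small = SpectralStack(
            pixels=np.zeros((3, 8, 8)), wavelengths=[400, 500, 600]
        )
        with pytest.raises(ValueError):
            extract_features(small, region)


class TestMeanSpectrum:
    def test_uniform_seed_gives_constant_row(self):
        stack, mask = disc_stack(value=40.0)
        table = mean_spectrum({1: [(stack, region_from_mask(mask))]})
        np.testing.assert_allclose(table.loc[1].to_numpy(), 40.0)

    def test_equal_area_seeds_average(self):
        s20, m = disc_stack(value=20.0)
        s60, _ = disc_stack(value=60.0)
        table = mean_spectrum(
            {1: [(s20, region_from_mask(m)), (s60, region_from_mask(m))]}
        )
        np.testing.assert_allclose(table.loc[1].to_numpy(), 40.0)

    def test_merged_group_is_area_weighted_mean(self):
        big, mb = disc_stack(radius=40, value=30.0)
        small, ms = disc_stack(radius=20, pad=30, value=60.0)
        ta = mean_spectrum({1: [(big, region_from_mask(mb))]})
        tb = mean_spectrum({1: [(small, region_from_mask(ms))]})
        merged = mean_spectrum(
            {1: [(big, region_from_mask(mb)), (small, region_from_mask(ms))]}
        )
        na, nb = mb.sum(), ms.sum()
        expected = (ta.loc[1] * na + tb.loc[1] * nb) / (na + nb)
        np.testing.assert_allclose(merged.loc[1].to_numpy(), expected.to_numpy())

    def test_synthetic_classes_spread_more_in_nir(self, small_dataset):
        stacks, records = small_dataset
        groups = {}
        for stack, rec in zip(stacks, records):
            regions = segment_seeds(stack)
            region = max(regions, key=lambda r: r.area)
            groups.setdefault(rec.true_class, []).append((stack, region))
        table = mean_spectrum(groups)
        wl = np.array(table.columns, dtype=float)
        spread = table.max(axis=0) - table.min(axis=0)
        assert spread[wl >= 780].mean() > spread[wl <= 700].mean()
        assert table.to_numpy().min() >= 0 and table.to_numpy().max() <= 100

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty"):
            mean_spectrum({2: []})
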