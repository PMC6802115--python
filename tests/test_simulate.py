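"""Generators: CSR, dimer fields, FFO filaments, sheets, observation model."""

import math
from dataclasses import replace

import numpy as np
import pytest

from ffosheet import (
    Box,
    add_localization_noise,
    dominant_period,
    filament_width,
    power_spectrum,
    render_striation_image,
    simulate_csr,
    simulate_dimer_field,
    simulate_ffo,
    simulate_sheet,
    thin_detection,
)


def pair_distances(coords):
    """Within-dimer label distances for interleaved pair layout."""
    return np.linalg.norm(coords[0::2] - coords[1::2], axis=1)


class TestCSR:
    def test_empty_and_deterministic(self, slab_box):
        assert len(simulate_csr(0, slab_box, 0)) == 0
        a = simulate_csr(500, slab_box, 42).coords
        b = simulate_csr(500, slab_box, 42).coords
        assert np.array_equal(a, b)

    def test_mean_within_3se_of_box_center(self):
        box = Box.from_extent((1000.0, 1000.0, 1000.0))
        pts = simulate_csr(10_000, box, 7).coords
        se = box.extent / np.sqrt(12.0) / np.sqrt(10_000)
        assert np.all(np.abs(pts.mean(axis=0) - box.center) < 3 * se)


class TestDimerField:
    def test_within_pair_distance_is_exactly_11nm(self, params, slab_box):
        pat = simulate_dimer_field(400, slab_box, params, 1)
        assert len(pat) == 800
        assert np.allclose(pair_distances(pat.coords), 11.0, atol=1e-9)

    def test_pair_axis_lies_in_the_membrane_plane(self, params, slab_box):
        pat = simulate_dimer_field(100, slab_box, params, 2)
        dz = pat.coords[0::2, 2] - pat.coords[1::2, 2]
        assert np.allclose(dz, 0.0, atol=1e-12)

    def test_nn_distance_concentrates_at_11nm_in_sparse_box(self, params):
        # sparse: ~1000 dimers in an 8 µm square slab, so the nearest
        # neighbour of nearly every label is its dimer partner
        from scipy.spatial import cKDTree

        box = Box.from_extent((8000.0, 8000.0, 10.0))
        pat = simulate_dimer_field(1000, box, params, 3)
        d, _ = cKDTree(pat.coords).query(pat.coords, k=2)
        frac_at_11 = np.mean(np.abs(d[:, 1] - 11.0) < 0.5)
        assert frac_at_11 > 0.95


class TestFFO:
    def test_centre_spacing_is_5nm_and_single_dimer_reduces(self, params):
        pat = simulate_ffo(10, (0, 0, 0), (1, 0), params)
        centers = 0.5 * (pat.coords[0::2] + pat.coords[1::2])
        gaps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        assert np.allclose(gaps, 5.0, atol=1e-9)
        single = simulate_ffo(1, (0, 0, 0), (0, 1), params)
        assert len(single) == 2
        assert np.linalg.norm(single.coords[0] - single.coords[1]) == pytest.approx(11.0)

    def test_label_envelope_follows_the_tilt_projection(self, params):
        pat = simulate_ffo(50, (0, 0, 0), (1, 0), params)
        # perpendicular (y) extent of the labels: the 11 nm pair projected
        # through the 40 degree tilt
        extent = pat.coords[:, 1].max() - pat.coords[:, 1].min()
        assert extent == pytest.approx(11.0 * math.sin(math.radians(40.0)), rel=1e-9)

    def test_zero_axis_is_an_error(self, params):
        with pytest.raises(ValueError, match="nonzero"):
            simulate_ffo(3, (0, 0, 0), (0, 0), params)


class TestFilamentWidth:
    def test_crystal_defaults_give_about_14nm(self, params):
        assert filament_width(params) == pytest.approx(22.0 * math.sin(math.radians(40.0)))
        assert round(filament_width(params)) == 14

    def test_projection_limits(self, params):
        assert filament_width(replace(params, tilt_deg=90.0)) == pytest.approx(22.0)
        assert filament_width(replace(params, tilt_deg=1e-6)) == pytest.approx(0.0, abs=1e-5)


class TestSheet:
    def test_sheet_fraction_of_labels_within_one_dimer(self, params, slab_box):
        n = 5000
        pat = simulate_sheet(n, slab_box, params, 0)
        n_sheet = int(np.sum(pat.labels == "sheet"))
        assert len(pat) == n
        assert abs(n_sheet - 0.4 * n) <= 2  # rounding to whole dimers

    def test_zero_fraction_reduces_to_pure_dimer_field(self, params, slab_box):
        pat = simulate_sheet(1000, slab_box, replace(params, sheet_fraction=0.0), 1)
        assert np.all(pat.labels == "free")
        assert np.allclose(pair_distances(pat.coords), 11.0, atol=1e-9)

    def test_ground_truth_labels_stay_within_a_half_dimer_of_the_box(self, params,
                                                                     slab_box):
        # dimer centres are uniform in the box, so a label can overhang by at
        # most half the pair separation; sheet-patch labels are fully inside
        pat = simulate_sheet(4000, slab_box, params, 2)
        margin = params.dimer_label_distance / 2.0
        grown = Box(slab_box.lo - margin, slab_box.hi + margin)
        assert np.all(grown.contains(pat.coords))
        assert np.all(slab_box.contains(pat.coords[pat.labels == "sheet"]))

    def test_within_pair_distance_holds_for_sheet_and_free(self, params, slab_box):
        for alignment in ("parallel", "antiparallel"):
            pat = simulate_sheet(2000, slab_box, replace(params, alignment=alignment), 3)
            assert np.allclose(pair_distances(pat.coords), 11.0, atol=1e-9)

    def test_patch_too_large_for_box_is_an_error(self, params):
        tiny = Box.from_extent((100.0, 100.0, 100.0))
        with pytest.raises(ValueError, match="larger box"):
            simulate_sheet(100_000, tiny, params, 0)

    def test_odd_label_count_rejected(self, params, slab_box):
        with pytest.raises(ValueError, match="even"):
            simulate_sheet(101, slab_box, params, 0)


class TestObservationModel:
    def test_thinning_limits(self, params, slab_box):
        pat = simulate_dimer_field(200, slab_box, params, 0)
        assert len(thin_detection(pat, 0.0, 1)) == 0
        kept = thin_detection(pat, 1.0, 1)
        assert np.array_equal(kept.coords, pat.coords)

    def test_thinning_count_is_binomial(self, params, slab_box):
        pat = simulate_csr(10_000, slab_box, 1)
        kept = len(thin_detection(pat, 0.1, 2))
        sd = math.sqrt(10_000 * 0.1 * 0.9)
        assert abs(kept - 1000) < 3 * sd

    def test_sequential_thinning_composes_multiplicatively(self, params, slab_box):
        pat = simulate_csr(2000, slab_box, 0)
        p, q = 0.5, 0.6
        seeds = np.random.SeedSequence(9).spawn(50)
        counts = [
            len(thin_detection(thin_detection(pat, p, s.spawn(1)[0]), q, s))
            for s in seeds
        ]
        se = math.sqrt(2000 * p * q * (1 - p * q) / 50)
        assert abs(np.mean(counts) - 2000 * p * q) < 3 * se

    def test_noise_sd_matches_accuracy_within_5pct(self, params, slab_box):
        pat = simulate_csr(10_000, slab_box, 3)
        noisy = add_localization_noise(pat, params, 4)
        disp = noisy.coords - pat.coords
        sd = disp.std(axis=0, ddof=1)
        assert sd[0] == pytest.approx(20.0, rel=0.05)
        assert sd[1] == pytest.approx(20.0, rel=0.05)
        assert sd[2] == pytest.approx(40.0, rel=0.05)

    def test_zero_accuracy_is_identity_and_count_conserved(self, slab_box, params):
        pat = simulate_dimer_field(100, slab_box, params, 5)
        silent = add_localization_noise(pat, replace(params, accuracy_xy=0.0), 6)
        assert np.array_equal(silent.coords, pat.coords)
        noisy = add_localization_noise(pat, params, 7)
        assert len(noisy) == len(pat)

    def test_generators_are_bitwise_reproducible(self, params, slab_box):
        for make in (
            lambda s: simulate_csr(300, slab_box, s).coords,
            lambda s: simulate_dimer_field(150, slab_box, params, s).coords,
            lambda s: simulate_sheet(600, slab_box, params, s).coords,
            lambda s: thin_detection(simulate_csr(300, slab_box, 0), 0.5, s).coords,
            lambda s: add_localization_noise(simulate_csr(300, slab_box, 0), params, s).coords,
        ):
            assert np.array_equal(make(11), make(11))


class TestStriationImage:
    def test_empty_patch_is_all_zero(self, params):
        img = render_striation_image(params, 128, 0.5, n_dimers=0)
        assert img.shape == (128, 128)
        assert np.all(img == 0)

    def test_nyquist_violation_is_an_error(self, params):
        with pytest.raises(ValueError, match="Nyquist"):
            render_striation_image(params, 128, 3.0)

    def test_autocorrelation_first_peak_at_the_5nm_pitch(self, params):
        from scipy.signal import find_peaks

        img = np.asarray(render_striation_image(params, 512, 0.5), dtype=float)
        profile = img.sum(axis=0) - img.sum(axis=0).mean()
        ac = np.correlate(profile, profile, "full")[len(profile) - 1:]
        peaks, _ = find_peaks(ac)
        assert peaks[0] * 0.5 == pytest.approx(5.0, abs=0.5)

    def test_doubling_spacing_doubles_the_measured_pitch(self, params):
        periods = []
        for s in (5.0, 10.0):
            p = replace(params, intra_filament_spacing=s)
            img = render_striation_image(p, 512, 0.5)
            res = dominant_period(power_spectrum(img, 0.5), (0.6 * s, 1.5 * s))
            periods.append(res.period)
        assert periods[1] / periods[0] == pytest.approx(2.0, rel=0.02)
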