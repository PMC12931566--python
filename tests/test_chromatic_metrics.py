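"""Channel metrics, perilesional normalization, residuals, and reports."""

import itertools

import numpy as np
import pytest

from polychromia import (
    ChannelEntropies,
    DeltaTriple,
    ROIMask,
    RGBImage,
    build_lesion_report,
    channel_entropies,
    compare_reports,
    melanoma_preset,
    nevus_preset,
    normalize_to_perilesional,
    pairwise_deltas,
    polychromia_index,
    red_asymmetry,
    render_scene,
    residual_difference,
    residual_percent,
    roi_chromatic_metrics,
)


def image_from_channels(r, g, b):
    return RGBImage(
        red=np.array(r, dtype=np.uint8).reshape(2, 2),
        green=np.array(g, dtype=np.uint8).reshape(2, 2),
        blue=np.array(b, dtype=np.uint8).reshape(2, 2),
    )


FULL = ROIMask(np.ones((2, 2), dtype=bool), "lesional")


class TestChannelEntropies:
    def test_constant_color_image(self, constant_image, full_mask):
        e = channel_entropies(constant_image(), full_mask((2, 2)))
        assert e.as_tuple() == (0.0, 0.0, 0.0)

    def test_permuted_channels_share_entropy(self):
        img = image_from_channels([3, 1, 4, 1], [1, 4, 1, 3], [0, 0, 0, 0])
        e = channel_entropies(img, FULL)
        assert e.h_r == e.h_g

    def test_hand_computed_channel_multisets(self):
        # R={0,0,128,255}->1.5 bits; G constant->0; B={0,255,0,255}->1 bit
        img = image_from_channels([0, 0, 128, 255], [7, 7, 7, 7], [0, 255, 0, 255])
        e = channel_entropies(img, FULL)
        assert e.h_r == pytest.approx(1.5, abs=1e-12)
        assert e.h_g == 0.0
        assert e.h_b == pytest.approx(1.0, abs=1e-12)


class TestDerivedMetrics:
    @pytest.mark.parametrize(
        "entropies, deltas",
        [
            ((7.22, 7.31, 7.19), (0.09, 0.03, 0.12)),  # melanoma lesional ROI
            ((6.89, 6.92, 6.88), (0.03, 0.01, 0.04)),  # nevus lesional ROI
            ((5.0, 5.0, 5.0), (0.0, 0.0, 0.0)),
        ],
    )
    def test_pairwise_deltas(self, entropies, deltas):
        d = pairwise_deltas(ChannelEntropies(*entropies))
        assert d.as_tuple() == pytest.approx(deltas, abs=1e-12)

    @pytest.mark.parametrize(
        "entropies, expected",
        [
            ((7.22, 7.31, 7.19), 0.03),
            ((5.0, 5.0, 5.0), 0.0),
            ((1.0, 2.0, 2.0), 1.0),
        ],
    )
    def test_red_asymmetry(self, entropies, expected):
        assert red_asymmetry(ChannelEntropies(*entropies)) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize(
        "deltas, expected",
        [
            ((0.09, 0.03, 0.12), 0.08),
            ((0.03, 0.01, 0.04), 0.08 / 3),  # prints as 0.026
            ((0.0, 0.0, 0.0), 0.0),
        ],
    )
    def test_polychromia_index(self, deltas, expected):
        assert polychromia_index(DeltaTriple(*deltas)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_ip_invariant_under_channel_permutation(self, rng):
        for _ in range(200):
            h = rng.uniform(0, 8, 3)
            ips = {
                round(polychromia_index(pairwise_deltas(ChannelEntropies(*perm))), 12)
                for perm in itertools.permutations(h)
            }
            assert len(ips) == 1

    def test_red_asymmetry_not_permutation_invariant(self):
        e = ChannelEntropies(1.0, 2.0, 3.0)
        swapped = ChannelEntropies(2.0, 1.0, 3.0)  # move the red channel
        assert red_asymmetry(e) != red_asymmetry(swapped)

    def test_triangle_relation_and_ip_bounds(self, rng):
        for _ in range(1000):
            d = pairwise_deltas(ChannelEntropies(*rng.uniform(0, 8, 3)))
            trip = sorted(d.as_tuple())
            assert trip[2] <= trip[0] + trip[1] + 1e-12
            ip = polychromia_index(d)
            assert -1e-12 <= ip <= max(d.as_tuple()) + 1e-12


class TestNormalization:
    def test_entropy_and_mean_subtraction(self):
        # melanoma green entropy 7.31-6.90 and mean green 131.44-109.73
        assert 7.31 - 6.90 == pytest.approx(0.41, abs=1e-12)
        les = roi_chromatic_metrics(
            image_from_channels([0, 0, 128, 255], [7, 7, 7, 7], [0, 255, 0, 255]), FULL
        )
        norm = normalize_to_perilesional(les, les)
        assert norm.entropies.as_tuple() == (0.0, 0.0, 0.0)
        assert norm.deltas.as_tuple() == (0.0, 0.0, 0.0)
        assert norm.a_r == 0.0 and norm.i_p == 0.0
        assert norm.channel_means == (0.0, 0.0, 0.0)
        assert norm.channel_sds == (0.0, 0.0, 0.0)

    def test_normalized_ip_equals_mean_of_signed_normalized_deltas(self, rng):
        img_a = image_from_channels(
            rng.integers(0, 256, 4), rng.integers(0, 256, 4), rng.integers(0, 256, 4)
        )
        img_b = image_from_channels(
            rng.integers(0, 256, 4), rng.integers(0, 256, 4), rng.integers(0, 256, 4)
        )
        les = roi_chromatic_metrics(img_a, FULL)
        per = roi_chromatic_metrics(img_b, FULL)
        norm = normalize_to_perilesional(les, per)
        assert norm.i_p == pytest.approx(
            sum(norm.deltas.as_tuple()) / 3, abs=1e-12
        )


class TestResiduals:
    @pytest.mark.parametrize(
        "mel, nev, expected",
        [
            (9.47, -0.24, 9.71),
            (10.25, -2.06, 12.31),
            (0.34, 0.34, 0.0),
        ],
    )
    def test_residual_difference(self, mel, nev, expected):
        assert residual_difference(mel, nev) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "residual, nev, expected",
        [
            (0.36, -0.02, 1800.0),
            (6.37, 1.16, pytest.approx(549.1, abs=0.05)),
        ],
    )
    def test_residual_percent(self, residual, nev, expected):
        assert residual_percent(residual, nev) == pytest.approx(expected, rel=1e-9)

    def test_zero_reference_is_undefined(self):
        assert residual_percent(1.0, 0.0) is None


class TestLesionReport:
    def test_constant_scene_all_zero(self, constant_image):
        img = constant_image(shape=(4, 4))
        lesional = ROIMask(
            np.pad(np.ones((2, 2), dtype=bool), 1), "lesional"
        )
        perilesional = ROIMask(~lesional.selected, "perilesional")
        report = build_lesion_report(img, lesional, perilesional)
        assert report.lesional.entropies.as_tuple() == (0.0, 0.0, 0.0)
        assert report.lesional.deltas.as_tuple() == (0.0, 0.0, 0.0)
        assert report.lesional.i_p == 0.0
        assert report.normalized.i_p == 0.0

    def test_normalized_block_is_recomputable(self):
        img, les, peri = render_scene(melanoma_preset(7))
        report = build_lesion_report(img, les, peri)
        redo = normalize_to_perilesional(report.lesional, report.perilesional)
        assert report.normalized == redo

    def test_melanoma_preset_has_larger_normalized_ip(self):
        seed = 11
        img_m, les_m, peri_m = render_scene(melanoma_preset(seed))
        img_n, les_n, peri_n = render_scene(nevus_preset(seed))
        rep_m = build_lesion_report(img_m, les_m, peri_m, lesion_id="mel")
        rep_n = build_lesion_report(img_n, les_n, peri_n, lesion_id="nev")
        assert rep_m.normalized.i_p > rep_n.normalized.i_p

    def test_composite_entropy_equals_grayscale_in_mean_dialect(self):
        img, les, peri = render_scene(melanoma_preset(3))
        report = build_lesion_report(img, les, peri)
        assert (
            report.composite_lesional.entropy_bits
            == report.grayscale_lesional.entropy_bits
        )

    def test_stacked_dialect_differs_and_uses_3n(self):
        img, les, peri = render_scene(melanoma_preset(3))
        report = build_lesion_report(img, les, peri, composite_dialect="stacked")
        assert report.options["composite_dialect"] == "stacked"
        # stacked composite mixes three decorrelated channels: entropy needn't
        # match grayscale
        assert (
            report.composite_lesional.entropy_bits
            != report.grayscale_lesional.entropy_bits
        )

    def test_compare_report_with_itself(self):
        img, les, peri = render_scene(nevus_preset(5))
        d = build_lesion_report(img, les, peri).to_dict()
        rows = compare_reports(d, d)
        assert all(row["residual"] == 0.0 for row in rows)
        assert all(
            row["residual_percent"] in (None, 0.0) for row in rows
        )
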