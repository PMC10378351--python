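"""Pair generation, dimension raising, grayscale scaling and PNG I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import survimage as sv
from survimage.imaging import ImagingError, make_image

from conftest import make_manual_cohort, make_tpm_cohort


class TestGeneratePairs:
    def test_five_patient_ordering(self):
        # P00..P04 get decreasing survival, mirroring N1..N5
        cohort = make_manual_cohort([500, 400, 300, 200, 100])
        pairs = sv.generate_pairs(cohort)
        assert len(pairs) == 10
        assert pairs[:4] == [
            ("P00", "P01"), ("P00", "P02"), ("P00", "P03"), ("P00", "P04")
        ]
        assert pairs[4] == ("P01", "P02")

    @pytest.mark.parametrize("n,expected", [(2, 1), (5, 10), (49, 1176)])
    def test_pair_count(self, n, expected):
        cohort = make_manual_cohort(range(100, 100 + 10 * n, 10), n_genes=4)
        assert len(sv.generate_pairs(cohort)) == expected

    def test_orientation_is_longer_first(self):
        cohort = make_manual_cohort([10, 999, 55])
        for longer, shorter in sv.generate_pairs(cohort):
            assert cohort.survival_of(longer) > cohort.survival_of(shorter)

    def test_tied_survival_rejected(self):
        cohort = make_manual_cohort([100, 100, 300])
        with pytest.raises(ImagingError, match="tied"):
            sv.generate_pairs(cohort)


class TestDifferenceVector:
    def test_tls_and_tsl_are_negations(self):
        longer = np.array([5.0, 1.0, 0.0])
        shorter = np.array([2.0, 1.0, 3.0])
        tls = sv.difference_vector(longer, shorter, "TLS")
        tsl = sv.difference_vector(longer, shorter, "TSL")
        np.testing.assert_array_equal(tls, [3, 0, -3])
        np.testing.assert_array_equal(tsl, -tls)

    def test_self_difference_is_zero(self):
        v = np.array([1.0, 2.0])
        for label in ("TLS", "TSL"):
            np.testing.assert_array_equal(sv.difference_vector(v, v, label), [0, 0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ImagingError, match="shapes"):
            sv.difference_vector(np.ones(3), np.ones(4), "TLS")


class TestRaiseDimension:
    def test_three_value_scaling(self):
        pixels, vmin, vmax = sv.raise_dimension(np.array([-3.0, 0.0, 3.0]))
        np.testing.assert_array_equal(pixels, [[0, 128], [255, 0]])
        assert (vmin, vmax) == (-3.0, 3.0)

    def test_constant_vector_maps_to_zero(self):
        pixels, _, _ = sv.raise_dimension(np.full(5, 7.0))
        assert pixels.shape == (3, 3)
        assert not pixels.any()

    def test_full_scale_geometry(self):
        """60,483 genes -> 246x246 with 33 zero trailing cells, minimal side."""
        g = 60_483
        assert sv.matrix_side(g) == 246
        assert 245**2 < g <= 246**2
        rng = np.random.default_rng(0)
        pixels, _, _ = sv.raise_dimension(rng.normal(size=g))
        assert pixels.shape == (246, 246)
        assert not pixels.ravel()[g:].any()
        assert pixels.ravel()[g:].size == 33

    @pytest.mark.parametrize("g,side", [(1, 1), (4, 2), (5, 3), (9, 3), (10, 4)])
    def test_side_is_minimal(self, g, side):
        assert sv.matrix_side(g) == side
        assert (side - 1) ** 2 < g <= side**2

    def test_non_finite_rejected(self):
        with pytest.raises(ImagingError, match="finite"):
            sv.raise_dimension(np.array([1.0, np.nan]))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10**6))
    def test_complement_and_inversion(self, seed):
        """TSL pixels mirror TLS (255 - p) at data cells; stored extremes
        invert the quantization to within half a gray step."""
        rng = np.random.default_rng(seed)
        g = int(rng.integers(2, 40))
        v = rng.normal(scale=rng.lognormal(0, 1), size=g)
        if np.ptp(v) == 0:
            v[0] += 1.0
        tls = make_image(v, np.zeros(g), "TLS", "a", "b")
        tsl = make_image(v, np.zeros(g), "TSL", "a", "b")
        data = np.arange(g)
        assert np.array_equal(
            tsl.pixels.ravel()[data], 255 - tls.pixels.ravel()[data]
        )
        assert not tls.pixels.ravel()[g:].any()
        assert not tsl.pixels.ravel()[g:].any()
        recovered = sv.recover_difference(tls)
        np.testing.assert_allclose(
            recovered, v, atol=(tls.vmax - tls.vmin) / 510 + 1e-12
        )


class TestBuildImageSet:
    def test_count_law_and_balance(self):
        cohort = make_manual_cohort([10, 20, 30])
        images = sv.build_image_set(cohort)
        assert len(images) == 6
        labels = [img.label for img in images]
        assert labels.count("TLS") == labels.count("TSL") == 3

    def test_requires_tpm(self, tpm_cohort):
        fpkm = sv.Cohort(
            records=tpm_cohort.records,
            expression=sv.ExpressionMatrix(
                tpm_cohort.expression.gene_ids,
                tpm_cohort.expression.sample_ids,
                tpm_cohort.expression.values,
                "FPKM",
            ),
        )
        with pytest.raises(ImagingError, match="TPM"):
            sv.build_image_set(fpkm)

    def test_subset_restricts_pairing(self, tpm_cohort):
        ids = tpm_cohort.sample_ids[:3]
        images = sv.build_image_set(tpm_cohort, ids)
        assert len(images) == 6
        seen = {sid for img in images for sid in (img.longer_id, img.shorter_id)}
        assert seen <= set(ids)


class TestPngIO:
    def test_lossless_round_trip(self, tmp_path, tpm_cohort):
        img = sv.build_image_set(tpm_cohort)[0]
        path = tmp_path / img.filename
        sv.write_png(img, path)
        back = sv.read_png(path, expected_side=img.side)
        np.testing.assert_array_equal(back, img.pixels)

    def test_all_zero_round_trip(self, tmp_path):
        img = make_image(np.full(4, 3.0), np.full(4, 3.0), "TLS", "a", "b")
        path = tmp_path / "zero.png"
        sv.write_png(img, path)
        assert not sv.read_png(path).any()

    def test_wrong_dimensions_rejected(self, tmp_path, tpm_cohort):
        img = sv.build_image_set(tpm_cohort)[0]
        path = tmp_path / "img.png"
        sv.write_png(img, path)
        with pytest.raises(ImagingError, match="side"):
            sv.read_png(path, expected_side=img.side + 1)

    def test_manifest_written(self, tmp_path):
        cohort = make_manual_cohort([10, 20, 30])
        images = sv.build_image_set(cohort)
        manifest = sv.write_image_set(images, tmp_path / "imgs")
        assert manifest.exists()
        import json

        entries = json.loads(manifest.read_text())
        assert len(entries) == 6
        assert {e["label"] for e in entries} == {"TLS", "TSL"}
        for e in entries:
            assert (tmp_path / "imgs" / e["file"]).exists()
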