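"""Morphometrics: cell detection/density, nerve length density, diameters, SNR."""

import numpy as np
import pytest

from transocular.phantoms import PhantomSpec, gen_endothelial_mosaic, gen_nerve_layer
from transocular.pipeline import highpass
from transocular.quantify import (
    CellDetections,
    NerveTrace,
    cell_density,
    detect_cells,
    mean_cell_diameter,
    nerve_length_density,
    skeleton_length_mm,
    snr_db,
    trace_nerves,
)


class TestDetectCells:
    def _phantom(self, seed=0, density=3200.0):
        spec = PhantomSpec(seed=seed, cell_density=density)
        img, gt = gen_endothelial_mosaic(spec)
        return spec, highpass(img, 121), gt

    def test_recovers_bright_cell_count(self):
        spec, img, gt = self._phantom()
        det = detect_cells(img, "bright", expected_diameter_um=gt.cell_diameter_um,
                           pixel_pitch=spec.pixel_pitch, mask=gt.bright_mask)
        n_true = int((gt.cell_signs > 0).sum())
        assert abs(len(det) - n_true) <= 0.06 * n_true

    def test_sign_symmetric_on_inverted_image(self):
        spec, img, gt = self._phantom()
        bright = detect_cells(img, "bright", gt.cell_diameter_um,
                              pixel_pitch=spec.pixel_pitch)
        dark_inv = detect_cells(-img, "dark", gt.cell_diameter_um,
                                pixel_pitch=spec.pixel_pitch)
        assert np.array_equal(bright.centers, dark_inv.centers)

    def test_blank_image_no_detections(self):
        det = detect_cells(np.zeros((64, 64)), "bright", 20.0, pixel_pitch=1.0)
        assert len(det) == 0

    def test_affine_intensity_invariance(self):
        spec, img, gt = self._phantom()
        a = detect_cells(img, "bright", gt.cell_diameter_um, pixel_pitch=1.0)
        b = detect_cells(3.0 * img + 17.0, "bright", gt.cell_diameter_um,
                         pixel_pitch=1.0)
        assert np.array_equal(a.centers, b.centers)

    def test_missing_pitch_rejected(self):
        with pytest.raises(ValueError):
            detect_cells(np.zeros((8, 8)), "bright", 20.0, pixel_pitch=None)


class TestCellDensity:
    def test_healthy_endothelium_arithmetic(self):
        d = CellDetections(centers=np.zeros((288, 2)), sign="bright",
                           area_mm2=0.09, pixel_pitch=1.0)
        assert cell_density(d) == pytest.approx(3200.0)

    def test_no_cells(self):
        d = CellDetections(centers=np.zeros((0, 2)), sign="bright",
                           area_mm2=1.0, pixel_pitch=1.0)
        assert cell_density(d) == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            CellDetections(centers=np.zeros((1, 2)), sign="bright",
                           area_mm2=0.0, pixel_pitch=1.0)

    @pytest.mark.parametrize("target", [3200.0, 5000.0])
    def test_phantom_density_recovery(self, target):
        """Endothelium- and lens-epithelium-like densities recover within 10%."""
        errs = []
        for seed in range(3):
            spec = PhantomSpec(seed=seed, cell_density=target)
            img, gt = gen_endothelial_mosaic(spec)
            det = detect_cells(highpass(img, 121), "bright",
                               expected_diameter_um=gt.cell_diameter_um,
                               pixel_pitch=spec.pixel_pitch, mask=gt.bright_mask)
            errs.append(cell_density(det) / gt.cell_density - 1)
        assert max(abs(e) for e in errs) < 0.10


class TestNerveLengthDensity:
    def test_single_straight_segment(self):
        trace = NerveTrace(polylines=[np.array([[0.0, 0.0], [0.0, 1000.0]])],
                           pixel_pitch=1.0, area_mm2=1.0)
        assert nerve_length_density(trace) == pytest.approx(1.0)

    def test_empty_trace(self):
        trace = NerveTrace(polylines=[], pixel_pitch=1.0, area_mm2=1.0)
        assert nerve_length_density(trace) == 0.0

    def test_skeleton_estimator_on_lines(self):
        """Kulpa-weighted links measure straight digital lines within 6%."""
        sk = np.zeros((101, 101), bool)
        sk[50, 10:91] = True  # 80 px horizontal
        assert skeleton_length_mm(sk, 1.0) * 1000 == pytest.approx(80, rel=0.06)
        sk2 = np.eye(81, dtype=bool)  # 80*sqrt(2) px diagonal
        assert skeleton_length_mm(sk2, 1.0) * 1000 == pytest.approx(
            80 * np.sqrt(2), rel=0.06
        )

    def test_phantom_density_recovery(self):
        errs = []
        for seed in range(3):
            spec = PhantomSpec(seed=seed, nerve_density=22.0)
            img, gt = gen_nerve_layer(spec)
            trace = trace_nerves(highpass(img, 121), pixel_pitch=spec.pixel_pitch)
            errs.append(nerve_length_density(trace) / gt.nerve_density - 1)
        assert max(abs(e) for e in errs) < 0.10


class TestMeanCellDiameter:
    def test_arithmetic_mean(self):
        assert mean_cell_diameter([38.0, 40.0, 42.0]) == pytest.approx(40.0)

    def test_single_value(self):
        assert mean_cell_diameter([17.5]) == 17.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_cell_diameter([])

    def test_phantom_layer_diameters(self):
        """Epithelial-layer-scale mosaics recover cell diameter within 15%.

        The diameter is measured from the image as the circle-equivalent of
        the detected nearest-neighbour spacing, mimicking manual calliper
        measurements on the cell mosaic.
        """
        from scipy.spatial import cKDTree

        for target_diam in (40.0, 20.0):
            density = 4e6 / (np.pi * target_diam**2)
            spec = PhantomSpec(seed=1, cell_density=density, fov_mm=(0.4, 0.4))
            img, gt = gen_endothelial_mosaic(spec)
            proc = highpass(img, 121)
            centers = np.vstack([
                detect_cells(proc, sign, expected_diameter_um=target_diam,
                             pixel_pitch=spec.pixel_pitch).centers
                for sign in ("bright", "dark")
            ])
            # lattice constant from the six nearest neighbours of each cell;
            # circle-equivalent diameter of a hexagonal cell is 1.05x that
            nn, _ = cKDTree(centers).query(centers, k=7)
            spacing = np.median(nn[:, 1:].mean(axis=1)) * spec.pixel_pitch
            measured = mean_cell_diameter([1.05 * spacing])
            assert measured == pytest.approx(target_diam, rel=0.15)


class TestSnrDb:
    def test_equal_signal_noise_zero_db(self, rng):
        img = np.zeros((64, 64))
        img[:32] = 100.0
        img[32:] = rng.normal(0, 100.0, (32, 64))
        v = snr_db(img, (slice(0, 32), slice(0, 64)), (slice(32, 64), slice(0, 64)))
        assert v == pytest.approx(0.0, abs=1.0)

    def test_35_db_case(self, rng):
        img = np.zeros((200, 200))
        img[50:150, 50:150] = 100.0
        img[:40, :40] = rng.normal(0, 1.779, (40, 40))
        v = snr_db(img, (slice(50, 150), slice(50, 150)), (slice(0, 40), slice(0, 40)))
        assert v == pytest.approx(35.0, abs=0.5)

    def test_scale_invariance(self, rng):
        img = rng.normal(10, 1, (64, 64))
        rois = ((slice(0, 32), slice(0, 64)), (slice(32, 64), slice(0, 64)))
        assert snr_db(img, *rois) == pytest.approx(snr_db(7.3 * img, *rois), rel=1e-9)

    def test_power_convention_flag(self, rng):
        img = rng.normal(10, 1, (64, 64))
        rois = ((slice(0, 32), slice(0, 64)), (slice(32, 64), slice(0, 64)))
        assert snr_db(img, *rois) == pytest.approx(2 * snr_db(img, *rois, power=True))

    def test_zero_noise_rejected(self):
        img = np.ones((16, 16))
        with pytest.raises(ValueError):
            snr_db(img, (slice(0, 8), slice(0, 16)), (slice(8, 16), slice(0, 16)))
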