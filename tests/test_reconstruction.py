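"""FBP, SART, SIRT and photon-starvation correction."""

import numpy as np
import pytest

from bctsim import materials
from bctsim.projector import (
    ConcentricPhantom,
    Sinogram,
    expected_sinogram,
    path_lengths,
    projection_angles,
    sample_sinogram,
    to_line_integrals,
)
from bctsim.reconstruction import fbp, sart, sirt, starvation_correct

D, G, E = 6.0, 0.143, 28.0
PIX = 0.24


@pytest.fixture(scope="module")
def noiseless():
    ph = ConcentricPhantom(D, G)
    exp = expected_sinogram(ph, E, 1e7, n_proj=400, pixel_mm=PIX)
    return ph, to_line_integrals(exp)


def _region_masks(n_det, pixel_mm):
    s = (np.arange(n_det) - (n_det - 1) / 2.0) * pixel_mm / 10.0
    X, Y = np.meshgrid(s, s, indexing="xy")
    r = np.hypot(X, Y)
    return r, {
        "detail": r < 0.5 * 0.6,
        "ring": (r > 0.5 * 1.1) & (r < 0.5 * np.sqrt(2.0) * 0.9),
        "background": (r > 1.0) & (r < D / 2.0 * 0.8),
        "support": r < D / 2.0,
    }


class TestFbp:
    def test_noiseless_values_match_ground_truth(self, noiseless):
        ph, p = noiseless
        rec = fbp(p, "ramlak")
        _, m = _region_masks(rec.image.shape[0], rec.pixel_mm)
        mu_g = float(materials.linear_attenuation(materials.glandular(), E))
        mu_a = float(materials.linear_attenuation(materials.adipose(), E))
        assert rec.image[m["detail"]].mean() == pytest.approx(mu_g, rel=0.01)
        assert rec.image[m["ring"]].mean() == pytest.approx(mu_a, rel=0.01)

    def test_linearity(self, noiseless):
        _, p = noiseless
        from dataclasses import replace

        r1 = fbp(p, "hamming").image
        r2 = fbp(replace(p, data=2.0 * p.data), "hamming").image
        np.testing.assert_allclose(r2, 2.0 * r1, rtol=1e-10, atol=1e-12)

    def test_radial_symmetry(self, noiseless):
        _, p = noiseless
        rec = fbp(p, "ramlak")
        r, m = _region_masks(rec.image.shape[0], rec.pixel_mm)
        # angular spread of the radial profile: bin by radius, compare std/mean;
        # bins touching the material boundaries (r = 0.5 and sqrt(2)/2 cm) mix
        # different radii of a discontinuous profile and are excluded
        sel = (
            m["support"] & (r > 0.2) & (r < 2.5)
            & (np.abs(r - 0.5) > 0.12) & (np.abs(r - 0.5 * np.sqrt(2)) > 0.12)
        )
        rbin = np.round(r[sel] / 0.1).astype(int)
        vals = rec.image[sel]
        for b in np.unique(rbin):
            ring_vals = vals[rbin == b]
            assert ring_vals.std() < 0.02 * abs(ring_vals.mean())

    def test_dc_fidelity(self, noiseless):
        ph, p = noiseless
        rec = fbp(p, "ramlak")
        r, m = _region_masks(rec.image.shape[0], rec.pixel_mm)
        mu_g = float(materials.linear_attenuation(materials.glandular(), E))
        mu_a = float(materials.linear_attenuation(materials.adipose(), E))
        mu_m = float(materials.linear_attenuation(ph.background, E))
        R = D / 2.0
        area = np.pi * R**2
        a_det = np.pi * 0.25
        true_mean = (mu_g * a_det + mu_a * a_det + mu_m * (area - 2 * a_det)) / area
        assert rec.image[m["support"]].mean() == pytest.approx(true_mean, rel=0.01)

    def test_rejects_bad_input(self, noiseless):
        _, p = noiseless
        from dataclasses import replace

        bad = replace(p, data=np.where(np.arange(p.data.shape[1]) == 0, np.nan, p.data))
        with pytest.raises(ValueError):
            fbp(bad)
        with pytest.raises(ValueError):
            fbp(replace(p, kind="sampled"))


class TestIterative:
    def test_zero_sinogram_fixed_point(self):
        sino = Sinogram(np.zeros((16, 21)), projection_angles(16), 0.5, 1.0,
                        0.0, "line_integral")
        assert np.all(sart(sino, n_iter=3).image == 0.0)
        assert np.all(sirt(sino, n_iter=3).image == 0.0)

    @pytest.fixture(scope="class")
    @staticmethod
    def small_case():
        ph = ConcentricPhantom(4.0, 0.25)
        exp = expected_sinogram(ph, E, 1e7, n_proj=60, pixel_mm=0.48)
        p = to_line_integrals(exp)
        # ground-truth mu map on the reconstruction grid
        n = exp.n_det
        s = (np.arange(n) - (n - 1) / 2.0) * 0.048
        X, Y = np.meshgrid(s, s, indexing="xy")
        r = np.hypot(X, Y)
        mu_g = float(materials.linear_attenuation(materials.glandular(), E))
        mu_a = float(materials.linear_attenuation(materials.adipose(), E))
        mu_m = float(materials.linear_attenuation(ph.background, E))
        truth = np.where(r <= 0.5, mu_g,
                         np.where(r <= 0.5 * np.sqrt(2), mu_a,
                                  np.where(r <= 2.0, mu_m, 0.0)))
        return p, truth

    def test_rmse_decreases_with_iterations(self, small_case):
        p, truth = small_case
        rmse = []
        for n_iter in (1, 2, 5, 10, 20, 50):
            img = sirt(p, n_iter=n_iter).image
            rmse.append(np.sqrt(np.mean((img - truth) ** 2)))
        assert all(a > b for a, b in zip(rmse, rmse[1:]))

    def test_all_algorithms_agree_on_noiseless_signal(self, small_case):
        p, truth = small_case
        n = truth.shape[0]
        s = (np.arange(n) - (n - 1) / 2.0) * 0.048
        X, Y = np.meshgrid(s, s, indexing="xy")
        r = np.hypot(X, Y)
        interior = r < 0.4  # detail interior, away from edges
        vals = {
            "fbp": fbp(p, "ramlak").image[interior].mean(),
            "sart": sart(p, n_iter=30).image[interior].mean(),
            "sirt": sirt(p, n_iter=200).image[interior].mean(),
        }
        ref = vals["fbp"]
        for v in vals.values():
            assert v == pytest.approx(ref, rel=0.02)


class TestStarvationCorrection:
    def _sino(self, data):
        return Sinogram(np.asarray(data, dtype=float),
                        projection_angles(len(data)), 0.5, 1e3, 0.0, "sampled")

    def test_identity_without_zeros(self):
        sino = self._sino([[5.0, 6.0, 7.0], [8.0, 9.0, 10.0]])
        out = starvation_correct(sino)
        np.testing.assert_array_equal(out.data, sino.data)

    def test_single_zero_interpolates_midpoint(self):
        out = starvation_correct(self._sino([[80.0, 0.0, 120.0]]))
        assert out.data[0, 1] == pytest.approx(100.0)
        assert out.mask[0, 1]

    def test_zero_run_interpolated_across(self):
        out = starvation_correct(self._sino([[10.0, 0.0, 0.0, 0.0, 50.0]]))
        np.testing.assert_allclose(out.data[0], [10.0, 20.0, 30.0, 40.0, 50.0])

    def test_edge_zero_takes_nearest_value(self):
        out = starvation_correct(self._sino([[0.0, 0.0, 30.0, 40.0]]))
        np.testing.assert_allclose(out.data[0], [30.0, 30.0, 30.0, 40.0])

    def test_fully_starved_row_rejected(self):
        with pytest.raises(ValueError):
            starvation_correct(self._sino([[0.0, 0.0, 0.0]]))

    def test_requires_counts_sinogram(self):
        sino = self._sino([[1.0, 2.0, 3.0]])
        from dataclasses import replace

        with pytest.raises(ValueError):
            starvation_correct(replace(sino, kind="line_integral"))


def test_slice_written_as_float_tiff_with_sidecar(tmp_path, noiseless):
    import tifffile

    from bctsim.reconstruction import write_slice

    _, p = noiseless
    rec = fbp(p, "hamming")
    path = str(tmp_path / "slice.tif")
    write_slice(rec, path)
    img = tifffile.imread(path)
    assert img.dtype == np.float32 and img.shape == rec.image.shape
    sidecar = (tmp_path / "slice.tif.txt").read_text()
    assert "algorithm = fbp" in sidecar and "filter = hamming" in sidecar
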