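import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from myelotrace import orientation as ori
from myelotrace import synth
from myelotrace.circular import circ_mean_deg

from conftest import render_stripes


class TestPreprocess:
    def test_constant_plane_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning):
            out = ori.preprocess_myelin(np.full((32, 32), 7.0))
        assert np.all(out == 0)

    def test_bright_line_maximal_on_the_line(self):
        img = np.zeros((40, 40))
        img[:, 19:22] = 10.0                  # wide enough to survive median
        out = ori.preprocess_myelin(img)
        inner = out[5:-5]
        assert inner[:, 19:22].mean() > 5 * inner[:, [5, 34]].mean()

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, (16, 16),
                      elements=st.floats(0, 100, allow_nan=False)))
    def test_output_range_unit_interval(self, img):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = ori.preprocess_myelin(img)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestStructureTensor:
    def test_vertical_stripes_read_90_with_full_coherence(self):
        """Intensity varying along x only means one dominant (vertical)
        direction: C = 1, phi = 90."""
        phi, e, c = ori.structure_tensor_window(render_stripes(90.0, (24, 24)))
        assert phi == pytest.approx(90.0, abs=1e-6)
        assert c == pytest.approx(1.0, abs=1e-9)
        assert e > 0

    def test_constant_window_zero_energy_zero_coherence(self):
        phi, e, c = ori.structure_tensor_window(np.ones((24, 24)))
        assert e == 0.0
        assert c == 0.0

    def test_isotropic_window_zero_coherence(self):
        # equal-power orthogonal gratings: lambda_max = lambda_min
        iso = render_stripes(90.0, (24, 24)) + render_stripes(0.0, (24, 24))
        _, e, c = ori.structure_tensor_window(iso)
        assert e > 0
        assert c == pytest.approx(0.0, abs=0.01)

    @pytest.mark.parametrize("theta", [0.0, 30.0, 45.0, 120.0])
    def test_rotated_stripes_recovered_within_one_degree(self, theta):
        img = render_stripes(theta, (48, 48), period=12.0)
        phi, _, c = ori.structure_tensor_window(img[12:36, 12:36])
        err = (phi - theta + 90.0) % 180.0 - 90.0
        assert abs(err) <= 1.0
        assert c > 0.9

    def test_coherence_invariant_to_affine_intensity_rescaling(self, rng):
        w = rng.random((24, 24))
        _, _, c0 = ori.structure_tensor_window(w)
        _, _, c1 = ori.structure_tensor_window(3.7 * w + 11.0)
        assert c1 == pytest.approx(c0, rel=1e-12)

    def test_angle_consistent_with_eigendecomposition(self, rng):
        """The half-angle formula must agree with the principal axis of J
        computed by direct eigendecomposition."""
        for _ in range(20):
            w = rng.random((16, 16))
            phi, e, c = ori.structure_tensor_window(w)
            gy, gx = np.gradient(w)
            J = np.array([[np.mean(gx * gx), np.mean(gx * gy)],
                          [np.mean(gx * gy), np.mean(gy * gy)]])
            vals, vecs = np.linalg.eigh(J)
            assert e == pytest.approx(vals.sum())
            assert c == pytest.approx((vals[1] - vals[0]) / vals.sum(),
                                      abs=1e-10)
            # ridge direction: eigenvector of the *smaller* eigenvalue,
            # read in the y-up visual convention
            v = vecs[:, 0]
            ang = np.rad2deg(np.arctan2(-v[1], v[0])) % 180.0
            assert abs((phi - ang + 90) % 180 - 90) < 1e-6

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            ori.structure_tensor_window(np.ones((2, 5)))


class TestOrientationField:
    def test_gate_thresholds_trivial_cases(self):
        img = render_stripes(30.0, (96, 96))
        df0 = ori.orientation_field(img, window=24, gate_threshold=0.0,
                                    preprocess=False)
        assert df0["retained"].all()
        dfh = ori.orientation_field(img, window=24, gate_threshold=1e12,
                                    preprocess=False)
        assert not dfh["retained"].any()

    def test_rotation_by_90_degrees_shifts_phi(self):
        img = render_stripes(30.0, (96, 96))
        a = ori.orientation_field(img, window=24, gate_threshold=0.0,
                                  preprocess=False)
        b = ori.orientation_field(np.rot90(img), window=24, gate_threshold=0.0,
                                  preprocess=False)
        ma = circ_mean_deg(a["phi_raw"])
        mb = circ_mean_deg(b["phi_raw"])
        err = (mb - (ma + 90.0) + 90.0) % 180.0 - 90.0
        assert abs(err) <= 2.0

    def test_window_larger_than_plane_rejected(self):
        with pytest.raises(ValueError):
            ori.orientation_field(np.ones((16, 16)), window=24)

    def test_synthetic_fibre_plane_mean_recovered(self):
        layers = [synth.LayerDesign("L4", 90.0, 3.0, n_per_plane=120)]
        stack, _ = synth.gen_fibre_volume(layers, surface_coeffs=(0, 0, 6),
                                          shape=(1, 360, 360),
                                          layer_boundaries_um=[0.0, 180.0],
                                          seed=2)
        df = ori.orientation_field(stack.channel(0)[0], window=24,
                                   gate_quantile=0.6)
        kept = df[df["retained"]]
        assert circ_mean_deg(kept["phi_raw"]) == pytest.approx(90.0, abs=1.0)


class TestCorticalSurface:
    def test_flat_surface_recovered_with_tangent_zero(self):
        af = synth.gen_af_surface((0.0, 0.0, 30.0), shape=(1, 200, 200))
        fit = ori.fit_cortical_surface(af.channel(0)[0])
        a, b, c = fit["coeffs"]
        assert abs(a) < 1e-5 and abs(b) < 1e-3
        assert c == pytest.approx(30.0, abs=0.3)
        tang = fit["tangent_angle_map"][60:180, 20:180]
        assert np.all(np.minimum(tang, 180.0 - tang) < 1.0)

    def test_quadratic_coefficients_round_trip_within_one_percent(self):
        coeffs = (1e-3, -0.35, 60.0)
        af = synth.gen_af_surface(coeffs, shape=(1, 400, 400), blur=2.0)
        fit = ori.fit_cortical_surface(af.channel(0)[0])
        for got, true in zip(fit["coeffs"], coeffs):
            assert got == pytest.approx(true, rel=0.01, abs=1e-5)

    def test_distance_increases_with_depth(self):
        af = synth.gen_af_surface((2e-4, -0.05, 40.0), shape=(1, 300, 300))
        fit = ori.fit_cortical_surface(af.channel(0)[0])
        assert np.all(np.diff(fit["distance_map"][:, 150]) > 0)

    def test_degenerate_plane_rejected(self):
        with pytest.raises(ValueError):
            ori.fit_cortical_surface(np.linspace(0, 1, 64 * 64).reshape(64, 64) * 0
                                     + np.tile(np.linspace(0, 1, 64), (64, 1)) * 0
                                     + 1.0 + np.zeros((64, 64)))


class TestCorrectAndLayer:
    def _field(self, rows, phi=90.0):
        return pd.DataFrame({"plane": 0, "row": rows,
                             "col": [100.0] * len(rows),
                             "phi_raw": phi, "energy": 1.0, "coherence": 1.0,
                             "retained": True})

    def test_flat_surface_leaves_phi_unchanged(self):
        af = synth.gen_af_surface((0.0, 0.0, 10.0), shape=(1, 300, 300))
        surf = ori.fit_cortical_surface(af.channel(0)[0])
        field = self._field([50.0, 120.0], phi=77.0)
        out = ori.correct_and_layer(field, surf, [0, 15, 50, 75, 110, 160])
        assert np.allclose(out["phi_corrected"], 77.0, atol=0.5)

    def test_locally_normal_fibres_read_90_despite_curvature(self):
        """Fibres everywhere normal to a curved surface: the corrected
        angle is ~90 at all lateral positions although raw angles vary."""
        coeffs = (8e-4, -0.3, 50.0)
        af = synth.gen_af_surface(coeffs, shape=(1, 400, 400))
        surf = ori.fit_cortical_surface(af.channel(0)[0])
        cols = np.array([60.0, 150.0, 250.0, 340.0])
        rows = synth.surface_row(coeffs, cols) + 80.0
        # oracle: exact normal through each point via brute-force nearest
        # point on the quadratic
        xs = np.linspace(0, 399, 20000)
        curve = np.column_stack([xs, synth.surface_row(coeffs, xs)])
        phi_raw = []
        for x, y in zip(cols, rows):
            nearest = curve[np.argmin((curve[:, 0] - x) ** 2
                                      + (curve[:, 1] - y) ** 2)]
            dx, dy = x - nearest[0], y - nearest[1]
            phi_raw.append(np.rad2deg(np.arctan2(-dy, dx)) % 180.0)
        field = pd.DataFrame({"plane": 0, "row": rows, "col": cols,
                              "phi_raw": phi_raw,
                              "energy": 1.0, "coherence": 1.0,
                              "retained": True})
        out = ori.correct_and_layer(field, surf, [0, 200])
        assert np.allclose(out["phi_corrected"], 90.0, atol=1.5)
        assert np.ptp(field["phi_raw"]) > 5.0

    def test_boundary_tie_goes_to_deeper_layer(self):
        af = synth.gen_af_surface((0.0, 0.0, 0.5), shape=(1, 300, 300),
                                  blur=0)
        surf = ori.fit_cortical_surface(af.channel(0)[0])
        # window centre exactly on the L1|L2/3 boundary depth
        depth_px = surf["distance_map"][100, 150]
        b1 = depth_px * 0.54
        field = self._field([100.0])
        out = ori.correct_and_layer(field, surf, [0.0, b1, 200.0, 250.0,
                                                  300.0, 350.0])
        assert out["layer"].iloc[0] == "L2/3"

    def test_l6_and_out_of_range_windows_dropped(self):
        af = synth.gen_af_surface((0.0, 0.0, 10.0), shape=(1, 300, 300))
        surf = ori.fit_cortical_surface(af.channel(0)[0])
        # depths: one above surface, one L1, one L6, one beyond range
        field = self._field([5.0, 20.0, 250.0, 296.0])
        bounds = [0, 15, 40, 60, 90, 120]
        out = ori.correct_and_layer(field, surf, bounds)
        assert len(out) == 1
        assert out["layer"].iloc[0] == "L1"
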