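import numpy as np
import pytest

from reference_impls import (
    brute_force_insertion,
    fft_dominant_orientation,
    finite_difference_orientation,
)
from shadowcue.probe import (
    COMPONENT_STEP_DEG,
    N_COMPONENTS,
    DegenerateMapError,
    EdgeMap,
    ProbeBoundsError,
    composite_probe,
    make_probe_spec,
    render_probe,
    select_insertion_point,
    sobel_edge_map,
)


class TestProbeSpec:
    def test_component_geometry(self):
        spec = make_probe_spec(True, 0.0, seed=0)
        assert N_COMPONENTS == 16
        assert COMPONENT_STEP_DEG == pytest.approx(11.25)
        ors = spec.component_orientations()
        assert ors[0] == 0.0
        assert ors[2] == pytest.approx(22.5)  # third component
        assert ors[-1] == pytest.approx(168.75)
        assert np.allclose(np.diff(ors[:9]), 11.25)

    def test_amplitude_decomposition(self):
        spec = make_probe_spec(False, 30.0, seed=3)
        assert np.allclose(spec.amplitudes, spec.noise + spec.signal)
        assert np.count_nonzero(spec.signal) == 1
        assert spec.signal[8] == pytest.approx(0.40)  # +90 deg component
        cong = make_probe_spec(True, 30.0, seed=3)
        assert cong.signal[0] == pytest.approx(0.40)

    def test_congruent_signal_tracks_reference(self):
        spec = make_probe_spec(True, 30.0, seed=1)
        assert spec.component_orientations()[0] == pytest.approx(30.0)

    def test_noise_free_single_component(self):
        spec = make_probe_spec(True, 0.0, noise_mean=0.0, noise_sd=0.0, seed=0)
        assert np.count_nonzero(spec.amplitudes) == 1

    def test_noise_clipped_nonnegative(self):
        spec = make_probe_spec(True, 0.0, noise_mean=0.0, noise_sd=0.05, seed=4)
        assert (spec.noise >= 0).all()

    def test_phases_uniform_range(self):
        spec = make_probe_spec(True, 0.0, seed=2)
        assert ((spec.phases >= 0) & (spec.phases < 360)).all()


class TestRenderProbe:
    @pytest.mark.parametrize("ref", [0.0, 45.0, 90.0, 135.0])
    def test_spectral_orientation_tracks_reference(self, ref):
        """FFT oracle: the dominant spectral orientation of a noise-free
        congruent probe stays within half a component step of the
        reference (rendered well above Nyquist to isolate geometry)."""
        spec = make_probe_spec(True, ref, noise_mean=0.0, noise_sd=0.0, seed=0)
        patch, window = render_probe(spec, px_per_degree=16.0)
        # analyze the contrast modulation, not the luminance pedestal
        measured = fft_dominant_orientation((patch - 0.5) * window)
        d = abs(measured - ref) % 180
        assert min(d, 180 - d) <= COMPONENT_STEP_DEG / 2

    def test_zero_contrast_uniform(self):
        spec = make_probe_spec(True, 0.0, noise_mean=0.0, noise_sd=0.0,
                               signal_contrast=0.0, seed=0)
        patch, _ = render_probe(spec)
        assert np.allclose(patch, 0.5)

    def test_amplitude_bound(self):
        spec = make_probe_spec(True, 10.0, seed=5)
        patch, _ = render_probe(spec)
        assert np.max(np.abs(patch - 0.5)) <= spec.amplitudes.sum() / 2 + 1e-12


class TestSobel:
    def test_constant_zero_magnitude(self):
        em = sobel_edge_map(np.full((20, 20), 0.3))
        assert (em.magnitude == 0).all()
        assert np.isnan(em.orientation).all()

    def test_vertical_step_edge_orientation(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 1.0
        em = sobel_edge_map(img)
        col = em.orientation[5:15, 9]
        assert np.allclose(col, 90.0)  # vertical edge

    def test_horizontal_step_edge_orientation(self):
        img = np.zeros((20, 20))
        img[10:, :] = 1.0
        em = sobel_edge_map(img)
        assert np.allclose(em.orientation[9, 5:15], 0.0)

    def test_orientation_convention_against_finite_differences(self):
        """On a smooth oblique ramp the Sobel orientation must agree with
        an independent central-difference oracle."""
        rng = np.random.default_rng(0)
        y, x = np.mgrid[0:24, 0:24]
        img = np.sin(0.3 * x + 0.55 * y)
        em = sobel_edge_map(img)
        _, ref = finite_difference_orientation(img)
        interior = em.orientation[2:-2, 2:-2]
        oracle = ref[2:-2, 2:-2]
        d = np.abs(interior - oracle) % 180
        d = np.minimum(d, 180 - d)
        assert np.nanmax(d) < 2.0

    def test_transpose_maps_orientation(self):
        # transposition reflects about the diagonal: theta -> (90 - theta)
        y, x = np.mgrid[0:24, 0:24]
        img = np.sin(0.3 * x + 0.55 * y)
        a = sobel_edge_map(img)
        b = sobel_edge_map(img.T)
        assert np.allclose(b.magnitude, a.magnitude.T)
        d = np.abs(b.orientation - (90.0 - a.orientation.T) % 180.0) % 180
        d = np.minimum(d, 180 - d)
        assert np.nanmax(d) < 1e-9


def _random_edge_maps(rng, shape=(20, 20)):
    mag = rng.random(shape)
    orient = rng.random(shape) * 180.0
    return EdgeMap(magnitude=mag, orientation=orient)


class TestInsertionPoint:
    def test_matches_brute_force_reference(self):
        """Noise-free selection equals an independent loop-based
        recomputation pixel-for-pixel on random 20x20 map pairs."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            d = _random_edge_maps(rng)
            m = _random_edge_maps(rng)
            res = select_insertion_point(d, m, "image_driven", noise_amplitude=0.0)
            ref_point, ref_orient, ref_map = brute_force_insertion(
                d.magnitude, d.orientation, m.magnitude
            )
            assert res.point == ref_point
            assert res.local_orientation == pytest.approx(ref_orient)
            assert np.allclose(res.insertion_map, ref_map, atol=1e-10)

    def test_role_symmetry(self):
        """Swapping driver/modulator converts image-driven into
        object-driven selection exactly."""
        rng = np.random.default_rng(1)
        a, b = _random_edge_maps(rng), _random_edge_maps(rng)
        r1 = select_insertion_point(a, b, "object_driven", noise_amplitude=0.0)
        r2 = select_insertion_point(b, a, "image_driven", noise_amplitude=0.0)
        assert r1.point == r2.point
        assert r1.local_orientation == r2.local_orientation
        assert np.allclose(r1.insertion_map, r2.insertion_map)

    def test_single_bright_pixel_argmax(self):
        # corner suppression is disabled here: an isolated bright point is
        # itself a Harris corner, and the example isolates argmax mechanics
        mag = np.zeros((100, 90))
        mag[50, 40] = 1.0
        orient = np.full((100, 90), 30.0)
        driver = EdgeMap(magnitude=mag, orientation=orient)
        modulator = EdgeMap(magnitude=np.zeros((100, 90)), orientation=orient)
        res = select_insertion_point(
            driver, modulator, "image_driven",
            noise_amplitude=0.0, corner_top_fraction=0.0,
        )
        assert res.point == (40, 50)
        assert res.local_orientation == 30.0

    def test_modulator_suppresses_its_ridge(self):
        """A driver ridge crossing a modulator-bright ridge is avoided
        where the modulator is bright."""
        h, w = 40, 40
        driver_mag = np.zeros((h, w))
        driver_mag[20, :] = 1.0  # horizontal driver ridge
        mod_mag = np.zeros((h, w))
        mod_mag[:, 20] = 1.0  # vertical modulator ridge
        d = EdgeMap(driver_mag, np.zeros((h, w)))
        m = EdgeMap(mod_mag, np.zeros((h, w)))
        res = select_insertion_point(d, m, "image_driven", noise_amplitude=0.0)
        assert res.point[1] == 20  # on the driver ridge
        assert abs(res.point[0] - 20) > 4  # away from the modulator ridge
        ref_point, _, _ = brute_force_insertion(driver_mag, d.orientation, mod_mag)
        assert res.point == ref_point

    def test_constant_driver_raises(self):
        rng = np.random.default_rng(2)
        d = EdgeMap(np.ones((20, 20)), np.zeros((20, 20)))
        m = _random_edge_maps(rng)
        with pytest.raises(DegenerateMapError):
            select_insertion_point(d, m, "image_driven", noise_amplitude=0.0)

    def test_corner_masked_pixels_never_selected(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            d = _random_edge_maps(rng)
            m = _random_edge_maps(rng)
            res = select_insertion_point(d, m, "image_driven", noise_amplitude=0.0)
            from shadowcue.probe import harris_response, _minmax_normalize

            mm = _minmax_normalize(d.magnitude, what="driver", allow_constant=False)
            corner = harris_response(mm)
            thresh = np.percentile(corner, 90.0)
            col, row = res.point
            assert corner[row, col] <= thresh

    def test_noise_reproducible_per_seed(self):
        rng_maps = np.random.default_rng(4)
        d, m = _random_edge_maps(rng_maps), _random_edge_maps(rng_maps)
        a = select_insertion_point(d, m, "image_driven", seed=11)
        b = select_insertion_point(d, m, "image_driven", seed=11)
        assert a.point == b.point


class TestComposite:
    def test_identity_under_full_opacity(self):
        spec = make_probe_spec(True, 20.0, seed=1)
        patch, window = render_probe(spec)
        scene = np.full((100, 90), 0.7)
        out = composite_probe(scene, patch, window, (45, 50))
        half = patch.shape[0] // 2
        core = window > 0.999
        region = out[50 - half : 50 + half + 1, 45 - half : 45 + half + 1]
        assert np.allclose(region[core], patch[core])

    def test_zero_contrast_blends_toward_half(self):
        spec = make_probe_spec(True, 0.0, noise_mean=0, noise_sd=0,
                               signal_contrast=0.0, seed=0)
        patch, window = render_probe(spec)
        scene = np.full((100, 90), 0.8)
        out = composite_probe(scene, patch, window, (45, 50))
        changed = out != 0.8
        half = patch.shape[0] // 2
        assert changed[50 - half : 50 + half + 1, 45 - half : 45 + half + 1].any()
        assert (out[changed] < 0.8).all()  # pulled toward 0.5
        outside = np.ones_like(out, dtype=bool)
        outside[50 - half : 50 + half + 1, 45 - half : 45 + half + 1] = False
        assert (out[outside] == 0.8).all()

    def test_out_of_bounds_raises(self):
        spec = make_probe_spec(True, 0.0, seed=1)
        patch, window = render_probe(spec)
        with pytest.raises(ProbeBoundsError):
            composite_probe(np.full((100, 90), 0.5), patch, window, (1, 1))
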