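import numpy as np
import pytest

from blinktrack.dxb import decay_map
from blinktrack.exceptions import ConfigurationError, InvalidInputError
from blinktrack.simulate import (
    BeamModel,
    CrystalEnsemble,
    _wrap_angle,
    render_dxb_movie,
    render_dxt_movie,
    rocking_intensity,
    simulate_orientations,
    stokes_einstein_debye,
)


class TestOrientationPaths:
    def test_frozen_dynamics(self):
        truth = simulate_orientations(5, 0.0, 0.1, 50, seed=1)
        assert np.all(truth.theta_paths == truth.theta_paths[0])
        assert np.all(truth.chi_paths == truth.chi_paths[0])

    def test_path_shape_includes_initial_state(self):
        truth = simulate_orientations(3, 0.01, 0.1, 20, seed=1)
        assert truth.theta_paths.shape == (21, 3)

    def test_brownian_variance_law(self):
        # Var(theta(t) - theta(0)) = 2 * d_rot * t at t = 100 dt
        d_rot, dt = 0.02, 0.05
        truth = simulate_orientations(10_000, d_rot, dt, 100, seed=7)
        disp = truth.theta_paths[100] - truth.theta_paths[0]
        assert disp.var() == pytest.approx(2 * d_rot * 100 * dt, rel=0.05)
        disp_chi = truth.chi_paths[100] - truth.chi_paths[0]
        assert disp_chi.var() == pytest.approx(2 * d_rot * 100 * dt, rel=0.05)

    def test_determinism(self):
        a = simulate_orientations(10, 0.01, 0.1, 30, seed=99)
        b = simulate_orientations(10, 0.01, 0.1, 30, seed=99)
        assert np.array_equal(a.theta_paths, b.theta_paths)
        assert np.array_equal(a.chi_paths, b.chi_paths)

    def test_negative_d_rot(self):
        with pytest.raises(InvalidInputError):
            simulate_orientations(5, -0.1, 0.1, 10, seed=1)

    def test_chi_init_override(self):
        chi = np.linspace(-1, 1, 4)
        truth = simulate_orientations(4, 0.0, 0.1, 5, seed=1, chi_init=chi)
        assert np.array_equal(truth.chi_paths[0], chi)
        with pytest.raises(InvalidInputError):
            simulate_orientations(5, 0.0, 0.1, 5, seed=1, chi_init=chi)

    def test_initial_capture_window(self):
        truth = simulate_orientations(
            1000, 0.0, 0.1, 1, seed=3, theta_init_halfwidth=0.02
        )
        assert np.all(np.abs(truth.theta_paths[0]) <= 0.02)


class TestRockingIntensity:
    def test_exact_bragg(self, mono_beam):
        assert rocking_intensity(0.0, mono_beam) == 1.0

    def test_one_sigma(self):
        beam = BeamModel(mode="monochromatic", rocking_width=2e-3)
        assert rocking_intensity(2e-3, beam) == pytest.approx(
            np.exp(-0.5), rel=1e-12
        )

    @pytest.mark.parametrize("bandwidth", [0.01, 0.1, 0.5])
    def test_broadband_widens(self, bandwidth):
        mono = BeamModel(mode="monochromatic", rocking_width=1e-3)
        broad = BeamModel(
            mode="broadband",
            rocking_width=1e-3,
            bandwidth=bandwidth,
            bragg_theta=0.17,
        )
        assert broad.effective_width >= mono.effective_width
        # differentiated Bragg law: w_bw = tan(theta_B) * dE/E
        expected = np.hypot(1e-3, np.tan(0.17) * bandwidth)
        assert broad.effective_width == pytest.approx(expected, rel=1e-12)

    def test_broadband_requires_bandwidth(self):
        with pytest.raises(InvalidInputError):
            BeamModel(mode="broadband", rocking_width=1e-3)

    def test_bad_mode(self):
        with pytest.raises(InvalidInputError):
            BeamModel(mode="white")


class TestEnsembleAndHelpers:
    def test_crystal_ensemble_validation(self):
        CrystalEnsemble(10, 0.01)
        with pytest.raises(InvalidInputError):
            CrystalEnsemble(10, -0.01)
        with pytest.raises(InvalidInputError):
            CrystalEnsemble(10, 0.01, radius_nm=0)

    def test_stokes_einstein_debye(self):
        # 70 nm diameter sphere in water at 293 K: k_B T / (8 pi eta r^3)
        d = stokes_einstein_debye(293.0, 1.0e-3, 35e-9)
        expected = 1.380649e-23 * 293.0 / (8 * np.pi * 1.0e-3 * 35e-9**3)
        assert d == pytest.approx(expected, rel=1e-12)
        # colder + more viscous => slower
        assert stokes_einstein_debye(273.0, 1.8e-3, 35e-9) < d

    def test_wrap_angle(self, rng):
        x = rng.uniform(-20, 20, 1000)
        w = _wrap_angle(x, 2 * np.pi)
        assert np.all(w >= -np.pi) and np.all(w < np.pi)
        assert np.allclose(np.sin(w), np.sin(x), atol=1e-12)


class TestRenderDxb:
    def _small_setup(self, toy_geom, au111_ring, d_rot=0.0, n_frames=20,
                     substeps=5, seed=11):
        exposure = 0.2
        truth = simulate_orientations(
            20, d_rot, exposure / substeps, n_frames * substeps, seed=seed,
            theta_init_halfwidth=0.3,
        )
        return truth, exposure

    def test_static_scene(self, toy_geom, au111_ring, mono_beam):
        truth, exposure = self._small_setup(toy_geom, au111_ring)
        movie = render_dxb_movie(
            truth, toy_geom, au111_ring, mono_beam, photons_per_crystal=100,
            background=0.2, exposure=exposure, poisson=False, seed=1,
            substeps=5,
        )
        assert np.array_equal(movie.frames[0], movie.frames[-1])

    def test_photon_bookkeeping(self, toy_geom, au111_ring, mono_beam):
        """Noise off: total counts equal background plus deposited photons."""
        exposure, substeps, n_frames, n_crystals = 0.2, 5, 20, 20
        truth = simulate_orientations(
            n_crystals, 5e-4, exposure / substeps, n_frames * substeps,
            seed=11, theta_init_halfwidth=0.05,
        )
        photons, background = 150.0, 0.3
        movie = render_dxb_movie(
            truth, toy_geom, au111_ring, mono_beam,
            photons_per_crystal=photons, background=background,
            exposure=exposure, poisson=False, seed=1, substeps=substeps,
        )
        # bookkeeping is exact only while every footprint stays interior
        assert np.nanmax(np.abs(truth.spot_tracks - 16.0)) < 12.0
        expected = 0.0
        theta_blocks = truth.theta_paths[1:].reshape(
            n_frames, substeps, n_crystals
        )
        for f in range(n_frames):
            w = rocking_intensity(theta_blocks[f], mono_beam).mean(axis=0)
            expected += photons * w.sum()
        expected += n_frames * background * toy_geom.n_rows * toy_geom.n_cols
        assert movie.frames.sum() == pytest.approx(expected, rel=1e-9)

    def test_poisson_preserves_mean(self, toy_geom, au111_ring, mono_beam):
        truth, exposure = self._small_setup(
            toy_geom, au111_ring, d_rot=0.0, n_frames=400
        )
        kwargs = dict(
            photons_per_crystal=100, background=0.2, exposure=exposure,
            substeps=5,
        )
        clean = render_dxb_movie(
            truth, toy_geom, au111_ring, mono_beam, poisson=False, seed=1,
            **kwargs,
        )
        noisy = render_dxb_movie(
            truth, toy_geom, au111_ring, mono_beam, poisson=True, seed=2,
            **kwargs,
        )
        mu = clean.frames.mean(axis=0)
        hot = mu > 1.0
        se = np.sqrt(mu[hot] / clean.n_frames)
        dev = np.abs(noisy.frames.mean(axis=0)[hot] - mu[hot]) / se
        # all bright pixels within 5 standard errors, typical within 3
        assert np.median(dev) < 3.0
        assert dev.max() < 6.0

    def test_determinism(self, toy_geom, au111_ring, mono_beam):
        truth1, exposure = self._small_setup(toy_geom, au111_ring, d_rot=0.01)
        truth2, _ = self._small_setup(toy_geom, au111_ring, d_rot=0.01)
        kwargs = dict(
            photons_per_crystal=100, background=0.2, exposure=exposure,
            poisson=True, seed=42, substeps=5,
        )
        m1 = render_dxb_movie(truth1, toy_geom, au111_ring, mono_beam, **kwargs)
        m2 = render_dxb_movie(truth2, toy_geom, au111_ring, mono_beam, **kwargs)
        assert np.array_equal(m1.frames, m2.frames)

    def test_requires_monochromatic(self, toy_geom, au111_ring):
        truth, exposure = self._small_setup(toy_geom, au111_ring)
        beam = BeamModel(
            mode="broadband", rocking_width=1e-3, bandwidth=0.1, bragg_theta=0.17
        )
        with pytest.raises(ConfigurationError):
            render_dxb_movie(
                truth, toy_geom, au111_ring, beam, exposure=exposure,
                substeps=5,
            )

    def test_substep_mismatch(self, toy_geom, au111_ring, mono_beam):
        truth, exposure = self._small_setup(toy_geom, au111_ring)
        with pytest.raises(ConfigurationError):
            render_dxb_movie(
                truth, toy_geom, au111_ring, mono_beam, exposure=exposure,
                substeps=7,
            )


class TestRenderDxt:
    def _broad_beam(self, two_theta):
        return BeamModel(
            mode="broadband", rocking_width=1e-3, bandwidth=0.1,
            bragg_theta=two_theta / 2,
        )

    def test_static_tracks(self, dxt_geom):
        from blinktrack.geometry import bragg_two_theta

        tt = bragg_two_theta(dxt_geom.wavelength, 4.0782, (1, 1, 1))
        truth = simulate_orientations(
            5, 0.0, 0.01, 50, seed=3, theta_init_halfwidth=1e-4
        )
        movie, truth = render_dxt_movie(
            truth, dxt_geom, self._broad_beam(tt), two_theta_center=tt,
            photons_per_crystal=1000, exposure=0.01, seed=1,
        )
        assert np.all(truth.spot_tracks == truth.spot_tracks[0])

    def test_tracks_match_rendered_centroids(self, dxt_geom):
        """Centroid of the rendered (noise-free) frame sits on the track."""
        from blinktrack.geometry import bragg_two_theta

        tt = bragg_two_theta(dxt_geom.wavelength, 4.0782, (1, 1, 1))
        truth = simulate_orientations(
            1, 1e-5, 0.01, 30, seed=5, theta_init_halfwidth=1e-4
        )
        movie, truth = render_dxt_movie(
            truth, dxt_geom, self._broad_beam(tt), two_theta_center=tt,
            photons_per_crystal=1000, background=0.0, exposure=0.01, seed=1,
        )
        for f in range(movie.n_frames):
            img = movie.frames[f]
            total = img.sum()
            rr, cc = np.mgrid[: img.shape[0], : img.shape[1]]
            crow = (rr * img).sum() / total
            ccol = (cc * img).sum() / total
            assert abs(crow - truth.spot_tracks[f, 0, 0]) < 0.1
            assert abs(ccol - truth.spot_tracks[f, 0, 1]) < 0.1

    def test_step_variance_scales_with_d_rot(self, dxt_geom):
        from blinktrack.geometry import bragg_two_theta

        tt = bragg_two_theta(dxt_geom.wavelength, 4.0782, (1, 1, 1))
        msds = []
        for d_rot in (1e-5, 2e-5):
            truth = simulate_orientations(
                10, d_rot, 0.01, 1000, seed=21, theta_init_halfwidth=1e-4
            )
            _, truth = render_dxt_movie(
                truth, dxt_geom, self._broad_beam(tt), two_theta_center=tt,
                photons_per_crystal=1000, exposure=0.01, seed=1,
            )
            steps = np.diff(truth.spot_tracks, axis=0)
            msds.append((steps**2).sum(axis=-1).mean())
        assert msds[1] / msds[0] == pytest.approx(2.0, rel=0.10)

    def test_requires_broadband(self, dxt_geom, mono_beam):
        truth = simulate_orientations(2, 0.0, 0.01, 10, seed=1)
        with pytest.raises(ConfigurationError):
            render_dxt_movie(
                truth, dxt_geom, mono_beam, two_theta_center=0.33,
                exposure=0.01,
            )


class TestGroundTruthExport:
    def test_csv_columns(self, tmp_path, toy_geom, au111_ring, mono_beam):
        import pandas as pd

        truth = simulate_orientations(
            3, 0.01, 0.04, 50, seed=2, theta_init_halfwidth=0.3
        )
        render_dxb_movie(
            truth, toy_geom, au111_ring, mono_beam, exposure=0.2,
            poisson=False, seed=1, substeps=5,
        )
        path = tmp_path / "truth.csv"
        truth.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "crystal_id", "frame", "theta_tilt_rad", "chi_rad",
            "row_px", "col_px",
        ]
        assert len(df) == 10 * 3  # 50 steps / 5 substeps frames x 3 crystals


class TestEndToEndHook:
    def test_gamma_monotone_in_d_rot(self, toy_geom, au111_ring):
        """Fitted decay constants order the simulated diffusion grid."""
        beam = BeamModel(mode="monochromatic", rocking_width=0.6)
        n_frames, substeps, exposure = 250, 5, 0.2
        medians = []
        for i, d_rot in enumerate([0.01, 0.04, 0.16]):
            truth = simulate_orientations(
                150, d_rot, exposure / substeps, n_frames * substeps,
                seed=60 + i, theta_init_halfwidth=np.pi,
            )
            movie = render_dxb_movie(
                truth, toy_geom, au111_ring, beam,
                photons_per_crystal=3000.0, background=0.5,
                exposure=exposure, poisson=False, seed=70 + i,
                substeps=substeps, theta_period=2 * np.pi,
                tilt_projection=0.4,
            )
            dist, _, _ = decay_map(
                movie, au111_ring, max_lag=n_frames // 2, min_mean=2.0,
                window="pooled",
            )
            medians.append(dist.median)
        assert medians[0] < medians[1] < medians[2]
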