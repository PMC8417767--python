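"""EBB inversion: data reduction, beamformer prior, ReML, free energy."""

import numpy as np
import pytest

from orientmeg.forward import fit_sphere, sphere_leadfield
from orientmeg.inversion import (InversionComponents, InversionError,
                                 SourceModel, coherence_smooth, ebb_prior,
                                 invert, make_source_model, peak_vertex,
                                 reduce_data, reml_optimize)
from orientmeg.mesh_core import geodesic_distances, geodesic_kernel
from orientmeg.orientation import link_vectors, rotate_field_on_cone
from orientmeg.simulate import simulate_dataset


@pytest.fixture(scope="module")
def inverse_setup(folded_decimated, helmet_small):
    """Source space, link lead field and a clean 0 dB dataset."""
    dec, dmap = folded_decimated
    center, _ = fit_sphere(dec.pial.vertices)
    link = link_vectors(dec)
    lf = sphere_leadfield(dec.pial.vertices, link.vectors, helmet_small,
                          center)
    kernel = geodesic_kernel(dec.pial, 5.0)
    ds = simulate_dataset(dec.pial, lf, 17, 0.0, n_trials=64, seed=21)
    reduced = reduce_data(ds)
    model = SourceModel("pial", link, dec.pial.vertices, lf, dec.pial)
    return dict(dec=dec, dmap=dmap, center=center, link=link, lf=lf,
                kernel=kernel, ds=ds, reduced=reduced, model=model,
                helmet=helmet_small)


class TestReduceData:
    def test_window_sample_count(self, inverse_setup):
        red = inverse_setup["reduced"]
        assert red.window.stop - red.window.start == 25  # 100 ms at 250 Hz
        assert red.temporal_projector.shape == (25, 4)

    def test_rank2_data_leaves_trailing_modes_empty(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(30, 2))
        v = rng.normal(size=(40, 2))
        data = u @ v.T
        red = reduce_data(data, fs=250.0, n_temporal_modes=4)
        assert red.singular_values[2] < 1e-9 * red.singular_values[0]
        assert red.singular_values[3] < 1e-9 * red.singular_values[0]

    def test_svd_beats_random_projectors(self, inverse_setup, rng):
        ds = inverse_setup["ds"]
        red = reduce_data(ds)
        avg = ds.average()[:, red.window]
        kept = np.linalg.norm(avg @ red.temporal_projector) ** 2
        for _ in range(10):
            Q, _ = np.linalg.qr(rng.normal(size=(25, 4)))
            assert np.linalg.norm(avg @ Q) ** 2 <= kept + 1e-9

    def test_short_window_raises(self, inverse_setup):
        with pytest.raises(InversionError):
            reduce_data(inverse_setup["ds"], n_temporal_modes=4,
                        window_ms=8.0)


class TestEbbPrior:
    def test_peak_at_active_source(self, inverse_setup):
        """At high SNR the beamformer variance estimate peaks at the active
        source despite the lead-field-strength normalization."""
        s = inverse_setup
        ds = simulate_dataset(s["dec"].pial, s["lf"], 17, 20.0, n_trials=64,
                              seed=22)
        red = reduce_data(ds)
        gamma = ebb_prior(s["lf"].gain, red.Y_trials)
        assert np.argmax(gamma) == 17

    def test_quadratic_homogeneity(self, inverse_setup):
        red = inverse_setup["reduced"]
        g1 = ebb_prior(inverse_setup["lf"].gain, red.Y_trials)
        g2 = ebb_prior(inverse_setup["lf"].gain, 3.0 * red.Y_trials)
        np.testing.assert_allclose(g2, 9.0 * g1, rtol=1e-9)

    def test_zero_data_raises(self, inverse_setup):
        with pytest.raises(InversionError, match="lambda"):
            ebb_prior(inverse_setup["lf"].gain, np.zeros((60, 4)))


class TestCoherenceSmooth:
    def test_zero_fwhm_is_diagonal(self, inverse_setup, rng):
        dec = inverse_setup["dec"]
        gamma = rng.uniform(size=dec.n_vertices)
        Q = coherence_smooth(gamma, dec.pial, fwhm_mm=0.0)
        np.testing.assert_allclose(Q, np.diag(gamma), atol=1e-15)

    def test_symmetric_psd(self, inverse_setup, rng):
        dec = inverse_setup["dec"]
        gamma = rng.uniform(size=dec.n_vertices)
        Q = coherence_smooth(gamma, dec.pial, fwhm_mm=5.0,
                             kernel=inverse_setup["kernel"])
        np.testing.assert_allclose(Q, Q.T, atol=1e-12)
        assert np.linalg.eigvalsh(Q).min() > -1e-10

    def test_trace_preserved_on_source_mesh(self, inverse_setup, rng):
        dec = inverse_setup["dec"]
        gamma = rng.uniform(size=dec.n_vertices)
        Q = coherence_smooth(gamma, dec.pial, fwhm_mm=5.0)
        assert np.trace(Q) == pytest.approx(gamma.sum(), rel=0.05)


class TestReml:
    def test_parameter_recovery(self):
        """Recover the scale factors of a 2*Qeps + 3*B covariance mixture
        within 10% over 20 random seeds."""
        worst = 0.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            nc = 16
            A = rng.normal(size=(nc, nc))
            B = A @ A.T / nc
            C = 2.0 * np.eye(nc) + 3.0 * B
            n = 10_000
            Y = np.linalg.cholesky(C) @ rng.normal(size=(nc, n))
            res = reml_optimize(Y @ Y.T / n, (np.eye(nc), B), n)
            rel = np.abs(np.exp(res.lambda_hat) - [2.0, 3.0]) / [2.0, 3.0]
            worst = max(worst, rel.max())
        assert worst < 0.10

    def test_free_energy_identity_and_nonnegative_complexity(self):
        rng = np.random.default_rng(5)
        nc = 12
        A = rng.normal(size=(nc, nc))
        B = A @ A.T / nc
        C = 1.0 * np.eye(nc) + 0.5 * B
        Y = np.linalg.cholesky(C) @ rng.normal(size=(nc, 500))
        res = reml_optimize(Y @ Y.T / 500, (np.eye(nc), B), 500)
        assert res.F == pytest.approx(res.accuracy - res.complexity,
                                      abs=1e-9)
        assert res.complexity >= 0.0

    def test_identity_fit_trace(self):
        """When the model covariance equals the sample covariance the trace
        term is exactly the channel count."""
        rng = np.random.default_rng(2)
        nc = 10
        A = rng.normal(size=(nc, nc))
        B = A @ A.T / nc
        C_Y = 2.0 * np.eye(nc) + 3.0 * B   # population covariance as data
        res = reml_optimize(C_Y, (np.eye(nc), B), 1000, tol=1e-10)
        C_i = np.exp(res.lambda_hat[0]) * np.eye(nc) \
            + np.exp(res.lambda_hat[1]) * B
        assert np.trace(C_Y @ np.linalg.inv(C_i)) == pytest.approx(nc,
                                                                   rel=1e-3)


class TestInvert:
    def test_free_energy_decomposition(self, inverse_setup):
        res = invert(inverse_setup["reduced"], inverse_setup["model"],
                     smoothing_kernel=inverse_setup["kernel"])
        assert res.F == pytest.approx(res.accuracy - res.complexity,
                                      abs=1e-9)
        assert res.complexity >= 0.0

    def test_localization_within_5mm(self, inverse_setup):
        """True-orientation inversion of a clean dataset peaks within 5 mm
        geodesic of the simulated center."""
        res = invert(inverse_setup["reduced"], inverse_setup["model"],
                     smoothing_kernel=inverse_setup["kernel"])
        vtx, tc = peak_vertex(res)
        near = geodesic_distances(inverse_setup["dec"].pial, 17, 5.0)
        assert vtx in near
        assert tc.shape == (25,)

    def test_zero_data_gives_zero_estimate(self, inverse_setup):
        red = inverse_setup["reduced"]
        zero = type(red)(np.zeros_like(red.Y), np.zeros_like(red.Y_trials),
                         red.temporal_projector, red.window, red.fs,
                         red.singular_values)
        res = invert(zero, inverse_setup["model"],
                     smoothing_kernel=inverse_setup["kernel"])
        np.testing.assert_allclose(res.J_hat, 0.0, atol=1e-15)

    def test_rescaling_leaves_free_energy_unchanged(self, inverse_setup):
        """Global rescaling of the data shifts every model's F equally (here:
        not at all, by internal normalization), preserving model ranking."""
        red = inverse_setup["reduced"]
        scaled = type(red)(100.0 * red.Y, 100.0 * red.Y_trials,
                           red.temporal_projector, red.window, red.fs,
                           red.singular_values)
        f0 = invert(red, inverse_setup["model"],
                    smoothing_kernel=inverse_setup["kernel"]).F
        f1 = invert(scaled, inverse_setup["model"],
                    smoothing_kernel=inverse_setup["kernel"]).F
        assert f1 == pytest.approx(f0, abs=1e-6)

    def test_true_model_beats_rotated_model(self, inverse_setup, rng):
        """At 0 dB the true-orientation model exceeds a 45-degree-rotated
        model by more than the +-3 significance threshold."""
        s = inverse_setup
        res0 = invert(s["reduced"], s["model"], smoothing_kernel=s["kernel"])
        rot = rotate_field_on_cone(s["link"], 45.0, rng)
        lf = sphere_leadfield(s["dec"].pial.vertices, rot.vectors,
                              s["helmet"], s["center"])
        model = SourceModel("pial", rot, s["dec"].pial.vertices, lf,
                            s["dec"].pial)
        res1 = invert(s["reduced"], model, smoothing_kernel=s["kernel"])
        assert res0.F - res1.F > 3.0

    def test_peak_vertex_tie_breaks_low_index(self, inverse_setup):
        res = invert(inverse_setup["reduced"], inverse_setup["model"],
                     smoothing_kernel=inverse_setup["kernel"])
        res.J_hat = np.zeros_like(res.J_hat)
        res.J_hat[3] = res.J_hat[7] = 1.0
        vtx, _ = peak_vertex(res)
        assert vtx == 3


def test_result_and_leadfield_io_roundtrip(inverse_setup, tmp_path):
    from orientmeg.forward import read_leadfield, write_leadfield
    from orientmeg.inversion import (read_inversion_result,
                                     write_inversion_result)
    res = invert(inverse_setup["reduced"], inverse_setup["model"],
                 smoothing_kernel=inverse_setup["kernel"])
    write_inversion_result(res, tmp_path / "inv.h5")
    back = read_inversion_result(tmp_path / "inv.h5")
    np.testing.assert_array_equal(back["J_hat"], res.J_hat)
    assert back["F"] == res.F
    assert back["window"] == res.window
    lf = inverse_setup["lf"]
    write_leadfield(lf, tmp_path / "lf.h5")
    lf2 = read_leadfield(tmp_path / "lf.h5")
    np.testing.assert_array_equal(lf2.gain, lf.gain)


class TestSourceModels:
    def test_combined_doubles_sources(self, folded_pair, folded_decimated,
                                      helmet_small):
        dec, dmap = folded_decimated
        single = make_source_model(dec, dmap, helmet_small, "link_vectors",
                                   "pial")
        combined = make_source_model(dec, dmap, helmet_small, "link_vectors",
                                     "combined", "combined")
        assert combined.n_sources == 2 * single.n_sources
        assert combined.leadfield.gain.shape[1] == 2 * single.n_sources

    def test_cross_surface_model(self, folded_pair, folded_decimated,
                                 helmet_small):
        """Source locations and orientation surface can differ."""
        dec, dmap = folded_decimated
        m = make_source_model(dec, dmap, helmet_small,
                              "downsampled_normals", "white", "pial")
        assert m.location_surface == "white"
        assert m.orientation.surface == "pial"
        np.testing.assert_array_equal(m.positions, dec.white.vertices)

    def test_original_mesh_methods_require_pair(self, folded_decimated,
                                                helmet_small):
        dec, dmap = folded_decimated
        with pytest.raises(InversionError, match="original pair"):
            make_source_model(dec, dmap, helmet_small,
                              "cortical_patch_statistics", "pial")
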