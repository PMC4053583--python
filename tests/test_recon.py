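import numpy as np
import pytest

import apitv as av
from apitv.recon import (
    APITV,
    ART,
    ASDPOCS,
    ReconParams,
    api_tv_reconstruct,
    art_reconstruct,
    art_sweep,
    asd_pocs_reconstruct,
    enforce_positivity,
    tv_descent_phase,
)


@pytest.fixture
def tiny_system(rng):
    """Small consistent system: sinogram generated from a known image."""
    geom = av.ScanGeometry(sod=10.0, sdd=20.0, n_views=4, n_det=3,
                           det_pitch=1.5, image_n=2, pixel_size=1.0)
    truth = av.ImageGrid(np.abs(rng.normal(size=(2, 2))) + 0.5)
    sino = av.forward_project(truth, geom)
    return geom, truth, sino


# -- positivity -------------------------------------------------------------


def test_positivity_keeps_positive_images():
    img = av.ImageGrid(np.array([[1.0, 2.0], [0.5, 3.0]]))
    np.testing.assert_array_equal(enforce_positivity(img).data, img.data)


def test_positivity_clamps_negatives():
    img = av.ImageGrid(np.array([[-1.0, 2.0]] * 2))
    np.testing.assert_array_equal(
        enforce_positivity(img).data, np.array([[0.0, 2.0]] * 2)
    )


def test_positivity_idempotent(rng):
    img = av.ImageGrid(rng.normal(size=(4, 4)))
    once = enforce_positivity(img)
    np.testing.assert_array_equal(enforce_positivity(once).data, once.data)


# -- ART --------------------------------------------------------------------


def test_art_converges_on_consistent_system(tiny_system):
    geom, truth, sino = tiny_system
    img = av.ImageGrid(np.zeros((2, 2)))
    norms = av.row_norms(geom)
    for _ in range(50):
        img = art_sweep(img, sino, geom, 1.0, ray_norms=norms)
    residual = np.linalg.norm(av.forward_project(img, geom).data - sino.data)
    assert residual < 1e-10


def test_art_fixed_point_at_solution(tiny_system):
    geom, truth, sino = tiny_system
    after = art_sweep(truth, sino, geom, 1.0)
    np.testing.assert_allclose(after.data, truth.data, atol=1e-12)


def test_art_zero_data_zero_init_stays_zero(tiny_system):
    geom, _, _ = tiny_system
    zero_sino = av.Sinogram(np.zeros((4, 3)), geom)
    img = art_sweep(av.ImageGrid(np.zeros((2, 2))), zero_sino, geom, 1.0)
    np.testing.assert_array_equal(img.data, 0.0)


def test_art_shape_mismatch(tiny_system):
    geom, _, sino = tiny_system
    with pytest.raises(ValueError):
        art_sweep(av.ImageGrid(np.zeros((3, 3))), sino, geom)


# -- TV descent phase -------------------------------------------------------


def test_tv_phase_zero_step_is_identity(rng):
    img = av.ImageGrid(rng.normal(size=(6, 6)))
    out = tv_descent_phase(img, None, ReconParams(alpha=0.0), 0.0)
    np.testing.assert_array_equal(out.data, img.data)


def test_tv_phase_constant_image_unchanged():
    img = av.ImageGrid(np.full((6, 6), 1.5))
    out = tv_descent_phase(img, img, ReconParams(alpha=1.0), 0.1)
    np.testing.assert_array_equal(out.data, img.data)


def test_tv_phase_decreases_blended_objective():
    from apitv.tv import tv_norm

    f = np.zeros((8, 8))
    f[:, 4:] = 1.0
    f[2, 3] = 0.4  # perturb one pixel off the piecewise-constant truth
    truth = np.zeros((8, 8))
    truth[:, 4:] = 1.0
    params = ReconParams(alpha=1.0, n_tv=1, tau=1e-8)
    out = tv_descent_phase(av.ImageGrid(f), av.ImageGrid(truth), params, 0.01)
    before = tv_norm(f - truth, params.tau)
    after = tv_norm(out.data - truth, params.tau)
    assert after < before


# -- solver equivalences ----------------------------------------------------


def test_alpha_zero_is_bit_identical_to_asd_pocs(tiny_system):
    geom, truth, sino = tiny_system
    params = ReconParams(alpha=0.0, n_main=5)
    a = api_tv_reconstruct(sino, geom, prior=None, params=params, truth=truth)
    b = asd_pocs_reconstruct(sino, geom, params=params, truth=truth)
    np.testing.assert_array_equal(a.image.data, b.image.data)
    np.testing.assert_array_equal(a.residual_history, b.residual_history)
    np.testing.assert_array_equal(a.error_history, b.error_history)


def test_art_equals_api_tv_without_tv_phase(tiny_system):
    geom, truth, sino = tiny_system
    a = art_reconstruct(sino, geom, params=ReconParams(n_main=5))
    b = api_tv_reconstruct(
        sino, geom, prior=truth, params=ReconParams(alpha=0.85, n_tv=0, n_main=5)
    )
    np.testing.assert_array_equal(a.image.data, b.image.data)


def test_api_tv_requires_prior_when_alpha_positive(tiny_system):
    geom, _, sino = tiny_system
    with pytest.raises(ValueError, match="prior"):
        APITV(sino, geom, prior=None, params=ReconParams(alpha=0.85))


def test_prior_grid_mismatch_rejected(tiny_system):
    geom, _, sino = tiny_system
    bad_prior = av.ImageGrid(np.zeros((4, 4)))
    with pytest.raises(ValueError):
        APITV(sino, geom, prior=bad_prior, params=ReconParams())


# -- stopping and determinism ----------------------------------------------


def test_epsilon_zero_runs_all_main_loops(tiny_system):
    geom, truth, sino = tiny_system
    res = asd_pocs_reconstruct(sino, geom, params=ReconParams(n_main=7))
    assert res.iterations_run == 7
    assert len(res.residual_history) == 7


def test_huge_epsilon_stops_immediately(tiny_system):
    geom, _, sino = tiny_system
    res = asd_pocs_reconstruct(sino, geom, params=ReconParams(n_main=7, epsilon=1e12))
    assert res.iterations_run == 1


def test_shuffled_ray_order_is_deterministic_given_seed(tiny_system):
    geom, truth, sino = tiny_system
    params = ReconParams(n_main=4, ray_order="shuffle", seed=7)
    a = asd_pocs_reconstruct(sino, geom, params=params, truth=truth)
    b = asd_pocs_reconstruct(sino, geom, params=params, truth=truth)
    np.testing.assert_array_equal(a.image.data, b.image.data)
    np.testing.assert_array_equal(a.residual_history, b.residual_history)


# -- invariants on the half-scale study ------------------------------------


def test_outputs_are_nonnegative(sino128, truth128):
    geom = sino128.geom
    params = ReconParams(n_main=3)
    for model in (ART, ASDPOCS):
        res = model(sino128, geom, params=params).fit()
        assert np.all(res.image.data >= 0.0)
    res = APITV(sino128, geom, prior=truth128, params=params).fit()
    assert np.all(res.image.data >= 0.0)


def test_perfect_prior_beats_asd_pocs_everywhere(sino128, truth128):
    """With the truth supplied as prior, the prior-regularized arm is at
    least as accurate as ASD-POCS at every recorded iteration."""
    geom = sino128.geom
    params = ReconParams(n_main=15)
    api = APITV(sino128, geom, prior=truth128, params=params, truth=truth128).fit()
    asd = ASDPOCS(sino128, geom, params=params, truth=truth128).fit()
    assert np.all(api.error_history <= asd.error_history)


def test_tv_regularization_beats_plain_art(sino128, truth128):
    geom = sino128.geom
    params = ReconParams(n_main=15)
    art = ART(sino128, geom, params=params, truth=truth128).fit()
    asd = ASDPOCS(sino128, geom, params=params, truth=truth128).fit()
    assert asd.final_error < art.final_error


def test_residual_history_decreases_early_on_consistent_data(sino128, truth128):
    res = ASDPOCS(sino128, sino128.geom, params=ReconParams(n_main=10)).fit()
    assert np.all(np.diff(res.residual_history) < 0)


def test_dense_view_art_converges_toward_truth(truth128):
    geom = av.ScanGeometry(n_views=240, n_det=256, image_n=128)
    sino = av.forward_project(truth128, geom)
    res = ART(sino, geom, params=ReconParams(n_main=10), truth=truth128).fit()
    assert np.all(np.diff(res.error_history) < 0)
    assert res.final_error < res.error_history[0] / 10


# -- results object ---------------------------------------------------------


def test_results_summary_and_histories(tiny_system):
    geom, truth, sino = tiny_system
    res = asd_pocs_reconstruct(sino, geom, params=ReconParams(n_main=3), truth=truth)
    text = res.summary()
    assert "ASD-POCS" in text and "iterations" in text
    assert len(res.error_history) == res.iterations_run
    curve = av.convergence_curve(res)
    assert len(curve) == 3
    assert np.all(curve["error"].to_numpy() >= 0)


def test_convergence_curve_requires_truth(tiny_system):
    geom, _, sino = tiny_system
    res = asd_pocs_reconstruct(sino, geom, params=ReconParams(n_main=2))
    with pytest.raises(ValueError, match="truth"):
        av.convergence_curve(res)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(alpha=1.5),
        dict(lambda_art=0.0),
        dict(lambda_art=2.0),
        dict(n_main=0),
        dict(epsilon=-1.0),
        dict(tv_step_rule="bogus"),
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        ReconParams(**kwargs)
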