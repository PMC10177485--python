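import numpy as np
import pytest
from scipy.special import roots_legendre
from scipy.spatial.transform import Rotation

from verdictbrain import compartments as cpt
from verdictbrain.scheme import AcquisitionScheme

MU = np.array([0.3, 0.5, np.sqrt(1 - 0.34)])


def dense_direction_average(d, scheme, kappa=None, mu=None, n_polar=128, n_azim=128):
    """Brute-force (Watson-weighted) spherical average of stick attenuations
    on a dense deterministic grid; independent oracle for AstroSticks and
    WatsonSticks."""
    t, w = roots_legendre(n_polar)
    t = 0.5 * (t + 1.0)
    w = 0.5 * w
    phi = 2 * np.pi * np.arange(n_azim) / n_azim
    s = np.sqrt(1 - t**2)
    vecs = np.column_stack([
        np.outer(s, np.cos(phi)).ravel(),
        np.outer(s, np.sin(phi)).ravel(),
        np.repeat(t, n_azim),
    ])
    if kappa is None:
        dens = np.repeat(w, n_azim)
    else:
        mu = np.asarray(mu, float)
        dens = np.repeat(w, n_azim) * np.exp(kappa * ((vecs @ mu) ** 2) - kappa)
    dens = dens / dens.sum()
    proj2 = (scheme.directions @ vecs.T) ** 2
    out = np.exp(-scheme.b_si[:, None] * d * proj2) @ dens
    return np.where(scheme.is_b0, 1.0, out)


ALL_KERNELS = [
    ("ball", lambda s: cpt.ball_signal(2e-9, s)),
    ("stick", lambda s: cpt.stick_signal(2e-9, MU, s)),
    ("zeppelin", lambda s: cpt.zeppelin_signal(1.5e-9, 0.5e-9, MU, s)),
    ("tensor", lambda s: cpt.tensor_signal(
        [1.7e-9, 0.5e-9, 0.3e-9], cpt.tensor_frame(1.0, 0.4, 0.2), s)),
    ("astrosticks", lambda s: cpt.astrosticks_signal(1.5e-8, s)),
    ("sphere", lambda s: cpt.sphere_signal(0.9e-9, 8.0, s)),
    ("cylinder", lambda s: cpt.cylinder_signal(1.5e-9, 5.0, MU, s)),
    ("watson", lambda s: cpt.watson_sticks_signal(2e-9, 3.0, MU, s)),
]


@pytest.mark.parametrize("name,kernel", ALL_KERNELS, ids=[k[0] for k in ALL_KERNELS])
def test_unit_attenuation_at_b0_and_range(name, kernel, protocol):
    sig = kernel(protocol)
    assert np.all(sig[protocol.is_b0] == 1.0)
    assert np.all(sig > 0) and np.all(sig <= 1.0 + 1e-12)


class TestClosedForms:
    def test_ball(self, one_shot):
        s = one_shot(1000, 10, 50)
        assert cpt.ball_signal(3e-9, s)[0] == pytest.approx(np.exp(-3), rel=1e-10)
        s50 = one_shot(50, 5, 22)
        # vascular pseudo-diffusivity regime
        assert cpt.ball_signal(1.5e-8, s50)[0] == pytest.approx(np.exp(-0.75), rel=1e-10)

    def test_stick_projections(self, one_shot):
        s = one_shot(1000, 10, 50, direction=(1, 0, 0))
        assert cpt.stick_signal(2e-9, [0, 1, 0], s)[0] == pytest.approx(1.0)
        assert cpt.stick_signal(2e-9, [1, 0, 0], s)[0] == pytest.approx(np.exp(-2))

    def test_zeppelin_limits(self, one_shot, weighted):
        s = one_shot(1000, 10, 50, direction=(1, 0, 0))
        assert cpt.zeppelin_signal(2e-9, 2e-9, MU, weighted) == pytest.approx(
            cpt.ball_signal(2e-9, weighted)
        )
        assert cpt.zeppelin_signal(2e-9, 0.5e-9, [1, 0, 0], s)[0] == pytest.approx(
            np.exp(-2)
        )
        assert cpt.zeppelin_signal(2e-9, 0.5e-9, [0, 1, 0], s)[0] == pytest.approx(
            np.exp(-0.5)
        )

    def test_tensor_limits(self, weighted, one_shot):
        frame = cpt.tensor_frame(1.2, -0.7, 0.3)
        iso = cpt.tensor_signal([2e-9] * 3, frame, weighted)
        assert iso == pytest.approx(cpt.ball_signal(2e-9, weighted))
        zep = cpt.tensor_signal([1.7e-9, 0.6e-9, 0.6e-9], frame, weighted)
        assert zep == pytest.approx(
            cpt.zeppelin_signal(1.7e-9, 0.6e-9, frame[:, 0], weighted)
        )
        e1 = cpt.tensor_frame(np.pi / 2, 0.0, 0.0)[:, 0]
        s = one_shot(1000, 10, 50, direction=tuple(e1))
        got = cpt.tensor_signal([1.7e-9, 0.6e-9, 0.3e-9],
                                cpt.tensor_frame(np.pi / 2, 0.0, 0.0), s)[0]
        assert got == pytest.approx(np.exp(-1e9 * 1.7e-9))

    def test_odi(self):
        assert cpt.odi_from_kappa(1.0) == pytest.approx(0.5)
        assert cpt.odi_from_kappa(0.0) == 1.0
        assert cpt.kappa_from_odi(0.5) == pytest.approx(1.0)


class TestOrientationAverages:
    def test_astrosticks_matches_direction_average(self, weighted):
        got = cpt.astrosticks_signal(4e-8, weighted)
        ref = dense_direction_average(4e-8, weighted)
        assert np.abs(got - ref).max() < 1e-6

    def test_astrosticks_dominates_parallel_stick(self, weighted):
        dv = 1.5e-8
        assert np.all(
            cpt.astrosticks_signal(dv, weighted) >= np.exp(-weighted.b_si * dv) - 1e-12
        )

    def test_astrosticks_taylor_branch_continuity(self, one_shot):
        # values straddling the series/closed-form switch at b·dv = 1e-4
        lo = cpt.astrosticks_signal(9.99e-14, one_shot(1000, 10, 50))[0]
        hi = cpt.astrosticks_signal(1.001e-13, one_shot(1000, 10, 50))[0]
        assert abs(lo - hi) < 1e-7

    def test_watson_kappa0_equals_astrosticks(self, weighted):
        got = cpt.watson_sticks_signal(2e-9, 0.0, MU, weighted)
        assert np.abs(got - cpt.astrosticks_signal(2e-9, weighted)).max() < 1e-4

    def test_watson_quadrature_against_dense_oracle(self, weighted):
        for kappa in (1.0, 16.0, 64.0):
            got = cpt.watson_sticks_signal(1.5e-9, kappa, MU, weighted)
            ref = dense_direction_average(1.5e-9, weighted, kappa=kappa, mu=MU,
                                          n_polar=256, n_azim=64)
            assert np.abs(got - ref).max() < 1e-6

    def test_watson_concentration_limit_is_stick(self, weighted):
        got = cpt.watson_sticks_signal(2e-9, 1e4, MU, weighted)
        ref = cpt.stick_signal(2e-9, MU, weighted)
        assert np.abs(got - ref).max() < 1e-3


class TestRestrictedKernels:
    def test_sphere_limits(self, one_shot):
        s = one_shot(2500, 20, 50)
        assert cpt.sphere_signal(0.9e-9, 8.0, s)[1] == 1.0  # b=0 record
        assert cpt.sphere_signal(0.9e-9, 0.05, s)[0] == pytest.approx(1.0, abs=1e-6)

    def test_sphere_monotone_in_gradient(self):
        b_values = [250, 500, 1000, 2000, 3000]
        sch = AcquisitionScheme(
            b=np.array(b_values + [0.0]),
            directions=np.vstack([np.tile([1.0, 0, 0], (5, 1)), [0, 0, 0]]),
            delta=np.full(6, 15.0),
            Delta=np.full(6, 50.0),
            te=np.full(6, 80.0),
            shell=np.array([0, 1, 2, 3, 4, -1]),
        )
        sig = cpt.sphere_signal(0.9e-9, 9.0, sch)[:5]
        assert np.all(np.diff(sig) < 0)

    def test_gpd_regression_values(self, one_shot):
        # frozen from this implementation after verifying the series against
        # the defining autocorrelation double integral and random-walk MC
        got = cpt.sphere_signal(0.9e-9, 10.0, one_shot(2500, 20, 50))[0]
        assert got == pytest.approx(0.4835424576, rel=1e-9)
        got_c = cpt.cylinder_signal(2e-9, 5.0, [0, 0, 1], one_shot(2500, 20, 50))[0]
        assert got_c == pytest.approx(0.8982068372, rel=1e-8)

    def test_gpd_root_tables(self):
        assert cpt._sphere_roots()[0] == pytest.approx(2.0815759778, rel=1e-9)
        assert cpt._cylinder_roots()[0] == pytest.approx(1.8411837813, rel=1e-9)

    def test_cylinder_parallel_is_free(self, one_shot):
        s = one_shot(1000, 10, 50, direction=(0, 0, 1))
        got = cpt.cylinder_signal(2e-9, 5.0, [0, 0, 1], s)[0]
        assert got == pytest.approx(np.exp(-2), rel=1e-12)

    def test_cylinder_narrow_is_unattenuated_perpendicular(self, one_shot):
        s = one_shot(3000, 20, 50, direction=(1, 0, 0))
        got = cpt.cylinder_signal(2e-9, 0.05, [0, 0, 1], s)[0]
        assert got == pytest.approx(1.0, abs=1e-6)


class TestRotationProperties:
    @pytest.mark.parametrize("trial", range(10))
    def test_isotropic_invariance_and_oriented_equivariance(self, trial, weighted):
        rot = Rotation.random(random_state=trial).as_matrix()
        rotated = AcquisitionScheme(
            b=weighted.b.copy(),
            directions=weighted.directions @ rot.T,
            delta=weighted.delta.copy(),
            Delta=weighted.Delta.copy(),
            te=weighted.te.copy(),
            shell=weighted.shell.copy(),
        )
        for iso in (
            lambda s: cpt.ball_signal(2e-9, s),
            lambda s: cpt.astrosticks_signal(1.5e-8, s),
            lambda s: cpt.sphere_signal(0.9e-9, 8.0, s),
        ):
            assert np.allclose(iso(weighted), iso(rotated), atol=1e-12)
        mu_rot = rot @ MU
        assert np.allclose(
            cpt.stick_signal(2e-9, MU, weighted),
            cpt.stick_signal(2e-9, mu_rot, rotated), atol=1e-12,
        )
        assert np.allclose(
            cpt.zeppelin_signal(1.5e-9, 0.5e-9, MU, weighted),
            cpt.zeppelin_signal(1.5e-9, 0.5e-9, mu_rot, rotated), atol=1e-12,
        )
        assert np.allclose(
            cpt.watson_sticks_signal(2e-9, 4.0, MU, weighted),
            cpt.watson_sticks_signal(2e-9, 4.0, mu_rot, rotated), atol=1e-9,
        )


class TestValidation:
    def test_negative_diffusivity_rejected(self, weighted):
        with pytest.raises(ValueError):
            cpt.ball_signal(-1e-9, weighted)
        with pytest.raises(ValueError):
            cpt.zeppelin_signal(0.5e-9, 1e-9, MU, weighted)  # d_par < d_perp
        with pytest.raises(ValueError):
            cpt.sphere_signal(0.9e-9, -1.0, weighted)
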