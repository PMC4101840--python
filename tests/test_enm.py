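"""Spring networks, Hessian mechanics, covariance, and MSF."""

import numpy as np
import pytest

from enmstress import (
    EnsembleParams,
    SiteVector,
    build_anm,
    build_hessian,
    build_pfanm,
    covariance_from_hessian,
    msf_approx,
    msf_from_covariance,
    potential_energy,
    site_stiffness,
    znorm,
)

from conftest import collinear_trace, triangle_trace, two_site_trace


class TestNetworkConstruction:
    def test_pfanm_inverse_square_constants(self):
        net = build_pfanm(two_site_trace(2.0))
        assert net.kij[0, 1] == pytest.approx(0.25)

    def test_pfanm_triangle_unit_constants(self):
        net = build_pfanm(triangle_trace(1.0))
        off = net.kij[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_pfanm_collinear_constant_ratio(self):
        net = build_pfanm(collinear_trace())
        assert net.kij[0, 1] == pytest.approx(1 / 3.8**2)
        assert net.kij[1, 2] == pytest.approx(1 / 3.8**2)
        assert net.kij[0, 2] / net.kij[0, 1] == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "distance, expected_k", [(5.0, 1.0), (13.0, 1.0), (14.0, 0.0)]
    )
    def test_anm_cutoff_boundary_inclusive(self, distance, expected_k):
        net = build_anm(two_site_trace(distance), rcut=13.0)
        assert net.kij[0, 1] == expected_k

    def test_rest_lengths_equal_equilibrium_distances(self, globule):
        net = build_pfanm(globule)
        np.testing.assert_allclose(net.d0, globule.distance_matrix())


class TestSiteStiffness:
    def test_collinear_hand_summation(self):
        k = site_stiffness(build_pfanm(collinear_trace())).values
        assert k[0] == pytest.approx(1 / 3.8**2 + 1 / 7.6**2)
        assert k[1] == pytest.approx(2 / 3.8**2)

    def test_anm_triangle(self):
        k = site_stiffness(build_anm(triangle_trace(5.0), rcut=13.0)).values
        np.testing.assert_allclose(k, 2.0)

    def test_double_counting_identity(self, globule):
        net = build_pfanm(globule)
        total = site_stiffness(net).values.sum()
        iu = np.triu_indices(net.n_sites, k=1)
        assert total == pytest.approx(2.0 * net.kij[iu].sum())


class TestPotentialEnergy:
    def test_zero_at_equilibrium(self, globule, helix50):
        for trace in (globule, helix50):
            for net in (build_pfanm(trace), build_anm(trace)):
                assert potential_energy(net, trace.coords) == 0.0

    def test_single_stretched_spring(self):
        from enmstress import SpringNetwork

        trace = two_site_trace(3.8)
        net = SpringNetwork(
            trace=trace,
            model="custom",
            kij=np.array([[0.0, 2.0], [2.0, 0.0]]),
            d0=trace.distance_matrix(),
        )
        conf = np.array([[0.0, 0, 0], [4.3, 0, 0]])
        assert potential_energy(net, conf) == pytest.approx(0.5 * 2.0 * 0.25)

    def test_dimension_mismatch_raises(self, globule):
        net = build_pfanm(globule)
        with pytest.raises(ValueError):
            potential_energy(net, globule.coords[:-1])

    def test_quadratic_consistency_with_hessian(self, globule):
        net = build_pfanm(globule)
        h = build_hessian(net)
        rng = np.random.default_rng(0)
        u = rng.normal(size=3 * net.n_sites)
        u *= 1e-3 / np.linalg.norm(u)
        v = potential_energy(net, globule.coords + u.reshape(-1, 3))
        quad = 0.5 * u @ h @ u
        assert abs(v - quad) / quad < 1e-3


class TestHessian:
    def test_symmetry(self, globule):
        h = build_hessian(build_pfanm(globule))
        assert np.max(np.abs(h - h.T)) < 1e-12

    def test_translation_and_rotation_invariance(self, globule):
        h = build_hessian(build_pfanm(globule))
        n = globule.n_sites
        for axis in range(3):
            t = np.zeros((n, 3))
            t[:, axis] = 1.0
            assert np.max(np.abs(h @ t.ravel())) < 1e-10
        centred = globule.coords - globule.coords.mean(axis=0)
        for axis in range(3):
            omega = np.zeros(3)
            omega[axis] = 1.0
            rot = np.cross(omega, centred)
            assert np.max(np.abs(h @ rot.ravel())) < 1e-8

    def test_matches_finite_difference_of_potential(self):
        from enmstress import make_helix_trace

        from conftest import finite_difference_hessian

        trace = make_helix_trace(20)
        net = build_pfanm(trace)
        h = build_hessian(net)
        num = finite_difference_hessian(net, step=1e-4)
        assert np.max(np.abs(num - h)) < 1e-5 * np.max(np.abs(h))


class TestCovariance:
    def test_two_site_analytic_spectrum_and_msf(self, params):
        # single spring k: one vibrational mode of eigenvalue 2k, 5 rigid modes
        k = 1.0
        net = build_pfanm(two_site_trace(1.0))  # d=1 gives k=1
        h = build_hessian(net)
        cov = covariance_from_hessian(h, expected_zero_modes=5)
        nonzero = cov.eigenvalues[cov.eigenvalues > 1e-8]
        assert nonzero.size == 1
        assert nonzero[0] == pytest.approx(2 * k)
        msf = msf_from_covariance(cov, params)
        np.testing.assert_allclose(msf.values, 1 / (4 * k))

    def test_connected_globule_has_six_zero_modes(self, globule):
        for net in (build_pfanm(globule), build_anm(globule)):
            cov = covariance_from_hessian(build_hessian(net))
            assert cov.n_zero_modes == 6

    def test_pseudo_inverse_defining_property(self, globule):
        h = build_hessian(build_pfanm(globule))
        c = covariance_from_hessian(h).covariance
        resid = np.linalg.norm(h @ c @ h - h) / np.linalg.norm(h)
        assert resid < 1e-6

    def test_disconnected_anm_reports_excess_zero_modes(self, globule):
        h = build_hessian(build_anm(globule, rcut=4.0))
        with pytest.raises(ValueError, match="disconnected or degenerate"):
            covariance_from_hessian(h)


class TestMsf:
    def test_positive_everywhere(self, globule, helix50, params):
        for trace in (globule, helix50):
            cov = covariance_from_hessian(build_hessian(build_pfanm(trace)))
            assert msf_from_covariance(cov, params).values.min() > 0

    def test_beta_rescales_msf_but_not_zscores(self, globule):
        cov = covariance_from_hessian(build_hessian(build_pfanm(globule)))
        msf1 = msf_from_covariance(cov, EnsembleParams(beta=1.0), "g")
        msf2 = msf_from_covariance(cov, EnsembleParams(beta=2.0), "g")
        np.testing.assert_allclose(msf2.values, msf1.values / 2)
        np.testing.assert_allclose(
            znorm(msf1).values, znorm(msf2).values, atol=1e-12
        )

    def test_helix_termini_more_mobile_than_core(self, helix50, params):
        cov = covariance_from_hessian(build_hessian(build_pfanm(helix50)))
        msf = msf_from_covariance(cov, params).values
        assert msf[0] > msf[25] and msf[-1] > msf[25]

    def test_exact_msf_vs_independent_pinv(self, helix50, params):
        h = build_hessian(build_pfanm(helix50))
        cov = covariance_from_hessian(h)
        msf = msf_from_covariance(cov, params).values
        # independent dense-solver route
        c_ref = np.linalg.pinv(h, rcond=1e-8, hermitian=True)
        msf_ref = np.diag(c_ref).reshape(-1, 3).sum(axis=1)
        np.testing.assert_allclose(msf, msf_ref, rtol=1e-8)


class TestMsfApprox:
    def test_point_value(self, params):
        k = SiteVector("p", np.array([1.5, 3.0]), "k_i")
        np.testing.assert_allclose(msf_approx(k, params).values, [1.0, 0.5])

    def test_zscored_approx_equals_zscored_reciprocal_stiffness(self, globule, params):
        k = site_stiffness(build_pfanm(globule))
        approx = msf_approx(k, params)
        recip = SiteVector(globule.protein_id, 1.0 / k.values, "other")
        np.testing.assert_allclose(
            znorm(approx).values, znorm(recip).values, atol=1e-10
        )

    def test_rejects_zero_stiffness(self, params):
        with pytest.raises(ValueError):
            msf_approx(SiteVector("p", np.array([1.0, 0.0]), "k_i"), params)

    def test_tracks_exact_msf_on_globules(self, globules, params):
        from enmstress import pearson

        for trace in globules:
            net = build_pfanm(trace)
            cov = covariance_from_hessian(build_hessian(net))
            exact = msf_from_covariance(cov, params, trace.protein_id)
            approx = msf_approx(site_stiffness(net), params)
            assert pearson(znorm(exact).values, znorm(approx).values) > 0.6
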