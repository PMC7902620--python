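"""Chain-observable identities, independent brute-force oracles and
parameter-recovery checks."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from idpchain import (
    ChainModelSpec,
    CorrelationProfile,
    Ensemble,
    InternalDistanceProfile,
    contact_count_series,
    contact_map,
    fit_flory,
    fit_flory_two_regime,
    fit_persistence,
    fit_power_law_tail,
    generate_freely_rotating,
    internal_distance_profile,
    orientational_correlation,
    radius_of_gyration,
    rg_histogram,
)
from idpchain.exceptions import FitError, IdpChainError
from idpchain.hremd_tools import ScalarSeries


def single_frame(points):
    return Ensemble(coords=np.asarray(points, dtype=float)[None, :, :])


class TestRadiusOfGyration:
    def test_two_beads(self):
        ens = single_frame([[0, 0, 0], [1.0, 0, 0]])
        assert radius_of_gyration(ens).value[0] == pytest.approx(0.5)

    def test_square_corners(self):
        # four beads on a square of side a: every bead is a/sqrt(2) from
        # the centroid, so Rg = a/sqrt(2)
        a = 0.7
        ens = single_frame([[0, 0, 0], [a, 0, 0], [a, a, 0], [0, a, 0]])
        assert radius_of_gyration(ens).value[0] == pytest.approx(
            a / np.sqrt(2)
        )

    def test_ideal_chain_closed_form(self, fjc_large):
        # discrete ideal chain: <Rg^2> = b^2 (N^2 - 1) / (6N) ~ (N-1)b^2/6
        rg2 = radius_of_gyration(fjc_large).value ** 2
        expected = 0.38**2 * (100**2 - 1) / (6 * 100)
        assert rg2.mean() == pytest.approx(expected, rel=0.05)


class TestRgHistogram:
    def test_constant_series(self):
        s = ScalarSeries(t=np.arange(4), value=np.full(4, 1.5))
        h = rg_histogram(s, n_bins=5)
        assert np.count_nonzero(h.density) == 1
        assert h.mean == 1.5

    def test_density_normalised(self, rng):
        s = ScalarSeries(t=np.arange(500), value=rng.gamma(3.0, size=500))
        h = rg_histogram(s, n_bins=20)
        widths = np.diff(h.edges)
        assert (h.density * widths).sum() == pytest.approx(1.0)

    def test_histogram_mean_consistent(self, rng):
        s = ScalarSeries(t=np.arange(2000), value=rng.normal(3, 0.5, 2000))
        h = rg_histogram(s, n_bins=30)
        centers = 0.5 * (h.edges[:-1] + h.edges[1:])
        widths = np.diff(h.edges)
        binned_mean = (centers * h.density * widths).sum()
        assert abs(binned_mean - h.mean) < widths.max()

    def test_too_few_bins(self):
        s = ScalarSeries(t=np.arange(3), value=np.arange(3.0))
        with pytest.raises(IdpChainError):
            rg_histogram(s, n_bins=1)


def brute_force_correlation(ens, s_max):
    """Double loop over frames and bond indices — independent oracle."""
    out = []
    for s in range(1, s_max + 1):
        acc = []
        for t in range(ens.n_frames):
            bonds = np.diff(ens.coords[t], axis=0)
            u = bonds / np.linalg.norm(bonds, axis=1, keepdims=True)
            for i in range(u.shape[0] - s):
                acc.append(float(u[i] @ u[i + s]))
        out.append(np.mean(acc))
    return np.array(out)


class TestOrientationalCorrelation:
    def test_rod_is_fully_correlated(self, rod):
        prof = orientational_correlation(rod)
        np.testing.assert_allclose(prof.value, 1.0, atol=1e-12)

    def test_right_angle_kink(self):
        ens = single_frame([[0, 0, 0], [0.38, 0, 0], [0.38, 0.38, 0]])
        prof = orientational_correlation(ens, s_max=1)
        assert prof.value[0] == pytest.approx(0.0, abs=1e-15)

    def test_matches_brute_force_exactly(self, small_random_ensemble):
        prof = orientational_correlation(small_random_ensemble, s_max=5)
        oracle = brute_force_correlation(small_random_ensemble, 5)
        np.testing.assert_allclose(prof.value, oracle, rtol=1e-12)

    def test_freely_rotating_oracle(self):
        ens = generate_freely_rotating(
            ChainModelSpec(60, 3000, bond_cos=0.5, seed=8)
        )
        prof = orientational_correlation(ens, s_max=3)
        # s = 1 is exact by cone construction (stderr 0); s = 2 is sampled
        for s, expected in ((1, 0.5), (2, 0.25)):
            assert abs(prof.at(s) - expected) <= 3 * prof.stderr[s - 1] + 1e-12

    def test_zero_length_bond_names_location(self):
        coords = np.zeros((1, 3, 3))
        coords[0, 2] = [1, 0, 0]  # residues 1 and 2 coincide
        with pytest.raises(IdpChainError, match="frame 0"):
            orientational_correlation(Ensemble(coords=coords), s_max=1)


class TestPersistenceFit:
    def test_exact_exponential_decay(self):
        s = np.arange(1, 8)
        prof = CorrelationProfile(s=s, value=np.exp(-s / 1.6))
        fit = fit_persistence(prof)
        assert fit.k == pytest.approx(1.6, abs=1e-12)
        assert fit.l_p == pytest.approx(0.608, abs=1e-12)

    def test_decay_constant_from_bond_cosine(self):
        # freely rotating chain with g = 0.8: C(s) = g^s, k = -1/ln g
        s = np.arange(1, 6)
        prof = CorrelationProfile(s=s, value=0.8**s)
        fit = fit_persistence(prof)
        assert fit.k == pytest.approx(-1 / np.log(0.8), abs=1e-10)

    def test_no_decay_is_an_error(self):
        prof = CorrelationProfile(s=np.arange(1, 6), value=np.ones(5))
        with pytest.raises(FitError, match="decay"):
            fit_persistence(prof)

    def test_nonpositive_values_suggest_shorter_range(self):
        prof = CorrelationProfile(
            s=np.arange(1, 5), value=[0.5, 0.2, -0.01, 0.01]
        )
        with pytest.raises(FitError, match="shorter"):
            fit_persistence(prof, s_fit_max=4)


class TestPowerLawTail:
    @pytest.mark.parametrize("exponent", [-1.5, 0.0, -2.0])
    def test_identity_recovery(self, exponent):
        s = np.arange(5, 14)
        prof = CorrelationProfile(s=s, value=s.astype(float) ** exponent)
        fit = fit_power_law_tail(prof, 5, 13)
        assert fit.exponent == pytest.approx(exponent, abs=1e-10)

    def test_nonpositive_values_rejected(self):
        prof = CorrelationProfile(s=np.arange(5, 10),
                                  value=[1, 0.5, 0.0, 0.2, 0.1])
        with pytest.raises(FitError):
            fit_power_law_tail(prof, 5, 9)


class TestInternalDistances:
    def test_rod_linear_scaling(self, rod):
        prof = internal_distance_profile(rod)
        np.testing.assert_allclose(prof.r, 0.38 * prof.s, rtol=1e-12)

    def test_three_bead_hand_computation(self):
        ens = single_frame([[0, 0, 0], [0.38, 0, 0], [0.38, 0.38, 0]])
        prof = internal_distance_profile(ens)
        assert prof.r[0] == pytest.approx(0.38)
        assert prof.r[1] == pytest.approx(0.38 * np.sqrt(2))

    def test_ideal_chain_mean_squared_distance(self, fjc_large):
        # <R_s^2> = s b^2 exactly for the freely jointed chain
        for s in (5, 10, 20):
            d2 = (
                np.linalg.norm(
                    fjc_large.coords[:, s:, :] - fjc_large.coords[:, :-s, :],
                    axis=2,
                )
                ** 2
            )
            per_frame = d2.mean(axis=1)
            se = per_frame.std() / np.sqrt(per_frame.size)
            assert abs(per_frame.mean() - s * 0.38**2) < 3 * se

    def test_ideal_chain_mean_distance_gaussian_limit(self, fjc_large):
        # for Gaussian-distributed R_s, <|R_s|> = sqrt(8 s / (3 pi)) b
        prof = internal_distance_profile(fjc_large)
        for s in (15, 25):
            expected = np.sqrt(8 * s / (3 * np.pi)) * 0.38
            assert prof.r[s - 1] == pytest.approx(expected, rel=0.02)


class TestFloryFits:
    def test_noiseless_identity_recovery(self):
        s = np.arange(1, 60)
        prof = InternalDistanceProfile(s=s, r=0.4 * s**0.70)
        reg = fit_flory(prof, 1, 10)
        assert reg.nu == pytest.approx(0.70, abs=1e-6)
        assert reg.r0 == pytest.approx(0.4, abs=1e-6)

    def test_two_regime_piecewise_power_law(self):
        # nu = 0.70 below the split, 0.43 above, joined continuously at s=10
        s = np.arange(1, 60)
        r = np.where(s <= 10, 0.4 * s**0.70,
                     0.4 * 10**0.70 * (s / 10) ** 0.43)
        fit = fit_flory_two_regime(InternalDistanceProfile(s=s, r=r))
        assert fit.tail_fitted
        assert fit.regimes[0].nu == pytest.approx(0.70, abs=1e-6)
        assert fit.regimes[0].r0 == pytest.approx(0.4, abs=1e-6)
        assert fit.regimes[1].nu == pytest.approx(0.43, abs=1e-6)

    def test_rod_has_unit_exponent_in_both_regimes(self):
        # a 30-bead rod, long enough for the tail regime
        coords = np.zeros((1, 30, 3))
        coords[..., 0] = 0.38 * np.arange(30)
        fit = fit_flory_two_regime(
            internal_distance_profile(Ensemble(coords=coords))
        )
        for reg in fit.regimes:
            assert reg.nu == pytest.approx(1.0, abs=1e-10)
            assert reg.r0 == pytest.approx(0.38, abs=1e-10)

    def test_gaussian_coil_tail_exponent(self, fjc_large):
        prof = internal_distance_profile(fjc_large)
        fit = fit_flory_two_regime(prof, split=10, s_max=50)
        tail = fit.regimes[1]
        assert abs(tail.nu - 0.5) < 3 * max(tail.nu_stderr, 0.005)

    def test_short_profile_skips_tail_regime(self):
        s = np.arange(1, 12)
        prof = InternalDistanceProfile(s=s, r=0.4 * s**0.5)
        fit = fit_flory_two_regime(prof, split=10)
        assert not fit.tail_fitted
        assert len(fit.regimes) == 1


class TestContacts:
    def test_rod_has_no_nonlocal_contacts(self, rod):
        series = contact_count_series(rod, cutoff=0.5, min_separation=2)
        assert (series.value == 0).all()

    def test_collapsed_cluster_is_complete_graph(self, rng):
        n = 8
        coords = rng.normal(scale=0.01, size=(2, n, 3))
        series = contact_count_series(Ensemble(coords=coords), cutoff=0.8,
                                      min_separation=1)
        assert (series.value == n * (n - 1) / 2).all()

    def test_zero_cutoff_gives_zero_contacts(self, small_random_ensemble):
        series = contact_count_series(small_random_ensemble, cutoff=0.0,
                                      min_separation=1)
        assert (series.value == 0).all()

    def test_contact_map_band_structure(self, rod):
        cmap = contact_map(rod, cutoff=0.5)  # < 2 bonds' reach
        assert np.allclose(np.diag(cmap), 1.0)
        band = np.abs(np.subtract.outer(*[np.arange(10)] * 2)) <= 1
        assert (cmap[~band] == 0).all()
        assert (cmap[band] == 1).all()

    def test_contact_map_symmetric_and_bounded(self, small_random_ensemble):
        cmap = contact_map(small_random_ensemble, cutoff=0.8)
        np.testing.assert_array_equal(cmap, cmap.T)
        assert ((0 <= cmap) & (cmap <= 1)).all()


class TestRigidMotionInvariance:
    def test_observables_invariant_under_rotation_translation(
        self, small_random_ensemble, rng
    ):
        ens = small_random_ensemble
        moved = np.empty_like(ens.coords)
        for t in range(ens.n_frames):
            quat = rng.normal(size=4)
            rot = Rotation.from_quat(quat / np.linalg.norm(quat))
            moved[t] = rot.apply(ens.coords[t]) + rng.uniform(-3, 3, 3)
        ens2 = Ensemble(coords=moved)
        np.testing.assert_allclose(
            radius_of_gyration(ens2).value,
            radius_of_gyration(ens).value, rtol=1e-10,
        )
        np.testing.assert_allclose(
            internal_distance_profile(ens2).r,
            internal_distance_profile(ens).r, rtol=1e-10,
        )
        np.testing.assert_allclose(
            orientational_correlation(ens2, 5).value,
            orientational_correlation(ens, 5).value, atol=1e-10,
        )
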