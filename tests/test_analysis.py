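"""Density profiles, fronts, correlation functions, fits, Flory-Huggins."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bfmswell import (
    CHAIN,
    DRUG,
    SOLVENT,
    FrontThresholds,
    correlation_analysis,
    density_profiles,
    detect_fronts,
    fit_exponential,
    fit_powerlaw,
    flory_huggins_chi,
    flory_huggins_chi_general,
    orientational_correlation,
    swelling_content,
    swelling_kinetics_fit,
    translational_correlation,
)
from bfmswell.analysis import DensityProfiles


# ---------------------------------------------------------------------------
# Density profiles
# ---------------------------------------------------------------------------


class TestDensityProfiles:
    def test_plaquette_mass_splits_across_two_rows(self, make_traj):
        traj = make_traj(
            pos=[[[3, 7]]], species=[DRUG], chain_id=[-1], index_in_chain=[-1],
            width=16, height=16,
        )
        profiles = density_profiles(traj, bin_width=1)
        rho = profiles.rho[DRUG][0]
        assert rho[7] > 0 and rho[8] > 0
        assert np.count_nonzero(rho) == 2
        assert rho[7] == pytest.approx(2 / 16)

    def test_profiles_conserve_species_totals(self, mini_trajectory):
        profiles = density_profiles(mini_trajectory, bin_width=2)
        area = profiles.bin_width * profiles.box_width
        for species in (CHAIN, DRUG, SOLVENT):
            n = np.count_nonzero(mini_trajectory.species == species)
            sums = profiles.rho[species].sum(axis=1) * area
            assert np.allclose(sums, 4 * n)

    def test_bin_width_below_one_is_error(self, mini_trajectory):
        with pytest.raises(ValueError):
            density_profiles(mini_trajectory, bin_width=0)

    def test_chain_and_solvent_profiles_are_complementary(self, mini_trajectory):
        """Where polymer density is high, solvent density is low (the two
        most abundant species compete for the same sites)."""
        profiles = density_profiles(mini_trajectory, bin_width=4)
        rho_c = profiles.rho[CHAIN][-1]
        rho_s = profiles.rho[SOLVENT][-1]
        dense_c = rho_c > np.median(rho_c[rho_c > 0])
        sparse_c = (rho_c > 0) & ~dense_c
        assert rho_s[dense_c].mean() < rho_s[sparse_c].mean()


# ---------------------------------------------------------------------------
# Fronts
# ---------------------------------------------------------------------------


def _step_profiles(n_bins=60, sf_pos=20, ef_pos=40, pf_pos=10):
    """A monotone hydration stack: glassy core below sf_pos (bulk chain
    density), gel up to ef_pos (half density), solvent penetrating down to
    pf_pos."""
    y = np.arange(n_bins) + 0.5
    rho_c = np.where(y < sf_pos, 0.8, np.where(y < ef_pos, 0.3, 0.0))
    rho_s = np.where(y > pf_pos, np.where(y < sf_pos, 0.2, 0.7), 0.0)
    rho_d = np.zeros(n_bins)
    return DensityProfiles(
        times=np.array([0]),
        bin_edges=np.arange(n_bins + 1.0),
        bin_width=1,
        box_width=64,
        rho={CHAIN: rho_c[None], SOLVENT: rho_s[None], DRUG: rho_d[None]},
    )


class TestFronts:
    def test_step_profiles_yield_fronts_at_step_locations(self):
        profiles = _step_profiles()
        thresholds = FrontThresholds(theta_pf=0.05, theta_sf=0.4, theta_ef=0.05)
        fronts = detect_fronts(profiles, thresholds)
        assert fronts.pf[0] == pytest.approx(10, abs=1.0)
        assert fronts.sf[0] == pytest.approx(20, abs=1.0)
        assert fronts.ef[0] == pytest.approx(40, abs=1.0)

    def test_monotone_stack_orders_pf_sf_ef(self):
        fronts = detect_fronts(
            _step_profiles(), FrontThresholds(theta_pf=0.05, theta_sf=0.4, theta_ef=0.05)
        )
        assert fronts.pf[0] <= fronts.sf[0] <= fronts.ef[0]

    def test_all_zero_profiles_give_missing_fronts(self):
        n = 20
        profiles = DensityProfiles(
            times=np.array([0]),
            bin_edges=np.arange(n + 1.0),
            bin_width=1,
            box_width=16,
            rho={s: np.zeros((1, n)) for s in (CHAIN, DRUG, SOLVENT)},
        )
        fronts = detect_fronts(
            profiles, FrontThresholds(theta_pf=0.1, theta_sf=0.1, theta_ef=0.1)
        )
        assert math.isnan(fronts.pf[0]) and math.isnan(fronts.ef[0])

    def test_simulated_run_penetration_advances_and_erosion_recedes(self, mini_trajectory):
        profiles = density_profiles(mini_trajectory, bin_width=2)
        fronts = detect_fronts(profiles)
        # solvent reaches deeper and the outermost polymer moves outward
        assert fronts.pf[-1] < fronts.pf[0]
        assert fronts.ef[-1] > fronts.ef[0]


# ---------------------------------------------------------------------------
# Correlation functions
# ---------------------------------------------------------------------------


class TestOrientationalCorrelation:
    def test_initial_value_is_one_and_frozen_chains_stay_one(self, make_traj):
        # two frozen 2-mers, repeated over 4 snapshots
        frame = [[2, 2], [4, 3], [10, 10], [12, 11]]
        traj = make_traj(
            pos=[frame] * 4,
            species=[CHAIN] * 4,
            chain_id=[0, 0, 1, 1],
            index_in_chain=[0, 1, 0, 1],
        )
        times, cee = orientational_correlation(traj)
        assert cee[0] == pytest.approx(1.0)
        assert np.allclose(cee, 1.0)

    def test_uniform_random_reorientation_decorrelates(self, make_traj):
        from bfmswell.bfm_core import BOND_LENGTHS_SQ, enumerate_bond_vectors

        rng = np.random.default_rng(5)
        vectors = np.array(sorted(enumerate_bond_vectors(BOND_LENGTHS_SQ)))
        n_chains = 400
        heads = np.column_stack(
            [np.arange(n_chains) * 0 + 50, np.arange(n_chains) * 0 + 50]
        )
        frames = []
        for snap in range(2):
            v = vectors[rng.integers(len(vectors), size=n_chains)]
            frame = np.zeros((2 * n_chains, 2), dtype=int)
            frame[0::2] = heads
            frame[1::2] = heads + v
            frames.append(frame)
        traj = make_traj(
            pos=frames,
            species=[CHAIN] * (2 * n_chains),
            chain_id=np.repeat(np.arange(n_chains), 2),
            index_in_chain=np.tile([0, 1], n_chains),
            width=128, height=128,
        )
        _, cee = orientational_correlation(traj)
        # per-chain products give the sampling error of the ensemble mean
        v0 = frames[0][1::2] - frames[0][0::2]
        v1 = frames[1][1::2] - frames[1][0::2]
        prods = (v0 * v1).sum(axis=1) / (v0 * v0).sum(axis=1).mean()
        sem = prods.std(ddof=1) / math.sqrt(n_chains)
        assert abs(cee[1]) < 3 * sem

    def test_no_activated_chains_gives_empty_result(self, make_traj):
        traj = make_traj(
            pos=[[[2, 2], [4, 3]]] * 2,
            species=[CHAIN, CHAIN],
            chain_id=[0, 0],
            index_in_chain=[0, 1],
            chain_active=np.zeros((2, 1), dtype=bool),
        )
        times, cee = orientational_correlation(traj)
        assert times.size == 0 and cee.size == 0


class TestTranslationalCorrelation:
    def test_zero_at_t0_and_rigid_translation(self, make_traj):
        frame0 = [[2, 2], [4, 3], [10, 10], [12, 11]]
        frame1 = [[4, 2], [6, 3], [12, 10], [14, 11]]  # all chains shifted (2,0)
        traj = make_traj(
            pos=[frame0, frame1],
            species=[CHAIN] * 4,
            chain_id=[0, 0, 1, 1],
            index_in_chain=[0, 1, 0, 1],
        )
        _, dr2 = translational_correlation(traj)
        assert dr2[0] == 0.0
        assert dr2[1] == pytest.approx(4.0)

    def test_independent_random_walks_grow_linearly(self, make_traj):
        rng = np.random.default_rng(11)
        n_walkers, n_snap, steps_per_snap = 300, 21, 100
        steps = rng.integers(0, 4, size=(n_walkers, (n_snap - 1) * steps_per_snap))
        dxy = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]])[steps]
        paths = np.concatenate(
            [np.zeros((n_walkers, 1, 2), dtype=int), np.cumsum(dxy, axis=1)], axis=1
        )
        frames = paths[:, ::steps_per_snap].transpose(1, 0, 2) + 500
        stamps = np.arange(n_snap) * steps_per_snap
        traj = make_traj(
            pos=frames,
            species=[CHAIN] * n_walkers,
            chain_id=np.arange(n_walkers),
            index_in_chain=[0] * n_walkers,
            stamps=stamps,
            width=1024, height=1024,
        )
        _, dr2 = translational_correlation(traj)
        slope = np.polyfit(stamps, dr2, 1)[0]
        # each lattice step has unit squared displacement: slope == 1
        assert slope == pytest.approx(1.0, rel=0.1)


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------


class TestFits:
    def test_exponential_exact_recovery(self):
        t = np.linspace(0, 5000, 20)
        assert fit_exponential(t, np.exp(-t / 1000)) == pytest.approx(1000, rel=1e-9)

    def test_exponential_constant_series_flags_infinity(self):
        t = np.linspace(0, 10, 10)
        assert fit_exponential(t, np.ones(10)) == math.inf

    def test_exponential_needs_five_points(self):
        with pytest.raises(ValueError):
            fit_exponential([0, 1, 2], [1.0, 0.9, 0.8])

    def test_powerlaw_exact_recovery(self):
        t = np.linspace(1, 100, 30)
        alpha, beta = fit_powerlaw(t, 2.0 * t)
        assert alpha == pytest.approx(2.0)
        assert beta == pytest.approx(1.0)

    def test_powerlaw_excludes_nonpositive_and_errors_when_too_few(self):
        with pytest.raises(ValueError):
            fit_powerlaw(np.arange(10.0), np.zeros(10))

    def test_noisy_recovery_is_unbiased(self):
        """Median relative errors stay below 5% at 1% noise, 50 replicates."""
        rng = np.random.default_rng(3)
        t = np.linspace(0, 5000, 20)
        tau_errs = []
        t2 = np.linspace(1, 100, 30)
        beta_errs = []
        for _ in range(50):
            noisy = np.exp(-t / 1000) * (1 + 0.01 * rng.normal(size=t.size))
            tau_errs.append(abs(fit_exponential(t, noisy) - 1000) / 1000)
            noisy2 = t2**2 * (1 + 0.01 * rng.normal(size=t2.size))
            beta_errs.append(abs(fit_powerlaw(t2, noisy2)[1] - 2) / 2)
        assert np.median(tau_errs) < 0.05
        assert np.median(beta_errs) < 0.05


class TestSwellingKinetics:
    def test_fitted_model_has_zero_initial_swelling(self):
        t = np.linspace(0, 200, 80)
        fit = swelling_kinetics_fit(t, 7.7 * (1 - np.exp(-0.022 * t)))
        assert fit.seq * (1 - math.exp(-fit.k * 0.0)) == 0.0
        assert fit.seq == pytest.approx(7.7, rel=1e-6)
        assert fit.k == pytest.approx(0.022, rel=1e-6)

    def test_step_like_data_gives_plateau_mean(self):
        t = np.linspace(0, 100, 40)
        s = np.where(t > 0.5, 5.0, 0.0)
        fit = swelling_kinetics_fit(t, s)
        assert fit.seq == pytest.approx(5.0, rel=0.02)

    def test_non_saturating_window_is_flagged(self):
        t = np.linspace(0, 10, 20)  # k*t_max = 0.22 << 2
        fit = swelling_kinetics_fit(t, 7.7 * (1 - np.exp(-0.022 * t)))
        assert fit.low_confidence

    def test_simulated_proxy_starts_at_zero(self, mini_trajectory):
        series = swelling_content(mini_trajectory)
        assert series.values[0] == 0.0


# ---------------------------------------------------------------------------
# Flory-Huggins
# ---------------------------------------------------------------------------


class TestFloryHuggins:
    @pytest.mark.parametrize(
        "h, expected", [(2 / 3, 0.0), (0.0, 19.2), (1.0, -9.6)]
    )
    def test_reference_values(self, h, expected):
        assert flory_huggins_chi(h, 0.8) == pytest.approx(expected)

    @given(h=st.floats(-2, 6, allow_nan=False), eps0=st.floats(0.01, 2))
    @settings(max_examples=50, deadline=None)
    def test_general_form_agrees_with_specialization(self, h, eps0):
        general = flory_huggins_chi_general(24, 0.0, eps0 * h, eps0 * (1 - h))
        assert flory_huggins_chi(h, eps0) == pytest.approx(general, rel=1e-12, abs=1e-12)

    def test_linear_in_h(self):
        hs = np.linspace(-1, 5, 13)
        chis = np.array([flory_huggins_chi(h) for h in hs])
        assert np.allclose(np.diff(chis, 2), 0)


def test_analysis_is_deterministic_on_same_trajectory(mini_trajectory):
    a = correlation_analysis(mini_trajectory)
    b = correlation_analysis(mini_trajectory)
    assert np.array_equal(a.cee, b.cee) and np.array_equal(a.dr2, b.dr2)
    assert a.tau == b.tau and a.beta == b.beta
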