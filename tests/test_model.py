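import numpy as np
import pytest

import hfnctrial as ht
from hfnctrial.model import _split_rhat

from oracles import grid_prob_hr_greater


def exponential_dataset(n, true_hr, rate0=1 / 35.0, seed=0, censor=720.0):
    """Constant-hazard PH data: control rate ``rate0``, treated rate*HR."""
    rng = np.random.default_rng(seed)
    arm = rng.integers(0, 2, n)
    rate = rate0 * np.where(arm == 1, true_hr, 1.0)
    t = rng.exponential(1.0 / rate)
    event = (t <= censor).astype(int)
    return ht.SurvivalDataset(np.minimum(t, censor), event, arm)


class TestLogLikelihood:
    def test_no_effect_symmetry_between_arms(self, cubic_basis):
        t, e = [20.0, 20.0], [1, 1]
        ll0 = ht.log_likelihood(ht.SurvivalDataset(t, e, [0, 0]), cubic_basis,
                                0.0, -1.0, np.full(6, 1 / 6))
        ll1 = ht.log_likelihood(ht.SurvivalDataset(t, e, [1, 1]), cubic_basis,
                                0.0, -1.0, np.full(6, 1 / 6))
        assert ll0 == pytest.approx(ll1)

    def test_single_subject_concentrated_gamma_hand_value(self, cubic_basis):
        # gamma concentrated on component 3; one treated subject weaned at 30 h
        from scipy.integrate import quad

        gamma = np.zeros(6)
        gamma[3] = 1.0
        t, beta, beta0 = 30.0, 0.4, -2.0
        m3 = cubic_basis.mspline(t)[3]
        i3 = quad(lambda s: cubic_basis.mspline(s)[3], 0, t, limit=200)[0]
        expected = (beta0 + np.log(m3) + beta) - np.exp(beta0) * i3 * np.exp(beta)
        ds = ht.SurvivalDataset([t], [1], [1])
        assert ht.log_likelihood(ds, cubic_basis, beta, beta0, gamma) == \
            pytest.approx(expected, abs=1e-6)

    def test_reduces_to_exponential_ph_loglik(self, small_dataset):
        # constant-hazard stub: hazard exp(beta0)/U, cumulative exp(beta0) t/U
        upper = 100.0
        basis = ht.constant_basis(upper)
        beta, beta0 = 0.3, -1.2
        lam = np.exp(beta0) / upper
        d, t, a = (small_dataset.event, small_dataset.time_hours,
                   small_dataset.arm)
        textbook = np.sum(d * (np.log(lam) + beta * a)
                          - lam * t * np.exp(beta * a))
        got = ht.log_likelihood(small_dataset, basis, beta, beta0, np.ones(1))
        assert got == pytest.approx(textbook)

    def test_event_beyond_support_gives_minus_inf(self):
        basis = ht.constant_basis(10.0)
        ds = ht.SurvivalDataset([20.0], [1], [0])
        assert ht.log_likelihood(ds, basis, 0.0, 0.0, np.ones(1)) == -np.inf

    def test_invalid_gamma_rejected(self, cubic_basis, small_dataset):
        with pytest.raises(ValueError):
            ht.log_likelihood(small_dataset, cubic_basis, 0.0, 0.0,
                              np.full(6, 0.5))


class TestPosteriorProbabilities:
    def test_point_mass_above_threshold(self):
        draws = ht.PosteriorDraws(np.full(100, np.log(1.3)), np.zeros(100),
                                  np.full((100, 1), 1.0))
        assert ht.posterior_prob_hr_greater(draws, 1.0) == 1.0
        assert ht.posterior_prob_hr_less(draws, 1.15) == 0.0

    def test_threshold_below_minimum_hr(self):
        rng = np.random.default_rng(1)
        draws = ht.PosteriorDraws(rng.normal(0, 1, 500), np.zeros(500),
                                  np.full((500, 1), 1.0))
        below = np.exp(draws.beta.min()) - 1e-6
        assert ht.posterior_prob_hr_greater(draws, below) == 1.0

    def test_complement_identity(self):
        rng = np.random.default_rng(2)
        draws = ht.PosteriorDraws(rng.normal(0, 1, 999), np.zeros(999),
                                  np.full((999, 1), 1.0))
        p_up = ht.posterior_prob_hr_greater(draws, 1.15)
        p_dn = ht.posterior_prob_hr_less(draws, 1.15)
        assert p_up + p_dn == pytest.approx(1.0)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            ht.PosteriorDraws(np.empty(0), np.empty(0), np.empty((0, 1)))


class TestFit:
    def test_prior_only_is_symmetric(self, small_dataset):
        model = ht.MSplinePHModel(small_dataset)
        res = model.fit(prior_only=True, draws=20000, seed=0)
        se = 0.5 / np.sqrt(20000)
        assert abs(res.prob_hr_greater(1.0) - 0.5) < 3 * se

    def test_parameter_recovery_constant_hazard(self):
        ds = exponential_dataset(2000, true_hr=1.5, seed=3)
        res = ht.MSplinePHModel(ds).fit(method="laplace", seed=0)
        assert res.hr_mean == pytest.approx(1.5, rel=0.10)

    def test_bias_shrinks_with_sample_size(self):
        errs = []
        for n in (200, 2000):
            reps = [
                ht.MSplinePHModel(exponential_dataset(n, 1.5, seed=s))
                .fit(method="laplace", draws=2000, seed=s).hr_mean
                for s in range(5)
            ]
            errs.append(abs(np.mean(reps) - 1.5))
        assert errs[1] < errs[0]

    @pytest.mark.parametrize("method", ["laplace", "mcmc"])
    def test_matches_grid_oracle_small_fixture(self, small_dataset, method):
        upper = float(small_dataset.time_hours.max()) + 5.0
        model = ht.MSplinePHModel(small_dataset,
                                  basis=ht.constant_basis(upper))
        res = model.fit(method=method, draws=8000, seed=0)
        oracle = grid_prob_hr_greater(small_dataset.time_hours,
                                      small_dataset.event,
                                      small_dataset.arm, upper)
        assert res.prob_hr_greater(1.0) == pytest.approx(oracle, abs=0.03)

    def test_arm_relabel_negates_beta(self, medium_dataset):
        flipped = ht.SurvivalDataset(medium_dataset.time_hours,
                                     medium_dataset.event,
                                     1 - medium_dataset.arm)
        r1 = ht.MSplinePHModel(medium_dataset).fit("mcmc", draws=6000, seed=4)
        r2 = ht.MSplinePHModel(flipped).fit("mcmc", draws=6000, seed=4)
        sd = r1.draws.beta.std()
        assert np.mean(r1.draws.beta) == pytest.approx(
            -np.mean(r2.draws.beta), abs=4 * sd / np.sqrt(1000))

    def test_seed_determinism(self, medium_dataset):
        model = ht.MSplinePHModel(medium_dataset)
        a = model.fit("mcmc", draws=2000, seed=9)
        b = model.fit("mcmc", draws=2000, seed=9)
        assert np.array_equal(a.draws.beta, b.draws.beta)
        assert np.array_equal(a.draws.gamma, b.draws.gamma)

    def test_zero_events_rejected(self):
        ds = ht.SurvivalDataset([10.0, 20.0, 30.0], [0, 0, 0], [0, 1, 0])
        with pytest.raises(ValueError):
            ht.MSplinePHModel(ds)

    def test_convergence_diagnostics_reported(self, medium_dataset):
        res = ht.MSplinePHModel(medium_dataset).fit("mcmc", draws=2000, seed=5)
        assert "rhat_beta" in res.diagnostics
        assert res.diagnostics["rhat_beta"] <= 1.05
        assert res.converged

    def test_simplex_draws_valid(self, medium_dataset):
        res = ht.MSplinePHModel(medium_dataset).fit("laplace", seed=6)
        g = res.draws.gamma
        assert g.shape[1] == 6
        assert np.all(g >= 0)
        assert np.abs(g.sum(axis=1) - 1).max() < 1e-8

    def test_summary_table(self, medium_dataset):
        res = ht.MSplinePHModel(medium_dataset).fit("laplace", seed=7)
        s = res.summary()
        assert {"mean", "sd", "q2.5", "q97.5"} <= set(s.columns)
        assert "hr" in s.index


def test_split_rhat_flags_disjoint_chains():
    rng = np.random.default_rng(0)
    good = rng.normal(size=(4, 500))
    bad = good + np.arange(4)[:, None] * 5
    assert _split_rhat(good) < 1.05
    assert _split_rhat(bad) > 1.5


def test_dataset_table_round_trip(tmp_path, medium_dataset):
    p = tmp_path / "surv.tsv"
    medium_dataset.write_table(p)
    back = ht.SurvivalDataset.read_table(p)
    assert np.allclose(back.time_hours, medium_dataset.time_hours)
    assert np.array_equal(back.event, medium_dataset.event)
    assert np.array_equal(back.arm, medium_dataset.arm)
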