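"""HMM fitting, likelihood/decoding correctness and state summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

import divestates as ds
from divestates.hmm import HmmFit, _emission_logpdf, _n_params


def random_fit(rng, K, F=4):
    return HmmFit(
        n_states=K,
        pi=rng.dirichlet(np.ones(K)),
        A=rng.dirichlet(np.ones(K), size=K),
        mu=rng.uniform(0, 1, (K, F)),
        sigma=rng.uniform(0.05, 0.5, (K, F)),
        loglik=0.0,
        aic=0.0,
        n_params=_n_params(K, F),
        seed=0,
        converged=True,
    )


def brute_force(fit, x):
    """Exhaustive path enumeration: marginal log-likelihood and best path."""
    K, T = fit.n_states, x.shape[0]
    logB = _emission_logpdf(x, fit.mu, fit.sigma)
    tot, best, bestpath = -np.inf, -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(fit.pi[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(fit.A[path[t - 1], path[t]]) + logB[t, path[t]]
        tot = np.logaddexp(tot, lp)
        if lp > best:
            best, bestpath = lp, path
    return tot, bestpath


class TestForward:
    def test_length_one_sequence_is_mixture_density(self):
        rng = np.random.default_rng(0)
        fit = random_fit(rng, 3)
        x = rng.uniform(0, 1, (1, 4))
        logB = _emission_logpdf(x, fit.mu, fit.sigma)
        expected = np.log(np.sum(fit.pi * np.exp(logB[0])))
        assert ds.forward_loglik(fit, x) == pytest.approx(expected, abs=1e-10)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            K = int(rng.integers(2, 4))
            T = int(rng.integers(2, 7))
            fit = random_fit(rng, K)
            x = rng.uniform(0, 1, (T, 4))
            tot, _ = brute_force(fit, x)
            assert ds.forward_loglik(fit, x) == pytest.approx(tot, abs=1e-8)

    def test_impossible_observation_flags_not_crashes(self):
        rng = np.random.default_rng(2)
        fit = random_fit(rng, 2)
        # scales small enough that the density underflows to an exact zero
        fit.sigma = np.full_like(fit.sigma, 1e-200)
        x = np.full((3, 4), 0.5)
        fit.mu = np.zeros_like(fit.mu)
        with pytest.warns(UserWarning, match="impossible"):
            assert ds.forward_loglik(fit, x) == -np.inf

    def test_invariant_to_sequence_order(self):
        rng = np.random.default_rng(3)
        fit = random_fit(rng, 3)
        seqs = [rng.uniform(0, 1, (rng.integers(3, 9), 4)) for _ in range(4)]
        lls = [ds.forward_loglik(fit, s) for s in seqs]
        assert sum(lls) == pytest.approx(sum(ds.forward_loglik(fit, s) for s in seqs[::-1]))


class TestViterbi:
    def test_matches_exhaustive_argmax(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            K = int(rng.integers(2, 4))
            T = int(rng.integers(2, 7))
            fit = random_fit(rng, K)
            x = rng.uniform(0, 1, (T, 4))
            _, bestpath = brute_force(fit, x)
            decoded = ds.decode(fit, [x])
            assert tuple(decoded.viterbi[0]) == bestpath

    def test_identical_emissions_tie_break_to_first_state(self):
        K = 3
        fit = HmmFit(
            n_states=K,
            pi=np.full(K, 1 / K),
            A=np.full((K, K), 1 / K),
            mu=np.tile(np.full(4, 0.5), (K, 1)),
            sigma=np.tile(np.full(4, 0.2), (K, 1)),
            loglik=0.0,
            aic=0.0,
            n_params=_n_params(K, 4),
            seed=0,
            converged=True,
        )
        x = np.random.default_rng(5).uniform(0, 1, (6, 4))
        decoded = ds.decode(fit, [x])
        assert np.all(decoded.viterbi[0] == 0)

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        fit = random_fit(rng, 3)
        decoded = ds.decode(fit, [rng.uniform(0, 1, (50, 4))])
        assert np.allclose(decoded.posterior[0].sum(axis=1), 1.0, atol=1e-9)


class TestEm:
    def test_one_state_closed_form(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.5, 0.1, (200, 4)).clip(0, 1)
        fit = ds.fit_em([x], 1, seed=0)
        assert np.allclose(fit.mu[0], x.mean(axis=0), atol=1e-6)
        # closed-form independent-Gaussian log-likelihood at the MLE
        sd = x.std(axis=0)
        ll = float(np.sum(-0.5 * ((x - x.mean(0)) / sd) ** 2
                          - np.log(sd) - 0.5 * np.log(2 * np.pi)))
        assert fit.loglik == pytest.approx(ll, rel=1e-6)

    def test_loglik_non_decreasing_over_iterations(self):
        rng = np.random.default_rng(8)
        x = np.vstack(
            [rng.normal(0.3, 0.05, (150, 4)), rng.normal(0.7, 0.05, (150, 4))]
        ).clip(0, 1)
        lls = []
        for it in range(1, 15):
            f = ds.fit_em([x], 2, seed=3, max_iter=it, tol=0.0)
            lls.append(f.loglik)
        assert np.all(np.diff(lls) >= -1e-8)

    def test_aic_formula(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, (100, 4))
        fit = ds.fit_em([x], 2, seed=1, max_iter=20)
        assert fit.n_params == (2 - 1) + 2 * (2 - 1) + 2 * 2 * 4
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)

    def test_permuting_states_preserves_likelihood(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 1, (80, 4))
        fit = ds.fit_em([x], 3, seed=2, max_iter=30)
        perm = [2, 0, 1]
        swapped = HmmFit(
            n_states=3,
            pi=fit.pi[perm],
            A=fit.A[np.ix_(perm, perm)],
            mu=fit.mu[perm],
            sigma=fit.sigma[perm],
            loglik=0.0,
            aic=0.0,
            n_params=fit.n_params,
            seed=0,
            converged=True,
        )
        assert ds.forward_loglik(swapped, x) == pytest.approx(
            ds.forward_loglik(fit, x), abs=1e-8
        )

    def test_agrees_with_hmmlearn_scoring(self):
        from hmmlearn.hmm import GaussianHMM

        rng = np.random.default_rng(11)
        fit = random_fit(rng, 3)
        x = rng.uniform(0, 1, (120, 4))
        gh = GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        gh.startprob_ = fit.pi
        gh.transmat_ = fit.A
        gh.means_ = fit.mu
        gh.covars_ = fit.sigma**2
        assert ds.forward_loglik(fit, x) == pytest.approx(gh.score(x), abs=1e-8)


class TestSelection:
    def seqs(self):
        rng = np.random.default_rng(12)
        x = np.vstack(
            [rng.normal(0.25, 0.05, (400, 4)), rng.normal(0.75, 0.05, (400, 4))]
        ).clip(0, 1)
        rng.shuffle(x)  # mixture, not blocks; enough for AIC ordering
        return [x]

    def test_two_state_beats_one_state_aic(self):
        seqs = self.seqs()
        one = ds.fit_em(seqs, 1, seed=0)
        table, best = ds.select_model(seqs, states=(2,), n_restarts=5, base_seed=0)
        assert best[2].aic < one.aic

    def test_best_of_restarts_is_min(self):
        seqs = self.seqs()
        fits = [ds.fit_em(seqs, 2, seed=0 + r, max_iter=50) for r in range(5)]
        table, best = ds.select_model(seqs, states=(2,), n_restarts=5, base_seed=0,
                                      max_iter=50)
        conv = [f.aic for f in fits if f.converged]
        assert best[2].aic == pytest.approx(min(conv))

    def test_more_restarts_never_increase_retained_aic(self):
        seqs = self.seqs()
        _, best5 = ds.select_model(seqs, states=(2,), n_restarts=5, base_seed=7,
                                   max_iter=50)
        _, best10 = ds.select_model(seqs, states=(2,), n_restarts=10, base_seed=7,
                                    max_iter=50)
        assert best10[2].aic <= best5[2].aic + 1e-9


class TestSummaries:
    def test_canonical_labels_follow_descriptor_rules(self):
        means = pd.DataFrame(
            {
                "max_depth": [30.0, 90.0, 35.0, 16.0],
                "bottom_time": [2700.0, 600.0, 120.0, 580.0],
                "dive_time": [4200.0, 2100.0, 1000.0, 1500.0],
                "surface_interval": [150.0, 1200.0, 2400.0, 70.0],
            }
        )
        mapping, fallback = ds.canonical_labels(means)
        assert mapping == {0: 1, 1: 2, 2: 3, 3: 4}
        assert not fallback

    def test_collision_falls_back_to_depth_ordering(self):
        means = pd.DataFrame(
            {
                "max_depth": [90.0, 50.0, 35.0, 16.0],
                "bottom_time": [2700.0, 600.0, 120.0, 580.0],  # deepest also longest
                "max_depth_dup": [0, 0, 0, 0],
                "surface_interval": [0, 0, 0, 0],
            }
        ).drop(columns="max_depth_dup")
        mapping, fallback = ds.canonical_labels(means)
        assert fallback
        assert mapping[0] == 2 and mapping[3] == 4

    def test_reported_transition_rows_sum_to_one(self):
        rng = np.random.default_rng(13)
        cfg = ds.default_sim_config(seed=14)
        sim = ds.simulate_dive_sequence(cfg, 800)
        df = pd.DataFrame(
            {
                "id": "a",
                "max_depth": [d.max_depth for d in sim],
                "bottom_time": [d.bottom_time for d in sim],
                "dive_time": [d.dive_time for d in sim],
                "surface_interval": [d.surface_interval for d in sim],
            }
        )
        _, X = ds.fit_transform(df)
        fits = [ds.fit_em([X], 4, seed=s) for s in range(5)]
        best = min([f for f in fits if f.converged], key=lambda f: f.aic)
        decoded = ds.decode(best, [X])
        summary = ds.summarise_states(best, decoded, df)
        assert np.allclose(summary["A"].sum(axis=1), 1.0, atol=1e-9)
        # diagonally dominant truth recovered as self-transition dominance
        assert summary["self_transition_dominant"]
        # canonical labels match the generator's on most dives
        truth = np.array([d.state for d in sim])
        assert (summary["states"] == truth).mean() > 0.9
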