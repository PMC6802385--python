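"""HMM engine: transitions, emissions, forward/Viterbi oracles, EM, AIC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from divehmm.hmm import (
    HmmSpec,
    aic,
    canonical_relabel,
    count_parameters,
    em_fit,
    emission_logdensity,
    forward_loglik,
    permute_states,
    transition_matrix,
    viterbi,
)
from divehmm.hmm import _emission_loglik, _prepare
from divehmm.simulate import generate_dive_dataset

from conftest import (
    chain_config,
    make_feature_frame,
    separated_emissions,
    sticky_matrix,
)


def random_spec(rng, N, p=0, covariate=None):
    return HmmSpec(
        n_states=N,
        cont_coef=rng.normal(0, 1, (N, 4, 2)),
        cont_sd=rng.uniform(0.3, 1.5, (N, 4)),
        bin_coef=rng.normal(0, 1, (N, 2, 2)),
        trans_coef=rng.normal(0, 0.8, (N, max(N - 1, 0), 1 + p)),
        pi=rng.dirichlet(np.ones(N)),
        transition_covariate=covariate,
    )


class TestTransitionMatrix:
    def test_zero_coefficients_give_uniform_rows(self):
        spec = random_spec(np.random.default_rng(0), 5)
        spec.trans_coef[:] = 0.0
        assert np.allclose(transition_matrix(spec), 0.2)

    def test_two_state_softmax_by_hand(self):
        spec = random_spec(np.random.default_rng(0), 2)
        spec.trans_coef[:] = 0.0
        spec.trans_coef[0, 0, 0] = np.log(3.0)
        P = transition_matrix(spec)
        assert P[0] == pytest.approx([0.25, 0.75], abs=1e-14)

    def test_rows_normalized_for_random_coefficients(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            N = int(rng.integers(2, 6))
            p = int(rng.integers(0, 3))
            spec = random_spec(rng, N, p)
            z = rng.normal(0, 2, p)
            P = transition_matrix(spec, z)
            assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-12
            assert (P > 0).all()

    def test_covariate_levels_give_distinct_matrices(self):
        spec = random_spec(np.random.default_rng(2), 3, p=1, covariate="sex")
        P0, P1 = transition_matrix(spec, [0.0]), transition_matrix(spec, [1.0])
        assert not np.allclose(P0, P1)


class TestEmissionLogdensity:
    def _spec_at_mean(self):
        spec = random_spec(np.random.default_rng(3), 2)
        spec.cont_coef[:, :, 0] = np.log([[5, 5, 5, 0.5], [5, 5, 5, 0.5]])
        spec.cont_coef[:, :, 1] = 0.0
        spec.cont_sd[:] = 1.0
        spec.bin_coef[:] = 0.0  # p = 0.5 for both binary channels
        return spec

    def _dive(self, buzz=1, slow=0):
        return pd.Series({"max_depth_m": 5.0, "jerk_peak": 5.0,
                          "roll_med_deg": 5.0, "heading_var": 0.5,
                          "buzz": buzz, "slow_click": slow, "sex": "F"})

    def test_closed_form_at_the_mean(self):
        val = emission_logdensity(self._spec_at_mean(), self._dive(), 1)
        assert val == pytest.approx(4 * (-0.5 * np.log(2 * np.pi))
                                    + 2 * np.log(0.5), abs=1e-12)

    def test_doubling_sigma_costs_ln2_at_the_mean(self):
        spec = self._spec_at_mean()
        base = emission_logdensity(spec, self._dive(), 1)
        spec.cont_sd[0, 2] *= 2.0
        assert emission_logdensity(spec, self._dive(), 1) == pytest.approx(
            base - np.log(2.0), abs=1e-12)

    def test_buzz_probability_contribution(self):
        # a buzz under p = 0.64 contributes ln 0.64 relative to p = 0.5
        spec = self._spec_at_mean()
        p = 0.64
        spec.bin_coef[0, 0, 0] = np.log(p / (1 - p))
        val = emission_logdensity(spec, self._dive(buzz=1), 1)
        assert val == pytest.approx(4 * (-0.5 * np.log(2 * np.pi))
                                    + np.log(p) + np.log(0.5), abs=1e-12)


def brute_force(spec, data):
    deps, _ = _prepare(data, spec.transition_covariate)
    total_ll = 0.0
    paths = {}
    for d in deps:
        logE = _emission_loglik(spec, d)
        P = transition_matrix(spec, d.z)
        T, N = logE.shape
        tot = -np.inf
        best, best_path = -np.inf, None
        for path in itertools.product(range(N), repeat=T):
            lp = np.log(spec.pi[path[0]]) + logE[0, path[0]]
            for t in range(1, T):
                lp += np.log(P[path[t - 1], path[t]]) + logE[t, path[t]]
            tot = np.logaddexp(tot, lp)
            if lp > best:
                best, best_path = lp, path
        total_ll += tot
        paths[d.deployment_id] = (np.array(best_path) + 1, best)
    return total_ll, paths


class TestForwardAndViterbiOracles:
    def test_matches_path_enumeration(self):
        """Forward log-likelihood and Viterbi agree with brute-force path
        enumeration on 200 random fixtures (N <= 3, T <= 6)."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            N = int(rng.integers(1, 4))
            T = int(rng.integers(1, 7))
            spec = random_spec(rng, N)
            data = make_feature_frame(rng, T)
            ll = forward_loglik(spec, data)
            bll, bpaths = brute_force(spec, data)
            assert abs(ll - bll) < 1e-8
            v = viterbi(spec, data)["a"]
            bpath, bscore = bpaths["a"]
            # the decoded path must attain the enumerated optimum
            deps, _ = _prepare(data, None)
            logE = _emission_loglik(spec, deps[0])
            P = transition_matrix(spec)
            score = np.log(spec.pi[v[0] - 1]) + logE[0, v[0] - 1]
            for t in range(1, T):
                score += np.log(P[v[t - 1] - 1, v[t] - 1]) + logE[t, v[t] - 1]
            assert score == pytest.approx(bscore, abs=1e-8)

    def test_single_state_reduces_to_emission_sum(self):
        rng = np.random.default_rng(8)
        spec = random_spec(rng, 1)
        data = make_feature_frame(rng, 20)
        deps, _ = _prepare(data, None)
        expected = _emission_loglik(spec, deps[0]).sum()
        assert forward_loglik(spec, data) == pytest.approx(expected, abs=1e-9)
        assert (viterbi(spec, data)["a"] == 1).all()

    def test_deployments_are_independent(self):
        rng = np.random.default_rng(9)
        spec = random_spec(rng, 2)
        a = make_feature_frame(rng, 1, deployment="a")
        b = make_feature_frame(rng, 1, deployment="b")
        both = pd.concat([a, b], ignore_index=True)
        assert forward_loglik(spec, both) == pytest.approx(
            forward_loglik(spec, a) + forward_loglik(spec, b), abs=1e-10)


class TestParameterCounting:
    @pytest.mark.parametrize("N,p,k", [
        (5, 1, 124), (5, 0, 104), (5, 2, 144), (4, 1, 91), (3, 1, 62),
    ])
    def test_formula(self, N, p, k):
        assert count_parameters(N, p) == k

    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            count_parameters(1, 0)

    def test_aic(self):
        assert aic(0.0, 1) == 2.0
        assert aic(-15296.366, 124) == pytest.approx(30840.732)
        # equal-k models differ by -2 delta-loglik
        assert aic(-10.0, 5) - aic(-12.0, 5) == pytest.approx(
            -2.0 * (-10.0 - -12.0))


class TestEmFit:
    def test_monotone_loglik(self, separated_3state_fit):
        trace = np.asarray(separated_3state_fit["fit"].em_trace)
        assert np.diff(trace).min() > -1e-8

    def test_posterior_rows_normalized(self, separated_3state_fit):
        post = separated_3state_fit["fit"].posterior
        cols = [c for c in post.columns if c.startswith("p_state")]
        assert np.abs(post[cols].sum(axis=1) - 1.0).max() < 1e-9

    def test_parameter_recovery(self, separated_3state_fit):
        """Relabeled estimates recover the generating emissions within 0.05
        ln-units and transition probabilities within 0.03.

        Transitions are compared against the realized chain's empirical
        frequencies — the information actually present in one finite
        dataset; closeness to the generating matrix itself is covered by
        the multi-replicate bias test below."""
        fix = separated_3state_fit
        fit = canonical_relabel(fix["fit"])
        true_depths = np.log([2.0, 20.0, 200.0])
        est = fit.spec.cont_coef[:, 0, 0]
        order = np.argsort(fit.state_stats["ln_depth_mean"])
        # map canonical states back to generator order by depth
        est_sorted = est[order]
        assert np.abs(est_sorted - true_depths).max() < 0.05
        counts = np.zeros((3, 3))
        for seq in fix["truth"].values():
            s = seq - 1
            np.add.at(counts, (s[:-1], s[1:]), 1)
        empirical = counts / counts.sum(axis=1, keepdims=True)
        P = transition_matrix(fit.spec)
        P_sorted = P[np.ix_(order, order)]
        assert np.abs(P_sorted - empirical).max() < 0.03
        assert np.abs(P_sorted - fix["P"]).max() < 0.05
        # binary channels: estimator matches the realized per-state rates
        probs = 1.0 / (1.0 + np.exp(-fit.spec.bin_coef[order, :, 0]))
        table, truth = fix["table"], fix["truth"]
        for gen_state in (1, 2, 3):
            sub = table[(table.true_state == gen_state) & (table.sex == "F")]
            assert probs[gen_state - 1, 0] == pytest.approx(
                sub["buzz"].mean(), abs=0.02)
            assert probs[gen_state - 1, 1] == pytest.approx(
                sub["slow_click"].mean(), abs=0.02)

    def test_viterbi_recovers_truth_on_separated_data(self, separated_3state_fit):
        fix = separated_3state_fit
        fit = canonical_relabel(fix["fit"])
        order = np.argsort(fit.state_stats["ln_depth_mean"])
        inv = np.empty(3, dtype=int)
        inv[order] = np.arange(3)
        hits = total = 0
        for dep, seq in fix["truth"].items():
            decoded = inv[fit.viterbi[dep] - 1] + 1
            hits += (decoded == seq).sum()
            total += len(seq)
        assert hits / total >= 0.95

    def test_transition_bias_over_replicates(self):
        """Mean transition-probability bias < 0.02 over 20 seeded replicates
        at n = 5000 dives."""
        P = sticky_matrix(3, 0.75)
        emissions = separated_emissions(3, [2.0, 20.0, 200.0])
        biases = []
        for rep in range(20):
            cfg = chain_config(3, 1250, P, seed=100 + rep)
            table, _ = generate_dive_dataset(cfg, emissions)
            fit = em_fit(table, 3, n_restarts=1, max_iter=200, tol=1e-5,
                         seed=rep)
            order = np.argsort(fit.state_stats["ln_depth_mean"])
            Pf = transition_matrix(fit.spec)[np.ix_(order, order)]
            biases.append(Pf - P)
        assert np.abs(np.mean(biases, axis=0)).max() < 0.02

    def test_single_state_closed_form(self):
        rng = np.random.default_rng(12)
        data = pd.concat(
            [make_feature_frame(rng, 60, deployment="a", sex="F"),
             make_feature_frame(rng, 60, deployment="b", sex="M")],
            ignore_index=True)
        fit = em_fit(data, 1, n_restarts=1, max_iter=5, seed=0)
        Y = np.log(data["max_depth_m"].to_numpy())
        sex = (data["sex"] == "M").to_numpy()
        m0, m1 = Y[~sex].mean(), Y[sex].mean()
        assert fit.spec.cont_coef[0, 0, 0] == pytest.approx(m0, abs=1e-9)
        assert fit.spec.cont_coef[0, 0, 1] == pytest.approx(m1 - m0, abs=1e-9)
        resid = Y - np.where(sex, m1, m0)
        assert fit.spec.cont_sd[0, 0] == pytest.approx(
            np.sqrt(np.mean(resid**2)), abs=1e-9)
        p0 = data.loc[~sex, "buzz"].mean()
        est_p0 = 1.0 / (1.0 + np.exp(-fit.spec.bin_coef[0, 0, 0]))
        assert est_p0 == pytest.approx(p0, abs=1e-9)

    def test_fitted_likelihood_dominates_generating_spec(self, separated_3state_fit):
        """Consistency smoke test: the MLE's log-likelihood is at least the
        generating spec's on the same data (equivalently its AIC is no
        worse at equal k)."""
        from divehmm.simulate import derive_lognormal_params

        fix = separated_3state_fit
        em = fix["emissions"]
        N = 3
        cont_coef = np.zeros((N, 4, 2))
        cont_sd = np.zeros((N, 4))
        bin_coef = np.zeros((N, 2, 2))
        chans = ("max_depth", "jerk_peak", "roll", "heading_variance")
        for j in range(N):
            for v, ch in enumerate(chans):
                mu, sd = derive_lognormal_params(em[j].lognormal(ch, "F"))
                cont_coef[j, v, 0] = mu
                cont_sd[j, v] = max(sd, 1e-3)
            for b, probs in enumerate((em[j].buzz_prob, em[j].slow_click_prob)):
                p = np.clip(probs["F"], 1e-6, 1 - 1e-6)
                bin_coef[j, b, 0] = np.log(p / (1 - p))
        P = fix["P"]
        trans_coef = np.log(P[:, 1:] / P[:, [0]])[:, :, None]
        true_spec = HmmSpec(N, cont_coef, cont_sd, bin_coef, trans_coef,
                            np.full(N, 1 / 3))
        ll_true = forward_loglik(true_spec, fix["table"])
        assert fix["fit"].loglik >= ll_true - 1e-6

    def test_too_few_observations_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError):
            em_fit(make_feature_frame(rng, 2), 5, n_restarts=1, seed=0)


class TestCanonicalRelabel:
    def test_idempotent(self, separated_3state_fit):
        once = canonical_relabel(separated_3state_fit["fit"])
        twice = canonical_relabel(once)
        assert np.allclose(once.spec.cont_coef, twice.spec.cont_coef)
        assert np.allclose(once.spec.trans_coef, twice.spec.trans_coef)
        for dep in once.viterbi:
            assert np.array_equal(once.viterbi[dep], twice.viterbi[dep])

    def test_invariant_under_random_permutations(self, separated_3state_fit):
        fit = separated_3state_fit["fit"]
        canon = canonical_relabel(fit)
        rng = np.random.default_rng(14)
        for _ in range(5):
            perm = rng.permutation(3)
            scrambled = permute_states(fit, perm)
            back = canonical_relabel(scrambled)
            assert np.allclose(back.spec.cont_coef, canon.spec.cont_coef,
                               atol=1e-9)
            assert np.allclose(back.spec.pi, canon.spec.pi, atol=1e-9)

    def test_loglik_invariant(self, separated_3state_fit):
        fix = separated_3state_fit
        fit = fix["fit"]
        relabeled = canonical_relabel(fit)
        ll0 = forward_loglik(fit.spec, fix["table"])
        ll1 = forward_loglik(relabeled.spec, fix["table"])
        assert abs(ll0 - ll1) < 1e-9
        assert abs(ll0 - fit.loglik) < 1e-6
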