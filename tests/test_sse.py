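"""Time-sliced SSE model family: specs, likelihood oracles, comparison."""

import numpy as np
import pytest

from mimodiv import sse
from mimodiv.trees import MkParams, mk_loglik, read_newick
from tests.conftest import neutral_tree

FOUR_TIP = "(((A:1,B:1):1,C:2):1,D:3);"


def _random_params(spec, rng, lo=0.02, hi=0.6):
    return spec.expand(rng.uniform(lo, hi, size=spec.n_params))


class TestModelSet:
    def test_contains_best_model_structure(self):
        specs = sse.build_model_set(7.0)
        names = {s.name for s in specs}
        assert "indEarly_depLate_asymmetric_variable@7" in names
        assert len(specs) == len(names) == 18

    def test_parameter_counting(self):
        simple = sse.SSEModelSpec(7.0, "dependent", "dependent", "symmetric", "constant")
        rich = sse.SSEModelSpec(7.0, "dependent", "dependent", "asymmetric", "variable")
        assert simple.n_params < rich.n_params
        assert rich.n_params == 12
        # the richest spec carries four distinct observed-state rates:
        # evergreen->deciduous and back, separately in each epoch
        assert {"q01_early", "q10_early", "q01_late", "q10_late"} <= set(
            rich.param_names
        )

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            sse.SSEModelSpec(None, "dependent", "independent", "asymmetric", "constant")
        with pytest.raises(ValueError):
            sse.SSEModelSpec(-1.0, "dependent", "dependent", "asymmetric", "constant")
        with pytest.raises(ValueError):
            sse.build_model_set(0.0)

    def test_expand_respects_sharing(self):
        spec = sse.SSEModelSpec(7.0, "independent", "dependent", "symmetric", "constant")
        p = _random_params(spec, np.random.default_rng(0))
        lam_e, lam_l = p.lam
        # independent early: lambda keyed by hidden class (indices 0,1 repeat)
        assert lam_e[0] == lam_e[2] and lam_e[1] == lam_e[3]
        # dependent late: lambda keyed by observed state
        assert lam_l[0] == lam_l[1] and lam_l[2] == lam_l[3]
        # symmetric + constant: one observed rate everywhere
        off = p.Q[:, 0, 2], p.Q[:, 2, 0]
        assert np.allclose(off[0], off[1])
        np.testing.assert_allclose(p.Q.sum(axis=2), 0.0, atol=1e-12)


class TestLikelihood:
    @pytest.mark.parametrize("sym,tv", [("asymmetric", "variable"), ("symmetric", "constant")])
    def test_slice_invariance(self, sym, tv):
        """Equal epoch parameters give the unsliced likelihood exactly."""
        tree, traits, _ = neutral_tree(5, 40)
        states = traits.states_for(tree)
        rng = np.random.default_rng(2)
        sliced = sse.SSEModelSpec(tree.root_age / 3, "dependent", "dependent", sym, tv)
        flat = sse.SSEModelSpec(None, "dependent", "dependent", sym, "constant")
        xf = rng.uniform(0.02, 0.5, size=flat.n_params)
        names_f = flat.param_names
        vals = dict(zip(names_f, xf))
        xs = []
        for nm in sliced.param_names:
            base = nm.replace("_early", "_const").replace("_late", "_const")
            xs.append(vals[base])
        ll_s = sse.sse_loglik(tree, states, sliced, sliced.expand(np.array(xs)))
        ll_f = sse.sse_loglik(tree, states, flat, flat.expand(xf))
        assert ll_s == pytest.approx(ll_f, abs=1e-6)

    def test_factorization_pure_birth(self, three_tip):
        """State-independent rates: SSE = Yule tree density x Mk likelihood."""
        lam, q01, q10 = 0.4, 0.3, 0.1
        spec = sse.SSEModelSpec(None, "dependent", "dependent", "asymmetric", "constant")
        x = np.array([lam, lam, 1e-9, q01, q10, 1e-9])
        states = np.array([0, 1, 0])
        ll = sse.sse_loglik(
            three_tip, states, spec, spec.expand(x),
            root_weighting="flat", condition_on_survival=False,
        )
        n = three_tip.n_tips
        bd = (n - 1) * np.log(lam) - lam * three_tip.total_branch_length()
        mk = mk_loglik(three_tip, states, MkParams(q01, q10), root_prior="flat")
        assert ll == pytest.approx(bd + mk, abs=1e-4)

    def test_factorization_with_extinction(self, three_tip):
        """With mu > 0 the one-state birth-death factor comes from an
        independent scipy integration of the D/E equations."""
        from scipy.integrate import solve_ivp

        lam, mu, q01, q10 = 0.4, 0.15, 0.3, 0.1
        spec = sse.SSEModelSpec(None, "dependent", "dependent", "asymmetric", "constant")
        x = np.array([lam, lam, mu, q01, q10, 1e-9])
        states = np.array([0, 1, 0])
        ll = sse.sse_loglik(
            three_tip, states, spec, spec.expand(x),
            root_weighting="flat", condition_on_survival=False,
        )

        def rhs(t, y):
            E, D = y
            return [
                mu - (lam + mu) * E + lam * E * E,
                -(lam + mu) * D + 2 * lam * E * D,
            ]

        def branch(y0, t0, t1):
            sol = solve_ivp(rhs, (t0, t1), y0, rtol=1e-10, atol=1e-12)
            return sol.y[:, -1]

        # postorder over ((A:1,B:1):1,C:2)
        EA = branch([0.0, 1.0], 0, 1)
        EB = branch([0.0, 1.0], 0, 1)
        node = [EA[0], lam * EA[1] * EB[1]]
        up = branch(node, 1, 2)
        EC = branch([0.0, 1.0], 0, 2)
        D_root = lam * up[1] * EC[1]
        mk = mk_loglik(three_tip, states, MkParams(q01, q10), root_prior="flat")
        assert ll == pytest.approx(np.log(D_root) + mk, abs=1e-4)

    @pytest.mark.parametrize("mu", [0.0, 0.1])
    def test_fine_step_euler_oracle(self, mu):
        """4-tip sliced likelihood matches an explicit-Euler integration."""
        tree = read_newick(FOUR_TIP)
        states = np.array([0, 1, 1, 0])
        spec = sse.SSEModelSpec(1.5, "independent", "dependent", "asymmetric", "variable")
        rng = np.random.default_rng(4)
        x = rng.uniform(0.05, 0.5, size=spec.n_params)
        x[[2, 5]] = mu
        params = spec.expand(x)
        ll = sse.sse_loglik(
            tree, states, spec, params,
            root_weighting="flat", condition_on_survival=False,
        )

        def euler_branch(y, a0, a1, dt=1e-4):
            t = a0
            while t < a1 - 1e-12:
                h = min(dt, a1 - t)
                e_ix = 0 if t + h / 2 > 1.5 else 1
                lam, mus, Q = params.lam[e_ix], params.mu[e_ix], params.Q[e_ix]
                E, D = y[:4], y[4:]
                dE = np.empty(4)
                dD = np.empty(4)
                for i in range(4):
                    qi = -Q[i, i]
                    sE = sum(Q[i, j] * E[j] for j in range(4) if j != i)
                    sD = sum(Q[i, j] * D[j] for j in range(4) if j != i)
                    diag = lam[i] + mus[i] + qi
                    dE[i] = mus[i] - diag * E[i] + lam[i] * E[i] ** 2 + sE
                    dD[i] = -diag * D[i] + 2 * lam[i] * E[i] * D[i] + sD
                y = y + h * np.concatenate([dE, dD])
                t += h
            return y

        age = tree.node_age
        ys = {}
        for v in tree.postorder:
            if v < tree.n_tips:
                y0 = np.zeros(8)
                y0[4 + 2 * states[v]] = 1.0
                y0[4 + 2 * states[v] + 1] = 1.0
            else:
                kids = tree.children[v]
                parts = [
                    euler_branch(ys.pop(c), age[c], age[v]) for c in kids
                ]
                e_ix = 0 if age[v] > 1.5 else 1
                y0 = parts[0].copy()
                y0[4:] = parts[0][4:] * parts[1][4:] * params.lam[e_ix]
            ys[v] = y0
        expected = np.log(np.mean(ys[tree.root][4:]))
        assert ll == pytest.approx(expected, abs=1e-3)

    def test_sampling_fraction_direction(self):
        """Sampling fraction acts through the tip D (factor rho per tip,
        lowering the likelihood) and the E equations (higher extinction-or-
        unsampled probability, raising D along branches). Verified
        empirically: at moderate fractions the E-side effect dominates, so
        the log-likelihood rises monotonically as the fraction drops."""
        tree, traits, _ = neutral_tree(6, 40)
        states = traits.states_for(tree)
        lls = []
        for f in (1.0, 0.7, 0.4):
            spec = sse.SSEModelSpec(
                5.0, "dependent", "dependent", "asymmetric", "constant",
                sampling_fraction=(f, f),
            )
            x = np.array([0.3, 0.2, 0.05, 0.3, 0.2, 0.05, 0.1, 0.05, 0.02])
            lls.append(sse.sse_loglik(tree, states, spec, spec.expand(x)))
        assert lls[0] < lls[1] < lls[2]

    def test_no_negative_d_clipping_in_standard_run(self):
        tree, traits, _ = neutral_tree(8, 60)
        states = traits.states_for(tree)
        spec = sse.SSEModelSpec(7.0, "independent", "dependent", "asymmetric", "variable")
        cache = {}
        sse.sse_loglik(
            tree, states, spec, _random_params(spec, np.random.default_rng(1)),
            _cache=cache,
        )
        assert cache.get("clipped", 0) == 0


class TestComparison:
    def test_single_fit_weight_one(self):
        w = sse.akaike_weights(np.array([123.4]))
        np.testing.assert_allclose(w, [1.0])

    def test_two_fits_closed_form(self):
        # equal logL, k differing by one: dAIC = 2 -> weights from exp(-d/2)
        w = sse.akaike_weights(np.array([100.0, 102.0]))
        expected = np.array([1.0, np.exp(-1.0)])
        expected /= expected.sum()
        np.testing.assert_allclose(w, expected, atol=1e-12)
        assert w[0] == pytest.approx(0.7311, abs=1e-4)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        w = sse.akaike_weights(rng.uniform(100, 200, size=18))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mixed_datasets_rejected(self):
        spec = sse.SSEModelSpec(None, "dependent", "dependent", "asymmetric", "constant")
        p = _random_params(spec, np.random.default_rng(0))
        f1 = sse.SSEFit(spec, p, -100.0, 6, data_id="a")
        f2 = sse.SSEFit(spec, p, -100.0, 6, data_id="b")
        with pytest.raises(ValueError, match="different datasets"):
            sse.compare_sse_models([f1, f2])

    def test_fit_records_starts_and_aic(self):
        tree, traits, _ = neutral_tree(9, 35)
        spec = sse.SSEModelSpec(None, "dependent", "dependent", "asymmetric", "constant")
        fit = sse.fit_sse(tree, traits, spec, n_starts=2, seed=1, maxiter=60)
        assert len(fit.starts) == 2
        assert fit.loglik >= max(s["loglik"] for s in fit.starts) - 1e-9
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
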