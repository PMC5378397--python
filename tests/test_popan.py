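"""POPAN likelihood, fitting, information criteria and model averaging."""

import numpy as np
import pytest
from scipy import optimize

from helpers import oracle_loglik
from petrelpop import datasets
from petrelpop.capture import EncounterHistoryTable, histories_to_marray
from petrelpop.popan import (
    ALL_SPECS,
    PopanModelSpec,
    PopanParams,
    aicc,
    akaike_weights,
    count_parameters,
    fit_popan,
    model_average,
    parse_model_spec,
    popan_loglik,
)


def _marray(hist_strings):
    hists = np.array([[int(c) for c in s] for s in hist_strings])
    t = EncounterHistoryTable(list(range(1, hists.shape[1] + 1)), hists)
    return histories_to_marray(t)


class TestLoglik:
    def test_forced_outcome_has_probability_one(self):
        # one bird, present from the start, certain survival and detection
        params = PopanParams(phi=[1.0], p=[1.0, 1.0], beta=[1.0, 0.0], N=1)
        assert popan_loglik(params, _marray(["11"])) == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_oracle_on_tiny_instances(self):
        # every T <= 3, N <= 5 shape with random parameters and histories
        rng = np.random.default_rng(42)
        checked = 0
        for T in (2, 3):
            for N in range(1, 6):
                for _ in range(20):
                    phi = rng.uniform(0.05, 0.95, T - 1)
                    p = rng.uniform(0.05, 0.95, T)
                    beta = rng.dirichlet(np.ones(T))
                    n = int(rng.integers(1, N + 1))
                    hists = []
                    for _ in range(n):
                        h = tuple(rng.integers(0, 2, T))
                        while sum(h) == 0:
                            h = tuple(rng.integers(0, 2, T))
                        hists.append(h)
                    params = PopanParams(phi=phi, p=p, beta=beta, N=N)
                    got = popan_loglik(params, _marray(["".join(map(str, h)) for h in hists]))
                    want = oracle_loglik(hists, phi, p, beta, N)
                    assert got == pytest.approx(want, abs=1e-10)
                    checked += 1
        assert checked == 200

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            PopanParams(phi=[0.5], p=[0.5, 0.5], beta=[-0.1, 1.1], N=10)
        params = PopanParams(phi=[0.5], p=[0.5, 0.5], beta=[0.5, 0.5], N=1)
        with pytest.raises(ValueError, match="at least"):
            popan_loglik(params, _marray(["11", "10"]))


class TestFit:
    def test_perfect_detection_estimates_n_observed(self):
        marr = _marray(["1111"] * 30)
        fit = fit_popan(PopanModelSpec(".", ".", "."), marr, seed=0, n_starts=3)
        assert fit.N == pytest.approx(30, abs=0.5)
        assert fit.params.p.min() > 0.95

    def test_mle_agrees_with_natural_scale_optimizer(self):
        """Identity-link (bounded natural-scale) optimization reaches the
        same maximum as the logit/log parameterization."""
        rng = np.random.default_rng(1)
        from petrelpop.simulate import PopanSimConfig, gen_popan_histories

        tab, _ = gen_popan_histories(PopanSimConfig(N=120, T=5, p=0.4), seed=5)
        marr = histories_to_marray(tab)
        fit = fit_popan(PopanModelSpec(".", ".", "."), marr, seed=0)
        n = marr.n_observed
        T = marr.T

        def nll(z):
            phi, p, b, f0 = z
            beta = np.r_[1 - (T - 1) * b, np.full(T - 1, b)]
            try:
                return -popan_loglik(
                    PopanParams(phi=[phi] * (T - 1), p=[p] * T, beta=beta,
                                N=n + f0),
                    marr,
                )
            except ValueError:
                return np.inf

        best = np.inf
        for _ in range(5):
            x0 = [rng.uniform(0.3, 0.9), rng.uniform(0.2, 0.6),
                  rng.uniform(0.01, 0.2), rng.uniform(1, n)]
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B",
                bounds=[(1e-4, 1 - 1e-4), (1e-4, 1 - 1e-4),
                        (1e-4, 1 / (T - 1) - 1e-4), (1e-3, 10 * n)],
            )
            best = min(best, res.fun)
        assert fit.logL == pytest.approx(-best, abs=1e-3)

    def test_parameter_recovery_smoke(self):
        from petrelpop.simulate import PopanSimConfig, gen_popan_histories

        tab, _ = gen_popan_histories(PopanSimConfig(N=400, T=8, p=0.4), seed=3)
        marr = histories_to_marray(tab)
        fit = fit_popan(PopanModelSpec(".", ".", "."), marr, seed=0, n_starts=3)
        assert abs(fit.N - 400) / 400 < 0.15
        assert abs(fit.params.phi[0] - 0.76) < 0.1


class TestParameterCounting:
    @pytest.mark.parametrize(
        "structure,expected",
        [(s, k) for s, _, k in datasets.MODEL_TABLE],
        ids=[PopanModelSpec(*s).name for s, _, _ in datasets.MODEL_TABLE],
    )
    def test_all_eight_structures_match_published_counts(self, structure, expected):
        assert count_parameters(PopanModelSpec(*structure), T=10) == expected

    def test_count_is_independent_of_t_for_constant_models(self):
        assert count_parameters(PopanModelSpec(".", ".", "."), T=2) == 4


class TestAicc:
    def test_direct_formula(self):
        assert aicc(-50, 2, 100) == pytest.approx(100 + 4 + 12 / 97)
        assert aicc(-50, 0, 100) == pytest.approx(100.0)

    def test_monotone_in_loglik(self):
        assert aicc(-60, 3, 50) > aicc(-50, 3, 50)

    def test_undefined_for_tiny_samples(self):
        with pytest.raises(ValueError):
            aicc(-50, 10, 11)


class TestWeights:
    def test_published_aicc_column_reproduces_published_weights(self):
        from petrelpop import datasets

        _, w = akaike_weights(datasets.MODEL_AICC)
        assert w[0] == pytest.approx(0.78356, abs=5e-6)
        assert w[1] == pytest.approx(0.20255, abs=5e-6)
        assert w.sum() == pytest.approx(1.0)

    def test_degenerate_cases(self):
        _, w = akaike_weights([123.4])
        assert w.tolist() == [1.0]
        _, w = akaike_weights([10.0, 10.0])
        assert w.tolist() == pytest.approx([0.5, 0.5])


class TestModelAverage:
    @staticmethod
    def _fake_fit(N, se, aicc_value):
        from dataclasses import dataclass

        @dataclass
        class F:
            N: float
            se_N: float
            AICc: float
            converged: bool = True
            spec: PopanModelSpec = PopanModelSpec()
            K: int = 4

        return F(N, se, aicc_value)

    def test_single_model_reduces_to_conditional(self):
        ms = model_average([self._fake_fit(280, 30, 100.0)])
        assert ms.averaged_N == 280
        assert ms.unconditional_se == 30
        assert ms.model_variation_pct == pytest.approx(0.0)

    def test_two_equal_weight_models_direct_formula(self):
        ms = model_average(
            [self._fake_fit(280, 30, 100.0), self._fake_fit(300, 30, 100.0)]
        )
        assert ms.averaged_N == pytest.approx(290)
        assert ms.unconditional_se == pytest.approx(np.sqrt(30**2 + 10**2), abs=1e-4)

    def test_best_model_has_largest_weight(self, published_marray):
        fits = [
            fit_popan(s, published_marray, seed=7, n_starts=3)
            for s in [PopanModelSpec(".", "t", "."), PopanModelSpec(".", ".", ".")]
        ]
        ms = model_average(fits)
        assert ms.weights[np.argmin([f.AICc for f in fits])] == ms.weights.max()


def test_model_spec_grammar():
    assert parse_model_spec("phi(.) p(t) b(.)") == PopanModelSpec(".", "t", ".")
    assert parse_model_spec("PHI(t)p(.)B(t)") == PopanModelSpec("t", ".", "t")
    with pytest.raises(ValueError):
        parse_model_spec("phi(x) p(t) b(.)")
    assert len(ALL_SPECS) == 8
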