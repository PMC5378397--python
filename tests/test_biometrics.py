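"""Dimorphism index, two-sample tests, discriminant sexing, repeatability."""

import numpy as np
import pytest

from helpers import oracle_icc_oneway, oracle_lda_coefficients, oracle_pooled_t
from petrelpop import datasets
from petrelpop.biometrics import (
    TRAITS,
    BiometricRecord,
    bonferroni_alpha,
    icc_repeatability,
    lda_classify,
    lda_fit,
    pooled_t,
    pooled_t_summary,
    sdi,
    welch_t_summary,
)
from petrelpop.simulate import BiometricsSimConfig, gen_biometrics


class TestSdi:
    @pytest.mark.parametrize(
        "trait,expected",
        [("tarsus", 1.4), ("bill", 0.6), ("depth_base", 3.2),
         ("depth_nostril", 4.4), ("head", 1.8), ("wing", 1.0)],
    )
    def test_published_trait_values(self, trait, expected):
        male = datasets.BIOMETRICS_MALE[trait][0]
        female = datasets.BIOMETRICS_FEMALE[trait][0]
        assert sdi(male, female) == expected

    def test_sign_and_degenerate_cases(self):
        assert sdi(10.0, 10.0) == 0.0
        assert sdi(10.0, 9.0) > 0 > sdi(9.0, 10.0)
        with pytest.raises(ValueError):
            sdi(0.0, 1.0)


class TestTwoSampleTests:
    def test_identical_groups_give_zero_t(self):
        t, df, p = pooled_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert df == 4

    def test_pooled_matches_textbook_formula_on_fixed_vectors(self):
        a, b = [3.1, 2.8, 3.5], [2.2, 2.9, 2.4]
        t, df, _ = pooled_t(a, b)
        assert t == pytest.approx(oracle_pooled_t(a, b), abs=1e-12)
        assert df == 4

    def test_summary_pooled_on_published_nostril_summaries(self):
        # raw-data statistic printed as 6.554; rounded summaries agree to ~2sf
        t, df, _ = pooled_t_summary(9.85, 0.39, 49, 9.42, 0.33, 72)
        assert df == 119
        assert t == pytest.approx(6.5, abs=0.2)

    @pytest.mark.parametrize(
        "s1,s2,t_exp,df_exp",
        [
            ((34.97, 1.00, 121), (38.0, 1.6, 185), -20.381, 303.45),
            ((273.0, 5.2, 121), (271.0, 5.9, 337), 3.499, 238.38),
        ],
    )
    def test_welch_from_summaries_printed_precision(self, s1, s2, t_exp, df_exp):
        t, df, p = welch_t_summary(*s1, *s2)
        assert t == pytest.approx(t_exp, abs=5e-4)
        assert df == pytest.approx(df_exp, abs=5e-3)
        assert p < 0.01

    def test_welch_equals_pooled_for_balanced_equal_variance(self):
        tw, _, _ = welch_t_summary(10.0, 2.0, 30, 11.0, 2.0, 30)
        tp, _, _ = pooled_t_summary(10.0, 2.0, 30, 11.0, 2.0, 30)
        assert tw == pytest.approx(tp, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            welch_t_summary(1, 0.0, 10, 2, 0.0, 10)
        with pytest.raises(ValueError):
            pooled_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pooled_t([2.0, 2.0], [2.0, 2.0])


def test_bonferroni_published_and_trivial():
    assert bonferroni_alpha(0.05, 6) == 0.008
    assert bonferroni_alpha(0.05, 5) == 0.010
    assert bonferroni_alpha(0.05, 1) == 0.05
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)


def _records_from_frame(df):
    return [
        BiometricRecord(bird_id=row["id"], sex=row["sex"],
                        **{t: row[t] for t in TRAITS})
        for _, row in df.iterrows()
    ]


class TestDiscriminantSexing:
    def test_separated_classes_classify_perfectly(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(20):
            records.append(BiometricRecord(
                f"f{i}", "female", *(10 + 0.1 * rng.standard_normal(6))))
            records.append(BiometricRecord(
                f"m{i}", "male", *(20 + 0.1 * rng.standard_normal(6))))
        model, test = lda_fit(records, seed=1)
        assert all(lda_classify(model, r)[0] == r.sex for r in records)

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        Xf = rng.normal([10, 20], [1.0, 2.0], size=(30, 2))
        Xm = rng.normal([11, 22], [1.0, 2.0], size=(25, 2))
        records = [
            BiometricRecord(f"f{i}", "female", tarsus=a, bill=b)
            for i, (a, b) in enumerate(Xf)
        ] + [
            BiometricRecord(f"m{i}", "male", tarsus=a, bill=b)
            for i, (a, b) in enumerate(Xm)
        ]
        model, _ = lda_fit(records, train_fraction=1.0, seed=0,
                           traits=["tarsus", "bill"])
        # same split (all records) so the oracle sees identical data
        cf, kf, cm, km = oracle_lda_coefficients(Xf, Xm)
        assert model.coef[0] == pytest.approx(cf, rel=1e-9)
        assert model.coef[1] == pytest.approx(cm, rel=1e-9)
        assert model.const[0] == pytest.approx(kf, rel=1e-9)
        assert model.const[1] == pytest.approx(km, rel=1e-9)

    def test_agrees_with_sklearn_predictions(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        df = gen_biometrics(BiometricsSimConfig(n_male=60, n_female=60), seed=4)
        records = _records_from_frame(df)
        model, _ = lda_fit(records, train_fraction=1.0, seed=0)
        X = np.array([r.values() for r in records])
        y = [r.sex for r in records]
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        ours = [lda_classify(model, r)[0] for r in records]
        assert (np.asarray(ours) == sk.predict(X)).mean() == 1.0

    def test_classification_invariant_to_trait_rescaling(self):
        df = gen_biometrics(BiometricsSimConfig(n_male=40, n_female=40), seed=6)
        records = _records_from_frame(df)
        model, test = lda_fit(records, seed=3)
        before = [lda_classify(model, r)[0] for r in test]
        scaled = [
            BiometricRecord(r.bird_id, r.sex, tarsus=r.tarsus * 10, bill=r.bill,
                            depth_base=r.depth_base, depth_nostril=r.depth_nostril,
                            head=r.head, wing=r.wing)
            for r in records
        ]
        model2, test2 = lda_fit(scaled, seed=3)  # same seed -> same split
        after = [lda_classify(model2, r)[0] for r in test2]
        assert before == after

    def test_tie_breaks_to_female_and_missing_traits_error(self):
        rng = np.random.default_rng(8)
        records = [
            BiometricRecord(f"f{i}", "female", *(10 + rng.standard_normal(6)))
            for i in range(10)
        ] + [
            BiometricRecord(f"m{i}", "male", *(12 + rng.standard_normal(6)))
            for i in range(10)
        ]
        model, _ = lda_fit(records, train_fraction=1.0, seed=0)
        # a degenerate model whose class functions coincide ties every
        # record exactly; the documented convention assigns female
        from petrelpop.biometrics import DiscriminantModel

        tied = DiscriminantModel(
            traits=model.traits, classes=model.classes,
            coef=np.vstack([model.coef[0], model.coef[0]]),
            const=np.array([model.const[0], model.const[0]]),
            pooled_cov=model.pooled_cov, means=model.means,
        )
        r = BiometricRecord("tie", "unknown", *model.means.mean(axis=0))
        assert lda_classify(tied, r)[0] == "female"
        with pytest.raises(ValueError, match="missing"):
            lda_classify(model, BiometricRecord("x", "unknown", tarsus=35.0))

    def test_collinear_traits_raise_naming_them(self):
        records = [
            BiometricRecord(f"f{i}", "female", tarsus=v, bill=2 * v)
            for i, v in enumerate([10.0, 11.0, 12.0, 13.0])
        ] + [
            BiometricRecord(f"m{i}", "male", tarsus=v, bill=2 * v)
            for i, v in enumerate([11.0, 12.0, 13.0, 14.0])
        ]
        with pytest.raises(ValueError, match="collinear"):
            lda_fit(records, train_fraction=1.0, seed=0, traits=["tarsus", "bill"])


class TestRepeatability:
    def test_identical_duplicates_give_icc_one(self):
        d = np.tile(np.arange(10.0)[:, None], (1, 2))
        icc, p = icc_repeatability(d)
        assert icc == 1.0

    def test_pure_noise_gives_icc_near_zero(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal((100, 2))
        icc, _ = icc_repeatability(d)
        assert abs(icc) < 0.1

    def test_matches_variance_components_oracle(self):
        rng = np.random.default_rng(5)
        bird = rng.normal(0, 2.0, 12)
        d = bird[:, None] + rng.normal(0, 0.5, (12, 2))
        icc, p = icc_repeatability(d)
        assert icc == pytest.approx(oracle_icc_oneway(d), abs=1e-12)
        assert 0 < p < 0.05

    def test_matches_pingouin_oneway_icc(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(9)
        bird = rng.normal(0, 1.0, 15)
        d = bird[:, None] + rng.normal(0, 0.6, (15, 2))
        icc, _ = icc_repeatability(d)
        long = pd.DataFrame(
            {
                "bird": np.repeat(np.arange(15), 2),
                "rater": np.tile([0, 1], 15),
                "y": d.ravel(),
            }
        )
        tbl = pg.intraclass_corr(long, targets="bird", raters="rater",
                                 ratings="y")
        ref = tbl.iloc[0]["ICC"]  # first row: one-way single-rater ICC
        assert icc == pytest.approx(float(ref), abs=1e-6)

    def test_zero_between_bird_variance_warns(self):
        with pytest.warns(UserWarning):
            icc, _ = icc_repeatability(np.ones((6, 2)))
        assert icc == 0.0
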