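import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import timegen as tg
from timegen.errors import DegenerateDataError, InvalidDesignError, InvalidInputError, InvalidSpecError
from timegen.stats import PowerSpec


class TestNormalizedEffect:
    def test_table_means_example(self):
        """Visual-millisecond condition means give a ~5% overestimation index."""
        assert tg.normalized_effect(0.366, 0.405) == pytest.approx(0.0506, abs=1e-4)

    def test_zero_at_equality(self):
        assert tg.normalized_effect(0.4, 0.4) == 0.0

    @given(a=st.floats(0.01, 10), b=st.floats(0.01, 10), c=st.floats(0.01, 100))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_antisymmetry_scale_invariance_and_bounds(self, a, b, c):
        e = tg.normalized_effect(a, b)
        assert e == pytest.approx(-tg.normalized_effect(b, a), abs=1e-14)
        assert tg.normalized_effect(c * a, c * b) == pytest.approx(e, rel=1e-10)
        assert -1 < e < 1

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            tg.normalized_effect(-0.1, 0.4)


class TestHrModulation:
    def test_visual_group_scale(self):
        assert tg.hr_modulation(151, 80) == pytest.approx(71)

    def test_zero_at_equality(self):
        assert tg.hr_modulation(80, 80) == 0.0


class TestPower:
    def test_study_power_computation(self):
        """d = 0.88 requires 19 participants for 95% power at alpha 0.05."""
        spec = PowerSpec(effect_size_d=0.88, alpha=0.05, power_target=0.95)
        assert tg.required_n(spec) == 19
        assert tg.paired_t_power(0.88, 19, 0.05) >= 0.95
        assert tg.paired_t_power(0.88, 18, 0.05) < 0.95

    def test_power_monotone_in_n_and_d(self):
        p = [tg.paired_t_power(0.88, n) for n in range(5, 40)]
        assert np.all(np.diff(p) > 0)
        q = [tg.paired_t_power(d, 19) for d in (0.3, 0.6, 0.9, 1.2)]
        assert np.all(np.diff(q) > 0)

    def test_power_approaches_one(self):
        assert tg.paired_t_power(0.88, 2000) > 0.9999

    @pytest.mark.parametrize("d", [0.5, 0.88, 1.2, 3.0])
    def test_required_n_is_exact_argmin(self, d):
        spec = PowerSpec(effect_size_d=d)
        n = tg.required_n(spec)
        assert tg.paired_t_power(d, n) >= 0.95
        if n > 2:
            assert tg.paired_t_power(d, n - 1) < 0.95

    def test_invalid_spec_rejected(self):
        with pytest.raises(InvalidSpecError):
            tg.required_n(PowerSpec(effect_size_d=-1))
        with pytest.raises(InvalidSpecError):
            PowerSpec(effect_size_d=0.5, alpha=1.5)


class TestJzsBayesFactor:
    def test_null_sample_favors_null(self):
        # symmetric sample with mean exactly zero
        res = tg.jzs_bf_onesample([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert res.bf10 < 1
        assert res.favors == "H0"

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.normal(0.3, 1.0, size=rng.integers(5, 40))
            from scipy import stats as sps

            t = sps.ttest_1samp(x, 0).statistic
            ours = tg.jzs_bf_onesample(x).bf10
            theirs = float(pg.bayesfactor_ttest(t, len(x), paired=True))
            # pingouin's own quadrature carries ~1e-4 relative slack
            assert ours == pytest.approx(theirs, rel=1e-3)

    def test_agrees_with_bic_approximation_at_large_t(self):
        """For a clearly non-null sample the JZS BF lands within an order of
        magnitude of the BIC-based approximation exp((BIC0 - BIC1)/2)."""
        rng = np.random.default_rng(1)
        x = rng.normal(1.0, 1.0, 30)
        n = len(x)
        rss1 = np.sum((x - x.mean()) ** 2)
        rss0 = np.sum(x**2)
        bic1 = n * np.log(rss1 / n) + 2 * np.log(n)
        bic0 = n * np.log(rss0 / n) + 1 * np.log(n)
        bf_bic = np.exp((bic0 - bic1) / 2)
        ours = tg.jzs_bf_onesample(x).bf10
        assert abs(np.log10(ours) - np.log10(bf_bic)) < 1.0

    def test_evidence_labels_follow_thresholds(self):
        from timegen.stats import BayesResult

        assert BayesResult.from_bf10(10**0.65).evidence_label == "substantial"
        assert BayesResult.from_bf10(10**0.2).evidence_label == "weak"
        assert BayesResult.from_bf10(10**1.5).evidence_label == "strong"
        assert BayesResult.from_bf10(10**3.89).evidence_label == "decisive"
        weak_null = BayesResult.from_bf10(10**-0.3)
        assert weak_null.favors == "H0" and weak_null.evidence_label == "weak"
        sub_null = BayesResult.from_bf10(10**-0.56)
        assert sub_null.favors == "H0" and sub_null.evidence_label == "substantial"

    def test_label_consistent_with_bf_magnitude(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(rng.uniform(-1, 1), 1.0, 20)
            res = tg.jzs_bf_onesample(x)
            assert (res.bf10 > 10**0.47 and res.favors == "H1") == (
                res.evidence_label != "weak" and res.favors == "H1"
            )

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DegenerateDataError):
            tg.jzs_bf_onesample([1.0, 1.0, 1.0])
        with pytest.raises(InvalidInputError):
            tg.jzs_bf_onesample([1.0])


class TestCorrelationBF:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, res = tg.correlation_with_bf(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert res.favors == "H1" and res.bf10 > 10**2

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        for r, n in [(0.37, 23), (-0.078, 29), (-0.14, 23), (0.097, 29)]:
            # reconstruct series with this exact sample correlation
            x = np.arange(n, dtype=float)
            x = (x - x.mean()) / x.std()
            y = r * x + np.sqrt(1 - r**2) * _orthonormal(x)
            r_hat, res = tg.correlation_with_bf(x, y)
            assert r_hat == pytest.approx(r, abs=1e-12)
            assert res.bf10 == pytest.approx(float(pg.bayesfactor_pearson(r, n)), rel=1e-6)

    def test_independent_gaussians_favor_null(self):
        """n = 29 independent pairs typically give substantial null evidence."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(10):
            x, y = rng.normal(size=(2, 29))
            r, res = tg.correlation_with_bf(x, y)
            if res.lbf < -0.3:
                hits += 1
        assert hits >= 7

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 15))
        r1, _ = tg.correlation_with_bf(x, y)
        r2, _ = tg.correlation_with_bf(3 * x - 1, -2 * y + 5)
        assert abs(r2) == pytest.approx(abs(r1), rel=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateDataError):
            tg.correlation_with_bf([1, 1, 1, 1], [1, 2, 3, 4])


def _orthonormal(x):
    rng = np.random.default_rng(99)
    z = rng.normal(size=len(x))
    z = z - z.mean()
    z = z - x * (z @ x) / (x @ x)
    return z / z.std()


def _synthetic_pse_table(seed, motor_delta=-0.05, n_per_modality=25):
    """Long-format PSE table with a purely additive motor effect.

    The motor shift is the same absolute size in every modality/range cell and
    the noise is homoscedastic, so all interaction terms are null by
    construction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for modality, n in (("visual", n_per_modality), ("auditory", n_per_modality)):
        for i in range(n):
            pid = f"{modality[:1]}{i}"
            intercept = rng.normal(0, 0.02)
            for rng_label, ref in (("milliseconds", 0.4), ("seconds", 2.0)):
                for motor in ("rest", "run"):
                    shift = motor_delta if motor == "run" else 0.0
                    rows.append(
                        {
                            "participant_id": pid,
                            "modality": modality,
                            "range": rng_label,
                            "motor": motor,
                            "pse_s": ref + shift + intercept + rng.normal(0, 0.05),
                        }
                    )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_pure_motor_effect_detected_without_interactions(self):
        table = _synthetic_pse_table(seed=4)
        res = tg.mixed_anova(table, "pse_s")
        assert res.loc["Motor", "p"] < 0.01
        assert res.loc["Range", "p"] < 0.001
        for term in ("Modality*Range", "Modality*Motor", "Range*Motor",
                     "Modality*Range*Motor"):
            assert res.loc[term, "p"] > 0.01

    def test_null_motor_effect_calibrated(self):
        table = _synthetic_pse_table(seed=8, motor_delta=0.0)
        res = tg.mixed_anova(table, "pse_s")
        assert res.loc["Motor", "F"] < 5

    def test_row_order_invariance(self):
        table = _synthetic_pse_table(seed=6)
        shuffled = table.sample(frac=1, random_state=0).reset_index(drop=True)
        a = tg.mixed_anova(table, "pse_s")
        b = tg.mixed_anova(shuffled, "pse_s")
        assert np.allclose(a["F"], b["F"], rtol=1e-6)

    def test_unbalanced_design_supported(self):
        table = _synthetic_pse_table(seed=5)
        # drop one modality for a third of the participants
        drop = [f"v{i}" for i in range(8)]
        table = table[~((table.participant_id.isin(drop)) & (table.modality == "auditory"))]
        res = tg.mixed_anova(table, "pse_s")
        assert res.loc["Motor", "p"] < 0.01

    def test_single_level_factor_rejected(self):
        table = _synthetic_pse_table(seed=7)
        with pytest.raises(InvalidDesignError):
            tg.mixed_anova(table[table.motor == "rest"], "pse_s")


class TestNormalityCheck:
    def test_gaussian_sample_typically_passes(self):
        rng = np.random.default_rng(21)
        passes = sum(
            tg.normality_check(rng.normal(size=29))[1] > 0.05 for _ in range(20)
        )
        assert passes >= 17

    def test_heavy_tailed_sample_typically_fails(self):
        rng = np.random.default_rng(22)
        fails = sum(
            tg.normality_check(rng.standard_t(1, size=50))[1] < 0.05 for _ in range(20)
        )
        assert fails >= 16

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            tg.normality_check([1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            tg.normality_check([3.0, 3.0, 3.0, 3.0])
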