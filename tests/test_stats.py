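import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from micronetfun import (
    FunctionTable,
    MultifunctionalityModel,
    detrended_regress,
    multifunctionality_avg,
    multifunctionality_multidim,
    regress,
    sequential_anova,
    treatment_anova_tukey,
)
from micronetfun.containers import BENEFIT, LOSS
from .oracles import sequential_ss_bruteforce


def make_functions(values, loss=()):
    vals = pd.DataFrame(values)
    direction = pd.Series(
        {c: (LOSS if c in set(loss) else BENEFIT) for c in vals.columns})
    return FunctionTable(vals, direction)


class TestAveragingIndex:
    def test_hand_computed_four_sample_table(self):
        ft = make_functions({"f1": [1.0, 2.0, 3.0, 4.0],
                             "f2": [2.0, 2.0, 4.0, 4.0]})
        idx = multifunctionality_avg(ft)
        z1 = sps.zscore([1, 2, 3, 4], ddof=1)
        z2 = sps.zscore([2, 2, 4, 4], ddof=1)
        np.testing.assert_allclose(idx.to_numpy(), (z1 + z2) / 2, atol=1e-12)

    def test_grand_mean_zero(self, rng):
        ft = make_functions(
            {f"f{i}": rng.random(12) for i in range(5)}, loss=["f4"])
        assert multifunctionality_avg(ft).mean() == pytest.approx(0.0, abs=1e-12)

    def test_loss_functions_inverted(self, rng):
        base = rng.random(10)
        ft_benefit = make_functions({"f1": base})
        ft_loss = make_functions({"f1": -base}, loss=["f1"])
        np.testing.assert_allclose(multifunctionality_avg(ft_benefit),
                                   multifunctionality_avg(ft_loss), atol=1e-12)

    def test_constant_function_rejected(self):
        ft = make_functions({"f1": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            multifunctionality_avg(ft)


class TestMultidimIndex:
    def test_rank_one_case_matches_averaging(self, rng):
        base = rng.standard_normal(15)
        ft = make_functions({"f1": 2 * base + 1, "f2": -3 * base,
                             "f3": 0.5 * base})
        avg = multifunctionality_avg(ft)
        md = multifunctionality_multidim(ft)
        r = np.corrcoef(avg, md)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_loss_flag_orientation_invariance(self, rng):
        vals = {f"f{i}": rng.standard_normal(12) for i in range(4)}
        ft_a = make_functions(dict(vals), loss=["f3"])
        flipped = dict(vals)
        flipped["f3"] = -vals["f3"]
        ft_b = make_functions(flipped)  # raw sign flip + benefit flag
        np.testing.assert_allclose(multifunctionality_multidim(ft_a),
                                   multifunctionality_multidim(ft_b),
                                   atol=1e-10)

    def test_model_reports_correlation(self, rng):
        shared = rng.standard_normal(20)
        vals = {f"f{i}": shared + 0.4 * rng.standard_normal(20)
                for i in range(6)}
        res = MultifunctionalityModel(make_functions(vals)).fit()
        assert res.correlation_between >= 0.8
        assert res.to_frame().shape == (20, 2)


class TestRegress:
    def test_identity(self, rng):
        x = rng.standard_normal(20)
        r = regress(x, x)
        assert r.SES == pytest.approx(1.0)
        assert r.R2 == pytest.approx(1.0)

    def test_orthogonal(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        xc = x - x.mean()
        yc = y - y.mean()
        yc -= xc * (xc @ yc) / (xc @ xc)  # exact orthogonalization
        r = regress(yc, x)
        assert r.SES == pytest.approx(0.0, abs=1e-10)

    def test_ses_equals_pearson_r(self, rng):
        x = rng.standard_normal(25)
        y = 0.4 * x + rng.standard_normal(25)
        r = regress(y, x)
        rho, p = sps.pearsonr(x, y)
        assert r.SES == pytest.approx(rho, abs=1e-10)
        assert r.R2 == pytest.approx(rho**2, abs=1e-10)
        assert r.P == pytest.approx(p, rel=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            regress(np.ones(5), np.arange(5.0))


class TestDetrended:
    def test_collinear_with_covariate_degenerate(self):
        cov = np.arange(20.0)
        x = 2 * cov + 1
        y = np.random.default_rng(0).standard_normal(20)
        r = detrended_regress(y, x, cov)
        assert r.degenerate

    def test_independent_covariate_close_to_plain(self):
        deltas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(60)
            y = 0.5 * x + rng.standard_normal(60)
            cov = rng.standard_normal(60)
            deltas.append(detrended_regress(y, x, cov).SES - regress(y, x).SES)
        assert abs(np.mean(deltas)) < 0.05

    def test_recovers_partial_effect_sign(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rich = rng.standard_normal(50)
            x = 0.8 * rich + rng.standard_normal(50)
            y = x + rich + 0.5 * rng.standard_normal(50)
            hits += detrended_regress(y, x, rich).SES > 0
        assert hits >= 18


class TestSequentialAnova:
    def test_orthogonal_terms_order_invariant(self, rng):
        n = 40
        A = rng.standard_normal((n, 3))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        terms = pd.DataFrame(Q, columns=["t1", "t2", "t3"])
        y = Q @ np.array([1.0, 2.0, 0.5]) + 0.3 * rng.standard_normal(n)
        a = sequential_anova(y, terms)
        b = sequential_anova(y, terms[["t3", "t1", "t2"]])
        for t in ["t1", "t2", "t3"]:
            assert a.pct_ss[t] == pytest.approx(b.pct_ss[t], abs=1e-8)

    def test_single_driver_absorbs_all_signal(self, rng):
        n = 30
        t1 = rng.standard_normal(n)
        terms = pd.DataFrame({"t1": t1, "t2": rng.standard_normal(n)})
        y = 2 * t1
        a = sequential_anova(y, terms)
        assert a.pct_ss["t1"] == pytest.approx(100.0, abs=1e-8)
        assert a.pct_ss["t2"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_nested_ss_oracle(self, rng):
        n = 35
        terms = pd.DataFrame({
            "t1": rng.standard_normal(n),
            "t2": rng.standard_normal(n),
            "t3": rng.standard_normal(n),
        })
        y = terms["t1"].to_numpy() + 0.5 * terms["t3"].to_numpy() \
            + rng.standard_normal(n)
        a = sequential_anova(y, terms)
        ss, rss = sequential_ss_bruteforce(
            y, [terms[c].to_numpy()[:, None] for c in terms.columns])
        total = ((y - y.mean()) ** 2).sum()
        for t, s in zip(terms.columns, ss):
            assert a.pct_ss[t] == pytest.approx(100 * s / total, abs=1e-8)
        assert a.pct_ss["residual"] == pytest.approx(100 * rss / total,
                                                     abs=1e-8)

    def test_pct_ss_sums_to_hundred(self, rng):
        n = 48
        terms = pd.DataFrame({"t1": rng.standard_normal(n),
                              "t2": rng.standard_normal(n)})
        y = rng.standard_normal(n)
        treatment = np.repeat(list("abcdef"), 8)
        block = np.tile(np.arange(8), 6)
        a = sequential_anova(y, terms, treatment=treatment, block=block,
                             sterile_contrast=True, sterile_label="f")
        assert a.table["pct_ss"].sum() == pytest.approx(100.0, abs=1e-8)
        assert list(a.table.index) == [
            "block", "t1", "t2", "sterile_vs_rest", "treatment", "residual"]


class TestTukey:
    def test_separated_levels_get_distinct_letters(self, rng):
        y = np.concatenate([rng.standard_normal(8),
                            rng.standard_normal(8) + 10.0])
        tr = np.repeat(["lo", "hi"], 8)
        res = treatment_anova_tukey(y, tr)
        assert res.letters["hi"] != res.letters["lo"]

    def test_null_levels_share_letter(self):
        share = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(32)
            tr = np.repeat(list("abcd"), 8)
            res = treatment_anova_tukey(y, tr)
            share += len(set(res.letters.values())) == 1
        assert share >= 18  # all-one-letter in >= 90% of null runs

    def test_letters_stable_under_relabeling(self, rng):
        y = np.concatenate([rng.standard_normal(8) + mu
                            for mu in (0.0, 0.2, 8.0)])
        tr1 = np.repeat(["a", "b", "c"], 8)
        tr2 = np.repeat(["z", "q", "m"], 8)
        r1 = treatment_anova_tukey(y, tr1)
        r2 = treatment_anova_tukey(y, tr2)
        mapping = {"a": "z", "b": "q", "c": "m"}
        for lv, letter in r1.letters.items():
            assert r2.letters[mapping[lv]] == letter

    def test_singleton_level_rejected(self, rng):
        y = rng.standard_normal(5)
        with pytest.raises(ValueError, match="singleton"):
            treatment_anova_tukey(y, ["a", "a", "b", "b", "c"])
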