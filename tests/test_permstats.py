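"""Permutation ANOVA: F oracles, exact exhaustive p-values, FL scheme."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from shoalkin.permstats import (
    EXHAUSTIVE_LIMIT,
    FactorialDataset,
    anova_f,
    permutation_anova,
    within_speed_sweep,
)

statsmodels = pytest.importorskip("statsmodels.api")
from statsmodels.formula.api import ols  # noqa: E402
from statsmodels.stats.anova import anova_lm  # noqa: E402


def sm_f(df: pd.DataFrame, formula: str) -> pd.DataFrame:
    """Sequential (Type I) ANOVA table from statsmodels as an oracle."""
    return anova_lm(ols(formula, data=df).fit(), typ=1)


class TestFOracle:
    def test_one_way_matches_statsmodels(self, rng):
        y = rng.normal(size=18)
        a = np.repeat(["l", "j", "ad"], 6)
        ds = FactorialDataset(y=y, a=a)
        got = anova_f(ds, "one_way")["A"]
        ref = sm_f(pd.DataFrame({"y": y, "a": a}), "y ~ C(a)")
        assert got.f == pytest.approx(ref.loc["C(a)", "F"], rel=1e-9)
        assert got.df == int(ref.loc["C(a)", "df"])

    def test_two_way_matches_statsmodels_balanced(self, rng):
        y = rng.normal(size=24)
        a = np.tile(np.repeat(["l", "j", "ad"], 4), 2)
        b = np.repeat([28.0, 32.0], 12)
        ds = FactorialDataset(y=y, a=a, b=b)
        got = anova_f(ds, "two_way_interaction")
        ref = sm_f(
            pd.DataFrame({"y": y, "a": a, "b": b.astype(str)}),
            "y ~ C(a) * C(b)",
        )
        assert got["A"].f == pytest.approx(ref.loc["C(a)", "F"], rel=1e-9)
        assert got["B"].f == pytest.approx(ref.loc["C(b)", "F"], rel=1e-9)
        assert got["A:B"].f == pytest.approx(ref.loc["C(a):C(b)", "F"], rel=1e-9)
        assert got["A:B"].df == 2

    def test_two_way_matches_statsmodels_unbalanced(self, rng):
        # sequential SS is order-dependent when cells are unbalanced; the
        # oracle uses the same A-then-B-then-interaction order
        y = rng.normal(size=21)
        a = np.array(["l"] * 7 + ["j"] * 6 + ["ad"] * 8)
        b = np.array(
            [28, 28, 28, 32, 32, 32, 32] + [28, 28, 32, 32, 32, 32] + [28] * 4 + [32] * 4,
            dtype=float,
        )
        ds = FactorialDataset(y=y, a=a, b=b)
        got = anova_f(ds, "two_way_interaction")
        ref = sm_f(
            pd.DataFrame({"y": y, "a": a, "b": b.astype(str)}),
            "y ~ C(a) * C(b)",
        )
        for term, key in [("A", "C(a)"), ("B", "C(b)"), ("A:B", "C(a):C(b)")]:
            assert got[term].f == pytest.approx(ref.loc[key, "F"], rel=1e-9)


class TestExhaustiveOneWay:
    def test_exact_p_two_groups_of_three(self):
        # {1,2,3} vs {4,5,6}: F = 13.5; only the split and its mirror reach
        # it among C(6,3) = 20 arrangements -> exact p = 2/20
        ds = FactorialDataset(
            y=np.array([1.0, 2, 3, 4, 5, 6]), a=np.repeat(["a", "b"], 3)
        )
        res = permutation_anova(ds, "one_way", seed=0)
        assert res.method == "exhaustive"
        assert res.m_permutations == 20
        assert res.terms["A"].f == pytest.approx(13.5)
        assert res.terms["A"].p == pytest.approx(2.0 / 20.0, abs=1e-12)

    def test_identity_always_counted(self, rng):
        # exact p is at least 1/n_arrangements for any data
        y = rng.normal(size=8)
        ds = FactorialDataset(y=y, a=np.repeat(["a", "b"], 4))
        res = permutation_anova(ds, "one_way")
        assert res.terms["A"].p >= 1.0 / 70.0 - 1e-12

    def test_constant_response_p_is_one(self):
        ds = FactorialDataset(y=np.full(6, 2.0), a=np.repeat(["a", "b"], 3))
        res = permutation_anova(ds, "one_way")
        assert res.terms["A"].p == pytest.approx(1.0)


class TestMonteCarlo:
    def _big(self, rng, shift=0.0):
        y = rng.normal(size=30)
        a = np.repeat(["a", "b", "c"], 10)
        y[a == "c"] += shift
        return FactorialDataset(y=y, a=a)

    def test_large_design_uses_monte_carlo(self, rng):
        ds = self._big(rng)
        res = permutation_anova(ds, "one_way", m_permutations=199, seed=3)
        assert res.method == "monte_carlo"
        # multinomial arrangement count for 30 in groups of 10 >> limit
        assert res.m_permutations == 199
        assert 1.0 / 200.0 <= res.terms["A"].p <= 1.0

    def test_seed_determinism(self, rng):
        ds = self._big(rng)
        p1 = permutation_anova(ds, "one_way", 499, seed=11).terms["A"].p
        p2 = permutation_anova(ds, "one_way", 499, seed=11).terms["A"].p
        assert p1 == p2

    def test_strong_effect_minimal_p(self, rng):
        ds = self._big(rng, shift=30.0)
        res = permutation_anova(ds, "one_way", m_permutations=499, seed=0)
        assert res.terms["A"].p == pytest.approx(1.0 / 500.0)

    def test_m_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_anova(self._big(rng), "one_way", m_permutations=50)


class TestFreedmanLane:
    def _dataset(self, rng, inter=0.0):
        a = np.tile(np.repeat(["l", "j", "ad"], 4), 2)
        b = np.repeat(["cool", "warm"], 12)
        y = rng.normal(size=24) + (a == "j") * 1.0 + (b == "warm") * 0.5
        y += inter * ((a == "ad") & (b == "warm"))
        return FactorialDataset(y=y, a=a, b=b)

    def test_f_matches_plain_anova(self, rng):
        ds = self._dataset(rng)
        res = permutation_anova(ds, "two_way_interaction", 199, seed=1)
        ref = anova_f(ds, "two_way_interaction")
        for term in ("A", "B", "A:B"):
            assert res.terms[term].f == pytest.approx(ref[term].f, rel=1e-12)
            assert 0.0 < res.terms[term].p <= 1.0
        assert res.method == "freedman_lane"

    def test_large_interaction_detected(self, rng):
        ds = self._dataset(rng, inter=25.0)
        res = permutation_anova(ds, "two_way_interaction", 999, seed=2)
        assert res.terms["A:B"].p <= 0.01

    def test_missing_factor_b_rejected(self, rng):
        ds = FactorialDataset(y=rng.normal(size=8), a=np.repeat(["a", "b"], 4))
        with pytest.raises(ValueError):
            permutation_anova(ds, "two_way_interaction")

    def test_unknown_model_rejected(self, rng):
        ds = FactorialDataset(y=rng.normal(size=8), a=np.repeat(["a", "b"], 4))
        with pytest.raises(ValueError):
            permutation_anova(ds, "three_way")


class TestWithinSpeedSweep:
    def _table(self, rng):
        rows = []
        for speed in (1.5, 3.0):
            for stage in ("larva", "juvenile"):
                for temp in (28.0, 32.0):
                    # 3.0 BL/s lacks the 32 C treatment for larvae
                    if speed == 3.0 and stage == "larva" and temp == 32.0:
                        continue
                    for _ in range(4):
                        rows.append(
                            {
                                "speed_bl_s": speed,
                                "stage": stage,
                                "treatment_temp_c": temp,
                                "tbf_hz": rng.normal(10.0 + (stage == "larva") * 8),
                            }
                        )
        return pd.DataFrame(rows)

    def test_terms_reported_per_speed(self, rng):
        out = within_speed_sweep(
            self._table(rng), ["tbf_hz"], m_permutations=99, seed=0
        )
        assert set(out["speed_bl_s"]) == {1.5, 3.0}
        at_15 = out[out["speed_bl_s"] == 1.5]
        assert set(at_15["term"]) == {"A", "B", "A:B"}
        assert "p_bh" in out.columns
        # the missing larva x 32 C cell at 3.0 BL/s leaves the interaction
        # with zero estimable df there; its p is NaN by design
        testable = out[out["df"] > 0]
        degenerate = out[out["df"] == 0]
        assert ((testable["p_perm"] > 0) & (testable["p_perm"] <= 1)).all()
        assert degenerate["p_perm"].isna().all()
        assert (testable["p_bh"] >= testable["p_perm"] - 1e-12).all()

    def test_single_factor_level_skipped(self, rng, caplog):
        df = self._table(rng)
        df = df[~((df["speed_bl_s"] == 3.0) & (df["stage"] == "juvenile"))]
        import logging

        with caplog.at_level(logging.WARNING, logger="shoalkin.permstats"):
            out = within_speed_sweep(df, ["tbf_hz"], m_permutations=99)
        assert set(out["speed_bl_s"]) == {1.5}
        assert any("skipping" in r.message for r in caplog.records)

    def test_strong_stage_effect_flagged(self, rng):
        out = within_speed_sweep(
            self._table(rng), ["tbf_hz"], m_permutations=999, seed=5
        )
        a_rows = out[out["term"] == "A"]
        assert a_rows["significant"].all()


class TestDatasetValidation:
    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            FactorialDataset(y=np.arange(6.0), a=np.repeat("a", 6))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FactorialDataset(y=np.arange(6.0), a=np.repeat(["a", "b"], 2))

    def test_exhaustive_limit_constant(self):
        assert EXHAUSTIVE_LIMIT == 20_000
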