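"""Structure pipeline: screening, importance, partial dependence, break points."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streamdiag.structure import (
    collinearity_screen,
    detect_breakpoints,
    importance_rank,
    partial_dependence,
    select_relationships,
)


def _step_table(n=200, threshold=5.0, jump=10.0, noise=0.5, seed=0, x_max=10.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, x_max, n)
    y = jump * (x >= threshold) + rng.normal(0, noise, n)
    return pd.DataFrame({"x": x, "y": y})


class TestCollinearityScreen:
    def test_pair_above_threshold_loses_one_member(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=300)
        b = a + rng.normal(scale=0.25, size=300)  # |rho| ~ 0.95
        c = rng.normal(size=300)
        table = pd.DataFrame({"a": a, "b": b, "c": c})
        res = collinearity_screen(table, ["a", "b", "c"], threshold=0.8)
        assert len(res.dropped) == 1
        assert res.dropped[0][0] in ("a", "b")
        assert "c" in res.kept

    def test_uncorrelated_variables_all_kept(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        res = collinearity_screen(table, list("abcd"), threshold=0.8)
        assert res.dropped == [] and sorted(res.kept) == list("abcd")

    def test_identical_triple_drops_exactly_two(self):
        x = np.arange(100, dtype=float)
        table = pd.DataFrame({"a": x, "b": x, "c": x})
        res = collinearity_screen(table, ["a", "b", "c"], threshold=0.8)
        assert len(res.kept) == 1 and len(res.dropped) == 2

    def test_constant_variable_reported_and_kept(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"a": rng.normal(size=50), "k": np.ones(50)})
        res = collinearity_screen(table, ["a", "k"], threshold=0.8)
        assert res.constant == ["k"] and "k" in res.kept

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_survivors_always_satisfy_threshold(self, seed):
        """Property: after screening, no kept pair exceeds the threshold and
        dropped + kept partition the input variables."""
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 7))
        latent = rng.normal(size=(120, 2))
        cols = {}
        for i in range(p):
            w = rng.normal(size=2)
            cols[f"v{i}"] = latent @ w + rng.normal(scale=rng.uniform(0.05, 2), size=120)
        table = pd.DataFrame(cols)
        res = collinearity_screen(table, list(cols), threshold=0.8)
        assert sorted(res.kept + [d for d, _, _ in res.dropped]) == sorted(cols)
        corr = table[res.kept].corr(method="spearman").abs()
        np.fill_diagonal(corr.values, 0.0)
        assert (corr.values <= 0.8 + 1e-12).all()


class TestImportanceRank:
    def test_step_signal_ranked_first_and_selected(self):
        """Known generator: y depends on x1 only; across 20 seeds the signal
        predictor must usually win against 7 spurious ones (majority vote)."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 150
            table = pd.DataFrame(
                {f"x{i}": rng.uniform(0, 10, n) for i in range(1, 9)}
            )
            table["y"] = 8.0 * (table["x1"] >= 5.0) + rng.normal(0, 1.0, n)
            ranking = importance_rank(
                table, "y", [f"x{i}" for i in range(1, 9)], n_trees=100, seed=seed
            )
            assert len(ranking.selected) == 2  # ceil(8 / 4)
            if ranking.ranking[0][0] == "x1" and "x1" in ranking.selected:
                wins += 1
        assert wins >= 15

    def test_pure_noise_still_selects_quartile(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame({f"x{i}": rng.uniform(size=100) for i in range(5)})
        table["y"] = rng.normal(size=100)
        ranking = importance_rank(table, "y", [f"x{i}" for i in range(5)], n_trees=50)
        assert len(ranking.selected) == 2  # ceil(5 / 4)

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="rows"):
            importance_rank(table, "y", ["x"])

    def test_constant_response_rejected(self):
        table = pd.DataFrame({"x": np.arange(40.0), "y": np.ones(40)})
        with pytest.raises(ValueError, match="constant"):
            importance_rank(table, "y", ["x"])

    def test_deterministic_for_fixed_seed(self):
        table = _step_table(n=100, seed=5).rename(columns={"x": "x1"})
        table["x2"] = np.random.default_rng(6).uniform(0, 10, 100)
        r1 = importance_rank(table, "y", ["x1", "x2"], n_trees=50, seed=3)
        r2 = importance_rank(table, "y", ["x1", "x2"], n_trees=50, seed=3)
        assert r1.ranking == r2.ranking


class TestPartialDependence:
    def test_constant_response_flat_curve(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"x": rng.uniform(0, 10, 100), "y": np.zeros(100)})
        table.loc[0, "y"] = 1e-9  # dodge the constant-response guard
        ranking = importance_rank(table, "y", ["x"], n_trees=30)
        grid = np.linspace(table["x"].min(), table["x"].max(), 11)
        curve, _ = partial_dependence(ranking, "x", grid)
        assert np.ptp(curve) <= 1e-9

    def test_step_jump_localized_at_threshold(self):
        table = _step_table(n=400, threshold=5.0, jump=10.0, noise=0.5, seed=1)
        ranking = importance_rank(table, "y", ["x"], n_trees=100, seed=1)
        grid = np.linspace(0.5, 9.5, 19)  # spacing 0.5
        curve, flags = partial_dependence(ranking, "x", grid)
        assert not flags.any()
        jump_at = grid[np.argmax(np.abs(np.diff(curve)))] + 0.25
        assert abs(jump_at - 5.0) <= 0.5

    def test_extrapolated_grid_points_flagged(self):
        table = _step_table(n=100, seed=2)
        ranking = importance_rank(table, "y", ["x"], n_trees=30)
        with pytest.warns(UserWarning, match="extrapolated"):
            _, flags = partial_dependence(ranking, "x", np.array([-5.0, 5.0, 50.0]))
        assert flags.tolist() == [True, False, True]


class TestDetectBreakpoints:
    def test_single_threshold_recovered(self):
        table = _step_table(n=200, threshold=5.0, jump=10.0, noise=0.5, seed=4)
        bset = detect_breakpoints(table, "y", "x", n_perm=999, seed=4)
        assert len(bset.breaks) >= 1
        strongest = bset.breaks[int(np.argmax(bset.sharpness))]
        assert abs(strongest - 5.0) <= 0.5
        assert all(p < 0.05 for p in bset.p_values)

    def test_constant_response_yields_no_breaks(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame({"x": rng.uniform(0, 10, 100), "y": np.full(100, 3.0)})
        bset = detect_breakpoints(table, "y", "x", n_perm=199, seed=8)
        assert bset.breaks == []

    def test_double_staircase_capped_at_two_breaks(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 10, 400)
        y = 5.0 * (x >= 3.0) + 5.0 * (x >= 7.0) + rng.normal(0, 0.3, 400)
        table = pd.DataFrame({"x": x, "y": y})
        bset = detect_breakpoints(table, "y", "x", n_perm=499, seed=9)
        assert len(bset.breaks) == 2  # never three: states are capped at three
        assert abs(bset.breaks[0] - 3.0) <= 0.5
        assert abs(bset.breaks[1] - 7.0) <= 0.5

    def test_null_response_rarely_splits(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            table = pd.DataFrame(
                {"x": rng.uniform(0, 10, 200), "y": rng.normal(size=200)}
            )
            bset = detect_breakpoints(table, "y", "x", n_perm=499, seed=seed)
            hits += bool(bset.breaks)
        assert hits <= 4  # alpha = 0.05 with some slack at 20 draws


class TestSelectRelationships:
    def _ranking(self, response, selected, iqr=8.0):
        from streamdiag.structure import ImportanceRanking

        ranking = [(s, 1.0 - 0.1 * i) for i, s in enumerate(selected)]
        ranking += [("noise", 0.01)]
        return ImportanceRanking(response, ranking, list(selected), iqr)

    def _bset(self, stressor, breaks, sharpness):
        from streamdiag.structure import BreakPointSet

        return BreakPointSet(stressor, breaks, sharpness, [0.001] * len(breaks))

    def test_top_quartile_with_break_kept(self):
        rankings = {"m": self._ranking("m", ["s1"])}
        breaksets = {("m", "s1"): self._bset("s1", [5.0], [6.0])}
        assert select_relationships(rankings, breaksets) == [("s1", "m")]

    def test_flat_partial_dependence_rejected(self):
        rankings = {"m": self._ranking("m", ["s1"], iqr=8.0)}
        # jump below 25% of the response IQR: no sharp break, no edge
        breaksets = {("m", "s1"): self._bset("s1", [5.0], [1.0])}
        assert select_relationships(rankings, breaksets) == []

    def test_below_quartile_sharp_break_rejected(self):
        rankings = {"m": self._ranking("m", ["s1"])}
        breaksets = {
            ("m", "s1"): self._bset("s1", [5.0], [6.0]),
            ("m", "s2"): self._bset("s2", [2.0], [9.0]),  # sharp but not selected
        }
        assert select_relationships(rankings, breaksets) == [("s1", "m")]

    def test_empty_breakset_rejected(self):
        rankings = {"m": self._ranking("m", ["s1"])}
        breaksets = {("m", "s1"): self._bset("s1", [], [])}
        assert select_relationships(rankings, breaksets) == []
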