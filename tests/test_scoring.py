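"""Rank engine and undirected signature score, checked against brute force."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sigbridge as sb
from sigbridge.scoring import _deviation_bounds


def brute_force_score(set_ranks, n):
    """Independent normaliser: enumerate every placement of m genes on the
    tie-free grid 0..n-1 for the min/max achievable mean deviation."""
    m = len(set_ranks)
    center = np.median(np.arange(n))
    raw = np.mean([abs(r - center) for r in set_ranks])
    means = [np.mean([abs(r - center) for r in combo])
             for combo in combinations(range(n), m)]
    lo, hi = min(means), max(means)
    return min(max((raw - lo) / (hi - lo), 0.0), 1.0)


class TestRankGenes:
    @pytest.mark.parametrize("counts,expected", [
        ([5, 7, 7, 10], [0, 1, 1, 3]),
        ([1, 2, 3, 4, 5], [0, 1, 2, 3, 4]),
        ([9, 9, 9], [0, 0, 0]),
    ])
    def test_competition_ranks(self, counts, expected):
        assert sb.rank_genes(counts).tolist() == expected

    def test_monotone_invariance(self):
        counts = np.array([3, 19, 19, 200, 7])
        base = sb.rank_genes(counts)
        for f in (np.log, lambda x: 3 * x, lambda x: x + 7):
            assert (sb.rank_genes(f(counts)) == base).all()

    def test_all_tied_warns_half(self):
        with pytest.warns(UserWarning):
            rel = sb.relative_ranks([4, 4, 4])
        assert (rel == 0.5).all()


class TestSingscoreUndirected:
    def _relranks(self, n):
        return pd.Series(np.arange(n) / (n - 1),
                         index=[f"g{i}" for i in range(n)])

    def test_extreme_placement_scores_one(self):
        rel = self._relranks(5)
        assert sb.singscore_undirected(rel, ["g0", "g4"]) == pytest.approx(1.0)

    def test_central_placement_scores_zero(self):
        rel = self._relranks(5)
        assert sb.singscore_undirected(rel, ["g1", "g2"]) == pytest.approx(0.0)

    def test_matches_brute_force_all_3_subsets_of_7(self):
        rel = self._relranks(7)
        for combo in combinations(range(7), 3):
            got = sb.singscore_undirected(rel, [f"g{i}" for i in combo])
            assert got == pytest.approx(brute_force_score(combo, 7), abs=1e-12)

    def test_missing_gene_raises(self):
        with pytest.raises(KeyError, match="absent"):
            sb.singscore_undirected(self._relranks(5), ["g0", "nope"])

    def test_bounds_monotone_in_set_size(self):
        lo5, hi5 = _deviation_bounds(11, 5)
        lo1, hi1 = _deviation_bounds(11, 1)
        assert lo5 > lo1 and hi5 < hi1


class TestStableGeneRanks:
    def test_hand_worked_levels(self):
        counts = pd.Series({"a": 1, "b": 50, "c": 500, "h1": 10, "h2": 100})
        rel = sb.stable_gene_ranks(counts, ["h1", "h2"])
        assert rel["a"] == pytest.approx(1 / 6)
        assert rel["b"] == pytest.approx(3 / 6)
        assert rel["c"] == pytest.approx(5 / 6)

    def test_gene_above_all_stables_alone(self):
        counts = pd.Series({"g": 1000, "x": 1, "h1": 10, "h2": 20, "h3": 30})
        rel = sb.stable_gene_ranks(counts, ["h1", "h2", "h3"])
        assert rel["g"] == pytest.approx(3.5 / 4)
        assert rel["x"] == pytest.approx(0.5 / 4)

    def test_all_relranks_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(3)
        counts = pd.Series(rng.integers(0, 100, 50),
                           index=[f"g{i}" for i in range(50)])
        rel = sb.stable_gene_ranks(counts, ["g0", "g1", "g2"])
        assert ((rel > 0) & (rel < 1)).all()

    def test_missing_stable_gene_raises(self):
        with pytest.raises(KeyError):
            sb.stable_gene_ranks(pd.Series({"a": 1}), ["zz"])


class TestSkewTransform:
    def test_uniform_reference_gives_identity(self):
        m = 200
        y = (np.arange(1, m + 1) - 0.5) / m
        t = sb.fit_skew_transform(y)
        assert abs(t.intercept) < 1e-9 and abs(t.slope - 1) < 1e-9

    def test_top_half_compression_closed_form(self):
        m = 100
        y = 0.5 + 0.5 * (np.arange(1, m + 1) - 0.5) / m
        t = sb.fit_skew_transform(y)
        assert t.intercept == pytest.approx(0.5, abs=1e-12)
        assert t.slope == pytest.approx(0.5, abs=1e-12)

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(8)
        m = 60
        x = (np.arange(1, m + 1) - 0.5) / m
        y = np.sort(np.clip(0.3 + 0.6 * x + rng.normal(0, 0.02, m), 0, 1))
        t = sb.fit_skew_transform(y)
        grid = np.linspace(-0.5, 1.5, 401)
        best, best_sse = None, np.inf
        for a in grid:
            for b in np.linspace(0.05, 2.0, 391):
                sse = np.sum((y - (a + b * x)) ** 2)
                if sse < best_sse:
                    best, best_sse = (a, b), sse
        assert t.intercept == pytest.approx(best[0], abs=5e-3)
        assert t.slope == pytest.approx(best[1], abs=5e-3)

    def test_degenerate_reference_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            sb.fit_skew_transform(np.full(20, 0.4))

    def test_apply_preserves_order(self):
        rng = np.random.default_rng(1)
        rel = pd.Series(rng.random(40))
        out = sb.apply_skew(rel, sb.SkewTransform(0.3, 0.6))
        assert (np.argsort(out.to_numpy()) == np.argsort(rel.to_numpy())).all()
        assert sb.apply_skew(pd.Series([0.0]), sb.SkewTransform(0.5, 0.5))[0] == 0.5

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            sb.SkewTransform(0.0, -1.0)


class TestScoreTable:
    def test_scores_in_unit_interval_and_sizes(self, small_cohort):
        t = sb.score_table(small_cohort.panel_counts, small_cohort.signatures,
                           "no_stable")
        assert ((t.scores >= 0) & (t.scores <= 1)).all().all()
        assert t.sizes["inflammation_18"] == 18

    def test_single_sample_property(self, tiny_counts):
        sigs = sb.SignatureCollection({"s1": ["g0", "g5", "g9"],
                                       "s2": ["g2", "g3"]})
        base = sb.score_table(tiny_counts, sigs).scores
        dup = tiny_counts.copy()
        dup["extra"] = tiny_counts["s0"]
        withdup = sb.score_table(dup, sigs).scores
        pd.testing.assert_frame_equal(base, withdup[base.columns])

    def test_per_sample_rescaling_invariance(self, tiny_counts):
        sigs = sb.SignatureCollection({"s1": ["g0", "g5", "g9"]})
        base = sb.score_table(tiny_counts, sigs).scores
        scaled = tiny_counts * pd.Series([1, 3, 10, 0.5, 7, 2],
                                         index=tiny_counts.columns)
        pd.testing.assert_frame_equal(
            base, sb.score_table(scaled, sigs).scores)

    def test_part_equals_no_stable_on_overlap_universe(self, tiny_counts):
        sigs = sb.SignatureCollection({"s1": ["g0", "g5"]})
        full = sb.score_table(tiny_counts, sigs, "no_stable").scores
        part = sb.score_table(tiny_counts, sigs, "part",
                              overlap=list(tiny_counts.index)).scores
        pd.testing.assert_frame_equal(full, part)

    def test_uncontained_signature_excluded_with_report(self, tiny_counts):
        sigs = sb.SignatureCollection({"ok": ["g0", "g1"],
                                       "bad": ["g0", "zz"]})
        t = sb.score_table(tiny_counts, sigs)
        assert list(t.scores.index) == ["ok"]
        assert t.excluded == {"bad": ["zz"]}

    def test_no_scorable_signature_raises(self, tiny_counts):
        sigs = sb.SignatureCollection({"bad": ["zz", "yy"]})
        with pytest.raises(ValueError, match="no signature"):
            sb.score_table(tiny_counts, sigs)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=10 ** 6), min_size=4,
                max_size=40, unique=True),
       st.data())
def test_property_score_invariant_to_monotone_transform(counts, data):
    """Any strictly increasing count transform leaves the score unchanged."""
    genes = [f"g{i}" for i in range(len(counts))]
    m = data.draw(st.integers(min_value=1, max_value=len(counts)))
    members = genes[:m]
    df = pd.DataFrame({"s": counts}, index=genes)
    sigs = sb.SignatureCollection({"sig": members})
    base = sb.score_table(df, sigs).scores.iloc[0, 0]
    transformed = sb.score_table(np.log1p(df * 13), sigs).scores.iloc[0, 0]
    assert transformed == pytest.approx(base, abs=1e-12)
    assert 0.0 <= base <= 1.0
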