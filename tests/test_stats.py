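import itertools

import numpy as np
import pytest

from mossbranch import (
    BranchingPattern,
    PatternDataset,
    adjacent_branch_fraction,
    aiz_size,
    basal_branch_proportion,
    fit_branch_length_model,
    fit_position_polynomial,
    generate_regression_fixture,
    mean_min_branch_distance,
    position_distribution,
    stochastic_dataset,
    summarize,
)
from mossbranch.null_models import NullModelParams
from mossbranch.stats import pooled_min_branch_distance
from mossbranch.synthetic import table_as_datasets


def pat(L, *positions):
    return BranchingPattern(L=L, branch_positions=tuple(positions))


class TestPerGametophoreDescriptors:
    @pytest.mark.parametrize(
        "pattern,expected",
        [(pat(30, 9, 20), 10), (pat(30, 30), 0), (pat(30), None)],
    )
    def test_aiz(self, pattern, expected):
        assert aiz_size(pattern) == expected

    @pytest.mark.parametrize(
        "pattern,expected",
        [
            (pat(30, 5, 9, 20), (4 + 4 + 11) / 3),
            (pat(30, 5), None),
            (pat(30, 5, 6), 1.0),
        ],
    )
    def test_mean_min_distance(self, pattern, expected):
        got = mean_min_branch_distance(pattern)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)

    def test_aiz_plus_deepest_branch_is_length(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            L = int(rng.integers(5, 40))
            k = int(rng.integers(1, 5))
            pos = tuple(sorted(rng.choice(L, size=min(k, L), replace=False) + 1))
            p = pat(L, *pos)
            assert aiz_size(p) + max(pos) == L


class TestDatasetDescriptors:
    def test_adjacent_fraction(self):
        ds = PatternDataset([pat(30, 3, 4), pat(30, 5, 9), pat(30)])
        frac, count = adjacent_branch_fraction(ds)
        assert (frac, count) == (pytest.approx(1 / 3), 1)
        none = PatternDataset([pat(30), pat(25)])
        assert adjacent_branch_fraction(none) == (0.0, 0)

    def test_basal_proportion(self):
        ds = PatternDataset([pat(30, 2), pat(30, 7), pat(30, 1, 3)])
        assert basal_branch_proportion(ds, depth=5) == pytest.approx(2 / 3)
        assert basal_branch_proportion(ds, depth=0) == 0.0

    def test_position_distribution_degenerate(self):
        ds = PatternDataset([pat(20, 1), pat(30, 1)])
        freqs = position_distribution(ds)
        assert freqs["freq_base"].iloc[0] == 1.0
        assert (freqs["freq_base"].iloc[1:] == 0.0).all()
        # conditioning: positions 21..30 eligible in one gametophore only
        assert freqs["n_eligible"].iloc[25] == 1

    def test_position_distribution_flat_for_stochastic_null(self):
        ds = stochastic_dataset(
            NullModelParams(p=0.05, length_range=(30, 30)), n=8000, seed=4
        )
        freqs = position_distribution(ds)
        se = np.sqrt(0.05 * 0.95 / 8000)
        assert (np.abs(freqs["freq_base"] - 0.05) < 4 * se).all()

    def test_statistics_invariant_under_reordering(self):
        ds = PatternDataset([pat(30, 4, 9), pat(22, 5), pat(35, 2, 3, 20)])
        rev = PatternDataset(list(ds)[::-1])
        assert summarize(ds) == summarize(rev)

    def test_summarize_single_branch_free_gametophore(self):
        s = summarize(PatternDataset([pat(25)]))
        assert s.mean_branch_number == 0.0
        assert s.mean_aiz is None and s.mean_min_distance is None
        assert s.as_row()["mean_aiz"] == "n.d."

    def test_summarize_matches_hand_computation(self):
        ds = PatternDataset([pat(30, 5, 9, 20), pat(25, 10), pat(28)])
        s = summarize(ds)
        assert s.mean_branch_number == pytest.approx((3 + 1 + 0) / 3)
        assert s.mean_aiz == pytest.approx((10 + 15) / 2)
        assert s.n_min_distance == 1
        assert s.mean_min_distance == pytest.approx(19 / 3)


class TestBruteForceOracle:
    """Every statistic recomputed by exhaustive enumeration on tiny datasets."""

    def _brute(self, ds):
        aiz, dists, adj, basal = [], [], 0, 0
        for p in ds:
            pos = p.branch_positions
            if pos:
                aiz.append(p.L - sorted(pos)[-1])
                if min(pos) <= 5:
                    basal += 1
            if len(pos) >= 2:
                per_branch = []
                for a in pos:
                    per_branch.append(min(abs(a - b) for b in pos if b != a))
                dists.append(sum(per_branch) / len(per_branch))
            if any(b - a == 1 for a, b in itertools.combinations(sorted(pos), 2)):
                adj += 1
        return aiz, dists, adj, basal

    def test_all_statistics_match_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            pats = []
            for _ in range(int(rng.integers(1, 6))):
                L = int(rng.integers(6, 40))
                k = int(rng.integers(0, 5))
                pos = tuple(rng.choice(L, size=min(k, L), replace=False) + 1)
                pats.append(pat(L, *pos))
            ds = PatternDataset(pats)
            aiz, dists, adj, basal = self._brute(ds)
            s = summarize(ds)
            if aiz:
                assert s.mean_aiz == pytest.approx(np.mean(aiz))
            else:
                assert s.mean_aiz is None
            if dists:
                assert s.mean_min_distance == pytest.approx(np.mean(dists))
            else:
                assert s.mean_min_distance is None
            assert s.adjacent_count == adj
            assert s.basal_proportion == pytest.approx(basal / len(ds))


class TestPolynomialFit:
    def test_nested_polynomial_recovered(self):
        x = np.arange(1, 31, dtype=float)
        y = 0.02 + 0.003 * x - 0.0001 * x**2
        fit = fit_position_polynomial(y, degree=7)
        assert np.allclose(fit.fitted, y, atol=1e-10)

    def test_constant_frequencies(self):
        fit = fit_position_polynomial(np.full(20, 0.25), degree=3)
        assert fit.coefficients[0] == pytest.approx(0.25, abs=1e-9)
        assert np.allclose(fit.coefficients[1:], 0.0, atol=1e-9)

    def test_underdetermined_fit_rejected(self):
        with pytest.raises(ValueError):
            fit_position_polynomial(np.ones(5), degree=7)


class TestRegression:
    def test_noiseless_common_model_keeps_only_intercept_and_slope(self):
        table, _ = generate_regression_fixture(
            2.0, 0.0, 0.2, 0.0, noise_sd=0.0, n_per_group=40, seed=1
        )
        # keep B = 2 + 0.2 L integral so branch counts represent it exactly
        table["L"] = (table["L"] // 5) * 5
        table["B"] = 2.0 + 0.2 * table["L"]
        a, b = table_as_datasets(table)
        res = fit_branch_length_model(a, b)
        assert set(res.terms) == {"a0", "a2"}
        assert res.coefficient("a0") == pytest.approx(2.0, abs=1e-8)
        assert res.coefficient("a2") == pytest.approx(0.2, abs=1e-8)
        assert not res.groups_differ

    def test_group_shift_detected_and_recovered(self):
        table, _ = generate_regression_fixture(
            2.0, 3.0, 0.2, 0.0, noise_sd=0.5, n_per_group=200, seed=2
        )
        a, b = table_as_datasets(table)
        res = fit_branch_length_model(a, b)
        assert res.groups_differ
        assert "a1" in res.terms and "a3" not in res.terms
        assert res.coefficient("a1") == pytest.approx(3.0, abs=0.5)

    def test_interaction_hierarchy_respected(self):
        table, _ = generate_regression_fixture(
            -4.45, 2.52, 0.2, -0.12, noise_sd=0.3, n_per_group=500, seed=3
        )
        a, b = table_as_datasets(table)
        res = fit_branch_length_model(a, b)
        assert res.groups_differ
        assert "a3" in res.terms
        for t in res.elimination_order:
            assert t != "a1" or "a3" in res.elimination_order[: res.elimination_order.index(t)]

    def test_degenerate_design_rejected(self):
        a = PatternDataset([pat(30, 5), pat(30, 6, 9)])
        b = PatternDataset([pat(30), pat(30, 2)])
        with pytest.raises(ValueError):
            fit_branch_length_model(a, b)


def test_pooled_distance_variant():
    ds = PatternDataset([pat(30, 5, 9, 20), pat(25, 3, 4)])
    # pooled: distances 4,4,11 and 1,1 -> mean 21/5
    assert pooled_min_branch_distance(ds) == pytest.approx(21 / 5)
    assert pooled_min_branch_distance(PatternDataset([pat(10, 2)])) is None
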