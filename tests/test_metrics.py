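"""Interaction metrics: importance, range statistics, strengths, γ, decay fits."""

import numpy as np
import pandas as pd
import pytest

import walklrp as w
from walklrp.lrp import RuleConfig, WalkRelevanceMap
from walklrp.metrics import ImportanceDistribution


def _map_on(conformer, walks, relevances, depth=1, y=None):
    rel = np.asarray(relevances, float)
    return WalkRelevanceMap(
        walks=list(walks),
        relevances=rel,
        y=float(rel.sum()) if y is None else y,
        depth=depth,
        rule=RuleConfig(),
        conformer=conformer,
    )


@pytest.fixture()
def tri():
    return w.Conformer(["C"] * 3, [[0, 0, 0], [0, 0, 1.5], [0, 0, 3.0]])


class TestWalkImportance:
    def test_single_walk_probability_one(self, tri):
        dist = w.walk_importance(_map_on(tri, [(0, 1)], [-2.5]))
        assert dist.p.tolist() == [1.0]

    def test_equal_absolute_relevances_uniform(self, tri):
        dist = w.walk_importance(
            _map_on(tri, [(0, 0), (0, 1), (1, 0), (1, 1)], [0.5, -0.5, 0.5, -0.5])
        )
        assert np.allclose(dist.p, 0.25)

    def test_normalisation_tight(self, trained6, cluster6_data):
        rmap = w.walk_relevances(trained6.params_, trained6.config_, cluster6_data[2])
        dist = w.walk_importance(rmap)
        assert abs(dist.p.sum() - 1.0) < 1e-12
        assert np.all((dist.p >= 0) & (dist.p <= 1))

    def test_all_zero_relevances_rejected(self, tri):
        with pytest.raises(w.ZeroRelevanceError):
            w.walk_importance(_map_on(tri, [(0, 1)], [0.0], y=0.0))


class TestInteractionRange:
    def _two_walk_dist(self):
        pos = np.array([[0, 0, 0], [0, 0, 1.0], [0, 0, 8.0]])
        conf = w.Conformer(["C"] * 3, pos)
        return ImportanceDistribution(
            walks=[(0, 1), (0, 2)],
            p=np.array([0.9995, 0.0005]),
            extents=np.array([1.0, 8.0]),
            conformer=conf,
        )

    def test_threshold_range_follows_p_min(self):
        dist = self._two_walk_dist()
        assert w.interaction_range(dist, "threshold", p_min=0.001) == 1.0
        assert w.interaction_range(dist, "threshold", p_min=0.0001) == 8.0

    def test_threshold_zero_p_min_rejected(self):
        with pytest.raises(ValueError, match="p_min"):
            w.interaction_range(self._two_walk_dist(), "threshold", p_min=0.0)

    def test_no_qualifying_walk_warns_and_returns_zero(self):
        dist = self._two_walk_dist()
        with pytest.warns(UserWarning, match="range reported as 0"):
            assert w.interaction_range(dist, "threshold", p_min=1.1) == 0.0

    def _even_pair(self):
        conf = w.Conformer(["C"] * 2, [[0, 0, 0], [0, 0, 1.0]])
        return ImportanceDistribution(
            walks=[(0, 0), (0, 1)],
            p=np.array([0.5, 0.5]),
            extents=np.array([1.0, 3.0]),
            conformer=conf,
        )

    def test_power_range_expected_distance_and_a4(self):
        dist = self._even_pair()
        assert w.interaction_range(dist, "power", a=1.0) == pytest.approx(2.0)
        expected = (0.5 * 1.0 + 0.5 * 81.0) ** 0.25
        assert w.interaction_range(dist, "power", a=4.0) == pytest.approx(expected)

    def test_power_range_approaches_max_from_below(self):
        dist = self._even_pair()
        big = w.interaction_range(dist, "power", a=64.0)
        assert 2.95 < big < 3.0

    def test_power_range_monotone_in_a(self):
        dist = self._even_pair()
        vals = [w.interaction_range(dist, "power", a=a) for a in (1, 2, 4, 8, 16)]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_threshold_nonincreasing_in_p_min(self, trained6, cluster6_data):
        dist = w.walk_importance(
            w.walk_relevances(trained6.params_, trained6.config_, cluster6_data[3])
        )
        vals = [
            w.interaction_range(dist, "threshold", p_min=p)
            for p in (1e-5, 1e-4, 1e-3, 1e-2)
        ]
        assert all(x >= y for x, y in zip(vals, vals[1:]))

    def test_invalid_power_parameter(self):
        with pytest.raises(ValueError, match="a must be"):
            w.interaction_range(self._even_pair(), "power", a=0.0)


class TestPairStrength:
    def test_hand_set_map_arithmetic(self, tri):
        rmap = _map_on(
            tri, [(0, 0), (0, 1), (1, 1), (0, 2)], [0.2, 0.3, 0.1, 0.4], y=1.0
        )
        table = w.pair_interaction_strength(rmap, mode="inclusive")
        s = {(r.i, r.j): r.strength for r in table.itertuples()}
        assert s[(0, 1)] == pytest.approx(0.3)
        assert s[(0, 2)] == pytest.approx(0.4)
        assert s[(1, 2)] == 0.0

    def test_two_atom_inclusive_equals_exclusive(self):
        conf = w.Conformer(["C", "C"], [[0, 0, 0], [0, 0, 1.2]])
        rmap = _map_on(conf, [(0, 1), (1, 0), (0, 0)], [0.25, 0.25, 0.5], y=1.0)
        inc = w.pair_interaction_strength(rmap, "inclusive")
        exc = w.pair_interaction_strength(rmap, "exclusive")
        assert inc["strength"].iloc[0] == exc["strength"].iloc[0] == pytest.approx(0.5)

    def test_inclusive_dominates_exclusive(self, trained6, cluster6_data):
        rmap = w.walk_relevances(trained6.params_, trained6.config_, cluster6_data[4])
        inc = w.pair_interaction_strength(rmap, "inclusive")
        exc = w.pair_interaction_strength(rmap, "exclusive")
        assert np.all(
            inc["strength"].to_numpy() >= exc["strength"].to_numpy() - 1e-15
        )

    def test_self_strength_counts_single_atom_walks(self, tri):
        rmap = _map_on(tri, [(0, 0), (0, 1)], [0.5, 0.5], y=1.0)
        assert w.self_strength(rmap, 0) == pytest.approx(0.5)
        assert w.self_strength(rmap, 2) == 0.0


class TestElementPairMatrix:
    def test_single_pair_log10(self):
        table = pd.DataFrame(
            dict(i=[0], j=[1], elem_i=["H"], elem_j=["H"], distance=[0.8],
                 mode=["inclusive"], strength=[0.01])
        )
        mats = w.element_pair_matrix(table)
        assert mats.split == 1.6
        assert mats.bonded.loc["H", "H"] == pytest.approx(-2.0)
        assert np.isnan(mats.nonbonded.loc["H", "H"])

    def test_symmetric_under_element_swap(self):
        table = pd.DataFrame(
            dict(i=[0, 1], j=[2, 3], elem_i=["C", "H"], elem_j=["H", "C"],
                 distance=[2.0, 2.4], mode=["inclusive"] * 2, strength=[0.1, 0.001])
        )
        mats = w.element_pair_matrix(table)
        assert mats.nonbonded.loc["C", "H"] == mats.nonbonded.loc["H", "C"]
        assert mats.nonbonded.loc["C", "H"] == pytest.approx((-1 - 3) / 2)

    def test_nonpositive_strengths_counted_not_logged(self):
        table = pd.DataFrame(
            dict(i=[0, 0], j=[1, 2], elem_i=["C", "C"], elem_j=["C", "C"],
                 distance=[1.0, 1.0], mode=["inclusive"] * 2, strength=[0.1, 0.0])
        )
        mats = w.element_pair_matrix(table)
        assert mats.n_nonpositive == 1
        assert mats.bonded.loc["C", "C"] == pytest.approx(-1.0)


class TestManyBodyness:
    @staticmethod
    def _bin_table(strengths, distance=2.0):
        n = len(strengths)
        return pd.DataFrame(
            dict(i=range(n), j=range(1, n + 1), elem_i=["C"] * n, elem_j=["C"] * n,
                 distance=[distance] * n, mode=["inclusive"] * n, strength=strengths)
        )

    def test_equal_strengths_zero_gamma(self):
        prof = w.many_bodyness(self._bin_table([0.3] * 25), min_count=10)
        assert prof.gamma_bar == 0.0

    def test_factor_ten_gives_unit_gamma(self):
        prof = w.many_bodyness(self._bin_table([1.0] * 9 + [10.0]), min_count=5)
        assert prof.gamma_bar == pytest.approx(1.0)

    def test_factor_hundred_gives_two(self):
        prof = w.many_bodyness(self._bin_table([1.0] * 9 + [100.0]), min_count=5)
        assert prof.gamma_bar == pytest.approx(2.0)

    def test_gamma_invariant_under_scaling(self):
        base = [0.2, 0.5, 1.0, 2.0, 4.0] * 5
        p1 = w.many_bodyness(self._bin_table(base), min_count=10)
        p2 = w.many_bodyness(self._bin_table([s * 37.5 for s in base]), min_count=10)
        assert p1.gamma_bar == pytest.approx(p2.gamma_bar, rel=1e-12)

    def test_small_bins_dropped_and_counted(self):
        table = pd.concat(
            [self._bin_table([1.0] * 30, 2.0), self._bin_table([1.0] * 3, 4.0)],
            ignore_index=True,
        )
        prof = w.many_bodyness(table, bin_width=0.5, min_count=20)
        assert prof.dropped_bins == 1
        assert len(prof.table) == 1

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError, match="empty"):
            w.many_bodyness(self._bin_table([0.0] * 5), min_count=1)


class TestDecayFit:
    @staticmethod
    def _samples(fn, rng, n=4000, lo=1.0, hi=8.0):
        r = rng.uniform(lo, hi, n)
        s = fn(r) * (1.0 + 0.01 * rng.normal(size=n))
        return r, s

    def test_exponential_recovered(self):
        rng = np.random.default_rng(1)
        r, s = self._samples(lambda r: 3.0 * np.exp(-1.7 * r), rng)
        fit = w.decay_fit(distances=r, strengths=s, bin_width=0.5)
        assert fit.preferred == "exponential"
        assert fit.exp_rate == pytest.approx(1.7, rel=0.05)

    def test_power_law_recovered(self):
        rng = np.random.default_rng(2)
        r, s = self._samples(lambda r: r ** -6.0, rng)
        fit = w.decay_fit(distances=r, strengths=s, bin_width=0.5)
        assert fit.preferred == "power"
        assert fit.pow_exponent == pytest.approx(-6.0, abs=0.3)

    def test_constant_profile_flagged_degenerate(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(1, 8, 500)
        fit = w.decay_fit(distances=r, strengths=np.full(500, 2.0), bin_width=0.5)
        assert fit.degenerate

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="5 occupied"):
            w.decay_fit(
                distances=np.array([1.0] * 10), strengths=np.ones(10), bin_width=0.5
            )
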