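import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from sdbsound.biomarker_selection import (
    DiscriminatorSets,
    anova_screen,
    assemble_biomarker,
    load_reference_discriminators,
    one_way_anova,
    select_discriminators,
    svm_rank_features,
    tukey_pairwise,
)

GROUPS4 = np.repeat(["normal", "mild", "moderate", "severe"], 30)


def _table(data: dict) -> pd.DataFrame:
    return pd.DataFrame(data)


class TestAnova:
    def test_identical_groups(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = np.array(["normal"] * 3 + ["mild"] * 3)
        f_stat, p = one_way_anova(values, groups)
        assert f_stat == 0.0
        assert p == 1.0

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([np.zeros(4), np.full(4, 10.0)]) + 1e-6 * rng.standard_normal(8)
        groups = np.array(["normal"] * 4 + ["severe"] * 4)
        _, p = one_way_anova(values, groups)
        assert p < 1e-6

    def test_all_constant_convention(self):
        values = np.full(8, 3.0)
        groups = np.array(["normal"] * 4 + ["severe"] * 4)
        assert one_way_anova(values, groups) == (0.0, 1.0)

    def test_constant_within_separated_between(self):
        values = np.array([0.0] * 4 + [1.0] * 4)
        groups = np.array(["normal"] * 4 + ["severe"] * 4)
        f_stat, p = one_way_anova(values, groups)
        assert np.isinf(f_stat)
        assert p == 0.0

    def test_matches_scipy(self, rng):
        for _ in range(25):
            values = rng.standard_normal(120)
            f_mine, p_mine = one_way_anova(values, GROUPS4)
            f_ref, p_ref = f_oneway(*(values[GROUPS4 == g] for g in
                                      ("normal", "mild", "moderate", "severe")))
            assert f_mine == pytest.approx(f_ref, abs=1e-9)
            assert p_mine == pytest.approx(p_ref, abs=1e-9)

    def test_type_one_error_rate(self):
        # Monte-Carlo: fraction of null features passing at alpha=0.05
        rng = np.random.default_rng(42)
        passes = []
        for _ in range(10):
            table = _table({f"f{k}": rng.standard_normal(120) for k in range(100)})
            screen = anova_screen(table, GROUPS4, alpha=0.05)
            passes.append(screen["passed"].mean())
        assert np.mean(passes) == pytest.approx(0.05, abs=0.02)

    def test_needs_two_subjects_per_group(self):
        values = np.array([1.0, 2.0, 3.0])
        groups = np.array(["normal", "normal", "mild"])
        with pytest.raises(ValueError):
            one_way_anova(values, groups)


class TestTukey:
    def test_identical_groups_p_near_one(self):
        values = np.tile([1.0, 2.0, 3.0, 4.0], 4)
        groups = np.repeat(["normal", "mild", "moderate", "severe"], 4)
        out = tukey_pairwise(values, groups)
        assert np.all(out["p"] >= 0.999)

    def test_single_shifted_group(self):
        # fixed seed: null-pair p-values fluctuate, the planted contrast does not
        values = np.random.default_rng(1).standard_normal(120)
        values[GROUPS4 == "severe"] += 10.0  # 10 pooled SDs
        out = tukey_pairwise(values, GROUPS4)
        severe = (out["group1"] == "severe") | (out["group2"] == "severe")
        assert np.all(out.loc[severe, "p"] < 1e-4)
        assert np.all(out.loc[~severe, "p"] > 0.9)

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            values = rng.standard_normal(120)
            mine = tukey_pairwise(values, GROUPS4)
            ref = pairwise_tukeyhsd(values, GROUPS4)
            ref_pairs = {
                tuple(sorted((a, b))): p
                for (a, b), p in zip(
                    [(ref.groupsunique[i], ref.groupsunique[j])
                     for i in range(4) for j in range(i + 1, 4)],
                    ref.pvalues,
                )
            }
            for row in mine.itertuples():
                key = tuple(sorted((row.group1, row.group2)))
                assert abs(row.p - ref_pairs[key]) < 1e-6

    def test_unequal_group_sizes_kramer(self):
        rng = np.random.default_rng(3)
        groups = np.array(["normal"] * 10 + ["mild"] * 20 + ["moderate"] * 30
                          + ["severe"] * 15)
        values = rng.standard_normal(groups.size)
        mine = tukey_pairwise(values, groups)
        ref = pairwise_tukeyhsd(values, groups)
        assert np.allclose(sorted(mine["p"]), sorted(ref.pvalues), atol=1e-6)

    def test_degenerate_variance_flagged(self):
        values = np.tile([5.0], 16)
        groups = np.repeat(["normal", "mild", "moderate", "severe"], 4)
        out = tukey_pairwise(values, groups)
        assert np.all(out["p"] == 1.0)

    def test_anova_f_consistent_with_tukey_pooled_variance(self, rng):
        # same pooled within-group variance underlies both routes
        values = rng.standard_normal(120)
        f_mine, _ = one_way_anova(values, GROUPS4)
        arrays = [values[GROUPS4 == g] for g in ("normal", "mild", "moderate", "severe")]
        msw = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (120 - 4)
        grand = values.mean()
        msb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays) / 3
        assert f_mine == pytest.approx(msb / msw, abs=1e-9)


class TestSelectDiscriminators:
    def _planted_table(self, rng, shift_group="normal", n_null=20):
        data = {}
        values = rng.standard_normal(120)
        values[GROUPS4 == shift_group] += 5.0
        data["planted"] = values
        for k in range(n_null):
            data[f"null{k}"] = rng.standard_normal(120)
        return _table(data)

    def test_planted_normal_shift_recovered(self, rng):
        table = self._planted_table(rng, "normal")
        sets = select_discriminators(table, GROUPS4)
        assert "planted" in sets["normal"]
        for g in ("mild", "moderate", "severe"):
            assert "planted" not in sets[g]

    def test_constant_feature_in_no_set(self, rng):
        table = self._planted_table(rng)
        table["flat"] = 1.0
        sets = select_discriminators(table, GROUPS4)
        for g in ("normal", "mild", "moderate", "severe"):
            assert "flat" not in sets[g]

    def test_monotone_far_apart_in_all_sets(self, rng):
        shifts = {"normal": 0.0, "mild": 10.0, "moderate": 20.0, "severe": 30.0}
        values = rng.standard_normal(120)
        for g, s in shifts.items():
            values[GROUPS4 == g] += s
        table = _table({"mono": values, "noise": rng.standard_normal(120)})
        sets = select_discriminators(table, GROUPS4)
        for g in shifts:
            assert "mono" in sets[g]

    def test_scale_invariance(self, rng):
        table = self._planted_table(rng)
        sets_a = select_discriminators(table, GROUPS4)
        scaled = table * 1e6 + 42.0  # monotone affine transform
        sets_b = select_discriminators(scaled, GROUPS4)
        assert sets_a.sets == sets_b.sets

    def test_requires_four_groups(self, rng):
        table = _table({"x": rng.standard_normal(60)})
        groups = np.repeat(["normal", "severe"], 30)
        with pytest.raises(ValueError):
            select_discriminators(table, groups)

    def test_null_discriminator_rate_below_half_alpha(self):
        rng = np.random.default_rng(11)
        counts, total = 0, 0
        for _ in range(5):
            table = _table({f"n{k}": rng.standard_normal(120) for k in range(200)})
            sets = select_discriminators(table, GROUPS4)
            counts += sets.total_entries()
            total += 4 * 200
        assert counts / total < 0.05 / 2


class TestBiomarker:
    def test_union_dedup(self):
        sets = DiscriminatorSets(sets={"normal": ["A", "B"], "mild": [],
                                       "moderate": ["B", "C"], "severe": []})
        assert assemble_biomarker(sets) == ["A", "B", "C"]

    def test_disjoint_sets(self):
        sets = DiscriminatorSets(sets={"normal": ["A", "B"], "mild": [],
                                       "moderate": ["C", "D", "E"], "severe": []})
        assert len(assemble_biomarker(sets)) == 5

    def test_empty_union_warns(self):
        with pytest.warns(UserWarning):
            assert assemble_biomarker(DiscriminatorSets()) == []


class TestReferenceFixture:
    def test_total_entries(self):
        fixture = load_reference_discriminators()
        assert len(fixture) == 132

    @pytest.mark.parametrize("group,count", [("normal", 62), ("moderate", 7),
                                             ("severe", 63)])
    def test_per_group_counts(self, group, count):
        fixture = load_reference_discriminators()
        assert (fixture["group"] == group).sum() == count

    def test_mild_set_empty(self):
        fixture = load_reference_discriminators()
        assert (fixture["group"] == "mild").sum() == 0

    def test_no_duplicate_entries_within_group(self):
        fixture = load_reference_discriminators()
        assert not fixture.duplicated(["group", "column"]).any()


class TestSVMRanking:
    def test_informative_features_top_ranked(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = np.repeat([0, 1], 30)
            data = {f"noise{k}": rng.standard_normal(60) for k in range(20)}
            data["info1"] = labels * 8.0 + rng.standard_normal(60)
            data["info2"] = labels * -6.0 + rng.standard_normal(60)
            _, top2 = svm_rank_features(_table(data), labels, top_k=2, seed=seed)
            if set(top2) == {"info1", "info2"}:
                hits += 1
        assert hits >= 18

    def test_top_k_all_is_identity(self, rng):
        table = _table({f"f{k}": rng.standard_normal(40) for k in range(5)})
        labels = np.repeat([0, 1], 20)
        ranking, top = svm_rank_features(table, labels, top_k=5)
        assert sorted(top) == sorted(table.columns)
        assert ranking == top

    def test_top_k_too_large_warns(self, rng):
        table = _table({f"f{k}": rng.standard_normal(40) for k in range(3)})
        labels = np.repeat([0, 1], 20)
        with pytest.warns(UserWarning):
            _, top = svm_rank_features(table, labels, top_k=10)
        assert len(top) == 3

    def test_duplicate_column_deterministic_tiebreak(self, rng):
        labels = np.repeat([0, 1], 20)
        base = rng.standard_normal(40)
        table = _table({"a": base, "b": base.copy(),
                        "info": labels * 5.0 + 0.1 * rng.standard_normal(40)})
        r1, _ = svm_rank_features(table, labels, top_k=3)
        r2, _ = svm_rank_features(table, labels, top_k=3)
        assert r1 == r2  # documented: ties broken by column order, reproducibly
        assert r1[0] == "info"
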