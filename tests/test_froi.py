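"""fROI selection, extraction, repeated-measures ANOVAs and validations."""

import numpy as np
import pandas as pd
import pytest

from froipipe.froi import (
    SearchSpace,
    SplitHalfError,
    define_froi,
    extract_froi_means,
    froi_threshold_sweep,
    localize_visual_responsive,
    resample_subsamples,
    rm_anova_2x2,
    rm_anova_oneway,
)
from froipipe.glm import BetaMap

SHAPE = (10, 8, 6)


def centered_affine(shape=SHAPE, voxel=1.0):
    aff = np.diag([voxel] * 3 + [1.0])
    aff[:3, 3] = -voxel * (np.array(shape) - 1) / 2.0
    return aff


def bmap(data, label="map", run=1):
    return BetaMap(np.asarray(data, dtype=float), centered_affine(), label, run)


@pytest.fixture()
def space():
    return SearchSpace("space", np.ones(SHAPE, dtype=bool), centered_affine())


class TestDefineFROI:
    def test_top_pct_arithmetic(self, space):
        rng = np.random.default_rng(0)
        pref = bmap(np.abs(rng.normal(size=SHAPE)) + 0.1)  # all voxels prefer
        targ = bmap(rng.normal(size=SHAPE))
        froi = define_froi(pref, targ, space, top_pct=10)
        for hemi, hmask in space.hemisphere_masks().items():
            n_pref = int(hmask.sum())
            assert froi.voxels[hemi].shape[0] == int(np.ceil(0.1 * n_pref))

    def test_top_100_selects_every_preference_voxel(self, space):
        rng = np.random.default_rng(1)
        pref = bmap(rng.normal(size=SHAPE))
        targ = bmap(rng.normal(size=SHAPE))
        froi = define_froi(pref, targ, space, top_pct=100)
        assert froi.size == int((pref.data > 0).sum())

    def test_matches_exhaustive_sort_oracle(self, space):
        rng = np.random.default_rng(2)
        pref = bmap(rng.normal(size=SHAPE))
        targ = bmap(rng.normal(size=SHAPE))
        froi = define_froi(pref, targ, space, top_pct=25)
        for hemi, hmask in space.hemisphere_masks().items():
            cand = [tuple(v) for v in np.argwhere(hmask & (pref.data > 0))]
            k = max(1, int(np.ceil(0.25 * len(cand))))
            oracle = set(sorted(cand, key=lambda v: -targ.data[v])[:k])
            got = {tuple(v) for v in froi.voxels[hemi]}
            # identical up to ties in the target contrast (none expected here)
            assert got == oracle

    def test_monotone_containment(self, space):
        rng = np.random.default_rng(3)
        pref = bmap(rng.normal(size=SHAPE))
        targ = bmap(rng.normal(size=SHAPE))
        prev: set = set()
        for pct in (5, 10, 25, 50, 100):
            cur = {
                (h, tuple(v))
                for h in ("left", "right")
                for v in define_froi(pref, targ, space, top_pct=pct).voxels[h]
            }
            assert prev <= cur
            prev = cur

    def test_strictly_positive_preference_required(self, space):
        pref = bmap(np.zeros(SHAPE))  # zero everywhere: no voxel qualifies
        targ = bmap(np.ones(SHAPE))
        with pytest.raises(ValueError, match="no preference voxels"):
            define_froi(pref, targ, space)

    def test_single_hemisphere_preference_warns(self, space):
        pref_data = np.zeros(SHAPE)
        pref_data[:4] = 1.0  # low-x half only -> left hemisphere (x world < 0)
        targ = bmap(np.ones(SHAPE))
        with pytest.warns(UserWarning, match="right"):
            froi = define_froi(bmap(pref_data), targ, space)
        assert froi.voxels["right"].shape[0] == 0
        assert froi.voxels["left"].shape[0] >= 1

    def test_invalid_pct(self, space):
        with pytest.raises(ValueError):
            define_froi(bmap(np.ones(SHAPE)), bmap(np.ones(SHAPE)), space, top_pct=0)


class TestExtract:
    def _froi(self, space):
        pref = bmap(np.ones(SHAPE), run=1)
        targ = bmap(np.ones(SHAPE), run=1)
        return define_froi(pref, targ, space, top_pct=100)

    def test_constant_map(self, space):
        froi = self._froi(space)
        means = extract_froi_means({"c": bmap(np.full(SHAPE, 3.25), run=2)}, froi)
        assert means["c"] == pytest.approx(3.25)

    def test_two_voxel_mean(self):
        mask = np.zeros(SHAPE, dtype=bool)
        mask[0, 0, 0] = mask[9, 7, 5] = True
        sp = SearchSpace("two", mask, centered_affine())
        froi = define_froi(bmap(np.ones(SHAPE), run=1), bmap(np.ones(SHAPE), run=1), sp, 100)
        data = np.zeros(SHAPE)
        data[0, 0, 0], data[9, 7, 5] = 1.0, 3.0
        assert extract_froi_means({"c": bmap(data, run=2)}, froi)["c"] == pytest.approx(2.0)

    def test_matches_explicit_loop_oracle(self, space):
        rng = np.random.default_rng(4)
        froi = self._froi(space)
        data = rng.normal(size=SHAPE)
        got = extract_froi_means({"c": bmap(data, run=2)}, froi)["c"]
        vals = [data[tuple(v)] for h in ("left", "right") for v in froi.voxels[h]]
        assert got == pytest.approx(sum(vals) / len(vals))

    def test_split_half_discipline_enforced(self, space):
        froi = self._froi(space)  # defined on run 1
        with pytest.raises(SplitHalfError):
            extract_froi_means({"c": bmap(np.ones(SHAPE), run=1)}, froi)

    def test_nan_voxels_excluded_with_warning(self, space):
        froi = self._froi(space)
        data = np.ones(SHAPE)
        data[0, 0, 0] = np.nan
        with pytest.warns(UserWarning, match="NaN"):
            means = extract_froi_means({"c": bmap(data, run=2)}, froi)
        assert means["c"] == pytest.approx(1.0)


class TestRMAnovaOneway:
    def test_identical_columns(self):
        Y = np.tile(np.random.default_rng(0).normal(size=(6, 1)), (1, 3))
        res = rm_anova_oneway(Y)
        assert res["F"] == 0.0 and res["p"] == 1.0

    def test_two_conditions_f_is_squared_paired_t(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        Y = rng.normal(size=(9, 2))
        res = rm_anova_oneway(Y)
        t, p = stats.ttest_rel(Y[:, 0], Y[:, 1])
        assert res["F"] == pytest.approx(t**2)
        assert res["p"] == pytest.approx(p)

    def test_matches_ss_oracle_and_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(8, 3))
        res = rm_anova_oneway(Y)
        # explicit sums-of-squares oracle
        grand = Y.mean()
        ss_cond = 8 * ((Y.mean(axis=0) - grand) ** 2).sum()
        ss_subj = 3 * ((Y.mean(axis=1) - grand) ** 2).sum()
        ss_err = ((Y - grand) ** 2).sum() - ss_cond - ss_subj
        assert res["F"] == pytest.approx((ss_cond / 2) / (ss_err / 14))
        long = (
            pd.DataFrame(Y, columns=list("abc"))
            .reset_index()
            .melt(id_vars="index", var_name="cond")
        )
        tab = pg.rm_anova(data=long, dv="value", within="cond", subject="index")
        assert res["F"] == pytest.approx(float(tab["F"][0]))
        assert res["p"] == pytest.approx(float(tab["p_unc"][0]))

    def test_pairwise_has_fdr_column(self):
        res = rm_anova_oneway(np.random.default_rng(3).normal(size=(6, 3)))
        assert set(res["pairwise"].columns) >= {"a", "b", "t", "p", "q"}
        assert len(res["pairwise"]) == 3

    def test_missing_cell_rejected(self):
        Y = np.random.default_rng(0).normal(size=(5, 3))
        Y[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_oneway(Y)


class TestRMAnova2x2:
    def test_all_identical_cells(self):
        Y = np.tile(np.random.default_rng(0).normal(size=(7, 1)), (1, 4))
        effects = rm_anova_2x2(Y)["effects"]
        assert np.all(effects["F"] == 0.0)

    def test_pure_interaction(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 1))
        d = 0.8
        # +d, -d, -d, +d pattern: interaction only
        Y = base + np.array([[d, -d, -d, d]])
        res = rm_anova_2x2(Y)["effects"].set_index("effect")
        assert res.loc["interaction", "F"] > 1e3
        assert res.loc["species", "F"] == pytest.approx(0.0, abs=1e-18)
        assert res.loc["category", "F"] == pytest.approx(0.0, abs=1e-18)

    def test_matches_pingouin_two_way_within(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(9, 4))
        res = rm_anova_2x2(Y)["effects"].set_index("effect")
        rows = []
        for s in range(9):
            for j, (sp, cat) in enumerate(
                [("c", "face"), ("c", "body"), ("h", "face"), ("h", "body")]
            ):
                rows.append({"subj": s, "species": sp, "cat": cat, "val": Y[s, j]})
        tab = pg.rm_anova(
            data=pd.DataFrame(rows), dv="val", within=["species", "cat"], subject="subj"
        ).set_index("Source")
        assert res.loc["species", "F"] == pytest.approx(float(tab.loc["species", "F"]))
        assert res.loc["category", "F"] == pytest.approx(float(tab.loc["cat", "F"]))
        assert res.loc["interaction", "F"] == pytest.approx(float(tab.loc["species * cat", "F"]))


class TestSweepAndResampling:
    def _maps(self, seed=0):
        rng = np.random.default_rng(seed)
        pref = bmap(rng.normal(size=SHAPE), "pref", run=1)
        targ = bmap(rng.normal(size=SHAPE), "targ", run=1)
        tests = {c: bmap(rng.normal(size=SHAPE), c, run=2) for c in ("x", "y")}
        return pref, targ, tests

    def test_grid_100_equals_whole_preference_mask(self, space):
        pref, targ, tests = self._maps()
        sweep = froi_threshold_sweep(pref, targ, tests, space, pct_grid=[100])
        froi = define_froi(pref, targ, space, top_pct=100)
        means = extract_froi_means(tests, froi)
        for cond in tests:
            row = sweep[(sweep["condition"] == cond)]
            assert row["value"].iloc[0] == pytest.approx(means[cond])

    def test_grid_10_identical_to_main_analysis(self, space):
        pref, targ, tests = self._maps(1)
        sweep = froi_threshold_sweep(pref, targ, tests, space, pct_grid=[10])
        main = extract_froi_means(tests, define_froi(pref, targ, space, top_pct=10))
        for cond in tests:
            assert sweep.loc[sweep["condition"] == cond, "value"].iloc[0] == pytest.approx(
                main[cond]
            )

    def test_default_grid_is_1_then_steps_of_5(self, space):
        pref, targ, tests = self._maps(2)
        sweep = froi_threshold_sweep(pref, targ, tests, space)
        assert sorted(sweep["top_pct"].unique()) == [1.0] + list(range(5, 101, 5))

    def test_resample_full_sample_is_degenerate(self):
        rng = np.random.default_rng(0)
        Y = pd.DataFrame(rng.normal(size=(10, 3)))
        out = resample_subsamples(Y, n_sub=10, n_iter=5, seed=1)
        assert out["F"].nunique() == 1  # same subject set every iteration

    def test_resample_power_with_planted_effect(self):
        rng = np.random.default_rng(1)
        n = 40
        Y = rng.normal(size=(n, 3))
        Y[:, 1] += 2.0  # Cohen's d = 2 for the middle condition
        out = resample_subsamples(pd.DataFrame(Y), n_sub=15, n_iter=200, seed=2)
        assert out["significant"].mean() >= 0.95

    def test_resample_rejects_oversized_subsample(self):
        with pytest.raises(ValueError):
            resample_subsamples(pd.DataFrame(np.zeros((5, 3))), n_sub=6, n_iter=1)


class TestLocalizer:
    def test_all_zero_maps_give_no_search_spaces(self):
        maps = np.zeros((5,) + SHAPE)
        atlas = {"a": np.ones(SHAPE, dtype=bool)}
        with pytest.warns(UserWarning, match="no cluster"):
            result, spaces = localize_visual_responsive(
                maps, atlas, n_perm=32, seed=0, affine=centered_affine()
            )
        assert spaces == [] and result.significant_clusters == []

    def test_planted_region_recovered_as_search_space(self):
        rng = np.random.default_rng(0)
        region = np.zeros(SHAPE, dtype=bool)
        region[2:7, 2:6, 1:5] = True
        maps = rng.normal(0, 1, size=(12,) + SHAPE)
        maps[:, region] += 5.0
        atlas = {"hit": region, "miss": ~region}
        result, spaces = localize_visual_responsive(
            maps, atlas, cdt_p=0.005, n_perm=500, seed=1, affine=centered_affine()
        )
        assert "hit" in [s.name for s in spaces]
        sig = np.zeros(SHAPE, dtype=bool)
        for c in result.significant_clusters:
            sig[tuple(c.voxels.T)] = True
        assert (sig & region).sum() / region.sum() >= 0.8
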