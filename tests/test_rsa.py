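"""Searchlight geometry and pattern-similarity maps."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest

from froipipe.rsa import (
    COMPARISONS,
    FISHER_R_CAP,
    SearchlightSpec,
    TrialPatternStack,
    searchlight_set_similarities,
    searchlight_similarity,
    similarity_contrast_pair,
    sphere_offsets,
    valid_centers,
)


class TestSphereOffsets:
    def test_dog_preset_81_voxels(self):
        assert sphere_offsets(4.0, 1.5).shape[0] == 81
        assert sphere_offsets(4.0, 1.5, "exclusive").shape[0] == 81  # no lattice point on boundary

    def test_human_preset_251_voxels_exclusive(self):
        assert sphere_offsets(8.0, 2.0, "exclusive").shape[0] == 251
        assert sphere_offsets(8.0, 2.0, "inclusive").shape[0] == 257  # boundary points exist

    def test_tiny_radius_center_only(self):
        offs = sphere_offsets(0.5, 1.0)
        assert offs.shape == (1, 3) and tuple(offs[0]) == (0, 0, 0)

    def test_symmetry_under_sign_flips_and_axis_permutations(self):
        offs = {tuple(o) for o in sphere_offsets(4.0, 1.5)}
        assert (0, 0, 0) in offs
        for o in list(offs):
            for signs in ([1, 1, -1], [1, -1, 1], [-1, 1, 1], [-1, -1, -1]):
                assert tuple(np.array(o) * signs) in offs
            for perm in permutations(o):
                assert perm in offs

    def test_matches_bounding_box_oracle(self):
        r, v = 6.0, 2.0
        got = sphere_offsets(r, v, "inclusive").shape[0]
        count = 0
        for x in range(-5, 6):
            for y in range(-5, 6):
                for z in range(-5, 6):
                    if (v * x) ** 2 + (v * y) ** 2 + (v * z) ** 2 <= r**2:
                        count += 1
        assert got == count

    def test_anisotropic_voxels(self):
        # 1.5 x 1.5 x 2 mm acquisition: fewer planes fit along z
        offs = sphere_offsets(4.0, (1.5, 1.5, 2.0))
        assert offs[:, 2].max() == 2
        assert offs.shape[0] < 81

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sphere_offsets(0.0, 1.0)
        with pytest.raises(ValueError):
            sphere_offsets(4.0, 1.0, "open")


class TestValidCenters:
    def test_interior_of_large_cube_valid(self):
        spec = SearchlightSpec(2.0, 1.0, 15)
        mask = np.ones((12, 12, 12), dtype=bool)
        valid = valid_centers(mask, spec)
        assert valid[6, 6, 6]
        # sphere has 33 voxels; deep interior always complete
        assert valid[3:9, 3:9, 3:9].all()

    def test_mask_smaller_than_threshold(self):
        spec = SearchlightSpec(10.0, 1.0, 15)
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:4, 2:4, 2:4] = True  # 8 voxels < 15 required
        assert not valid_centers(mask, spec).any()

    def test_matches_per_voxel_count_oracle(self):
        rng = np.random.default_rng(0)
        spec = SearchlightSpec(2.0, 1.0, 10)
        mask = rng.random((9, 9, 7)) > 0.35
        valid = valid_centers(mask, spec)
        offs = spec.offsets
        for c in np.argwhere(mask):
            coords = c + offs
            ok = np.all((coords >= 0) & (coords < mask.shape), axis=1)
            n_in = int(mask[tuple(coords[ok].T)].sum())
            assert valid[tuple(c)] == (n_in >= 10)


def make_stack(betas, conditions, mask=None, runs=None):
    betas = np.asarray(betas, dtype=float)
    if mask is None:
        mask = np.ones(betas.shape[1:], dtype=bool)
    labels = pd.DataFrame(
        {
            "condition": conditions,
            "run": runs if runs is not None else [1] * len(conditions),
            "block_index": range(len(conditions)),
        }
    )
    return TrialPatternStack(betas, labels, mask, np.eye(4))


class TestSearchlightSimilarity:
    def test_identical_patterns_hit_fisher_cap(self):
        rng = np.random.default_rng(0)
        pat = rng.normal(size=(5, 5, 3))
        stack = make_stack([pat, pat], ["a", "a"])
        spec = SearchlightSpec(1.5, 1.0, 2)
        smap = searchlight_similarity(stack, spec, ["a"])
        valid = np.isfinite(smap.data)
        assert valid.any()
        assert np.allclose(smap.data[valid], np.arctanh(FISHER_R_CAP))

    def test_orthogonal_patterns_give_zero(self):
        a = np.zeros((4, 4, 2))
        b = np.zeros((4, 4, 2))
        # exactly anticorrelated halves -> r = 0 needs orthogonal, use sign patterns
        a[::2] = 1.0
        a[1::2] = -1.0
        b[:, ::2] = 1.0
        b[:, 1::2] = -1.0
        stack = make_stack([a, b], ["a", "a"])
        spec = SearchlightSpec(10.0, 1.0, 2)  # one sphere covering everything
        smap = searchlight_similarity(stack, spec, ["a"])
        center = tuple(np.array(a.shape) // 2)
        assert smap.data[center] == pytest.approx(0.0, abs=1e-12)

    def test_single_sphere_matches_flat_loop_oracle(self):
        rng = np.random.default_rng(1)
        betas = rng.normal(size=(6, 3, 3, 3))
        stack = make_stack(betas, ["a"] * 6)
        spec = SearchlightSpec(5.0, 1.0, 2)
        smap = searchlight_similarity(stack, spec, ["a"])
        center = (1, 1, 1)
        flat = betas.reshape(6, -1)
        zs = []
        for i, j in combinations(range(6), 2):
            r = np.corrcoef(flat[i], flat[j])[0, 1]
            zs.append(np.arctanh(np.clip(r, -FISHER_R_CAP, FISHER_R_CAP)))
        assert smap.data[center] == pytest.approx(np.mean(zs), abs=1e-12)

    def test_full_map_matches_triple_loop_oracle(self):
        """10 x 10 x 6 grid, 36 random trials, naive per-center recount."""
        rng = np.random.default_rng(2)
        shape = (10, 10, 6)
        betas = rng.normal(size=(36,) + shape)
        conds = [c for c in ("a", "b", "c", "d", "e", "f") for _ in range(6)]
        mask = rng.random(shape) > 0.15
        stack = make_stack(betas, conds, mask=mask)
        spec = SearchlightSpec(2.0, 1.0, 5)
        trials = [i for i, c in enumerate(conds) if c in ("a", "b")]
        smap = searchlight_similarity(stack, spec, ["a", "b"])
        offs = spec.offsets
        flat = betas.reshape(36, -1)
        maskf = mask.ravel()
        naive = np.full(shape, np.nan)
        for cx in range(shape[0]):
            for cy in range(shape[1]):
                for cz in range(shape[2]):
                    if not mask[cx, cy, cz]:
                        continue
                    coords = np.array([cx, cy, cz]) + offs
                    ok = np.all((coords >= 0) & (coords < shape), axis=1)
                    ix = np.ravel_multi_index(coords[ok].T, shape)
                    ix = ix[maskf[ix]]
                    if ix.size < spec.min_gray_voxels:
                        continue
                    zs = []
                    for i, j in combinations(trials, 2):
                        r = np.corrcoef(flat[i, ix], flat[j, ix])[0, 1]
                        zs.append(np.arctanh(np.clip(r, -FISHER_R_CAP, FISHER_R_CAP)))
                    naive[cx, cy, cz] = np.mean(zs)
        assert np.array_equal(np.isnan(smap.data), np.isnan(naive))
        assert np.nanmax(np.abs(smap.data - naive)) < 1e-10

    def test_invariance_to_trial_order_and_global_rescaling(self):
        rng = np.random.default_rng(3)
        betas = rng.normal(size=(8, 6, 6, 4))
        stack = make_stack(betas, ["a"] * 8)
        spec = SearchlightSpec(2.0, 1.0, 5)
        ref = searchlight_similarity(stack, spec, ["a"]).data
        perm = rng.permutation(8)
        shuffled = make_stack(betas[perm], ["a"] * 8)
        scaled = make_stack(3.5 * betas + 1.0, ["a"] * 8)
        assert np.allclose(
            ref, searchlight_similarity(shuffled, spec, ["a"]).data, equal_nan=True
        )
        assert np.allclose(
            ref, searchlight_similarity(scaled, spec, ["a"]).data, atol=1e-10, equal_nan=True
        )

    def test_zero_variance_trial_pairs_skipped(self):
        rng = np.random.default_rng(4)
        flatpat = rng.normal(size=(4, 4, 2))
        constant = np.ones((4, 4, 2))
        stack = make_stack([flatpat, constant, rng.normal(size=(4, 4, 2))], ["a"] * 3)
        spec = SearchlightSpec(10.0, 1.0, 2)
        smap = searchlight_similarity(stack, spec, ["a"])
        center = (2, 2, 1)
        # only the pair of the two varying trials contributes
        r = np.corrcoef(flatpat.ravel(), stack.betas[2].ravel())[0, 1]
        assert smap.data[center] == pytest.approx(np.arctanh(r), abs=1e-10)


class TestComparisons:
    def _stack(self, seed=0):
        rng = np.random.default_rng(seed)
        conds = [c for c in ("dog_face", "human_face", "dog_body", "human_body", "object", "scrambled") for _ in range(6)]
        runs = [1, 1, 1, 2, 2, 2] * 6
        betas = rng.normal(size=(36, 6, 6, 4))
        return make_stack(betas, conds, runs=runs)

    def test_unknown_comparison_id(self):
        with pytest.raises(KeyError):
            similarity_contrast_pair(self._stack(), SearchlightSpec(2.0, 1.0, 5), "z")

    def test_pooled_faces_set_has_66_pairs(self):
        a, _ = similarity_contrast_pair(self._stack(), SearchlightSpec(2.0, 1.0, 5), "a")
        assert a.n_pairs == 66  # C(12, 2)

    def test_within_species_switch_drops_cross_species_pairs(self):
        stack = self._stack()
        spec = SearchlightSpec(2.0, 1.0, 5)
        sets = {"faces": ["dog_face", "human_face"]}
        pooled = searchlight_set_similarities(stack, spec, sets)["faces"]
        within = searchlight_set_similarities(
            stack, spec, sets, within_species_pairs_only=True
        )["faces"]
        assert pooled.n_pairs == 66
        assert within.n_pairs == 30  # 2 x C(6, 2)

    def test_identical_planted_species_patterns_cancel_in_e(self):
        rng = np.random.default_rng(5)
        shape = (6, 6, 4)
        pattern = rng.normal(size=shape)
        betas = []
        conds = []
        for c in ("dog_face", "human_face"):
            for _ in range(6):
                betas.append(pattern + 0.05 * rng.normal(size=shape))
                conds.append(c)
        stack = make_stack(np.array(betas), conds)
        a, b = similarity_contrast_pair(stack, SearchlightSpec(2.0, 1.0, 5), "e")
        valid = np.isfinite(a.data) & np.isfinite(b.data)
        assert valid.any()
        # same generative pattern for both species: difference ~ 0
        assert np.abs(a.data[valid] - b.data[valid]).mean() < 0.2

    def test_registry_covers_all_six_contrasts(self):
        assert sorted(COMPARISONS) == list("abcdef")
        faces, objects = COMPARISONS["a"]
        assert set(faces) == {"dog_face", "human_face"} and objects == ("object",)


def test_planted_animate_pattern_elevates_contrast_c():
    """A shared multivoxel pattern across animate trials, absent for
    objects, must raise animate-set similarity above object-set
    similarity inside the planted region."""
    rng = np.random.default_rng(6)
    shape = (8, 8, 5)
    region = np.zeros(shape, dtype=bool)
    region[2:6, 2:6, 1:4] = True
    shared = np.zeros(shape)
    shared[region] = rng.normal(0, 1.5, region.sum())
    betas, conds = [], []
    for c in ("dog_face", "human_face", "dog_body", "human_body", "object", "scrambled"):
        for _ in range(6):
            base = rng.normal(0, 1.0, shape)
            if c not in ("object", "scrambled"):
                base = base + shared
            betas.append(base)
            conds.append(c)
    stack = make_stack(np.array(betas), conds)
    a, b = similarity_contrast_pair(stack, SearchlightSpec(2.0, 1.0, 5), "c")
    diff = a.data - b.data
    inner = region.copy()
    assert np.nanmean(diff[inner]) > 0.2
    assert np.nanmean(diff[inner]) > np.nanmean(diff[~inner]) + 0.1
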