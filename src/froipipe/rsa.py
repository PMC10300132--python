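"""Whole-brain searchlight representational similarity analysis.

Per-block (single-trial) beta patterns are compared within a spherical
searchlight moved over a gray-matter mask: every unordered pair of
trials in a category set is Pearson-correlated over the sphere's voxels,
correlations are Fisher z-transformed, and the mean z is assigned to the
sphere's center voxel.  Six similarity contrasts (faces, bodies or all
animate images versus inanimate objects; faces versus bodies; and
conspecific versus heterospecific faces or bodies) pair two such maps
per participant for group-level sign-flip inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .glm import BetaMap
from .synthdata import CONDITIONS, SPECIES_OF

__all__ = [
    "SearchlightSpec",
    "DOG_SEARCHLIGHT",
    "HUMAN_SEARCHLIGHT",
    "TrialPatternStack",
    "SimilarityMap",
    "COMPARISONS",
    "sphere_offsets",
    "valid_centers",
    "searchlight_similarity",
    "searchlight_set_similarities",
    "similarity_contrast_pair",
    "write_similarity_map",
]

#: |r| is capped here before atanh so identical patterns stay finite.
FISHER_R_CAP = 1.0 - 1e-6


def sphere_offsets(
    radius_mm: float,
    voxel_mm: float | Sequence[float],
    boundary: str = "inclusive",
) -> np.ndarray:
    """Integer voxel offsets whose mm distance from the center is within radius.

    ``boundary`` decides whether lattice points exactly on the sphere
    surface count ("inclusive": distance <= r) or not ("exclusive":
    distance < r).  Anisotropic voxels are supported via a per-axis size.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    v = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    if (v <= 0).any():
        raise ValueError("voxel sizes must be positive")
    if boundary not in ("inclusive", "exclusive"):
        raise ValueError("boundary must be 'inclusive' or 'exclusive'")
    half = np.floor(radius_mm / v).astype(int)
    axes = [np.arange(-h, h + 1) for h in half]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    d = np.sqrt((v[0] * X) ** 2 + (v[1] * Y) ** 2 + (v[2] * Z) ** 2)
    keep = d <= radius_mm if boundary == "inclusive" else d < radius_mm
    offs = np.column_stack([X[keep], Y[keep], Z[keep]])
    return offs[np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0]))]


@dataclass
class SearchlightSpec:
    radius_mm: float
    voxel_mm: float | tuple[float, float, float]
    min_gray_voxels: int
    boundary: str = "inclusive"
    _offsets: np.ndarray | None = field(default=None, repr=False)

    @property
    def offsets(self) -> np.ndarray:
        if self._offsets is None:
            self._offsets = sphere_offsets(self.radius_mm, self.voxel_mm, self.boundary)
        return self._offsets

    @property
    def n_voxels(self) -> int:
        return self.offsets.shape[0]


#: Dog preset: r = 4 mm on the 1.5 mm resliced grid (81-voxel sphere),
#: at least 15 gray-matter voxels per searchlight.
DOG_SEARCHLIGHT = SearchlightSpec(4.0, 1.5, 15, "inclusive")

#: Human preset: r = 8 mm counted on a 2 mm grid with an exclusive
#: boundary (251-voxel sphere), at least 30 gray-matter voxels.
HUMAN_SEARCHLIGHT = SearchlightSpec(8.0, 2.0, 30, "exclusive")


@dataclass
class TrialPatternStack:
    """Per-trial beta maps with labels and the gray-matter mask."""

    betas: np.ndarray  # (n_trials, x, y, z)
    labels: pd.DataFrame  # columns: condition, run, block_index
    mask: np.ndarray  # 3D bool gray-matter mask
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.betas.ndim != 4:
            raise ValueError("betas must be (n_trials, x, y, z)")
        if len(self.labels) != self.betas.shape[0]:
            raise ValueError("labels and betas disagree on trial count")
        for col in ("condition", "run", "block_index"):
            if col not in self.labels.columns:
                raise ValueError(f"labels table lacks '{col}'")

    @classmethod
    def from_beta_maps(cls, maps: Sequence[BetaMap], mask: np.ndarray) -> "TrialPatternStack":
        labels = pd.DataFrame(
            {
                "condition": [m.extra.get("condition", m.label) for m in maps],
                "run": [m.run for m in maps],
                "block_index": [m.extra.get("block_index", i) for i, m in enumerate(maps)],
            }
        )
        return cls(np.stack([m.data for m in maps]), labels, mask, maps[0].affine)

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    def trials_of(self, conditions: Sequence[str]) -> np.ndarray:
        return np.flatnonzero(self.labels["condition"].isin(list(conditions)).to_numpy())


@dataclass
class SimilarityMap:
    """Mean Fisher-z similarity per valid searchlight center (NaN elsewhere)."""

    data: np.ndarray
    affine: np.ndarray
    label: str
    participant: str | None = None
    n_pairs: int = 0


def valid_centers(mask: np.ndarray, spec: SearchlightSpec) -> np.ndarray:
    """In-mask voxels whose sphere covers at least ``min_gray_voxels`` mask voxels."""
    from scipy import ndimage

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    offs = spec.offsets
    half = np.abs(offs).max(axis=0)
    kernel = np.zeros(2 * half + 1, dtype=float)
    kernel[tuple((offs + half).T)] = 1.0
    counts = ndimage.correlate(mask.astype(float), kernel, mode="constant", cval=0.0)
    return mask & (np.round(counts).astype(int) >= spec.min_gray_voxels)


def _pair_list(
    trials: np.ndarray,
    labels: pd.DataFrame,
    within_species_pairs_only: bool,
) -> list[tuple[int, int]]:
    """Unordered distinct trial pairs of a set (self-pairs excluded).

    Pairs spanning the two runs are included.  With
    ``within_species_pairs_only`` pairs mixing dog and human stimuli are
    dropped (pairs involving species-free trials are kept).
    """
    species = [SPECIES_OF.get(labels["condition"].iloc[int(t)], "none") for t in trials]
    pairs = []
    for (ai, a), (bi, b) in combinations(enumerate(trials), 2):
        if within_species_pairs_only:
            sa, sb = species[ai], species[bi]
            if sa != "none" and sb != "none" and sa != sb:
                continue
        pairs.append((int(a), int(b)))
    return pairs


def _resolve_trials(stack: TrialPatternStack, trial_set) -> np.ndarray:
    if callable(trial_set):
        keep = [i for i in range(stack.n_trials) if trial_set(stack.labels.iloc[i])]
        return np.asarray(keep, dtype=int)
    trial_set = list(trial_set)
    if trial_set and isinstance(trial_set[0], str):
        return stack.trials_of(trial_set)
    return np.asarray(trial_set, dtype=int)


def searchlight_set_similarities(
    stack: TrialPatternStack,
    spec: SearchlightSpec,
    sets: Mapping[str, Sequence],
    within_species_pairs_only: bool = False,
) -> dict[str, SimilarityMap]:
    """Mean within-set pairwise Fisher-z similarity maps, one per set.

    All sets are evaluated in a single pass over searchlight centers:
    per center, the trial x voxel matrix over in-mask sphere voxels is
    correlated once (every unordered pair of distinct trials), each r is
    Fisher z-transformed after capping |r| at 1 - 1e-6, and each set's
    mean z over its pair list lands at the center voxel.  Trials with a
    zero-variance pattern inside a sphere contribute no pairs there; a
    center where a set has no usable pair stays NaN.
    """
    shape = stack.betas.shape[1:]
    if stack.mask.shape != shape:
        raise ValueError("mask grid does not match beta maps")
    flat = stack.betas.reshape(stack.n_trials, -1)
    finite = np.isfinite(flat).all(axis=0).reshape(shape)
    mask = stack.mask & finite

    trial_sets = {name: _resolve_trials(stack, ts) for name, ts in sets.items()}
    for name, tr in trial_sets.items():
        if tr.size < 2:
            raise ValueError(f"set '{name}' has fewer than 2 trials")
    union = np.unique(np.concatenate(list(trial_sets.values())))
    pos = {int(t): i for i, t in enumerate(union)}
    pair_idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, tr in trial_sets.items():
        pairs = _pair_list(tr, stack.labels, within_species_pairs_only)
        if not pairs:
            raise ValueError(f"set '{name}' has no admissible trial pairs")
        pair_idx[name] = (
            np.array([pos[a] for a, _ in pairs]),
            np.array([pos[b] for _, b in pairs]),
        )

    centers3d = valid_centers(mask, spec)
    centers = np.argwhere(centers3d)
    offs = spec.offsets
    sub = flat[union]  # (T, V)

    out = {name: np.full(shape, np.nan) for name in trial_sets}
    z_cap = np.arctanh(FISHER_R_CAP)
    mask_flat = mask.ravel()
    shp = np.asarray(shape)
    for c in centers:
        coords = c + offs
        inside = np.all((coords >= 0) & (coords < shp), axis=1)
        coords = coords[inside]
        flat_ix = np.ravel_multi_index(coords.T, shape)
        flat_ix = flat_ix[mask_flat[flat_ix]]
        if flat_ix.size < 2:
            continue
        M = sub[:, flat_ix]
        sd = M.std(axis=1)
        ok = sd > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(M)
        z = np.arctanh(np.clip(C, -FISHER_R_CAP, FISHER_R_CAP))
        np.clip(z, -z_cap, z_cap, out=z)
        for name, (ia, ib) in pair_idx.items():
            good = ok[ia] & ok[ib]
            if good.any():
                out[name][tuple(c)] = z[ia[good], ib[good]].mean()
    return {
        name: SimilarityMap(
            out[name], stack.affine, name, n_pairs=pair_idx[name][0].size
        )
        for name in trial_sets
    }


def searchlight_similarity(
    stack: TrialPatternStack,
    spec: SearchlightSpec,
    trial_set,
    within_species_pairs_only: bool = False,
    label: str = "set",
) -> SimilarityMap:
    """Mean pairwise-similarity map for one trial set (see set version)."""
    maps = searchlight_set_similarities(
        stack, spec, {label: trial_set}, within_species_pairs_only
    )
    return maps[label]


#: The six group comparisons: each entry gives the two trial sets whose
#: mean within-set similarities enter the paired test.
COMPARISONS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "a": (("dog_face", "human_face"), ("object",)),  # faces vs objects
    "b": (("dog_body", "human_body"), ("object",)),  # bodies vs objects
    "c": (("dog_face", "human_face", "dog_body", "human_body"), ("object",)),  # animate
    "d": (("dog_face", "human_face"), ("dog_body", "human_body")),  # faces vs bodies
    "e": (("dog_face",), ("human_face",)),  # conspecific vs heterospecific faces
    "f": (("dog_body",), ("human_body",)),  # conspecific vs heterospecific bodies
}


def similarity_contrast_pair(
    stack: TrialPatternStack,
    spec: SearchlightSpec,
    comparison: str,
    within_species_pairs_only: bool = False,
) -> tuple[SimilarityMap, SimilarityMap]:
    """The two per-participant similarity maps entering one paired test."""
    if comparison not in COMPARISONS:
        raise KeyError(f"unknown comparison '{comparison}' (use one of {sorted(COMPARISONS)})")
    set_a, set_b = COMPARISONS[comparison]
    maps = searchlight_set_similarities(
        stack,
        spec,
        {"+".join(set_a): list(set_a), "+".join(set_b): list(set_b)},
        within_species_pairs_only,
    )
    return maps["+".join(set_a)], maps["+".join(set_b)]


def write_similarity_map(smap: SimilarityMap, path: str | Path, spec: SearchlightSpec | None = None) -> Path:
    import json

    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(smap.data.astype(np.float32), smap.affine), str(path))
    sidecar = {"label": smap.label, "participant": smap.participant, "n_pairs": smap.n_pairs}
    if spec is not None:
        sidecar.update(
            {
                "radius_mm": spec.radius_mm,
                "voxel_mm": spec.voxel_mm,
                "min_gray_voxels": spec.min_gray_voxels,
                "boundary": spec.boundary,
                "sphere_voxels": spec.n_voxels,
            }
        )
    path.with_name(path.name.split(".")[0] + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str)
    )
    return path
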