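"""Split-half functional region-of-interest (fROI) analysis.

A localizer run defines, inside an anatomical search space, the voxels
preferring one category over another (e.g. bodies > faces) and keeps the
top percentage with the strongest target contrast (e.g. bodies >
objects) per hemisphere.  Response magnitudes are then read out from the
statistically independent left-out run, compared across conditions with
repeated-measures ANOVAs (planned comparisons FDR-corrected), and
validated by a top-percent sweep and a subject-resampling analysis.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glm import BetaMap
from .inference import ClusterResult, fdr_bh, permutation_onesample_test

__all__ = [
    "SearchSpace",
    "FROI",
    "SplitHalfError",
    "localize_visual_responsive",
    "define_froi",
    "extract_froi_means",
    "rm_anova_oneway",
    "rm_anova_2x2",
    "froi_threshold_sweep",
    "resample_subsamples",
    "write_froi",
]

DEFAULT_SWEEP_GRID = (1,) + tuple(range(5, 101, 5))


class SplitHalfError(RuntimeError):
    """Localizer and test data come from the same run (circularity)."""


@dataclass
class SearchSpace:
    """Named anatomical mask within which fROIs are defined."""

    name: str
    mask: np.ndarray  # 3D bool
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"search space '{self.name}' is empty")

    def hemisphere_masks(self) -> dict[str, np.ndarray]:
        """Split by the sign of the world x coordinate (x <= 0 -> left)."""
        idx = np.indices(self.mask.shape).reshape(3, -1)
        world_x = (np.asarray(self.affine)[:3, :3] @ idx)[0] + np.asarray(self.affine)[0, 3]
        left = (world_x <= 0).reshape(self.mask.shape)
        return {"left": self.mask & left, "right": self.mask & ~left}


@dataclass
class FROI:
    """Per-hemisphere voxel sets selected inside a search space."""

    name: str
    voxels: dict[str, np.ndarray]  # hemisphere -> (k, 3) voxel indices
    shape: tuple[int, int, int]
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return sum(v.shape[0] for v in self.voxels.values())

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for v in self.voxels.values():
            if v.size:
                m[tuple(v.T)] = True
        return m


# ---------------------------------------------------------------------------
# Localization
# ---------------------------------------------------------------------------


def localize_visual_responsive(
    subject_maps: Sequence[BetaMap] | np.ndarray,
    atlas: Mapping[str, np.ndarray],
    cdt_p: float = 0.005,
    alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> tuple[ClusterResult, list[SearchSpace]]:
    """Group visual-stimulation localizer: which atlas regions respond?

    Runs a one-sample permutation test across subjects on the
    all-conditions > baseline contrast maps, keeps clusters surviving
    cluster-level FWE at ``alpha`` (cluster-defining p ``cdt_p``), and
    returns every atlas region that intersects a surviving cluster as a
    search space (the whole region, mirroring the use of whole gyri).
    """
    if isinstance(subject_maps, np.ndarray):
        data = subject_maps
    else:
        data = np.stack([m.data for m in subject_maps])
        if affine is None and subject_maps:
            affine = subject_maps[0].affine
    if data.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    result = permutation_onesample_test(
        data, n_perm=n_perm, cdt_p=cdt_p, alpha=alpha, seed=seed, mask=mask, affine=affine
    )
    sig = result.significant_clusters
    spaces: list[SearchSpace] = []
    if not sig:
        warnings.warn("no cluster survived; returning no search spaces", stacklevel=2)
        return result, spaces
    sig_mask = np.zeros(data.shape[1:], dtype=bool)
    for c in sig:
        sig_mask[tuple(c.voxels.T)] = True
    for name, region in atlas.items():
        if (np.asarray(region, dtype=bool) & sig_mask).any():
            spaces.append(SearchSpace(name, region, affine if affine is not None else np.eye(4)))
    return result, spaces


# ---------------------------------------------------------------------------
# fROI definition and extraction
# ---------------------------------------------------------------------------


def define_froi(
    preference: BetaMap,
    target: BetaMap,
    space: SearchSpace,
    top_pct: float = 10.0,
    name: str | None = None,
) -> FROI:
    """Two-step fROI selection inside one search space.

    Step 1 keeps in-space voxels with a strictly positive preference
    contrast (e.g. bodies > faces).  Step 2 keeps, per hemisphere, the
    k voxels with the largest target contrast (e.g. bodies > objects),
    k = max(1, ceil(top_pct/100 x preference-voxel count)).  Ties are
    broken by voxel index so selections are deterministic and nested
    across increasing percentages.
    """
    if not 0 < top_pct <= 100:
        raise ValueError("top_pct must be in (0, 100]")
    pref = np.asarray(preference.data, dtype=float)
    targ = np.asarray(target.data, dtype=float)
    if pref.shape != space.mask.shape or targ.shape != space.mask.shape:
        raise ValueError("map and search-space grids differ")
    eligible = space.mask & np.isfinite(pref) & np.isfinite(targ) & (pref > 0)

    voxels: dict[str, np.ndarray] = {}
    for hemi, hmask in space.hemisphere_masks().items():
        cand = np.argwhere(eligible & hmask)
        if cand.shape[0] == 0:
            warnings.warn(
                f"fROI '{name or space.name}': no preference voxels in {hemi} hemisphere",
                stacklevel=2,
            )
            voxels[hemi] = np.empty((0, 3), dtype=int)
            continue
        k = max(1, math.ceil(top_pct / 100.0 * cand.shape[0]))
        vals = targ[tuple(cand.T)]
        order = np.argsort(-vals, kind="stable")[:k]
        voxels[hemi] = cand[np.sort(order)]
    if all(v.shape[0] == 0 for v in voxels.values()):
        raise ValueError(f"fROI '{name or space.name}': no preference voxels in either hemisphere")
    return FROI(
        name or space.name,
        voxels,
        space.mask.shape,
        space.affine,
        provenance={
            "search_space": space.name,
            "preference_contrast": preference.label,
            "target_contrast": target.label,
            "top_pct": top_pct,
            "localizer_run": preference.run,
        },
    )


def extract_froi_means(
    test_maps: Mapping[str, BetaMap],
    froi: FROI,
    enforce_split_half: bool = True,
) -> dict[str, float]:
    """Unweighted mean over bilateral fROI voxels, per condition contrast.

    Rejects maps from the run that defined the fROI (split-half
    discipline) whenever both run labels are known.  NaN voxels inside
    the fROI are excluded (count reported); an all-NaN fROI is an error.
    """
    if froi.size == 0:
        raise ValueError("fROI is empty")
    loc_run = froi.provenance.get("localizer_run")
    vox = np.concatenate([v for v in froi.voxels.values() if v.size], axis=0)
    out: dict[str, float] = {}
    for cond, m in test_maps.items():
        if enforce_split_half and loc_run is not None and m.run is not None and m.run == loc_run:
            raise SplitHalfError(
                f"map '{m.label}' comes from run {m.run}, which defined fROI '{froi.name}'"
            )
        vals = np.asarray(m.data, dtype=float)[tuple(vox.T)]
        bad = ~np.isfinite(vals)
        if bad.all():
            raise ValueError(f"all fROI voxels are NaN for condition '{cond}'")
        if bad.any():
            warnings.warn(f"excluding {int(bad.sum())} NaN voxels from '{froi.name}'", stacklevel=2)
        out[cond] = float(vals[~bad].mean())
    return out


# ---------------------------------------------------------------------------
# Repeated-measures ANOVAs
# ---------------------------------------------------------------------------


def _as_matrix(values, columns: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    if isinstance(values, pd.DataFrame):
        df = values if columns is None else values.loc[:, list(columns)]
        return df.to_numpy(dtype=float), [str(c) for c in df.columns]
    arr = np.asarray(values, dtype=float)
    names = [f"c{i}" for i in range(arr.shape[1])] if columns is None else list(columns)
    return arr, names


def rm_anova_oneway(values, alpha: float = 0.05) -> dict:
    """One-way repeated-measures ANOVA with subject as blocking factor.

    ``values`` is a complete subjects x conditions table.  Returns the
    omnibus F with (k-1, (k-1)(n-1)) degrees of freedom plus all planned
    pairwise paired t-tests with BH-FDR adjusted q-values.
    """
    Y, names = _as_matrix(values)
    if np.isnan(Y).any():
        raise ValueError("table has missing cells")
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = Y.mean()
    ss_subj = k * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((Y - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_cond
    df1, df2 = k - 1, (k - 1) * (n - 1)
    tiny = 1e-12 * max(ss_tot, 1e-300)  # relative guard against identical columns
    ms_err = ss_err / df2
    if ss_cond <= tiny:
        F = 0.0
    elif ms_err <= tiny:
        F = np.inf
    else:
        F = (ss_cond / df1) / ms_err
    p = 1.0 if F == 0 else float(stats.f.sf(F, df1, df2))
    eta_p2 = float(ss_cond / (ss_cond + ss_err)) if (ss_cond + ss_err) > 0 else 0.0

    scale = max(float(np.abs(Y).max()), 1e-300)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            d = Y[:, i] - Y[:, j]
            if d.std(ddof=1) <= 1e-12 * scale:
                t, pp = (
                    (0.0, 1.0)
                    if abs(d.mean()) <= 1e-12 * scale
                    else (np.sign(d.mean()) * np.inf, 0.0)
                )
            else:
                t, pp = stats.ttest_rel(Y[:, i], Y[:, j])
            rows.append({"a": names[i], "b": names[j], "t": float(t), "df": n - 1, "p": float(pp)})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["q"] = fdr_bh(pairwise["p"].to_numpy())
    return {
        "F": float(F),
        "df1": df1,
        "df2": df2,
        "p": p,
        "eta_p2": eta_p2,
        "pairwise": pairwise,
        "significant": p < alpha,
    }


_CELLS_2X2 = (
    "conspecific_face",
    "conspecific_body",
    "heterospecific_face",
    "heterospecific_body",
)


def rm_anova_2x2(values, cells: Sequence[str] = _CELLS_2X2) -> dict:
    """2 x 2 within-subject ANOVA (species x image category).

    Each effect in a fully within 2x2 design is a paired t-test on a
    per-subject contrast score (its F is the squared t with df (1, n-1)):
    species = conspecific - heterospecific, category = face - body,
    interaction = the difference of species effects across categories.
    Post-hoc paired comparisons (species within each category) are
    BH-FDR corrected.
    """
    Y, names = _as_matrix(values, cells if isinstance(values, pd.DataFrame) else None)
    if Y.shape[1] != 4:
        raise ValueError("2x2 ANOVA needs exactly 4 cells")
    if np.isnan(Y).any():
        raise ValueError("table has missing cells")
    n = Y.shape[0]
    cf, cb, hf, hb = Y.T
    scores = {
        "species": (cf + cb - hf - hb) / 2.0,
        "category": (cf + hf - cb - hb) / 2.0,
        "interaction": (cf - cb) - (hf - hb),
    }
    scale = max(float(np.abs(Y).max()), 1e-300)
    rows = []
    for eff, s in scores.items():
        sd = s.std(ddof=1)
        if sd <= 1e-10 * scale:  # relative guard: scores that are zero up to rounding
            t = 0.0 if abs(s.mean()) <= 1e-10 * scale else np.sign(s.mean()) * np.inf
        else:
            t = s.mean() / (sd / np.sqrt(n))
        F = float(t**2)
        p = 1.0 if F == 0 else float(stats.f.sf(F, 1, n - 1))
        rows.append({"effect": eff, "F": F, "df1": 1, "df2": n - 1, "p": p})
    effects = pd.DataFrame(rows)

    post = []
    for cat, (a, b) in {"face": (cf, hf), "body": (cb, hb)}.items():
        t, p = stats.ttest_rel(a, b)
        if np.isnan(t):
            t, p = 0.0, 1.0
        post.append(
            {"comparison": f"conspecific_vs_heterospecific_{cat}", "t": float(t), "df": n - 1, "p": float(p)}
        )
    posthoc = pd.DataFrame(post)
    posthoc["q"] = fdr_bh(posthoc["p"].to_numpy())
    return {"effects": effects, "posthoc": posthoc}


# ---------------------------------------------------------------------------
# Validation analyses
# ---------------------------------------------------------------------------


def froi_threshold_sweep(
    preference: BetaMap,
    target: BetaMap,
    test_maps: Mapping[str, BetaMap],
    space: SearchSpace,
    pct_grid: Sequence[float] = DEFAULT_SWEEP_GRID,
) -> pd.DataFrame:
    """Repeat define+extract for a grid of top-percent cut-offs.

    Returns a tidy table (top_pct, condition, value, froi_size) for one
    subject and one search space; the default grid is 1% then 5..100% in
    steps of 5.
    """
    if any(not 0 < p <= 100 for p in pct_grid):
        raise ValueError("pct_grid values must be in (0, 100]")
    rows = []
    for pct in pct_grid:
        froi = define_froi(preference, target, space, top_pct=pct)
        means = extract_froi_means(test_maps, froi)
        for cond, val in means.items():
            rows.append(
                {"top_pct": float(pct), "condition": cond, "value": val, "froi_size": froi.size}
            )
    return pd.DataFrame(rows)


def resample_subsamples(
    subject_values: pd.DataFrame,
    n_sub: int = 15,
    n_iter: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Subject-resampling validation of the one-way RM-ANOVA.

    Draws ``n_iter`` subsamples of ``n_sub`` subjects without
    replacement, reruns the ANOVA on each, and returns the empirical
    distribution of (F, p, partial eta squared, significance).
    """
    if n_sub > len(subject_values):
        raise ValueError(f"n_sub={n_sub} exceeds available subjects ({len(subject_values)})")
    if n_sub < 2:
        raise ValueError("n_sub must be >= 2")
    rng = np.random.default_rng(seed)
    Y = subject_values.to_numpy(dtype=float) if isinstance(subject_values, pd.DataFrame) else np.asarray(subject_values, dtype=float)
    rows = []
    for it in range(n_iter):
        pick = np.sort(rng.choice(len(Y), size=n_sub, replace=False))
        res = rm_anova_oneway(Y[pick], alpha=alpha)
        rows.append(
            {
                "iteration": it,
                "F": res["F"],
                "p": res["p"],
                "eta_p2": res["eta_p2"],
                "significant": res["p"] < alpha,
            }
        )
    return pd.DataFrame(rows)


def write_froi(froi: FROI, nifti_path: str | Path, sidecar_path: str | Path | None = None) -> Path:
    """Serialize an fROI as a 0/1/2 label map (left=1, right=2) + JSON sidecar."""
    import nibabel as nib

    nifti_path = Path(nifti_path)
    nifti_path.parent.mkdir(parents=True, exist_ok=True)
    labels = np.zeros(froi.shape, dtype=np.uint8)
    for code, hemi in ((1, "left"), (2, "right")):
        v = froi.voxels.get(hemi)
        if v is not None and v.size:
            labels[tuple(v.T)] = code
    nib.save(nib.Nifti1Image(labels, froi.affine), str(nifti_path))
    if sidecar_path is None:
        sidecar_path = nifti_path.with_suffix("").with_suffix(".json")
    prov = dict(froi.provenance)
    prov.update({"name": froi.name, "size": froi.size})
    Path(sidecar_path).write_text(json.dumps(prov, indent=2, default=str))
    return nifti_path
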