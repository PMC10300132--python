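"""Group-level nonparametric inference shared by all pipeline stages.

One-sample and paired tests by sign-flip permutation of subject maps,
with cluster-level family-wise-error correction against the max-extent
null distribution (the SnPM-style procedure), plus cluster extent
thresholds and Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Cluster",
    "ClusterResult",
    "permutation_onesample_test",
    "permutation_paired_test",
    "cluster_extent_threshold",
    "fdr_bh",
]

# 18-connectivity: faces + edges (SPM's default for cluster forming).
_CONN18 = ndimage.generate_binary_structure(3, 2)


@dataclass
class Cluster:
    voxels: np.ndarray  # (k, 3) voxel indices
    extent: int
    peak_ijk: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    peak_stat: float
    p_corrected: float

    @property
    def significant(self) -> bool:  # at the alpha the result was run with
        return bool(self._significant)

    _significant: bool = field(default=False, repr=False)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray  # 3D, NaN outside the analysis mask
    t_threshold: float  # cluster-defining statistic value
    cdt_p: float
    null_max_extents: np.ndarray
    n_perm: int
    alpha: float
    exhaustive: bool

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected < self.alpha]

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "extent": [c.extent for c in self.clusters],
                "peak_x_mm": [c.peak_mm[0] for c in self.clusters],
                "peak_y_mm": [c.peak_mm[1] for c in self.clusters],
                "peak_z_mm": [c.peak_mm[2] for c in self.clusters],
                "peak_t": [c.peak_stat for c in self.clusters],
                "p_corrected": [c.p_corrected for c in self.clusters],
            }
        )


def _one_sample_t(signed: np.ndarray, ss: np.ndarray, n: int) -> np.ndarray:
    """t statistics for sign-flipped data given precomputed sums of squares.

    ``signed`` is (P, V) of per-permutation sums s_p = sum_i sign_pi * d_iv;
    sign flips leave sum(d^2) unchanged, so the sample variance is
    (ss - n*mean^2) / (n-1) for every permutation.
    """
    mean = signed / n
    var = (ss - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.where(var > 0, t, 0.0)


def _max_cluster_extent(supra3d: np.ndarray) -> int:
    labels, nlab = ndimage.label(supra3d, structure=_CONN18)
    if nlab == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def permutation_paired_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray | None,
    n_perm: int = 5000,
    cdt_p: float = 0.005,
    alpha: float = 0.05,
    seed: int = 0,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> ClusterResult:
    """Paired sign-flip permutation test with cluster-level FWE correction.

    Subject difference maps D = A - B are tested voxel-wise with a paired
    t; the cluster-defining threshold is the two-sided t quantile at
    ``cdt_p`` applied to the positive tail (contrasts are directed).
    Clusters use 18-connectivity.  The null is built by randomly flipping
    the sign of whole subject difference maps — exhaustively over all 2^n
    patterns when 2^n <= n_perm, otherwise by ``n_perm`` random draws —
    and recording the maximal cluster extent each time.  Corrected p is
    the rank of the observed extent in that null (with the observed
    statistic added to the null when sampling, so p > 0 always).
    """
    A = np.asarray(maps_a, dtype=float)
    if maps_b is None:
        D4 = A
    else:
        B = np.asarray(maps_b, dtype=float)
        if A.shape != B.shape:
            raise ValueError("maps_a and maps_b shapes differ")
        D4 = A - B
    if D4.ndim != 4:
        raise ValueError("maps must be (n_subjects, x, y, z)")
    n = D4.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    shape = D4.shape[1:]
    if affine is None:
        affine = np.eye(4)
    finite = np.isfinite(D4).all(axis=0)
    if mask is not None:
        finite &= np.asarray(mask, dtype=bool)
    if not finite.any():
        raise ValueError("no voxel is finite in every subject map")

    D = D4[:, finite]  # (n, V)
    ss = (D**2).sum(axis=0)
    df = n - 1
    t_thr = float(stats.t.isf(cdt_p / 2.0, df))

    t_obs = _one_sample_t(D.sum(axis=0)[None, :], ss, n)[0]
    if (np.ptp(D, axis=0) == 0).any() and (D != 0).any():
        warnings.warn("degenerate-variance voxels set to t = 0", stacklevel=2)
    t_map = np.full(shape, np.nan)
    t_map[finite] = t_obs

    supra = np.zeros(shape, dtype=bool)
    supra[finite] = t_obs > t_thr
    labels, nlab = ndimage.label(supra, structure=_CONN18)

    exhaustive = 2**n <= n_perm
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
    n_used = signs.shape[0]

    null_max = np.empty(n_used, dtype=int)
    chunk = max(1, int(2e7 // max(D.shape[1], 1)))
    supra_buf = np.zeros(shape, dtype=bool)
    for start in range(0, n_used, chunk):
        S = signs[start : start + chunk]
        t_perm = _one_sample_t(S @ D, ss, n)
        for r in range(t_perm.shape[0]):
            supra_buf[...] = False
            supra_buf[finite] = t_perm[r] > t_thr
            null_max[start + r] = _max_cluster_extent(supra_buf)

    clusters: list[Cluster] = []
    for lab in range(1, nlab + 1):
        vox = np.argwhere(labels == lab)
        extent = vox.shape[0]
        tvals = t_map[tuple(vox.T)]
        peak = tuple(int(v) for v in vox[np.argmax(tvals)])
        peak_mm = tuple(float(x) for x in (np.asarray(affine) @ np.array([*peak, 1.0]))[:3])
        if exhaustive:
            p = float((null_max >= extent).sum() / n_used)
        else:
            p = float((1 + (null_max >= extent).sum()) / (1 + n_used))
        c = Cluster(vox, extent, peak, peak_mm, float(tvals.max()), p)
        c._significant = p < alpha
        clusters.append(c)
    clusters.sort(key=lambda c: -c.extent)
    return ClusterResult(
        clusters, t_map, t_thr, cdt_p, null_max, n_used, alpha, exhaustive
    )


def permutation_onesample_test(
    maps: np.ndarray,
    n_perm: int = 5000,
    cdt_p: float = 0.005,
    alpha: float = 0.05,
    seed: int = 0,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> ClusterResult:
    """One-sample test against zero; identical machinery with B = 0."""
    return permutation_paired_test(
        maps, None, n_perm=n_perm, cdt_p=cdt_p, alpha=alpha, seed=seed, mask=mask, affine=affine
    )


def cluster_extent_threshold(null_max_extents, alpha: float = 0.05) -> int:
    """Smallest extent k with P(max null extent >= k) <= alpha."""
    null = np.asarray(null_max_extents)
    if null.size == 0:
        raise ValueError("empty null sample")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    for k in range(1, int(null.max()) + 2):
        if (null >= k).mean() <= alpha:
            return k
    return int(null.max()) + 1  # pragma: no cover - loop always returns


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
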