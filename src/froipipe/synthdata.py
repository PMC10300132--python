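"""Synthetic study generator: stimuli, block designs, ground truth, BOLD runs.

Emulates a two-run block-design visual category experiment as run in a
comparative dog/human scanner study: six conditions (dog faces, dog
bodies, human faces, human bodies, inanimate objects, grid-scrambled
controls), three 12-s blocks per condition per run with five images per
block, baselines jittered between 3 and 7 s, no condition repeated
back-to-back, and every image shown exactly once across the two runs.

The forward model is the same linear convolution model the analysis
assumes: per-voxel time series = baseline + sum over conditions of
amplitude x (boxcar convolved with the HRF) + low-frequency drift +
white Gaussian noise.  Ground truth (which region responds how much to
which condition, plus optional multivoxel patterns for similarity
analyses) is explicit, so every downstream stage can be checked against
what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import DOG_HRF, HRFParams, condition_regressors, dct_drift_basis, _convolved_boxcar

__all__ = [
    "CONDITIONS",
    "SPECIES_OF",
    "CATEGORY_OF",
    "StimulusEntry",
    "StimulusSet",
    "Block",
    "Baseline",
    "RunDesign",
    "GroundTruth",
    "MotionTrace",
    "StimulusExhaustedError",
    "InfeasibleDesignError",
    "generate_stimulus_set",
    "randomize_block_order",
    "build_run_design",
    "simulate_bold_run",
    "simulate_motion_trace",
    "ellipsoid_mask",
    "default_ground_truth",
    "write_bold_run",
    "write_events",
    "write_motion",
    "write_mask",
]

#: Canonical condition order used throughout the package.
CONDITIONS = ("dog_face", "dog_body", "human_face", "human_body", "object", "scrambled")

#: Stimulus species per condition ("none" for objects and scrambles).
SPECIES_OF = {
    "dog_face": "dog",
    "dog_body": "dog",
    "human_face": "human",
    "human_body": "human",
    "object": "none",
    "scrambled": "none",
}

#: Image category per condition (scrambles carry no category).
CATEGORY_OF = {
    "dog_face": "face",
    "dog_body": "body",
    "human_face": "face",
    "human_body": "body",
    "object": "object",
    "scrambled": "scrambled",
}

DEFAULT_SEED = 20230627

# Spatial-extent targets (% foreground) mirroring the reported stimulus
# statistics: faces ~58.5, bodies ~29.4, objects half-matched to each.
_EXTENT_MEAN = {"face": 58.5, "body": 29.4}
_EXTENT_SD = 7.5
_BACKGROUND_GRAY = 128


class StimulusExhaustedError(RuntimeError):
    """Raised when a condition runs out of unused images."""


class InfeasibleDesignError(RuntimeError):
    """Raised when no repeat-free block order exists (or none was found)."""


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------


@dataclass
class StimulusEntry:
    image_id: str
    condition: str
    species: str
    image: np.ndarray  # (H, W, 3) uint8
    source_id: str | None = None  # for scrambles: the image that was scrambled
    target_extent: float | None = None


@dataclass
class StimulusSet:
    """All images of the study, with per-condition bookkeeping."""

    entries: list[StimulusEntry]
    n_per_condition: int
    image_size: int

    def __post_init__(self) -> None:
        ids = [e.image_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("image_ids are not unique")
        for c in CONDITIONS:
            n = sum(e.condition == c for e in self.entries)
            if n != self.n_per_condition:
                raise ValueError(f"condition {c} has {n} entries, expected {self.n_per_condition}")

    def __len__(self) -> int:
        return len(self.entries)

    def ids_for(self, condition: str) -> list[str]:
        return [e.image_id for e in self.entries if e.condition == condition]

    def entry(self, image_id: str) -> StimulusEntry:
        for e in self.entries:
            if e.image_id == image_id:
                return e
        raise KeyError(image_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": [e.image_id for e in self.entries],
                "condition": [e.condition for e in self.entries],
                "species": [e.species for e in self.entries],
                "source_id": [e.source_id for e in self.entries],
            }
        )


def _hsv_to_rgb(h: float, s: float, v: float) -> tuple[int, int, int]:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
    r, g, b = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return int(round(r * 255)), int(round(g * 255)), int(round(b * 255))


def _draw_shape(size: int, extent_pct: float, hue: float, rng: np.random.Generator) -> np.ndarray:
    """Colored ellipse on uniform mid-gray, with ~extent_pct% foreground."""
    frac = np.clip(extent_pct / 100.0, 0.02, 0.75)
    img = np.full((size, size, 3), _BACKGROUND_GRAY, dtype=np.uint8)
    aspect = rng.uniform(0.6, 1.6)
    a = math.sqrt(frac * size * size * aspect / math.pi)
    b = a / aspect
    # clamp so the ellipse fits inside the frame
    scale = min(1.0, (size / 2 - 1) / max(a, b))
    a, b = a * scale, b * scale
    cy = size / 2 + rng.uniform(-size * 0.05, size * 0.05)
    cx = size / 2 + rng.uniform(-size * 0.05, size * 0.05)
    yy, xx = np.mgrid[0:size, 0:size]
    mask = ((yy - cy) / b) ** 2 + ((xx - cx) / a) ** 2 <= 1.0
    color = _hsv_to_rgb(hue % 1.0, rng.uniform(0.6, 0.95), 0.75)
    img[mask] = color
    return img


def _grid_scramble(image: np.ndarray, grid: int, rng: np.random.Generator) -> np.ndarray:
    """Partition the image into grid x grid tiles and permute them."""
    h, w = image.shape[:2]
    if h % grid or w % grid:
        raise ValueError(f"image size {h}x{w} not divisible by grid {grid}")
    th, tw = h // grid, w // grid
    tiles = [
        image[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
        for i in range(grid)
        for j in range(grid)
    ]
    perm = rng.permutation(len(tiles))
    out = np.empty_like(image)
    for k, p in enumerate(perm):
        i, j = divmod(k, grid)
        out[i * th : (i + 1) * th, j * tw : (j + 1) * tw] = tiles[p]
    return out


def generate_stimulus_set(
    n_per_condition: int = 30,
    seed: int = DEFAULT_SEED,
    image_size: int = 128,
    scramble_grid: int = 8,
) -> StimulusSet:
    """Generate 6 x ``n_per_condition`` synthetic stimuli.

    Non-scrambled images are colored ellipses on a uniform mid-gray
    background; spatial extent (% foreground) is drawn per category around
    the reported stimulus means (faces ~58.5%, bodies ~29.4%, objects
    half-matched to each).  Scrambles are grid-scrambled copies of a
    subset drawn as equally as possible from the five other conditions.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    entries: list[StimulusEntry] = []
    sources = [c for c in CONDITIONS if c != "scrambled"]
    for cond in sources:
        cat = CATEGORY_OF[cond]
        for k in range(n_per_condition):
            if cat == "object":
                # half matched to body extent, half to face extent
                mean = _EXTENT_MEAN["body"] if k % 2 == 0 else _EXTENT_MEAN["face"]
            else:
                mean = _EXTENT_MEAN[cat]
            target = float(np.clip(rng.normal(mean, _EXTENT_SD), 8.0, 75.0))
            img = _draw_shape(image_size, target, rng.uniform(0, 1), rng)
            entries.append(
                StimulusEntry(f"{cond}_{k:03d}", cond, SPECIES_OF[cond], img, None, target)
            )

    # scrambled subset: as equal a draw from the 5 source conditions as possible
    base, rem = divmod(n_per_condition, len(sources))
    counts = {c: base for c in sources}
    for c in rng.permutation(sources)[:rem]:
        counts[str(c)] += 1
    k = 0
    for cond in sources:
        pool = [e for e in entries if e.condition == cond]
        picks = rng.choice(len(pool), size=counts[cond], replace=False)
        for p in picks:
            src = pool[int(p)]
            entries.append(
                StimulusEntry(
                    f"scrambled_{k:03d}",
                    "scrambled",
                    "none",
                    _grid_scramble(src.image, scramble_grid, rng),
                    src.image_id,
                )
            )
            k += 1
    return StimulusSet(entries, n_per_condition, image_size)


# ---------------------------------------------------------------------------
# Block order and run design
# ---------------------------------------------------------------------------


def randomize_block_order(
    conditions: list[str],
    blocks_per_condition: int,
    seed: int = DEFAULT_SEED,
    max_retries: int = 10_000,
) -> list[str]:
    """Random block order with no condition presented twice in a row.

    Rejection-samples uniform shuffles of the block multiset until a
    repeat-free arrangement appears, so every valid sequence is equally
    likely.  Infeasible multisets (max multiplicity > ceil(total/2)) are
    rejected up front.
    """
    if blocks_per_condition < 1 or not conditions:
        raise ValueError("need at least one condition and one block per condition")
    pool = [c for c in conditions for _ in range(blocks_per_condition)]
    total = len(pool)
    max_mult = max(pool.count(c) for c in set(pool))
    if max_mult > (total + 1) // 2:
        raise InfeasibleDesignError(
            f"no repeat-free arrangement exists (multiplicity {max_mult} of {total})"
        )
    rng = np.random.default_rng(seed)
    arr = np.array(pool, dtype=object)
    for _ in range(max_retries):
        perm = rng.permutation(arr)
        if all(perm[i] != perm[i + 1] for i in range(total - 1)):
            return [str(c) for c in perm]
    raise InfeasibleDesignError(f"no repeat-free arrangement found in {max_retries} draws")


@dataclass
class Block:
    onset: float  # s
    duration: float  # s
    condition: str
    image_ids: list[str] = field(default_factory=list)


@dataclass
class Baseline:
    onset: float
    duration: float


@dataclass
class RunDesign:
    """One run: ordered stimulus blocks, jittered baselines, scan count."""

    blocks: list[Block]
    baselines: list[Baseline]
    tr: float
    n_scans: int

    def validate(self, jitter_range: tuple[float, float] = (3.0, 7.0)) -> None:
        prev_end = -np.inf
        prev_cond = None
        for b in self.blocks:
            if b.onset < prev_end - 1e-9:
                raise ValueError("block onsets overlap or are not increasing")
            if b.condition == prev_cond:
                raise ValueError("two consecutive blocks share a condition")
            if b.onset >= self.n_scans * self.tr:
                raise ValueError("block onset beyond run end")
            prev_end = b.onset + b.duration
            prev_cond = b.condition
        lo, hi = jitter_range
        for bl in self.baselines:
            if not (lo - 1e-9 <= bl.duration <= hi + 1e-9):
                raise ValueError(f"baseline duration {bl.duration} outside [{lo}, {hi}]")

    def events_table(self) -> pd.DataFrame:
        """BIDS-events-style table (onset, duration, trial_type)."""
        return pd.DataFrame(
            {
                "onset": [b.onset for b in self.blocks],
                "duration": [b.duration for b in self.blocks],
                "trial_type": [b.condition for b in self.blocks],
            }
        )


def build_run_design(
    order: list[str],
    stimulus_set: StimulusSet,
    tr: float = 1.0,
    jitter_range: tuple[float, float] = (3.0, 7.0),
    seed: int = DEFAULT_SEED,
    used_ids: set[str] | None = None,
    images_per_block: int = 5,
    block_duration: float = 12.0,
) -> RunDesign:
    """Lay out one run: leading baseline, then block/baseline alternation.

    One baseline precedes the first block and one sits between every pair
    of consecutive blocks (|order| baselines per run); durations are
    continuous-uniform on ``jitter_range``.  Images are consumed without
    replacement: pass the same ``used_ids`` set for both runs so each
    image is presented exactly once across the study.  Run length is the
    last block offset rounded up to a whole number of TRs.
    """
    rng = np.random.default_rng(seed)
    if used_ids is None:
        used_ids = set()
    pools: dict[str, list[str]] = {}
    for cond in set(order):
        avail = [i for i in stimulus_set.ids_for(cond) if i not in used_ids]
        rng.shuffle(avail)
        pools[cond] = avail

    blocks: list[Block] = []
    baselines: list[Baseline] = []
    t = 0.0
    for k, cond in enumerate(order):
        gap = float(rng.uniform(*jitter_range))
        baselines.append(Baseline(t, gap))
        t += gap
        pool = pools[cond]
        if len(pool) < images_per_block:
            raise StimulusExhaustedError(
                f"condition '{cond}' has only {len(pool)} unused images, needs {images_per_block}"
            )
        ids = [pool.pop() for _ in range(images_per_block)]
        used_ids.update(ids)
        blocks.append(Block(t, block_duration, cond, ids))
        t += block_duration
    n_scans = int(math.ceil(t / tr))
    design = RunDesign(blocks, baselines, tr, n_scans)
    design.validate(jitter_range)
    return design


# ---------------------------------------------------------------------------
# Ground truth and BOLD simulation
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Planted activation layout on a voxel grid.

    ``amplitudes`` maps region name -> condition -> response amplitude
    (signal units over baseline).  ``patterns`` optionally adds a fixed
    multivoxel pattern per condition (full 3D map, shared arrays allowed);
    ``block_jitter_sd`` adds an independent random pattern per block inside
    ``block_jitter_region`` so that trials of one condition are similar but
    not identical (what similarity analyses need).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    regions: dict[str, np.ndarray]  # name -> 3D bool mask
    amplitudes: dict[str, dict[str, float]]
    baseline: float = 100.0
    noise_sd: float = 2.0
    drift_amplitude: float = 1.0
    drift_cutoff_s: float = 128.0
    tr: float = 1.0
    hrf: HRFParams = DOG_HRF
    patterns: dict[str, np.ndarray] = field(default_factory=dict)
    block_jitter_sd: float = 0.0
    block_jitter_region: str | None = None
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if not self.allow_overlap:
            total = np.zeros(self.shape, dtype=int)
            for m in self.regions.values():
                total += m.astype(int)
            if (total > 1).any():
                raise ValueError("regions overlap; pass allow_overlap=True if intended")
        for region, amps in self.amplitudes.items():
            if region not in self.regions:
                raise KeyError(f"amplitude table names unknown region '{region}'")
            for cond, a in amps.items():
                if not np.isfinite(a):
                    raise ValueError(f"amplitude for ({region}, {cond}) is not finite")

    def amplitude_map(self, condition: str) -> np.ndarray:
        out = np.zeros(self.shape, dtype=float)
        for region, amps in self.amplitudes.items():
            a = amps.get(condition, 0.0)
            if a:
                out[self.regions[region]] += a
        if condition in self.patterns:
            out = out + self.patterns[condition]
        return out


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters per scan."""

    params: np.ndarray  # (n_scans, 6): tx, ty, tz (mm), rx, ry, rz (rad)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion params must be (n_scans, 6)")
        if not np.isfinite(self.params).all():
            raise ValueError("motion params contain non-finite values")

    @property
    def n_scans(self) -> int:
        return self.params.shape[0]


def simulate_motion_trace(
    n_scans: int,
    spike_spec: dict | None = None,
    seed: int = DEFAULT_SEED,
    wander_amplitude: float = 0.02,
    rotation_wander: float = 5e-4,
) -> MotionTrace:
    """Smooth low-amplitude wander plus step displacements at given scans.

    ``spike_spec`` is ``{"times": [...], "magnitudes": [...]}``; each spike
    is a sustained step of that magnitude (mm) on the x-translation, so it
    produces exactly one framewise-displacement exceedance.
    """
    if n_scans < 2:
        raise ValueError("need at least 2 scans")
    rng = np.random.default_rng(seed)
    t = np.arange(n_scans)
    params = np.zeros((n_scans, 6))
    amps = [wander_amplitude] * 3 + [rotation_wander] * 3
    for j, a in enumerate(amps):
        if a > 0:
            # sum of a few slow sinusoids: smooth, band-limited wander
            for _ in range(3):
                f = rng.uniform(0.2, 1.5) / n_scans
                params[:, j] += a * rng.uniform(0.3, 1.0) * np.sin(
                    2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)
                )
    if spike_spec:
        times = list(spike_spec.get("times", []))
        mags = list(spike_spec.get("magnitudes", []))
        if len(times) != len(mags):
            raise ValueError("spike times and magnitudes differ in length")
        for when, mag in zip(times, mags):
            when = int(when)
            if not 0 <= when < n_scans:
                raise ValueError(f"spike time {when} outside [0, {n_scans})")
            params[when:, 0] += float(mag)
    return MotionTrace(params)


def simulate_bold_run(
    design: RunDesign,
    truth: GroundTruth,
    motion: MotionTrace | None = None,
    seed: int = DEFAULT_SEED,
    motion_artifact_gain: float = 0.0,
) -> np.ndarray:
    """Forward-model one 4D run (x, y, z, t) from design and ground truth.

    Signal: baseline + per-condition amplitude maps times the convolved
    boxcars, plus optional per-block pattern jitter, plus low-frequency
    drift drawn in the discrete-cosine span below the high-pass cutoff,
    plus white Gaussian noise.  ``motion_artifact_gain`` (signal units per
    mm of framewise displacement) optionally injects global intensity
    artifacts at high-motion scans so scrubbing has something to remove.
    """
    if abs(design.tr - truth.tr) > 1e-9:
        raise ValueError(f"design TR {design.tr} does not match ground truth TR {truth.tr}")
    rng = np.random.default_rng(seed)
    shape = truth.shape
    n = design.n_scans
    nvox = int(np.prod(shape))

    conds = sorted({b.condition for b in design.blocks}, key=CONDITIONS.index)
    X, names = condition_regressors(design, truth.hrf, conds)
    A = np.stack([truth.amplitude_map(c).ravel() for c in names])  # (C, V)
    data = X @ A  # (T, V)

    if truth.block_jitter_sd > 0 and truth.block_jitter_region is not None:
        patch = truth.regions[truth.block_jitter_region].ravel()
        for b in design.blocks:
            reg = _convolved_boxcar([b.onset], [b.duration], n, design.tr, truth.hrf)
            jitter = rng.normal(0.0, truth.block_jitter_sd, patch.sum())
            data[:, patch] += np.outer(reg, jitter)

    if truth.drift_amplitude > 0:
        basis = dct_drift_basis(n, design.tr, truth.drift_cutoff_s)
        if basis.shape[1]:
            coef = rng.normal(0.0, truth.drift_amplitude, (basis.shape[1], nvox))
            data += basis @ coef

    if motion is not None and motion_artifact_gain:
        from .glm import compute_fd

        fd = compute_fd(motion)
        data += motion_artifact_gain * fd[:, None]

    if truth.noise_sd > 0:
        data += rng.normal(0.0, truth.noise_sd, data.shape)
    data += truth.baseline

    vol = np.ascontiguousarray(data.T.reshape(shape + (n,)))
    assert np.isfinite(vol).all()
    return vol


# ---------------------------------------------------------------------------
# Default ground-truth layout
# ---------------------------------------------------------------------------


def ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float] | None = None,
    semiaxes: tuple[float, float, float] | None = None,
) -> np.ndarray:
    if center is None:
        center = tuple((s - 1) / 2.0 for s in shape)
    if semiaxes is None:
        semiaxes = tuple(s * 0.45 for s in shape)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return r2 <= 1.0


def _box(shape, lo, hi) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return m


def default_ground_truth(
    species: str = "dog",
    shape: tuple[int, int, int] = (32, 32, 24),
    voxel_mm: float = 1.5,
    seed: int = DEFAULT_SEED,
    noise_sd: float = 2.0,
    hrf: HRFParams | None = None,
    pattern_sd: float = 1.5,
    block_jitter_sd: float = 0.75,
) -> tuple[GroundTruth, np.ndarray]:
    """Desk-scale ground truth: a brain ellipsoid with planted regions.

    Regions (disjoint, inside the brain mask):
      * ``visual``     — responds to every condition (search-space seed);
      * ``body_gyrus`` / ``face_gyrus`` — bilateral visually responsive
        "gyri" that serve as anatomical search spaces;
      * ``body_core`` / ``face_core``  — small bilateral cores inside the
        gyri (about a tenth of the space, matching the scale top-percent
        selection can recover) where bodies (faces) respond extra;
      * ``animacy_patch`` — all conditions respond, and the four animate
        conditions share a multivoxel pattern absent for objects, with
        per-block jitter (the target of the similarity analysis).

    Returns (ground truth, brain mask).  The affine is RAS with the grid
    centered on x = 0 so both hemispheres are populated.
    """
    rng = np.random.default_rng(seed)
    if hrf is None:
        from .glm import DOG_HRF, HUMAN_HRF

        hrf = DOG_HRF if species == "dog" else HUMAN_HRF
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0
    brain = ellipsoid_mask(shape)

    def fbox(fl, fh, mirror=False):
        lo = tuple(int(round(f * s)) for f, s in zip(fl, shape))
        hi = tuple(max(int(round(f * s)), l + 1) for f, s, l in zip(fh, shape, lo))
        m = _box(shape, lo, hi)
        if mirror:  # bilateral: union with the x-mirrored box
            m = m | m[::-1, :, :]
        return m

    # bands along y (posterior to anterior); bilateral gyri mirrored in x.
    # Grid-relative boxes keep the layout valid on any desk-scale shape,
    # with an explicit subtraction chain as belt and braces.
    visual = fbox((0.12, 0.10, 0.25), (0.88, 0.26, 0.75)) & brain
    body_gyrus = fbox((0.08, 0.30, 0.33), (0.44, 0.46, 0.58), mirror=True) & brain
    body_core = fbox((0.16, 0.34, 0.38), (0.28, 0.42, 0.52), mirror=True) & brain
    face_gyrus = fbox((0.08, 0.50, 0.33), (0.44, 0.66, 0.58), mirror=True) & brain
    face_core = fbox((0.16, 0.54, 0.38), (0.28, 0.62, 0.52), mirror=True) & brain
    patch = fbox((0.30, 0.70, 0.33), (0.70, 0.88, 0.58)) & brain
    body_gyrus &= ~(visual | body_core)
    face_gyrus &= ~(visual | body_gyrus | body_core | face_core)
    face_core &= ~(visual | body_gyrus | body_core)
    patch &= ~(visual | body_gyrus | body_core | face_gyrus | face_core)

    all_conds = {c: 2.5 for c in CONDITIONS}
    responsive = dict(all_conds, scrambled=1.5)
    amplitudes = {
        "visual": dict(all_conds),
        # gyri respond to everything; only the cores prefer a category
        "body_gyrus": dict(responsive),
        "face_gyrus": dict(responsive),
        "body_core": {
            "dog_body": 4.5,
            "human_body": 4.5,
            "dog_face": 2.5,
            "human_face": 2.5,
            "object": 2.5,
            "scrambled": 1.5,
        },
        "face_core": {
            "dog_face": 4.5,
            "human_face": 4.5,
            "dog_body": 2.5,
            "human_body": 2.5,
            "object": 2.5,
            "scrambled": 1.5,
        },
        "animacy_patch": {c: 2.0 for c in CONDITIONS},
    }

    patterns: dict[str, np.ndarray] = {}
    if pattern_sd > 0:
        shared = np.zeros(shape)
        shared[patch] = rng.normal(0.0, pattern_sd, patch.sum())
        for c in ("dog_face", "human_face", "dog_body", "human_body"):
            patterns[c] = shared  # same array: the planted animate pattern

    truth = GroundTruth(
        shape=shape,
        affine=affine,
        regions={
            "visual": visual,
            "body_gyrus": body_gyrus,
            "body_core": body_core,
            "face_gyrus": face_gyrus,
            "face_core": face_core,
            "animacy_patch": patch,
        },
        amplitudes=amplitudes,
        noise_sd=noise_sd,
        hrf=hrf,
        patterns=patterns,
        block_jitter_sd=block_jitter_sd,
        block_jitter_region="animacy_patch",
    )
    return truth, brain


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def write_bold_run(volume: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))
    return path


def write_events(design: RunDesign, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    design.events_table().to_csv(path, sep="\t", index=False)
    return path


def write_motion(motion: MotionTrace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, motion.params, fmt="%.6f")
    return path


def write_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))
    return path
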