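"""Study configuration and species presets.

A :class:`StudyConfig` bundles every tunable of the synthetic study —
cohort size, grid, acquisition timing, haemodynamic model, motion and
scrubbing settings, searchlight geometry, statistical thresholds and the
master seed — with validated dog and human presets.  Configs can be
loaded from a flat TOML key-value file.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .glm import DOG_HRF, HUMAN_HRF, HRFParams
from .rsa import DOG_SEARCHLIGHT, HUMAN_SEARCHLIGHT, SearchlightSpec

__all__ = ["SpeciesPreset", "PRESETS", "StudyConfig", "derive_seed"]

DEFAULT_SEED = 20230627


@dataclass(frozen=True)
class SpeciesPreset:
    """Analysis settings that differ between the two simulated samples."""

    name: str
    hrf: HRFParams
    searchlight: SearchlightSpec
    fd_radius_mm: float  # head radius converting rotations to mm
    cdt_p: float  # cluster-defining p
    voxel_mm: float
    motion_spike_rate: float  # expected fraction of scans with an FD spike


PRESETS: dict[str, SpeciesPreset] = {
    # Dog sample: earlier-peaking HRF, small head, r=4mm searchlight on the
    # 1.5 mm grid (81 voxels), lenient cluster-defining p, ~8% spiky scans.
    "dog": SpeciesPreset("dog", DOG_HRF, DOG_SEARCHLIGHT, 30.0, 0.005, 1.5, 0.08),
    # Human sample: canonical HRF, 50 mm head radius, r=8mm searchlight
    # counted exclusively on a 2 mm grid (251 voxels), stricter cdt, ~1% spikes.
    "human": SpeciesPreset("human", HUMAN_HRF, HUMAN_SEARCHLIGHT, 50.0, 0.001, 2.0, 0.01),
}


@dataclass
class StudyConfig:
    species: str = "dog"
    n_subjects: int = 15
    n_per_condition: int = 30
    grid: tuple[int, int, int] = (32, 32, 24)
    tr: float = 1.0
    blocks_per_condition: int = 3
    images_per_block: int = 5
    block_duration_s: float = 12.0
    jitter_range_s: tuple[float, float] = (3.0, 7.0)
    n_runs: int = 2
    noise_sd: float = 2.0
    hpf_cutoff_s: float = 128.0
    fd_threshold_mm: float = 0.5
    top_pct: float = 10.0
    alpha: float = 0.05
    n_perm: int = 5000
    resample_n_sub: int = 15
    resample_n_iter: int = 1000
    within_species_pairs_only: bool = False
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        self.validate()

    @property
    def preset(self) -> SpeciesPreset:
        return PRESETS[self.species]

    def validate(self) -> None:
        if self.species not in PRESETS:
            raise ValueError(f"unknown species '{self.species}' (use {sorted(PRESETS)})")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if self.n_runs != 2:
            raise ValueError("the split-half design requires exactly 2 runs")
        need = self.blocks_per_condition * self.images_per_block * self.n_runs
        if self.n_per_condition < need:
            raise ValueError(
                f"n_per_condition={self.n_per_condition} cannot fill "
                f"{need} image slots per condition"
            )
        if len(self.grid) != 3 or any(g < 4 for g in self.grid):
            raise ValueError("grid must be three dimensions of at least 4 voxels")
        lo, hi = self.jitter_range_s
        if not 0 < lo <= hi:
            raise ValueError("jitter range must satisfy 0 < lo <= hi")
        if not 0 < self.top_pct <= 100:
            raise ValueError("top_pct must be in (0, 100]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 10:
            raise ValueError("n_perm must be >= 10")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must fit in a signed 32-bit integer")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = list(self.grid)
        d["jitter_range_s"] = list(self.jitter_range_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "grid" in d:
            d["grid"] = tuple(d["grid"])
        if "jitter_range_s" in d:
            d["jitter_range_s"] = tuple(d["jitter_range_s"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Load from a flat TOML key-value file (or JSON, by extension)."""
        path = Path(path)
        if path.suffix == ".json":
            return cls.from_dict(json.loads(path.read_text()))
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def derive_seed(base: int, *tags) -> int:
    """Stable per-stage substream seed below 2**31 from the master seed."""
    key = "|".join([str(base), *map(str, tags)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)
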