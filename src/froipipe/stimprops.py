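"""Low-level visual properties of the stimulus set and their group tests.

Hue, saturation and contrast are read off the HSV representation of each
image (mean hue, mean saturation, standard deviation of the value
channel); spatial extent is the percentage of pixels that differ from the
uniform background.  Group tests mirror the activation analyses: pooled
two-sample t-tests plus, per property, a one-way ANOVA over image
category and a species x category two-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skimage.color import rgb2hsv

from .synthdata import CATEGORY_OF, StimulusSet

__all__ = [
    "PropertyRecord",
    "compute_image_properties",
    "stimulus_property_table",
    "two_sample_ttest",
    "property_anovas",
    "write_property_table",
]

PROPERTIES = ("hue", "saturation", "contrast", "spatial_extent")


@dataclass(frozen=True)
class PropertyRecord:
    image_id: str
    hue: float  # mean HSV hue, [0, 1)
    saturation: float  # mean HSV saturation, [0, 1]
    contrast: float  # SD of the HSV value channel, input units
    spatial_extent: float  # % pixels differing from background

    def __post_init__(self) -> None:
        vals = (self.hue, self.saturation, self.contrast, self.spatial_extent)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("property record contains NaN/inf")
        if not (0 <= self.hue < 1 and 0 <= self.saturation <= 1):
            raise ValueError("hue must be in [0,1) and saturation in [0,1]")
        if self.contrast < 0 or not (0 <= self.spatial_extent <= 100):
            raise ValueError("contrast must be >= 0 and spatial_extent in [0,100]")


def compute_image_properties(
    image: np.ndarray,
    background: tuple[float, float, float] = (128, 128, 128),
    image_id: str = "",
    background_tolerance: float = 2.0,
) -> PropertyRecord:
    """HSV-based properties of one RGB image.

    Hue and saturation are pixel means of the HSV hue/saturation channels
    (achromatic pixels contribute hue 0); contrast is the population SD
    of the value channel, reported on the input intensity scale (so a
    [0,255] image yields 255x the contrast of its [0,1] rescaling).
    Spatial extent is the percentage of pixels whose RGB differs from
    ``background`` by more than ``background_tolerance`` intensity levels
    in any channel (exact match suffices for synthetic stimuli; the
    tolerance absorbs compression noise in imported photos).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            f"expected an RGB image (H, W, 3); got shape {image.shape} — "
            "convert grayscale/RGBA input explicitly first"
        )
    img = image.astype(float)
    scale = 1.0 if img.max() <= 1.0 and not np.issubdtype(image.dtype, np.integer) else 255.0
    hsv = rgb2hsv(img / scale)
    hue = float(hsv[..., 0].mean() % 1.0)
    sat = float(hsv[..., 1].mean())
    contrast = float(hsv[..., 2].std()) * scale

    bg = np.asarray(background, dtype=float)
    if scale == 1.0:
        bg = bg / 255.0 if bg.max() > 1 else bg
        tol = background_tolerance / 255.0
    else:
        tol = background_tolerance
    fg = (np.abs(img - bg) > tol).any(axis=2)
    extent = 100.0 * fg.mean()
    return PropertyRecord(image_id, hue, sat, contrast, extent)


def stimulus_property_table(stimulus_set: StimulusSet) -> pd.DataFrame:
    """One row per image: condition labels plus the four property measures."""
    rows = []
    for e in stimulus_set.entries:
        rec = compute_image_properties(e.image, image_id=e.image_id)
        rows.append(
            {
                "image_id": e.image_id,
                "condition": e.condition,
                "species": e.species,
                "category": CATEGORY_OF[e.condition],
                "hue": rec.hue,
                "saturation": rec.saturation,
                "contrast": rec.contrast,
                "spatial_extent": rec.spatial_extent,
            }
        )
    return pd.DataFrame(rows)


def two_sample_ttest(a, b) -> dict:
    """Student two-sample t with pooled variance; df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return {"t": 0.0, "df": df, "p": 1.0}
        # degenerate: zero pooled variance with unequal means
        return {"t": float(np.sign(diff)) * np.inf, "df": df, "p": 0.0, "degenerate": True}
    t = diff / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": df, "p": float(p)}


def property_anovas(records: pd.DataFrame) -> dict[str, dict[str, pd.DataFrame]]:
    """Per property: one-way category ANOVA and 2-way species x category ANOVA.

    The one-way ANOVA compares faces, bodies and inanimate objects
    (species pooled, scrambles excluded); the two-way ANOVA crosses
    species (dog, human) with category (face, body) including the
    interaction.  Type-II sums of squares on the (balanced) table.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    req = {"category", "species", *PROPERTIES}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks columns: {sorted(missing)}")

    oneway = records[records["category"].isin(["face", "body", "object"])]
    twoway = records[records["category"].isin(["face", "body"])]
    for cat in ("face", "body", "object"):
        if not (oneway["category"] == cat).any():
            raise ValueError(f"no images in category cell '{cat}'")
    for sp in ("dog", "human"):
        for cat in ("face", "body"):
            if not ((twoway["species"] == sp) & (twoway["category"] == cat)).any():
                raise ValueError(f"no images in cell (species={sp}, category={cat})")

    def _sanitize(tab: pd.DataFrame) -> pd.DataFrame:
        # degenerate data (zero effect and/or zero residual SS) -> F = 0, p = 1
        zero = tab["sum_sq"].abs() < 1e-12
        tab.loc[zero, "F"] = 0.0
        tab.loc[zero, "PR(>F)"] = 1.0
        return tab

    out: dict[str, dict[str, pd.DataFrame]] = {}
    for prop in PROPERTIES:
        m1 = ols(f"{prop} ~ C(category)", data=oneway).fit()
        t1 = _sanitize(sm.stats.anova_lm(m1, typ=2))
        m2 = ols(f"{prop} ~ C(species) * C(category)", data=twoway).fit()
        t2 = _sanitize(sm.stats.anova_lm(m2, typ=2))
        out[prop] = {"oneway_category": t1, "twoway_species_x_category": t2}
    return out


def write_property_table(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False)
    return path
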