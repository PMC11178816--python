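"""Constrained stratified sampling of landscape pixels.

Sample units are drawn per stratum (zone x forest type) from pixels that
pass four eligibility filters -- treed class, pure 3x3 forest-type
neighbourhood, 3x3 homogeneity of canopy cover and height (CV below a
threshold), and stand age above a minimum -- subject to a global minimum
pairwise distance and a per-stratum cap.  Pixels are visited in seeded
random order and accepted greedily.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .dhi import DHILayers
from .landscape import (
    DHI_NAMES,
    NEVER_DISTURBED,
    STRUCTURE_ATTRS,
    TREED_CODES,
    LandscapeBundle,
    substream,
)

__all__ = ["SamplingConfig", "eligibility_mask", "draw_sample", "window_cv"]

log = logging.getLogger(__name__)

#: fixed column order of the emitted sample table
SAMPLE_COLUMNS = (
    "row", "col", "x", "y", "zone", "forest_type",
    *STRUCTURE_ATTRS, *DHI_NAMES,
)


@dataclass
class SamplingConfig:
    """Eligibility and thinning parameters.

    cv_threshold : strict upper bound on the windowed CV of canopy cover
        and canopy height (sample sd over the 9 window values / mean).
    window : odd moving-window edge length in pixels.
    min_distance : minimum pairwise centre-to-centre distance in metres,
        enforced globally across strata by default.
    cap : maximum sample units per stratum.
    min_stand_age : years since disturbance required for eligibility
        (strictly more than this at the reference year).
    """

    cv_threshold: float = 0.5
    window: int = 3
    min_distance: float = 1000.0
    cap: int = 500
    min_stand_age: int = 35
    reference_year: int = 2015
    global_spacing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_threshold <= 0:
            raise ValueError("cv_threshold must be > 0")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.cap < 1:
            raise ValueError("cap must be >= 1")


def window_cv(band: np.ndarray, window: int = 3) -> np.ndarray:
    """Moving-window coefficient of variation (sample sd / mean).

    NaNs are treated by excluding any window that touches one (result
    NaN there); border pixels with incomplete windows are NaN.
    """
    n = window * window
    finite = np.isfinite(band)
    filled = np.where(finite, band, 0.0)
    ksum = ndimage.uniform_filter(filled, size=window, mode="constant") * n
    ksq = ndimage.uniform_filter(filled * filled, size=window, mode="constant") * n
    kcnt = ndimage.uniform_filter(finite.astype(float), size=window, mode="constant") * n
    full = np.abs(kcnt - n) < 0.5
    mean = ksum / n
    var = np.maximum(ksq - n * mean * mean, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.sqrt(var) / mean
    cv[~full] = np.nan
    half = window // 2
    cv[:half, :] = np.nan
    cv[-half:, :] = np.nan
    cv[:, :half] = np.nan
    cv[:, -half:] = np.nan
    return cv


def _pure_neighbourhood(types: np.ndarray, window: int = 3) -> np.ndarray:
    """True where every pixel in the window shares the centre's class."""
    half = window // 2
    out = np.zeros(types.shape, dtype=bool)
    core = np.ones(types.shape, dtype=bool)
    for dr in range(-half, half + 1):
        for dc in range(-half, half + 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(np.roll(types, dr, axis=0), dc, axis=1)
            core &= shifted == types
    out[half:-half, half:-half] = core[half:-half, half:-half]
    return out


def eligibility_mask(landscape: LandscapeBundle, config: SamplingConfig) -> np.ndarray:
    """Boolean raster of pixels passing all four eligibility filters.

    (a) treed forest type; (b) all window neighbours share the forest
    type; (c) windowed CV of canopy cover AND canopy height strictly
    below ``cv_threshold``; (d) undisturbed, or disturbed strictly more
    than ``min_stand_age`` years before the reference year.  Border
    pixels with incomplete windows are ineligible.
    """
    if config.window > min(landscape.shape):
        raise ValueError("window larger than the raster")
    treed = landscape.treed_mask
    pure = _pure_neighbourhood(landscape.forest_type, config.window)
    cv_cover = window_cv(landscape.structure["canopy_cover"], config.window)
    cv_height = window_cv(landscape.structure["canopy_height"], config.window)
    with np.errstate(invalid="ignore"):
        homogeneous = (cv_cover < config.cv_threshold) & (cv_height < config.cv_threshold)
    dist = landscape.disturbance_year
    age_ok = (dist == NEVER_DISTURBED) | (config.reference_year - dist > config.min_stand_age)
    return treed & pure & homogeneous & age_ok


class _SpacingIndex:
    """Grid-hash accept/reject for a global minimum pairwise distance."""

    def __init__(self, min_distance: float):
        self.d = float(min_distance)
        self.cells: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def accepts(self, x: float, y: float) -> bool:
        if self.d <= 0:
            return True
        ci, cj = int(x // self.d), int(y // self.d)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for px, py in self.cells.get((ci + di, cj + dj), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < self.d * self.d:
                        return False
        return True

    def add(self, x: float, y: float) -> None:
        if self.d <= 0:
            return
        self.cells.setdefault((int(x // self.d), int(y // self.d)), []).append((x, y))


def draw_sample(
    landscape: LandscapeBundle,
    dhis: DHILayers,
    config: SamplingConfig,
    eligible: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw the stratified, distance-thinned sample and extract attributes.

    Strata are zone x forest-type combinations, visited in sorted order;
    within a stratum, eligible pixels are visited in seeded random order
    and accepted greedily if at least ``min_distance`` metres from every
    already-accepted pixel (across all strata when ``global_spacing``),
    stopping at the per-stratum cap.  Pixels whose DHIs are nodata are
    excluded up front so the table carries no missing attribute values.
    """
    if eligible is None:
        eligible = eligibility_mask(landscape, config)
    eligible = eligible & dhis.valid & np.isfinite(dhis.variation)
    if not eligible.any():
        raise ValueError("no eligible pixels in any stratum")
    rng = substream(config.seed, "sampling")

    strata = sorted(
        {(int(z), int(t)) for z, t in
         zip(landscape.zones[eligible], landscape.forest_type[eligible])}
    )
    all_strata = {
        (int(z), int(t))
        for z in np.unique(landscape.zones)
        for t in np.unique(landscape.forest_type) if t in TREED_CODES
    }
    for empty in sorted(all_strata - set(strata)):
        log.info("stratum zone=%d type=%d has no eligible pixels", *empty)

    index = _SpacingIndex(config.min_distance)
    rows_out: list[tuple] = []
    for zone, ftype in strata:
        sel = eligible & (landscape.zones == zone) & (landscape.forest_type == ftype)
        rr, cc = np.nonzero(sel)
        order = rng.permutation(len(rr))
        if not config.global_spacing:
            index = _SpacingIndex(config.min_distance)
        taken = 0
        for k in order:
            if taken >= config.cap:
                break
            r, c = int(rr[k]), int(cc[k])
            x, y = landscape.pixel_xy(np.array(r), np.array(c))
            x, y = float(x), float(y)
            if not index.accepts(x, y):
                continue
            index.add(x, y)
            taken += 1
            rows_out.append(
                (r, c, x, y, zone, ftype)
                + tuple(float(landscape.structure[a][r, c]) for a in STRUCTURE_ATTRS)
                + (float(dhis.cumulative[r, c]), float(dhis.minimum[r, c]),
                   float(dhis.variation[r, c]))
            )
    table = pd.DataFrame(rows_out, columns=list(SAMPLE_COLUMNS))
    table.attrs["config"] = config
    return table
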