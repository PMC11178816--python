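"""Synthetic-year compositing: QA-filtered scenes to monthly median NDVI.

A multi-year, irregular series of (red, NIR, QA) scenes is summarized into
a *synthetic year*: for each pixel and each calendar month, the median of
every unmasked NDVI observation of that month across all years, the year
of acquisition being disregarded.  Months with no valid observation at a
pixel are flagged invalid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .landscape import Scene, SceneSeries

__all__ = ["SyntheticYear", "compute_ndvi", "build_synthetic_year"]

log = logging.getLogger(__name__)


@dataclass
class SyntheticYear:
    """12 monthly median NDVI bands plus a per-month validity mask.

    ``ndvi[i]`` is the median NDVI of calendar month i+1; NaN where
    ``valid[i]`` is False (no unmasked observation).
    """

    ndvi: np.ndarray   # (12, rows, cols), NaN where invalid
    valid: np.ndarray  # (12, rows, cols) bool

    @property
    def complete(self) -> np.ndarray:
        """Pixels with a valid median for all 12 months."""
        return self.valid.all(axis=0)


def compute_ndvi(scene: Scene) -> np.ndarray:
    """Per-pixel (NIR - red)/(NIR + red); QA-masked pixels become NaN.

    Pixels where red + NIR == 0 are undefined and set to NaN; their count
    is reported through the module logger.
    """
    red = np.asarray(scene.red, dtype=np.float64)
    nir = np.asarray(scene.nir, dtype=np.float64)
    denom = nir + red
    bad_denom = denom == 0
    n_bad = int(bad_denom.sum())
    if n_bad:
        log.warning("scene %04d-%02d: %d pixels with red+NIR == 0 set to nodata",
                    scene.year, scene.month, n_bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(bad_denom, np.nan, (nir - red) / np.where(bad_denom, 1.0, denom))
    ndvi[scene.qa != Scene.QA_VALID] = np.nan
    return ndvi


def build_synthetic_year(series: SceneSeries, gapfill: str | None = None) -> SyntheticYear:
    """Median-composite a scene series into the 12-month synthetic year.

    Parameters
    ----------
    series : SceneSeries
        Co-registered scenes; every calendar month must be represented by
        at least one scene somewhere in the series.
    gapfill : {None, "linear"}
        With ``"linear"``, pixels that have at least one valid month get
        their invalid months filled by circular linear interpolation
        across the month axis (and are marked valid).  The default leaves
        gaps as nodata; downstream DHI computation then skips those
        pixels, which makes the gap-free-composite assumption explicit.
    """
    scenes = list(series)
    if not scenes:
        raise ValueError("scene series is empty")
    months_present = {sc.month for sc in scenes}
    missing = sorted(set(range(1, 13)) - months_present)
    if missing:
        raise ValueError(
            f"cannot form a 12-month synthetic year: no scenes for months {missing}"
        )
    shape = scenes[0].red.shape
    ndvi = np.full((12,) + shape, np.nan)
    valid = np.zeros((12,) + shape, dtype=bool)
    for month in range(1, 13):
        obs = [compute_ndvi(sc) for sc in scenes if sc.month == month]
        stack = np.stack(obs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            med = np.nanmedian(stack, axis=0)
        has_obs = np.isfinite(stack).any(axis=0)
        ndvi[month - 1] = np.where(has_obs, med, np.nan)
        valid[month - 1] = has_obs

    if gapfill == "linear":
        ndvi, valid = _gapfill_circular(ndvi, valid)
    elif gapfill is not None:
        raise ValueError(f"unknown gapfill mode {gapfill!r}")
    return SyntheticYear(ndvi=ndvi, valid=valid)


def _gapfill_circular(ndvi: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Circular linear interpolation across months for partially valid pixels."""
    out = ndvi.copy()
    newvalid = valid.copy()
    n_valid = valid.sum(axis=0)
    fill_px = np.argwhere((n_valid > 0) & (n_valid < 12))
    months = np.arange(12)
    for r, c in fill_px:
        good = valid[:, r, c]
        mg = months[good]
        # wrap the month axis so interpolation crosses the Dec->Jan seam
        xp = np.concatenate([mg, mg + 12, mg + 24])
        fp = np.tile(ndvi[good, r, c], 3)
        out[~good, r, c] = np.interp(months[~good] + 12, xp, fp)
        newvalid[:, r, c] = True
    return out, newvalid
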