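"""Dynamic Habitat Indices from a synthetic year of monthly NDVI.

Three intra-annual productivity summaries per pixel, each grounded in a
species-energy hypothesis:

* cumulative DHI — sum of the 12 monthly values (available energy),
* minimum DHI — minimum of the 12 monthly values (environmental stress),
* variation DHI — coefficient of variation sd(x)/mean(x) of the 12
  monthly values (environmental stability).

Negative monthly NDVI (snow scenes) is legitimate and flows into the
cumulative and minimum indices; only the CV is guarded, since it loses
meaning when the monthly mean is zero and flips sign when negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .compositing import SyntheticYear

__all__ = ["DHILayers", "compute_dhis"]

log = logging.getLogger(__name__)


@dataclass
class DHILayers:
    """The three DHI rasters plus bookkeeping masks.

    ``valid`` marks pixels where all 12 months had data (or were
    gap-filled); everything else is NaN.  ``negative_mean`` flags pixels
    whose monthly mean is negative: their CV is computed but its sign is
    ambiguous.
    """

    cumulative: np.ndarray
    minimum: np.ndarray
    variation: np.ndarray
    valid: np.ndarray
    negative_mean: np.ndarray

    def stack(self) -> np.ndarray:
        return np.stack([self.cumulative, self.minimum, self.variation])


def compute_dhis(year: SyntheticYear, ddof: int = 1) -> DHILayers:
    """Compute the three DHIs over pixels with a complete synthetic year.

    Parameters
    ----------
    year : SyntheticYear
        12 monthly median NDVI bands with validity mask.
    ddof : int
        Delta degrees of freedom of the standard deviation in the
        variation DHI; 1 (sample sd) by default.
    """
    complete = year.complete
    x = np.where(complete[None], year.ndvi, np.nan)
    with np.errstate(invalid="ignore"):
        cumulative = x.sum(axis=0)
        minimum = x.min(axis=0)
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=ddof)
        variation = np.where(mean != 0, sd / np.where(mean == 0, 1.0, mean), np.nan)
    zero_mean = complete & (mean == 0)
    n_zero = int(zero_mean.sum())
    if n_zero:
        log.warning("variation DHI undefined at %d pixels with zero monthly mean", n_zero)
    negative_mean = complete & (mean < 0)
    n_neg = int(negative_mean.sum())
    if n_neg:
        log.warning("variation DHI sign-ambiguous at %d pixels with negative monthly mean",
                    n_neg)
    return DHILayers(
        cumulative=cumulative,
        minimum=minimum,
        variation=variation,
        valid=complete,
        negative_mean=negative_mean,
    )
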