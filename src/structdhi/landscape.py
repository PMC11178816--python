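"""Synthetic landscape, scene-series and direct-sample generators.

Every downstream stage of the pipeline (compositing, DHIs, sampling,
ordination) is exercised on data produced here, with a *known*
structure-to-productivity coupling so that recovery of variance explained
can be checked against an analytic ground truth.

Two generation modes share one coupling model.  Writing ``X`` for the
column-standardized structure attributes, ``B`` for the coupling matrix
and ``E`` for iid Gaussian noise with per-response standard deviations
``noise_sd``, the latent response signal is always

    S = X B + E.

* In *direct mode* (:func:`generate_direct_sample`) the rows of ``S`` are
  emitted as a plain sample table: predictors are independent standard
  normals, so the population fraction of response variance explained is
  the closed form of :func:`true_variance_explained`.
* In *raster mode* (:func:`generate_scene_series`) the first two columns
  of ``S`` perturb the per-pixel seasonal NDVI curve (column 0 shifts the
  growing-season baseline, column 1 the seasonal amplitude, both scaled
  by ``phenology_scale``); reflectance scenes are back-solved from the
  resulting NDVI so the full raster pipeline carries the same ground
  truth, up to compositing and sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "STRUCTURE_ATTRS",
    "PRIMARY_ATTRS",
    "MODELLED_ATTRS",
    "DHI_NAMES",
    "FOREST_TYPES",
    "TREED_CODES",
    "NEVER_DISTURBED",
    "SeasonalParams",
    "CouplingSpec",
    "LandscapeBundle",
    "Scene",
    "SceneSeries",
    "coupling_for_r2",
    "generate_landscape",
    "generate_scene_series",
    "generate_direct_sample",
    "structure_covariance",
    "true_variance_explained",
]

#: the six structure attributes, in canonical band order
STRUCTURE_ATTRS = (
    "canopy_height",          # m, 95th percentile of return heights
    "canopy_cover",           # %, proportion of returns above 2 m
    "structural_complexity",  # unitless CV of return heights
    "basal_area",             # m2/ha
    "aboveground_biomass",    # t/ha
    "stem_volume",            # m3/ha
)
#: attributes measured directly from lidar returns
PRIMARY_ATTRS = STRUCTURE_ATTRS[:3]
#: attributes allometrically modelled from lidar plus ancillary data
MODELLED_ATTRS = STRUCTURE_ATTRS[3:]

#: response columns, canonical order (cumulative, minimum, variation DHI)
DHI_NAMES = ("dhi_cum", "dhi_min", "dhi_var")

#: forest-type raster codes; 0 is the non-treed background
FOREST_TYPES = {
    0: "non_treed",
    1: "coniferous",
    2: "broadleaf",
    3: "mixedwood",
    4: "wetland_treed",
}
TREED_CODES = (1, 2, 3, 4)

#: disturbance-year sentinel for never-disturbed pixels
NEVER_DISTURBED = 0

# marginal loadings of each attribute on the shared latent productivity
# field; pairwise correlation of attributes j,k is w_j*w_k by construction
_LATENT_WEIGHTS = {
    "canopy_height": 0.85,
    "canopy_cover": 0.80,
    "structural_complexity": -0.45,
    "basal_area": 0.88,
    "aboveground_biomass": 0.90,
    "stem_volume": 0.92,
}

# per-attribute marginal median / log-scale sd / upper clip (units as
# above).  Attributes are log-normal: right-skewed with local variability
# proportional to level, as in imputed structure products — this is also
# what makes the ln transform the natural analysis scale
_ATTR_SCALES = {
    "canopy_height": (18.0, 0.45, None),
    "canopy_cover": (55.0, 0.30, 100.0),
    "structural_complexity": (0.55, 0.40, None),
    "basal_area": (28.0, 0.50, None),
    "aboveground_biomass": (140.0, 0.55, None),
    "stem_volume": (230.0, 0.60, None),
}

# substream labels: all randomness flows from the root seed through these
_STREAMS = {"landscape": 1, "scenes": 2, "sampling": 3, "direct": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name]]))


@dataclass(frozen=True)
class SeasonalParams:
    """Per-forest-type seasonal NDVI curve: sinusoid clamped below by a floor.

    ``ndvi(m) = max(baseline + amplitude * cos(2*pi*(m - peak_month)/12), floor)``

    The winter floor models the reflectance of a snow-covered scene; it is
    lowered further for colder (higher-index) zones via
    ``CouplingSpec.zone_floor_step``, so minimum DHI can decouple from the
    canopy signal in cold zones.
    """

    baseline: float
    amplitude: float
    peak_month: float = 7.0
    winter_floor: float = 0.1


def _default_seasonal() -> dict[int, SeasonalParams]:
    return {
        0: SeasonalParams(0.25, 0.15, 7.0, 0.02),
        1: SeasonalParams(0.50, 0.42, 7.0, 0.12),   # coniferous
        2: SeasonalParams(0.42, 0.45, 7.0, 0.08),   # broadleaf
        3: SeasonalParams(0.46, 0.44, 7.0, 0.10),   # mixedwood
        4: SeasonalParams(0.40, 0.40, 7.0, 0.06),   # wetland-treed
    }


def _default_coupling() -> np.ndarray:
    # moderate default coupling: population variance explained ~0.3 per
    # response channel under independent predictors
    return coupling_for_r2(0.3, p=6, q=3)


@dataclass
class CouplingSpec:
    """Full parameterization of the synthetic generators.

    Parameters
    ----------
    grid_rows, grid_cols : int
        Raster dimensions; at least 9 in each direction so 3x3 windows fit.
    pixel_size : float
        Pixel edge length in metres (projected CRS).
    n_zones : int
        Number of climatic zones; laid out as contiguous vertical strips,
        higher index = colder.
    forest_type_probs : tuple of 4 floats
        Landscape proportions of the treed classes (coniferous, broadleaf,
        mixedwood, wetland-treed).  Together with ``non_treed_prob`` they
        must sum to 1.
    coupling_matrix : (p, q) ndarray
        Maps standardized structure to the latent response signal.
    noise_sd : tuple of q floats
        Residual standard deviation of each response channel.
    phenology_scale : float
        NDVI units per unit of latent signal when perturbing the seasonal
        curve in raster mode.
    obs_noise_sd : float
        Per-scene NDVI observation noise (atmosphere/sensor proxy).
    cloud_prob : float
        Independent per-pixel, per-scene probability of a cloud/shadow QA
        flag.
    disturbance_frac : float
        Fraction of pixels assigned a disturbance year, uniform over the
        50 years up to ``reference_year``.
    zone_floor_step : float
        How much lower the winter NDVI floor sits per zone index step.
    """

    grid_rows: int = 200
    grid_cols: int = 200
    pixel_size: float = 30.0
    n_zones: int = 4
    forest_type_probs: tuple[float, float, float, float] = (0.50, 0.18, 0.10, 0.07)
    non_treed_prob: float = 0.15
    coupling_matrix: np.ndarray = field(default_factory=_default_coupling)
    noise_sd: tuple[float, ...] = (1.0, 1.0, 1.0)
    seasonal_params: dict[int, SeasonalParams] = field(default_factory=_default_seasonal)
    phenology_scale: float = 0.05
    obs_noise_sd: float = 0.02
    cloud_prob: float = 0.15
    disturbance_frac: float = 0.15
    reference_year: int = 2015
    zone_floor_step: float = 0.08
    latent_weights: tuple[float, ...] = tuple(_LATENT_WEIGHTS[a] for a in STRUCTURE_ATTRS)
    smooth_sigma: float = 3.0
    noise_smooth_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.coupling_matrix = np.asarray(self.coupling_matrix, dtype=float)
        if self.coupling_matrix.ndim != 2:
            raise ValueError("coupling_matrix must be 2-D (p x q)")
        self.validate()

    @property
    def n_predictors(self) -> int:
        return self.coupling_matrix.shape[0]

    @property
    def n_responses(self) -> int:
        return self.coupling_matrix.shape[1]

    def validate(self) -> None:
        total = sum(self.forest_type_probs) + self.non_treed_prob
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"forest_type_probs plus non_treed_prob must sum to 1, got {total!r}"
            )
        if len(self.forest_type_probs) != 4:
            raise ValueError("exactly 4 treed forest-type proportions required")
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd entries must be >= 0")
        if len(self.noise_sd) != self.n_responses:
            raise ValueError("noise_sd length must match coupling_matrix columns")
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise ValueError("cloud_prob must lie in [0, 1]")
        if min(self.grid_rows, self.grid_cols) < 9:
            raise ValueError("grid dimensions must be >= 9 (room for 3x3 windows)")
        if not 0.0 <= self.disturbance_frac <= 1.0:
            raise ValueError("disturbance_frac must lie in [0, 1]")


@dataclass
class LandscapeBundle:
    """Co-registered rasters: structure bands, zones, forest type, disturbance.

    Float structure bands use NaN as the nodata sentinel (non-treed
    pixels); integer rasters use ``NEVER_DISTURBED`` (0) for the
    disturbance-year sentinel.  ``x_origin``/``y_origin`` are the
    coordinates of the top-left corner; rows run southwards.
    """

    structure: dict[str, np.ndarray]
    zones: np.ndarray
    forest_type: np.ndarray
    disturbance_year: np.ndarray
    pixel_size: float
    x_origin: float = 0.0
    y_origin: float = 0.0
    crs: str = "EPSG:3005"

    @property
    def shape(self) -> tuple[int, int]:
        return self.forest_type.shape

    @property
    def treed_mask(self) -> np.ndarray:
        return np.isin(self.forest_type, TREED_CODES)

    def pixel_xy(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Projected centre coordinates (m) of pixel (row, col)."""
        x = self.x_origin + (np.asarray(cols) + 0.5) * self.pixel_size
        y = self.y_origin - (np.asarray(rows) + 0.5) * self.pixel_size
        return x, y


@dataclass
class Scene:
    """One acquisition: red/NIR reflectance plus a 3-level QA code.

    QA codes: 0 = valid, 1 = cloud or shadow, 2 = out of range.
    """

    year: int
    month: int
    red: np.ndarray
    nir: np.ndarray
    qa: np.ndarray

    QA_VALID = 0
    QA_CLOUD = 1
    QA_RANGE = 2


@dataclass
class SceneSeries:
    """Ordered, co-registered scenes spanning the ten-year window."""

    scenes: list[Scene]

    def __iter__(self):
        return iter(self.scenes)

    def __len__(self) -> int:
        return len(self.scenes)


# ---------------------------------------------------------------------------
# coupling helpers


def structure_covariance(spec: CouplingSpec) -> np.ndarray:
    """Theoretical correlation matrix of the standardized structure bands.

    Follows from the single shared latent field: corr(j, k) = w_j * w_k
    for j != k, 1 on the diagonal.
    """
    w = np.asarray(spec.latent_weights, dtype=float)
    cov = np.outer(w, w)
    np.fill_diagonal(cov, 1.0)
    return cov


def coupling_for_r2(
    target_r2: float,
    p: int = 6,
    q: int = 3,
    noise_sd: float | Sequence[float] = 1.0,
    cov: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic coupling matrix with a prescribed variance explained.

    Each response column j gets a coefficient vector b_j satisfying
    ``b_j' C b_j / (b_j' C b_j + sd_j^2) = target_r2`` where ``C`` is the
    predictor covariance (identity for direct mode).  The columns are
    C-orthogonal, so *any* linear mixture of the response channels has
    the same population variance explained — which makes the analytic
    ground truth invariant to how the DHIs mix the phenology channels.
    """
    if not 0.0 <= target_r2 < 1.0:
        raise ValueError("target_r2 must lie in [0, 1)")
    C = np.eye(p) if cov is None else np.asarray(cov, dtype=float)
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (q,))
    if target_r2 == 0.0:
        return np.zeros((p, q))
    if q > p:
        raise ValueError("cannot build more C-orthogonal channels than predictors")
    # deterministic DCT-II seed directions (mutually independent), then
    # Gram-Schmidt in the C inner product so the channels carry
    # independent signal
    j = np.arange(p)[:, None]
    k = np.arange(q)[None, :]
    base = np.cos(np.pi * (2 * j + 1) * k / (2 * p))
    B = np.zeros((p, q))
    for k in range(q):
        v = base[:, k].copy()
        for m in range(k):
            v -= (B[:, m] @ C @ v) / (B[:, m] @ C @ B[:, m]) * B[:, m]
        signal_var = v @ C @ v
        if signal_var <= 0:
            raise ValueError("degenerate predictor covariance")
        want = target_r2 / (1.0 - target_r2) * sd[k] ** 2
        B[:, k] = v * math.sqrt(want / signal_var)
    return B


def true_variance_explained(spec: CouplingSpec, cov: np.ndarray | None = None) -> float:
    """Population fraction of standardized response variance explained.

    Mean over responses j of ``b_j' C b_j / (b_j' C b_j + sigma_j^2)``
    with ``C`` the predictor covariance (identity by default, matching
    the independent-predictor direct mode).
    """
    B = spec.coupling_matrix
    sd = np.asarray(spec.noise_sd, dtype=float)
    C = np.eye(B.shape[0]) if cov is None else np.asarray(cov, dtype=float)
    signal = np.einsum("jk,jl,lk->k", B, C, B)
    if np.all(signal == 0) and np.all(sd == 0):
        raise ValueError("all-zero coupling and all-zero noise: fraction undefined")
    return float(np.mean(signal / (signal + sd**2)))


# ---------------------------------------------------------------------------
# landscape generation


def _majority_smooth(types: np.ndarray, n_classes: int) -> np.ndarray:
    """One 3x3 majority pass; ties keep the centre pixel's class."""
    padded = np.pad(types, 1, mode="edge")
    rows, cols = types.shape
    counts = np.zeros((n_classes, rows, cols), dtype=np.int8)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            win = padded[1 + dr : 1 + dr + rows, 1 + dc : 1 + dc + cols]
            for c in range(n_classes):
                counts[c] += win == c
    best = counts.argmax(axis=0)
    best_count = counts.max(axis=0)
    centre_count = np.take_along_axis(counts, types[None].astype(np.intp), axis=0)[0]
    keep_centre = centre_count == best_count
    return np.where(keep_centre, types, best).astype(types.dtype)


def generate_landscape(spec: CouplingSpec) -> LandscapeBundle:
    """Generate a co-registered landscape bundle from the spec.

    Zones are contiguous vertical strips.  Forest types are drawn iid per
    pixel and majority-smoothed once so pure 3x3 neighbourhoods exist.
    The six structure bands share a spatially smooth latent productivity
    field plus independent noise, making the modelled attributes mutually
    correlated (pairwise r >= ~0.7 at default weights).  Non-treed pixels
    carry NaN in the structure bands.
    """
    spec.validate()
    rows, cols = spec.grid_rows, spec.grid_cols
    if cols < spec.n_zones * 3:
        raise ValueError(
            f"grid of {cols} columns too small for {spec.n_zones} zones "
            "(need >= 3 columns per zone)"
        )
    rng = substream(spec.seed, "landscape")

    # zones: vertical strips, equal width up to remainder
    edges = np.linspace(0, cols, spec.n_zones + 1).astype(int)
    zones = np.zeros((rows, cols), dtype=np.int16)
    for z in range(spec.n_zones):
        zones[:, edges[z] : edges[z + 1]] = z

    # forest types: iid categorical then one majority-smoothing pass
    probs = np.array([spec.non_treed_prob, *spec.forest_type_probs])
    types = rng.choice(len(probs), size=(rows, cols), p=probs).astype(np.int8)
    types = _majority_smooth(types, len(probs))

    # shared latent productivity field, unit variance after smoothing
    latent = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), spec.smooth_sigma)
    latent = (latent - latent.mean()) / latent.std()

    treed = np.isin(types, TREED_CODES)
    structure: dict[str, np.ndarray] = {}
    for name, w in zip(STRUCTURE_ATTRS, spec.latent_weights):
        # attribute-specific noise is itself spatially smooth: imputed
        # structure rasters vary gradually, not pixel-to-pixel
        eps = rng.standard_normal((rows, cols))
        if spec.noise_smooth_sigma > 0:
            eps = ndimage.gaussian_filter(eps, spec.noise_smooth_sigma)
            eps = (eps - eps.mean()) / eps.std()
        z = w * latent + math.sqrt(max(0.0, 1.0 - w * w)) * eps
        median, log_sd, hi = _ATTR_SCALES[name]
        band = median * np.exp(log_sd * z)
        if hi is not None:
            band = np.minimum(band, hi)
        band[~treed] = np.nan
        structure[name] = band

    disturbance = np.full((rows, cols), NEVER_DISTURBED, dtype=np.int32)
    n_dist = int(round(spec.disturbance_frac * rows * cols))
    if n_dist > 0:
        flat = rng.choice(rows * cols, size=n_dist, replace=False)
        years = rng.integers(spec.reference_year - 49, spec.reference_year + 1, size=n_dist)
        disturbance.ravel()[flat] = years

    return LandscapeBundle(
        structure=structure,
        zones=zones,
        forest_type=types,
        disturbance_year=disturbance,
        pixel_size=spec.pixel_size,
    )


# ---------------------------------------------------------------------------
# phenology + scenes


def standardized_structure(landscape: LandscapeBundle, log: bool = True) -> np.ndarray:
    """Stack of the six structure bands z-scored over treed pixels.

    By default the z-score is taken on the ln(1 + x) scale: structure
    effects on productivity are treated as proportional rather than
    absolute, which also matches the ln-z standardization applied before
    ordination, so the coupled signal stays linear end to end.  Non-treed
    pixels come out as 0 (they carry no coupling signal).
    """
    treed = landscape.treed_mask
    out = np.zeros((len(STRUCTURE_ATTRS),) + landscape.shape)
    for i, name in enumerate(STRUCTURE_ATTRS):
        band = landscape.structure[name]
        if log:
            band = np.log1p(band)
        vals = band[treed]
        sd = vals.std()
        if sd == 0:
            continue
        z = (band - vals.mean()) / sd
        out[i] = np.where(treed, z, 0.0)
    return out


def empirical_structure_covariance(spec: CouplingSpec, log: bool = True) -> np.ndarray:
    """Monte-Carlo correlation matrix of the (log-scale) standardized bands.

    Generates one landscape from the spec and measures the correlation of
    the standardized structure stack over treed pixels.  Used to
    construct couplings whose population variance explained is exact on
    the scale the ordination analyzes (the analytic ``wwᵀ`` form of
    :func:`structure_covariance` holds on the raw scale only).
    """
    land = generate_landscape(spec)
    Z = standardized_structure(land, log=log)
    treed = land.treed_mask
    return np.corrcoef(np.stack([Z[i][treed] for i in range(Z.shape[0])]))


def phenology_fields(
    landscape: LandscapeBundle, spec: CouplingSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (baseline, amplitude, peak month, floor) of the NDVI curve.

    baseline/amplitude = forest-type defaults shifted by the coupled
    latent signal (X B + E, scaled to NDVI units); the winter floor drops
    with zone index to emulate longer snow cover in colder zones.
    """
    rows, cols = landscape.shape
    base = np.empty((rows, cols))
    amp = np.empty((rows, cols))
    peak = np.empty((rows, cols))
    floor = np.empty((rows, cols))
    for code, par in spec.seasonal_params.items():
        sel = landscape.forest_type == code
        base[sel] = par.baseline
        amp[sel] = par.amplitude
        peak[sel] = par.peak_month
        floor[sel] = par.winter_floor
    floor -= spec.zone_floor_step * landscape.zones

    Z = standardized_structure(landscape)  # (6, rows, cols)
    B = spec.coupling_matrix
    sd = np.asarray(spec.noise_sd, dtype=float)
    n_chan = min(2, B.shape[1])
    for chan in range(n_chan):
        signal = np.tensordot(B[:, chan], Z, axes=1)
        signal = signal + sd[chan] * rng.standard_normal((rows, cols))
        if chan == 0:
            base = base + spec.phenology_scale * signal
        else:
            amp = amp + spec.phenology_scale * signal
    return base, amp, peak, floor


def seasonal_ndvi(
    month: float,
    base: np.ndarray,
    amp: np.ndarray,
    peak: np.ndarray,
    floor: np.ndarray,
) -> np.ndarray:
    """Evaluate the clamped sinusoid at a (fractional) month."""
    curve = base + amp * np.cos(2.0 * np.pi * (month - peak) / 12.0)
    return np.clip(np.maximum(curve, floor), -1.0, 1.0)


def generate_scene_series(landscape: LandscapeBundle, spec: CouplingSpec) -> SceneSeries:
    """Ten years of monthly mid-month scenes co-registered with the landscape.

    True NDVI follows each pixel's coupled seasonal curve; observation
    noise is added, the result clamped to [-1, 1], and red/NIR are
    back-solved under a constant brightness red+NIR = 0.5 so recomputing
    (NIR - red)/(NIR + red) returns the noisy NDVI exactly.  QA flags are
    planted independently per pixel per scene with ``cloud_prob``.
    """
    rng = substream(spec.seed, "scenes")
    base, amp, peak, floor = phenology_fields(landscape, spec, rng)
    years = range(spec.reference_year - 4, spec.reference_year + 6)  # 10-year window
    scenes = []
    shape = landscape.shape
    for year in years:
        for month in range(1, 13):
            ndvi = seasonal_ndvi(float(month), base, amp, peak, floor)
            if spec.obs_noise_sd > 0:
                ndvi = ndvi + spec.obs_noise_sd * rng.standard_normal(shape)
            ndvi = np.clip(ndvi, -1.0, 1.0)
            total = 0.5  # red + NIR brightness; keeps both bands in [0, 0.5]
            nir = total * (1.0 + ndvi) / 2.0
            red = total - nir
            if spec.cloud_prob > 0:
                qa = (rng.random(shape) < spec.cloud_prob).astype(np.uint8) * Scene.QA_CLOUD
            else:
                qa = np.zeros(shape, dtype=np.uint8)
            scenes.append(Scene(year=year, month=month, red=red, nir=nir, qa=qa))
    return SceneSeries(scenes)


# ---------------------------------------------------------------------------
# direct mode


def generate_direct_sample(spec: CouplingSpec, n: int) -> pd.DataFrame:
    """Analytic test harness: emit Y = X B + E as a flat sample table.

    Predictors are independent standard normals named after the structure
    attributes (or ``x<i>`` beyond six); responses are named after the
    DHIs (or ``y<i>`` beyond three).  ``df.attrs['true_variance_explained']``
    carries the closed-form ground truth.
    """
    if n < 10:
        raise ValueError(f"direct sample needs n >= 10, got {n}")
    rng = substream(spec.seed, "direct")
    p, q = spec.coupling_matrix.shape
    X = rng.standard_normal((n, p))
    E = rng.standard_normal((n, q)) * np.asarray(spec.noise_sd, dtype=float)
    Y = X @ spec.coupling_matrix + E
    xnames = [STRUCTURE_ATTRS[i] if i < 6 else f"x{i}" for i in range(p)]
    ynames = [DHI_NAMES[i] if i < 3 else f"y{i}" for i in range(q)]
    df = pd.DataFrame(np.hstack([X, Y]), columns=xnames + ynames)
    df.attrs["true_variance_explained"] = true_variance_explained(spec)
    df.attrs["predictors"] = xnames
    df.attrs["responses"] = ynames
    return df


# ---------------------------------------------------------------------------
# raster I/O (plain multiband TIFF + JSON sidecar; see structdhi.raster)


def write_landscape(landscape: LandscapeBundle, path: str | Path) -> None:
    from . import raster

    path = Path(path)
    bands = [landscape.structure[a] for a in STRUCTURE_ATTRS]
    bands += [
        landscape.zones.astype(np.float64),
        landscape.forest_type.astype(np.float64),
        landscape.disturbance_year.astype(np.float64),
    ]
    names = list(STRUCTURE_ATTRS) + ["zones", "forest_type", "disturbance_year"]
    raster.write_raster(
        path,
        np.stack(bands),
        band_names=names,
        pixel_size=landscape.pixel_size,
        x_origin=landscape.x_origin,
        y_origin=landscape.y_origin,
        crs=landscape.crs,
        nodata="nan",
    )


def read_landscape(path: str | Path) -> LandscapeBundle:
    from . import raster

    data, meta = raster.read_raster(path)
    names = meta["band_names"]
    idx = {n: i for i, n in enumerate(names)}
    structure = {a: data[idx[a]] for a in STRUCTURE_ATTRS}
    return LandscapeBundle(
        structure=structure,
        zones=data[idx["zones"]].astype(np.int16),
        forest_type=data[idx["forest_type"]].astype(np.int8),
        disturbance_year=data[idx["disturbance_year"]].astype(np.int32),
        pixel_size=meta["pixel_size"],
        x_origin=meta["x_origin"],
        y_origin=meta["y_origin"],
        crs=meta["crs"],
    )


def write_scene_series(series: SceneSeries, directory: str | Path, *,
                       pixel_size: float, x_origin: float = 0.0,
                       y_origin: float = 0.0, crs: str = "EPSG:3005") -> None:
    from . import raster

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sc in series:
        raster.write_raster(
            directory / f"scene_{sc.year:04d}_{sc.month:02d}.tif",
            np.stack([sc.red, sc.nir, sc.qa.astype(np.float32)]),
            band_names=["red", "nir", "qa"],
            pixel_size=pixel_size,
            x_origin=x_origin,
            y_origin=y_origin,
            crs=crs,
        )


def read_scene_series(directory: str | Path) -> SceneSeries:
    from . import raster

    scenes = []
    for path in sorted(Path(directory).glob("scene_????_??.tif")):
        data, _ = raster.read_raster(path)
        year, month = int(path.stem[6:10]), int(path.stem[11:13])
        scenes.append(
            Scene(year=year, month=month, red=data[0].astype(np.float32),
                  nir=data[1].astype(np.float32), qa=data[2].astype(np.uint8))
        )
    if not scenes:
        raise FileNotFoundError(f"no scene_<YYYY>_<MM>.tif files under {directory}")
    return SceneSeries(scenes)
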