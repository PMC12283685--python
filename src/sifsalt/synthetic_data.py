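"""Synthetic scene generator: fluorescence, salinity and land-use inputs.

Emulates the statistical structure of the three observational inputs the
analysis pipeline consumes, so that every downstream stage can be exercised
and validated without any external archive:

* a CSIF-like fluorescence record: one strictly positive value per site
  every ``cadence_days`` days, built as seasonal sinusoid x land-cover
  baseline x salinity suppression x multiplicative Gamma noise;
* WoSIS-like topsoil (0-10 cm) salinity samples: one georeferenced EC
  observation (dS/m) per site per year, drawn from a spatially correlated
  log-scale field with interannual variability;
* GLC_FCS30D-like land-cover ids per site per year, mostly stable with a
  controllable fraction of single-switch change events.

Salinity suppresses fluorescence multiplicatively through per-class factors
(non-increasing with salinity class).  Sensitivity is assigned at the
1-degree-cell level: in cells flagged insensitive the suppression factor is
replaced by a per-site draw that is independent of the true class, so class
carries no fluorescence signal there (variance-matched null).

Interannual salinity variability is deliberately the dominant component of
the latent EC field: a standardized index referenced to each site's own
climatology can only express drivers that vary within that history, and
observed saline-land extents in arid irrigated basins indeed swing strongly
from year to year.  See the methods note for the full rationale.

Everything is reproducible from ``(SceneConfig, seed)`` alone; the three
public generators draw from independent, fixed substreams so each can be
called on its own and still agree with :func:`generate_scene`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.interpolate import RegularGridInterpolator

from .types import ConfigError, InputError, LC_GROUPS
from .sensitivity_screen import ec_to_class

__all__ = [
    "SceneConfig",
    "SyntheticTruth",
    "Scene",
    "generate_truth",
    "generate_salinity_field",
    "generate_landuse",
    "generate_fluor_series",
    "generate_scene",
    "default_scene_config",
    "typical_training_scenario",
    "shifted_transfer_scenario",
    "trend_cohort_scenario",
]

# Land-cover sampling weights, loosely matching an arid Central-Asian mix
# (grassland/steppe dominant, substantial cropland, little forest).
_LC_POOL: tuple[int, ...] = (130, 10, 20, 150, 120, 11, 61, 153, 181, 184)
_LC_WEIGHTS: tuple[float, ...] = (
    0.30, 0.15, 0.15, 0.12, 0.08, 0.05, 0.05, 0.04, 0.03, 0.03
)

# Mean fluorescence level per land-cover group (CSIF-like relative units).
_LC_BASELINE: dict[str, float] = {
    "rainfed_cropland": 1.00,
    "herbaceous_cover": 0.90,
    "irrigated_cropland": 1.20,
    "forest": 1.10,
    "shrubland": 0.70,
    "grassland": 0.80,
    "sparse_vegetation": 0.45,
    "wetland": 0.95,
}

# Fixed substream keys so each generator is independently reproducible.
_STREAM_SITES = 1
_STREAM_EC = 2
_STREAM_LANDUSE = 3
_STREAM_FLUOR = 4
_STREAM_CELLS = 5


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    The defaults describe the package's reference study conditions:
    2,000 sites on a 10 x 6 degree arid-zone domain observed every 4 days
    over 2000-2020, a uniform five-class salinity mix, 40% of 1-degree
    cells carrying a real salinity-fluorescence signal, and suppression
    factors declining from 1.0 (non-saline) to 0.4 (extremely saline).
    """

    n_sites: int = 2000
    lon_range: tuple[float, float] = (60.0, 70.0)
    lat_range: tuple[float, float] = (40.0, 46.0)
    years: tuple[int, int] = (2000, 2020)
    cadence_days: int = 4
    seasonal_amplitude: float = 0.45
    seasonal_phase: float = 0.54  # fraction of year at which the sinusoid peaks
    suppression_per_class: tuple[float, ...] = (1.0, 0.80, 0.65, 0.50, 0.40)
    noise_shape: float = 50.0  # Gamma shape of multiplicative noise (mean 1)
    frac_landuse_change: float = 0.10
    frac_sensitive_cells: float = 0.40
    seed: int = 0

    # latent EC field -------------------------------------------------------
    class_mix: str = "uniform"  # "uniform" | "lognormal"
    log_ec_mean: float = 1.0  # lognormal mode only
    log_ec_sd: float = 1.2  # lognormal mode only
    spatial_sd: float = 0.30  # persistent between-site latent spread
    temporal_sd: float = 0.95  # interannual within-site latent spread
    correlation_length_deg: float = 0.5
    ec_range: tuple[float, float] = (0.2, 64.0)
    latent_shift: float = 0.0  # additive latent mean shift (saltier domain)
    frac_trend_increasing: float = 0.0
    trend_rate: float = 0.08  # latent s.d. units per year for trending sites

    # behaviour of insensitive cells ---------------------------------------
    insensitive_mode: str = "null"  # "null" | "shifted"
    shift_power: float = 0.5  # suppression ** power in "shifted" mode

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        for name, (lo, hi) in (("lon_range", self.lon_range),
                               ("lat_range", self.lat_range)):
            if not hi > lo:
                raise ConfigError(f"{name} has zero or negative width")
        if self.years[1] < self.years[0]:
            raise ConfigError("years span is empty")
        if not 1 <= self.cadence_days <= 28:
            raise ConfigError(
                "cadence_days must be in [1, 28] so every calendar month "
                "receives at least one observation"
            )
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ConfigError("seasonal_amplitude must lie in [0, 1)")
        supp = self.suppression_per_class
        if len(supp) != 5 or not all(0.0 < s <= 1.0 for s in supp):
            raise ConfigError("suppression_per_class needs 5 factors in (0, 1]")
        if any(a < b for a, b in zip(supp, supp[1:])):
            raise ConfigError(
                "suppression factors must be non-increasing with class"
            )
        for name, frac in (("frac_landuse_change", self.frac_landuse_change),
                           ("frac_sensitive_cells", self.frac_sensitive_cells),
                           ("frac_trend_increasing", self.frac_trend_increasing)):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.noise_shape <= 0:
            raise ConfigError("noise_shape must be positive")
        if self.class_mix not in ("uniform", "lognormal"):
            raise ConfigError(f"unknown class_mix {self.class_mix!r}")
        if self.insensitive_mode not in ("null", "shifted"):
            raise ConfigError(f"unknown insensitive_mode {self.insensitive_mode!r}")
        if not self.ec_range[0] > 0:
            raise ConfigError("ec_range must be strictly positive")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SyntheticTruth:
    """Ground truth of one scene, reproducible from ``(SceneConfig, seed)``.

    ``sites`` has one row per site (coordinates, cell, land-cover
    trajectory, baseline, cell sensitivity flag, trend sign); ``samples``
    one row per (site, year) with the true EC and class; ``cells`` one row
    per 1-degree cell with its true sensitivity flag.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    cells: pd.DataFrame


@dataclass
class Scene:
    """A complete generated scene: truth plus the three observational tables."""

    cfg: SceneConfig
    truth: SyntheticTruth
    samples: pd.DataFrame
    landuse: pd.DataFrame
    fluor: pd.DataFrame


# ---------------------------------------------------------------------------
# latent spatial field
# ---------------------------------------------------------------------------

def _spatial_field(cfg: SceneConfig, lon: np.ndarray,
                   lat: np.ndarray) -> np.ndarray:
    """Standard-normal spatially correlated values at the site positions.

    White noise on a lattice at half the correlation length, smoothed with a
    Gaussian kernel of that length, re-standardized, then interpolated."""
    rng = cfg.rng(_STREAM_SITES + 100)
    spacing = cfg.correlation_length_deg / 2.0
    pad = 4 * cfg.correlation_length_deg
    gx = np.arange(cfg.lon_range[0] - pad, cfg.lon_range[1] + pad + spacing,
                   spacing)
    gy = np.arange(cfg.lat_range[0] - pad, cfg.lat_range[1] + pad + spacing,
                   spacing)
    white = rng.standard_normal((gy.size, gx.size))
    smooth = gaussian_filter(white, sigma=cfg.correlation_length_deg / spacing,
                             mode="reflect")
    smooth /= max(smooth.std(), 1e-12)
    interp = RegularGridInterpolator((gy, gx), smooth, method="linear")
    return interp(np.column_stack([lat, lon]))


def _latent_to_ec(cfg: SceneConfig, u: np.ndarray) -> np.ndarray:
    """Map latent uniforms to EC.  In ``uniform`` mix mode the unit interval
    is split into five equal class bands and EC is log-uniform within each
    band, so the marginal class mix is uniform while the spatial/temporal
    latent structure is preserved monotonically."""
    u = np.clip(u, 1e-9, 1 - 1e-9)
    lows = np.array([cfg.ec_range[0], 2.0, 4.0, 8.0, 16.0])
    highs = np.array([2.0, 4.0, 8.0, 16.0, cfg.ec_range[1]])
    band = np.minimum((u * 5).astype(int), 4)
    frac = u * 5 - band
    return np.exp(np.log(lows[band])
                  + frac * (np.log(highs[band]) - np.log(lows[band])))


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def generate_truth(cfg: SceneConfig) -> SyntheticTruth:
    """Generate the full ground truth for a scene."""
    years = np.array(cfg.year_list)
    n, ny = cfg.n_sites, years.size

    rng_sites = cfg.rng(_STREAM_SITES)
    lon = rng_sites.uniform(*cfg.lon_range, size=n)
    lat = rng_sites.uniform(*cfg.lat_range, size=n)
    cell_lon = np.floor(lon).astype(int)
    cell_lat = np.floor(lat).astype(int)

    # cell sensitivity flags
    rng_cells = cfg.rng(_STREAM_CELLS)
    cx = np.arange(int(np.floor(cfg.lon_range[0])),
                   int(np.ceil(cfg.lon_range[1])))
    cy = np.arange(int(np.floor(cfg.lat_range[0])),
                   int(np.ceil(cfg.lat_range[1])))
    all_cells = [(int(a), int(b)) for a in cx for b in cy]
    order = rng_cells.permutation(len(all_cells))
    k = int(round(cfg.frac_sensitive_cells * len(all_cells)))
    sensitive_cells = {all_cells[i] for i in order[:k]}
    cells = pd.DataFrame(all_cells, columns=["cell_lon", "cell_lat"])
    cells["sensitive"] = [c in sensitive_cells for c in all_cells]
    site_sensitive = np.array(
        [(a, b) in sensitive_cells for a, b in zip(cell_lon, cell_lat)]
    )

    # latent EC field: persistent spatial component + interannual noise
    rng_ec = cfg.rng(_STREAM_EC)
    z_spatial = _spatial_field(cfg, lon, lat)
    z_time = rng_ec.standard_normal((n, ny))
    scale = float(np.hypot(cfg.spatial_sd, cfg.temporal_sd))
    latent = (cfg.spatial_sd * z_spatial[:, None]
              + cfg.temporal_sd * z_time) / max(scale, 1e-12)
    latent = latent + cfg.latent_shift

    trend_sign = (rng_ec.random(n) < cfg.frac_trend_increasing).astype(int)
    if cfg.frac_trend_increasing > 0:
        latent = latent + (trend_sign[:, None] * cfg.trend_rate
                           * (years - years[0])[None, :])

    if cfg.class_mix == "uniform":
        from scipy.stats import norm
        ec = _latent_to_ec(cfg, norm.cdf(latent))
    else:
        ec = np.exp(cfg.log_ec_mean + cfg.log_ec_sd * latent)
        ec = np.clip(ec, cfg.ec_range[0], cfg.ec_range[1])
    clazz = ec_to_class(ec)

    # land-use trajectory: single switch event for the changing fraction
    rng_lu = cfg.rng(_STREAM_LANDUSE)
    lc_id = rng_lu.choice(_LC_POOL, size=n, p=_LC_WEIGHTS)
    changes = rng_lu.random(n) < cfg.frac_landuse_change
    if cfg.years[1] == cfg.years[0]:
        changes[:] = False  # a single-year span has no mid-span switch
    change_year = np.where(
        changes,
        rng_lu.integers(cfg.years[0] + 1, max(cfg.years[1], cfg.years[0] + 1)
                        + 1, size=n),
        -1,
    )
    # switched-to id: a different draw from the pool
    lc_id2 = lc_id.copy()
    if changes.any():
        alt = rng_lu.choice(_LC_POOL, size=int(changes.sum()), p=_LC_WEIGHTS)
        same = alt == lc_id[changes]
        while same.any():
            alt[same] = rng_lu.choice(_LC_POOL, size=int(same.sum()),
                                      p=_LC_WEIGHTS)
            same = alt == lc_id[changes]
        lc_id2[changes] = alt

    group = np.array([LC_GROUPS[i] for i in lc_id])
    baseline = (np.array([_LC_BASELINE[g] for g in group])
                * np.exp(rng_sites.normal(0.0, 0.10, size=n)))

    sites = pd.DataFrame({
        "site_id": np.arange(n),
        "lon": lon, "lat": lat,
        "cell_lon": cell_lon, "cell_lat": cell_lat,
        "lc_id": lc_id, "lc_id_after": lc_id2,
        "change_year": change_year,
        "lc_group": group,
        "baseline": baseline,
        "sensitive": site_sensitive,
        "trend_sign": trend_sign,
    })
    samples = pd.DataFrame({
        "site_id": np.repeat(np.arange(n), ny),
        "year": np.tile(years, n),
        "ec": ec.ravel(),
        "salinity_class": clazz.ravel(),
    })
    return SyntheticTruth(sites=sites, samples=samples, cells=cells)


# ---------------------------------------------------------------------------
# observational tables
# ---------------------------------------------------------------------------

def _landuse_id_at(truth: SyntheticTruth, years: np.ndarray) -> np.ndarray:
    """(n_sites, n_years) land-cover id matrix from the truth trajectory."""
    s = truth.sites
    before = s["lc_id"].to_numpy()[:, None]
    after = s["lc_id_after"].to_numpy()[:, None]
    cy = s["change_year"].to_numpy()[:, None]
    return np.where((cy >= 0) & (years[None, :] >= cy), after, before)


def generate_salinity_field(cfg: SceneConfig,
                            truth: SyntheticTruth | None = None) -> pd.DataFrame:
    """WoSIS-like annual topsoil EC samples.

    One row per (site, year): ``site_id, lon, lat, year, ec_dsm,
    salinity_class, lc_id``.  EC is strictly positive, spatially correlated
    on the log scale, and spans all five classes when the configured class
    mix requests it."""
    if truth is None:
        truth = generate_truth(cfg)
    years = np.array(cfg.year_list)
    lc_mat = _landuse_id_at(truth, years)
    out = truth.samples.copy()
    out = out.rename(columns={"ec": "ec_dsm"})
    s = truth.sites
    out["lon"] = np.repeat(s["lon"].to_numpy(), years.size)
    out["lat"] = np.repeat(s["lat"].to_numpy(), years.size)
    out["lc_id"] = lc_mat.ravel()
    return out[["site_id", "lon", "lat", "year", "ec_dsm",
                "salinity_class", "lc_id"]]


def generate_landuse(cfg: SceneConfig,
                     truth: SyntheticTruth | None = None) -> pd.DataFrame:
    """Land-cover id per site per year (``site_id, year, lc_id``)."""
    if truth is None:
        truth = generate_truth(cfg)
    years = np.array(cfg.year_list)
    lc_mat = _landuse_id_at(truth, years)
    return pd.DataFrame({
        "site_id": np.repeat(truth.sites["site_id"].to_numpy(), years.size),
        "year": np.tile(years, len(truth.sites)),
        "lc_id": lc_mat.ravel(),
    })


def generate_fluor_series(cfg: SceneConfig,
                          truth: SyntheticTruth | None = None) -> pd.DataFrame:
    """CSIF-like fluorescence series for every site.

    Long table ``site_id, date, value`` on the configured cadence.  Values
    are seasonal sinusoid x land-cover baseline x class suppression x
    Gamma(mean 1) multiplicative noise, hence strictly positive.  In
    insensitive cells the class suppression is replaced according to
    ``cfg.insensitive_mode``:

    * ``"null"`` — a per-site constant drawn uniformly from the suppression
      values, independent of the true class (variance-matched null);
    * ``"shifted"`` — ``suppression ** shift_power``, an attenuated but
      real signal, for transfer-learning target scenes.
    """
    if truth is None:
        truth = generate_truth(cfg)
    if len(truth.sites) != cfg.n_sites:
        raise InputError("truth does not match the configuration")
    years = np.array(cfg.year_list)
    n, ny = cfg.n_sites, years.size

    start = np.datetime64(f"{cfg.years[0]}-01-01")
    end = np.datetime64(f"{cfg.years[1] + 1}-01-01")
    dates = np.arange(start, end, np.timedelta64(cfg.cadence_days, "D"))
    nd = dates.size
    date_year = dates.astype("datetime64[Y]").astype(int) + 1970
    year_start = dates.astype("datetime64[Y]").astype("datetime64[D]")
    doy = (dates - year_start).astype(int)
    frac = (doy + 0.5) / 365.25
    seasonal = 1.0 + cfg.seasonal_amplitude * np.sin(
        2 * np.pi * (frac - cfg.seasonal_phase + 0.25)
    )

    supp = np.asarray(cfg.suppression_per_class)
    clazz = truth.samples["salinity_class"].to_numpy().reshape(n, ny)
    factor = supp[clazz]  # (n, ny)
    insens = ~truth.sites["sensitive"].to_numpy()
    rng = cfg.rng(_STREAM_FLUOR)
    if insens.any():
        if cfg.insensitive_mode == "null":
            const = rng.choice(supp, size=int(insens.sum()))
            factor[insens, :] = const[:, None]
        else:  # shifted: attenuated but real signal
            factor[insens, :] = supp[clazz[insens, :]] ** cfg.shift_power

    year_idx = date_year - cfg.years[0]
    fac_obs = factor[:, year_idx]  # (n, nd)
    noise = rng.gamma(cfg.noise_shape, 1.0 / cfg.noise_shape, size=(n, nd))
    baseline = truth.sites["baseline"].to_numpy()
    values = baseline[:, None] * seasonal[None, :] * fac_obs * noise

    return pd.DataFrame({
        "site_id": np.repeat(np.arange(n), nd),
        "date": np.tile(dates, n),
        "value": values.ravel(),
    })


def generate_scene(cfg: SceneConfig) -> Scene:
    """Generate truth plus the three observational tables in one call."""
    truth = generate_truth(cfg)
    return Scene(
        cfg=cfg,
        truth=truth,
        samples=generate_salinity_field(cfg, truth),
        landuse=generate_landuse(cfg, truth),
        fluor=generate_fluor_series(cfg, truth),
    )


# ---------------------------------------------------------------------------
# named scenarios
# ---------------------------------------------------------------------------

def default_scene_config(seed: int = 0) -> SceneConfig:
    """The reference end-to-end scene (2,000 sites x 21 years, 40% of cells
    sensitive)."""
    return SceneConfig(seed=seed)


def typical_training_scenario(seed: int = 0, n_sites: int = 300) -> SceneConfig:
    """A compact all-sensitive scene used to benchmark native per-cell
    classifiers: every cell carries the full salinity-fluorescence signal."""
    return SceneConfig(
        n_sites=n_sites,
        lon_range=(60.0, 62.0),
        lat_range=(40.0, 41.0),
        frac_sensitive_cells=1.0,
        frac_landuse_change=0.0,
        seed=seed,
    )


def shifted_transfer_scenario(seed: int = 0,
                              n_target_sites: int = 150,
                              latent_shift: float = 0.5
                              ) -> tuple[SceneConfig, SceneConfig]:
    """Source and target configurations for the transfer-learning benchmark.

    The target domain is saltier (latent mean shifted by ``latent_shift``
    standard deviations, default one half), which changes the class mix and
    therefore the mapping from standardized-anomaly features to absolute
    class labels — the kind of distribution shift transfer adaptation must
    absorb."""
    src = typical_training_scenario(seed=seed)
    tgt = SceneConfig(
        n_sites=n_target_sites,
        lon_range=(64.0, 65.0),
        lat_range=(40.0, 41.0),
        frac_sensitive_cells=1.0,
        frac_landuse_change=0.0,
        latent_shift=latent_shift,
        seed=seed + 20011,
    )
    return src, tgt


def trend_cohort_scenario(seed: int = 0, n_sites: int = 600,
                          frac_increasing: float = 0.7) -> SceneConfig:
    """A cohort for trend-recovery experiments: a known fraction of sites
    salinize steadily while the rest hold a persistent level.

    Interannual latent noise is reduced relative to the reference scene so
    that "stable" sites are genuinely stable in level — trend detection on a
    class-index series is only well-posed when year-to-year class churn is
    smaller than the planted drift.  The cohort starts on the non-saline
    side (negative latent shift): a salinizing site must have headroom below
    the top class, otherwise its class-index trend is censored."""
    return SceneConfig(
        n_sites=n_sites,
        lon_range=(60.0, 64.0),
        lat_range=(40.0, 42.0),
        spatial_sd=0.45,
        temporal_sd=0.20,
        latent_shift=-0.8,
        frac_trend_increasing=frac_increasing,
        trend_rate=0.10,
        frac_landuse_change=0.0,
        seed=seed,
    )
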