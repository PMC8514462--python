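"""FAOSTAT-like synthetic data with known ground truth for every stage.

Each synthetic country has a piecewise-linear richness trajectory (two
breakpoints, three segment slopes), a geometric rank-abundance profile whose
decay parameter follows a configurable schedule (controlling Pielou
evenness), an absolute latitude tied to a quadratic richness gradient, and a
continent/region/HDI structure for the mixed models.  All randomness flows
from the single config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "EvennessSchedule",
    "CountryTruth",
    "SyntheticConfig",
    "piecewise_mean",
    "geometric_proportions",
    "evenness_of_theta",
    "generate_country_series",
    "generate_dataset",
    "latitude_gradient_sample",
    "nested_design_sample",
    "to_faostat_csv",
]


@dataclass(frozen=True)
class EvennessSchedule:
    """Linear ramp of the geometric rank-abundance decay parameter.

    ``theta = 1`` gives equal areas (J = 1); smaller theta concentrates
    area in the top-ranked crops, lowering evenness.  The ramp runs across
    the full year range, giving a monotone (or flat) J trajectory.
    """

    theta_start: float = 1.0
    theta_end: float = 1.0

    def __post_init__(self):
        for v in (self.theta_start, self.theta_end):
            if not 0 < v <= 1:
                raise ConfigurationError("theta must be in (0, 1]")

    def theta(self, years: np.ndarray) -> np.ndarray:
        t = np.asarray(years, dtype=float)
        if t.size == 1 or t[-1] == t[0]:
            return np.full(t.shape, self.theta_start)
        frac = (t - t[0]) / (t[-1] - t[0])
        return self.theta_start + frac * (self.theta_end - self.theta_start)


@dataclass(frozen=True)
class CountryTruth:
    """Ground truth for one synthetic country."""

    name: str
    s0: float
    psi1: float
    psi2: float
    slopes: tuple[float, float, float]  # per-segment slopes
    sigma: float = 0.0
    evenness: EvennessSchedule = field(default_factory=EvennessSchedule)
    latitude: float = 30.0
    continent: str = "c1"
    region: str = "c1-r1"
    hdi: float = 0.7
    total_area: float = 1e6


@dataclass
class SyntheticConfig:
    """Full-dataset generator configuration; ``seed`` is mandatory."""

    seed: int
    n_countries: int = 30
    year_start: int = 1961
    year_end: int = 2017
    psi1: float = 1980.0
    psi2: float = 1995.0
    slopes: tuple[float, float, float] = (0.0, 1.0, 0.0)
    s0: float | None = None  # default: derived from the latitude gradient
    richness_sigma: float = 0.0
    theta_start: float = 0.9
    theta_end: float = 0.7
    gradient_beta: tuple[float, float, float] = (20.0, 1.5, -0.02)
    gradient_sd: float = 0.0
    lat_range: tuple[float, float] = (0.0, 70.0)
    n_continents: int = 5
    regions_per_continent: int = 2
    onset_sd_continent: float = 0.0
    onset_sd_region: float = 0.0
    onset_sd_country: float = 0.0
    hdi_onset_slope: float = 0.0
    total_area: float = 1e6

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if not (self.year_start < self.psi1 < self.psi2 < self.year_end):
            raise ConfigurationError("need year_start < psi1 < psi2 < year_end")
        for name in ("richness_sigma", "gradient_sd", "onset_sd_continent",
                     "onset_sd_region", "onset_sd_country"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.s0 is not None and self.s0 < 1:
            raise ConfigurationError("s0 must be >= 1")


def piecewise_mean(years, s0: float, psi1: float, psi2: float, slopes) -> np.ndarray:
    """Two-breakpoint piecewise-linear mean anchored at the first year.

    ``slopes`` are the three per-segment slopes; the hinge parametrization
    used by the trend model is recovered as ``b = slopes[0]``,
    ``c = slopes[1] - slopes[0]``, ``d = slopes[2] - slopes[1]``.
    """
    t = np.asarray(years, dtype=float)
    b = slopes[0]
    c = slopes[1] - slopes[0]
    d = slopes[2] - slopes[1]
    return (
        s0
        + b * (t - t[0])
        + c * np.clip(t - psi1, 0.0, None)
        + d * np.clip(t - psi2, 0.0, None)
    )


def geometric_proportions(theta: float, s: int) -> np.ndarray:
    """Ranked geometric abundance proportions ``p_i ∝ theta^(i-1)``."""
    if not 0 < theta <= 1:
        raise ConfigurationError("theta must be in (0, 1]")
    if s < 1:
        raise ConfigurationError("s must be >= 1")
    w = theta ** np.arange(s, dtype=float)
    return w / w.sum()


def evenness_of_theta(theta: float, s: int) -> float:
    """Pielou evenness implied by a geometric profile (NaN when s == 1)."""
    if s == 1:
        return float("nan")
    p = geometric_proportions(theta, s)
    h = -np.sum(p * np.log(p))
    return float(h / np.log(s))


def generate_country_series(
    truth: CountryTruth,
    years,
    rng: np.random.Generator,
    crop_pool,
) -> pd.DataFrame:
    """Generate long-format records for one country.

    Realized richness follows the piecewise mean (Gaussian noise on the
    latent scale, rounded, clipped to [1, pool size]); the crop identities
    are the leading entries of a country-specific permutation of the global
    pool, so crops are introduced/retired along the trajectory and presence
    counts — not just latent means — follow the configured path.
    """
    t = np.asarray(years, dtype=int)
    if not (t[0] < truth.psi1 < truth.psi2 < t[-1]):
        raise ConfigurationError(
            f"{truth.name}: breakpoints ({truth.psi1}, {truth.psi2}) outside "
            f"year range ({t[0]}, {t[-1]})"
        )
    pool = np.array(crop_pool)
    order = rng.permutation(pool.size)
    mu = piecewise_mean(t, truth.s0, truth.psi1, truth.psi2, truth.slopes)
    latent = mu + truth.sigma * rng.standard_normal(t.size)
    s_path = np.clip(np.rint(latent), 1, pool.size).astype(int)
    thetas = truth.evenness.theta(t)

    rows = []
    for year, s, theta in zip(t, s_path, thetas):
        crops = pool[order[:s]]
        p = geometric_proportions(float(theta), int(s))
        areas = p * truth.total_area
        for crop, area in zip(crops, areas):
            rows.append((truth.name, int(year), str(crop), float(area)))
    return pd.DataFrame(rows, columns=["country", "year", "crop_group", "area_ha"])


def _build_truths(config: SyntheticConfig, rng: np.random.Generator) -> list[CountryTruth]:
    n = config.n_countries
    names = [f"Country{idx:03d}" for idx in range(1, n + 1)]
    if len(set(names)) != n:
        raise ConfigurationError("duplicate country names")
    lat = rng.uniform(*config.lat_range, size=n)
    b0, b1, b2 = config.gradient_beta
    if config.s0 is None:
        s0 = np.clip(
            np.rint(b0 + b1 * lat + b2 * lat**2 + config.gradient_sd * rng.standard_normal(n)),
            2, None,
        )
    else:
        s0 = np.full(n, float(config.s0))
    hdi = rng.uniform(0.3, 0.95, size=n)

    continents = [f"c{idx + 1}" for idx in range(config.n_continents)]
    cont_eff = {c: config.onset_sd_continent * rng.standard_normal() for c in continents}
    regions = {
        c: [f"{c}-r{j + 1}" for j in range(config.regions_per_continent)]
        for c in continents
    }
    reg_eff = {
        r: config.onset_sd_region * rng.standard_normal()
        for c in continents
        for r in regions[c]
    }

    duration = config.psi2 - config.psi1
    lo = config.year_start + 3
    hi = config.year_end - 3 - duration
    truths = []
    schedule = EvennessSchedule(config.theta_start, config.theta_end)
    for i, name in enumerate(names):
        cont = continents[i % config.n_continents]
        reg = regions[cont][(i // config.n_continents) % config.regions_per_continent]
        onset = (
            config.psi1
            + cont_eff[cont]
            + reg_eff[reg]
            + config.onset_sd_country * rng.standard_normal()
            + config.hdi_onset_slope * (hdi[i] - 0.625)
        )
        onset = float(np.clip(onset, lo, hi))
        truths.append(
            CountryTruth(
                name=name,
                s0=float(s0[i]),
                psi1=onset,
                psi2=onset + duration,
                slopes=config.slopes,
                sigma=config.richness_sigma,
                evenness=schedule,
                latitude=float(lat[i]),
                continent=cont,
                region=reg,
                hdi=float(hdi[i]),
                total_area=config.total_area,
            )
        )
    return truths


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Generate records, country metadata, and truth tables.

    Returns ``(records, meta, truth)`` where ``records`` is the long-format
    table the ingest module emits, ``meta`` carries latitude / continent /
    region / HDI per country, and ``truth`` holds per-country parameter
    tables aligned with every downstream estimate.
    """
    rng = np.random.default_rng(config.seed)
    truths = _build_truths(config, rng)

    years = np.arange(config.year_start, config.year_end + 1)
    max_mu = max(
        float(np.max(piecewise_mean(years, tr.s0, tr.psi1, tr.psi2, tr.slopes)))
        for tr in truths
    )
    pool_size = max(int(math.ceil(max_mu + 5 * config.richness_sigma)) + 5, 40)
    pool = [f"crop{idx:03d}" for idx in range(pool_size)]

    frames = [generate_country_series(tr, years, rng, pool) for tr in truths]
    records = pd.concat(frames, ignore_index=True)

    meta = pd.DataFrame(
        {
            "country": [tr.name for tr in truths],
            "latitude_abs": [tr.latitude for tr in truths],
            "continent": [tr.continent for tr in truths],
            "region": [tr.region for tr in truths],
            "hdi": [tr.hdi for tr in truths],
            "total_area": [tr.total_area for tr in truths],
            "cultivated_area": [tr.total_area for tr in truths],
        }
    )
    truth_countries = pd.DataFrame(
        {
            "country": [tr.name for tr in truths],
            "s0": [tr.s0 for tr in truths],
            "psi1": [tr.psi1 for tr in truths],
            "psi2": [tr.psi2 for tr in truths],
            "slope1": [tr.slopes[0] for tr in truths],
            "slope2": [tr.slopes[1] for tr in truths],
            "slope3": [tr.slopes[2] for tr in truths],
            "onset": [tr.psi1 for tr in truths],
            "duration": [tr.psi2 - tr.psi1 for tr in truths],
            "rate": [tr.slopes[1] for tr in truths],
            "latitude_abs": [tr.latitude for tr in truths],
        }
    )
    truth = {
        "countries": truth_countries,
        "gradient": pd.DataFrame(
            [{"beta0": config.gradient_beta[0], "beta1": config.gradient_beta[1],
              "beta2": config.gradient_beta[2], "sd": config.gradient_sd}]
        ),
    }
    return records, meta, truth


def latitude_gradient_sample(
    n: int,
    beta: tuple[float, float, float] = (20.0, 1.5, -0.02),
    noise_sd: float = 2.0,
    seed: int | None = None,
    lat_range: tuple[float, float] = (0.0, 70.0),
) -> pd.DataFrame:
    """Direct (latitude, richness) sample from a quadratic gradient."""
    rng = np.random.default_rng(seed)
    lat = rng.uniform(*lat_range, size=n)
    s = beta[0] + beta[1] * lat + beta[2] * lat**2 + noise_sd * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "country": [f"Country{idx:03d}" for idx in range(1, n + 1)],
            "latitude_abs": lat,
            "S": s,
        }
    )


def nested_design_sample(
    n_continents: int = 6,
    regions_per_continent: int = 3,
    countries_per_region: int = 10,
    sd_continent: float = 2.0,
    sd_region: float = 1.0,
    sd_resid: float = 1.0,
    intercept: float = 0.0,
    hdi_slope: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Nested continent/region/country design for mixed-model recovery tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for ci in range(n_continents):
        cont = f"c{ci + 1}"
        u_c = sd_continent * rng.standard_normal()
        for ri in range(regions_per_continent):
            reg = f"{cont}-r{ri + 1}"
            u_r = sd_region * rng.standard_normal()
            for ki in range(countries_per_region):
                hdi = rng.uniform(0.3, 0.95)
                value = (
                    intercept + hdi_slope * hdi + u_c + u_r
                    + sd_resid * rng.standard_normal()
                )
                rows.append(
                    {"country": f"{reg}-k{ki + 1}", "continent": cont,
                     "region": reg, "hdi": hdi, "value": value}
                )
    return pd.DataFrame(rows)


def to_faostat_csv(records: pd.DataFrame, path) -> None:
    """Write records in the FAOSTAT bulk-download dialect the ingest reads."""
    out = pd.DataFrame(
        {
            "Area": records["country"],
            "Item": records["crop_group"],
            "Element": AREA_HARVESTED_LABEL,
            "Year": records["year"],
            "Unit": "ha",
            "Value": records["area_ha"],
        }
    )
    out.to_csv(path, index=False)


AREA_HARVESTED_LABEL = "Area harvested"
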