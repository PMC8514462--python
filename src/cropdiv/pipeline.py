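"""Configuration-driven orchestration of the full analysis.

Stage order: ingest (or synthesis) -> diversity table -> per-country
segmented fits (S and J) -> indicators and summaries -> composition
(Bray-Curtis, NMDS, PERMANOVA) -> latitudinal gradients -> HDI mixed
models.  Every stage writes a self-describing CSV; a JSON manifest records
the config hash, seed, per-stage row counts and the non-converged-country
list, so a rerun with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    composition_analysis as comp,
    data_ingest,
    diversity_metrics,
    gradient_models,
    indicators as ind,
    segmented_model as seg,
    socio_models,
    synthetic_data,
)
from .exceptions import ConfigurationError, FitNotConverged, PipelineError

logger = logging.getLogger("cropdiv")

_FIT_COLUMNS = [
    "country", "response", "a", "b", "c", "d", "psi1", "psi2",
    "r2", "p", "converged", "n", "reason",
]


@dataclass
class RunConfig:
    """Pipeline run configuration; exactly one of input/synthetic is active."""

    outdir: str = "results"
    seed: int = 0
    input: dict | None = None  # {production_csv, country_meta}
    synthetic: dict | None = None  # SyntheticConfig kwargs (seed filled from run seed)
    year_range: tuple[int, int] = (1961, 2017)
    init_psi1: float = 1975.0
    init_psi2: float = 2000.0
    overrides: dict = field(default_factory=dict)  # country -> [psi1, psi2]
    n_perm: int = 99
    nmds_starts: int = 4
    valid_countries: list | None = None

    def __post_init__(self):
        if (self.input is None) == (self.synthetic is None):
            raise ConfigurationError(
                "exactly one of 'input' and 'synthetic' must be configured"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "year_range" in raw:
            raw["year_range"] = tuple(raw["year_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["year_range"] = list(self.year_range)
        return d


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _fit_row(country: str, fit: seg.SegmentedFit) -> dict:
    return {
        "country": country, "response": fit.response_label,
        "a": fit.a, "b": fit.b, "c": fit.c, "d": fit.d,
        "psi1": fit.psi1, "psi2": fit.psi2, "r2": fit.r2, "p": fit.p_value,
        "converged": fit.converged, "n": fit.n, "reason": fit.reason or "",
    }


def _na_fit_row(country: str, response: str, reason: str) -> dict:
    row = dict.fromkeys(_FIT_COLUMNS, np.nan)
    row.update(country=country, response=response, converged=False,
               reason=reason, n=0)
    return row


def fit_country_series(
    series: pd.DataFrame,
    response: str,
    config: RunConfig,
) -> dict[str, seg.SegmentedFit]:
    """Fit the segmented model per country for one response column.

    Country-years where the response is undefined (J with S=1) are dropped.
    Per-country breakpoint initials come from ``config.overrides`` when
    present, else the global initials clipped into each country's range.
    """
    fits: dict[str, seg.SegmentedFit] = {}
    for country, grp in series.groupby("country", sort=True):
        grp = grp.dropna(subset=[response]).sort_values("year")
        years = grp["year"].to_numpy(dtype=float)
        y = grp[response].to_numpy(dtype=float)
        if years.size < 7:
            fits[country] = seg.SegmentedFit(
                a=np.nan, b=np.nan, c=np.nan, d=np.nan, psi1=np.nan,
                psi2=np.nan, r2=np.nan, p_value=np.nan, sse=np.nan,
                converged=False, n=int(years.size), response_label=response,
                reason=f"too few observations (n={years.size} < 7)",
            )
            continue
        if country in config.overrides:
            p1, p2 = config.overrides[country]
        else:
            span = years[-1] - years[0]
            p1 = float(np.clip(config.init_psi1, years[0] + 0.1 * span, years[-1] - 0.2 * span))
            p2 = float(np.clip(config.init_psi2, p1 + 0.1 * span, years[-1] - 0.1 * span))
        fits[country] = seg.fit_segmented(
            years, y, init_psi1=p1, init_psi2=p2, response_label=response
        )
    return fits


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write stage CSVs plus a manifest, return the
    manifest dict.  Any stage failure raises :class:`PipelineError` naming
    the stage; partial outputs are kept and flagged incomplete."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "files": {},
        "non_converged": {},
        "complete": False,
    }
    manifest_path = outdir / "manifest.json"

    def _write(name: str, df: pd.DataFrame):
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest["stages"][name] = int(len(df))
        manifest["files"][f"{name}.csv"] = _file_hash(path)

    def _dump_manifest():
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    stage = "ingest"
    try:
        if config.synthetic is not None:
            syn_kwargs = dict(config.synthetic)
            syn_kwargs.setdefault("seed", config.seed)
            syn = synthetic_data.SyntheticConfig(**syn_kwargs)
            records, meta, truth = synthetic_data.generate_dataset(syn)
            for name, df in truth.items():
                _write(f"truth_{name}", df)
        else:
            records, report = data_ingest.read_production_table(
                config.input["production_csv"], year_range=config.year_range
            )
            logger.info("ingest: %d rows kept, %d skipped", report.n_kept, report.n_skipped)
            records, _ = data_ingest.harmonize_crop_groups(records)
            if config.valid_countries:
                records, retained = data_ingest.filter_countries(
                    records, config.valid_countries
                )
                logger.info("ingest: %d countries retained", len(retained))
            meta = pd.read_csv(config.input["country_meta"])
        _write("records", records)
        _write("country_meta", meta)

        stage = "diversity"
        div = diversity_metrics.diversity_table(records)
        _write("diversity", div)

        stage = "segmented"
        bad = sorted(set(config.overrides) - set(div["country"].unique()))
        if bad:
            raise ConfigurationError(f"override for unknown country: {bad}")
        fit_rows = []
        indicator_rows = []
        for response in ("S", "J"):
            fits = fit_country_series(div, response, config)
            manifest["non_converged"][response] = sorted(
                c for c, f in fits.items() if not f.converged
            )
            for country, fit in fits.items():
                fit_rows.append(_fit_row(country, fit))
                try:
                    iset = ind.extract_indicators(fit, country=country)
                except FitNotConverged:
                    logger.warning(
                        "%s (%s): excluded, %s", country, response, fit.reason
                    )
                    continue
                indicator_rows.append(dataclasses.asdict(iset))
        _write("segmented_fits", pd.DataFrame(fit_rows, columns=_FIT_COLUMNS))

        stage = "indicators"
        idf = pd.DataFrame(
            indicator_rows, columns=["country", "metric", "onset", "duration", "rate"]
        )
        _write("indicators", idf)
        summary_rows = []
        for metric, grp in idf.groupby("metric"):
            for name in ("onset", "duration", "rate"):
                vals = grp[name].to_numpy(dtype=float)
                if np.isfinite(vals).sum() >= 5:
                    summary_rows.append(
                        dataclasses.asdict(ind.summarize_indicator(vals, name, metric=metric))
                    )
        _write("indicator_summaries", pd.DataFrame(summary_rows))

        stage = "composition"
        mat = comp.community_matrix(records)
        dist = comp.bray_curtis_matrix(mat.to_numpy())
        coords, stress = comp.nmds(
            dist, k=2, n_starts=config.nmds_starts, seed=config.seed
        )
        countries = mat.index.get_level_values("country").to_numpy()
        years = mat.index.get_level_values("year").to_numpy()
        disp = comp.per_group_dispersion(coords, years)
        coords_df = pd.DataFrame(
            {
                "country": countries,
                "year": years,
                "axis1": coords[:, 0],
                "axis2": coords[:, 1],
                "stress": stress,
                "year_dispersion": [disp[y] for y in years],
            }
        )
        _write("nmds_coords", coords_df)
        table = comp.permanova(
            dist,
            comp.composition_terms(countries, years),
            n_perm=config.n_perm,
            seed=config.seed,
        )
        _write("permanova", table.reset_index())

        stage = "gradients"
        y0, y1 = int(div["year"].min()), int(div["year"].max())
        both = set(div.loc[div["year"] == y0, "country"]) & set(
            div.loc[div["year"] == y1, "country"]
        )
        lat = meta.set_index("country")["latitude_abs"]
        grad_rows = []
        for yr in (y0, y1):
            sub = div[(div["year"] == yr) & div["country"].isin(both)]
            sub = sub[sub["country"].isin(lat.index)]
            if len(sub) < 10 or sub["country"].map(lat).nunique() < 3:
                logger.warning("gradients: skipping year %d (too few countries)", yr)
                continue
            fit = gradient_models.fit_latitude_gradient(
                lat.loc[sub["country"]].to_numpy(), sub["S"].to_numpy(), year=yr
            )
            grad_rows.append(dataclasses.asdict(fit))
        _write("latitude_gradient", pd.DataFrame(grad_rows))

        ind_wide = idf[idf["metric"] == "S"].set_index("country")[
            ["onset", "duration", "rate"]
        ]
        area_cols = [c for c in ("total_area", "cultivated_area") if c in meta.columns]
        if area_cols and len(ind_wide) >= 3:
            areg = gradient_models.area_regression(
                ind_wide, meta.set_index("country")[area_cols]
            )
            _write("area_regressions", areg)

        stage = "socio"
        socio_rows = []
        meta_idx = meta.set_index("country")
        for metric, grp in idf.groupby("metric"):
            joined = grp.set_index("country").join(
                meta_idx[["hdi", "continent", "region"]], how="inner"
            )
            for name in ("onset", "duration", "rate"):
                d = joined.dropna(subset=[name, "hdi", "continent", "region"])
                if d["continent"].nunique() < 2 or len(d) < 10:
                    logger.warning(
                        "socio: skipping %s/%s (insufficient structure)", metric, name
                    )
                    continue
                transformed, label = socio_models.transform_indicator(
                    d[name].to_numpy(), name, metric=metric
                )
                frame = d[["hdi", "continent", "region"]].copy()
                frame["value"] = transformed
                res = socio_models.fit_hdi_mixed_model(
                    frame, metric=metric, indicator=name, transform_label=label
                )
                socio_rows.append(dataclasses.asdict(res))
        _write("socio_models", pd.DataFrame(socio_rows))

        manifest["complete"] = True
        _dump_manifest()
        return manifest
    except Exception as exc:
        manifest["complete"] = False
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _dump_manifest()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
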