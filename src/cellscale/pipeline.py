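"""End-to-end orchestration: views/masks -> geometry -> indices -> growth -> SMA.

The pipeline reproduces the structure of an allometric-scaling study on
unicellular algae: per-species cell geometry and shape indices, replicate
growth-rate fits, derived traits (per-cell dry mass, density), a table of
SMA fits for the six canonical trait pairs, and correlations of the
µmax-scaling residuals with morphology.  Species means are aggregated
before any regression — each regression point is one species.

Every output CSV starts with a ``#`` comment line declaring units, and a
JSON run log records package versions, the seed and all chosen parameters
so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import residual_correlations, sma_table
from .geometry import DEFAULT_N_SLABS, CellViews, cell_shape_indices, stack_cell
from .growth import fit_growth_table
from .synthetic import (
    make_lobed_cell,
    simulate_growth_series,
)

logger = logging.getLogger("cellscale")

__all__ = ["PipelineConfig", "derive_traits", "run_pipeline", "SMA_PAIRS"]

#: The six canonical trait pairs (response, predictor) reported by the
#: pipeline's scaling table.
SMA_PAIRS: list[tuple[str, str]] = [
    ("mumax", "dry_mass"),
    ("mumax", "volume"),
    ("mumax", "surface"),
    ("dry_mass", "volume"),
    ("surface", "volume"),
    ("surface", "dry_mass"),
]

#: Traits correlated against the residuals of the mumax ~ dry_mass scaling.
RESIDUAL_TRAITS = ["alpha", "beta", "gamma", "delta", "density", "surface"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-serialisable)."""

    output_dir: str = "cellscale_out"
    seed: int = 0
    n_slabs: int = DEFAULT_N_SLABS
    pixel_size: float | None = None  #: µm per pixel, required for mask input
    smoothing: float | None = None  #: spline penalty; None -> GCV
    dilution_fraction: float = 0.0  #: 0 disables the serial-dilution correction
    views_csv: str | None = None  #: per-species frontal/apical measurements
    widths_csv: str | None = None  #: long-format width profiles per species
    counts_csv: str | None = None  #: growth series (species, replicate, day, cells_per_ml)
    traits_csv: str | None = None  #: extra per-species traits (dry_mass, ...)
    simulate: dict | None = None  #: synthetic-bundle parameters (see docs)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_slabs < 2:
            raise ValueError("n_slabs must be >= 2")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def derive_traits(record: dict) -> dict:
    """Fill in derived traits of one species record.

    Per-cell dry mass is pellet dry mass divided by the cell count; density
    is dry mass over volume (µg/µm³).  Fields whose ingredients are absent
    stay absent — no error.
    """
    out = dict(record)
    pellet = out.get("pellet_mass")
    count = out.get("cell_count")
    if pellet is not None and count is not None:
        if count == 0:
            raise ValueError("cell count of zero; per-cell mass undefined")
        out["dry_mass"] = pellet / count
    mass = out.get("dry_mass")
    volume = out.get("volume")
    if mass is not None and volume is not None and np.isfinite(mass) and np.isfinite(volume):
        out["density"] = mass / volume
    return out


def _write_csv(df: pd.DataFrame, path: Path, units: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {units}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")


def _views_from_tables(
    views_df: pd.DataFrame, widths_df: pd.DataFrame | None, n_slabs: int
) -> dict[str, CellViews]:
    out: dict[str, CellViews] = {}
    for _, row in views_df.iterrows():
        sp = str(row["species"])
        if widths_df is not None and sp in set(widths_df["species"].astype(str)):
            w = (
                widths_df[widths_df["species"].astype(str) == sp]
                .sort_values("station")["width_um"]
                .to_numpy(float)
            )
        else:
            # no measured profile: assume an elliptic thickness section
            u = np.linspace(-1.0, 1.0, n_slabs + 1)
            w = row["W_um"] * np.sqrt(np.clip(1.0 - u**2, 0.0, None))
        wmax = w.max()
        out[sp] = CellViews(
            A_f=float(row["A_f_um2"]),
            P_f=float(row["P_f_um2"] if "P_f_um2" in row else row["P_f_um"]),
            L=float(row["L_um"]),
            W=float(row["W_um"]),
            T=float(row["T_um"]),
            widths=w / wmax * float(row["W_um"]),
        )
    return out


def _synthetic_bundle(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a self-contained study: lobed cells spanning two orders of
    magnitude in volume, plus replicate growth series whose µ follows a
    quarter-power law in dry mass."""
    sim = dict(cfg.simulate or {})
    n_species = int(sim.get("n_species", 12))
    n_replicates = int(sim.get("n_replicates", 4))
    noise_sigma = float(sim.get("noise_sigma", 0.1))
    mu_slope = float(sim.get("mu_slope", -0.25))
    rng = np.random.default_rng(cfg.seed)
    r0s = np.geomspace(10.0, 100.0, n_species)  # µm; volume spans ~3 decades
    rows = []
    counts = []
    for i, r0 in enumerate(r0s):
        sp = f"sp{i + 1:02d}"
        eps = rng.uniform(0.05, 0.35)
        flat = rng.uniform(0.25, 0.6)
        cell = make_lobed_cell(r0, m=8, eps=eps, flat=flat, n=cfg.n_slabs)
        geom = stack_cell(cell.views)
        idx = cell_shape_indices(cell.views, geom)
        # dry mass follows a sublinear mass~volume law with lognormal spread
        dry_mass = 10 ** (-3.0 + 0.77 * np.log10(geom.V) + rng.normal(0, 0.05))
        mu = 10 ** (-0.3 + mu_slope * np.log10(dry_mass) + rng.normal(0, 0.04))
        mu = float(np.clip(mu, 0.05, 1.2))
        rows.append(
            dict(
                species=sp,
                volume=geom.V,
                surface=geom.S,
                dry_mass=dry_mass,
                alpha=idx.alpha,
                beta=idx.beta,
                gamma=idx.gamma,
                delta=idx.delta,
                true_mu=mu,
            )
        )
        for rep in range(n_replicates):
            series = simulate_growth_series(
                mu=mu,
                K=1e5,
                N0=100.0,
                days=np.arange(0.0, 36.0, 4.0),
                noise_sigma=noise_sigma,
                seed=int(rng.integers(2**31 - 1)),
                species=sp,
                replicate=f"r{rep + 1}",
            )
            counts.append(
                pd.DataFrame(
                    dict(
                        species=series.species,
                        replicate=series.replicate,
                        day=series.times,
                        cells_per_ml=series.abundances,
                    )
                )
            )
    return pd.DataFrame(rows), pd.concat(counts, ignore_index=True)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run all stages and write the report bundle; returns output paths.

    Stages: geometry (views/masks or synthetic), growth fitting, trait
    derivation, the six-pair SMA table, and residual correlations.  Fails
    with a stage-labelled error when an input is missing or malformed.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- stage: geometry ---------------------------------------------------
    if cfg.simulate is not None:
        geo_df, counts = _synthetic_bundle(cfg)
    else:
        if cfg.views_csv is None:
            raise RuntimeError("geometry stage: no views_csv (or simulate block) given")
        views_df = pd.read_csv(cfg.views_csv, comment="#")
        widths_df = pd.read_csv(cfg.widths_csv, comment="#") if cfg.widths_csv else None
        views = _views_from_tables(views_df, widths_df, cfg.n_slabs)
        rows = []
        for sp, v in views.items():
            geom = stack_cell(v)
            idx = cell_shape_indices(v, geom)
            rows.append(
                dict(
                    species=sp,
                    volume=geom.V,
                    surface=geom.S,
                    alpha=idx.alpha,
                    beta=idx.beta,
                    gamma=idx.gamma,
                    delta=idx.delta,
                )
            )
        geo_df = pd.DataFrame(rows)
        if cfg.counts_csv is None:
            raise RuntimeError("growth stage: no counts_csv given")
        counts = pd.read_csv(cfg.counts_csv, comment="#")
    geo_path = out / "geometry.csv"
    _write_csv(
        geo_df.drop(columns=["true_mu"], errors="ignore"),
        geo_path,
        "units: volume µm³, surface µm², indices dimensionless",
    )
    paths["geometry"] = geo_path
    logger.info("geometry stage: %d species", len(geo_df))

    # --- stage: growth ------------------------------------------------------
    try:
        per_rep, per_species = fit_growth_table(
            counts, smoothing=cfg.smoothing, dilution_fraction=cfg.dilution_fraction
        )
    except Exception as err:
        raise RuntimeError(f"growth stage: {err}") from err
    rep_path = out / "growth_replicates.csv"
    _write_csv(per_rep, rep_path, "units: mumax 1/day, t_at_max day")
    sp_path = out / "growth_species.csv"
    _write_csv(per_species, sp_path, "units: mumax 1/day (mean across replicates)")
    paths["growth_replicates"] = rep_path
    paths["growth_species"] = sp_path
    logger.info("growth stage: %d replicates, %d species", len(per_rep), len(per_species))

    # --- stage: traits ------------------------------------------------------
    traits = geo_df.merge(
        per_species[["species", "mumax"]], on="species", how="inner"
    )
    if cfg.traits_csv is not None:
        extra = pd.read_csv(cfg.traits_csv, comment="#")
        traits = traits.merge(extra, on="species", how="left")
    records = [derive_traits(r) for r in traits.to_dict("records")]
    traits = pd.DataFrame(records)
    traits_path = out / "traits.csv"
    _write_csv(
        traits,
        traits_path,
        "units: volume µm³, surface µm², dry_mass µg/cell, density µg/µm³, mumax 1/day",
    )
    paths["traits"] = traits_path

    # --- stage: scaling -----------------------------------------------------
    if len(traits) < 3:
        raise RuntimeError("scaling stage: need at least 3 species for SMA")
    pairs = [p for p in SMA_PAIRS if p[0] in traits.columns and p[1] in traits.columns]
    try:
        table, fits = sma_table(traits, pairs)
    except Exception as err:
        raise RuntimeError(f"scaling stage: {err}") from err
    sma_path = out / "sma_table.csv"
    _write_csv(table, sma_path, "units: slopes/intercepts on log10-log10 axes")
    paths["sma"] = sma_path

    key = ("mumax", "dry_mass") if ("mumax", "dry_mass") in fits else pairs[0]
    res_traits = [t for t in RESIDUAL_TRAITS if t in traits.columns]
    if res_traits:
        res = residual_correlations(traits, fits[key], res_traits)
        res_path = out / "residual_correlations.csv"
        _write_csv(
            res,
            res_path,
            f"Pearson r of {key[0]}~{key[1]} SMA residuals vs traits; "
            "p two-sided, unadjusted",
        )
        paths["residuals"] = res_path

    # --- run log ------------------------------------------------------------
    log_path = out / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(
            dict(
                cellscale_version=__version__,
                python=platform.python_version(),
                numpy=np.__version__,
                pandas=pd.__version__,
                seed=cfg.seed,
                n_slabs=cfg.n_slabs,
                smoothing="gcv" if cfg.smoothing is None else cfg.smoothing,
                dilution_fraction=cfg.dilution_fraction,
                sma_pairs=[list(p) for p in pairs],
            ),
            fh,
            indent=2,
        )
    paths["run_log"] = log_path
    logger.info("pipeline complete: %s", out)
    return paths
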