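"""End-to-end orchestration: synthetic inputs -> preprocessing ->
phenology -> monthly UDs -> plastic layer -> exposure scores ->
jurisdiction attribution -> report tables and maps.

Stages exchange plain-text artifacts (CSV / GeoJSON) under an output
directory so individual stages can be re-run, and a JSON manifest records
the configuration, package versions, seed and input checksums. All
randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demo as demo_mod
from . import exposure as exp
from . import landmask, phenology, plastic, synthetic, tracks, ud
from .grids import GlobalDensityGrid, GlobalGrid
from .jurisdiction import (
    JurisdictionLayer,
    assign_cells,
    breeding_country_linkage,
    partition_score,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    outdir: str = "pipeline-out"
    seed: int = 0
    simulate: bool = True  # generate demo-world inputs under outdir/inputs
    tracks_csv: str | None = None
    colonies_csv: str | None = None
    schedules_csv: str | None = None
    plastic_csvs: list[str] = field(default_factory=list)
    land_csv: str | None = None
    jurisdictions_geojson: str | None = None
    speed_max: float = 90.0
    resample_interval_h: float = 12.0
    min_locations_per_month: int = 5
    kde_bandwidth_km: float = 200.0
    kde_cell_km: float = 10.0
    isopleth_level: float = 0.95
    model_noise_sigma: float = 0.7

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise StageError(f"[config] unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def preprocess_config(self) -> tracks.PreprocessConfig:
        return tracks.PreprocessConfig(
            speed_max=self.speed_max,
            resample_interval_h=self.resample_interval_h,
            min_locations_per_month=self.min_locations_per_month,
        )

    def paths(self) -> dict[str, Path]:
        out = Path(self.outdir)
        return {
            "inputs": out / "inputs",
            "derived": out / "derived",
            "results": out / "results",
            "report": out / "report",
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# --- stage: simulate -------------------------------------------------------


def stage_simulate(cfg: RunConfig) -> dict[str, Path]:
    """Generate the demo world and write all pipeline inputs as text."""
    inputs = cfg.paths()["inputs"]
    inputs.mkdir(parents=True, exist_ok=True)
    world = demo_mod.demo_world(cfg.seed)
    specs = demo_mod.demo_population_specs()
    frames = [
        synthetic.simulate_population_tracks(world, spec, cfg.seed) for spec in specs
    ]
    tracks.write_tracks_csv(pd.concat(frames, ignore_index=True), inputs / "tracks.csv")
    tracks.write_colonies_csv(world.colonies, inputs / "colonies.csv")
    sched_rows = []
    for pop, series in demo_mod.demo_published_schedules().items():
        for month, label in series.items():
            sched_rows.append({"id": pop, "month": month, "label": label})
    pd.DataFrame(sched_rows).to_csv(inputs / "schedules.csv", index=False)
    layers = synthetic.derive_model_layers(world, cfg.seed, cfg.model_noise_sigma)
    for i, layer in enumerate(layers):
        layer.grid.to_csv(inputs / f"plastic_model_{i}.csv")
    lat2d, lon2d = world.grid.cell_centers()
    pd.DataFrame(
        {"lon": lon2d[world.land_mask], "lat": lat2d[world.land_mask]}
    ).to_csv(inputs / "land.csv", index=False)
    world.jurisdictions.to_geojson(inputs / "jurisdictions.geojson")
    return {p.name: p for p in inputs.iterdir()}


def _input_path(cfg: RunConfig, attr: str, default_name: str) -> Path:
    explicit = getattr(cfg, attr)
    if explicit:
        path = Path(explicit)
    else:
        path = cfg.paths()["inputs"] / default_name
    if not path.exists():
        raise StageError(f"[inputs] missing input file: {path}")
    return path


def load_land_mask(cfg: RunConfig, grid: GlobalGrid | None = None):
    grid = grid or GlobalGrid()
    path = _input_path(cfg, "land_csv", "land.csv")
    df = pd.read_csv(path)
    mask = np.zeros(grid.shape, dtype=bool)
    if len(df):
        ilat, ilon = grid.cell_index(df["lon"].to_numpy(), df["lat"].to_numpy())
        mask[ilat, ilon] = True
    return landmask.from_grid_mask(mask, grid)


# --- stage: preprocess -----------------------------------------------------


def stage_preprocess(cfg: RunConfig) -> Path:
    derived = cfg.paths()["derived"]
    derived.mkdir(parents=True, exist_ok=True)
    raw = tracks.read_tracks_csv(_input_path(cfg, "tracks_csv", "tracks.csv"))
    colonies = tracks.read_colonies_csv(_input_path(cfg, "colonies_csv", "colonies.csv"))
    clean = tracks.preprocess_tracks(raw, colonies, cfg.preprocess_config())
    out = derived / "clean_tracks.csv"
    tracks.write_tracks_csv(clean, out)
    logger.info("preprocess: %d raw -> %d retained locations", len(raw), len(clean))
    return out


# --- stage: phenology ------------------------------------------------------


def stage_phenology(cfg: RunConfig) -> Path:
    derived = cfg.paths()["derived"]
    clean = tracks.read_tracks_csv(derived / "clean_tracks.csv")
    colonies = tracks.read_colonies_csv(_input_path(cfg, "colonies_csv", "colonies.csv"))
    schedules = phenology.read_schedules_csv(
        _input_path(cfg, "schedules_csv", "schedules.csv")
    )
    frames = []
    for pop, sub in clean.groupby("population"):
        colony = colonies[str(pop)]
        published = schedules.get(str(pop))
        if published is None:
            published = schedules.get(colony.species_id)
        frames.append(phenology.population_phenology(sub, colony, published))
    out = derived / "phenology.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    return out


# --- stage: ud -------------------------------------------------------------


def stage_ud(cfg: RunConfig) -> Path:
    """Monthly global UD grids per population, written as one long-form CSV
    (population, month, lon, lat, mass) of positive cells."""
    derived = cfg.paths()["derived"]
    clean = tracks.read_tracks_csv(derived / "clean_tracks.csv")
    is_land = load_land_mask(cfg)
    rows = []
    for pop, sub in clean.groupby("population"):
        months = ud.month_filter(sub, cfg.min_locations_per_month)
        for month, pts in sorted(months.items()):
            grid = ud.monthly_global_ud(
                pts,
                is_land,
                h=cfg.kde_bandwidth_km,
                cell_km=cfg.kde_cell_km,
                level=cfg.isopleth_level,
                population_id=str(pop),
                month=month,
            )
            lat2d, lon2d = grid.grid.cell_centers()
            pos = grid.values > 0
            rows.append(
                pd.DataFrame(
                    {
                        "population": str(pop),
                        "month": month,
                        "lon": lon2d[pos],
                        "lat": lat2d[pos],
                        "mass": grid.values[pos],
                    }
                )
            )
    out = derived / "monthly_uds.csv"
    pd.concat(rows, ignore_index=True).to_csv(out, index=False)
    return out


def load_monthly_uds(cfg: RunConfig) -> dict[str, dict[int, GlobalDensityGrid]]:
    df = pd.read_csv(cfg.paths()["derived"] / "monthly_uds.csv")
    grid = GlobalGrid()
    out: dict[str, dict[int, GlobalDensityGrid]] = {}
    for (pop, month), sub in df.groupby(["population", "month"]):
        values = np.zeros(grid.shape)
        ilat, ilon = grid.cell_index(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        values[ilat, ilon] = sub["mass"].to_numpy()
        out.setdefault(str(pop), {})[int(month)] = GlobalDensityGrid(values, grid)
    return out


# --- stage: plastic --------------------------------------------------------


def stage_plastic(cfg: RunConfig) -> Path:
    derived = cfg.paths()["derived"]
    derived.mkdir(parents=True, exist_ok=True)
    if cfg.plastic_csvs:
        paths = [Path(p) for p in cfg.plastic_csvs]
    else:
        paths = [cfg.paths()["inputs"] / f"plastic_model_{i}.csv" for i in range(3)]
    for p in paths:
        if not p.exists():
            raise StageError(f"[plastic] missing model grid: {p}")
    layers = [
        plastic.PlasticModelLayer(p.stem, GlobalDensityGrid.from_csv(p)) for p in paths
    ]
    combined = plastic.build_combined_layer(layers)
    out = derived / "combined_plastic.csv"
    combined.to_csv(out)
    return out


def load_combined_plastic(cfg: RunConfig) -> GlobalDensityGrid:
    grid = GlobalDensityGrid.from_csv(cfg.paths()["derived"] / "combined_plastic.csv")
    return grid.normalize()


# --- stage: score ----------------------------------------------------------


def stage_score(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    results_dir = cfg.paths()["results"]
    results_dir.mkdir(parents=True, exist_ok=True)
    colonies = tracks.read_colonies_csv(_input_path(cfg, "colonies_csv", "colonies.csv"))
    phen = pd.read_csv(cfg.paths()["derived"] / "phenology.csv")
    uds = load_monthly_uds(cfg)
    plastic_grid = load_combined_plastic(cfg)

    monthly_rows, season_rows, pop_rows = [], [], []
    population_scores: dict[str, float] = {}
    population_uds: dict[str, GlobalDensityGrid] = {}
    pop_coverage: dict[str, float] = {}
    pop_exposure_maps: dict[str, GlobalDensityGrid] = {}
    for pop, months in uds.items():
        labels = dict(
            zip(
                phen.loc[phen["population_id"] == pop, "month"],
                phen.loc[phen["population_id"] == pop, "label"],
            )
        )
        monthly_scores: dict[int, float] = {}
        monthly_maps = []
        monthly_norm_uds = []
        for month, grid in sorted(months.items()):
            res = exp.month_exposure(grid, plastic_grid, pop, month)
            monthly_scores[month] = res.score
            monthly_maps.append(res.map)
            monthly_norm_uds.append(grid.normalize())
            monthly_rows.append(
                {
                    "population_id": pop,
                    "month": month,
                    "label": labels.get(month, ""),
                    "score": res.score,
                    "missing_plastic_fraction": res.missing_plastic_fraction,
                }
            )
        population_scores[pop] = exp.population_score(monthly_scores)
        population_uds[pop] = exp.mean_monthly_map(monthly_norm_uds).normalize()
        pop_exposure_maps[pop] = exp.mean_monthly_map(monthly_maps)
        pop_coverage[pop] = exp.coverage_weight(labels)
        for label, score in exp.season_score(monthly_scores, labels).items():
            season_rows.append({"population_id": pop, "season": label, "score": score})
        pop_rows.append(
            {
                "population_id": pop,
                "species_id": colonies[pop].species_id,
                "n_months": len(monthly_scores),
                "score": population_scores[pop],
                "coverage_weight": pop_coverage[pop],
                "population_size": colonies[pop].population_size,
            }
        )

    # species level
    species_rows = []
    species_uds: dict[str, GlobalDensityGrid] = {}
    species_coverage: dict[str, float] = {}
    species_scores: dict[str, float] = {}
    categories: dict[str, str] = {}
    pops_by_species: dict[str, list[str]] = {}
    for pop in population_scores:
        pops_by_species.setdefault(colonies[pop].species_id, []).append(pop)
    for sp, pops in pops_by_species.items():
        sizes = {p: colonies[p].population_size for p in pops}
        species_scores[sp] = exp.species_score(
            {p: population_scores[p] for p in pops}, sizes,
            {p: pop_coverage[p] for p in pops},
        )
        species_uds[sp] = exp.weighted_species_ud(
            {p: population_uds[p] for p in pops}, sizes
        )
        species_coverage[sp] = max(pop_coverage[p] for p in pops)
        categories[sp] = colonies[pops[0]].iucn_category
        species_rows.append(
            {
                "species_id": sp,
                "n_populations": len(pops),
                "score": species_scores[sp],
                "coverage_weight": species_coverage[sp],
                "iucn_category": categories[sp],
            }
        )

    all_sp = exp.all_species_map(species_uds, species_coverage, plastic_grid)
    shares = exp.category_share(species_scores, categories)
    richness = exp.richness_map(species_uds)
    reference = exp.uniform_plastic_reference(plastic_grid)

    out = {
        "monthly_scores": pd.DataFrame(monthly_rows),
        "season_scores": pd.DataFrame(season_rows),
        "population_scores": pd.DataFrame(pop_rows),
        "species_scores": pd.DataFrame(species_rows),
        "category_shares": pd.DataFrame(
            [{"iucn_category": k, "share": v} for k, v in shares.items()]
        ),
    }
    for name, df in out.items():
        df.to_csv(results_dir / f"{name}.csv", index=False)
    all_sp.map.to_csv(results_dir / "all_species_exposure_map.csv")
    lat2d, lon2d = GlobalGrid().cell_centers()
    pos = richness > 0
    pd.DataFrame(
        {"lon": lon2d[pos], "lat": lat2d[pos], "richness": richness[pos]}
    ).to_csv(results_dir / "richness_map.csv", index=False)
    pd.DataFrame(
        [
            {
                "quantity": "all_species_score",
                "value": all_sp.score,
            },
            {"quantity": "uniform_plastic_reference", "value": reference},
        ]
    ).to_csv(results_dir / "summary_scores.csv", index=False)
    # stash per-population exposure maps for the partition stage
    rows = []
    for pop, emap in pop_exposure_maps.items():
        pos = emap.values > 0
        rows.append(
            pd.DataFrame(
                {
                    "population": pop,
                    "lon": lon2d[pos],
                    "lat": lat2d[pos],
                    "value": emap.values[pos],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(
        cfg.paths()["derived"] / "population_exposure_maps.csv", index=False
    )
    return out


# --- stage: partition ------------------------------------------------------


def stage_partition(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    results_dir = cfg.paths()["results"]
    layer = JurisdictionLayer.from_geojson(
        _input_path(cfg, "jurisdictions_geojson", "jurisdictions.geojson")
    )
    grid = GlobalGrid()
    assignment = assign_cells(layer, grid)
    all_sp = GlobalDensityGrid.from_csv(results_dir / "all_species_exposure_map.csv")
    all_shares = partition_score(all_sp, assignment, layer)
    all_shares.to_csv(results_dir / "jurisdiction_shares.csv", index=False)

    pop_maps = pd.read_csv(cfg.paths()["derived"] / "population_exposure_maps.csv")
    colonies = tracks.read_colonies_csv(_input_path(cfg, "colonies_csv", "colonies.csv"))
    pop_shares: dict[str, pd.DataFrame] = {}
    frames = []
    for pop, sub in pop_maps.groupby("population"):
        values = np.zeros(grid.shape)
        ilat, ilon = grid.cell_index(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        values[ilat, ilon] = sub["value"].to_numpy()
        shares = partition_score(GlobalDensityGrid(values, grid), assignment, layer)
        shares.insert(0, "population_id", str(pop))
        pop_shares[str(pop)] = shares
        frames.append(shares)
    pd.concat(frames, ignore_index=True).to_csv(
        results_dir / "population_jurisdiction_shares.csv", index=False
    )
    linkage = breeding_country_linkage(
        pop_shares, {p: colonies[p].breeding_country for p in pop_shares}
    )
    linkage.to_csv(results_dir / "breeding_country_linkage.csv", index=False)
    return {"all_species": all_shares, "linkage": linkage}


# --- stage: report ---------------------------------------------------------


def make_report(cfg: RunConfig) -> Path:
    """Ranked tables plus square-root-scaled, percentile-capped map images.

    Capping affects rendering only, never tabulated scores.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results_dir = cfg.paths()["results"]
    report_dir = cfg.paths()["report"]
    report_dir.mkdir(parents=True, exist_ok=True)
    species = pd.read_csv(results_dir / "species_scores.csv")
    species.sort_values("score", ascending=False).to_csv(
        report_dir / "species_ranking.csv", index=False
    )
    shares = pd.read_csv(results_dir / "jurisdiction_shares.csv")
    shares.sort_values("fraction", ascending=False).to_csv(
        report_dir / "jurisdiction_table.csv", index=False
    )
    emap = GlobalDensityGrid.from_csv(results_dir / "all_species_exposure_map.csv")
    values = np.where(np.isnan(emap.values), 0.0, emap.values)
    positive = values[values > 0]
    cap = np.percentile(positive, 90.0) if positive.size else 1.0
    display = np.sqrt(np.minimum(values, cap))
    fig, ax = plt.subplots(figsize=(10, 5))
    ax.imshow(display, origin="lower", extent=(-180, 180, -90, 90), cmap="viridis")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title("All-species plastic exposure risk (sqrt scale, capped at P90)")
    fig.savefig(report_dir / "all_species_exposure_map.png", dpi=120)
    plt.close(fig)
    return report_dir


# --- run-all ---------------------------------------------------------------


STAGES = ("simulate", "preprocess", "phenology", "ud", "plastic", "score", "partition", "report")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write a run manifest. Raises StageError with
    a stage-tagged message on failure."""
    for p in cfg.paths().values():
        p.mkdir(parents=True, exist_ok=True)
    stage_fns = {
        "simulate": stage_simulate,
        "preprocess": stage_preprocess,
        "phenology": stage_phenology,
        "ud": stage_ud,
        "plastic": stage_plastic,
        "score": stage_score,
        "partition": stage_partition,
        "report": make_report,
    }
    for stage in STAGES:
        if stage == "simulate" and not cfg.simulate:
            continue
        try:
            stage_fns[stage](cfg)
        except StageError:
            raise
        except Exception as err:  # noqa: BLE001 - tag and re-raise
            raise StageError(f"[{stage}] {err}") from err
    manifest = write_manifest(cfg)
    return manifest


def write_manifest(cfg: RunConfig) -> dict:
    import plastic_exposure

    inputs = cfg.paths()["inputs"]
    checksums = (
        {p.name: _sha256(p) for p in sorted(inputs.iterdir())} if inputs.exists() else {}
    )
    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "versions": {
            "plastic_exposure": getattr(plastic_exposure, "__version__", "0"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "input_checksums": checksums,
    }
    path = Path(cfg.outdir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
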