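"""Config-driven orchestration: simulate -> landform -> indices ->
features -> pca -> forest -> ctree.

Every stage reads and writes plain text (CSV / JSON / ASCII grid) under
one output directory, so a run is diff-able and re-running a stage with
unchanged inputs rewrites identical bytes. A single global seed fans out
to per-stage seeds through a stable hash of the stage name, so stages
can be re-run in isolation and still reproduce.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .landform import (
    curvature,
    elevation_deviation,
    extract_at_points,
    mountain_mass_index,
    read_ascii_grid,
    slope_percent,
    write_ascii_grid,
)
from .modeling import (
    ForestConfig,
    fit_ctree,
    fit_forest,
    summarize_terminal_nodes,
)
from .multivariate import pca
from .synthetic import (
    EffectSpec,
    MetSpec,
    TerrainSpec,
    generate_dem,
    generate_hourly_met,
    generate_regional_covariates,
    generate_treeline_points,
)
from .topoclimate import indices_table, read_hourly_csv, summaries_table, write_hourly_csv

__all__ = [
    "PipelineConfig",
    "DependencyError",
    "STAGES",
    "run_pipeline",
    "run_stage",
    "validate_inputs",
    "stage_seed",
]

STAGES = ["simulate", "landform", "indices", "features", "pca", "forest", "ctree"]

#: default deviation-generating effect for synthetic runs: treelines dip
#: on concave, gentle terrain and in very wet regions
_DEFAULT_EFFECT = {
    "intercept": 150.0,
    "beta_curvature": -80.0,
    "beta_slope": -0.2,
    "threshold_terms": [["annual_precipitation", 5664.0, 120.0]],
    "noise_sd": 20.0,
}


class DependencyError(RuntimeError):
    """A stage's upstream outputs are missing."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Settings for a full synthetic-analysis run.

    Dict-valued fields override the corresponding spec/config defaults
    (:class:`TerrainSpec`, :class:`MetSpec`, :class:`EffectSpec`,
    :class:`ForestConfig`, conditional-tree settings).
    """

    out_dir: str = "runs/demo"
    seed: int = 0
    n_sites: int = 2
    points_per_site: int = 50
    stages: list = field(default_factory=lambda: list(STAGES))
    terrain: dict = field(default_factory=dict)
    met_jan: dict = field(default_factory=dict)
    met_jul: dict = field(default_factory=dict)
    effect: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECT))
    forest: dict = field(default_factory=lambda: {"n_trees": 300})
    ctree: dict = field(default_factory=lambda: {"n_permutations": 999})
    n_pd_variables: int = 3

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {', '.join(unknown)}")
        if self.n_sites < 1 or self.points_per_site < 2:
            raise ValueError("need >= 1 site and >= 2 points per site")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _site_ids(cfg: PipelineConfig) -> list[str]:
    return [f"site{k:02d}" for k in range(cfg.n_sites)]


def _require(out: Path, names: list[str], stage: str) -> None:
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise DependencyError(
            f"stage '{stage}' requires missing upstream outputs: "
            + ", ".join(missing)
        )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[str]:
    files: list[str] = []
    regional = generate_regional_covariates(
        cfg.n_sites, seed=stage_seed(cfg.seed, "regional")
    )
    regional.to_csv(out / "regional.csv", index=False)
    files.append("regional.csv")

    all_points = []
    for k, site in enumerate(_site_ids(cfg)):
        terrain = TerrainSpec(
            **{**cfg.terrain, "seed": stage_seed(cfg.seed, f"terrain:{site}")}
        )
        dem = generate_dem(terrain)
        write_ascii_grid(dem, out / f"dem_{site}.asc")
        files.append(f"dem_{site}.asc")

        effect = EffectSpec(
            **{
                **cfg.effect,
                "threshold_terms": [
                    tuple(t) for t in cfg.effect.get("threshold_terms", [])
                ],
                "seed": stage_seed(cfg.seed, f"points:{site}"),
            }
        )
        site_cov = pd.DataFrame(
            np.repeat(
                regional.iloc[[k]].drop(columns="site_id").to_numpy(),
                cfg.points_per_site,
                axis=0,
            ),
            columns=regional.columns.drop("site_id"),
        )
        points = generate_treeline_points(
            dem, effect, cfg.points_per_site, site, covariates=site_cov
        )
        all_points.append(
            points[["point_id", "site_id", "easting", "northing", "elevation",
                    "deviation_true"]]
        )

        for month, factory, overrides in (
            ("jan", MetSpec.january, cfg.met_jan),
            ("jul", MetSpec.july, cfg.met_jul),
        ):
            spec = factory(
                **{**overrides, "seed": stage_seed(cfg.seed, f"met:{site}:{month}")}
            )
            series = generate_hourly_met(dem, spec, points)
            write_hourly_csv(series, out / f"met_{site}_{month}.csv")
            files.append(f"met_{site}_{month}.csv")

    pd.concat(all_points, ignore_index=True).to_csv(out / "points.csv", index=False)
    files.append("points.csv")
    return files


def _stage_landform(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, ["points.csv"] + [f"dem_{s}.asc" for s in _site_ids(cfg)], "landform")
    points = pd.read_csv(out / "points.csv")
    parts = []
    for site in _site_ids(cfg):
        dem = read_ascii_grid(out / f"dem_{site}.asc")
        sub = points[points["site_id"] == site].copy()
        sub = extract_at_points(slope_percent(dem), sub, column="slope_percent")
        sub = extract_at_points(curvature(dem), sub, column="curvature")
        sub["mountain_mass_index"] = mountain_mass_index(dem)
        parts.append(sub)
    feat = elevation_deviation(pd.concat(parts, ignore_index=True))
    cols = [
        "point_id", "site_id", "easting", "northing", "elevation",
        "slope_percent", "curvature", "elevation_deviation",
        "site_max_elevation", "mountain_mass_index",
    ]
    feat[cols].to_csv(out / "landform.csv", index=False)
    return ["landform.csv"]


def _stage_indices(cfg: PipelineConfig, out: Path) -> list[str]:
    met_files = [
        f"met_{s}_{m}.csv" for s in _site_ids(cfg) for m in ("jan", "jul")
    ]
    _require(out, met_files, "indices")
    series = [s for f in met_files for s in read_hourly_csv(out / f)]
    indices_table(series).to_csv(out / "indices.csv", index=False)
    summaries_table(series).to_csv(out / "summaries.csv", index=False)
    return ["indices.csv", "summaries.csv"]


def _stage_features(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(
        out, ["landform.csv", "indices.csv", "summaries.csv", "regional.csv"],
        "features",
    )
    landform = pd.read_csv(out / "landform.csv")
    indices = pd.read_csv(out / "indices.csv")
    summaries = pd.read_csv(out / "summaries.csv")
    regional = pd.read_csv(out / "regional.csv")

    wide = indices.pivot(
        index=["point_id", "site_id"],
        columns="month",
        values=["photoinhibition", "desiccation", "frost", "insolation"],
    )
    wide.columns = [f"{var}_{month}" for var, month in wide.columns]
    wide = wide.reset_index()

    winter = summaries[["point_id", "jul_temp_min", "jul_temp_max"]].rename(
        columns={"jul_temp_min": "winter_temp_min", "jul_temp_max": "winter_temp_max"}
    )
    table = (
        landform.merge(wide, on=["point_id", "site_id"], validate="1:1")
        .merge(winter, on="point_id", validate="1:1")
        .merge(regional, on="site_id", validate="m:1")
    )
    report = validate_inputs({"features": table})
    bad = report[~report["passed"]]
    if len(bad):
        raise ValueError(f"feature validation failed: {bad.iloc[0]['detail']}")
    table.to_csv(out / "features.csv", index=False)
    return ["features.csv"]


def _stage_pca(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, ["summaries.csv"], "pca")
    summaries = pd.read_csv(out / "summaries.csv")
    mat = summaries.drop(columns=["point_id", "site_id"])
    # constant columns carry no variation to decompose (e.g. winter RH
    # maxima saturated at 100 %); drop them rather than fail the ordination
    scale = mat.abs().mean() + 1.0
    mat = mat.loc[:, mat.std(ddof=1) > 1e-9 * scale]
    result = pca(mat)
    result.loadings_.round(10).to_csv(out / "pca_loadings.csv", index_label="variable")
    pd.DataFrame(
        {
            "component": result.loadings_.columns,
            "proportion": np.round(result.explained_variance_ratio_, 12),
        }
    ).to_csv(out / "pca_proportions.csv", index=False)
    scores = result.scores_.round(10)
    scores.insert(0, "point_id", summaries["point_id"].to_numpy())
    scores.to_csv(out / "pca_scores.csv", index=False)
    return ["pca_loadings.csv", "pca_proportions.csv", "pca_scores.csv"]


def _stage_forest(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, ["features.csv"], "forest")
    table = pd.read_csv(out / "features.csv")
    config = ForestConfig(**{**cfg.forest, "seed": stage_seed(cfg.seed, "forest")})
    forest = fit_forest(table, config)
    importance = forest.permutation_importance()
    importance.round(10).to_csv(out / "importance.csv", index=False)
    with open(out / "forest.json", "w") as fh:
        json.dump(
            {"oob_r2": round(forest.oob_r2_, 10), "n_trees": config.n_trees}, fh
        )
    top = importance["variable"].head(cfg.n_pd_variables)
    curves = pd.concat(
        [forest.partial_dependence(v) for v in top], ignore_index=True
    )
    curves.round(10).to_csv(out / "pd_curves.csv", index=False)
    return ["importance.csv", "forest.json", "pd_curves.csv"]


def _stage_ctree(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, ["features.csv"], "ctree")
    table = pd.read_csv(out / "features.csv")
    settings = {**cfg.ctree, "seed": stage_seed(cfg.seed, "ctree")}
    tree = fit_ctree(table, **settings)
    with open(out / "ctree.json", "w") as fh:
        fh.write(tree.to_json(indent=2))
    with open(out / "ctree.txt", "w") as fh:
        fh.write(tree.render_text() + "\n")
    summarize_terminal_nodes(tree).to_csv(out / "ctree_nodes.csv", index=False)
    return ["ctree.json", "ctree.txt", "ctree_nodes.csv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "landform": _stage_landform,
    "indices": _stage_indices,
    "features": _stage_features,
    "pca": _stage_pca,
    "forest": _stage_forest,
    "ctree": _stage_ctree,
}


def run_stage(cfg: PipelineConfig, stage: str) -> list[str]:
    """Run one stage; returns the files it wrote (relative to out_dir)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return _STAGE_FUNCS[stage](cfg, out)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order and write a manifest.

    Returns the manifest dict; any stage failure propagates with the
    stage named in the exception message.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "versions": _versions(),
        "stages": {},
        "timings_s": {},
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.perf_counter()
        try:
            files = _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:
            raise type(exc)(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = files
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _versions() -> dict:
    import sklearn

    return {
        "topotreeline": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------


def _check_hourly(df: pd.DataFrame) -> tuple[bool, str]:
    needed = ["site_id", "point_id", "timestamp_hour", "temp_c", "wind_ms",
              "rh_pct", "solar_wm2", "netrad_wm2", "rain_mm"]
    for col in needed:
        if col not in df.columns:
            return False, f"missing column '{col}'"
    bad_rh = df.index[(df["rh_pct"] < 0) | (df["rh_pct"] > 100)]
    if len(bad_rh):
        return False, f"rh_pct out of [0, 100] at row {bad_rh[0]}"
    bad_solar = df.index[df["solar_wm2"] < 0]
    if len(bad_solar):
        return False, f"solar_wm2 negative at row {bad_solar[0]}"
    return True, "ok"


def _check_features(df: pd.DataFrame) -> tuple[bool, str]:
    if "elevation_deviation" not in df.columns:
        return False, "missing column 'elevation_deviation'"
    bad = df.index[df["elevation_deviation"] < 0]
    if len(bad):
        return False, f"elevation_deviation negative at row {bad[0]}"
    na_cols = df.columns[df.isna().any()]
    if len(na_cols):
        return False, f"missing values in column '{na_cols[0]}'"
    return True, "ok"


def validate_inputs(inputs: dict) -> pd.DataFrame:
    """Validate pipeline tables; one report row per input.

    ``inputs`` maps a name to a DataFrame or a CSV path. Hourly
    meteorology tables (recognised by their column set) are checked for
    schema and physical ranges (RH in [0, 100], shortwave >= 0); feature
    tables for a non-negative response and complete cases. The report
    has columns (name, kind, passed, detail); unreadable files raise.
    """
    rows = []
    for name, obj in inputs.items():
        df = pd.read_csv(obj) if not isinstance(obj, pd.DataFrame) else obj
        if "temp_c" in df.columns or "timestamp_hour" in df.columns:
            kind, (ok, detail) = "hourly_met", _check_hourly(df)
        else:
            kind, (ok, detail) = "features", _check_features(df)
        rows.append({"name": name, "kind": kind, "passed": ok, "detail": detail})
    return pd.DataFrame(rows)
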