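"""File I/O, run configuration, and the end-to-end pipeline.

Interchange formats are deliberately plain: GeoJSON for tract polygons,
CSV for attributes and results, GAL text for weights, JSON for the run
manifest. ``run_all`` reproduces the full study workflow — generate or
ingest tracts, derive indices, univariate LISA on flood risk, bivariate
LISA for each configured variable pair plus sensitivity variables, and
the three profiling reports — deterministically from a single seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from . import __version__
from .indices import compute_index_table
from .lisa import DEFAULT_ALPHAS, DEFAULT_PERMUTATIONS, run_lisa
from .profiling import (
    cluster_population_summary,
    crosstab_ruca,
    demographic_comparison,
    ruca_class,
)
from .synth import PlantedBlock, SimConfig, synthesize_tracts
from .weights import build_queen_weights, row_standardize, write_gal

__all__ = [
    "read_tract_table", "write_tract_table", "RunConfig", "load_run_config",
    "run_all", "ValidationError",
]

logger = logging.getLogger(__name__)

#: Default bivariate pairs: flood risk against each inverted ICE variant.
DEFAULT_PAIRS = (
    ("p_flood_high", "ice_income"),
    ("p_flood_high", "ice_race"),
    ("p_flood_high", "ice_race_income"),
)

SENSITIVITY_Y = ("gini", "iod")
SENSITIVITY_X = ("p_ff7", "p_ff8", "p_ff9", "p_ff10")
PREVALENCE_Y = ("prev_asthma", "prev_copd", "prev_depression",
                "prev_diabetes", "prev_kidney_disease")

DEMOGRAPHIC_INDICATORS = (
    "population", "households", "n_nonwhite", "n_white",
    "prev_asthma", "prev_copd", "prev_depression", "prev_diabetes",
    "prev_kidney_disease", "gini", "iod",
)


class ValidationError(ValueError):
    """Configuration or input validation failure (CLI exit code 2)."""


# ---------------------------------------------------------------------------
# tract table I/O
# ---------------------------------------------------------------------------

def write_tract_table(df: pd.DataFrame, geojson_path, csv_path) -> None:
    """Write geometry+id as GeoJSON and attributes (sans geometry) as CSV."""
    features = [
        {
            "type": "Feature",
            "properties": {"tract_id": tid},
            "geometry": mapping(geom),
        }
        for tid, geom in zip(df["tract_id"], df["geometry"])
    ]
    with open(geojson_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    df.drop(columns=["geometry"]).to_csv(csv_path, index=False)


def read_tract_table(geojson_path, csv_path) -> pd.DataFrame:
    """Join a tract polygon GeoJSON with an attribute CSV on ``tract_id``.

    Row order follows the GeoJSON feature order. Every feature id must have
    exactly one CSV row; duplicates or gaps raise with the offending ids.
    """
    with open(geojson_path) as fh:
        gj = json.load(fh)
    feats = gj["features"]
    ids = [str(f["properties"]["tract_id"]) for f in feats]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate tract ids in GeoJSON: {dupes}")
    geoms = [shape(f["geometry"]) for f in feats]

    attrs = pd.read_csv(csv_path, dtype={"tract_id": str})
    if attrs["tract_id"].duplicated().any():
        dupes = sorted(attrs.loc[attrs["tract_id"].duplicated(), "tract_id"].unique())
        raise ValidationError(f"duplicate tract ids in CSV: {dupes}")
    missing = sorted(set(ids) - set(attrs["tract_id"]))
    if missing:
        raise ValidationError(f"CSV missing attribute rows for tract ids: {missing}")
    extra = sorted(set(attrs["tract_id"]) - set(ids))
    if extra:
        logger.warning("CSV rows without geometry ignored: %s", extra)
    table = attrs.set_index("tract_id").loc[ids].reset_index()
    table["geometry"] = geoms
    return table


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    sim: SimConfig | None = None          # synthetic mode
    geojson: str | None = None            # ingest mode
    csv: str | None = None
    pairs: tuple = DEFAULT_PAIRS
    sensitivity: bool = True
    health: bool = True
    permutations: int = DEFAULT_PERMUTATIONS
    seed: int = 0
    alphas: tuple = DEFAULT_ALPHAS
    weights_mode: str = "queen-row"       # or "queen-binary"
    out_dir: str = "results"

    def validate(self) -> None:
        if (self.sim is None) == (self.geojson is None):
            raise ValidationError("configure exactly one of synthetic (sim) or file input")
        if self.geojson is not None and self.csv is None:
            raise ValidationError("file input needs both geojson and csv paths")
        if self.weights_mode not in ("queen-row", "queen-binary"):
            raise ValidationError(f"unknown weights mode {self.weights_mode!r}")
        if self.permutations < 99:
            raise ValidationError("permutations must be >= 99")


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    sim = data.pop("sim", None)
    if sim is not None:
        blocks = tuple(PlantedBlock(**b) for b in sim.pop("planted_blocks", []))
        brackets = sim.pop("income_brackets", None)
        kwargs = dict(sim, planted_blocks=blocks)
        if brackets is not None:
            kwargs["income_brackets"] = tuple(
                (lo, hi) for lo, hi in (tuple(b) for b in brackets)
            )
        sim = SimConfig(**kwargs)
    pairs = tuple(tuple(p) for p in data.pop("pairs", DEFAULT_PAIRS))
    alphas = tuple(data.pop("alphas", DEFAULT_ALPHAS))
    return RunConfig(sim=sim, pairs=pairs, alphas=alphas, **data)


def _config_digest(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o).__name__)

    payload = dataclasses.asdict(cfg)
    payload.pop("out_dir", None)  # where results land doesn't change what they are
    blob = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _stage(name, stages, t0):
    # timings go to the log only; the manifest must be byte-reproducible
    logger.info("stage %s done at %.3fs", name, time.perf_counter() - t0)
    stages.append(name)


def run_all(cfg: RunConfig) -> dict:
    """Execute the full analysis workflow; returns a result bundle.

    Writes, under ``cfg.out_dir``: the synthetic (or ingested) tract table,
    the derived index table, the queen weights in GAL format, one LISA CSV
    per analysis, three profiling report CSVs per bivariate ICE pair, and a
    ``manifest.json`` tying outputs to the config hash, seed and version.
    All output is deterministic given the config.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: list = []
    t0 = time.perf_counter()

    # ---- generate or ingest -------------------------------------------------
    if cfg.sim is not None:
        df, w = synthesize_tracts(cfg.sim)
    else:
        df = read_tract_table(cfg.geojson, cfg.csv)
        w = row_standardize(build_queen_weights(df["geometry"], df["tract_id"]))
    if cfg.weights_mode == "queen-binary":
        w = build_queen_weights(df["geometry"], list(df["tract_id"]))
    write_tract_table(df, out / "tracts.geojson", out / "tracts.csv")
    write_gal(w, out / "weights.gal")
    _stage("generate", timings, t0)

    # ---- indices ------------------------------------------------------------
    table = compute_index_table(df)
    table.drop(columns=["geometry"]).to_csv(out / "indices.csv", index=False)
    _stage("indices", timings, t0)

    # ---- pre-flight: every configured variable must exist -------------------
    analyses = [("p_flood_high", None)] + [tuple(p) for p in cfg.pairs]
    if cfg.sensitivity:
        analyses += [("p_flood_high", y) for y in SENSITIVITY_Y]
        analyses += [(x, "ice_income") for x in SENSITIVITY_X]
    if cfg.health:
        analyses += [("p_flood_high", y) for y in PREVALENCE_Y]
    named = {v for pair in analyses for v in pair if v is not None}
    missing = sorted(v for v in named if v not in table.columns)
    if missing:
        raise ValidationError(f"configured variables not present in table: {missing}")

    # ---- LISA runs ----------------------------------------------------------
    n_before = len(table)
    used_cols = sorted(named)
    complete = table[used_cols].notna().all(axis=1).to_numpy()
    excluded = int((~complete).sum())
    if excluded:
        logger.warning("excluding %d tracts with missing analysis variables", excluded)
        keep_ids = table.loc[complete, "tract_id"]
        table = table.loc[complete].reset_index(drop=True)
        poly = table["geometry"]
        if cfg.weights_mode == "queen-binary":
            w = build_queen_weights(poly, list(keep_ids))
        else:
            w = row_standardize(build_queen_weights(poly, list(keep_ids)))

    results = {}
    global_i = {}
    for x, y in analyses:
        res = run_lisa(
            table, x, w, y=y, permutations=cfg.permutations,
            seed=cfg.seed, alphas=cfg.alphas,
        )
        key = x if y is None else f"{x}__{y}"
        results[key] = res
        global_i[key] = res.global_i
        res.table.to_csv(out / f"lisa_{key}.csv", index=False)
    _stage("lisa", timings, t0)

    # ---- profiling reports (per bivariate ICE pair) -------------------------
    ruca_classes = np.array([ruca_class(c) for c in table["ruca"]], dtype=object)
    indicators = [c for c in DEMOGRAPHIC_INDICATORS if c in table.columns]
    profile_files = []
    for x, y in cfg.pairs:
        res = results[f"{x}__{y}"]
        labels = res.labels(0.05).to_numpy()
        t1 = pd.DataFrame(
            [cluster_population_summary(labels, table, q) for q in ("HH", "LL", "LH", "HL")]
        )
        t3_rows = []
        for q in ("HH", "LL", "LH", "HL"):
            ct = crosstab_ruca(labels, ruca_classes, q)
            ct.insert(0, "cluster", q)
            t3_rows.append(ct)
        t3 = pd.concat(t3_rows, ignore_index=True)
        if (labels == "HH").sum() >= 2:
            t2 = demographic_comparison(labels, table, "HH", indicators)
        else:
            t2 = pd.DataFrame(
                columns=["indicator", "cluster_mean", "state_mean", "delta",
                         "t", "p", "stars", "significant"]
            )
        for name, frame in (("membership", t1), ("demographics", t2), ("ruca", t3)):
            path = out / f"profile_{name}_{x}__{y}.csv"
            frame.to_csv(path, index=False)
            profile_files.append(path.name)
    _stage("profiling", timings, t0)

    manifest = {
        "package": "floodlisa",
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": _config_digest(cfg),
        "n_tracts": n_before,
        "n_excluded_missing": excluded,
        "n_islands": int(len(w.islands)),
        "global_moran": {k: round(v, 10) for k, v in global_i.items()},
        "analyses": list(results),
        "profile_files": profile_files,
        "stages_completed": timings,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"table": table, "weights": w, "results": results, "manifest": manifest}
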