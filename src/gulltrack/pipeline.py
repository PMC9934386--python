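"""End-to-end orchestration: filter -> summaries -> phenology -> bouts ->
repeatability -> connectivity -> kernels, with reproducible CSV/JSON outputs.

Every run serializes its effective configuration and a config hash next to
the outputs, so reruns with the same seed and config are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bouts as bouts_mod
from . import connectivity as conn_mod
from . import geodesy, kernel_ud, phenology, repeatability, seasons, track_store
from .synthetic import SyntheticConfig, generate_cohort

ALL_STAGES = ("filter", "summarize", "phenology", "bouts", "dtw", "connectivity", "ud")


@dataclass
class RunConfig:
    """Input source, thresholds and stage toggles for one pipeline run."""

    input_csv: str | None = None          # else a synthetic cohort is generated
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    stages: tuple = ALL_STAGES
    min_days: int = 100
    active_day_km: float = phenology.ACTIVE_DAY_KM
    lat_band: tuple = (phenology.WINTER_RANGE_NORTH_LAT, phenology.BREEDING_RANGE_SOUTH_LAT)
    bout_min_h: float = bouts_mod.BOUT_MIN_H
    bout_max_h: float = bouts_mod.BOUT_MAX_H
    migration_bout_km: float = bouts_mod.MIGRATION_BOUT_KM
    diel_threshold_deg: float = -6.0
    n_perm: int = 10_000
    n_boot: int = 1000
    ud_smoothing_km: float = 100.0
    ud_cell_km: float = 50.0
    seed: int = 0
    outdir: str = "results/run"

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        syn = d.pop("synthetic", None)
        if syn is not None:
            for key in ("breeding_sites", "wintering_sites"):
                if key in syn:
                    syn[key] = tuple(tuple(p) for p in syn[key])
            d["synthetic"] = SyntheticConfig(**syn)
        for key in ("stages", "lat_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages and write versioned outputs.

    Returns a results dict with in-memory objects per stage and the list of
    files written.  Any stage failure propagates with a stage-tagged error.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    results: dict = {"outputs": written, "config_hash": cfg.config_hash()}

    if cfg.input_csv:
        tracks, parse_report = track_store.read_fix_table(cfg.input_csv)
        deployments = [track_store.Deployment(bird_id=t.bird_id) for t in tracks]
        truth = None
    else:
        tracks, deployments, truth = generate_cohort(cfg.synthetic)
        parse_report = None
    results["truth"] = truth
    dep_map = {d.bird_id: d for d in deployments}

    def _stage(name):
        return name in cfg.stages

    def _write(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False)
        written.append(str(p))

    try:
        if _stage("filter"):
            filtered, reports = [], {}
            for t in tracks:
                ft, rep = track_store.filter_fixes(t)
                filtered.append(ft)
                reports[t.bird_id] = rep.as_dict()
            tracks = filtered
            with open(out / "removal_report.json", "w") as fh:
                json.dump(reports, fh, indent=1)
            written.append(str(out / "removal_report.json"))
            tracks, excluded = track_store.apply_inclusion_filter(tracks, cfg.min_days)
            results["filter"] = {"reports": reports, "n_included": len(tracks),
                                 "n_excluded": len(excluded)}

        if _stage("summarize"):
            rows = pd.DataFrame([track_store.summarize_deployment(t) for t in tracks])
            _write(rows, "bird_summaries.csv")
            results["summaries"] = rows
            results["cohort"] = track_store.cohort_summary(rows)
            with open(out / "cohort_summary.json", "w") as fh:
                json.dump(results["cohort"], fh, indent=1, default=float)
            written.append(str(out / "cohort_summary.json"))

        daily = None
        if _stage("phenology") or _stage("dtw"):
            daily = pd.concat([phenology.daily_series(t) for t in tracks], ignore_index=True)
            daily = phenology.classify_active_days(daily, cfg.active_day_km, cfg.lat_band)
        if _stage("phenology"):
            windows = phenology.individual_windows(daily)
            wdf = pd.DataFrame(
                [
                    {
                        "bird_id": w.bird_id, "season": w.season, "year": w.year,
                        "first_active": w.first_active, "last_active": w.last_active,
                        "duration_days": w.duration_days, "n_active_days": w.n_active_days,
                        "prop_active": w.prop_active,
                        "prop_active_corrected": w.prop_active_corrected,
                        "route_fraction_active": phenology.route_fraction_on_active_days(daily, w),
                    }
                    for w in windows
                ]
            )
            _write(daily, "daily_series.csv")
            _write(wdf, "individual_windows.csv")
            results["phenology"] = {"daily": daily, "windows": windows, "windows_table": wdf}

        if _stage("bouts"):
            two_h = track_store.select_subsample(tracks, dep_map, "B")
            bout_tables = [
                bouts_mod.extract_bouts(t, cfg.bout_min_h, cfg.bout_max_h,
                                        cfg.migration_bout_km, cfg.diel_threshold_deg)
                for t in two_h
            ]
            bt = (pd.concat(bout_tables, ignore_index=True) if bout_tables
                  else bouts_mod.extract_bouts(track_store.Track("none", pd.DataFrame(
                      columns=track_store.FIX_COLUMNS))))
            _write(bt, "bouts.csv")
            comp_all = bouts_mod.diel_composition(bt, "all") if len(bt) else pd.DataFrame()
            comp_mig = (bouts_mod.diel_composition(bt, "migration_only")
                        if bt["is_migration"].any() else pd.DataFrame())
            if len(comp_all):
                _write(comp_all, "diel_composition_all.csv")
            if len(comp_mig):
                _write(comp_mig, "diel_composition_migration.csv")
            results["bouts"] = {"table": bt, "composition_all": comp_all,
                                "composition_migration": comp_mig}

        regular = None
        if _stage("dtw") or _stage("ud"):
            regular = []
            for t in tracks:
                if len(t) < 2:
                    continue
                rt = geodesy.regularize(t.fixes, "1D", bird_id=t.bird_id)
                pos = rt.positions
                regular.append(pd.DataFrame({
                    "bird_id": t.bird_id,
                    "date": seasons.to_local_dates(pos["timestamp"]),
                    "lat": pos["lat"], "lon": pos["lon"],
                }))
            regular = pd.concat(regular, ignore_index=True) if regular else pd.DataFrame(
                columns=["bird_id", "date", "lat", "lon"])

        if _stage("dtw"):
            segments = repeatability.seasonal_segments(regular)
            rows = []
            for season in (seasons.WINTER, seasons.SPRING, seasons.SUMMER, seasons.AUTUMN):
                within, between = repeatability.seasonal_dtw_sets(segments, season)
                row = {"season": season, "n_within": len(within), "n_between": len(between),
                       "mean_within": np.mean([r.value for r in within]) if within else np.nan,
                       "mean_between": np.mean([r.value for r in between]) if between else np.nan,
                       "perm_p": np.nan}
                if within and between:
                    perm = repeatability.permutation_diff_test(
                        [r.value for r in within], [r.value for r in between],
                        n_perm=cfg.n_perm, seed=cfg.seed)
                    row["perm_p"] = perm.p_value
                    row["observed_diff"] = perm.observed_diff
                rows.append(row)
            ddf = pd.DataFrame(rows)
            _write(ddf, "dtw_seasonal.csv")
            results["dtw"] = {"segments": segments, "summary": ddf}

        if _stage("connectivity"):
            cents = conn_mod.seasonal_centroids(tracks)
            if len(cents) >= 3:
                res = conn_mod.mantel_connectivity(cents, n_boot=cfg.n_boot, seed=cfg.seed)
                _write(cents, "seasonal_centroids.csv")
                mdf = pd.DataFrame([asdict(res)])
                _write(mdf, "mantel_connectivity.csv")
                results["connectivity"] = res
            else:
                results["connectivity"] = None

        if _stage("ud"):
            # first tracked year per bird so every individual weighs the same
            first_year = regular.groupby("bird_id")["date"].transform(
                lambda s: s.dt.year == s.dt.year.min())
            fy = regular[first_year]
            proj = geodesy.laea_for_points(fy["lat"], fy["lon"]) if len(fy) else None
            ud_rows = []
            for season in (seasons.WINTER, seasons.SPRING, seasons.SUMMER, seasons.AUTUMN):
                sel = fy[seasons.assign_season(fy["date"]) == season]
                if len(sel) == 0:
                    continue
                x, y = proj.forward(sel["lat"].to_numpy(), sel["lon"].to_numpy())
                grid = kernel_ud.utilization_distribution(
                    np.column_stack([x, y]), cfg.ud_smoothing_km, cfg.ud_cell_km)
                ud_rows.append({
                    "season": season, "n_positions": len(sel),
                    "area50_km2": kernel_ud.isopleth_area_km2(grid, 0.5),
                    "area95_km2": kernel_ud.isopleth_area_km2(grid, 0.95),
                })
            udf = pd.DataFrame(ud_rows)
            _write(udf, "ud_isopleth_areas.csv")
            results["ud"] = udf
    except Exception as err:  # re-raise with stage context preserved
        raise RuntimeError(f"pipeline failed: {err}") from err

    manifest = {
        "config_hash": cfg.config_hash(),
        "config": yaml.safe_load(yaml.safe_dump(asdict(cfg))),
        "outputs": written,
    }
    if parse_report is not None:
        manifest["parse_report"] = parse_report.as_dict()
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    written.append(str(out / "run_manifest.json"))
    return results
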