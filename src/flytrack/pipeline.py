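"""Stage-wise pipeline: simulate -> calibrate -> twilights -> locate ->
schedule -> phenology -> stats, with CSV artifacts between stages.

Each stage reads the previous stage's CSV from the artifact directory
and writes its own, so any stage can be re-run or inspected in
isolation.  A manifest records the configuration hash, seed and
package versions; re-running with the same configuration reproduces
the manifest byte-for-byte apart from the timestamp field.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import CalibrationModel, calibrate
from .fixtures import day_of_year, table1_fixture
from .geo import GeoPoint
from .light import (LightSeries, find_twilights, read_light,
                    read_twilights_csv, write_light_csv, write_twilights_csv)
from .locate import pair_twilights
from .phenology import (delimit_winter, detect_arrival, qc_rate_outlier,
                        records_to_frame, spring_metrics)
from .schedule import Schedule, segment_stationary
from .simulate import NoiseConfig, scenario, simulate_annual_track, simulate_light
from .sites import SITES
from .stats import fit_lm, group_summary, pearson_test
from .track import (LandMask, LocationPosterior, MCMCConfig, SpeedPrior,
                    sample_track_posterior)

log = logging.getLogger("flytrack")

STAGES = ["simulate", "calibrate", "twilights", "locate", "schedule", "phenology", "stats"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "flytrack_run"
    site: str = "EEI"
    seed: int = 1
    threshold: float = 0.5
    min_dark_minutes: float = 120.0
    truth_zenith_deg: float = 96.0
    calibration_days: int = 60
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    speed_prior: SpeedPrior = field(default_factory=SpeedPrior)
    land_mask_geojson: Optional[str] = None
    min_days: int = 2
    z_break: float = 2.0
    equinox_lon_only: bool = False
    equinox_window_days: int = 15
    qc_factor: float = 2.0
    alpha: float = 0.05
    scenario_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("noise", NoiseConfig), ("mcmc", MCMCConfig), ("speed_prior", SpeedPrior)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"config field 'site': unknown site {self.site!r}")
        if self.land_mask_geojson and not Path(self.land_mask_geojson).exists():
            raise ValueError(f"config field 'land_mask_geojson': no such file")
        if self.threshold <= 0:
            raise ValueError("config field 'threshold': must be > 0")


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' requires missing upstream artifact {path.name}; "
            "run the earlier stages first"
        )
    return path


def _config_hash(cfg: RunConfig) -> str:
    d = cfg.to_dict()
    d.pop("outdir", None)  # the analysis is defined by parameters, not paths
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, stages: Optional[Sequence[str]] = None) -> Path:
    """Execute the requested pipeline stages in order.

    Returns the artifact directory.  Stages not requested are skipped;
    a stage whose upstream artifact is missing raises with the artifact
    named.
    """
    cfg.validate()
    stages = list(stages) if stages else list(STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    site = SITES[cfg.site]

    timings = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.monotonic()
        log.info("stage %s ...", stage)

        if stage == "simulate":
            scen = scenario(cfg.site, **cfg.scenario_overrides)
            track = simulate_annual_track(scen, seed=cfg.seed)
            series = simulate_light(
                track, cfg.truth_zenith_deg, cfg.noise, seed=cfg.seed + 1
            )
            write_light_csv(series, out / "light.csv")
            track.positions.to_csv(out / "truth_positions.csv", index=False)
            truth = {k: str(v) for k, v in track.truth.items()}
            truth["fall_depart"] = scen.fall_depart.isoformat()
            truth["deploy"] = scen.deploy.isoformat()
            (out / "truth.json").write_text(json.dumps(truth, indent=1))

        elif stage == "calibrate":
            series = read_light(_need(out / "light.csv", stage))
            start = pd.Timestamp(series.times[0]).to_pydatetime()
            window = (start, start + dt.timedelta(days=cfg.calibration_days))
            calib = calibrate(series, site.point, window, cfg.threshold, cfg.min_dark_minutes)
            (out / "calibration.json").write_text(json.dumps(dataclasses.asdict(calib), indent=1))

        elif stage == "twilights":
            series = read_light(_need(out / "light.csv", stage))
            events = find_twilights(series, cfg.threshold, cfg.min_dark_minutes)
            write_twilights_csv(events, out / "twilights.csv")

        elif stage == "locate":
            events = read_twilights_csv(_need(out / "twilights.csv", stage))
            calib = CalibrationModel(**json.loads(_need(out / "calibration.json", stage).read_text()))
            pairs = pair_twilights(events)
            mask = LandMask.from_geojson(cfg.land_mask_geojson) if cfg.land_mask_geojson else None
            mcmc = dataclasses.replace(cfg.mcmc, seed=cfg.seed + 2)
            post = sample_track_posterior(pairs, calib, cfg.speed_prior, mask, mcmc)
            post.to_summary_csv(out / "posterior_summary.csv")

        elif stage == "schedule":
            post = LocationPosterior.from_summary_csv(_need(out / "posterior_summary.csv", stage))
            sched = segment_stationary(
                post, cfg.min_days, cfg.z_break, cfg.equinox_lon_only, cfg.equinox_window_days
            )
            sched.to_csv(out / "schedule.csv")

        elif stage == "phenology":
            sched = Schedule.from_csv(_need(out / "schedule.csv", stage))
            post = LocationPosterior.from_summary_csv(_need(out / "posterior_summary.csv", stage))
            search_from = None
            truth_file = out / "truth.json"
            if truth_file.exists():
                search_from = dt.date.fromisoformat(json.loads(truth_file.read_text())["fall_depart"])
            winter = delimit_winter(sched, search_from=search_from)
            if winter is None:
                records = []
            else:
                arrival = detect_arrival(post, site, winter.spring_initiation)
                rec = spring_metrics(sched, winter, arrival, site, individual_id=f"sim-{cfg.seed}")
                records = qc_rate_outlier([rec], cfg.qc_factor)
            records_to_frame(records).to_csv(out / "phenology.csv", index=False)

        elif stage == "stats":
            df = pd.read_csv(_need(out / "phenology.csv", stage))
            run_stats(df, out, alpha=cfg.alpha)

        timings[stage] = round(time.monotonic() - t0, 3)
        log.info("stage %s done in %.1fs", stage, timings[stage])

    manifest = {
        "package": "flytrack",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": stages,
        "timestamps": {"finished": dt.datetime.now().isoformat(), "timings_s": timings},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def run_stats(df: pd.DataFrame, out: Path, alpha: float = 0.05) -> None:
    """Group summaries and site models for a phenology table."""
    out.mkdir(parents=True, exist_ok=True)
    df = df.copy()
    for col in ("spring_initiation", "spring_arrival"):
        if col in df:
            df[col] = pd.to_datetime(df[col], errors="coerce").dt.date
    if "excluded" in df:
        df = df[~df["excluded"].fillna(False).astype(bool)]
    variables = [
        "n_winter_sites", "winter_duration_days", "n_spring_stopovers",
        "spring_duration_days", "spring_distance_km", "spring_rate_km_per_day",
        "spring_stopover_days", "spring_initiation", "spring_arrival",
    ]
    variables = [v for v in variables if v in df.columns]
    gs = group_summary(df, "group", variables)
    gs.to_csv(out / "group_summary.csv", index=False)

    if df["site"].nunique() > 1 and len(df) > df["site"].nunique() + 1:
        df["initiation_doy"] = day_of_year(df["spring_initiation"])
        df["arrival_doy"] = day_of_year(df["spring_arrival"])
        model_rows = []
        for resp in ("spring_duration_days", "spring_distance_km", "initiation_doy", "arrival_doy"):
            sub = df.dropna(subset=[resp])
            if sub["site"].nunique() < 2:
                continue
            fit = fit_lm(resp, ["site"], sub)
            frame = fit.to_frame()
            frame.insert(0, "response", resp)
            frame["df_resid"] = fit.df_resid
            model_rows.append(frame)
        if model_rows:
            pd.concat(model_rows).to_csv(out / "site_models.csv", index=False)


def stats_on_fixture(out: Path, alpha: float = 0.05) -> Path:
    """Run the stats stage on the packaged migration-history table."""
    out = Path(out)
    df = table1_fixture()
    run_stats(df, out, alpha=alpha)
    return out / "group_summary.csv"
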