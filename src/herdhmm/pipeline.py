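"""One-command orchestration of the full analysis.

Stages run in dependency order: simulate (optional) -> prepare ->
trajectory -> fit/select (or load a fixed model) -> decode -> annotate ->
summarise.  Every run writes a manifest naming, for each output file, the
SHA-256 of its inputs, the stage configuration hash and the global seed, so
artefacts are traceable; a stage whose input hashes match a previous run is
reused from cache rather than recomputed (multistart fitting is by far the
expensive stage).  All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import summaries, track_io
from .fit import FitOptions, multistart_fit, table1_bounds
from .landuse import LandUseMap, join_fixes
from .likelihood import viterbi
from .model import HmmModel, canonicalize, reference_model
from .synthetic import SimConfig, simulate_survey
from .trajectory import compute_steps


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0

    # input sources: either synthetic simulation or file paths
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    gps_path: str | None = None
    meta_path: str | None = None
    landuse_paths: tuple[str, ...] = ()
    legend_path: str | None = None

    # cleaning
    interval_min: float = 30.0
    tolerance_min: float = 5.0
    min_len: int = 10

    # model stage: "fit" with multistart, or "fixture" to decode with a
    # fixed model file (model_path, or the packaged reference model)
    model_stage: str = "fit"
    model_path: str | None = None
    n_states: int = 3
    n_restarts: int = 5
    covariates: tuple[str, ...] = ()
    step_family: str = "truncnorm"
    maxiter: int = 1000

    # summaries
    budget_keys: tuple[str, ...] = ("hour", "herd_type")
    stop_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("landuse_paths", "covariates", "budget_keys"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc.pop("out_dir")
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _hash_file(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class _Log:
    def __init__(self, path: pathlib.Path):
        self.path = path
        self.entries: list[dict] = []

    def stage(self, name: str, t0: float, **info):
        entry = {"stage": name, "elapsed_s": round(time.time() - t0, 3), **info}
        self.entries.append(entry)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> pathlib.Path:
    """Execute all stages; returns the output directory.

    Outputs: gps/metadata (if simulated), segments.csv, series.csv,
    model.json, decoded.csv, annotated.csv, budgets.csv, daily_metrics.csv,
    phases.json, report.json, manifest.json, log.jsonl.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "log.jsonl")
    (out / "log.jsonl").write_text("")
    chash = config.config_hash()
    manifest: dict[str, dict] = {}

    def note(fname: str, **inputs):
        manifest[fname] = {"config_hash": chash, "seed": config.seed, **inputs}

    # ---- inputs ----------------------------------------------------------
    t0 = time.time()
    if config.simulate:
        sim_cfg = SimConfig(seed=config.seed, **config.sim)
        survey = simulate_survey(sim_cfg, reference_model())
        survey.write(out / "input")
        gps_path = out / "input" / "gps.csv"
        meta_path = out / "input" / "metadata.csv"
        maps = survey.landuse
        note("input/gps.csv", source="synthetic")
        note("input/metadata.csv", source="synthetic")
        log.stage("simulate", t0, n_fixes=len(survey.gps))
    else:
        if not config.gps_path or not config.meta_path:
            raise ValueError("gps_path and meta_path required when simulate=false")
        gps_path = pathlib.Path(config.gps_path)
        meta_path = pathlib.Path(config.meta_path)
        legend = {}
        if config.legend_path:
            with open(config.legend_path) as fh:
                legend = yaml.safe_load(fh)
        maps = [
            LandUseMap.from_geojson(p, legend, priority=len(config.landuse_paths) - i,
                                    resolution_tag=pathlib.Path(p).stem)
            for i, p in enumerate(config.landuse_paths)
        ]

    # ---- prepare ---------------------------------------------------------
    t0 = time.time()
    gps, read_report = track_io.read_gps_table(gps_path)
    meta = track_io.read_metadata(meta_path)
    segments, filter_report = track_io.assign_and_segment(
        gps, meta,
        interval=dt.timedelta(minutes=config.interval_min),
        tolerance=dt.timedelta(minutes=config.tolerance_min),
        min_len=config.min_len,
    )
    centre = track_io.dataset_centre(gps)
    seg_frames = []
    for seg in segments:
        f = seg.fixes.copy()
        f["segment_id"] = seg.segment_id
        labels = track_io.label_time(f["timestamp"], centre)
        f["season"] = labels["season"].to_numpy()
        f["diel"] = labels["diel"].to_numpy()
        seg_frames.append(f)
    if not seg_frames:
        raise RuntimeError("prepare stage produced no usable segments")
    fixes = pd.concat(seg_frames, ignore_index=True)
    fixes.to_csv(out / "segments.csv", index=False)
    note("segments.csv", gps=_hash_file(gps_path), meta=_hash_file(meta_path))
    log.stage("prepare", t0, n_collected=filter_report.n_collected,
              n_usable=filter_report.n_usable,
              pct_removed=round(filter_report.pct_removed, 3))

    # ---- trajectory ------------------------------------------------------
    t0 = time.time()
    cov_cols = tuple(c for c in config.covariates if c in fixes.columns)
    series = [compute_steps(seg, covariate_columns=cov_cols) for seg in segments]
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(
        out / "series.csv", index=False
    )
    note("series.csv", segments=_hash_file(out / "segments.csv"))
    log.stage("trajectory", t0, n_segments=len(series),
              n_obs=sum(s.n_obs for s in series))

    # ---- model -----------------------------------------------------------
    t0 = time.time()
    model_file = out / "model.json"
    if config.model_stage == "fixture":
        model = (HmmModel.load(config.model_path) if config.model_path
                 else reference_model())
        model.save(model_file, provenance={"source": config.model_path or
                                           "packaged reference model",
                                           "config_hash": chash})
        log.stage("model", t0, mode="fixture")
    elif config.model_stage == "fit":
        cache_key = {"series": _hash_file(out / "series.csv"),
                     "n_states": config.n_states, "n_restarts": config.n_restarts,
                     "seed": config.seed, "covariates": list(cov_cols),
                     "step_family": config.step_family, "maxiter": config.maxiter}
        cache_path = out / "model.cache.json"
        if cache_path.exists() and model_file.exists():
            try:
                if json.loads(cache_path.read_text()) == cache_key:
                    model = HmmModel.load(model_file)
                    log.stage("model", t0, mode="cached")
                else:
                    raise KeyError
            except (KeyError, ValueError):
                cache_path.unlink()
        if not (cache_path.exists() and model_file.exists()):
            p0 = float(np.mean([s.p0 for s in series]))
            bounds = (table1_bounds(p0) if config.n_states == 3 else None)
            best, summary = multistart_fit(
                series, config.n_states, bounds=bounds,
                n_restarts=config.n_restarts, seed=config.seed,
                covariates=cov_cols, step_family=config.step_family,
                opts=FitOptions(maxiter=config.maxiter),
            )
            model, _ = canonicalize(best.model)
            model.save(
                model_file,
                provenance={"loglik": best.loglik, "n_restarts": config.n_restarts,
                            "consensus": summary.consensus, "seed": config.seed,
                            "config_hash": chash},
            )
            cache_path.write_text(json.dumps(cache_key) + "\n")
            log.stage("model", t0, mode="fit", loglik=best.loglik,
                      consensus=summary.consensus)
    else:
        raise ValueError(f"unknown model_stage: {config.model_stage!r}")
    note("model.json", series=_hash_file(out / "series.csv"))

    # ---- decode ----------------------------------------------------------
    t0 = time.time()
    paths = viterbi(model, series)
    names = (summaries_state_names(model))
    decoded_rows = []
    for seg, s, path in zip(segments, series, paths):
        f = seg.fixes.copy()
        # observation t covers the step out of fix t; the final fix inherits
        state_idx = np.concatenate([path, path[-1:]]) if len(path) else np.array([])
        f["state"] = [names[i] for i in state_idx]
        f["segment_id"] = seg.segment_id
        steps = np.concatenate([s.steps, [np.nan]]) if s.n_obs else np.array([np.nan])
        f["step_m"] = steps
        decoded_rows.append(f)
    decoded = pd.concat(decoded_rows, ignore_index=True)
    labels = track_io.label_time(decoded["timestamp"], centre)
    decoded["season"] = labels["season"].to_numpy()
    decoded["diel"] = labels["diel"].to_numpy()
    decoded.to_csv(out / "decoded.csv", index=False)
    note("decoded.csv", model=_hash_file(model_file))
    log.stage("decode", t0, n_fixes=len(decoded))

    # ---- annotate --------------------------------------------------------
    t0 = time.time()
    annotated = join_fixes(decoded, maps) if maps else decoded.assign(
        unit="unclassified", source_layer="")
    annotated.to_csv(out / "annotated.csv", index=False)
    note("annotated.csv", decoded=_hash_file(out / "decoded.csv"))
    log.stage("annotate", t0)

    # ---- summarise -------------------------------------------------------
    t0 = time.time()
    budgets = summaries.activity_budget(annotated, keys=list(config.budget_keys))
    budgets.to_csv(out / "budgets.csv", index=False)
    metrics = summaries.daily_metrics(annotated, daytime_only=True)
    metrics.to_csv(out / "daily_metrics.csv", index=False)
    from shapely.geometry import Point

    home = Point(centre[1], centre[0]).buffer(0.03)  # ~3 km in degrees
    phase_docs = []
    for herd, grp in annotated.groupby("herd_id"):
        rec = summaries.detect_stops_and_phases(
            grp.sort_values("timestamp"), home,
            summaries.StopParams(seed=config.seed, **config.stop_params),
            herd_id=str(herd),
        )
        phase_docs.append(_phase_to_dict(rec))
    with open(out / "phases.json", "w") as fh:
        json.dump(phase_docs, fh, indent=2, default=str)
        fh.write("\n")
    note("budgets.csv", annotated=_hash_file(out / "annotated.csv"))
    note("daily_metrics.csv", annotated=_hash_file(out / "annotated.csv"))
    note("phases.json", annotated=_hash_file(out / "annotated.csv"))
    log.stage("summarise", t0, n_herds=int(annotated["herd_id"].nunique()))

    report = {
        "config_hash": chash,
        "seed": config.seed,
        "filter": {"n_collected": filter_report.n_collected,
                   "n_usable": filter_report.n_usable,
                   "pct_removed": filter_report.pct_removed,
                   "removed": filter_report.removed,
                   "n_duplicates": read_report.n_duplicates,
                   "n_malformed": len(read_report.issues)},
        "state_shares_pct": {
            name: round(100.0 * float((decoded["state"] == name).mean()), 2)
            for name in names
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def summaries_state_names(model: HmmModel) -> list[str]:
    if model.n_states == 3:
        return ["resting", "foraging", "travelling"]
    return [f"state{i + 1}" for i in range(model.n_states)]


def _phase_to_dict(rec) -> dict:
    return {
        "herd_id": rec.herd_id,
        "departure": str(rec.departure) if rec.departure else None,
        "return": str(rec.return_date) if rec.return_date else None,
        "stops": [
            {"lat": s.centroid_lat, "lon": s.centroid_lon,
             "start": str(s.start), "end": str(s.end),
             "duration_days": s.duration_days}
            for s in rec.stops
        ],
        "phases": [{"label": p[0], "start": str(p[1]), "end": str(p[2])}
                   for p in rec.phases],
        "stop_duration_cluster_means": rec.cluster_means,
    }
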