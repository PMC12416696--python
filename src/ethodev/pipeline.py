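"""End-to-end orchestration: clean -> classify -> devstats -> networks -> circadian.

A :class:`PipelineConfig` (plain YAML on disk) names either an input dataset
(canonical-h5 tracks + huddle CSV) or a simulation spec, plus thresholds,
stage toggles, an output directory and a master seed.  Per-stage seeds are
derived from the master seed with ``numpy.random.SeedSequence.spawn`` in a
fixed stage order, so each stage is independently reproducible.  Outputs are
deterministic CSV/GraphML artifacts plus a manifest recording the config
hash and a content hash per artifact.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior_classify as bc
from . import circadian as circ
from . import development_stats as ds
from . import social_networks as sn
from . import track_cleanup as tc
from .synthetic_data import SimConfig, inject_id_swaps, simulate_family
from .trajectory_io import (
    DailyBehaviorMatrix,
    HuddleTrack,
    TrackSet,
    load_huddles,
    load_trackset,
    write_daily_matrix,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("ethodev")

STAGES = ("clean", "classify", "devstats", "networks", "circadian")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; see module docstring."""

    out_dir: str = "ethodev_out"
    seed: int = 0
    tracks_path: str | None = None
    huddles_path: str | None = None
    simulate: dict | None = None  # kwargs for SimConfig
    inject_swaps_per_day: float = 0.0
    stages: tuple[str, ...] = STAGES
    jump_cm: float = tc.DEFAULT_JUMP_CM
    refit_cm: float = tc.DEFAULT_REFIT_CM
    max_gap_cm: float = 3.0
    max_huddle_gap_s: float = 30.0
    proximity_dist_cm: float = 5.0
    proximity_min_dur_ms: float = 200.0
    reference_day: int = 29
    ks_comparison: str = "previous_only"
    circadian_behavior: str = "food_hopper"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> "PipelineConfig":
        if self.simulate is None and self.tracks_path is None:
            raise ValueError("config must provide either tracks_path or a simulate spec")
        for p in (self.tracks_path, self.huddles_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for name in ("jump_cm", "refit_cm", "max_gap_cm", "max_huddle_gap_s",
                     "proximity_dist_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        return self


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    # output location and verbosity do not affect the computation
    d = {k: v for k, v in asdict(config).items() if k not in ("out_dir", "log_level")}
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(STAGES) + 1)
    seeds = {"simulate": int(children[0].generate_state(1)[0] % 2**31)}
    for stage, child in zip(STAGES, children[1:]):
        seeds[stage] = int(child.generate_state(1)[0] % 2**31)
    return seeds


def _classify(tracks: TrackSet, huddles: HuddleTrack, config: PipelineConfig):
    nest = bc.infer_nest_region(huddles)
    adults = [a.name for a in tracks.animals if a.age_class == "adult"]
    pups = [a.name for a in tracks.animals if a.age_class == "pup"]
    days = [int(d) for d in tracks.days()]
    matrices: dict[str, DailyBehaviorMatrix] = {}

    def mat(behavior: str, units: str, series_by_animal: dict[str, pd.Series]):
        df = pd.DataFrame(series_by_animal).T.reindex(columns=days)
        matrices[behavior] = DailyBehaviorMatrix(behavior, units, df)

    mat("open_exploration", "hrs/day",
        {n: bc.open_exploration(tracks, n, nest) for n in tracks.animal_names})
    mat("distance_traveled", "m/day",
        {n: bc.distance_traveled(tracks, n) for n in tracks.animal_names})
    for roi in tracks.cage.rois:
        mat(roi, "hrs/day",
            {n: bc.roi_occupancy(tracks, n, roi)[1] for n in tracks.animal_names})
    hud = bc.huddle_time(tracks, huddles)
    matrices["huddling"] = DailyBehaviorMatrix(
        "huddling", "hrs/day", hud.reindex(columns=days))
    params = bc.ProximityParams(config.proximity_dist_cm, config.proximity_min_dur_ms)
    prox: dict[str, pd.Series] = {}
    for n in tracks.animal_names:
        total = pd.Series(0.0, index=days)
        for other in tracks.animal_names:
            if other == n:
                continue
            bouts = bc.pairwise_proximity(tracks, n, other, params)
            total = total.add(bc.proximity_minutes_daily(tracks, bouts), fill_value=0.0)
        prox[n] = total
    mat("proximity", "min/day", prox)
    group = bc.group_time_daily(tracks)
    for key, df in group.items():
        matrices[f"group_{key}"] = DailyBehaviorMatrix(
            f"group_{key}", "hrs/day", df.reindex(columns=days))
    follow_counts = {}
    if pups and adults:
        pup_exits = np.sort(np.concatenate(
            [bc.nest_exits(tracks, huddles, nest, p) for p in pups]))
        adult_exits_all = {a: bc.nest_exits(tracks, huddles, nest, a) for a in adults}
        t = tracks.timestamps
        for d in days:
            sel = tracks.pnd == d
            lo, hi = t[sel][0], t[sel][-1]
            p_ex = pup_exits[(pup_exits >= lo) & (pup_exits <= hi)]
            a_ex = np.sort(np.concatenate(
                [v[(v >= lo) & (v <= hi)] for v in adult_exits_all.values()]))
            follow_counts[d] = bc.nest_following(p_ex, a_ex) / tracks.day_coverage(d)
    return matrices, nest, follow_counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the manifest dict."""
    t0 = time.time()
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": {},
        "artifacts": {},
    }

    def record(stage: str, **counts):
        manifest["stages"][stage] = {"elapsed_s": round(time.time() - t0, 3), **counts}
        log.info("stage %s done: %s", stage, counts)

    def artifact(name: str, path: Path):
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", seeds["simulate"])
        tracks, huddles, truth = simulate_family(SimConfig(**sim_kwargs))
        swap_log: list = []
        if config.inject_swaps_per_day > 0:
            tracks, swap_log = inject_id_swaps(
                tracks, config.inject_swaps_per_day, seed=seeds["simulate"])
            truth.swap_log = swap_log
    else:
        tracks = load_trackset(config.tracks_path)
        huddles = load_huddles(config.huddles_path) if config.huddles_path else HuddleTrack(
            np.empty((0, 4)))
    record("input", n_frames=tracks.n_frames, n_animals=len(tracks.animals))

    # --- clean ------------------------------------------------------------
    if "clean" in config.stages:
        # The jump criterion flags physically implausible per-frame
        # displacements.  If displacements above the threshold are routine
        # at this sampling interval (coarsely subsampled data), the
        # criterion cannot separate errors from locomotion — skip detection.
        step = np.linalg.norm(np.diff(tracks.positions, axis=0), axis=-1)
        contiguous = np.diff(tracks.timestamps) <= 1.5 / tracks.fps
        step = step[contiguous]
        frac_jump = np.nanmean(step > config.jump_cm) if np.isfinite(step).any() else 0.0
        if frac_jump > 1e-3:
            log.warning(
                "%.2f%% of frame steps exceed jump_cm=%.1f at dt=%.2fs; "
                "identity-switch detection skipped as unreliable",
                100 * frac_jump, config.jump_cm, 1.0 / tracks.fps,
            )
            events = []
        else:
            events = tc.detect_id_switches(tracks, config.jump_cm, config.refit_cm)
        tracks = tc.correct_id_switches(tracks, events)
        tracks, huddles = tc.interpolate_gaps(
            tracks, huddles, config.max_gap_cm, config.max_huddle_gap_s)
        p = out / "swap_log.csv"
        tc.write_swap_log(events, p)
        artifact("swap_log", p)
        record("clean", n_swaps=len(events))

    # --- classify ---------------------------------------------------------
    matrices = {}
    if "classify" in config.stages:
        matrices, nest, follow_counts = _classify(tracks, huddles, config)
        for name, m in matrices.items():
            p = out / f"behavior_{name}.csv"
            write_daily_matrix(m, p)
            artifact(f"behavior_{name}", p)
        if follow_counts:
            p = out / "nest_following.csv"
            pd.Series(follow_counts, name="count_per_day").rename_axis("pnd").to_csv(p)
            artifact("nest_following", p)
        record("classify", n_behaviors=len(matrices))

    # --- devstats ---------------------------------------------------------
    if "devstats" in config.stages and matrices:
        pups = [a.name for a in tracks.animals if a.age_class == "pup"]
        flags_rows, rel = [], {}
        for name, m in matrices.items():
            try:
                traj = ds.normalize_to_adult(m, reference_day=config.reference_day)
            except ValueError:
                continue
            rel[name] = traj.values
            if len(pups) >= 3:
                fl = ds.rapid_development_days(
                    traj.values, comparison=config.ks_comparison)
                flags_rows += [
                    (name, d, fl.p_adjusted.get(d, np.nan)) for d in sorted(fl.flagged_days)
                ]
        p = out / "rapid_development_flags.csv"
        pd.DataFrame(flags_rows, columns=["behavior", "pnd", "p_adj"]).to_csv(p, index=False)
        artifact("rapid_development_flags", p)
        overlap_rows = []
        names = sorted(rel)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if len(rel[a]) < 4 or len(rel[b]) < 4:
                    continue
                pct = ds.hull_overlap(rel[a], rel[b], seed=seeds["devstats"])
                overlap_rows.append((a, b, 3, pct))
        p = out / "hull_overlaps.csv"
        pd.DataFrame(
            overlap_rows, columns=["behavior_a", "behavior_b", "n_pcs", "percent"]
        ).to_csv(p, index=False)
        artifact("hull_overlaps", p)
        if rel:
            corr = ds.trajectory_correlations(rel)
            p = out / "trajectory_correlations.csv"
            corr.to_csv(p, index=False)
            artifact("trajectory_correlations", p)
        record("devstats", n_flag_rows=len(flags_rows), n_overlaps=len(overlap_rows))

    # --- networks ---------------------------------------------------------
    if "networks" in config.stages:
        rows = []
        graph_dir = out / "graphs"
        graph_dir.mkdir(exist_ok=True)
        for subset_name, subset in sn.network_subsets(tracks).items():
            for d in tracks.days():
                sel = tracks.pnd == d
                if sel.sum() < 2:
                    continue
                seq = sn.state_sequence(tracks, subset)[sel]
                g = sn.build_state_graph(seq, tracks.timestamps[sel], tracks.fps)
                m = sn.graph_metrics(g)
                rows.append((subset_name, int(d), m["size"], m["n_cycles"],
                             m["transitivity"], m["mean_path_length"]))
                if subset_name == "all-animals":
                    stem = graph_dir / f"all-animals_p{int(d)}"
                    sn.write_edge_list(g, stem.with_suffix(".csv"))
                    sn.write_graphml(g, stem.with_suffix(".graphml"))
                    artifact(f"graph_all-animals_p{int(d)}", stem.with_suffix(".csv"))
        p = out / "network_metrics.csv"
        pd.DataFrame(rows, columns=[
            "subset", "pnd", "size", "n_cycles", "transitivity", "mean_path_length"
        ]).to_csv(p, index=False)
        artifact("network_metrics", p)
        record("networks", n_graphs=len(rows))

    # --- circadian --------------------------------------------------------
    if "circadian" in config.stages:
        roi = config.circadian_behavior
        profiles: dict[tuple[str, int], np.ndarray] = {}
        prof_rows = []
        midnight_off = float(tracks.wall_seconds()[0] - tracks.timestamps[0])
        for name in tracks.animal_names:
            bouts, _ = bc.roi_occupancy(tracks, name, roi)
            for d in tracks.days():
                sel = tracks.pnd == d
                t = tracks.timestamps[sel]
                lo, hi = t[0], t[-1] + 1.0 / tracks.fps
                acc = np.zeros(24)
                for s, e in bouts.bouts:
                    s2, e2 = max(s, lo), min(e, hi)
                    tt = s2
                    while tt < e2:
                        wall = (tt + midnight_off) % 86400.0
                        h = int(wall // 3600)
                        seg = min(e2, tt + 3600.0 - wall % 3600.0) - tt
                        acc[h] += seg
                        tt += seg
                for h in range(24):
                    prof_rows.append((name, int(d), h, acc[h]))
                if acc.sum() > 0:
                    profiles[(name, int(d))] = acc / acc.sum()
        p = out / "circadian_profiles.csv"
        pd.DataFrame(prof_rows, columns=["animal", "pnd", "hour", "value"]).to_csv(
            p, index=False)
        artifact("circadian_profiles", p)
        days_avail = sorted({d for _, d in profiles})
        if len(days_avail) >= 6:
            res = circ.find_transitions(profiles)
            p = out / "circadian_transitions.csv"
            res.surface.assign(best_t1=res.t1, best_t2=res.t2).to_csv(p, index=False)
            artifact("circadian_transitions", p)
            record("circadian", t1=res.t1, t2=res.t2)
        else:
            record("circadian", skipped="fewer than 6 days with activity")

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    content = {
        "config_hash": manifest["config_hash"],
        "seed": manifest["seed"],
        "artifact_hashes": {k: v["sha256"] for k, v in manifest["artifacts"].items()},
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(content, sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
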