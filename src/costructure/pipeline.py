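"""End-to-end orchestration: config-driven runs from inputs to reports.

A run directory receives every stage artifact plus ``manifest.json`` (config
snapshot, seeds, package version, per-stage row counts), which suffices to
reproduce the run exactly.  Stages:

synth → features → dtw → costructure → regress → embed

Inputs are either a synthetic-generator config (``synth`` section) or paths
to a motif table, per-performance kinematic CSVs and per-performance sonic
tracks (precomputed f0/loudness/centroid CSVs, or WAV audio).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ingest, sonic
from .dtw import DtwParams, FEATURE_COLUMNS, build_distance_table
from .ingest import MotifRecord
from .kinematics import compute_kinematic_features
from .regression import DEFAULT_GRID, reports_frame, run_suite
from .stats import analyze_costructure, profile_summary, shuffle_null
from .synth import SynthConfig, SynthDataset, generate_dataset

__all__ = ["run_pipeline", "export_embedding", "load_config", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"{path} did not parse to a mapping")
    return cfg


def _synth_stage(cfg: dict, outdir: Path, manifest: dict) -> SynthDataset:
    synth_cfg = SynthConfig(**cfg.get("synth", {}))
    ds = generate_dataset(synth_cfg)
    ingest.write_motif_table(ds.motif_table, outdir / "motif_table.csv")
    manifest["stages"]["synth"] = {
        "n_motifs": len(ds.motif_table),
        "config": asdict(synth_cfg),
    }
    return ds


def _features_from_disk(cfg: dict, outdir: Path, manifest: dict):
    inputs = cfg.get("inputs")
    if not inputs or "motif_table" not in inputs:
        raise PipelineError("features", "config has no synth section and no inputs.motif_table")
    for key in ("kinematics",):
        if key not in inputs:
            raise PipelineError("features", f"inputs.{key} missing from config")
    records = ingest.read_motif_table(inputs["motif_table"])
    sonic_rate = float(cfg.get("sonic", {}).get("rate_hz", sonic.DEFAULT_FRAME_RATE_HZ))
    kin_rate = float(cfg.get("kinematic", {}).get("rate_hz", 60.0))

    son_feats: dict[str, sonic.SonicFeatures] = {}
    kin_feats: dict = {}
    excluded: list[str] = []
    perf_ids = sorted({r.performance_id for r in records})
    for perf in perf_ids:
        recs = [r for r in records if r.performance_id == perf]
        kin_path = inputs["kinematics"].get(perf) if isinstance(inputs["kinematics"], dict) else None
        if kin_path is None:
            raise PipelineError("features", f"no kinematics path for performance {perf!r}")
        frames = ingest.read_kinematics(kin_path, kin_rate)

        f0_path = inputs.get("f0", {}).get(perf)
        audio_path = inputs.get("audio", {}).get(perf)
        if f0_path is not None:
            _, f0_track = ingest.read_feature_series(f0_path, "f0")
            loud_track = cent_track = None
            if inputs.get("loudness", {}).get(perf):
                _, loud_track = ingest.read_feature_series(inputs["loudness"][perf], "loudness")
            if inputs.get("centroid", {}).get(perf):
                _, cent_track = ingest.read_feature_series(inputs["centroid"][perf], "centroid")
            if loud_track is None or cent_track is None:
                raise PipelineError(
                    "features",
                    f"performance {perf!r}: precomputed f0 without loudness/centroid "
                    "tracks requires audio",
                )
            wav = sr = None
        elif audio_path is not None:
            wav, sr = ingest.read_audio(audio_path)
            f0_track = loud_track = cent_track = None
        else:
            raise PipelineError("features", f"performance {perf!r} has neither f0 nor audio input")

        for rec in recs:
            try:
                if f0_track is not None:
                    feats, ok = sonic.compute_sonic_features(
                        None, None, sonic_rate,
                        f0_track=ingest.slice_motif(f0_track, sonic_rate, rec),
                        loudness_track=ingest.slice_motif(loud_track, sonic_rate, rec),
                        centroid_track=ingest.slice_motif(cent_track, sonic_rate, rec),
                    )
                else:
                    seg = ingest.slice_motif(wav, sr, rec)
                    feats, ok = sonic.compute_sonic_features(seg, sr, sonic_rate)
            except ValueError as e:
                warnings.warn(f"motif {rec.motif_id}: excluded ({e})", stacklevel=2)
                excluded.append(rec.motif_id)
                continue
            if not ok:
                excluded.append(rec.motif_id)
            son_feats[rec.motif_id] = feats

            segs = {
                seg: {k: ingest.slice_motif(d[k], kin_rate, rec) for k in ("pos", "vel", "acc")}
                for seg, d in frames.items()
            }
            kin_feats[rec.motif_id] = compute_kinematic_features(segs, kin_rate)
    manifest["stages"]["features"] = {
        "n_motifs": len(records),
        "excluded_pitch_gap": sorted(excluded),
    }
    return records, son_feats, kin_feats, excluded


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Run every stage under one config; returns the run directory."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {"version": __version__, "seed": seed, "config": cfg, "stages": {}}

    # --- features (synthetic or from disk) ---
    if "synth" in cfg:
        try:
            ds = _synth_stage(cfg, outdir, manifest)
        except (ValueError, TypeError) as e:
            raise PipelineError("synth", str(e)) from e
        records, son_feats, kin_feats, excluded = ds.motif_table, ds.sonic, ds.kinematic, []
        manifest["stages"]["features"] = {"n_motifs": len(records), "excluded_pitch_gap": []}
    else:
        records, son_feats, kin_feats, excluded = _features_from_disk(cfg, outdir, manifest)

    motif_df = ingest.motif_frame(records)

    # --- dtw ---
    try:
        params = DtwParams(**cfg.get("dtw", {}))
        table = build_distance_table(son_feats, kin_feats, motif_df, params, excluded=set(excluded))
    except ValueError as e:
        raise PipelineError("dtw", str(e)) from e
    ingest.write_distance_table(table, outdir / "distance_table.csv")
    manifest["stages"]["dtw"] = {"n_pairs": len(table), "params": asdict(params)}

    # --- costructure ---
    try:
        stats_cfg = cfg.get("costructure", {})
        profiles = analyze_costructure(
            table, motif_df[~motif_df["motif_id"].isin(excluded)],
            seed=seed, alpha=float(stats_cfg.get("alpha", 0.0001)),
        )
        summary = profile_summary(profiles)
        summary.to_csv(outdir / "costructure_profiles.csv", index=False, float_format="%.12g")
        if stats_cfg.get("shuffle_control", True):
            null_profiles = analyze_costructure(
                shuffle_null(table, seed), motif_df[~motif_df["motif_id"].isin(excluded)],
                seed=seed, alpha=float(stats_cfg.get("alpha", 0.0001)),
            )
            profile_summary(null_profiles).to_csv(
                outdir / "costructure_profiles_shuffled.csv", index=False, float_format="%.12g"
            )
        manifest["stages"]["costructure"] = {
            "n_tests": int(profiles[0].n_tests),
            "n_significant": int(summary["significant"].sum()),
        }
    except ValueError as e:
        raise PipelineError("costructure", str(e)) from e

    # --- regression ---
    reg_cfg = cfg.get("regression", {})
    if reg_cfg.get("enabled", True):
        try:
            reports = run_suite(
                table,
                performer_sets=reg_cfg.get("performer_sets"),
                targets=tuple(reg_cfg.get("targets", ("f0", "delta_f0", "loudness", "spectral_centroid"))),
                feature_sets=tuple(reg_cfg.get("feature_sets", ("randomized", "head", "hand", "all"))),
                seed=seed,
                grid={k: tuple(v) for k, v in reg_cfg["grid"].items()} if "grid" in reg_cfg else None,
            )
            reports_frame(reports).to_csv(outdir / "regression_reports.csv", index=False, float_format="%.12g")
            manifest["stages"]["regress"] = {"n_reports": len(reports)}
        except ValueError as e:
            raise PipelineError("regress", str(e)) from e

    # --- embedding export ---
    emb_cfg = cfg.get("embedding", {})
    if emb_cfg.get("enabled", False):
        feature = emb_cfg.get("feature", "f0")
        coords = export_embedding(table, feature, seed=seed)
        coords.to_csv(outdir / f"embedding_{feature}.csv", index=False, float_format="%.12g")
        manifest["stages"]["embed"] = {"feature": feature, "n_motifs": len(coords)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return outdir


def export_embedding(table: pd.DataFrame, feature: str, seed: int = 0) -> pd.DataFrame:
    """Seeded 2-D coordinates per motif from one precomputed distance column.

    A metric MDS projection of the motif-by-motif distance matrix; for
    qualitative map-making only — no statistics are performed on
    dimensionality-reduced coordinates.
    """
    from sklearn.manifold import MDS

    if feature not in FEATURE_COLUMNS:
        raise ValueError(f"unknown feature {feature!r}")
    col = table[feature]
    if col.isna().any():
        raise ValueError(f"distance column {feature!r} is incomplete")
    ids = sorted(set(table["motif_i"]) | set(table["motif_j"]))
    index = {m: k for k, m in enumerate(ids)}
    n = len(ids)
    D = np.zeros((n, n))
    for mi, mj, d in zip(table["motif_i"], table["motif_j"], col):
        D[index[mi], index[mj]] = D[index[mj], index[mi]] = d
    mds = MDS(n_components=2, metric="precomputed", init="random", random_state=seed)
    xy = mds.fit_transform(D)
    return pd.DataFrame({"motif_id": ids, "x": xy[:, 0], "y": xy[:, 1]})
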