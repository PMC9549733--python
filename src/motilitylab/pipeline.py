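"""End-to-end pipeline: ingest/simulate → filter → (drift-correct) →
features → state space → condition test, with deterministic, provenance-
stamped delimited-text outputs."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .driftcorr import apply_drift_correction, estimate_drift
from .features import FeatureParams, feature_table
from .io import TrackSet, filter_tracks, read_tracks_table, write_tracks_table
from .simulate import add_shared_drift, default_2d_config, default_3d_config, simulate_tracks
from .statespace import (
    cluster_1d,
    condition_cluster_test,
    normalized_feature_means,
    reduce_and_cluster,
    tsne_embed,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Run configuration; buildable from a YAML mapping via ``from_dict``."""

    scenario: str = "default_2d"  # default_2d | default_3d | input
    n_tracks: int = 120  # per condition, for simulated scenarios
    seed: int = 0
    min_length: int = 61
    inputs: list[dict] = field(default_factory=list)
    frame_interval: float = 10.0
    features: dict = field(default_factory=dict)
    var_target: float = 0.95
    max_components: int = 30
    k: int = 2
    perplexity: float = 35.0
    drift_threshold: float = 0.95
    n_fiducials: int = 10
    fiducial_jitter_sd: float = 0.2
    drift_spec: dict = field(default_factory=lambda: {"model": "sine", "amplitude": 5.0})
    outdir: str = "motilitylab_out"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def _provenance(cfg: RunConfig) -> list[str]:
    return [f"motilitylab {__version__}", f"config_hash={cfg.config_hash()}",
            f"seed={cfg.seed}"]


def _write_df(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in _provenance(cfg):
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=index, float_format="%.6f")


def _gather_inputs(cfg: RunConfig):
    """Returns (cells TrackSet, fiducials TrackSet | None, truth DataFrame | None)."""
    if cfg.scenario == "input":
        if not cfg.inputs:
            raise ValueError("scenario 'input' needs at least one inputs entry")
        tracks = []
        fids = []
        for spec in cfg.inputs:
            ts = read_tracks_table(
                spec["path"],
                dialect=spec.get("dialect", "generic"),
                frame_interval=spec.get("frame_interval", cfg.frame_interval),
                condition=spec.get("condition", "unspecified"),
            )
            (fids if spec.get("role") == "fiducial" else tracks).extend(ts.tracks)
        cells = TrackSet(tracks, tracks[0].frame_interval)
        fiducials = TrackSet(fids, fids[0].frame_interval) if fids else None
        return cells, fiducials, None

    base = default_2d_config if cfg.scenario == "default_2d" else default_3d_config
    if cfg.scenario not in ("default_2d", "default_3d"):
        raise ValueError(f"unknown scenario {cfg.scenario!r}")
    truth_rows = []
    all_tracks = []
    fiducials = None
    if cfg.scenario == "default_2d":
        for i, cond in enumerate(("untreated", "treated")):
            sim_cfg = base(n_tracks=cfg.n_tracks, seed=cfg.seed + i)
            ts, labels = simulate_tracks(sim_cfg, cond)
            all_tracks.extend(ts.tracks)
            truth_rows += [
                {"track_id": t.track_id, "condition": cond, "component": lab}
                for t, lab in zip(ts, labels)
            ]
        cells = TrackSet(all_tracks, all_tracks[0].frame_interval)
    else:
        # one shared construct drift for both conditions' cells
        for i, cond in enumerate(("untreated", "treated")):
            sim_cfg = base(n_tracks=cfg.n_tracks, seed=cfg.seed + i)
            ts, labels = simulate_tracks(sim_cfg, cond)
            all_tracks.extend(ts.tracks)
            truth_rows += [
                {"track_id": t.track_id, "condition": cond, "component": lab}
                for t, lab in zip(ts, labels)
            ]
        undrifted = TrackSet(all_tracks, all_tracks[0].frame_interval)
        scene = add_shared_drift(
            undrifted,
            cfg.drift_spec,
            n_fiducials=cfg.n_fiducials,
            fiducial_jitter_sd=cfg.fiducial_jitter_sd,
            seed=cfg.seed,
        )
        cells = scene.cells
        fiducials = scene.fiducials
    truth = pd.DataFrame(truth_rows)
    return cells, fiducials, truth


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis chain and write the output bundle.

    Writes (under cfg.outdir): tracks.csv, truth.csv (simulated runs),
    corrected_tracks.csv + drift_report.txt (3D runs), features.csv,
    labels.csv, chi2_report.txt, embedding.csv (when perplexity permits),
    normalized_means.csv, and distance_clusters.csv for 3D runs.  Identical
    config + seed produce byte-identical outputs.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": cfg.config_hash(), "outdir": str(out)}

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as e:  # noqa: BLE001 — rewrap with stage name
            raise StageError(name, e) from e

    cells, fiducials, truth = stage("ingest", _gather_inputs, cfg)
    write_tracks_table(cells, out / "tracks.csv", _provenance(cfg))
    if truth is not None:
        _write_df(truth, out / "truth.csv", cfg)

    if fiducials is not None:
        drift = stage("driftcorr", estimate_drift, fiducials, cfg.drift_threshold)
        cells = stage("driftcorr", apply_drift_correction, cells, drift)
        write_tracks_table(cells, out / "corrected_tracks.csv", _provenance(cfg))
        with open(out / "drift_report.txt", "w") as fh:
            for line in _provenance(cfg):
                fh.write(f"# {line}\n")
            fh.write(f"members: {','.join(drift.member_ids)}\n")
            fh.write(f"threshold: {drift.threshold}\n")
            fh.write(
                "mean_member_similarity: "
                f"{np.nanmean(drift.similarity):.4f}\n"
            )
        results["drift_members"] = drift.member_ids

    min_len = cfg.min_length if cfg.scenario != "default_3d" else 2
    filtered = stage("filter", filter_tracks, cells, min_len)
    if len(filtered) == 0:
        raise StageError("filter", ValueError("no track passed the length filter"))

    fparams = FeatureParams(**cfg.features) if cfg.features else FeatureParams()
    fm = stage("features", feature_table, filtered, fparams)
    _write_df(fm, out / "features.csv", cfg, index=True)
    results["n_tracks_analyzed"] = len(fm)

    ss = stage("statespace", reduce_and_cluster, fm, cfg.var_target,
               cfg.max_components, cfg.k)
    labels_df = pd.DataFrame(
        {"track_id": ss.track_ids, "condition": ss.conditions,
         "cluster": ss.cluster_labels}
    )
    _write_df(labels_df, out / "labels.csv", cfg)
    results["silhouette"] = ss.silhouette
    results["kept_components"] = ss.kept_components

    table, chi2, df_, p = stage(
        "statespace", condition_cluster_test, ss.cluster_labels, ss.conditions
    )
    with open(out / "chi2_report.txt", "w") as fh:
        for line in _provenance(cfg):
            fh.write(f"# {line}\n")
        fh.write(table.to_string() + "\n")
        props = table.div(table.sum(axis=1), axis=0)
        fh.write("\nproportions per condition:\n" + props.to_string() + "\n")
        fh.write(f"\nchi2={chi2:.6f} df={df_} p={p:.6g}\n")
    results.update({"chi2": chi2, "chi2_df": df_, "chi2_p": p,
                    "contingency": table})

    if cfg.perplexity < (len(fm) - 1) / 3:
        emb = stage("statespace", tsne_embed, ss.pc_scores, cfg.perplexity, cfg.seed)
        emb_df = pd.DataFrame(emb, columns=["tsne1", "tsne2"])
        emb_df.insert(0, "track_id", ss.track_ids)
        _write_df(emb_df, out / "embedding.csv", cfg)
    else:
        logger.info("skipping t-SNE: perplexity %.0f too large for n=%d",
                    cfg.perplexity, len(fm))

    nm = stage("statespace", normalized_feature_means, fm, ss.cluster_labels)
    _write_df(nm, out / "normalized_means.csv", cfg)

    if cfg.scenario == "default_3d" or (fiducials is not None):
        vals = fm["total_distance"].to_numpy()
        lab1d, means, sil1d = stage("statespace", cluster_1d, vals, cfg.k)
        d1 = pd.DataFrame({"track_id": fm.index, "condition": fm["condition"],
                           "distance_cluster": lab1d})
        _write_df(d1, out / "distance_clusters.csv", cfg)
        results["distance_cluster_means"] = means
        results["distance_cluster_silhouette"] = sil1d

    results["statespace"] = ss
    results["feature_table"] = fm
    return results
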