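"""End-to-end runner: simulate -> preprocess -> maps -> features -> embed -> stats.

Each stage writes its artifact under the configured output directory and
records a SHA-256 checksum in the run manifest, so two runs with the same
config and master seed can be compared file-by-file. Everything up to the
embedding is fully deterministic given the master seed; the ``manifold``
backend is additionally seeded but its output can vary across library
versions, which is why the ``linear`` backend is the default.
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

from . import embedding as emb
from . import features as feat
from . import maps as mapgen
from . import preprocess as pre
from . import simulate as sim
from . import stats as st
from .config import PipelineConfig, save_config
from .exceptions import SemgMapError
from .grid import ElectrodeGrid
from .io import write_feature_csv, write_recording_csv, write_stack_csv

log = logging.getLogger("semgmap")

ANALYZED_FEATURES = ("loc_x_mm", "loc_y_mm", "entropy_bits", "m1", "m2", "m3", "m4")


@dataclass
class RunManifest:
    config: dict
    checksums: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    failure: dict | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> tuple[RunManifest, dict]:
    """Execute the full analysis; returns the manifest and a results dict.

    The results dict carries the in-memory outputs downstream consumers
    need (feature table, per-condition polyhedron summaries, trend fits,
    ANOVA tables, cluster results) in addition to the on-disk artifacts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.to_dict())
    save_config(cfg, out / "config.yaml")
    grid = ElectrodeGrid()
    results: dict = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        recordings = []
        for trial in range(cfg.n_trials):
            rec = sim.simulate_recording(
                n_units=cfg.n_units,
                active_center=tuple(cfg.active_center),
                spread_mm=cfg.spread_mm,
                level=cfg.level,
                noise_rms=cfg.noise_rms,
                seed=cfg.stage_seed(f"simulate/{trial}"),
                grid=grid,
                fs_hz=cfg.fs_hz,
                plateau_samples=cfg.plateau_samples,
            )
            if cfg.bad_channels:
                rec = sim.inject_bad_channels(
                    rec,
                    list(cfg.bad_channels),
                    cfg.bad_channel_gain,
                    seed=cfg.stage_seed(f"inject/{trial}"),
                )
            path = write_recording_csv(rec, out / f"recording_{trial:02d}.csv")
            manifest.checksums[f"simulate/{trial}"] = _sha256(path)
            recordings.append(rec)
        manifest.timings_s[stage] = time.perf_counter() - t0

        stage = "preprocess"
        t0 = time.perf_counter()
        pcfg = pre.PreprocessConfig(
            band_low_hz=cfg.band_low_hz,
            band_high_hz=cfg.band_high_hz,
            filter_order=cfg.filter_order,
            z_threshold=cfg.z_threshold,
        )
        processed, reports = [], []
        for trial, rec in enumerate(recordings):
            rec = pre.mean_center(rec)
            rec = pre.segment_plateau(rec)
            rec = pre.bandpass_zero_lag(rec, pcfg)
            report = pre.detect_outliers(rec, pcfg)
            reports.append(report)
            processed.append(rec)
            path = write_recording_csv(rec, out / f"preprocessed_{trial:02d}.csv")
            manifest.checksums[f"preprocess/{trial}"] = _sha256(path)
        results["outlier_reports"] = reports
        manifest.timings_s[stage] = time.perf_counter() - t0

        stage = "maps"
        t0 = time.perf_counter()
        all_stacks: list[list[mapgen.ActivationMapStack]] = []
        stack_dir = out / "stacks"
        stack_dir.mkdir(exist_ok=True)
        for trial, (rec, report) in enumerate(zip(processed, reports)):
            stacks = mapgen.grid_search(
                rec,
                cfg.windows_ms,
                cfg.overlaps_pct,
                grid=grid,
                intensity=cfg.intensity,
                normalize=False,
            )
            # outlier repair at the map-pixel level, then per-stack normalization
            repaired = []
            for stack in stacks:
                vectors = stack.as_vectors(grid)
                if report.flagged:
                    vectors = pre.repair_channels(vectors, list(report.flagged), grid)
                stack = dataclasses.replace(stack, maps=grid.to_image(vectors))
                repaired.append(mapgen.normalize_stack(stack))
            for stack in repaired:
                name = (
                    f"trial{trial:02d}_w{stack.scheme.window_ms:g}"
                    f"_o{stack.scheme.overlap_pct:g}.csv"
                )
                path = write_stack_csv(stack, grid, stack_dir / name)
                manifest.checksums[f"maps/{name}"] = _sha256(path)
            all_stacks.append(repaired)
        manifest.timings_s[stage] = time.perf_counter() - t0

        stage = "features"
        t0 = time.perf_counter()
        tables = []
        for trial, stacks in enumerate(all_stacks):
            table = feat.feature_table(stacks, grid)
            table.insert(0, "trial", trial)
            tables.append(table)
        features = pd.concat(tables, ignore_index=True)
        path = write_feature_csv(features, out / "features.csv")
        manifest.checksums["features"] = _sha256(path)
        results["features"] = features
        manifest.timings_s[stage] = time.perf_counter() - t0

        stage = "embed"
        t0 = time.perf_counter()
        vectors, labels = [], []
        for stacks in all_stacks:
            for stack in stacks:
                vectors.append(stack.as_vectors(grid))
                labels.extend(
                    [(stack.scheme.window_ms, stack.scheme.overlap_pct)]
                    * stack.n_maps
                )
        pooled = np.vstack(vectors)
        label_arr = np.array([f"{w:g}|{o:g}" for w, o in labels])
        ecfg = emb.EmbeddingConfig(
            n_neighbors=cfg.n_neighbors,
            min_dist=cfg.min_dist,
            backend=cfg.backend,
            seed=cfg.stage_seed("embed"),
        )
        cloud = emb.embed(pooled, ecfg, labels=label_arr)
        cloud_df = pd.DataFrame(cloud.points, columns=["x", "y", "z"])
        cloud_df["window_ms"] = [w for w, _ in labels]
        cloud_df["overlap_pct"] = [o for _, o in labels]
        path = out / "embedding.csv"
        cloud_df.to_csv(path, index=False)
        manifest.checksums["embed"] = _sha256(path)
        summaries = emb.condition_summaries(cloud, voxel_grid=cfg.voxel_grid)
        summary_df = pd.DataFrame(
            {
                "window_ms": [float(s.condition.split("|")[0]) for s in summaries],
                "overlap_pct": [float(s.condition.split("|")[1]) for s in summaries],
                "volume_raw": [s.volume_raw for s in summaries],
                "volume_norm": [s.volume_norm for s in summaries],
                "entropy_bits": [s.entropy_bits for s in summaries],
                "n_points": [s.n_points for s in summaries],
                "degenerate": [s.degenerate for s in summaries],
            }
        )
        path = write_feature_csv(summary_df, out / "polyhedra.csv")
        manifest.checksums["polyhedra"] = _sha256(path)
        results["cloud"] = cloud
        results["polyhedra"] = summary_df
        # trend of volume / entropy against each factor (mean over the other)
        trends = {}
        for response in ("volume_norm", "entropy_bits"):
            for factor in ("overlap_pct", "window_ms"):
                agg = summary_df.groupby(factor)[response].mean()
                if len(agg) >= 4:
                    trends[f"{response}~{factor}"] = emb.fit_trend(
                        agg.index.to_numpy(float), agg.to_numpy(float)
                    )
        results["trends"] = trends
        manifest.timings_s[stage] = time.perf_counter() - t0

        stage = "stats"
        t0 = time.perf_counter()
        anova_tables, eta_classes, tukey_tables, clusters = {}, {}, {}, {}
        rng = np.random.default_rng(cfg.stage_seed("stats"))
        clean = features[~features["degenerate"]]
        for response in ANALYZED_FEATURES:
            res = st.two_way_anova(clean, response)
            anova_tables[response] = res
            eta_classes[response] = {
                name: st.classify_eta(eff.eta_sq)
                for name, eff in res.effects.items()
                if name != "residual"
            }
            tukey_tables[response] = {
                factor: st.tukey_kramer(
                    clean[response].to_numpy(),
                    clean[factor].to_numpy(),
                    alpha=cfg.alpha,
                )
                for factor in ("window_ms", "overlap_pct")
            }
            vals = clean[response].to_numpy()
            if vals.size > cfg.cluster_subsample:
                vals = rng.choice(vals, cfg.cluster_subsample, replace=False)
            clusters[response] = st.kmedoids_elbow(
                vals, k_max=min(cfg.k_max, vals.size - 1), seed=cfg.stage_seed("cluster")
            )
        results["anova"] = anova_tables
        results["eta_classes"] = eta_classes
        results["tukey"] = tukey_tables
        results["clusters"] = clusters
        report = _build_report(results)
        path = out / "report.json"
        path.write_text(json.dumps(report, indent=2))
        manifest.checksums["report"] = _sha256(path)
        results["report"] = report
        manifest.timings_s[stage] = time.perf_counter() - t0
    except SemgMapError as exc:
        manifest.failure = {"stage": stage, "error": str(exc)}
        (out / "manifest.json").write_text(manifest.to_json())
        raise
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest, results


def _build_report(results: dict) -> dict:
    report: dict = {"anova": {}, "clusters": {}, "trends": {}}
    for response, res in results["anova"].items():
        report["anova"][response] = {
            name: {
                "ss": eff.ss,
                "df": eff.df,
                "F": eff.F,
                "p": eff.p,
                "eta_sq": eff.eta_sq,
            }
            for name, eff in res.effects.items()
        }
        report["anova"][response]["eta_class"] = results["eta_classes"][response]
    for response, cl in results["clusters"].items():
        report["clusters"][response] = {
            "k": cl.k,
            "medoids": np.asarray(cl.medoids).ravel().tolist(),
        }
    for name, fit in results["trends"].items():
        report["trends"][name] = {
            "r_squared": fit.r_squared,
            "zero_crossings": list(fit.zero_crossings),
            "coefficients": fit.coefficients.tolist(),
        }
    return report
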