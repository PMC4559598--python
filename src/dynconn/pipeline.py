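"""End-to-end orchestration: config, seeding, per-stage outputs, manifest.

``run_pipeline`` ties the stages together for a cohort of subjects:
simulate (or load) regional time series and streamline counts, extract
windowed connectivity and temporal edge statistics, build per-window
networks and their topology series, construct structural networks and the
group backbone, and test structure-function coupling. Every stage draws
its seed deterministically from the master seed, every output file is
checksummed into a manifest, and an identical (config, seed) pair
reproduces identical checksums.
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

from . import coupling as cpl
from . import dynamics as dyn
from . import io as dio
from . import structural as st
from . import synthetic as syn
from .core import upper_triangle
from .dfc import (SlidingWindowSpec, category_comparison, classify_edges,
                  sliding_window_dfc, spatial_similarity, static_fc,
                  temporal_edge_stats, window_samples_from_seconds)
from .networks import ThresholdPolicy

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config", "save_config"]

log = logging.getLogger("dynconn")

_STAGES = ("simulate", "dfc", "network", "dynamics", "structural", "couple")


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    With ``parcellation_path`` unset the synthetic default preset supplies
    the cohort (``n_subjects`` subjects); otherwise time-series (and
    optionally streamline-count) files are loaded per subject.
    """

    output_dir: str = "dynconn_out"
    seed: int = 0
    n_subjects: int = 6
    window_seconds: float = 100.0
    step_samples: int = 1
    threshold_mode: str = "bonferroni_r"
    alpha_corr: float = 0.01
    target_sparsity: float | None = None
    n_perm: int = 10_000
    n_rand: int = 100
    swaps_per_edge: int = 10
    variability: str = "var"
    backbone_alpha: float = 0.05
    streamline_scale: float = 30.0
    parcellation_path: str | None = None
    timeseries_paths: list = field(default_factory=list)
    streamline_paths: list = field(default_factory=list)

    def policy(self) -> ThresholdPolicy:
        if self.threshold_mode == "sparsity":
            return ThresholdPolicy(mode="sparsity", target_sparsity=self.target_sparsity)
        return ThresholdPolicy(mode="bonferroni_r", alpha_corr=self.alpha_corr)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stage_seeds: dict
    outputs: dict          # relative path -> sha256
    skipped: list


def save_config(path: str | Path, config: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    cfg = RunConfig(**data)
    for p in [cfg.parcellation_path, *cfg.timeseries_paths, *cfg.streamline_paths]:
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configured input does not exist: {p}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % 2**31


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage; write TSV/JSON outputs and return the manifest."""
    from . import __version__

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: _stage_seed(config.seed, s) for s in _STAGES}
    written: dict[str, str] = {}
    skipped: list[str] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written[name] = _sha256(path)

    # --- simulate / ingest ------------------------------------------------
    if config.parcellation_path is None:
        parc, truth = syn.default_preset(seeds["simulate"])
        ss = np.random.SeedSequence(seeds["simulate"])
        subj_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2 * config.n_subjects)]
        tss = [
            syn.simulate_bold(truth, parc, syn.DEFAULT_PRESET.n_timepoints,
                              syn.DEFAULT_PRESET.sampling_interval,
                              seed=subj_seeds[i], subject_id=f"sub-{i:02d}")
            for i in range(config.n_subjects)
        ]
        counts = [
            syn.simulate_streamline_counts(truth, parc, scale=config.streamline_scale,
                                           seed=subj_seeds[config.n_subjects + i])
            for i in range(config.n_subjects)
        ]
    else:
        parc = dio.load_parcellation(config.parcellation_path)
        tss = [dio.load_timeseries(p) for p in config.timeseries_paths]
        counts = [dio.load_matrix(p, parc.region_id) for p in config.streamline_paths]
        if not tss:
            raise ValueError("stage simulate: no time series configured")
    emit("parcellation.tsv", lambda p: dio.save_parcellation(p, parc))

    # --- dfc --------------------------------------------------------------
    policy = config.policy()
    categories = classify_edges(parc)
    edge_stats_all, metric_stats_rows, hub_profiles = [], [], []
    spec = None
    for ts in tss:
        length = window_samples_from_seconds(config.window_seconds, ts.sampling_interval)
        spec = SlidingWindowSpec(length=length, step=config.step_samples)
        try:
            dfc = sliding_window_dfc(ts, spec)
            sfc = static_fc(ts)
        except ValueError as exc:
            raise RuntimeError(f"stage dfc, subject {ts.subject_id}: {exc}") from exc
        sim = spatial_similarity(sfc, dfc)
        stats = temporal_edge_stats(dfc, variability=config.variability)
        edge_stats_all.append(stats)
        emit(f"{ts.subject_id}_similarity.tsv",
             lambda p, s=sim, d=dfc: pd.DataFrame(
                 {"onset": d.window_onsets, "similarity": s}
             ).to_csv(p, sep="\t", index=False))
        emit(f"{ts.subject_id}_strength.tsv",
             lambda p, s=stats: dio.save_matrix(p, s.strength, parc.region_id))
        emit(f"{ts.subject_id}_variability.tsv",
             lambda p, s=stats: dio.save_matrix(p, s.variability, parc.region_id))

        # --- dynamics (network + metrics per window) ----------------------
        try:
            mts = dyn.metric_time_series(
                dfc, policy,
                dyn.NullSpec(n_rand=config.n_rand, swaps_per_edge=config.swaps_per_edge,
                             seed=seeds["dynamics"]),
            )
        except ValueError as exc:
            raise RuntimeError(f"stage dynamics, subject {ts.subject_id}: {exc}") from exc
        emit(f"{ts.subject_id}_metrics.tsv",
             lambda p, m=mts: m.metrics.to_csv(p, sep="\t", index=False))
        metric_stats_rows.append(
            dyn.temporal_metric_stats(mts).assign(subject=ts.subject_id))
        profile = dyn.hub_persistence(mts.degree)
        hub_profiles.append(profile)
        emit(f"{ts.subject_id}_hubs.tsv",
             lambda p, pr=profile: pd.DataFrame({
                 "region_id": parc.region_id,
                 "probability": pr.probability,
                 "degree_tvar": pr.degree_tvar,
                 "persistent": pr.persistent.astype(int),
             }).to_csv(p, sep="\t", index=False))

    # group: category comparison on the mean strength/variability matrices
    mean_strength = np.mean([s.strength for s in edge_stats_all], axis=0)
    mean_var = np.mean([s.variability for s in edge_stats_all], axis=0)
    report = {}
    for name, mat in [("strength", mean_strength), ("variability", mean_var)]:
        comps = category_comparison(mat, categories, n_perm=config.n_perm,
                                    seed=seeds["dfc"])
        report[name] = [
            {"pair": list(c.pair), "observed": c.result.observed,
             "p": c.result.p_value, "p_adjusted": c.p_adjusted}
            for c in comps
        ]
    emit("category_tests.json", lambda p: p.write_text(json.dumps(report, indent=2)))
    emit("metric_temporal_stats.tsv",
         lambda p: pd.concat(metric_stats_rows).to_csv(p, sep="\t", index_label="metric"))

    # --- structural + coupling -------------------------------------------
    if counts:
        nets = [st.sc_from_streamlines(c, parc) for c in counts]
        backbone = st.group_backbone(nets, alpha=config.backbone_alpha)
        emit("backbone.tsv", lambda p: dio.save_matrix(p, backbone.weights, parc.region_id))
        emit("backbone_p.tsv", lambda p: dio.save_matrix(p, backbone.p_values, parc.region_id))
        sprofile = st.structural_hub_profile(nets)
        emit("structural_hubs.tsv",
             lambda p: pd.DataFrame({
                 "region_id": parc.region_id,
                 "probability": sprofile.probability,
                 "persistent": sprofile.persistent.astype(int),
             }).to_csv(p, sep="\t", index=False))

        group_stats = temporal_edge_stats_like(mean_strength, mean_var,
                                               config.variability)
        try:
            presence = cpl.sc_presence_test(group_stats, backbone,
                                            n_perm=config.n_perm, seed=seeds["couple"])
            coup = cpl.sc_strength_coupling(group_stats, backbone, level="group_backbone")
            func_tvar = np.mean([pr.degree_tvar for pr in hub_profiles], axis=0)
            mean_sdeg = np.mean(
                [np.asarray((net.binary()).adjacency.sum(axis=1)) for net in nets], axis=0)
            nodal = cpl.nodal_coupling(func_tvar, sprofile.probability, mean_sdeg)
        except ValueError as exc:
            skipped.append("couple")
            log.info("coupling stage skipped: %s", exc)
        else:
            couple_report = {
                "presence": {k: {"observed": v.observed, "p": v.p_value}
                             for k, v in presence.items()},
                "strength_coupling": {
                    "r_strength_sc": coup.r_strength_sc, "p_strength_sc": coup.p_strength_sc,
                    "r_variability_sc": coup.r_variability_sc,
                    "p_variability_sc": coup.p_variability_sc,
                    "n_edges_sc_present": coup.n_edges_sc_present,
                },
                "nodal": nodal.to_dict(orient="records"),
            }
            emit("coupling.json",
                 lambda p: p.write_text(json.dumps(couple_report, indent=2)))
    else:
        skipped.append("structural")
        skipped.append("couple")
        log.info("no streamline inputs configured; structural and coupling stages skipped")

    cfg_hash = hashlib.sha256(
        yaml.safe_dump(asdict(config), sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(config_hash=cfg_hash, version=__version__,
                           stage_seeds=seeds, outputs=written, skipped=skipped)
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2))
    return manifest


def temporal_edge_stats_like(strength: np.ndarray, variability: np.ndarray,
                             kind: str = "var"):
    """Wrap precomputed group-mean matrices in a TemporalEdgeStats."""
    from .dfc import TemporalEdgeStats

    return TemporalEdgeStats(strength=strength, variability=variability,
                             variability_kind=kind)
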