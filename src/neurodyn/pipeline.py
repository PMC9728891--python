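"""End-to-end orchestration: prep -> GLM -> dFC -> spatiotemporal -> decoding.

A run consumes either a dataset directory (events TSV + ROI series TSV, as
written by :func:`neurodyn.synth.write_dataset`) or the built-in synthetic
preset, executes every stage with the configured thresholds, and writes all
artifacts (TSV/JSON plus figures) into a run directory together with a
machine-readable manifest: the full parameter set, the seed and a SHA-256
checksum per data artifact, sufficient to verify bit-for-bit reproduction.
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

from . import decoding, dfc, glm, plotting, prep, spatiotemporal, synth
from .core import write_events

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters, with the study defaults."""

    out_dir: str = "neurodyn-run"
    data_dir: str | None = None
    synthetic: str | None = None          # "paper-like" to simulate inputs
    seed: int = 0
    tr: float = 0.545
    # prep
    detrend_order: int = 3
    falff_threshold: float = 1.0
    falff_low: tuple = (0.01, 0.08)
    min_rt: float = 10.0
    min_trials: int = 13
    # glm
    event_duration: float = 1.0
    # dfc
    window_s: float = 10.0
    alpha: float = 0.05
    min_subjects: int = 8
    # spatiotemporal
    window_pct: float = 20.0
    step_pct: float = 5.0
    top_k: int = 20
    stmap_min_subjects: int = 8
    min_diff: int = 7
    # decoding
    decode_rois: tuple = synth.DEFAULT_DECODING_ROIS
    folds: int = 5
    permutations: int = 0

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, tuple):
                out[key] = list(value)
        return out

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("falff_low", "decode_rois"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path):
    frame.to_csv(path, sep="\t", index=False)


def _load_inputs(config: PipelineConfig):
    if config.synthetic:
        if config.synthetic != "paper-like":
            raise ValueError(f"unknown synthetic preset {config.synthetic!r}")
        dataset = synth.paper_like_cohort(config.seed)
        return dataset.trials, dataset.series
    if not config.data_dir:
        raise ValueError("either data_dir or synthetic preset must be given")
    data_dir = Path(config.data_dir)
    if not data_dir.exists():
        raise FileNotFoundError(f"data directory not found: {data_dir}")
    dataset = synth.read_dataset(data_dir)
    return dataset.trials, dataset.series


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    log_lines = []

    def stage(name):
        logger.info("stage: %s", name)
        log_lines.append(name)
        return time.perf_counter()

    t0 = stage("load")
    trials, series = _load_inputs(config)
    subject_ids = list(trials.keys())
    for sid in subject_ids:
        write_events(trials[sid], out / f"{sid}_events.tsv")
    timings["load"] = time.perf_counter() - t0

    # ------------------------------------------------------------------ prep
    t0 = stage("prep")
    detrended = {sid: prep.detrend_timeseries(series[sid], config.detrend_order)
                 for sid in subject_ids}
    falff_rows = []
    falff_scores = []
    for sid in subject_ids:
        report = prep.compute_falff(detrended[sid], low_band=config.falff_low,
                                    threshold=config.falff_threshold,
                                    detrend_order=config.detrend_order)
        falff_scores.append(report.falff)
        for roi, score, keep in zip(report.roi_ids, report.falff, report.keep_mask):
            falff_rows.append({"subject": sid, "roi_id": roi,
                               "falff": score, "keep": bool(keep)})
    _write_tsv(pd.DataFrame(falff_rows), out / "falff.tsv")
    roi_ids = detrended[subject_ids[0]].roi_ids
    group_falff = np.median(np.vstack(falff_scores), axis=0)
    kept_rois = tuple(r for r, s in zip(roi_ids, group_falff)
                      if s >= config.falff_threshold)
    included = prep.select_subjects(trials, config.min_rt, config.min_trials)
    (out / "subjects_included.json").write_text(json.dumps(
        {"included": included, "excluded": [s for s in subject_ids
                                            if s not in included],
         "min_rt": config.min_rt, "min_trials": config.min_trials},
        indent=2, sort_keys=True))
    timings["prep"] = time.perf_counter() - t0

    # ------------------------------------------------------------------- glm
    t0 = stage("glm")
    contrast_frames = []
    for sid in subject_ids:
        design = glm.build_design(trials[sid], detrended[sid].n_samples,
                                  config.tr, config.event_duration)
        fit = glm.fit_glm(detrended[sid], design)
        for name, vec in glm.standard_contrasts(design).items():
            frame = glm.contrast_map(fit, vec, name)
            frame.insert(0, "subject", sid)
            contrast_frames.append(frame)
    contrasts = pd.concat(contrast_frames, ignore_index=True)
    _write_tsv(contrasts, out / "glm_contrasts.tsv")
    group = (contrasts.groupby(["contrast", "roi_id"], as_index=False)
             .agg(median_t=("t", "median"), median_effect=("effect", "median")))
    _write_tsv(group, out / "glm_group.tsv")
    timings["glm"] = time.perf_counter() - t0

    # ------------------------------------------------------------------- dfc
    t0 = stage("dfc")
    kept_series = {sid: detrended[sid].subset(kept_rois) for sid in included}
    consensus = {}
    for anchor, epoch in (("trial_start", "start"), ("trial_end", "end")):
        spec = dfc.WindowSpec(anchor, config.window_s)
        stats = [dfc.subject_connectivity(
                    dfc.extract_windows(kept_series[sid], trials[sid], spec),
                    alpha=config.alpha)
                 for sid in included]
        consensus[epoch] = dfc.group_consistency(stats, config.min_subjects,
                                                 epoch=epoch)
        frame = consensus[epoch].edges.copy()
        frame.insert(0, "epoch", epoch)
        _write_tsv(frame, out / f"dfc_{epoch}.tsv")
    difference = dfc.connectivity_difference(consensus["start"], consensus["end"])
    _write_tsv(difference, out / "dfc_difference.tsv")
    timings["dfc"] = time.perf_counter() - t0

    # --------------------------------------------------------- spatiotemporal
    t0 = stage("spatiotemporal")
    maps = {}
    normalized_all = {}
    for condition in ("all", "yes", "no"):
        responses = []
        for sid in included:
            norm = spatiotemporal.normalize_trials(detrended[sid], trials[sid],
                                                   condition)
            if condition == "all":
                normalized_all[sid] = norm
            responses.append(spatiotemporal.normalize_response(
                spatiotemporal.fit_fir(norm)))
        maps[condition] = spatiotemporal.consensus_map(
            responses, config.window_pct, config.step_pct, config.top_k,
            config.stmap_min_subjects, condition)
        _write_tsv(maps[condition].to_frame(), out / f"stmap_{condition}.tsv")
    diff_map = spatiotemporal.condition_difference(maps["yes"], maps["no"],
                                                   config.min_diff)
    _write_tsv(diff_map.to_frame(retained_only=False), out / "stmap_difference.tsv")
    timings["spatiotemporal"] = time.perf_counter() - t0

    # -------------------------------------------------------------- decoding
    t0 = stage("decoding")
    decode_rois = tuple(r for r in config.decode_rois if r in roi_ids)
    decode_payload = {"rois": list(decode_rois)}
    if len(decode_rois) >= 2:
        table = decoding.build_feature_table(
            [normalized_all[sid] for sid in included], decode_rois)
        table.to_csv(out / "features.tsv", sep="\t", index=False)
        report = decoding.crossval_classify(table, n_folds=config.folds,
                                            seed=config.seed)
        decode_payload["cv"] = report.to_dict()
        if config.permutations:
            perm = decoding.permutation_chance(table, config.permutations,
                                               seed=config.seed,
                                               n_folds=config.folds)
            decode_payload["permutation"] = perm.to_dict()
    else:
        logger.warning("fewer than 2 decoding ROIs available; skipping decoding")
    (out / "decoding.json").write_text(
        json.dumps(decode_payload, indent=2, sort_keys=True))
    timings["decoding"] = time.perf_counter() - t0

    # --------------------------------------------------------------- figures
    t0 = stage("figures")
    plotting.render_connectogram(consensus["start"], out / "fig_dfc_start.png")
    plotting.render_connectogram(consensus["end"], out / "fig_dfc_end.png")
    plotting.render_connectivity_difference(difference, consensus["start"].roi_ids,
                                            out / "fig_dfc_difference.png")
    plotting.render_spatiotemporal(maps["all"], out / "fig_stmap_all.png")
    plotting.render_spatiotemporal(diff_map, out / "fig_stmap_difference.png")
    timings["figures"] = time.perf_counter() - t0

    # -------------------------------------------------------------- manifest
    artifacts = sorted(p for p in out.iterdir()
                       if p.suffix in (".tsv", ".json", ".png")
                       and p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "checksums": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    (out / "run.log").write_text(
        "\n".join(f"{name}: {timings.get(name, float('nan')):.2f}s"
                  for name in timings) + "\n")
    return out
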