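"""Dynamic functional connectivity over fixed trial-anchored windows.

Because trials are self-paced, windowed correlations are computed on a
fixed 10-second window either starting at stimulus onset or ending at the
button press. Per trial and ROI pair, a Pearson correlation and its
two-sided p-value (t transform, n-2 dof) are computed; non-significant
trials are discarded, the rest averaged into a subject-level edge value.
An edge is consistent at the group level when it is significant within
more than half of the subjects (>= 8 of 14 by default); the start-vs-end
difference graph classifies edges as start-only / end-only / both.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import RoiTimeSeriesSet, validate_events

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Fixed-length trial-anchored correlation window."""

    anchor: str = "trial_start"       # "trial_start" | "trial_end"
    length_s: float = 10.0

    def __post_init__(self):
        if self.anchor not in ("trial_start", "trial_end"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if not self.length_s > 0:
            raise ValueError("window length must be positive")

    def n_samples(self, tr: float) -> int:
        return int(np.floor(self.length_s / tr))


@dataclass
class TrialWindows:
    """Per-trial window segments for one subject."""

    subject_id: str
    roi_ids: tuple
    spec: WindowSpec
    segments: list          # list of (n_rois, n_window_samples) arrays
    trial_indices: list
    skipped: list


def extract_windows(series: RoiTimeSeriesSet, trials: pd.DataFrame,
                    spec: WindowSpec) -> TrialWindows:
    """Cut one fixed window per eligible trial.

    Trials shorter than the window are skipped (logged), not padded.
    Raises if no trial is eligible.
    """
    validate_events(trials)
    n = spec.n_samples(series.tr)
    segments, kept, skipped = [], [], []
    for k, trial in trials.reset_index(drop=True).iterrows():
        if trial["duration"] < spec.length_s:
            skipped.append(k)
            continue
        i0 = int(np.round(trial["onset"] / series.tr))
        # end of trial in whole TRs from onset, so both anchors stay inside
        i1 = min(i0 + int(np.floor(trial["duration"] / series.tr)),
                 series.n_samples)
        seg = (series.data[:, i0:i0 + n] if spec.anchor == "trial_start"
               else series.data[:, i1 - n:i1])
        if seg.shape[1] < n:
            skipped.append(k)
            continue
        segments.append(seg)
        kept.append(k)
    if skipped:
        logger.info("subject %s: skipped %d trials shorter than the %.1fs window",
                    series.subject_id, len(skipped), spec.length_s)
    if not segments:
        raise ValueError(
            f"subject {series.subject_id}: no trial is at least "
            f"{spec.length_s}s long")
    return TrialWindows(series.subject_id, series.roi_ids, spec,
                        segments, kept, skipped)


def corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t transform with n-2 dof."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


@dataclass
class EdgeStats:
    """Subject-level edge statistics for all ROI pairs.

    ``r`` and ``p`` are (n_pairs, n_trials); entries are NaN for trials
    where a pair involved a constant segment. ``significant`` marks edges
    retained in more than half of that pair's eligible trials.
    """

    subject_id: str
    roi_ids: tuple
    pairs: list                 # list of (roi_a, roi_b), roi_a < roi_b
    r: np.ndarray
    p: np.ndarray
    mean_r: np.ndarray
    n_eligible: np.ndarray
    n_retained: np.ndarray
    significant: np.ndarray
    alpha: float
    denominator: str

    def as_frame(self) -> pd.DataFrame:
        a, b = zip(*self.pairs)
        return pd.DataFrame({
            "roi_a": a, "roi_b": b,
            "n_eligible": self.n_eligible, "n_retained": self.n_retained,
            "mean_r": self.mean_r, "significant": self.significant,
        })


def subject_connectivity(windows: TrialWindows, alpha: float = 0.05,
                         denominator: str = "retained") -> EdgeStats:
    """Per-trial windowed correlations, thresholded and trial-averaged.

    ``denominator`` controls the averaging of significant correlations:
    ``"retained"`` divides by the number of retained (significant) trials,
    ``"all"`` by the number of eligible trials.
    """
    if denominator not in ("retained", "all"):
        raise ValueError("denominator must be 'retained' or 'all'")
    n_trials = len(windows.segments)
    if n_trials < 2:
        raise ValueError("need at least 2 eligible trials")
    n_roi = len(windows.roi_ids)
    pairs_idx = list(itertools.combinations(range(n_roi), 2))
    iu = np.triu_indices(n_roi, k=1)
    n = windows.segments[0].shape[1]

    r = np.empty((len(pairs_idx), n_trials))
    for t, seg in enumerate(windows.segments):
        sd = seg.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cmat = np.corrcoef(seg)
        cmat[sd == 0, :] = np.nan
        cmat[:, sd == 0] = np.nan
        if np.any(sd == 0):
            logger.info("subject %s trial %d: constant segment, pair r undefined",
                        windows.subject_id, windows.trial_indices[t])
        r[:, t] = cmat[iu]
    p = np.where(np.isnan(r), np.nan, corr_pvalues(np.nan_to_num(r), n))

    eligible = np.isfinite(r)
    retained = eligible & (p <= alpha)
    n_eligible = eligible.sum(axis=1)
    n_retained = retained.sum(axis=1)
    sum_r = np.where(retained, r, 0.0).sum(axis=1)
    denom = n_retained if denominator == "retained" else n_eligible
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_r = np.where(denom > 0, sum_r / np.maximum(denom, 1), np.nan)
    mean_r[(n_retained == 0) & (denominator == "retained")] = np.nan
    significant = n_retained > n_eligible / 2.0
    pairs = [(windows.roi_ids[i], windows.roi_ids[j]) for i, j in pairs_idx]
    return EdgeStats(windows.subject_id, windows.roi_ids, pairs, r, p, mean_r,
                     n_eligible, n_retained, significant, alpha, denominator)


@dataclass
class ConnectivityConsensus:
    """Group-level consensus edges for one window epoch."""

    roi_ids: tuple
    edges: pd.DataFrame     # roi_a, roi_b, n_subjects, mean_r, sign, retained
    min_subjects: int
    epoch: str

    @property
    def retained(self) -> pd.DataFrame:
        return self.edges[self.edges["retained"]].reset_index(drop=True)


def group_consistency(subject_stats, min_subjects: int = 8,
                      epoch: str = "trial_start") -> ConnectivityConsensus:
    """Count subjects per significant edge; retain counts >= min_subjects.

    The edge sign is the sign of the mean of the subject-level mean
    correlations (positive/negative consistent coupling).
    """
    if not subject_stats:
        raise ValueError("need at least one subject")
    first = subject_stats[0]
    for st in subject_stats[1:]:
        if st.pairs != first.pairs:
            raise ValueError("subjects have mismatched ROI universes")
    counts = np.sum([st.significant for st in subject_stats], axis=0)
    mean_rs = np.vstack([st.mean_r for st in subject_stats])
    with np.errstate(invalid="ignore"):
        grand = np.nanmean(np.where(np.isfinite(mean_rs), mean_rs, np.nan), axis=0)
    a, b = zip(*first.pairs)
    edges = pd.DataFrame({
        "roi_a": a, "roi_b": b,
        "n_subjects": counts.astype(int),
        "mean_r": grand,
        "sign": np.where(np.nan_to_num(grand) >= 0, "+", "-"),
        "retained": counts >= min_subjects,
    })
    return ConnectivityConsensus(first.roi_ids, edges, min_subjects, epoch)


def connectivity_difference(consensus_start: ConnectivityConsensus,
                            consensus_end: ConnectivityConsensus) -> pd.DataFrame:
    """Classify each edge: start_only, end_only, both or neither."""
    if consensus_start.roi_ids != consensus_end.roi_ids:
        raise ValueError("consensus graphs have different ROI universes")
    s = consensus_start.edges
    e = consensus_end.edges
    merged = s[["roi_a", "roi_b", "retained"]].merge(
        e[["roi_a", "roi_b", "retained"]], on=["roi_a", "roi_b"],
        suffixes=("_start", "_end"))
    category = np.select(
        [merged["retained_start"] & merged["retained_end"],
         merged["retained_start"],
         merged["retained_end"]],
        ["both", "start_only", "end_only"], default="neither")
    merged["category"] = category
    return merged[["roi_a", "roi_b", "category"]]
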