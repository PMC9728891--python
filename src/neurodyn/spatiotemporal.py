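"""Trial-length normalization, FIR response estimation and consensus maps.

Self-paced trials have different durations, so each subject's series is cut
into per-trial segments and linearly resampled to that subject's mean
response time in TR units (L samples). A finite-impulse-response (FIR)
design — one impulse regressor per post-onset lag, repeated at every trial
onset — then estimates the trial-locked hemodynamic response per ROI
without assuming an HRF shape; with non-overlapping equal-length trials the
FIR solution equals the per-lag across-trial mean. Each subject's response
is resampled again to 100 points, i.e. percent of decision time (0% =
stimulus onset, 100% = button press).

Subjects are combined by sliding a window (20% of decision time, 5% steps)
over the normalized axis: within each window, the ROIs owning the top-K
response peaks (by amplitude) are binned per subject; cells where at least
``min_subjects`` agree form the consensus map. Yes-vs-no condition maps are
contrasted cell-wise.

No hemodynamic-delay correction is applied: the response of a stage ending
at the button press peaks a few seconds later, i.e. in the *next* trial's
early windows, so late-stage activation deliberately appears carried over
to 0-15% of the normalized axis (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d

from .core import RoiTimeSeriesSet, validate_events

logger = logging.getLogger(__name__)

NORMALIZED_LENGTH = 100


def percent_to_seconds(pct: float, duration_s: float) -> float:
    """Map a percent-of-decision-time value to seconds for a given trial
    duration (e.g. 10% of a 45 s decision is 4.5 s)."""
    return pct / 100.0 * duration_s


@dataclass
class NormalizedTrialSeries:
    """Concatenated equal-length trial segments for one subject."""

    subject_id: str
    roi_ids: tuple
    data: np.ndarray        # (n_rois, n_trials * trial_length)
    trial_length: int       # L = round(mean RT / tr), samples
    labels: tuple           # response per kept trial, in order
    mean_rt_s: float
    tr: float

    @property
    def n_trials(self) -> int:
        return len(self.labels)

    @property
    def trial_bounds(self):
        """(start, end) sample index per trial segment."""
        L = self.trial_length
        return [(k * L, (k + 1) * L) for k in range(self.n_trials)]

    def segment(self, k: int) -> np.ndarray:
        i0, i1 = self.trial_bounds[k]
        return self.data[:, i0:i1]


def _resample_linear(segment: np.ndarray, length: int) -> np.ndarray:
    """Linear resampling of each row to ``length`` samples, endpoints kept."""
    m = segment.shape[1]
    if m == length:
        return segment.copy()
    src = np.linspace(0.0, 1.0, m)
    dst = np.linspace(0.0, 1.0, length)
    return interp1d(src, segment, axis=1, assume_sorted=True)(dst)


def normalize_trials(series: RoiTimeSeriesSet, trials: pd.DataFrame,
                     condition: str = "all") -> NormalizedTrialSeries:
    """Segment a subject's run into trials and equalize trial length.

    Each selected trial (``condition`` in {"all", "yes", "no"}) is linearly
    resampled to ``L = round(mean RT / tr)`` samples, where the mean is over
    the selected trials, then segments are concatenated in trial order.
    """
    validate_events(trials)
    if condition not in ("all", "yes", "no"):
        raise ValueError(f"unknown condition {condition!r}")
    selected = trials if condition == "all" else trials[trials["response"] == condition]
    if len(selected) == 0:
        raise ValueError(f"no trials with response {condition!r}")
    mean_rt = float(selected["duration"].mean())
    L = int(round(mean_rt / series.tr))
    if L < 2:
        raise ValueError("mean response time shorter than two TRs")
    segments, labels = [], []
    for _, trial in selected.iterrows():
        i0 = int(np.round(trial["onset"] / series.tr))
        i1 = int(np.round((trial["onset"] + trial["duration"]) / series.tr))
        if i1 > series.n_samples:
            raise ValueError(
                f"trial ending at {i1 * series.tr:.1f}s exceeds the series")
        segments.append(_resample_linear(series.data[:, i0:i1], L))
        labels.append(trial["response"])
    return NormalizedTrialSeries(series.subject_id, series.roi_ids,
                                 np.concatenate(segments, axis=1), L,
                                 tuple(labels), mean_rt, series.tr)


@dataclass
class FirResponseSet:
    """Estimated trial-locked response per ROI for one subject.

    ``weights`` has one column per post-onset lag (L = trial length);
    ``normalized`` is the same response resampled to the 0-100% axis
    (None until :func:`normalize_response` is applied).
    """

    subject_id: str
    roi_ids: tuple
    weights: np.ndarray                 # (n_rois, L)
    normalized: np.ndarray | None = None


def fir_design(n_trials: int, trial_length: int) -> np.ndarray:
    """FIR design matrix: impulse regressor per lag, repeated per trial."""
    T = n_trials * trial_length
    X = np.zeros((T, trial_length))
    for lag in range(trial_length):
        X[lag::trial_length, lag] = 1.0
    return X


def fit_fir(norm: NormalizedTrialSeries) -> FirResponseSet:
    """Least-squares FIR estimate of the trial-locked response.

    The design holds one impulse regressor per lag after trial onset, with
    a 1 at that lag of every trial. For the concatenated equal-length
    segments this system is orthogonal and the solution equals the per-lag
    mean across trials (asserted against that oracle in the tests).
    """
    if norm.n_trials < 2:
        raise ValueError("FIR estimation needs at least 2 trials")
    X = fir_design(norm.n_trials, norm.trial_length)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("FIR design is rank deficient")
    weights, _, _, _ = np.linalg.lstsq(X, norm.data.T, rcond=None)
    return FirResponseSet(norm.subject_id, norm.roi_ids, weights.T)


def normalize_response(fir: FirResponseSet,
                       n_points: int = NORMALIZED_LENGTH) -> FirResponseSet:
    """Resample FIR weights to the fixed percent-decision-time axis.

    Point i of the output sits at fraction i/(n_points-1) of the trial,
    0% = onset, 100% = button press. Identity when L == n_points.
    """
    if fir.weights.shape[1] < 2:
        raise ValueError("need at least 2 FIR lags to normalize")
    return replace(fir, normalized=_resample_linear(fir.weights, n_points))


def strict_local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (both neighbors lower); interior only."""
    y = np.asarray(y)
    idx = np.nonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))[0] + 1
    return idx


@dataclass
class SpatiotemporalMap:
    """ROI x window consensus counts on the percent-time axis."""

    roi_ids: tuple
    counts: np.ndarray          # (n_rois, n_windows) integer subject counts
    window_starts: np.ndarray   # percent
    window_pct: float
    step_pct: float
    top_k: int
    min_subjects: int
    n_subjects: int
    condition: str = "all"

    @property
    def thresholded(self) -> np.ndarray:
        """Counts with sub-threshold cells zeroed."""
        return np.where(self.counts >= self.min_subjects, self.counts, 0)

    def to_frame(self, thresholded_only: bool = False) -> pd.DataFrame:
        rois = np.repeat(self.roi_ids, len(self.window_starts))
        starts = np.tile(self.window_starts, len(self.roi_ids))
        counts = self.counts.ravel()
        frame = pd.DataFrame({
            "roi_id": rois, "window_start_pct": starts, "count": counts,
            "condition": self.condition,
        })
        if thresholded_only:
            frame = frame[frame["count"] >= self.min_subjects].reset_index(drop=True)
        return frame


def window_grid(window_pct: float = 20.0, step_pct: float = 5.0,
                total: int = NORMALIZED_LENGTH) -> np.ndarray:
    """Window start percents 0, step, ..., total - window (inclusive)."""
    if not 0 < window_pct <= total:
        raise ValueError("window_pct must lie in (0, 100]")
    if not 0 < step_pct <= window_pct:
        raise ValueError("step_pct must lie in (0, window_pct]")
    n = int(np.floor((total - window_pct) / step_pct + 1e-9)) + 1
    return np.arange(n) * step_pct


def consensus_map(responses, window_pct: float = 20.0, step_pct: float = 5.0,
                  top_k: int = 20, min_subjects: int = 8,
                  condition: str = "all") -> SpatiotemporalMap:
    """Bin the top-K response peaks per subject and sliding window.

    For every subject and window, strict local maxima of each ROI's
    normalized response are collected; the peaks are ranked by amplitude
    (ties broken by earlier time then lower ROI id) and the ROIs owning the
    ``top_k`` best peaks each increment their bin once. The thresholded
    view keeps cells where at least ``min_subjects`` subjects agree.
    """
    responses = list(responses)
    if not responses:
        raise ValueError("need at least one subject response")
    roi_ids = responses[0].roi_ids
    for resp in responses:
        if resp.roi_ids != roi_ids:
            raise ValueError("subjects have mismatched ROI sets")
        if resp.normalized is None:
            raise ValueError("responses must be normalized first "
                             "(see normalize_response)")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    starts = window_grid(window_pct, step_pct)
    counts = np.zeros((len(roi_ids), len(starts)), dtype=int)
    n_points = responses[0].normalized.shape[1]
    for resp in responses:
        # peak list per ROI, computed once over the full normalized axis
        peaks = []  # (amplitude, index, roi_position)
        for k in range(len(roi_ids)):
            y = resp.normalized[k]
            for i in strict_local_maxima(y):
                peaks.append((float(y[i]), int(i), k))
        for w, s in enumerate(starts):
            lo, hi = s, s + window_pct
            cands = [pk for pk in peaks if lo <= pk[1] < min(hi, n_points)]
            cands.sort(key=lambda pk: (-pk[0], pk[1], roi_ids[pk[2]]))
            if len({pk[2] for pk in cands}) < top_k and len(cands) < top_k:
                logger.debug("window %s: only %d candidate peaks for top_k=%d",
                             s, len(cands), top_k)
            hit = {pk[2] for pk in cands[:top_k]}
            for k in hit:
                counts[k, w] += 1
    return SpatiotemporalMap(roi_ids, counts, starts, window_pct, step_pct,
                             top_k, min_subjects, len(responses), condition)


@dataclass
class DifferenceMap:
    """Signed yes-minus-no consensus difference, thresholded cell-wise."""

    roi_ids: tuple
    diff: np.ndarray            # N_yes - N_no per cell
    window_starts: np.ndarray
    min_diff: int

    @property
    def retained(self) -> np.ndarray:
        return np.abs(self.diff) >= self.min_diff

    def to_frame(self, retained_only: bool = True) -> pd.DataFrame:
        rois = np.repeat(self.roi_ids, len(self.window_starts))
        starts = np.tile(self.window_starts, len(self.roi_ids))
        diff = self.diff.ravel()
        frame = pd.DataFrame({
            "roi_id": rois, "window_start_pct": starts, "n_yes_minus_n_no": diff,
            "dominant": np.where(diff >= 0, "yes", "no"),
        })
        if retained_only:
            frame = frame[np.abs(frame["n_yes_minus_n_no"]) >= self.min_diff]
            frame = frame.reset_index(drop=True)
        return frame


def condition_difference(map_yes: SpatiotemporalMap, map_no: SpatiotemporalMap,
                         min_diff: int = 7) -> DifferenceMap:
    """Cell-wise N_yes - N_no; retained where |difference| >= min_diff."""
    if (map_yes.roi_ids != map_no.roi_ids
            or not np.array_equal(map_yes.window_starts, map_no.window_starts)):
        raise ValueError("yes/no maps are on different grids")
    return DifferenceMap(map_yes.roi_ids, map_yes.counts - map_no.counts,
                         map_yes.window_starts, min_diff)


def earliest_window(map_: SpatiotemporalMap, roi_set) -> float | None:
    """Earliest window start (percent) where any ROI of the set is above
    threshold; None when the set never reaches consensus."""
    rows = [map_.roi_ids.index(r) for r in roi_set]
    above = map_.thresholded[rows].sum(axis=0) > 0
    hits = np.nonzero(above)[0]
    return float(map_.window_starts[hits[0]]) if hits.size else None


def stage_order(map_: SpatiotemporalMap, roi_sets) -> list | None:
    """ROI sets sorted by earliest above-threshold window.

    Returns the list of set indices in measured temporal order, or None if
    any set never crosses the consensus threshold. Because the hemodynamic
    delay is deliberately not corrected and trials abut, responses of
    stages ending at the press wrap to the next trial's early windows;
    planted orderings are therefore recovered up to a circular rotation.
    """
    onsets = []
    for i, rois in enumerate(roi_sets):
        e = earliest_window(map_, rois)
        if e is None:
            return None
        onsets.append((e, i))
    onsets.sort()
    return [i for _, i in onsets]


def is_rotation(measured, planted) -> bool:
    """True when ``measured`` is a circular rotation of ``planted``."""
    measured, planted = list(measured), list(planted)
    if len(measured) != len(planted):
        return False
    doubled = planted + planted
    return any(doubled[i:i + len(planted)] == measured
               for i in range(len(planted)))
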