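"""Shared containers and plain-text I/O.

The pipeline's canonical in-memory objects are deliberately small: a trial
table is a pandas DataFrame with exactly the columns ``onset``, ``duration``
and ``response`` (seconds; response in {"yes", "no"}), and a subject's signals
live in a :class:`RoiTimeSeriesSet` (ROI x time matrix sampled at the scanner
repetition time).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

EVENTS_COLUMNS = ("onset", "duration", "response")
RESPONSES = ("yes", "no")


@dataclass
class RoiTimeSeriesSet:
    """Per-subject ROI (or component) time-series matrix.

    Parameters
    ----------
    subject_id : str
        Identifier, e.g. ``"sub-03"``.
    roi_ids : sequence of int
        Region identifiers, one per row of ``data``. Purely metadata (for an
        anatomical atlas these would be atlas label integers).
    data : ndarray, shape (n_rois, n_samples)
        Signal in arbitrary units (percent signal change for the synthetic
        cohorts).
    tr : float
        Sampling interval in seconds.
    """

    subject_id: str
    roi_ids: tuple
    data: np.ndarray
    tr: float

    def __post_init__(self):
        self.roi_ids = tuple(int(r) for r in self.roi_ids)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_rois, n_samples) array")
        if self.data.shape[0] != len(self.roi_ids):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.roi_ids)} roi_ids"
            )
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("roi_ids must be unique")
        if not self.tr > 0:
            raise ValueError("tr must be positive")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.tr

    def index_of(self, roi_id: int) -> int:
        try:
            return self.roi_ids.index(int(roi_id))
        except ValueError:
            raise KeyError(f"ROI {roi_id} not in series") from None

    def with_data(self, data: np.ndarray) -> "RoiTimeSeriesSet":
        """Copy of this set with the signal matrix replaced."""
        return replace(self, data=np.asarray(data, dtype=float))

    def subset(self, roi_ids) -> "RoiTimeSeriesSet":
        """Row subset in the order of ``roi_ids``."""
        idx = [self.index_of(r) for r in roi_ids]
        return RoiTimeSeriesSet(self.subject_id, tuple(roi_ids),
                                self.data[idx].copy(), self.tr)


def validate_events(trials: pd.DataFrame) -> pd.DataFrame:
    """Check a trial table against the events contract; returns the table."""
    if tuple(trials.columns) != EVENTS_COLUMNS:
        raise ValueError(
            f"events table must have columns {EVENTS_COLUMNS}, got {tuple(trials.columns)}"
        )
    if len(trials) == 0:
        raise ValueError("events table is empty")
    if not (trials["duration"] > 0).all():
        raise ValueError("all trial durations must be positive")
    if not trials["response"].isin(RESPONSES).all():
        raise ValueError(f"responses must be one of {RESPONSES}")
    if not trials["onset"].is_monotonic_increasing:
        raise ValueError("onsets must be sorted")
    return trials


def write_events(trials: pd.DataFrame, path) -> Path:
    path = Path(path)
    validate_events(trials)
    trials.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_events(path) -> pd.DataFrame:
    trials = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return validate_events(trials)


def write_series(series: RoiTimeSeriesSet, path) -> Path:
    """Write the ROI x time matrix as TSV (first column ``roi_id``).

    Float values are written at full precision so a write/read round trip is
    lossless. The TR is not stored here; it travels in the dataset-level
    design file (see :func:`neurodyn.synth.write_dataset`).
    """
    path = Path(path)
    frame = pd.DataFrame(series.data, index=pd.Index(series.roi_ids, name="roi_id"))
    frame.columns = [f"t{j}" for j in range(series.n_samples)]
    frame.to_csv(path, sep="\t", float_format="%.17g")
    return path


def read_series(path, tr: float, subject_id: str | None = None) -> RoiTimeSeriesSet:
    frame = pd.read_csv(path, sep="\t", index_col="roi_id",
                        float_precision="round_trip")
    sid = subject_id if subject_id is not None else Path(path).stem.split("_")[0]
    return RoiTimeSeriesSet(sid, tuple(frame.index), frame.to_numpy(dtype=float), tr)
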