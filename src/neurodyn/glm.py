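"""Event-related GLM with the canonical double-gamma HRF.

The experiment is self-paced: each trial ends with a button press, and the
event regressors are short boxcars ending at the press (default 1 s long,
i.e. beginning 1 s before the press), one regressor for trials answered
"yes" and one for "no". Contrasts of interest are yes>no, no>yes and
both>baseline, tested per ROI with an ordinary-least-squares t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .core import RoiTimeSeriesSet, validate_events


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma HRF parameters (seconds).

    The kernel is ``g(t; peak_delay, peak_disp) - g(t; undershoot_delay,
    undershoot_disp) / undershoot_ratio`` where ``g`` is a gamma density with
    shape ``delay/dispersion`` and scale ``dispersion``, normalized to unit
    peak. Defaults are the standard canonical values (peak ~5 s after an
    impulse, undershoot around 15 s, undershoot a sixth of the peak).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    undershoot_ratio: float = 6.0
    duration: float = 32.0

    def __post_init__(self):
        for name in ("peak_delay", "undershoot_delay", "peak_disp",
                     "undershoot_disp", "undershoot_ratio", "duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.duration < self.undershoot_delay:
            raise ValueError("duration must cover the undershoot delay")


def double_gamma_hrf(params: HrfParams | None = None, tr: float = 0.545) -> np.ndarray:
    """Sample the canonical double-gamma HRF at the repetition time.

    Returns a 1-D kernel of length ``ceil(duration/tr)`` with unit peak.
    """
    if params is None:
        params = HrfParams()
    if not tr > 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, params.duration, tr)
    peak = gamma_dist.pdf(t, params.peak_delay / params.peak_disp,
                          scale=params.peak_disp)
    under = gamma_dist.pdf(t, params.undershoot_delay / params.undershoot_disp,
                           scale=params.undershoot_disp)
    kernel = peak - under / params.undershoot_ratio
    return kernel / kernel.max()


@dataclass
class DesignMatrix:
    """Named time x regressor matrix sampled at the TR."""

    names: list
    matrix: np.ndarray
    tr: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix shape does not match regressor names")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, list(self.names).index(name)]


def build_design(trials: pd.DataFrame, series_len: int, tr: float,
                 event_duration: float = 1.0,
                 hrf: HrfParams | None = None) -> DesignMatrix:
    """Assemble yes/no event regressors plus an intercept.

    Each trial contributes a boxcar of ``event_duration`` seconds ending at
    its button press (onset + duration), assigned to the regressor of its
    response, then convolved with the canonical HRF. Sample indices round
    toward the earlier TR.
    """
    validate_events(trials)
    if not event_duration > 0:
        raise ValueError("event_duration must be positive")
    boxcars = {"yes": np.zeros(series_len), "no": np.zeros(series_len)}
    for _, trial in trials.iterrows():
        press = trial["onset"] + trial["duration"]
        start = press - event_duration
        if start < 0:
            raise ValueError(f"event starting at {start:.3f}s precedes the series")
        if press > series_len * tr:
            raise ValueError(
                f"button press at {press:.3f}s lies beyond the series "
                f"({series_len * tr:.3f}s)")
        i0 = int(np.floor(start / tr))
        i1 = max(i0 + 1, int(np.floor(press / tr)))
        boxcars[trial["response"]][i0:min(i1, series_len)] = 1.0
    kernel = double_gamma_hrf(hrf, tr)
    cols = [np.convolve(boxcars[name], kernel)[:series_len] for name in ("yes", "no")]
    cols.append(np.ones(series_len))
    return DesignMatrix(["yes", "no", "intercept"], np.column_stack(cols), tr)


@dataclass
class GlmFit:
    """Per-ROI OLS estimates for one subject."""

    roi_ids: tuple
    beta: np.ndarray        # (n_rois, n_regressors)
    sigma2: np.ndarray      # (n_rois,) residual variance, RSS / dof
    dof: int
    design: DesignMatrix
    xtx_inv: np.ndarray


def fit_glm(series: RoiTimeSeriesSet, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares of every ROI series on the design matrix."""
    X = design.matrix
    if X.shape[0] != series.n_samples:
        raise ValueError("design rows must equal the series length")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via the QR diagonal
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [design.names[j] for j in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    Y = series.data.T  # (n_samples, n_rois)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = X.shape[0] - rank
    rss = (resid ** 2).sum(axis=0)
    # an exact fit leaves only rounding error in the residuals
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    rss[rss <= 1e-24 * np.maximum(tss, 1.0)] = 0.0
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    return GlmFit(series.roi_ids, beta.T, sigma2, dof, design, xtx_inv)


def standard_contrasts(design: DesignMatrix) -> dict:
    """The three standard contrasts on the yes/no regressors."""
    base = {name: 0.0 for name in design.names}

    def vec(weights):
        out = dict(base)
        out.update(weights)
        return np.array([out[name] for name in design.names])

    return {
        "yes>no": vec({"yes": 1.0, "no": -1.0}),
        "no>yes": vec({"yes": -1.0, "no": 1.0}),
        "both>baseline": vec({"yes": 1.0, "no": 1.0}),
    }


def contrast_map(fit: GlmFit, contrast: np.ndarray,
                 name: str | None = None) -> pd.DataFrame:
    """Effect size and t statistic of a contrast, per ROI.

    ``effect = c'beta`` and ``t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c)``.
    ROIs with zero residual variance get ``t = NaN`` and ``valid = False``.
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.beta.shape[1],):
        raise ValueError(
            f"contrast length {c.size} does not match {fit.beta.shape[1]} regressors")
    effect = fit.beta @ c
    scale = fit.sigma2 * float(c @ fit.xtx_inv @ c)
    valid = scale > 0
    t = np.full(effect.shape, np.nan)
    t[valid] = effect[valid] / np.sqrt(scale[valid])
    return pd.DataFrame({
        "roi_id": fit.roi_ids,
        "contrast": name if name is not None else "custom",
        "effect": effect,
        "t": t,
        "dof": fit.dof,
        "valid": valid,
    })
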