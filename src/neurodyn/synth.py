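"""Synthetic multi-subject self-paced BOLD cohorts with known ground truth.

The generator emulates a self-paced decision experiment: after a 10 s blank
lead-in, trials follow each other with no inter-stimulus interval (a new
stimulus appears the instant the button is pressed), so trial k+1 starts
exactly when trial k's response time elapses. Response times are drawn from
a truncated normal with a per-subject mean, mirroring the empirical pattern
that between-subject variability exceeds within-subject variability.

Regional "neural" activity is planted as stage boxcars on the normalized
decision-time axis (e.g. a visual stage over the first 20% of each trial),
scaled per response condition, convolved with the same canonical
double-gamma HRF the GLM stage assumes, and summed with structured noise:
AR(1)-autocorrelated Gaussian noise (optionally correlated within ROI
blocks, optionally only inside a trial epoch or response condition) plus a
slow sinusoidal + linear drift.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import truncnorm

from .core import EVENTS_COLUMNS, RoiTimeSeriesSet, read_events, read_series, \
    write_events, write_series
from .glm import HrfParams, double_gamma_hrf

__all__ = [
    "StudyDesign", "StageSpec", "CorrelationBlock", "NoiseSpec",
    "SyntheticDataset", "sample_trial_timings", "make_stage_template",
    "synthesize_subject", "synthesize_cohort", "write_dataset", "read_dataset",
    "paper_like_design", "paper_like_stages", "paper_like_noise",
    "paper_like_cohort", "DEFAULT_ROI_IDS", "DEFAULT_DECODING_ROIS",
]


@dataclass(frozen=True)
class StudyDesign:
    """Cohort-level experimental design.

    ``rt_mean_by_subject`` gives each subject's response-time distribution
    center (seconds); response times are truncated-normal on
    ``[rt_min, rt_max]`` with spread ``rt_sd``. ``lead_in_s`` is the blank
    baseline screen before the first trial and ``tail_s`` extra scan time
    after the last press so the final hemodynamic response is captured.
    """

    n_subjects: int = 20
    n_trials: int = 25
    tr: float = 0.545
    rt_min: float = 4.0
    rt_max: float = 45.0
    rt_mean_by_subject: tuple = ()
    rt_sd: float = 3.0
    yes_probability: float = 0.5
    rng_seed: int = 0
    lead_in_s: float = 10.0
    tail_s: float = 15.0

    def __post_init__(self):
        if self.n_trials < 1 or self.n_subjects < 1:
            raise ValueError("n_subjects and n_trials must be >= 1")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if not (0 < self.rt_min <= self.rt_max):
            raise ValueError("need 0 < rt_min <= rt_max")
        if not 0 <= self.yes_probability <= 1:
            raise ValueError("yes_probability must lie in [0, 1]")
        if self.rt_sd < 0:
            raise ValueError("rt_sd must be non-negative")
        means = self.rt_means
        for mu in means:
            if not self.rt_min <= mu <= self.rt_max:
                raise ValueError(
                    f"rt_mean {mu} outside [{self.rt_min}, {self.rt_max}]")

    @property
    def rt_means(self) -> tuple:
        """Per-subject RT centers; a scalar default of 18 s if unset."""
        if len(self.rt_mean_by_subject) == 0:
            return (18.0,) * self.n_subjects
        if len(self.rt_mean_by_subject) != self.n_subjects:
            raise ValueError("rt_mean_by_subject length must equal n_subjects")
        return tuple(float(m) for m in self.rt_mean_by_subject)

    @property
    def subject_ids(self) -> tuple:
        return tuple(f"sub-{i + 1:02d}" for i in range(self.n_subjects))


@dataclass(frozen=True)
class StageSpec:
    """A processing stage: ROI set active over a band of decision time.

    ``start_frac``/``end_frac`` are fractions of each trial's response time;
    amplitudes are percent signal change of the underlying neural boxcar,
    separately for yes- and no-answered trials.
    """

    name: str
    roi_ids: tuple
    start_frac: float
    end_frac: float
    amplitude_yes: float = 1.0
    amplitude_no: float = 1.0

    def __post_init__(self):
        if not (0 <= self.start_frac < self.end_frac <= 1):
            raise ValueError("need 0 <= start_frac < end_frac <= 1")
        if not (np.isfinite(self.amplitude_yes) and np.isfinite(self.amplitude_no)):
            raise ValueError("amplitudes must be finite")
        if len(self.roi_ids) == 0:
            raise ValueError("a stage needs at least one ROI")

    def amplitude(self, response: str) -> float:
        return self.amplitude_yes if response == "yes" else self.amplitude_no


@dataclass(frozen=True)
class CorrelationBlock:
    """Equicorrelated noise block with population correlation ``r``.

    ``epoch`` restricts the coupling to part of each trial
    (``"all" | "trial_start" | "trial_end"``, window ``epoch_length_s``) and
    ``condition`` to trials of one response (``"all" | "yes" | "no"``);
    outside the restriction the block's ROIs carry independent noise.
    Negative ``r`` is only well-defined for 2-ROI blocks.
    """

    roi_ids: tuple
    r: float
    epoch: str = "all"
    epoch_length_s: float = 10.0
    condition: str = "all"

    def __post_init__(self):
        if not -1 < self.r < 1:
            raise ValueError("block correlation must lie in (-1, 1)")
        if self.r < 0 and len(self.roi_ids) > 2:
            raise ValueError("negative correlation blocks support only 2 ROIs")
        if self.epoch not in ("all", "trial_start", "trial_end"):
            raise ValueError(f"unknown epoch {self.epoch!r}")
        if self.condition not in ("all", "yes", "no"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(self.roi_ids) < 2:
            raise ValueError("a correlation block needs >= 2 ROIs")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: AR(1) Gaussian noise + slow drift.

    ``white_sd`` is the marginal (stationary) noise standard deviation in
    signal units; ``ar_coef`` the lag-one autocorrelation (BOLD noise is
    strongly autocorrelated at sub-second TR, which also gives realistic
    fALFF > 1 for retained components). Drift is one slow sinusoid of
    amplitude ``drift_amplitude`` and period ``drift_period_s`` plus a
    linear term spanning the same amplitude over the run.
    """

    white_sd: float = 0.8
    ar_coef: float = 0.85
    drift_amplitude: float = 0.4
    drift_period_s: float = 128.0
    blocks: tuple = ()

    def __post_init__(self):
        if self.white_sd < 0:
            raise ValueError("white_sd must be >= 0")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must lie in [0, 1)")
        if not self.drift_period_s > 0:
            raise ValueError("drift_period_s must be positive")
        seen = set()
        for block in self.blocks:
            overlap = seen.intersection(block.roi_ids)
            if overlap:
                raise ValueError(
                    f"correlation blocks overlap on ROIs {sorted(overlap)}")
            seen.update(block.roi_ids)


@dataclass
class SyntheticDataset:
    """A full synthetic cohort plus its generating ground truth."""

    design: StudyDesign
    stages: tuple
    noise: NoiseSpec
    roi_ids: tuple
    trials: dict     # subject_id -> events DataFrame
    series: dict     # subject_id -> RoiTimeSeriesSet

    @property
    def subject_ids(self) -> tuple:
        return tuple(self.trials.keys())


def sample_trial_timings(design: StudyDesign) -> dict:
    """Draw per-subject trial tables (onset, duration, response).

    Trials are back-to-back: the first onset is at ``lead_in_s`` and each
    subsequent trial starts at the previous press. Reproducible from
    ``design.rng_seed``.
    """
    tables = {}
    for i, (sid, mu) in enumerate(zip(design.subject_ids, design.rt_means)):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(design.rng_seed), 101, i]))
        if design.rt_sd == 0:
            rt = np.full(design.n_trials, mu)
        else:
            a = (design.rt_min - mu) / design.rt_sd
            b = (design.rt_max - mu) / design.rt_sd
            rt = truncnorm.rvs(a, b, loc=mu, scale=design.rt_sd,
                               size=design.n_trials, random_state=rng)
        labels = np.where(rng.random(design.n_trials) < design.yes_probability,
                          "yes", "no")
        onsets = design.lead_in_s + np.concatenate(([0.0], np.cumsum(rt[:-1])))
        tables[sid] = pd.DataFrame(
            {"onset": onsets, "duration": rt, "response": labels},
            columns=list(EVENTS_COLUMNS))
    return tables


def make_stage_template(stage: StageSpec, rt: float, tr: float,
                        response: str = "yes") -> np.ndarray:
    """Trial-local neural boxcar for one stage, sampled at the TR.

    Length is ``ceil(rt/tr)``; sample i (at time ``i*tr`` from trial onset)
    is nonzero exactly when it falls in ``[start_frac*rt, end_frac*rt)``.
    """
    if not rt > 0:
        raise ValueError("rt must be positive")
    n = int(math.ceil(rt / tr))
    t = np.arange(n) * tr
    band = (t >= stage.start_frac * rt) & (t < stage.end_frac * rt)
    return stage.amplitude(response) * band.astype(float)


def _trial_sample_bounds(trials: pd.DataFrame, tr: float):
    """Start/end sample index per trial (round-to-nearest; contiguous)."""
    start = np.round(trials["onset"].to_numpy() / tr).astype(int)
    end = np.round((trials["onset"] + trials["duration"]).to_numpy() / tr).astype(int)
    return start, end


def _block_mask(block: CorrelationBlock, trials: pd.DataFrame, tr: float,
                n_samples: int) -> np.ndarray:
    """Boolean sample mask where a block's coupling is active."""
    if block.epoch == "all" and block.condition == "all":
        return np.ones(n_samples, dtype=bool)
    mask = np.zeros(n_samples, dtype=bool)
    starts, ends = _trial_sample_bounds(trials, tr)
    w = int(math.floor(block.epoch_length_s / tr))
    for (_, trial), i0, i1 in zip(trials.iterrows(), starts, ends):
        if block.condition != "all" and trial["response"] != block.condition:
            continue
        i1 = min(i1, n_samples)
        if block.epoch == "trial_start":
            mask[i0:min(i0 + w, i1)] = True
        elif block.epoch == "trial_end":
            mask[max(i0, i1 - w):i1] = True
        else:
            mask[i0:i1] = True
    return mask


def _correlated_innovations(trials: pd.DataFrame, noise: NoiseSpec,
                            roi_ids: tuple, tr: float, n_samples: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Unit-variance innovations with block-factorized correlation.

    Within a block's active mask each ROI is ``sqrt(1-|r|) e_i +/-
    sqrt(|r|) c`` for a shared factor ``c``, which has population pairwise
    correlation exactly ``r`` (sign flip on the second ROI for r < 0).
    """
    innov = rng.standard_normal((len(roi_ids), n_samples))
    index = {roi: k for k, roi in enumerate(roi_ids)}
    for block in noise.blocks:
        missing = [r for r in block.roi_ids if r not in index]
        if missing:
            raise ValueError(f"block ROIs {missing} absent from roi_ids")
        shared = rng.standard_normal(n_samples)
        mask = _block_mask(block, trials, tr, n_samples)
        root_r = math.sqrt(abs(block.r))
        root_1mr = math.sqrt(1 - abs(block.r))
        for j, roi in enumerate(block.roi_ids):
            sign = -1.0 if (block.r < 0 and j == 1) else 1.0
            row = index[roi]
            innov[row, mask] = (root_1mr * innov[row, mask]
                                + sign * root_r * shared[mask])
    return innov


def synthesize_subject(trials: pd.DataFrame, stages, noise: NoiseSpec,
                       tr: float, seed: int, roi_ids,
                       subject_id: str = "sub-01",
                       tail_s: float = 15.0,
                       hrf: HrfParams | None = None) -> RoiTimeSeriesSet:
    """Simulate one subject's ROI x time BOLD matrix.

    Signal = sum over trials and stages of HRF-convolved stage boxcars;
    noise = AR(1)-filtered (block-)correlated innovations scaled to
    ``white_sd`` marginal SD; drift = slow sinusoid (random phase per ROI)
    plus a linear ramp. Deterministic given ``seed``.
    """
    roi_ids = tuple(int(r) for r in roi_ids)
    last_press = float((trials["onset"] + trials["duration"]).iloc[-1])
    n_samples = int(math.ceil((last_press + tail_s) / tr))
    rng = np.random.default_rng(seed)

    neural = np.zeros((len(roi_ids), n_samples))
    index = {roi: k for k, roi in enumerate(roi_ids)}
    starts, _ = _trial_sample_bounds(trials, tr)
    for (_, trial), i0 in zip(trials.iterrows(), starts):
        for stage in stages:
            template = make_stage_template(stage, trial["duration"], tr,
                                           trial["response"])
            seg = template[:max(0, n_samples - i0)]
            for roi in stage.roi_ids:
                if roi in index:
                    neural[index[roi], i0:i0 + seg.size] += seg

    kernel = double_gamma_hrf(hrf, tr)
    signal = np.zeros_like(neural)
    for k in range(len(roi_ids)):
        if np.any(neural[k]):
            signal[k] = np.convolve(neural[k], kernel)[:n_samples]

    # drift phases drawn first so the noise stream does not depend on blocks
    phases = rng.uniform(0, 2 * np.pi, size=len(roi_ids))
    t = np.arange(n_samples) * tr
    drift = (noise.drift_amplitude
             * np.sin(2 * np.pi * t / noise.drift_period_s + phases[:, None])
             + noise.drift_amplitude * (t / t[-1] - 0.5) if n_samples > 1 else
             np.zeros((len(roi_ids), n_samples)))

    innov = _correlated_innovations(trials, noise, roi_ids, tr, n_samples, rng)
    phi = noise.ar_coef
    ar = lfilter([math.sqrt(1 - phi ** 2)], [1.0, -phi], innov, axis=1)
    data = signal + noise.white_sd * ar + drift
    return RoiTimeSeriesSet(subject_id, roi_ids, data, tr)


def synthesize_cohort(design: StudyDesign, stages, noise: NoiseSpec,
                      roi_ids=None) -> SyntheticDataset:
    """Generate a full cohort; ground truth is kept on the returned dataset.

    ``roi_ids`` defaults to the union of stage and block ROIs; pass the full
    ROI universe explicitly to include signal-free regions.
    """
    if roi_ids is None:
        ids = set()
        for stage in stages:
            ids.update(stage.roi_ids)
        for block in noise.blocks:
            ids.update(block.roi_ids)
        roi_ids = tuple(sorted(ids))
    roi_ids = tuple(int(r) for r in roi_ids)
    trials = sample_trial_timings(design)
    seed_rng = np.random.default_rng(
        np.random.SeedSequence([int(design.rng_seed), 202]))
    seeds = seed_rng.integers(0, 2 ** 31 - 1, size=design.n_subjects)
    series = {}
    for sid, seed in zip(design.subject_ids, seeds):
        series[sid] = synthesize_subject(
            trials[sid], stages, noise, design.tr, int(seed), roi_ids,
            subject_id=sid, tail_s=design.tail_s)
    return SyntheticDataset(design, tuple(stages), noise, roi_ids, trials, series)


# ---------------------------------------------------------------------------
# disk round trip

def _dataclass_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _dataclass_to_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_dataclass_to_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_dataset(dataset: SyntheticDataset, directory, nifti: bool = False) -> Path:
    """Write a cohort as plain-text files (events TSV + series TSV).

    With ``nifti=True`` additionally renders each subject into a small 4-D
    NIfTI volume (one voxel per ROI on a cubic grid, 3.3 mm voxels, TR in
    the 4th zoom) plus a 3-D integer label atlas, to exercise the volume
    path of the prep stage.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "design": _dataclass_to_jsonable(dataset.design),
        "stages": _dataclass_to_jsonable(dataset.stages),
        "noise": _dataclass_to_jsonable(dataset.noise),
        "roi_ids": list(dataset.roi_ids),
    }
    (directory / "design.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    for sid in dataset.subject_ids:
        write_events(dataset.trials[sid], directory / f"{sid}_events.tsv")
        write_series(dataset.series[sid], directory / f"{sid}_series.tsv")
    if nifti:
        _write_nifti(dataset, directory)
    return directory


def _roi_grid(roi_ids):
    side = int(math.ceil(len(roi_ids) ** (1 / 3)))
    shape = (side, side, side)
    coords = [np.unravel_index(k, shape) for k in range(len(roi_ids))]
    return shape, coords


def _write_nifti(dataset: SyntheticDataset, directory: Path):
    import nibabel as nib

    shape, coords = _roi_grid(dataset.roi_ids)
    affine = np.diag([3.3, 3.3, 3.3, 1.0])
    atlas = np.zeros(shape, dtype=np.int16)
    for roi, (x, y, z) in zip(dataset.roi_ids, coords):
        atlas[x, y, z] = roi
    nib.save(nib.Nifti1Image(atlas, affine), directory / "atlas.nii")
    for sid in dataset.subject_ids:
        series = dataset.series[sid]
        vol = np.zeros(shape + (series.n_samples,), dtype=np.float32)
        for k, (x, y, z) in enumerate(coords):
            vol[x, y, z, :] = series.data[k]
        img = nib.Nifti1Image(vol, affine)
        img.header.set_zooms((3.3, 3.3, 3.3, series.tr))
        nib.save(img, directory / f"{sid}_bold.nii")


def read_dataset(directory) -> SyntheticDataset:
    """Load a cohort written by :func:`write_dataset` (text files only)."""
    directory = Path(directory)
    meta = json.loads((directory / "design.json").read_text())
    design = StudyDesign(**{**meta["design"],
                            "rt_mean_by_subject": tuple(meta["design"]["rt_mean_by_subject"])})
    stages = tuple(StageSpec(**{**s, "roi_ids": tuple(s["roi_ids"])})
                   for s in meta["stages"])
    noise_meta = dict(meta["noise"])
    noise_meta["blocks"] = tuple(
        CorrelationBlock(**{**b, "roi_ids": tuple(b["roi_ids"])})
        for b in noise_meta.get("blocks", ()))
    noise = NoiseSpec(**noise_meta)
    roi_ids = tuple(meta["roi_ids"])
    trials, series = {}, {}
    for sid in design.subject_ids:
        trials[sid] = read_events(directory / f"{sid}_events.tsv")
        series[sid] = read_series(directory / f"{sid}_series.tsv", design.tr, sid)
    return SyntheticDataset(design, stages, noise, roi_ids, trials, series)


# ---------------------------------------------------------------------------
# paper-like preset

#: ROI universe of the preset: 120 anatomically-motivated integer labels.
DEFAULT_ROI_IDS = tuple(range(1, 121))

#: Ten-ROI subset used by the decoding stage by default: late decision
#: regions (5, 11, 21, 25), condition-coupled limbic/parietal ROIs
#: (45, 46, 69) and three task-free regions (71, 72, 109).
DEFAULT_DECODING_ROIS = (5, 11, 21, 25, 45, 46, 69, 71, 72, 109)


def paper_like_design(seed: int = 0) -> StudyDesign:
    """20 subjects, 25 self-paced trials, TR 0.545 s.

    Fourteen subjects have RT centers spread over 13-30 s; six are planted
    fast deciders (~6 s) whom the >10 s-for->=13-trials inclusion rule
    excludes, leaving 14 analyzable subjects.
    """
    kept = np.linspace(13.0, 30.0, 14)
    fast = [5.5, 6.0, 6.5, 5.8, 6.2, 6.8]
    means = list(kept)
    # interleave the fast subjects at fixed positions
    for pos, mu in zip((2, 5, 8, 11, 14, 17), fast):
        means.insert(pos, mu)
    return StudyDesign(n_subjects=20, n_trials=25, tr=0.545,
                       rt_min=4.0, rt_max=45.0,
                       rt_mean_by_subject=tuple(means),
                       rt_sd=3.0, yes_probability=0.5, rng_seed=seed)


def paper_like_stages() -> tuple:
    """Stage-ordered activations on the normalized decision-time axis.

    Early visual intake, mid-trial evaluation (cingulate/orbitofrontal),
    a late decision stage (prefrontal, yes-answers only), a mid-trial
    uncertainty stage (posterior default-mode/cerebellar, no-answers only)
    and a motor burst at the press. ROI integers follow anatomical-atlas
    numbering purely as metadata.
    """
    return (
        StageSpec("visual", (48, 51, 52), 0.00, 0.20, 1.0, 1.0),
        StageSpec("evaluation", (25, 26, 27), 0.35, 0.70, 1.0, 0.8),
        StageSpec("decision", (5, 11, 31), 0.55, 0.85, 1.2, 0.0),
        StageSpec("uncertainty", (71, 72, 109), 0.35, 0.70, 0.0, 1.0),
        StageSpec("motor", (61,), 0.90, 1.00, 1.0, 1.0),
    )


def paper_like_noise() -> NoiseSpec:
    """Structured noise with planted connectivity.

    A stationary visual block, an end-of-trial frontal coupling (visible
    only in press-anchored connectivity windows) and a yes-trial-only
    limbic coupling that carries the decodable condition signature.
    """
    return NoiseSpec(
        white_sd=0.8, ar_coef=0.85, drift_amplitude=0.4, drift_period_s=128.0,
        blocks=(
            CorrelationBlock((48, 51, 52), r=0.5),
            CorrelationBlock((5, 11), r=0.8, epoch="trial_end", epoch_length_s=10.0),
            CorrelationBlock((45, 46, 69), r=0.7, condition="yes"),
        ))


def paper_like_cohort(seed: int = 0) -> SyntheticDataset:
    """The default study-scale cohort (20 subjects, 120 ROIs)."""
    return synthesize_cohort(paper_like_design(seed), paper_like_stages(),
                             paper_like_noise(), roi_ids=DEFAULT_ROI_IDS)
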