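"""Digital health metrics from goal-directed peg-insertion recordings.

A trial is a synchronized stream of 3-D end-effector position (mm) and grip
force (N) recorded while the subject inserts nine virtual pegs into nine
holes, repeated several times. Each peg cycle decomposes into four phases:

* ``peg_approach`` — precise movement just before the peg is grasped;
* ``transport`` — gross movement from grasp onset (grip force rising
  through the 2 N threshold) to insertion (force falling back through it);
* ``hole_approach`` — precise movement just before insertion;
* ``return`` — gross movement from insertion to the next grasp onset.

Ten metrics summarize movement smoothness (log dimensionless jerk, spectral
arc length), efficiency (path length ratio), speed (maximum velocity),
precision (RMS jerk on the peg approach) and grip-force coordination
(force-rate peak count and force-rate spectral arc lengths). Raw values are
confound-adjusted against a healthy reference population and mapped to an
unbounded percentage scale on which 0 % is the healthy median and 100 % the
worst observed impaired performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    DegenerateSegmentError,
    InsufficientDataError,
    ParameterError,
    SegmentationError,
)

#: The ten core metrics, in canonical order.
METRIC_NAMES = (
    "log_jerk_transport",
    "log_jerk_return",
    "sparc_return",
    "path_length_ratio_transport",
    "path_length_ratio_return",
    "velocity_max_return",
    "jerk_peg_approach",
    "force_rate_num_peaks_transport",
    "force_rate_sparc_transport",
    "force_rate_sparc_hole_approach",
)

#: +1 where a larger raw value means worse performance, -1 where smaller is
#: worse (spectral arc lengths are negative and shrink with roughness; a
#: fast return is a healthy return).
WORSE_DIRECTION = pd.Series(
    {
        "log_jerk_transport": +1,
        "log_jerk_return": +1,
        "sparc_return": -1,
        "path_length_ratio_transport": +1,
        "path_length_ratio_return": +1,
        "velocity_max_return": -1,
        "jerk_peg_approach": +1,
        "force_rate_num_peaks_transport": +1,
        "force_rate_sparc_transport": -1,
        "force_rate_sparc_hole_approach": -1,
    }
)

CONFOUND_COVARIATES = ("age", "sex", "dominant_hand_tested", "stereo_vision_deficit")

PHASES = ("peg_approach", "transport", "hole_approach", "return")


@dataclass(frozen=True)
class BoardGeometry:
    """Peg start and hole target positions, millimetres, shape (9, 3) each."""

    pegs: np.ndarray
    holes: np.ndarray

    def __post_init__(self) -> None:
        for name in ("pegs", "holes"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (9, 3):
                raise ParameterError(f"{name} must have shape (9, 3)")
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class TrialRecording:
    """Uniformly sampled position + grip force series for one trial."""

    time: np.ndarray          # seconds, strictly increasing, uniform step
    position: np.ndarray      # (n, 3) millimetres
    grip_force: np.ndarray    # (n,) newtons, >= 0
    board: BoardGeometry
    n_repetitions: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.position, dtype=float)
        f = np.asarray(self.grip_force, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ParameterError("time must be 1-D with at least 2 samples")
        steps = np.diff(t)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ParameterError("time must be strictly increasing and uniform")
        if p.shape != (len(t), 3):
            raise ParameterError("position must have shape (n, 3)")
        if f.shape != (len(t),):
            raise ParameterError("grip_force must have shape (n,)")
        if np.any(f < 0):
            raise ParameterError("grip_force must be non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "grip_force", f)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt


@dataclass(frozen=True)
class PhaseSegment:
    """Half-open sample range [start, end) of one phase instance."""

    phase: str
    start: int
    end: int
    peg_index: int  # 1-9 within the repetition

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ParameterError(f"unknown phase {self.phase!r}")
        if not self.end > self.start:
            raise ParameterError("segment end must exceed start")


@dataclass(frozen=True)
class ReferencePopulation:
    """Normalization anchors and confound model from a healthy/impaired sample.

    ``healthy_median`` and ``worst_impaired`` anchor the 0 %/100 % scale per
    metric; ``confound_coefs`` holds per-metric linear coefficients for the
    covariates (age, sex, dominant_hand_tested, stereo_vision_deficit) fitted
    on the healthy sample, and ``covariate_means`` the healthy-sample means
    they are centred on.
    """

    healthy_median: pd.Series
    worst_impaired: pd.Series
    confound_coefs: pd.DataFrame
    covariate_means: pd.Series
    age_range: tuple[float, float] = (18.0, 90.0)
    worse_direction: pd.Series = field(default_factory=lambda: WORSE_DIRECTION.copy())

    def __post_init__(self) -> None:
        for m in METRIC_NAMES:
            if m not in self.healthy_median.index or m not in self.worst_impaired.index:
                raise ParameterError(f"reference anchors missing metric {m}")
            if self.worst_impaired[m] == self.healthy_median[m]:
                raise ParameterError(f"zero anchor span for metric {m}")


def read_trial_csv(path, board: BoardGeometry,
                   n_repetitions: int = 1) -> TrialRecording:
    """Read a trial from the documented CSV schema.

    Columns: ``t_s`` (seconds), ``x_mm``, ``y_mm``, ``z_mm``, ``force_N``.
    """
    df = pd.read_csv(path)
    required = ["t_s", "x_mm", "y_mm", "z_mm", "force_N"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParameterError(f"{path}: trial CSV missing columns {missing}")
    return TrialRecording(
        time=df["t_s"].to_numpy(float),
        position=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        grip_force=df["force_N"].to_numpy(float),
        board=board, n_repetitions=n_repetitions)


# --------------------------------------------------------------------------
# preprocessing


def preprocess(trial: TrialRecording,
               kinematic_cutoff: float = 10.0,
               force_cutoff: float = 20.0) -> TrialRecording:
    """Zero-phase 4th-order Butterworth low-pass of position and grip force."""
    nyquist = trial.sampling_rate / 2.0
    if not (0 < kinematic_cutoff < nyquist and 0 < force_cutoff < nyquist):
        raise ParameterError(
            f"cutoffs must lie in (0, {nyquist}) Hz for fs={trial.sampling_rate} Hz")
    bk, ak = signal.butter(4, kinematic_cutoff / nyquist)
    bf, af = signal.butter(4, force_cutoff / nyquist)
    pos = signal.filtfilt(bk, ak, trial.position, axis=0)
    force = np.clip(signal.filtfilt(bf, af, trial.grip_force), 0.0, None)
    return replace(trial, position=pos, grip_force=force)


# --------------------------------------------------------------------------
# phase segmentation


def _threshold_crossings(force: np.ndarray, threshold: float,
                         debounce: int = 5):
    """Rising/falling crossing indices after suppressing runs < debounce.

    Measurement noise near the threshold can chatter; runs of above/below
    state shorter than ``debounce`` samples are merged into the surrounding
    state before the crossings are read off.
    """
    above = force >= threshold
    if debounce > 1:
        above = above.copy()
        edges = np.flatnonzero(np.diff(above)) + 1
        bounds = np.concatenate([[0], edges, [len(above)]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if lo > 0 and hi - lo < debounce:
                above[lo:hi] = above[lo - 1]
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    falling = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    if above[0]:
        rising = np.insert(rising, 0, 0)
    return rising, falling


def segment_phases(trial: TrialRecording,
                   force_threshold: float = 2.0,
                   approach_radius: float = 15.0) -> list[PhaseSegment]:
    """Decompose a trial into peg-approach / transport / hole-approach / return.

    Grasp onsets and insertions are grip-force crossings of ``force_threshold``;
    approach phases open when the end-effector enters ``approach_radius`` (mm)
    around the involved peg or hole. Raises :class:`SegmentationError` when no
    complete grasp-release pair exists.
    """
    force = trial.grip_force
    pos = trial.position
    n = len(force)
    rising, falling = _threshold_crossings(force, force_threshold)
    if len(rising) == 0 or len(falling) == 0:
        raise SegmentationError("grip force never crosses the grasp threshold")

    segments: list[PhaseSegment] = []
    pairs: list[tuple[int, int]] = []
    for k, r in enumerate(rising):
        f_after = falling[falling > r]
        if len(f_after) == 0:
            break
        pairs.append((int(r), int(f_after[0])))
    if not pairs:
        raise SegmentationError("no grasp-release pair found (peg 1)")

    n_pegs = len(trial.board.pegs)
    for k, (g, rel) in enumerate(pairs):
        peg_index = k % n_pegs + 1
        peg = trial.board.pegs[peg_index - 1]
        hole = trial.board.holes[peg_index - 1]
        segments.append(PhaseSegment("transport", g, rel, peg_index))
        # return: insertion to next grasp onset (trial end for the last pair)
        ret_end = pairs[k + 1][0] if k + 1 < len(pairs) else n
        if ret_end - rel >= 2:
            segments.append(PhaseSegment("return", rel, ret_end, peg_index))
        # peg approach: entry of the radius around the grasped peg, backwards
        prev_end = pairs[k - 1][1] if k > 0 else 0
        j = g
        while j > prev_end and np.linalg.norm(pos[j - 1] - peg) <= approach_radius:
            j -= 1
        if g - j >= 2:
            segments.append(PhaseSegment("peg_approach", j, g, peg_index))
        # hole approach: entry of the radius around the target hole, backwards
        j = rel
        while j > g and np.linalg.norm(pos[j - 1] - hole) <= approach_radius:
            j -= 1
        if rel - j >= 2:
            segments.append(PhaseSegment("hole_approach", j, rel, peg_index))
    return segments


# --------------------------------------------------------------------------
# per-segment metrics


def _check_length(x: np.ndarray, min_len: int) -> None:
    if len(x) < min_len:
        raise DegenerateSegmentError(
            f"segment of {len(x)} samples; need at least {min_len}")


def _jerk(positions: np.ndarray, dt: float) -> np.ndarray:
    """Third time-derivative by repeated central differences, shape like input."""
    d = np.asarray(positions, dtype=float)
    for _ in range(3):
        d = np.gradient(d, dt, axis=0)
    return d


def path_length(positions: np.ndarray) -> float:
    diffs = np.diff(np.atleast_2d(np.asarray(positions, float).T).T, axis=0)
    return float(np.sum(np.linalg.norm(diffs, axis=1)))


def log_dimensionless_jerk(positions: np.ndarray, dt: float) -> float:
    """ln((T^5 / L^2) * integral of squared jerk); larger = less smooth.

    T is the segment duration and L the traveled path length, which makes
    the quantity invariant to spatial and temporal scaling.
    """
    pos = np.atleast_2d(np.asarray(positions, float).T).T
    _check_length(pos, 4)
    L = path_length(pos)
    if L == 0:
        raise DegenerateSegmentError("no movement in segment (zero path length)")
    T = (len(pos) - 1) * dt
    jerk_sq = np.sum(_jerk(pos, dt) ** 2, axis=1)
    integral = np.trapezoid(jerk_sq, dx=dt)
    return float(np.log(T ** 5 / L ** 2 * integral))


def spectral_arc_length(profile: np.ndarray, dt: float,
                        max_freq: float = 20.0,
                        amp_threshold: float = 0.05,
                        pad_level: int = 4) -> float:
    """Negative arc length of the normalized magnitude spectrum of a profile.

    The band runs from 0 Hz up to the last frequency below ``max_freq``
    whose normalized amplitude still reaches ``amp_threshold`` (adaptive
    cutoff); frequencies are normalized by the band width so the
    value is sampling-rate independent. More negative = less smooth.
    """
    x = np.asarray(profile, dtype=float)
    _check_length(x, 4)
    if not np.any(x != 0):
        raise DegenerateSegmentError("all-zero profile has no spectrum")
    fs = 1.0 / dt
    nfft = int(2 ** np.ceil(np.log2(len(x)) + pad_level))
    freqs = np.arange(nfft // 2 + 1) * fs / nfft
    mag = np.abs(np.fft.rfft(x, nfft))
    mag = mag / mag.max()
    in_band = freqs <= max_freq
    f_sel, m_sel = freqs[in_band], mag[in_band]
    above = np.flatnonzero(m_sel >= amp_threshold)
    # adaptive cutoff: keep the band up to the last supra-threshold component
    f_sel = f_sel[: above[-1] + 1]
    m_sel = m_sel[: above[-1] + 1]
    if len(f_sel) < 2:
        return 0.0  # spectrum collapses to DC (e.g. constant speed)
    span = f_sel[-1] - f_sel[0]
    arc = np.sqrt((np.diff(f_sel) / span) ** 2 + np.diff(m_sel) ** 2)
    return float(-np.sum(arc))


def speed_profile(positions: np.ndarray, dt: float) -> np.ndarray:
    pos = np.atleast_2d(np.asarray(positions, float).T).T
    vel = np.gradient(pos, dt, axis=0)
    return np.linalg.norm(vel, axis=1)


def path_length_ratio(positions: np.ndarray) -> float:
    """Traveled path divided by straight-line start-to-end distance (>= 1)."""
    pos = np.atleast_2d(np.asarray(positions, float).T).T
    _check_length(pos, 2)
    straight = float(np.linalg.norm(pos[-1] - pos[0]))
    traveled = path_length(pos)
    if straight <= 1e-9 * max(traveled, 1e-30):
        raise DegenerateSegmentError("segment starts and ends at the same point")
    return traveled / straight


def velocity_max(positions: np.ndarray, dt: float) -> float:
    """Maximum end-effector speed over the segment, mm/s."""
    pos = np.atleast_2d(np.asarray(positions, float).T).T
    _check_length(pos, 2)
    return float(np.max(speed_profile(pos, dt)))


def rms_jerk(positions: np.ndarray, dt: float) -> float:
    """Root-mean-square jerk magnitude; captures roughness of precise motion."""
    pos = np.atleast_2d(np.asarray(positions, float).T).T
    _check_length(pos, 4)
    jerk_sq = np.sum(_jerk(pos, dt) ** 2, axis=1)
    return float(np.sqrt(np.mean(jerk_sq)))


def force_rate(force: np.ndarray, dt: float) -> np.ndarray:
    return np.gradient(np.asarray(force, dtype=float), dt)


def force_rate_num_peaks(force: np.ndarray, dt: float,
                         prominence_fraction: float = 0.1) -> int:
    """Count of prominent local maxima in the (signed) grip-force rate.

    Prominence threshold is ``prominence_fraction`` of the force-rate
    peak-to-peak range; a monotone ramp therefore counts zero peaks.
    """
    rate = force_rate(force, dt)
    span = rate.max() - rate.min()
    if span <= 1e-9 * max(1.0, np.abs(rate).max()):
        return 0  # flat force-rate profile up to numerical jitter
    peaks, _ = signal.find_peaks(rate, prominence=prominence_fraction * span)
    return int(len(peaks))


def force_rate_sparc(force: np.ndarray, dt: float,
                     max_freq: float = 20.0,
                     amp_threshold: float = 0.05) -> float:
    """Spectral arc length of the grip-force-rate magnitude (<= 0)."""
    rate = np.abs(force_rate(force, dt))
    if not np.any(rate != 0):
        raise DegenerateSegmentError("all-zero force rate")
    return spectral_arc_length(rate, dt, max_freq=max_freq,
                               amp_threshold=amp_threshold)


# --------------------------------------------------------------------------
# trial-level metric vector


@dataclass(frozen=True)
class MetricConfig:
    """Tunables of the metric extraction pipeline (defaults in mm/N/Hz)."""

    apply_preprocess: bool = True
    kinematic_cutoff: float = 10.0
    force_cutoff: float = 20.0
    force_threshold: float = 2.0
    approach_radius: float = 15.0
    sparc_max_freq: float = 20.0
    sparc_amp_threshold: float = 0.05
    prominence_fraction: float = 0.1
    min_valid_movements: int = 5
    aggregator: Callable[[Sequence[float]], float] = np.median


def compute_metric_vector(trial: TrialRecording,
                          config: MetricConfig = MetricConfig()) -> pd.Series:
    """Raw values of the ten metrics for one trial.

    Each metric is evaluated per movement instance (one value per peg-cycle
    phase) and aggregated across all movements of the trial with
    ``config.aggregator`` (default: median). Raises
    :class:`InsufficientDataError` when fewer than
    ``config.min_valid_movements`` transport movements survive.
    """
    if config.apply_preprocess:
        trial = preprocess(trial, config.kinematic_cutoff, config.force_cutoff)
    segments = segment_phases(trial, config.force_threshold, config.approach_radius)
    dt = trial.dt
    per_metric: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}

    for seg in segments:
        pos = trial.position[seg.start:seg.end]
        force = trial.grip_force[seg.start:seg.end]
        try:
            if seg.phase == "transport":
                per_metric["log_jerk_transport"].append(
                    log_dimensionless_jerk(pos, dt))
                per_metric["path_length_ratio_transport"].append(
                    path_length_ratio(pos))
                per_metric["force_rate_num_peaks_transport"].append(
                    force_rate_num_peaks(force, dt, config.prominence_fraction))
                per_metric["force_rate_sparc_transport"].append(
                    force_rate_sparc(force, dt, config.sparc_max_freq,
                                     config.sparc_amp_threshold))
            elif seg.phase == "return":
                per_metric["log_jerk_return"].append(
                    log_dimensionless_jerk(pos, dt))
                per_metric["sparc_return"].append(
                    spectral_arc_length(speed_profile(pos, dt), dt,
                                        config.sparc_max_freq,
                                        config.sparc_amp_threshold))
                per_metric["path_length_ratio_return"].append(
                    path_length_ratio(pos))
                per_metric["velocity_max_return"].append(velocity_max(pos, dt))
            elif seg.phase == "peg_approach":
                per_metric["jerk_peg_approach"].append(rms_jerk(pos, dt))
            elif seg.phase == "hole_approach":
                per_metric["force_rate_sparc_hole_approach"].append(
                    force_rate_sparc(force, dt, config.sparc_max_freq,
                                     config.sparc_amp_threshold))
        except DegenerateSegmentError:
            continue  # a single degenerate movement should not void the trial

    n_transport = len(per_metric["log_jerk_transport"])
    if n_transport < config.min_valid_movements:
        raise InsufficientDataError(
            f"{n_transport} valid transport movements; "
            f"need {config.min_valid_movements}")
    values = {}
    for m in METRIC_NAMES:
        if not per_metric[m]:
            raise InsufficientDataError(f"no valid movements for metric {m}")
        values[m] = float(config.aggregator(per_metric[m]))
    return pd.Series(values, index=list(METRIC_NAMES), name="raw")


# --------------------------------------------------------------------------
# confound adjustment and normalization


def adjust_confounds(raw: pd.Series, covariates: dict,
                     reference: ReferencePopulation) -> pd.Series:
    """Remove the reference-fitted linear covariate contribution per metric.

    The subtraction is centred on the reference covariate means, so a
    subject with average covariates is returned unchanged. Covariates
    outside the reference age range trigger a warning but are extrapolated.
    """
    missing = [c for c in CONFOUND_COVARIATES if c not in covariates]
    if missing:
        raise ParameterError(f"missing covariates {missing}")
    lo, hi = reference.age_range
    if not lo <= covariates["age"] <= hi:
        warnings.warn(
            f"age {covariates['age']} outside reference support [{lo}, {hi}]; "
            "extrapolating the confound model", stacklevel=2)
    delta = pd.Series(
        {c: float(covariates[c]) - float(reference.covariate_means[c])
         for c in CONFOUND_COVARIATES})
    contribution = reference.confound_coefs[list(CONFOUND_COVARIATES)] @ delta
    return (raw - contribution.reindex(raw.index)).rename("adjusted")


def normalize_metrics(adjusted: pd.Series,
                      reference: ReferencePopulation) -> pd.Series:
    """Map metrics to the unbounded % scale (0 % healthy median, 100 % worst).

    Each metric is first oriented by its worse-direction, then affinely
    scaled by the healthy-median/worst-impaired anchor span. Values better
    than the healthy median come out negative.
    """
    out = {}
    for m in adjusted.index:
        d = float(reference.worse_direction[m])
        span = d * (reference.worst_impaired[m] - reference.healthy_median[m])
        if span <= 0:
            raise ParameterError(
                f"metric {m}: worst-impaired anchor not worse than healthy median")
        out[m] = 100.0 * d * (adjusted[m] - reference.healthy_median[m]) / span
    return pd.Series(out, index=adjusted.index, name="normalized_pct")
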