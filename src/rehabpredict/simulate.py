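"""Synthetic substitutes for everything the source cohort does not contain.

Three generators:

* :func:`gen_trial` — peg-insertion trial signals built from minimum-jerk
  point-to-point movements with controllable impairment knobs (tremor,
  path curvature, grip-force oscillation) and exactly planted grasp/release
  force events, returned together with the ground-truth phase boundaries;
* :func:`gen_reference_population` — a healthy/impaired reference sample of
  metric vectors with planted linear age/sex effects, packaged as the
  :class:`~rehabpredict.metrics.ReferencePopulation` used for confound
  adjustment and 0 %/100 % normalization;
* :func:`gen_cohort` — clinical cohorts with covariate distributions
  mimicking the study sample and a logistic responder model, whose pre/post
  scores are constructed so that SRD labeling reproduces the drawn
  responder status exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, ParticipantRecord
from .errors import ParameterError
from .labeling import SCALES, DEFAULT_SRD
from .metrics import (
    METRIC_NAMES,
    WORSE_DIRECTION,
    BoardGeometry,
    PhaseSegment,
    ReferencePopulation,
    TrialRecording,
)


def default_board() -> BoardGeometry:
    """A 3x3 peg grid on the left half of the workspace, holes mirrored right."""
    xs = (-120.0, -90.0, -60.0)
    ys = (-40.0, 0.0, 40.0)
    pegs = np.array([(x, y, 0.0) for y in ys for x in xs])
    holes = pegs * np.array([-1.0, 1.0, 1.0])
    return BoardGeometry(pegs=pegs, holes=holes)


def _min_jerk(start: np.ndarray, end: np.ndarray, n: int) -> np.ndarray:
    """Minimum-jerk point-to-point trajectory over n samples (inclusive ends)."""
    tau = np.linspace(0.0, 1.0, n)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return start[None, :] + s[:, None] * (end - start)[None, :]


@dataclass(frozen=True)
class TrialGenParams:
    """Knobs of the trial generator; all amplitudes are >= 0.

    Impairment knobs default to zero (an unimpaired trial); observation
    noise defaults to a small, realistic jitter that leaves force-threshold
    events within a sample or two of their planted positions.
    """

    sampling_rate: float = 100.0
    n_repetitions: int = 1
    move_duration: float = 1.0        # s, return / approach movements
    transport_duration: float = 1.2   # s, peg-to-hole movement
    dwell_duration: float = 0.3       # s, stationary grasp/release dwells
    force_peak: float = 6.0           # N, grip plateau during transport
    tremor_amplitude: float = 0.0     # mm
    tremor_freq: float = 4.0          # Hz, intention-tremor band
    curvature_gain: float = 0.0       # dimensionless transverse bow
    force_osc_amplitude: float = 0.0  # N, on the transport plateau
    force_osc_freq: float = 6.0       # Hz
    position_noise_sd: float = 0.2    # mm
    force_noise_sd: float = 0.02      # N
    seed: int | None = None
    board: BoardGeometry = field(default_factory=default_board)

    def __post_init__(self) -> None:
        for name in ("tremor_amplitude", "curvature_gain", "force_osc_amplitude",
                     "position_noise_sd", "force_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.sampling_rate <= 0 or self.n_repetitions < 1:
            raise ParameterError("sampling_rate and n_repetitions must be positive")
        if self.force_peak <= 2.5:
            raise ParameterError("force_peak must exceed the 2 N threshold margin")
        if self.force_osc_amplitude >= self.force_peak - 2.5:
            raise ParameterError(
                "force oscillation would push the plateau through the threshold")


def gen_trial(params: TrialGenParams = TrialGenParams()
              ) -> tuple[TrialRecording, list[PhaseSegment]]:
    """Simulate one trial; returns the recording and ground-truth segments.

    The grip force equals exactly 2 N at each planted grasp sample (rising)
    and release sample (falling), so detected transport boundaries are
    [grasp, release + 1) by construction. Ground truth is returned for the
    transport and return phases of every peg cycle.
    """
    fs = params.sampling_rate
    rng = np.random.default_rng(params.seed)
    board = params.board
    m = int(round(params.move_duration * fs))
    T = int(round(params.transport_duration * fs))
    d = max(int(round(params.dwell_duration * fs)), 4)
    half_d = d // 2
    lead = d

    pos_chunks: list[np.ndarray] = []
    rest = np.array([0.0, 0.0, 60.0])
    events: list[tuple[int, int, int]] = []   # (grasp_idx, release_idx, peg_index)
    cursor = 0

    def _append(chunk: np.ndarray) -> None:
        nonlocal cursor
        pos_chunks.append(chunk)
        cursor += len(chunk)

    _append(np.repeat(rest[None, :], lead, axis=0))
    current = rest
    for rep in range(params.n_repetitions):
        for k in range(9):
            peg, hole = board.pegs[k], board.holes[k]
            _append(_min_jerk(current, peg, m + 1)[1:])     # approach movement
            _append(np.repeat(peg[None, :], d, axis=0))     # grasp dwell
            grasp = cursor                                   # f == 2 N here, rising
            transport = _min_jerk(peg, hole, T + 1)[1:]
            if params.curvature_gain > 0:
                direction = hole - peg
                L = np.linalg.norm(direction)
                perp = np.cross(direction / L, np.array([0.0, 0.0, 1.0]))
                tau = np.linspace(0.0, 1.0, T + 1)[1:]
                transport = transport + (
                    params.curvature_gain * L * np.sin(np.pi * tau))[:, None] * perp
            _append(transport)
            _append(np.repeat(hole[None, :], d, axis=0))    # release dwell
            release = cursor - d + half_d                    # f == 2 N here, falling
            events.append((grasp, release, k + 1))
            current = hole
    _append(_min_jerk(current, rest, m + 1)[1:])
    _append(np.repeat(rest[None, :], lead, axis=0))

    pos = np.concatenate(pos_chunks, axis=0)
    n = len(pos)
    t = np.arange(n) / fs

    # grip force: linear through the exactly-2 N event knots (so threshold
    # crossings are steep and land on planted samples), with slope-matched
    # cubic-Hermite eases up to / down from the plateau so the clean force
    # rate is a smooth, narrowband bump rather than a train of corners
    def _hermite(f0: float, f1: float, m0: float, m1: float,
                 n_seg: int) -> np.ndarray:
        u = np.linspace(0.0, 1.0, n_seg + 1)
        h00 = 2 * u**3 - 3 * u**2 + 1
        h10 = u**3 - 2 * u**2 + u
        h01 = -2 * u**3 + 3 * u**2
        h11 = u**3 - u**2
        return f0 * h00 + m0 * h10 + f1 * h01 + m1 * h11

    force = np.zeros(n)
    for grasp, release, _k in events:
        T_seg = release - grasp
        rise = max(int(round(0.3 * T_seg)), 2)
        plateau_lo, plateau_hi = grasp + rise, release - rise
        ramp_up_start = grasp - d
        zero_at = release + half_d
        idx = np.arange(ramp_up_start, grasp + 1)
        force[idx] = 2.0 * (idx - ramp_up_start) / d      # crosses 2 N at grasp
        slope = 2.0 / d                                   # N per sample
        force[grasp:plateau_lo + 1] = _hermite(
            2.0, params.force_peak, slope * rise, 0.0, rise)
        force[plateau_lo:plateau_hi] = params.force_peak
        slope = 2.0 / half_d
        force[plateau_hi:release + 1] = _hermite(
            params.force_peak, 2.0, 0.0, -slope * rise, release - plateau_hi)
        if params.force_osc_amplitude > 0:
            seg = np.arange(grasp, release)
            env = np.sin(np.pi * (seg - grasp) / T_seg) ** 2
            force[seg] += params.force_osc_amplitude * env * np.sin(
                2 * np.pi * params.force_osc_freq * t[seg])
        idx = np.arange(release, min(zero_at, n - 1) + 1)
        force[idx] = np.clip(2.0 * (1.0 - (idx - release) / half_d), 0.0, None)

    if params.tremor_amplitude > 0:
        tremor_dir = np.array([0.0, 0.6, 0.8])
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * params.tremor_freq * t + phase)
        pos = pos + params.tremor_amplitude * wave[:, None] * tremor_dir

    if params.position_noise_sd > 0:
        pos = pos + rng.normal(0.0, params.position_noise_sd, size=pos.shape)
    if params.force_noise_sd > 0:
        force = np.clip(force + rng.normal(0.0, params.force_noise_sd, size=n),
                        0.0, None)

    trial = TrialRecording(time=t, position=pos, grip_force=force, board=board,
                           n_repetitions=params.n_repetitions)
    truth: list[PhaseSegment] = []
    for i, (grasp, release, k) in enumerate(events):
        truth.append(PhaseSegment("transport", grasp, release + 1, k))
        ret_end = events[i + 1][0] if i + 1 < len(events) else n
        truth.append(PhaseSegment("return", release + 1, ret_end, k))
    return trial, truth


# --------------------------------------------------------------------------
# reference population

#: Healthy central values used by the parametric reference generator:
#: medians of a calibration run of the unimpaired trial generator (default
#: knobs, 24 seeds), so that unimpaired trials land near the healthy centre.
_HEALTHY_BASE = pd.Series(
    {
        "log_jerk_transport": 10.07,
        "log_jerk_return": 10.50,
        "sparc_return": -1.40,
        "path_length_ratio_transport": 1.006,
        "path_length_ratio_return": 1.013,
        "velocity_max_return": 345.0,
        "jerk_peg_approach": 12500.0,
        "force_rate_num_peaks_transport": 2.0,
        "force_rate_sparc_transport": -4.9,
        "force_rate_sparc_hole_approach": -1.79,
    }
)

#: Healthy between-subject spread per metric (same units as the base values);
#: deliberately wider than the within-generator trial-to-trial variation.
_HEALTHY_SPREAD = pd.Series(
    {
        "log_jerk_transport": 0.5,
        "log_jerk_return": 0.5,
        "sparc_return": 0.08,
        "path_length_ratio_transport": 0.02,
        "path_length_ratio_return": 0.02,
        "velocity_max_return": 30.0,
        "jerk_peg_approach": 2500.0,
        "force_rate_num_peaks_transport": 1.5,
        "force_rate_sparc_transport": 1.0,
        "force_rate_sparc_hole_approach": 0.15,
    }
)


def gen_reference_population(n_healthy: int = 120,
                             n_impaired: int = 30,
                             age_slope_per_decade: float = 2.0,
                             sex_effect: float = 1.0,
                             impairment_range: tuple[float, float] = (1.0, 4.0),
                             seed: int | None = None
                             ) -> tuple[ReferencePopulation, pd.DataFrame]:
    """Parametric healthy/impaired reference sample of metric vectors.

    Each healthy subject's metric value is the healthy base plus planted
    linear age and sex effects plus unit-spread noise. Effect magnitudes
    are in units of the metric's healthy spread (signs drawn per metric);
    the defaults make the planted slopes well identified at n = 120
    (|slope| / standard error of roughly 35). Impaired subjects are shifted
    in the worse direction by a uniform multiple of the spread; the worst
    of them anchors 100 %. Returns the fitted
    :class:`ReferencePopulation` and the per-subject metric table, with the
    planted effects recorded in ``table.attrs``.
    """
    if n_healthy < 10:
        raise ParameterError("n_healthy must be at least 10")
    if n_impaired < 1:
        raise ParameterError("n_impaired must be at least 1")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(20.0, 80.0, size=n_healthy + n_impaired)
    sexes = rng.integers(0, 2, size=n_healthy + n_impaired)
    dominant = rng.integers(0, 2, size=n_healthy + n_impaired)
    stereo = (rng.random(n_healthy + n_impaired) < 0.1).astype(int)
    healthy = np.arange(n_healthy + n_impaired) < n_healthy

    age_slopes = {}
    sex_effects = {}
    table = pd.DataFrame({
        "subject_id": [f"REF{i:03d}" for i in range(n_healthy + n_impaired)],
        "group": np.where(healthy, "healthy", "impaired"),
        "age": ages, "sex": sexes,
        "dominant_hand_tested": dominant, "stereo_vision_deficit": stereo,
    })
    for m in METRIC_NAMES:
        spread = _HEALTHY_SPREAD[m]
        slope = rng.choice([-1.0, 1.0]) * age_slope_per_decade * spread / 10.0
        sex_eff = rng.choice([-1.0, 1.0]) * sex_effect * spread
        age_slopes[m], sex_effects[m] = slope, sex_eff
        vals = (_HEALTHY_BASE[m]
                + slope * (ages - 50.0)
                + sex_eff * sexes
                + rng.normal(0.0, spread, size=len(ages)))
        shift = rng.uniform(*impairment_range, size=len(ages)) * spread
        vals = np.where(healthy, vals, vals + WORSE_DIRECTION[m] * shift)
        table[m] = vals

    table.attrs["planted_age_slopes"] = age_slopes
    table.attrs["planted_sex_effects"] = sex_effects

    h = table[table["group"] == "healthy"]
    X = np.column_stack([
        np.ones(len(h)), h["age"], h["sex"],
        h["dominant_hand_tested"], h["stereo_vision_deficit"]])
    coefs = {}
    for m in METRIC_NAMES:
        beta, *_ = np.linalg.lstsq(X, h[m].to_numpy(), rcond=None)
        coefs[m] = beta[1:]
    confound_coefs = pd.DataFrame(
        coefs, index=["age", "sex", "dominant_hand_tested",
                      "stereo_vision_deficit"]).T

    imp = table[table["group"] == "impaired"]
    worst = pd.Series({
        m: float(imp[m].max() if WORSE_DIRECTION[m] > 0 else imp[m].min())
        for m in METRIC_NAMES})
    reference = ReferencePopulation(
        healthy_median=h[list(METRIC_NAMES)].median(),
        worst_impaired=worst,
        confound_coefs=confound_coefs,
        covariate_means=h[["age", "sex", "dominant_hand_tested",
                           "stereo_vision_deficit"]].mean(),
        age_range=(float(h["age"].min()), float(h["age"].max())),
    )
    return reference, table


# --------------------------------------------------------------------------
# cohorts with planted predictor-outcome structure


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic responder model: P(responder) = sigmoid(intercept + coefs.x).

    Feature names refer to the standardized generator covariates
    ``age_z``, ``chronicity_z``, ``sex`` (0/1), ``ms_PP``, ``ms_SP``.
    An empty coefficient dict with zero intercept is the exact null model
    (responder probability 1/2 for every dataset).
    """

    intercept: float = 0.0
    coefs: dict = field(default_factory=dict)


#: Planted master-data effect used by signal-recovery checks. The logistic
#: coefficient 10 on standardized age gives a Bayes accuracy of 0.945
#: (closed-form integral over the age distribution), above the 0.9 floor
#: the recovery tests assume.
STRONG_AGE_EFFECT = OutcomeModel(intercept=0.0, coefs={"age_z": 10.0})


@dataclass(frozen=True)
class CohortGenParams:
    """Cohort generator conditions; defaults mimic the study sample."""

    n_participants: int = 11
    sides_per_participant: int = 2
    age_mean: float = 56.7
    age_sd: float = 14.8
    chronicity_mean: float = 18.0
    chronicity_sd: float = 12.0
    p_female: float = 7 / 11
    ms_type_probs: tuple[float, float, float] = (6 / 11, 3 / 11, 2 / 11)  # RR, PP, SP
    group_probs: tuple[float, float, float] = (5 / 11, 5 / 11, 1 / 11)
    responder_margin: float = 0.5     # post-change overshoot, in SRD units
    outcome_models: dict = field(
        default_factory=lambda: {s: OutcomeModel() for s in SCALES})
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ParameterError("need at least 2 participants")
        if self.sides_per_participant not in (1, 2):
            raise ParameterError("sides_per_participant must be 1 or 2")
        if not 0 < self.responder_margin:
            raise ParameterError("responder_margin must be positive")


def bayes_accuracy(model: OutcomeModel, n_mc: int = 200_000,
                   seed: int = 0) -> float:
    """Monte-Carlo Bayes accuracy of an outcome model over the covariates."""
    rng = np.random.default_rng(seed)
    ms = rng.choice(3, size=n_mc, p=[6 / 11, 3 / 11, 2 / 11])
    feats = {
        "age_z": rng.normal(size=n_mc),
        "chronicity_z": rng.normal(size=n_mc),
        "sex": rng.integers(0, 2, size=n_mc).astype(float),
        "ms_PP": (ms == 1).astype(float),
        "ms_SP": (ms == 2).astype(float),
    }
    eta = model.intercept + sum(
        b * feats.get(name, 0.0) for name, b in model.coefs.items())
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(np.mean(np.maximum(p, 1.0 - p)))


def gen_cohort(params: CohortGenParams = CohortGenParams()
               ) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a cohort plus the responder status its scores encode.

    Responder datasets change by (1 + margin) x SRD in the improving
    direction; non-responders change by strictly less than one SRD either
    way, so SRD labeling reproduces the drawn status exactly.
    """
    rng = np.random.default_rng(params.seed)
    records: list[ParticipantRecord] = []
    label_rows: list[dict] = []
    srd = DEFAULT_SRD
    arat_jump = int(np.ceil((1 + params.responder_margin) * srd.arat))

    for i in range(params.n_participants):
        pid = f"S{i + 1:03d}"
        age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 20, 90))
        chron = float(np.clip(
            rng.normal(params.chronicity_mean, params.chronicity_sd), 0, 45))
        sex = "F" if rng.random() < params.p_female else "M"
        ms = rng.choice(["RR", "PP", "SP"], p=params.ms_type_probs)
        group = int(rng.choice([1, 2, 3], p=params.group_probs))
        edss = float(np.clip(np.round(rng.normal(6.0, 1.3) * 2) / 2, 0, 10))
        feats = {
            "age_z": (age - params.age_mean) / params.age_sd,
            "chronicity_z": (chron - params.chronicity_mean) / params.chronicity_sd,
            "sex": 1.0 if sex == "M" else 0.0,
            "ms_PP": 1.0 if ms == "PP" else 0.0,
            "ms_SP": 1.0 if ms == "SP" else 0.0,
        }
        sides = ("left", "right")[: params.sides_per_participant]
        for side in sides:
            scores: dict = {}
            labels = {"participant_id": pid, "side": side}
            for scale in SCALES:
                model = params.outcome_models[scale]
                eta = model.intercept + sum(
                    b * feats[name] for name, b in model.coefs.items())
                responder = bool(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
                labels[f"{scale}_responder"] = responder
                if scale == "arat":
                    pre = int(rng.integers(20, 57 - arat_jump))
                    post = pre + arat_jump if responder else int(
                        np.clip(pre + rng.integers(-5, 6), 0, 57))
                elif scale == "bbt":
                    pre = round(float(np.clip(rng.normal(40, 10), 5, 75)), 1)
                    delta = ((1 + params.responder_margin) * srd.bbt if responder
                             else rng.uniform(-0.9, 0.9) * srd.bbt)
                    post = round(max(pre + delta, 0.0), 1)
                else:  # nhpt: improvement = pre - post
                    pre = round(float(np.clip(rng.lognormal(np.log(35), 0.4),
                                              15, 200)), 2)
                    delta = ((1 + params.responder_margin) * srd.nhpt if responder
                             else rng.uniform(-0.9, 0.9) * srd.nhpt)
                    post = round(max(pre - delta, 1.0), 2)
                scores[f"{scale}_pre"], scores[f"{scale}_post"] = pre, post
            records.append(ParticipantRecord(
                participant_id=pid, side=side, age=age, sex=sex, ms_type=ms,
                chronicity=chron, intervention_group=group, edss=edss,
                disability_group=float(edss >= 6.0),
                motricity=float(np.clip(rng.normal(70, 15), 0, 100)),
                static_fatigue_index=float(np.clip(rng.normal(40, 20), 0, 100)),
                monofilament_index=float(np.clip(np.round(rng.normal(5, 2)), 2, 12)),
                sdmt=float(np.clip(np.round(rng.normal(40, 10)), 0, 110)),
                fahn_tremor=float(np.clip(np.round(rng.normal(2, 1.5)), 0, 6)),
                **scores))
            label_rows.append(labels)

    cohort = Cohort(records, provenance=f"synthetic cohort (seed={params.seed})")
    truth = pd.DataFrame(
        label_rows, index=pd.Index(cohort.dataset_ids, name="dataset_id"))
    return cohort, truth
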