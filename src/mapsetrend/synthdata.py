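"""Synthetic annulus tracks, surgical cohorts and multi-observer wall-motion ratings.

Everything downstream of the (unavailable) patient recordings is exercised
against data from this module, which therefore carries explicit ground truth.
All randomness flows from a single integer seed through
``numpy.random.SeedSequence.spawn`` so that independent aspects of a dataset
(noise, dropouts, ratings, ...) draw from independent, reproducible streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .extraction import AnnulusTrack
from .vocab import OBSERVERS, TIMEPOINTS, WALLS

# Calibration defaults: baseline per-wall automated MAPSE levels (mm), their
# spreads, per-wall baseline-to-ICU declines, and the manual global level and
# decline the generator is steered towards.
DEFAULT_WALL_PRE_MEAN = {"anterior": 8.7, "inferior": 11.2, "lateral": 11.3, "septal": 8.1}
DEFAULT_WALL_PRE_SD = {"anterior": 2.7, "inferior": 2.9, "lateral": 3.0, "septal": 2.0}
DEFAULT_WALL_DECLINE = {"anterior": -2.0, "inferior": -3.6, "lateral": -3.1, "septal": -1.8}
DEFAULT_MANUAL_GLOBAL_PRE_MEAN = 11.1
DEFAULT_MANUAL_GLOBAL_DECLINE = -3.5


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class TrackConfig:
    """Parameters of a synthetic annulus track.

    The longitudinal position is ``baseline_depth_mm + true_mapse_mm * s(t)``
    plus frame noise, where ``s`` is a smooth single-peaked waveform that is 0
    exactly at each R-wave and 1 at its within-cycle peak.  With the probe
    behind the left atrium the annulus moves *away* from it in systole, so the
    position increases from ED to ES.
    """

    heart_rate_bpm: float = 60.0
    fps: float = 50.0
    duration_s: float = 10.0
    true_mapse_mm: float = 10.0
    baseline_depth_mm: float = 80.0
    noise_sd_mm: float = 0.0
    dropout_prob: float = 0.0
    outlier_prob: float = 0.0
    outlier_mm: float = 8.0
    systolic_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ConfigurationError("fps must be > 0")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.heart_rate_bpm <= 0:
            raise ConfigurationError("heart_rate_bpm must be > 0")
        if self.true_mapse_mm < 0:
            raise ConfigurationError("true_mapse_mm must be >= 0")
        if self.noise_sd_mm < 0:
            raise ConfigurationError("noise_sd_mm must be >= 0")
        if not (0.0 < self.systolic_fraction < 1.0):
            raise ConfigurationError("systolic_fraction must be in (0, 1)")
        _check_prob("dropout_prob", self.dropout_prob)
        _check_prob("outlier_prob", self.outlier_prob)


def excursion_waveform(phase: np.ndarray, systolic_fraction: float = 0.35) -> np.ndarray:
    """Normalized systolic excursion at cycle phase in [0, 1).

    Raised-cosine upstroke from 0 at the R-wave to 1 at ``systolic_fraction``
    of the R-R interval, then a raised-cosine return to 0 at the next R-wave.
    """
    phase = np.asarray(phase, dtype=float)
    f = systolic_fraction
    up = 0.5 * (1.0 - np.cos(np.pi * phase / f))
    down = 0.5 * (1.0 + np.cos(np.pi * (phase - f) / (1.0 - f)))
    return np.where(phase < f, up, down)


def generate_annulus_track(cfg: TrackConfig) -> AnnulusTrack:
    """Generate one synthetic annulus track from a :class:`TrackConfig`.

    R-waves are placed at multiples of the R-R interval starting at t=0.
    Dropped frames are flagged undetected (position NaN); outlier frames are
    displaced by ``outlier_mm`` as single-frame spikes.
    """
    n_frames = int(round(cfg.fps * cfg.duration_s))
    times = np.arange(n_frames) / cfg.fps
    rr = 60.0 / cfg.heart_rate_bpm
    r_wave_times = np.arange(0.0, cfg.duration_s + 0.5 / cfg.fps, rr)

    phase = (times % rr) / rr
    pos = cfg.baseline_depth_mm + cfg.true_mapse_mm * excursion_waveform(phase, cfg.systolic_fraction)

    noise_rng, dropout_rng, outlier_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(3)
    )
    if cfg.noise_sd_mm > 0:
        pos = pos + noise_rng.normal(0.0, cfg.noise_sd_mm, size=n_frames)
    detected = dropout_rng.random(n_frames) >= cfg.dropout_prob
    outliers = detected & (outlier_rng.random(n_frames) < cfg.outlier_prob)
    pos = np.where(outliers, pos + cfg.outlier_mm, pos)
    pos = np.where(detected, pos, np.nan)

    return AnnulusTrack(times=times, long_pos_mm=pos, detected=detected, r_wave_times=r_wave_times, fps=cfg.fps)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic two-timepoint surgical cohort.

    Wall-level truth is drawn per patient at baseline and declined towards the
    postoperative timepoint; automatic and manual measurements share that
    truth plus independent method noise.  Manual measurements additionally
    carry a timepoint-specific calibration offset chosen so that the cohort's
    manual *global* level and decline match their configured targets even
    though the wall truths are calibrated on the automated scale (the two
    methods do not read identically in practice).  ``decline_shared_weight``
    is the fraction of decline variance shared across a patient's four walls;
    it is unconstrained by any published value.
    """

    n_patients: int = 49
    wall_pre_mean_mm: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WALL_PRE_MEAN))
    wall_pre_sd_mm: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WALL_PRE_SD))
    wall_decline_mm: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WALL_DECLINE))
    decline_sd_mm: float = 1.5
    decline_shared_weight: float = 0.5
    manual_global_pre_mean_mm: float = DEFAULT_MANUAL_GLOBAL_PRE_MEAN
    manual_global_decline_mm: float = DEFAULT_MANUAL_GLOBAL_DECLINE
    noise_sd_auto_mm: float = 0.9
    noise_sd_manual_mm: float = 0.9
    missing_prob_auto: float = 0.0
    missing_prob_manual: float = 0.0
    rwma_prevalence: float = 0.0
    rwma_dynamic_prob: float = 0.0
    rwma_mapse_penalty_mm: float = 2.0
    rater_agreement: float = 1.0
    indeterminate_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for w in WALLS:
            if w not in self.wall_pre_mean_mm or w not in self.wall_pre_sd_mm or w not in self.wall_decline_mm:
                raise ConfigurationError(f"wall parameter maps must cover wall {w!r}")
            if self.wall_pre_sd_mm[w] < 0:
                raise ConfigurationError("wall_pre_sd_mm values must be >= 0")
        for name in ("decline_sd_mm", "noise_sd_auto_mm", "noise_sd_manual_mm"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in (
            "missing_prob_auto", "missing_prob_manual", "rwma_prevalence",
            "rwma_dynamic_prob", "rater_agreement", "indeterminate_prob", "decline_shared_weight",
        ):
            _check_prob(name, getattr(self, name))

    @property
    def manual_offset_pre_mm(self) -> float:
        """Manual-vs-automated calibration offset at baseline."""
        return self.manual_global_pre_mean_mm - float(np.mean([self.wall_pre_mean_mm[w] for w in WALLS]))

    @property
    def manual_offset_icu_mm(self) -> float:
        """Manual calibration offset postoperatively (steers the global decline)."""
        mean_decline = float(np.mean([self.wall_decline_mm[w] for w in WALLS]))
        return self.manual_offset_pre_mm + (self.manual_global_decline_mm - mean_decline)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew: the quantity every estimate is checked against.

    ``walls`` has one row per (patient_id, wall, timepoint) with the true wall
    MAPSE (mm) and the true RWMA state; ``globals`` has one row per
    (patient_id, timepoint) with the true global MAPSE on both method scales
    and, at the ICU timepoint, the signs of the true changes.
    """

    walls: pd.DataFrame
    globals: pd.DataFrame
    config: CohortConfig


def _rating_for(truth: str, agreement: float, indeterminate_prob: float, rng: np.random.Generator) -> str:
    """One observer's rating of a wall whose true state is present/absent."""
    if rng.random() < indeterminate_prob:
        return "indeterminate"
    if rng.random() < agreement:
        return truth
    return "absent" if truth == "present" else "present"


def generate_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (measurement table, rating table, ground truth) for one cohort.

    The measurement table is long-format with columns
    ``patient_id, timepoint, wall, method, mapse_mm, n_cycles``; masked-missing
    rows are simply absent.  The rating table has one row per
    (patient, timepoint, wall, observer).
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    level_rng, decline_rng, rwma_rng, noise_rng, rating_rng, missing_rng = (
        np.random.default_rng(s) for s in streams
    )

    patient_ids = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    w_shared = np.sqrt(cfg.decline_shared_weight)
    w_indiv = np.sqrt(1.0 - cfg.decline_shared_weight)

    truth_rows: list[dict] = []
    meas_rows: list[dict] = []
    rating_rows: list[dict] = []
    global_rows: list[dict] = []

    for pid in patient_ids:
        z_shared = decline_rng.normal()
        pre: dict[str, float] = {}
        decline: dict[str, float] = {}
        rwma_pre: dict[str, bool] = {}
        rwma_icu: dict[str, bool] = {}
        for w in WALLS:
            pre[w] = cfg.wall_pre_mean_mm[w] + cfg.wall_pre_sd_mm[w] * level_rng.normal()
            z = w_shared * z_shared + w_indiv * decline_rng.normal()
            decline[w] = cfg.wall_decline_mm[w] + cfg.decline_sd_mm * z
            state = rwma_rng.random() < cfg.rwma_prevalence
            rwma_pre[w] = bool(state)
            rwma_icu[w] = bool(state ^ (rwma_rng.random() < cfg.rwma_dynamic_prob))

        for tp in TIMEPOINTS:
            wall_truth: dict[str, float] = {}
            for w in WALLS:
                base = pre[w] if tp == "pre_cpb" else pre[w] + decline[w]
                has_rwma = rwma_pre[w] if tp == "pre_cpb" else rwma_icu[w]
                truth = base - (cfg.rwma_mapse_penalty_mm if has_rwma else 0.0)
                wall_truth[w] = truth
                truth_rows.append(
                    {"patient_id": pid, "wall": w, "timepoint": tp,
                     "true_mapse_mm": truth, "rwma": has_rwma}
                )
                # measurements: auto then manual, independent noise
                manual_offset = cfg.manual_offset_pre_mm if tp == "pre_cpb" else cfg.manual_offset_icu_mm
                for method, sd, off, miss_p in (
                    ("auto", cfg.noise_sd_auto_mm, 0.0, cfg.missing_prob_auto),
                    ("manual", cfg.noise_sd_manual_mm, manual_offset, cfg.missing_prob_manual),
                ):
                    value = truth + off + (noise_rng.normal(0.0, sd) if sd > 0 else 0.0)
                    missing = missing_rng.random() < miss_p
                    if missing:
                        continue
                    if tp == "pre_cpb":
                        n_cycles = int(missing_rng.integers(3, 6))
                    else:
                        n_cycles = int(missing_rng.integers(5, 11))
                    meas_rows.append(
                        {"patient_id": pid, "timepoint": tp, "wall": w, "method": method,
                         "mapse_mm": value, "n_cycles": n_cycles}
                    )
                # three observers rate the wall
                truth_label = "present" if has_rwma else "absent"
                for obs in OBSERVERS:
                    rating_rows.append(
                        {"patient_id": pid, "timepoint": tp, "wall": w, "observer": obs,
                         "rating": _rating_for(truth_label, cfg.rater_agreement, cfg.indeterminate_prob, rating_rng)}
                    )
            true_global = float(np.mean([wall_truth[w] for w in WALLS]))
            manual_offset = cfg.manual_offset_pre_mm if tp == "pre_cpb" else cfg.manual_offset_icu_mm
            global_rows.append(
                {"patient_id": pid, "timepoint": tp,
                 "true_global_mapse_mm": true_global,
                 "true_global_manual_mm": true_global + manual_offset}
            )

    measurements = pd.DataFrame(meas_rows)
    ratings = pd.DataFrame(rating_rows)
    truth_walls = pd.DataFrame(truth_rows)
    truth_globals = pd.DataFrame(global_rows)

    # per-patient true change signs (manual-scale global change)
    g = truth_globals.pivot(index="patient_id", columns="timepoint", values="true_global_manual_mm")
    signs = np.sign(g["icu"] - g["pre_cpb"]).rename("true_global_change_sign")
    truth_globals = truth_globals.merge(signs.reset_index(), on="patient_id")

    return measurements, ratings, GroundTruth(walls=truth_walls, globals=truth_globals, config=cfg)


def generate_paired_changes(
    n_pairs: int,
    concordance_prob: float,
    lsc_mm: float = 1.8,
    seed: int = 0,
    walls: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Paired changes with a known probability of sign agreement.

    Every pair lies outside the exclusion zone (|delta| >= lsc on both axes),
    so the retained-pair concordance rate is an unbiased estimate of
    ``concordance_prob``.  Used by statistical-recovery tests.
    """
    _check_prob("concordance_prob", concordance_prob)
    if n_pairs < 1:
        raise ConfigurationError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    ref_sign = rng.choice([-1.0, 1.0], size=n_pairs)
    concordant = rng.random(n_pairs) < concordance_prob
    auto_sign = np.where(concordant, ref_sign, -ref_sign)
    ref_mag = lsc_mm + rng.exponential(1.0, size=n_pairs)
    auto_mag = lsc_mm + rng.exponential(1.0, size=n_pairs)
    wall_cycle = (walls or list(WALLS)) if walls != [] else list(WALLS)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n_pairs)],
            "wall": [wall_cycle[i % len(wall_cycle)] for i in range(n_pairs)],
            "delta_auto_mm": auto_sign * auto_mag,
            "delta_ref_mm": ref_sign * ref_mag,
        }
    )
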