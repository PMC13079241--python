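"""Annulus-track post-processing: cycle segmentation, quality control and aggregation.

The automated method receives a per-frame longitudinal annulus position
(distance from the transducer; smaller means closer to the probe) together
with ECG R-wave times.  Each consecutive R-wave pair delimits one candidate
cardiac cycle.  End-diastole (ED) is the detected frame closest to the probe
within a short window around the opening R-wave; end-systole (ES) is the
detected frame farthest from the probe before the next ED.  Per-cycle MAPSE
is the ES-to-ED longitudinal distance.  A cycle is rejected when adjacent
detected frames move more than ``max_jump_mm``, when the detected fraction of
frames falls below ``min_detection_fraction``, or when the cycle's
closest-to-probe point does not sit where ED is defined to be.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, ContractError, UndefinedRateError

logger = logging.getLogger(__name__)

QcStatus = Literal["accepted", "rejected"]
QcReason = Literal["none", "jump", "detection", "ed_anchor"]


@dataclass(frozen=True)
class AnnulusTrack:
    """Per-frame longitudinal annulus position with detection flags and R-wave anchors.

    Attributes
    ----------
    times : np.ndarray
        Frame timestamps in seconds, strictly increasing.
    long_pos_mm : np.ndarray
        Longitudinal distance from the transducer per frame (mm); NaN where
        the annulus was not detected.
    detected : np.ndarray
        Boolean detection flag per frame.
    r_wave_times : np.ndarray
        ECG R-wave times in seconds, strictly increasing.
    fps : float
        Acquisition frame rate (frames per second).
    """

    times: np.ndarray
    long_pos_mm: np.ndarray
    detected: np.ndarray
    r_wave_times: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        pos = np.asarray(self.long_pos_mm, dtype=float)
        det = np.asarray(self.detected, dtype=bool)
        rw = np.asarray(self.r_wave_times, dtype=float)
        if times.ndim != 1 or pos.shape != times.shape or det.shape != times.shape:
            raise ConfigurationError("times, long_pos_mm and detected must be 1-D arrays of equal length")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ConfigurationError("frame times must be strictly increasing")
        if rw.size >= 2 and not np.all(np.diff(rw) > 0):
            raise ConfigurationError("r_wave_times must be strictly increasing")
        if np.any(np.isfinite(pos) & ~det):
            raise ConfigurationError("long_pos_mm must be NaN where detected is False")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "long_pos_mm", pos)
        object.__setattr__(self, "detected", det)
        object.__setattr__(self, "r_wave_times", rw)

    @property
    def n_frames(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the post-detection algorithm.

    ``max_jump_mm`` and ``min_detection_fraction`` are the two hard rejection
    thresholds; ``ed_window_s`` is the half-width of the search window around
    the R-wave inside which ED must fall.  Cycle-count caps differ between the
    baseline and postoperative recordings.
    """

    max_jump_mm: float = 5.0
    min_detection_fraction: float = 0.60
    ed_window_s: float = 0.100
    max_cycles_pre: int = 5
    min_cycles_pre_target: int = 3
    max_cycles_icu: int = 10
    min_fps_warn: float = 40.0

    def __post_init__(self) -> None:
        if self.max_jump_mm <= 0:
            raise ConfigurationError("max_jump_mm must be > 0")
        if not (0 < self.min_detection_fraction <= 1):
            raise ConfigurationError("min_detection_fraction must be in (0, 1]")
        if self.ed_window_s <= 0:
            raise ConfigurationError("ed_window_s must be > 0")
        if self.max_cycles_pre < 1 or self.max_cycles_icu < 1:
            raise ConfigurationError("cycle caps must be >= 1")


@dataclass(frozen=True)
class CycleMeasurement:
    """One candidate cardiac cycle with its ED/ES samples and QC verdict."""

    cycle_index: int
    ed_time_s: Optional[float]
    ed_pos_mm: Optional[float]
    es_time_s: Optional[float]
    es_pos_mm: Optional[float]
    mapse_mm: Optional[float]
    qc_status: QcStatus
    qc_reason: QcReason
    # cycle span used for QC bookkeeping (opening R-wave to the next one)
    start_time_s: float = field(default=float("nan"))
    end_time_s: float = field(default=float("nan"))


@dataclass(frozen=True)
class WallMeasurement:
    """Recording-level MAPSE for one (patient, timepoint, wall, method)."""

    patient_id: str
    timepoint: str
    wall: str
    method: str
    mapse_mm: Optional[float]
    n_cycles_used: int
    feasible: bool

    def __post_init__(self) -> None:
        if self.feasible != (self.n_cycles_used >= 1):
            raise ContractError("feasible must hold exactly when n_cycles_used >= 1")


def _frames_in_window(track: AnnulusTrack, center: float, half_width: float) -> np.ndarray:
    """Indices of detected frames within +/- half_width of center."""
    mask = track.detected & (np.abs(track.times - center) <= half_width)
    return np.flatnonzero(mask)


def segment_cycles(track: AnnulusTrack, cfg: ExtractionConfig | None = None) -> list[CycleMeasurement]:
    """Split a track into candidate cycles, one per consecutive R-wave pair.

    ED is the detected frame with minimum longitudinal position (closest to
    the probe) within ``+/- cfg.ed_window_s`` of the cycle's opening R-wave;
    ES is the detected frame with maximum position between that ED and the
    next cycle's ED.  A cycle whose ED window contains no detected frame is
    returned already rejected with reason ``ed_anchor``.

    Returns the candidate list without applying the jump/detection QC rules;
    feed each element to :func:`qc_cycle` for the verdict.
    """
    cfg = cfg or ExtractionConfig()
    if track.fps < cfg.min_fps_warn:
        logger.warning(
            "frame rate %.1f fps is below the recommended floor of %.0f fps", track.fps, cfg.min_fps_warn
        )
    t0, t1 = (track.times[0], track.times[-1]) if track.n_frames else (0.0, 0.0)
    r_waves = track.r_wave_times[(track.r_wave_times >= t0 - cfg.ed_window_s) & (track.r_wave_times <= t1 + cfg.ed_window_s)]
    if r_waves.size < 2:
        logger.warning("fewer than 2 R-waves inside the track span; no cycles segmented")
        return []

    # ED anchor per R-wave (None when no detected frame lies in the window)
    ed_idx: list[Optional[int]] = []
    for r in r_waves:
        cand = _frames_in_window(track, float(r), cfg.ed_window_s)
        ed_idx.append(int(cand[np.argmin(track.long_pos_mm[cand])]) if cand.size else None)

    cycles: list[CycleMeasurement] = []
    for i in range(r_waves.size - 1):
        start, end = float(r_waves[i]), float(r_waves[i + 1])
        if ed_idx[i] is None:
            cycles.append(
                CycleMeasurement(i, None, None, None, None, None, "rejected", "ed_anchor", start, end)
            )
            continue
        ed = ed_idx[i]
        ed_time = float(track.times[ed])
        ed_pos = float(track.long_pos_mm[ed])
        # ES search ends at the next cycle's ED when it exists, else at the closing R-wave
        next_ed = ed_idx[i + 1]
        es_end = float(track.times[next_ed]) if next_ed is not None else end
        es_mask = track.detected & (track.times > ed_time) & (track.times < es_end)
        es_cand = np.flatnonzero(es_mask)
        if es_cand.size == 0:
            # nothing detected between ED and the next ED: nothing to measure
            cycles.append(
                CycleMeasurement(i, ed_time, ed_pos, None, None, None, "rejected", "detection", start, end)
            )
            continue
        es = int(es_cand[np.argmax(track.long_pos_mm[es_cand])])
        es_time = float(track.times[es])
        es_pos = float(track.long_pos_mm[es])
        cycles.append(
            CycleMeasurement(
                i, ed_time, ed_pos, es_time, es_pos, es_pos - ed_pos, "accepted", "none", start, end
            )
        )
    return cycles


def qc_cycle(cycle: CycleMeasurement, track: AnnulusTrack, cfg: ExtractionConfig | None = None) -> CycleMeasurement:
    """Apply the three rejection rules to a candidate cycle.

    In order: reject with reason ``jump`` when any adjacent pair of detected
    frames inside the cycle span differs by more than ``max_jump_mm`` (gaps
    spanning undetected frames do not count — they are punished by the
    detection rule); reject with reason ``detection`` when the detected
    fraction of frames is below ``min_detection_fraction``; reject with
    reason ``ed_anchor`` when the cycle's closest-to-probe point falls
    farther than ``ed_window_s`` from both bounding R-waves.  Otherwise the
    cycle is accepted.
    """
    cfg = cfg or ExtractionConfig()
    if cycle.qc_status == "rejected":
        return cycle

    span = (track.times >= cycle.start_time_s) & (track.times < cycle.end_time_s)
    idx = np.flatnonzero(span)
    det = track.detected[idx]
    pos = track.long_pos_mm[idx]

    # jump rule: adjacent frames, both detected
    if det.size >= 2:
        both = det[:-1] & det[1:]
        jumps = np.abs(np.diff(pos))[both]
        if jumps.size and np.nanmax(jumps) > cfg.max_jump_mm:
            return replace(cycle, qc_status="rejected", qc_reason="jump")

    # detection rule
    if det.size == 0 or det.mean() < cfg.min_detection_fraction:
        return replace(cycle, qc_status="rejected", qc_reason="detection")

    # ED-anchor rule: the minimum (closest to probe) must sit near an R-wave.
    # The closing R-wave is allowed because it anchors the next cycle's ED.
    det_idx = idx[det]
    t_min = float(track.times[det_idx[np.argmin(track.long_pos_mm[det_idx])]])
    near_open = abs(t_min - cycle.start_time_s) <= cfg.ed_window_s
    near_close = abs(t_min - cycle.end_time_s) <= cfg.ed_window_s
    if not (near_open or near_close):
        return replace(cycle, qc_status="rejected", qc_reason="ed_anchor")

    return replace(cycle, qc_status="accepted", qc_reason="none")


def qc_cycles(cycles: Sequence[CycleMeasurement], track: AnnulusTrack, cfg: ExtractionConfig | None = None) -> list[CycleMeasurement]:
    """Vector convenience: :func:`qc_cycle` over a candidate list."""
    return [qc_cycle(c, track, cfg) for c in cycles]


def measure_cycle_mapse(cycle: CycleMeasurement) -> float:
    """ES-to-ED longitudinal distance of an accepted cycle, in mm (>= 0)."""
    if cycle.qc_status != "accepted":
        raise ContractError("measure_cycle_mapse requires an accepted cycle")
    assert cycle.es_pos_mm is not None and cycle.ed_pos_mm is not None
    return cycle.es_pos_mm - cycle.ed_pos_mm


def aggregate_recording(
    cycles: Sequence[CycleMeasurement],
    timepoint: str,
    cfg: ExtractionConfig | None = None,
    *,
    patient_id: str = "",
    wall: str = "",
    method: str = "auto",
) -> WallMeasurement:
    """Average the earliest accepted cycles up to the timepoint's cap.

    Baseline (``pre_cpb``) recordings use at most ``max_cycles_pre`` cycles
    and log a low-cycle flag below ``min_cycles_pre_target``; postoperative
    (``icu``) recordings use at most ``max_cycles_icu``.  The recording is
    feasible as soon as one accepted cycle exists, irrespective of count.
    """
    cfg = cfg or ExtractionConfig()
    accepted = [c for c in cycles if c.qc_status == "accepted"]
    cap = cfg.max_cycles_pre if timepoint == "pre_cpb" else cfg.max_cycles_icu
    used = accepted[:cap]
    if any(c.qc_status != "accepted" for c in used):  # pragma: no cover - defensive
        raise ContractError("aggregation attempted to use a rejected cycle")
    if not used:
        return WallMeasurement(patient_id, timepoint, wall, method, None, 0, False)
    if timepoint == "pre_cpb" and len(used) < cfg.min_cycles_pre_target:
        logger.info(
            "pre-CPB recording (%s/%s) aggregated from only %d accepted cycle(s)",
            patient_id or "?", wall or "?", len(used),
        )
    mean = float(np.mean([measure_cycle_mapse(c) for c in used]))
    return WallMeasurement(patient_id, timepoint, wall, method, mean, len(used), True)


def feasibility_rate(measurements: Sequence[WallMeasurement], wall: str, method: str = "auto") -> float:
    """Percentage of recordings for a wall/method that produced a value."""
    rows = [m for m in measurements if m.wall == wall and m.method == method]
    if not rows:
        raise UndefinedRateError(f"no recordings for wall={wall!r}, method={method!r}")
    return 100.0 * sum(m.feasible for m in rows) / len(rows)


def extract_track(
    track: AnnulusTrack,
    timepoint: str,
    cfg: ExtractionConfig | None = None,
    *,
    patient_id: str = "",
    wall: str = "",
) -> tuple[WallMeasurement, list[CycleMeasurement]]:
    """Full per-recording chain: segment, QC, aggregate."""
    cfg = cfg or ExtractionConfig()
    cycles = qc_cycles(segment_cycles(track, cfg), track, cfg)
    wm = aggregate_recording(cycles, timepoint, cfg, patient_id=patient_id, wall=wall)
    return wm, cycles
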