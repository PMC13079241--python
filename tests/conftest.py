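import numpy as np
import pytest

from mapsetrend.extraction import ExtractionConfig
from mapsetrend.synthdata import CohortConfig, TrackConfig, generate_annulus_track, generate_cohort
from mapsetrend.trending import AnalysisConfig


@pytest.fixture
def ext_cfg():
    return ExtractionConfig()


@pytest.fixture
def analysis_cfg():
    return AnalysisConfig()


@pytest.fixture
def clean_track_cfg():
    """Noiseless 5-cycle track: hr=60, fps=50, 10 mm excursion."""
    return TrackConfig(
        heart_rate_bpm=60, fps=50, duration_s=5, true_mapse_mm=10.0,
        noise_sd_mm=0.0, dropout_prob=0.0, outlier_prob=0.0, seed=7,
    )


@pytest.fixture
def clean_track(clean_track_cfg):
    return generate_annulus_track(clean_track_cfg)


@pytest.fixture
def zero_noise_cohort():
    """Deterministic cohort: no noise, no missingness, no RWMA."""
    cfg = CohortConfig(
        n_patients=6,
        wall_pre_sd_mm={w: 0.0 for w in ("anterior", "inferior", "lateral", "septal")},
        decline_sd_mm=0.0,
        noise_sd_auto_mm=0.0,
        noise_sd_manual_mm=0.0,
        seed=3,
    )
    measurements, ratings, truth = generate_cohort(cfg)
    return cfg, measurements, ratings, truth


def inject_spike(track, frame_index: int, spike_mm: float):
    """Return a copy of a track with a single-frame position spike."""
    from mapsetrend.extraction import AnnulusTrack

    pos = track.long_pos_mm.copy()
    pos[frame_index] += spike_mm
    return AnnulusTrack(
        times=track.times.copy(),
        long_pos_mm=pos,
        detected=track.detected.copy(),
        r_wave_times=track.r_wave_times.copy(),
        fps=track.fps,
    )


def drop_frames(track, frame_indices):
    """Return a copy of a track with the given frames marked undetected."""
    from mapsetrend.extraction import AnnulusTrack

    pos = track.long_pos_mm.copy()
    det = track.detected.copy()
    det[frame_indices] = False
    pos[~det] = np.nan
    return AnnulusTrack(
        times=track.times.copy(),
        long_pos_mm=pos,
        detected=det,
        r_wave_times=track.r_wave_times.copy(),
        fps=track.fps,
    )
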