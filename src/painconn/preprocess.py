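"""fNIRS signal conditioning and trial segmentation.

Implements the ordered pipeline: channel quality control and spatial
interpolation of faulty channels, then per-channel (1) baseline mean
subtraction, (2) 3-SD artifact detection with local 6 s windowed-mean
offset correction, (3) zero-phase 4th-order Butterworth band-pass
0.01-0.2 Hz, (4) Daubechies-4 wavelet denoising with soft thresholding,
(5) min-max scaling to [0, 1]; finally HbT = HbO2 + HHb and segmentation
into 10 s labelled trials with NP-class balancing from rest periods.

Channel indices are 1-based throughout, matching the "channel 19" /
"ch05" naming convention of the field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .cohort import ConfigError, RawSession

__all__ = [
    "PreprocessConfig",
    "ChannelQualityReport",
    "Trial",
    "PreprocessedSession",
    "compute_channel_cv",
    "quality_report",
    "flag_and_repair",
    "baseline_correct",
    "correct_artifacts",
    "bandpass_filter",
    "wavelet_denoise",
    "minmax_scale",
    "compute_hbt",
    "preprocess_channel",
    "preprocess_session",
    "segment_trials",
    "preprocess_and_segment",
]

MODALITIES = ("hbo2", "hhb", "hbt")

#: faulty channel -> spatial neighbours whose mean replaces it (1-based)
DEFAULT_REPAIR_MAP: Mapping[int, tuple[int, ...]] = {
    19: (17, 18, 23),
    21: (20, 18, 22),
}


@dataclass(frozen=True)
class PreprocessConfig:
    artifact_sd_threshold: float = 3.0
    artifact_window: float = 6.0          # seconds, centred on the artifact run
    artifact_merge_gap: float = 0.5       # seconds; closer runs are merged
    filter_order: int = 4
    band: tuple[float, float] = (0.01, 0.2)
    wavelet: str = "db4"
    wavelet_level: int = 4
    scale_range: tuple[float, float] = (0.0, 1.0)
    cv_percentile: float = 95.0
    repair_map: Mapping[int, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_REPAIR_MAP))

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0.0 < lo < hi):
            raise ConfigError(f"band must satisfy 0 < low < high, got {self.band}")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        if self.scale_range[0] >= self.scale_range[1]:
            raise ConfigError("scale_range must be increasing")


@dataclass
class ChannelQualityReport:
    """Per-modality CV profile with flagged channels and their repair map."""

    cv: Mapping[str, np.ndarray]          # modality -> per-channel CV
    threshold: Mapping[str, float]        # modality -> 95th-percentile CV
    flagged: frozenset[int]               # 1-based channel indices (union)
    repair_map: Mapping[int, tuple[int, ...]]


@dataclass
class Trial:
    """One 10 s, single-modality segment: (n_channels, n_samples)."""

    subject_id: str
    modality: str                          # hbo2 | hhb | hbt
    label: str                             # NP | LP | HP
    data: np.ndarray
    session_id: str = "ses01"
    onset_s: float = 0.0


@dataclass
class PreprocessedSession:
    subject_id: str
    session_id: str
    fs: float
    events: pd.DataFrame
    data: Mapping[str, np.ndarray]        # modality -> (n_samples, n_channels)


# ---------------------------------------------------------------------------
# Channel quality control

def compute_channel_cv(session: RawSession, modality: str) -> np.ndarray:
    """Coefficient of variation per channel: SD / mean(|x|) over the session.

    Channels whose mean absolute signal is zero get ``inf`` and are always
    flagged downstream.
    """
    x = session.modality(modality)
    if x.size == 0:
        raise ConfigError("empty session")
    sd = x.std(axis=0)
    denom = np.abs(x).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(denom > 0, sd / np.where(denom > 0, denom, 1.0), np.inf)
    # all-zero channel: SD 0 and mean |x| 0 -> undefined, flag as faulty
    cv[(denom == 0)] = np.inf
    return cv


def quality_report(session: RawSession,
                   config: PreprocessConfig = PreprocessConfig()) -> ChannelQualityReport:
    """Flag channels with CV above the configured percentile (per modality, union)."""
    cvs: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    flagged: set[int] = set()
    for modality in ("hbo2", "hhb"):
        cv = compute_channel_cv(session, modality)
        finite = cv[np.isfinite(cv)]
        if finite.size == 0:
            warnings.warn("all channels have undefined CV; flagging every channel")
            thr = np.inf
            flagged.update(range(1, cv.size + 1))
        else:
            thr = float(np.percentile(finite, config.cv_percentile))
            flagged.update(int(c) + 1 for c in np.nonzero((cv > thr) | ~np.isfinite(cv))[0])
        cvs[modality] = cv
        thresholds[modality] = thr
    return ChannelQualityReport(cv=cvs, threshold=thresholds,
                                flagged=frozenset(flagged),
                                repair_map=dict(config.repair_map))


def flag_and_repair(session: RawSession,
                    report: ChannelQualityReport) -> RawSession:
    """Replace each flagged channel by the time-pointwise mean of its mapped
    neighbours, in both haemoglobin modalities; all channels are retained."""
    for ch in sorted(report.flagged):
        if ch not in report.repair_map:
            raise ConfigError(
                f"flagged channel {ch} has no repair-map entry; add one or "
                "exclude it from flagging")
        for nb in report.repair_map[ch]:
            if nb in report.flagged:
                raise ConfigError(
                    f"repair neighbour {nb} of channel {ch} is itself flagged")
    samples = session.samples.copy()
    for ch in sorted(report.flagged):
        nbs = report.repair_map[ch]
        for off in (0, 1):  # hbo2, hhb interleaved columns
            cols = [2 * (nb - 1) + off for nb in nbs]
            samples[:, 2 * (ch - 1) + off] = session.samples[:, cols].mean(axis=1)
    return replace(session, samples=samples)


# ---------------------------------------------------------------------------
# The five per-channel conditioning steps

def baseline_correct(x: np.ndarray) -> np.ndarray:
    """Step 1: per-channel mean subtraction."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ConfigError("empty series")
    return x - x.mean()


def _exceedance_runs(mask: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop); nearby runs merged."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    runs = [(int(a), int(b)) for a, b in zip(starts, stops)]
    merged = [runs[0]]
    for a, b in runs[1:]:
        if a - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def correct_artifacts(x: np.ndarray, fs: float,
                      config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Step 2: offset-correct motion-artifact segments.

    Samples deviating more than ``artifact_sd_threshold`` channel SDs from
    the channel mean form contiguous runs (merged if separated by less than
    ``artifact_merge_gap`` seconds).  Each run is shifted so that its mean
    matches the mean of the surrounding window (run excluded), preserving
    the within-run waveform.  Windows are truncated at record edges.
    """
    if fs <= 0:
        raise ConfigError("fs must be positive")
    x = np.asarray(x, dtype=float)
    mu, sd = x.mean(), x.std()
    if sd == 0:
        return x.copy()
    mask = np.abs(x - mu) > config.artifact_sd_threshold * sd
    runs = _exceedance_runs(mask, int(round(config.artifact_merge_gap * fs)))
    out = x.copy()
    half = int(round(config.artifact_window * fs / 2))
    for a, b in runs:
        centre = (a + b) // 2
        lo = max(0, centre - half)
        hi = min(x.size, centre + half)
        keep = np.ones(hi - lo, dtype=bool)
        keep[max(a, lo) - lo:min(b, hi) - lo] = False
        local = x[lo:hi][keep]
        local_mean = local.mean() if local.size else mu
        out[a:b] += local_mean - x[a:b].mean()
    return out


def bandpass_filter(x: np.ndarray, fs: float,
                    config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Step 3: zero-phase Butterworth band-pass (forward-backward)."""
    x = np.asarray(x, dtype=float)
    lo, hi = config.band
    if hi >= fs / 2:
        raise ConfigError(f"band high edge {hi} must be below Nyquist {fs / 2}")
    sos = sps.butter(config.filter_order, [lo, hi], btype="bandpass",
                     fs=fs, output="sos")
    # default sosfiltfilt padlen
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if x.size <= padlen:
        raise ConfigError(
            f"series of length {x.size} too short for zero-phase filtering; "
            f"need more than {padlen} samples")
    return sps.sosfiltfilt(sos, x)


def wavelet_denoise(x: np.ndarray,
                    config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Step 4: multilevel Daubechies wavelet soft-threshold denoising.

    The threshold is the universal threshold sigma * sqrt(2 ln N), with
    sigma estimated from the median absolute deviation of the finest
    detail level (the customary robust noise-scale estimate).
    """
    x = np.asarray(x, dtype=float)
    wav = pywt.Wavelet(config.wavelet)
    max_level = pywt.dwt_max_level(x.size, wav.dec_len)
    if max_level < 1:
        raise ConfigError(
            f"series of length {x.size} too short for wavelet {config.wavelet}")
    level = min(config.wavelet_level, max_level)
    coeffs = pywt.wavedec(x, wav, level=level)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest)) / 0.6745 if finest.size else 0.0
    thr = sigma * np.sqrt(2.0 * np.log(max(x.size, 2)))
    if thr > 0:
        coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft")
                                for c in coeffs[1:]]
    out = pywt.waverec(coeffs, wav)
    return out[:x.size]


def minmax_scale(x: np.ndarray,
                 value_range: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """Step 5: per-channel min-max scaling; constant input maps to midpoint."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ConfigError("empty series")
    lo, hi = value_range
    xmin, xmax = x.min(), x.max()
    if xmax == xmin:
        return np.full_like(x, (lo + hi) / 2.0)
    return lo + (x - xmin) * (hi - lo) / (xmax - xmin)


def compute_hbt(hbo2: np.ndarray, hhb: np.ndarray) -> np.ndarray:
    """Total haemoglobin: elementwise HbO2 + HHb (after preprocessing)."""
    hbo2 = np.asarray(hbo2, dtype=float)
    hhb = np.asarray(hhb, dtype=float)
    if hbo2.shape != hhb.shape:
        raise ConfigError(f"shape mismatch: {hbo2.shape} vs {hhb.shape}")
    return hbo2 + hhb


def preprocess_channel(x: np.ndarray, fs: float,
                       config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Steps 1-5 in order on a single channel series."""
    x = baseline_correct(x)
    x = correct_artifacts(x, fs, config)
    x = bandpass_filter(x, fs, config)
    x = wavelet_denoise(x, config)
    return minmax_scale(x, config.scale_range)


# ---------------------------------------------------------------------------
# Session-level pipeline and segmentation

def preprocess_session(session: RawSession,
                       config: PreprocessConfig = PreprocessConfig()
                       ) -> PreprocessedSession:
    """QC/repair, then the five steps per channel and modality, then HbT."""
    report = quality_report(session, config)
    repaired = flag_and_repair(session, report)
    data: dict[str, np.ndarray] = {}
    for modality in ("hbo2", "hhb"):
        raw = repaired.modality(modality)
        out = np.empty_like(raw)
        for c in range(raw.shape[1]):
            out[:, c] = preprocess_channel(raw[:, c], session.fs, config)
        data[modality] = out
    data["hbt"] = compute_hbt(data["hbo2"], data["hhb"])
    return PreprocessedSession(subject_id=session.subject_id,
                               session_id=session.session_id,
                               fs=session.fs, events=session.events.copy(),
                               data=data)


def _harvest_rests(events: pd.DataFrame, n_extra: int) -> pd.DataFrame:
    """The first ``n_extra`` rest periods that precede a subsequent pain
    stimulation; the harvested window is the final trial-length of each."""
    stim = events[events.label.isin(("LP", "HP"))]
    rests = events[events.label == "REST"]
    eligible = []
    for _, rest in rests.iterrows():
        rest_end = rest.onset_s + rest.duration_s
        if (stim.onset_s >= rest_end - 1e-9).any():
            eligible.append(rest)
        if len(eligible) == n_extra:
            break
    if len(eligible) < n_extra:
        raise ConfigError(
            f"only {len(eligible)} rest periods precede subsequent "
            f"stimulations; cannot harvest {n_extra} extra NP trials")
    return pd.DataFrame(eligible)


def segment_trials(psession: PreprocessedSession,
                   modalities: Sequence[str] = MODALITIES) -> list[Trial]:
    """Cut labelled trial windows and balance NP from rest periods.

    Yields, per modality, the pre-stimulus NP windows, the LP and HP
    stimulation windows, and enough extra NP windows (the final 10 s of
    distinct rest periods preceding subsequent stimulations) to equalise
    the three classes.
    """
    events = psession.events
    if events.empty:
        return []
    fs = psession.fs
    n_total = next(iter(psession.data.values())).shape[0]

    counts = events.label.value_counts()
    n_np = int(counts.get("NP", 0))
    n_lp = int(counts.get("LP", 0))
    n_hp = int(counts.get("HP", 0))
    if n_lp != n_hp:
        raise ConfigError(f"unbalanced stimulus events: LP={n_lp}, HP={n_hp}")
    n_extra = n_lp - n_np
    if n_extra < 0:
        raise ConfigError(f"more NP events ({n_np}) than LP/HP events ({n_lp})")

    trial_dur = float(events.loc[events.label != "REST", "duration_s"].iloc[0])
    windows: list[tuple[float, str]] = []
    for _, ev in events.iterrows():
        if ev.label in ("NP", "LP", "HP"):
            windows.append((float(ev.onset_s), str(ev.label)))
    if n_extra > 0:
        for _, rest in _harvest_rests(events, n_extra).iterrows():
            windows.append((float(rest.onset_s + rest.duration_s - trial_dur), "NP"))

    n_win = int(round(trial_dur * fs))
    trials: list[Trial] = []
    for modality in modalities:
        mat = psession.data[modality]
        for onset, label in windows:
            a = int(round(onset * fs))
            b = a + n_win
            if a < 0 or b > n_total:
                raise ConfigError(
                    f"event window [{onset}, {onset + trial_dur}) s ({label}) "
                    "extends outside the recording")
            trials.append(Trial(subject_id=psession.subject_id,
                                modality=modality, label=label,
                                data=mat[a:b].T.copy(),
                                session_id=psession.session_id,
                                onset_s=onset))
    return trials


def preprocess_and_segment(session: RawSession,
                           config: PreprocessConfig = PreprocessConfig(),
                           modalities: Sequence[str] = MODALITIES) -> list[Trial]:
    """Convenience: full pipeline from raw session to labelled trials."""
    return segment_trials(preprocess_session(session, config), modalities)
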