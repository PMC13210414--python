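"""Synthetic fNIRS cohort generator.

Emulates the structure of a 65-participant prefrontal fNIRS pain study:
24 channels of oxyhaemoglobin (HbO2) and 24 of deoxyhaemoglobin (HHb),
interleaved in columns and sampled at 50 Hz.  Each subject's session starts
with a no-pain baseline providing 6 pre-stimulus NP windows, followed by a
randomised sequence of 12 low-pain (LP) and 12 high-pain (HP) 10 s stimuli,
each followed by a 40 s rest period from which 6 extra NP windows are later
harvested to balance the classes.

The latent cortical signal is a stationary VAR(2) process whose AR poles sit
inside the haemodynamic band (~0.06 Hz), with a sparse set of directed,
class-dependent couplings between channels (the planted "ground truth" that
downstream Granger-causality features should recover).  On top of that the
generator layers slow drift, cardiac (~1.1 Hz) and respiratory (~0.25 Hz)
oscillations, white noise, rectangular motion spikes, and large-amplitude
noise on two designated corrupted channels (19 and 21 by default) so that
channel quality control has real work to do.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "CohortConfig",
    "PlantedEdge",
    "GroundTruth",
    "RawSession",
    "simulate_cohort",
    "iter_sessions",
    "simulate_session",
    "write_sessions",
    "read_session",
    "channel_columns",
]

#: The three pain classes, in ordinal order of intensity.
LABELS = ("NP", "LP", "HP")

_LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}


class ConfigError(ValueError):
    """Raised for invalid cohort or preprocessing configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Geometry, timing and noise scaling of the synthetic cohort.

    Defaults mirror the emulated study: 65 subjects, 24 channels at 50 Hz,
    10 s trials, 40 s rests, an initial 6:12:12 NP:LP:HP trial imbalance
    balanced by 6 extra NP windows harvested from rest periods, and two
    corrupted channels (19, 21; 1-based).
    """

    n_subjects: int = 65
    n_channels: int = 24
    fs: float = 50.0
    trial_duration: float = 10.0
    rest_duration: float = 40.0
    np_trials_initial: int = 6
    lp_trials: int = 12
    hp_trials: int = 12
    extra_np_trials: int = 6
    corrupted_channels: tuple[int, ...] = (19, 21)
    effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_channels", "np_trials_initial",
                     "lp_trials", "hp_trials"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.extra_np_trials < 0:
            raise ConfigError("extra_np_trials must be non-negative")
        for name in ("fs", "trial_duration", "rest_duration"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.rest_duration < self.trial_duration:
            raise ConfigError("rest_duration must be >= trial_duration so that "
                              "extra NP windows can be harvested from rests")
        bad = [c for c in self.corrupted_channels
               if not (1 <= c <= self.n_channels)]
        if bad:
            raise ConfigError(f"corrupted_channels outside 1..{self.n_channels}: {bad}")
        if self.np_trials_initial + self.extra_np_trials != self.lp_trials \
                or self.lp_trials != self.hp_trials:
            raise ConfigError(
                "class balance requires np_trials_initial + extra_np_trials "
                "== lp_trials == hp_trials "
                f"(got {self.np_trials_initial}+{self.extra_np_trials}, "
                f"{self.lp_trials}, {self.hp_trials})")
        # extra NP windows come from rests that precede a *subsequent* stimulus
        if self.extra_np_trials > self.lp_trials + self.hp_trials - 1:
            raise ConfigError("not enough rest periods preceding subsequent "
                              "stimulations to harvest extra NP trials")

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_duration * self.fs))

    @property
    def trials_per_class(self) -> int:
        return self.lp_trials

    @property
    def session_duration(self) -> float:
        n_stim = self.lp_trials + self.hp_trials
        return (self.np_trials_initial * self.trial_duration
                + n_stim * (self.trial_duration + self.rest_duration))

    @property
    def n_samples(self) -> int:
        return int(round(self.session_duration * self.fs))


@dataclass(frozen=True)
class PlantedEdge:
    """A directed channel coupling with class-dependent strength (1-based)."""

    source: int
    target: int
    strengths: Mapping[str, float]  # label -> VAR lag-1 coefficient

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ConfigError("planted edge must have source != target")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: couplings and nuisance-signal parameters."""

    planted_edges: tuple[PlantedEdge, ...]
    noise: Mapping[str, float | tuple[float, float]]


# Nuisance-signal parameters (amplitudes in the same arbitrary concentration
# units as the unit-variance latent signal).
_NOISE = {
    "drift_amplitude": 2.0,
    "drift_period_range": (300.0, 900.0),
    "drift_slope_range": (-0.5, 0.5),       # total linear change over session
    "cardiac_freq": 1.1,
    "cardiac_freq_sd": 0.05,
    "cardiac_amplitude": 0.5,
    "resp_freq": 0.25,
    "resp_freq_sd": 0.02,
    "resp_amplitude": 0.3,
    "white_sd": 0.3,
    "spike_rate_per_min": 1.0,
    "spike_duration_range": (0.2, 0.5),
    "spike_amplitude_range": (4.0, 8.0),    # multiples of channel SD
    "corrupted_sd_hbo2": 10.0,
    "corrupted_sd_hhb": 3.0,
    "hbo2_offset": (100.0, 5.0),            # mean, sd of per-channel DC level
    "hhb_offset": (70.0, 5.0),
    "hhb_coupling": -0.3,
    "hhb_noise_sd": 0.15,
    "var_pole_radius": 0.99,
    "var_peak_freq": 0.06,
}

# Class-dependent lag-1 coupling strengths (before effect_scale), monotone
# in pain intensity so that discriminative edges separate the classes.
_BASE_STRENGTHS = {"NP": 0.1, "LP": 0.45, "HP": 0.8}


def _default_edges(n_channels: int) -> tuple[tuple[int, int], ...]:
    """Directed (source, target) pairs forming a DAG (sources and targets
    disjoint), so couplings never destabilise the VAR."""
    if n_channels >= 24:
        # One driver per target, all channels outside the corrupted set
        # (19, 21) and their repair neighbourhoods (17, 18, 20, 22, 23):
        # repair overwrites corrupted channels with neighbour means, which
        # would either erase a planted coupling or manufacture proxy pairs.
        return ((7, 10), (3, 5), (14, 16), (6, 13))
    if n_channels < 2:
        raise ConfigError("need at least 2 channels for planted edges")
    edges = []
    for i in range(1, min(3, n_channels // 2) + 1):
        edges.append((i, n_channels - i + 1))
    return tuple(e for e in edges if e[0] != e[1])


def _ground_truth(config: CohortConfig) -> GroundTruth:
    edges = tuple(
        PlantedEdge(src, tgt,
                    {lab: config.effect_scale * _BASE_STRENGTHS[lab]
                     for lab in LABELS})
        for src, tgt in _default_edges(config.n_channels)
    )
    return GroundTruth(planted_edges=edges, noise=dict(_NOISE))


def _build_events(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    td, rd = config.trial_duration, config.rest_duration
    rows = []
    for i in range(config.np_trials_initial):
        rows.append((i * td, td, "NP"))
    t = config.np_trials_initial * td
    stim = np.array(["LP"] * config.lp_trials + ["HP"] * config.hp_trials)
    stim = stim[rng.permutation(stim.size)]
    for lab in stim:
        rows.append((t, td, str(lab)))
        rows.append((t + td, rd, "REST"))
        t += td + rd
    return pd.DataFrame(rows, columns=["onset_s", "duration_s", "label"])


def _condition_index(events: pd.DataFrame, n_samples: int, fs: float) -> np.ndarray:
    """Per-sample class index for the coupling matrices (REST behaves as NP)."""
    cond = np.zeros(n_samples, dtype=np.int8)  # NP
    for _, ev in events.iterrows():
        if ev.label in ("LP", "HP"):
            a = int(round(ev.onset_s * fs))
            b = min(n_samples, a + int(round(ev.duration_s * fs)))
            cond[a:b] = _LABEL_INDEX[ev.label]
    return cond


def _simulate_var(cond: np.ndarray, ground_truth: GroundTruth,
                  n_channels: int, rng: np.random.Generator,
                  burn_in: int = 500) -> np.ndarray:
    """Latent class-conditional VAR(2), unit-variance per channel.

    The diagonal AR(2) poles sit at radius r and angle 2*pi*f0/fs, which
    concentrates the spectrum inside the haemodynamic band without any
    post-hoc filtering; sparse lag-1 couplings switch with the condition.
    """
    noise = ground_truth.noise
    r = float(noise["var_pole_radius"])
    theta = 2.0 * np.pi * float(noise["var_peak_freq"]) / 50.0
    a1 = 2.0 * r * np.cos(theta)
    a2 = -r * r

    n = cond.size
    edges = ground_truth.planted_edges
    src = np.array([e.source - 1 for e in edges], dtype=int)
    tgt = np.array([e.target - 1 for e in edges], dtype=int)
    strength = np.array([[e.strengths[lab] for lab in LABELS] for e in edges])

    eps = rng.standard_normal((n + burn_in, n_channels))
    cond_full = np.concatenate([np.zeros(burn_in, dtype=np.int8), cond])
    x = np.zeros((n + burn_in, n_channels))
    for t in range(2, n + burn_in):
        xm1 = x[t - 1]
        x[t] = a1 * xm1 + a2 * x[t - 2] + eps[t]
        if edges:
            np.add.at(x[t], tgt, strength[:, cond_full[t]] * xm1[src])
    x = x[burn_in:]
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def _nuisance(n: int, n_channels: int, fs: float,
              noise: Mapping, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros((n, n_channels))
    period = rng.uniform(*noise["drift_period_range"])
    cardiac_f = rng.normal(noise["cardiac_freq"], noise["cardiac_freq_sd"])
    resp_f = rng.normal(noise["resp_freq"], noise["resp_freq_sd"])
    for c in range(n_channels):
        drift = (noise["drift_amplitude"]
                 * np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi)))
        drift += rng.uniform(*noise["drift_slope_range"]) * t / t[-1]
        cardiac = (noise["cardiac_amplitude"]
                   * np.sin(2 * np.pi * cardiac_f * t + rng.uniform(0, 2 * np.pi)))
        resp = (noise["resp_amplitude"]
                * np.sin(2 * np.pi * resp_f * t + rng.uniform(0, 2 * np.pi)))
        out[:, c] = drift + cardiac + resp
    out += rng.normal(0.0, noise["white_sd"], size=(n, n_channels))
    return out


def _add_spikes(fluct: np.ndarray, fs: float, noise: Mapping,
                rng: np.random.Generator) -> None:
    """Poisson-placed rectangular offsets exceeding 3 channel-SDs, in place."""
    n, n_channels = fluct.shape
    minutes = n / fs / 60.0
    for c in range(n_channels):
        sd = fluct[:, c].std()
        n_spk = rng.poisson(noise["spike_rate_per_min"] * minutes)
        for _ in range(n_spk):
            dur = int(round(rng.uniform(*noise["spike_duration_range"]) * fs))
            a = rng.integers(0, max(1, n - dur))
            amp = rng.uniform(*noise["spike_amplitude_range"]) * sd
            fluct[a:a + dur, c] += rng.choice((-1.0, 1.0)) * amp


@dataclass
class RawSession:
    """One subject/session record: time x 48 interleaved haemoglobin columns."""

    subject_id: str
    session_id: str
    samples: np.ndarray            # (n_samples, 2 * n_channels), interleaved
    fs: float
    events: pd.DataFrame           # onset_s, duration_s, label

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1] // 2

    def modality(self, modality: str) -> np.ndarray:
        """Return the (n_samples, n_channels) matrix for 'hbo2' or 'hhb'."""
        m = modality.lower()
        if m == "hbo2":
            return self.samples[:, 0::2]
        if m == "hhb":
            return self.samples[:, 1::2]
        raise ValueError(f"unknown raw modality {modality!r} (hbo2 or hhb)")


def simulate_session(config: CohortConfig, subject_index: int,
                     ground_truth: GroundTruth | None = None) -> RawSession:
    """Generate one subject's session deterministically from (config.seed, index)."""
    if ground_truth is None:
        ground_truth = _ground_truth(config)
    noise = ground_truth.noise
    # fixed-offset substream per subject, all driven by the single cohort seed
    rng = np.random.default_rng([config.seed, 7919, subject_index])

    events = _build_events(config, rng)
    n = config.n_samples
    cond = _condition_index(events, n, config.fs)

    latent = _simulate_var(cond, ground_truth, config.n_channels, rng)
    hbo2_fluct = latent + _nuisance(n, config.n_channels, config.fs, noise, rng)
    for ch in config.corrupted_channels:
        hbo2_fluct[:, ch - 1] += rng.normal(0.0, noise["corrupted_sd_hbo2"], n)
    _add_spikes(hbo2_fluct, config.fs, noise, rng)

    hhb_fluct = (noise["hhb_coupling"] * hbo2_fluct
                 + rng.normal(0.0, noise["hhb_noise_sd"],
                              size=(n, config.n_channels)))
    for ch in config.corrupted_channels:
        hhb_fluct[:, ch - 1] += rng.normal(0.0, noise["corrupted_sd_hhb"], n)

    mu_o, sd_o = noise["hbo2_offset"]
    mu_h, sd_h = noise["hhb_offset"]
    hbo2 = hbo2_fluct + rng.normal(mu_o, sd_o, config.n_channels)
    hhb = hhb_fluct + rng.normal(mu_h, sd_h, config.n_channels)

    samples = np.empty((n, 2 * config.n_channels))
    samples[:, 0::2] = hbo2
    samples[:, 1::2] = hhb
    sid = f"sub{subject_index + 1:02d}"
    return RawSession(subject_id=sid, session_id="ses01",
                      samples=samples, fs=config.fs, events=events)


def iter_sessions(config: CohortConfig) -> Iterator[RawSession]:
    """Yield sessions one at a time (memory-friendly for large cohorts)."""
    gt = _ground_truth(config)
    for s in range(config.n_subjects):
        yield simulate_session(config, s, gt)


def simulate_cohort(config: CohortConfig) -> tuple[list[RawSession], GroundTruth]:
    """Generate the full cohort.  Bit-identical for identical (config, seed)."""
    gt = _ground_truth(config)
    sessions = [simulate_session(config, s, gt) for s in range(config.n_subjects)]
    return sessions, gt


# ---------------------------------------------------------------------------
# File I/O: CSV signals (interleaved columns) + TSV events per session.

def channel_columns(n_channels: int) -> list[str]:
    cols = []
    for c in range(1, n_channels + 1):
        cols.append(f"ch{c:02d}_hbo2")
        cols.append(f"ch{c:02d}_hhb")
    return cols


def write_sessions(sessions: Sequence[RawSession],
                   directory: str | os.PathLike) -> list[Path]:
    """Write one signal CSV and one event TSV per session; returns file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for sess in sessions:
        base = f"{sess.subject_id}_{sess.session_id}"
        sig_path = directory / f"{base}_signals.csv"
        ev_path = directory / f"{base}_events.tsv"
        n = sess.samples.shape[0]
        df = pd.DataFrame(sess.samples, columns=channel_columns(sess.n_channels))
        df.insert(0, "time_s", np.arange(n) / sess.fs)
        try:
            df.to_csv(sig_path, index=False, float_format="%.17g")
            sess.events.to_csv(ev_path, sep="\t", index=False)
        except OSError as exc:  # pragma: no cover - environment dependent
            raise OSError(f"failed to write session files under {directory}: {exc}") from exc
        paths.extend([sig_path, ev_path])
    return paths


def read_session(signal_path: str | os.PathLike,
                 events_path: str | os.PathLike | None = None,
                 fs: float | None = None) -> RawSession:
    """Load a session written by :func:`write_sessions`."""
    signal_path = Path(signal_path)
    if events_path is None:
        events_path = signal_path.with_name(
            signal_path.name.replace("_signals.csv", "_events.tsv"))
    df = pd.read_csv(signal_path, float_precision="round_trip")
    t = df.pop("time_s").to_numpy()
    if fs is None:
        fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else 50.0
    events = pd.read_csv(events_path, sep="\t")
    stem = signal_path.name.replace("_signals.csv", "")
    parts = stem.split("_")
    subject_id = parts[0]
    session_id = parts[1] if len(parts) > 1 else "ses01"
    return RawSession(subject_id=subject_id, session_id=session_id,
                      samples=df.to_numpy(), fs=float(round(fs, 6)),
                      events=events)
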