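"""Trial-level brain-connectivity estimators and feature vectorisation.

For each 10 s, 24-channel trial the four measures are

* Pearson correlation       r_ij = cov(x_i, x_j) / (sigma_i sigma_j)
* partial correlation       rho_ij = -P_ij / sqrt(P_ii P_jj), P = inv(Sigma)
* magnitude-squared coherence  C_ij(f) = |S_ij(f)|^2 / (S_ii(f) S_jj(f)),
  Welch-estimated and scalarised by the band mean
* Granger causality (pairwise, lag order p):  for target i and source j,
  gc[i, j] = ln(RSS_restricted / RSS_full), where the restricted AR model
  uses p lags of x_i only and the full model adds p lags of x_j.

The three symmetric matrices contribute their upper triangles
(n(n-1)/2 features each) and Granger causality all off-diagonal entries
(n(n-1) features), giving 3*276 + 552 = 1380 named features at n = 24.
Feature names follow the field convention ``corr_ch01_ch02`` and
``granger_ch05_to_ch20`` (source first).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .cohort import ConfigError
from .preprocess import Trial

__all__ = [
    "ConnectivityConfig",
    "ConnectivitySet",
    "FeatureVector",
    "pearson_matrix",
    "partial_corr_matrix",
    "coherence_matrix",
    "granger_matrix",
    "compute_connectivity",
    "feature_names",
    "vectorise",
    "features_for_dataset",
    "ConnectivityFeaturizer",
    "n_features",
]

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class ConnectivityConfig:
    gc_order: int = 2                     # VAR lag order p for Granger causality
    ridge: float = 1e-6                   # delta: Sigma += delta*tr(Sigma)/n * I
    nperseg: int = 128                    # Welch segment length (samples)
    overlap: float = 0.5                  # fractional segment overlap
    band: tuple[float, float] = (0.01, 0.2)  # coherence scalarisation band, Hz

    def __post_init__(self) -> None:
        if self.gc_order < 1:
            raise ConfigError("gc_order must be >= 1")
        if self.ridge < 0:
            raise ConfigError("ridge must be non-negative")
        if not (0 <= self.overlap < 1):
            raise ConfigError("overlap must be in [0, 1)")


@dataclass
class ConnectivitySet:
    """The four 24x24 matrices for one trial, with provenance."""

    corr: np.ndarray
    pcorr: np.ndarray
    coh: np.ndarray
    gc: np.ndarray                        # gc[target, source]
    subject_id: str = ""
    modality: str = ""
    label: str = ""


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]


def _as_matrix(trial: Trial | np.ndarray) -> np.ndarray:
    x = trial.data if isinstance(trial, Trial) else np.asarray(trial, dtype=float)
    if x.ndim != 2:
        raise ConfigError("trial data must be 2-D (channels x samples)")
    return x


def pearson_matrix(trial: Trial | np.ndarray) -> np.ndarray:
    x = _as_matrix(trial)
    sd = x.std(axis=1)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise ConfigError(f"zero-variance channel(s) {list(dead + 1)}; "
                          "cannot compute Pearson correlation")
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def partial_corr_matrix(trial: Trial | np.ndarray,
                        ridge: float = 1e-6) -> np.ndarray:
    """Partial correlation from the (optionally ridge-regularised) precision
    matrix; diagonal reported as 1 by convention."""
    x = _as_matrix(trial)
    n = x.shape[0]
    sigma = np.cov(x)
    if ridge > 0:
        sigma = sigma + ridge * np.trace(sigma) / n * np.eye(n)
    try:
        prec = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as exc:
        raise ConfigError(
            "covariance matrix is singular; pass ridge > 0 to regularise"
        ) from exc
    d = np.sqrt(np.diag(prec))
    rho = -prec / np.outer(d, d)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def coherence_matrix(trial: Trial | np.ndarray, fs: float,
                     config: ConnectivityConfig = ConnectivityConfig()) -> np.ndarray:
    """Band-mean magnitude-squared coherence between all channel pairs.

    Welch cross-spectra with Hann taper and the configured segment length
    and overlap.  The scalar per pair is the mean of C_ij(f) over Welch
    bins inside ``config.band``; if the trial is too short for any non-DC
    bin to fall in the band, the lowest non-DC bin is used instead.
    """
    x = _as_matrix(trial)
    n_samp = x.shape[1]
    nperseg = min(config.nperseg, n_samp)
    noverlap = int(nperseg * config.overlap)
    step = nperseg - noverlap
    n_seg = (n_samp - nperseg) // step + 1
    if n_seg < 2:
        raise ConfigError(
            f"only {n_seg} spectral segment(s) of {nperseg} samples fit in "
            f"{n_samp} samples; coherence is degenerate with < 2 segments")
    f, sxy = sps.csd(x[:, None, :], x[None, :, :], fs=fs,
                     nperseg=nperseg, noverlap=noverlap, window="hann")
    auto = np.einsum("iif->if", sxy).real  # autospectra S_ii(f)
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, np.abs(sxy) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    lo, hi = config.band
    in_band = (f >= lo) & (f <= hi) & (f > 0)
    if not in_band.any():
        in_band = np.zeros_like(f, dtype=bool)
        in_band[np.argmax(f > 0)] = True    # lowest resolvable non-DC bin
    coh = c[:, :, in_band].mean(axis=2)
    coh = np.clip((coh + coh.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(coh, 1.0)
    return coh


def _lag_blocks(x: np.ndarray, p: int) -> np.ndarray:
    """(n_channels, n - p, p) design blocks: block[c, t, k] = x[c, p + t - 1 - k]."""
    n_ch, n = x.shape
    out = np.empty((n_ch, n - p, p))
    for k in range(p):
        out[:, :, k] = x[:, p - 1 - k:n - 1 - k]
    return out


def _rss(y: np.ndarray, design: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def granger_matrix(trial: Trial | np.ndarray,
                   p: int = 2) -> np.ndarray:
    """Pairwise Granger causality, gc[target, source] = ln(RSS_r / RSS_f).

    Restricted model: p own lags (+ intercept); full model adds p lags of
    the source channel.  Entries are clipped at 0; the diagonal is 0 and
    excluded from the feature vector.
    """
    x = _as_matrix(trial)
    n_ch, n_samp = x.shape
    if p < 1:
        raise ConfigError("lag order p must be >= 1")
    if n_samp <= p * (2 * p + 1):
        raise ConfigError(f"trial length {n_samp} too short for lag order {p}")
    blocks = _lag_blocks(x, p)
    ones = np.ones((n_samp - p, 1))
    gc = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        y = x[i, p:]
        if y.std() == 0:
            raise ConfigError(f"zero-variance target channel {i + 1}")
        design_r = np.hstack([blocks[i], ones])
        rss_r = _rss(y, design_r)
        if rss_r <= 0:
            raise ConfigError(
                f"restricted model for channel {i + 1} fits perfectly; "
                "Granger ratio undefined (degenerate regressors)")
        for j in range(n_ch):
            if j == i:
                continue
            design_f = np.hstack([blocks[i], blocks[j], ones])
            rss_f = _rss(y, design_f)
            gc[i, j] = np.log(rss_r / max(rss_f, 1e-300))
    return np.maximum(gc, 0.0)


def compute_connectivity(trial: Trial,
                         config: ConnectivityConfig = ConnectivityConfig(),
                         fs: float = 50.0) -> ConnectivitySet:
    return ConnectivitySet(
        corr=pearson_matrix(trial),
        pcorr=partial_corr_matrix(trial, ridge=config.ridge),
        coh=coherence_matrix(trial, fs=fs, config=config),
        gc=granger_matrix(trial, p=config.gc_order),
        subject_id=trial.subject_id, modality=trial.modality,
        label=trial.label)


# ---------------------------------------------------------------------------
# Vectorisation

def n_features(n_channels: int) -> int:
    """3 symmetric upper triangles + all directed off-diagonals."""
    return 3 * n_channels * (n_channels - 1) // 2 + n_channels * (n_channels - 1)


def feature_names(n_channels: int = 24) -> tuple[str, ...]:
    """Canonical layout: corr, pcorr, coh upper triangles (row-major, i < j),
    then granger over all ordered (source, target) pairs, source-major."""
    names: list[str] = []
    for measure in ("corr", "pcorr", "coh"):
        for i in range(1, n_channels + 1):
            for j in range(i + 1, n_channels + 1):
                names.append(f"{measure}_ch{i:02d}_ch{j:02d}")
    for a in range(1, n_channels + 1):
        for b in range(1, n_channels + 1):
            if a != b:
                names.append(f"granger_ch{a:02d}_to_ch{b:02d}")
    return tuple(names)


def _check_symmetric(m: np.ndarray, what: str) -> None:
    if np.abs(m - m.T).max() > _SYMMETRY_TOL:
        raise ConfigError(f"{what} matrix is asymmetric beyond tolerance")


def vectorise(cs: ConnectivitySet) -> FeatureVector:
    """Flatten a ConnectivitySet into the canonical named feature vector."""
    n = cs.corr.shape[0]
    for m, what in ((cs.corr, "correlation"), (cs.pcorr, "partial correlation"),
                    (cs.coh, "coherence")):
        _check_symmetric(m, what)
    iu = np.triu_indices(n, k=1)
    off = ~np.eye(n, dtype=bool)
    # granger names iterate (source a, target b); matrix is gc[target, source]
    values = np.concatenate([cs.corr[iu], cs.pcorr[iu], cs.coh[iu],
                             cs.gc.T[off]])
    return FeatureVector(values=values, names=feature_names(n))


def features_for_dataset(trials: Sequence[Trial], modality: str,
                         config: ConnectivityConfig = ConnectivityConfig(),
                         fs: float = 50.0) -> pd.DataFrame:
    """One row per trial of the given modality: subject, label + 1380 features."""
    subset = [t for t in trials if t.modality == modality]
    if not subset:
        raise ConfigError(f"no trials with modality {modality!r}")
    names = feature_names(subset[0].data.shape[0])
    rows = np.empty((len(subset), len(names)))
    for r, trial in enumerate(subset):
        try:
            rows[r] = vectorise(compute_connectivity(trial, config, fs)).values
        except Exception as exc:
            raise type(exc)(
                f"{exc} (subject {trial.subject_id}, modality {trial.modality}, "
                f"label {trial.label}, onset {trial.onset_s} s)") from exc
    df = pd.DataFrame(rows, columns=list(names))
    df.insert(0, "subject", [t.subject_id for t in subset])
    df.insert(1, "label", [t.label for t in subset])
    return df


class ConnectivityFeaturizer:
    """sklearn-style transformer: stacked trials -> connectivity features.

    ``transform`` accepts an array of shape (n_trials, n_channels,
    n_samples) and returns (n_trials, n_features).  Stateless; ``fit``
    exists for pipeline compatibility.
    """

    def __init__(self, gc_order: int = 2, ridge: float = 1e-6,
                 nperseg: int = 128, overlap: float = 0.5,
                 band: tuple[float, float] = (0.01, 0.2), fs: float = 50.0):
        self.gc_order = gc_order
        self.ridge = ridge
        self.nperseg = nperseg
        self.overlap = overlap
        self.band = band
        self.fs = fs

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("gc_order", "ridge", "nperseg", "overlap", "band", "fs")}

    def set_params(self, **params) -> "ConnectivityFeaturizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> ConnectivityConfig:
        return ConnectivityConfig(gc_order=self.gc_order, ridge=self.ridge,
                                  nperseg=self.nperseg, overlap=self.overlap,
                                  band=self.band)

    def fit(self, X=None, y=None) -> "ConnectivityFeaturizer":
        X = np.asarray(X) if X is not None else None
        if X is not None and X.ndim == 3:
            self.feature_names_ = feature_names(X.shape[1])
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ConfigError("expected (n_trials, n_channels, n_samples)")
        cfg = self._config()
        out = np.empty((X.shape[0], n_features(X.shape[1])))
        for r in range(X.shape[0]):
            cs = ConnectivitySet(
                corr=pearson_matrix(X[r]),
                pcorr=partial_corr_matrix(X[r], ridge=cfg.ridge),
                coh=coherence_matrix(X[r], fs=self.fs, config=cfg),
                gc=granger_matrix(X[r], p=cfg.gc_order))
            out[r] = vectorise(cs).values
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(getattr(self, "feature_names_", feature_names(24)))
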