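"""Connectivity estimators: oracle equivalences, direction recovery,
vectorisation layout and invariances."""

import numpy as np
import pytest

import painconn as pc
from painconn.cohort import ConfigError
from painconn.connectivity import (ConnectivityConfig, coherence_matrix,
                                   feature_names, granger_matrix, n_features,
                                   partial_corr_matrix, pearson_matrix,
                                   vectorise)


# ---------------------------------------------------------------------------
# Pearson correlation

def test_pearson_identical_and_anticorrelated_channels(rng):
    x = rng.normal(0, 1, 200)
    trial = np.vstack([x, x, -x + 3.0])
    r = pearson_matrix(trial)
    assert r[0, 1] == pytest.approx(1.0)
    assert r[0, 2] == pytest.approx(-1.0)
    assert np.allclose(np.diag(r), 1.0)


def test_pearson_matches_direct_covariance_formula():
    trial = np.array([[1.0, 2.0, 4.0, 3.0, 5.0],
                      [2.0, 1.0, 3.0, 5.0, 4.0],
                      [0.5, 2.5, 1.5, 4.5, 3.0]])
    r = pearson_matrix(trial)
    for i in range(3):
        for j in range(3):
            xi, xj = trial[i] - trial[i].mean(), trial[j] - trial[j].mean()
            expect = (xi * xj).mean() / (trial[i].std() * trial[j].std())
            assert r[i, j] == pytest.approx(expect, abs=1e-12)


def test_pearson_zero_variance_channel_errors():
    trial = np.vstack([np.ones(50), np.arange(50.0)])
    with pytest.raises(ConfigError, match="1"):
        pearson_matrix(trial)


# ---------------------------------------------------------------------------
# Partial correlation

def test_partial_corr_two_channels_equals_pearson(rng):
    trial = rng.normal(0, 1, (2, 400))
    rho = partial_corr_matrix(trial, ridge=0.0)
    r = pearson_matrix(trial)
    assert rho[0, 1] == pytest.approx(r[0, 1], abs=1e-10)


def test_partial_corr_suppresses_indirect_coupling(rng):
    """In a chain x1 -> x2 -> x3 the direct pairwise correlation r13 is
    strong, but controlling for x2 removes it."""
    n = 5000
    x1 = rng.normal(0, 1, n)
    x2 = 0.9 * x1 + rng.normal(0, 0.5, n)
    x3 = 0.9 * x2 + rng.normal(0, 0.5, n)
    trial = np.vstack([x1, x2, x3])
    rho = partial_corr_matrix(trial, ridge=0.0)
    r = pearson_matrix(trial)
    assert abs(r[0, 2]) > 0.5
    assert abs(rho[0, 2]) < 0.1


def _pcorr_by_residualisation(trial: np.ndarray) -> np.ndarray:
    """Brute-force oracle: correlate OLS residuals of x_i and x_j after
    regressing each on all remaining channels (plus intercept)."""
    n = trial.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            others = [k for k in range(n) if k not in (i, j)]
            design = np.column_stack([trial[others].T,
                                      np.ones(trial.shape[1])])
            ri = trial[i] - design @ np.linalg.lstsq(design, trial[i],
                                                     rcond=None)[0]
            rj = trial[j] - design @ np.linalg.lstsq(design, trial[j],
                                                     rcond=None)[0]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


def test_partial_corr_matches_residualisation_oracle(rng):
    for _ in range(10):
        trial = rng.normal(0, 1, (5, 120))
        rho = partial_corr_matrix(trial, ridge=0.0)
        oracle = _pcorr_by_residualisation(trial)
        assert np.allclose(rho, oracle, atol=1e-8)


# ---------------------------------------------------------------------------
# Coherence

def test_coherence_identical_channels_is_one(rng):
    x = rng.normal(0, 1, 2000)
    coh = coherence_matrix(np.vstack([x, x]), fs=50.0)
    assert coh[0, 1] == pytest.approx(1.0, abs=1e-9)


def test_coherence_blind_to_pure_delay():
    fs, n = 50.0, 5000
    t = np.arange(n + 20) / fs
    base = (np.sin(2 * np.pi * (fs / 128) * t)          # exactly bin 1
            + 0.5 * np.sin(2 * np.pi * 2 * (fs / 128) * t))
    x, y = base[:n], base[10:n + 10]                     # 0.2 s delay
    coh = coherence_matrix(np.vstack([x, y]), fs=fs)
    assert coh[0, 1] > 0.95


def test_coherence_independent_noise_decreases_with_segments(rng):
    def mean_coh(n):
        vals = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            coh = coherence_matrix(r.normal(0, 1, (2, n)), fs=50.0)
            vals.append(coh[0, 1])
        return np.mean(vals)

    short, long = mean_coh(1000), mean_coh(8000)
    assert long < short < 0.3


def test_coherence_single_segment_errors(rng):
    with pytest.raises(ConfigError, match="segment"):
        coherence_matrix(rng.normal(0, 1, (2, 128)), fs=50.0,
                         config=ConnectivityConfig(nperseg=128))


def test_coherence_bounds_and_symmetry(rng):
    coh = coherence_matrix(rng.normal(0, 1, (6, 500)), fs=50.0)
    assert np.allclose(coh, coh.T)
    assert coh.min() >= 0.0 and coh.max() <= 1.0


# ---------------------------------------------------------------------------
# Granger causality

def test_granger_null_on_independent_noise():
    vals = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        gc = granger_matrix(r.normal(0, 1, (2, 500)), p=2)
        vals.extend([gc[0, 1], gc[1, 0]])
    assert np.mean(vals) < 0.05


def test_granger_recovers_planted_direction():
    """x_i(t) = 0.8 x_j(t-1) + noise: the j -> i entry dominates."""
    wins = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        n = 500
        xj = r.normal(0, 1, n)
        xi = np.zeros(n)
        for t in range(1, n):
            xi[t] = 0.8 * xj[t - 1] + r.normal()
        gc = granger_matrix(np.vstack([xi, xj]), p=1)
        wins += gc[0, 1] > gc[1, 0]             # target row, source column
    assert wins >= 19


def test_granger_deterministic_lag_construction(rng):
    """x_j equal to x_i advanced by one sample: gc(j->i) explodes, the
    reverse stays near zero at p = 1."""
    noise = rng.normal(0, 1, 501)
    xi, xj = noise[:-1], noise[1:]              # xi(t) = xj(t-1)
    gc = granger_matrix(np.vstack([xi, xj]), p=1)
    assert gc[0, 1] > 5.0
    assert gc[1, 0] < 0.05


def test_granger_invalid_inputs():
    with pytest.raises(ConfigError):
        granger_matrix(np.random.default_rng(0).normal(0, 1, (2, 500)), p=0)
    with pytest.raises(ConfigError, match="short"):
        granger_matrix(np.random.default_rng(0).normal(0, 1, (2, 8)), p=3)


# ---------------------------------------------------------------------------
# Vectorisation

def test_feature_count_law():
    assert n_features(24) == 1380
    assert n_features(3) == 15
    for n in (2, 5, 10, 24):
        assert len(feature_names(n)) == n_features(n)


def test_feature_names_unique_and_canonical():
    names = feature_names(24)
    assert len(set(names)) == 1380
    assert names[0] == "corr_ch01_ch02"
    assert "granger_ch05_to_ch20" in names


def test_vectorise_small_set_and_gc_orientation(rng):
    trial = rng.normal(0, 1, (3, 600))
    cs = pc.compute_connectivity(
        pc.Trial(subject_id="s", modality="hbo2", label="NP", data=trial))
    fv = vectorise(cs)
    assert fv.values.size == 15
    # directed features read gc[target, source] at name source_to_target
    idx = fv.names.index("granger_ch01_to_ch03")
    assert fv.values[idx] == cs.gc[2, 0]
    idx = fv.names.index("corr_ch02_ch03")
    assert fv.values[idx] == cs.corr[1, 2]


def test_vectorise_rejects_asymmetric_symmetric_measure(rng):
    trial = rng.normal(0, 1, (3, 600))
    cs = pc.compute_connectivity(
        pc.Trial(subject_id="s", modality="hbo2", label="NP", data=trial))
    cs.corr = cs.corr.copy()
    cs.corr[0, 1] += 1e-3
    with pytest.raises(ConfigError, match="asymmetric"):
        vectorise(cs)


def test_measures_invariant_to_channel_affine_rescaling(rng):
    """Per-channel affine maps (as min-max scaling applies) leave all four
    measures unchanged."""
    x = rng.normal(0, 1, (4, 600))
    a = rng.uniform(0.5, 3.0, size=4)[:, None]
    b = rng.uniform(-2, 2, size=4)[:, None]
    y = a * x + b
    assert np.allclose(pearson_matrix(x), pearson_matrix(y), atol=1e-9)
    assert np.allclose(partial_corr_matrix(x, 0.0),
                       partial_corr_matrix(y, 0.0), atol=1e-7)
    assert np.allclose(coherence_matrix(x, 50.0), coherence_matrix(y, 50.0),
                       atol=1e-9)
    assert np.allclose(granger_matrix(x), granger_matrix(y), atol=1e-6)


# ---------------------------------------------------------------------------
# Dataset assembly

def test_features_table_shape_and_row_independence(small_trials, hbo2_table):
    n_hbo2 = sum(t.modality == "hbo2" for t in small_trials)
    assert hbo2_table.shape == (n_hbo2, 1382)
    # permuting trial order permutes rows only
    sub = [t for t in small_trials if t.modality == "hbo2"][:6]
    t1 = pc.features_for_dataset(sub, "hbo2")
    t2 = pc.features_for_dataset(sub[::-1], "hbo2")
    assert np.allclose(t1.iloc[::-1, 2:].to_numpy(), t2.iloc[:, 2:].to_numpy())


def test_featurizer_matches_functional_api(small_trials):
    sub = [t for t in small_trials if t.modality == "hbo2"][:3]
    stacked = np.stack([t.data for t in sub])
    feat = pc.ConnectivityFeaturizer().fit(stacked)
    X = feat.transform(stacked)
    table = pc.features_for_dataset(sub, "hbo2")
    assert np.allclose(X, table.iloc[:, 2:].to_numpy())
    assert list(feat.get_feature_names_out()) == list(table.columns[2:])


def test_featurizer_sklearn_params_roundtrip():
    feat = pc.ConnectivityFeaturizer(gc_order=3)
    assert feat.get_params()["gc_order"] == 3
    feat.set_params(ridge=1e-4)
    assert feat.get_params()["ridge"] == 1e-4
    with pytest.raises(ValueError):
        feat.set_params(bogus=1)
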