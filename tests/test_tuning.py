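"""Tuning maps, constrained fits, permutation significance, and
population distributions of optima."""

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from contourcode import tuning
from contourcode.tuning import (TuningCurve, build_tuning_map, cross_tuning,
                                curvature_map_weights, feature_edges,
                                fit_tuning, optimal_distribution,
                                permutation_test_tuning,
                                stimulus_feature_density)


# -- map construction -------------------------------------------------------

def test_constant_response_uniform_map():
    """Constant responses give occupied bins all equal to 1 after
    normalisation."""
    rng = np.random.default_rng(0)
    fv = rng.uniform(0, 1, 200)
    mp = build_tuning_map("closure", fv, np.full(200, 5.0))
    assert np.allclose(mp.normalized[mp.mask], 1.0)


def test_curvature_response_histogram_example():
    """One stimulus with 2 spikes and local curvatures {0.3, 0.7}: the
    response histogram carries mass 2 in each of the two bins."""
    edges = feature_edges("curvature")
    W, counts = curvature_map_weights({"s": np.array([0.3, 0.7])}, ["s"],
                                      edges)
    hist = W @ np.array([2.0])
    occupied = np.flatnonzero(hist)
    assert len(occupied) == 2
    np.testing.assert_allclose(hist[occupied], 2.0)
    # the tuning map is the mean: 2 spikes per occupied bin here too
    mp = build_tuning_map("curvature", {"s": np.array([0.3, 0.7])},
                          [2.0], stimulus_order=["s"])
    np.testing.assert_allclose(mp.values[occupied], 2.0)


def test_map_peak_recovers_generating_peak():
    """Responses proportional to a Gaussian of closure peak in the
    generating bin."""
    rng = np.random.default_rng(1)
    fv = rng.uniform(0, 1, 400)
    resp = np.exp(-((fv - 0.62) ** 2) / 0.2**2)
    mp = build_tuning_map("closure", fv, resp)
    peak_bin = np.argmax(mp.normalized)
    assert mp.edges[peak_bin] <= 0.62 <= mp.edges[peak_bin + 1]


def test_normalization_idempotent():
    rng = np.random.default_rng(2)
    fv = rng.uniform(0, 1, 100)
    mp = build_tuning_map("closure", fv, rng.poisson(5, 100).astype(float))
    once = mp.normalized
    again = build_tuning_map("closure", fv, once[
        np.clip(np.digitize(fv, mp.edges) - 1, 0, 9)]).normalized
    np.testing.assert_allclose(np.sort(np.unique(once / once.max())),
                               np.sort(np.unique(once)), atol=1e-12)
    assert once.max() == pytest.approx(1.0)
    assert again.max() == pytest.approx(1.0)


# -- fitting ----------------------------------------------------------------

def test_gaussian_fit_noiseless_recovery():
    """Exact map from a = 0.8, b = 0.5, c = 0.3 recovers the parameters to
    1e-3; strength = a/c."""
    x = np.linspace(0.05, 0.95, 10)
    y = 0.8 * np.exp(-((x - 0.5) ** 2) / 0.3**2)
    est = TuningCurve(family="gaussian").fit(x, y)
    assert est.params_["a"] == pytest.approx(0.8, abs=1e-3)
    assert est.params_["b"] == pytest.approx(0.5, abs=1e-3)
    assert est.params_["c"] == pytest.approx(0.3, abs=1e-3)
    assert est.strength_ == pytest.approx(0.8 / 0.3, rel=1e-2)


def test_cosine_fit_noiseless_recovery():
    """Exact curvature map from a = 0.4, c = 0.2, d = 0.5 recovers the
    parameters to 1e-3."""
    x = np.linspace(-0.95, 0.95, 20)
    y = 0.4 * np.cos(x - 0.2) + 0.5
    est = TuningCurve(family="cosine_curvature").fit(x, y)
    assert est.params_["a"] == pytest.approx(0.4, abs=1e-3)
    assert est.params_["c"] == pytest.approx(0.2, abs=1e-3)
    assert est.params_["d"] == pytest.approx(0.5, abs=1e-3)
    assert est.strength_ == pytest.approx(0.4, abs=1e-3)


def test_orientation_fit_constrained():
    x = np.radians(np.linspace(5, 175, 18))
    y = 0.6 * np.cos(x - 1.1) + 0.3
    y = np.clip(y, 0, 1)
    est = TuningCurve(family="cosine_orientation").fit(x, y)
    assert 0 <= est.params_["a"] <= 1
    assert 0 <= est.params_["c"] <= np.pi
    assert 0 <= est.params_["d"] <= 1
    assert est.params_["c"] == pytest.approx(1.1, abs=0.05)


def test_flat_map_low_strength():
    """A flat map yields a weaker Gaussian strength than a tuned map on the
    same bins (degenerate case)."""
    x = np.linspace(0.05, 0.95, 10)
    flat = TuningCurve(family="gaussian").fit(x, np.ones_like(x))
    tuned = TuningCurve(family="gaussian").fit(
        x, np.exp(-((x - 0.5) ** 2) / 0.15**2))
    assert flat.strength_ <= tuned.strength_


def test_fit_tuning_optimal_and_requirements():
    rng = np.random.default_rng(3)
    fv = rng.uniform(0, 1, 300)
    resp = 4 * np.exp(-((fv - 0.7) ** 2) / 0.2**2) + 0.5
    mp = build_tuning_map("closure", fv, resp)
    fit = fit_tuning(mp)
    assert fit.optimal == pytest.approx(0.7, abs=0.05)
    with pytest.raises(ValueError):
        TuningCurve().fit(np.array([0.1, 0.5, 0.9]), np.ones(3))


def test_curvature_optimal_in_range():
    """The cosine-curvature optimum is the in-range argmax even when the
    phase peak would fall outside [-1, 1]."""
    x = np.linspace(-0.95, 0.95, 20)
    y = -0.3 * np.cos(x - 0.0) + 0.6          # trough at 0, maxima at edges
    mp_like = tuning.TuningMap(feature="curvature",
                               edges=feature_edges("curvature"),
                               values=y, normalized=y / y.max(),
                               counts=np.ones(20), mask=np.ones(20, bool))
    fit = fit_tuning(mp_like)
    assert abs(fit.optimal) > 0.9


def test_estimator_clone_roundtrip():
    est = TuningCurve(family="cosine_curvature", n_starts=5)
    est2 = clone(est)
    assert est2.get_params() == est.get_params()


# -- permutation significance -----------------------------------------------

def test_permutation_strongly_tuned_significant():
    rng = np.random.default_rng(4)
    fv = rng.uniform(0, 1, 300)
    resp = 8 * np.exp(-((fv - 0.5) ** 2) / 0.25**2) + 0.5
    res = permutation_test_tuning("closure", fv, resp, n_perm=500, seed=0)
    assert res.significant
    assert res.p <= 0.01


def test_permutation_reproducible():
    rng = np.random.default_rng(5)
    fv = rng.uniform(0, 1, 120)
    resp = rng.poisson(4, 120).astype(float)
    a = permutation_test_tuning("closure", fv, resp, n_perm=300, seed=42)
    b = permutation_test_tuning("closure", fv, resp, n_perm=300, seed=42)
    assert a.p == b.p and a.significant == b.significant


def test_permutation_pvalues_superuniform():
    """Null p-values are (super-)uniform: KS test on 200 feature-blind
    Poisson neurons at n_perm = 200."""
    rng = np.random.default_rng(6)
    fv = rng.uniform(0, 1, 150)
    ps = []
    for i in range(200):
        resp = rng.poisson(5, 150).astype(float)
        ps.append(permutation_test_tuning("closure", fv, resp, n_perm=200,
                                          seed=100 + i).p)
    # permutation p-values stochastically dominate uniform under the null
    stat = stats.kstest(ps, "uniform", alternative="greater").pvalue
    assert stat > 0.01


def test_permutation_needs_occupied_bins():
    with pytest.raises(ValueError):
        permutation_test_tuning("closure", np.array([0.5] * 30),
                                np.ones(30), n_perm=50, seed=0)


# -- distributions of optima ------------------------------------------------

def test_optimal_distribution_uniform_density():
    edges = np.linspace(0, 1, 11)
    res = optimal_distribution([0.15, 0.35, 0.35], edges, np.full(10, 0.1))
    np.testing.assert_allclose(res.normalized * 0.1, res.raw)


def test_optimal_distribution_density_compensation():
    """Twice the stimulus density at the optimum's bin halves its
    normalised value relative to a unit-density bin."""
    edges = np.linspace(0, 1, 11)
    density = np.ones(10)
    density[9] = 2.0
    res = optimal_distribution([0.95, 0.95, 0.15], edges, density)
    assert res.normalized[9] == pytest.approx(res.raw[9] / 2.0)
    assert res.normalized[1] == pytest.approx(res.raw[1])


def test_optimal_distribution_empty_and_flagged():
    edges = np.linspace(0, 1, 11)
    res = optimal_distribution([], edges, np.ones(10))
    assert res.raw.sum() == 0 and not res.flagged
    density = np.ones(10)
    density[3] = 0.0
    res = optimal_distribution([0.35], edges, density)
    assert res.flagged and np.isnan(res.normalized[3])


def test_cross_tuning_single_neuron_and_oracle():
    ct = cross_tuning([0.85], [0.95], [0.4, 0.5], [0.0, 0.1])
    assert ct.neuron_counts.sum() == 1
    assert ct.neuron_counts[8, 19] == 1
    # ratio equals brute-force division on a random small case
    rng = np.random.default_rng(7)
    clos_opt = rng.uniform(0, 1, 25)
    curv_opt = rng.uniform(-1, 1, 25)
    sc = rng.uniform(0, 1, 300)
    sk = rng.uniform(-1, 1, 300)
    ct = cross_tuning(clos_opt, curv_opt, sc, sk)
    counts, _, _ = np.histogram2d(clos_opt, curv_opt,
                                  bins=[ct.closure_edges,
                                        ct.curvature_edges])
    dens, _, _ = np.histogram2d(sc, sk, bins=[ct.closure_edges,
                                              ct.curvature_edges])
    dens = dens / dens.sum()
    expect = np.where(dens > 0, counts / np.where(dens > 0, dens, 1),
                      np.nan)
    np.testing.assert_allclose(ct.normalized[ct.valid], expect[ct.valid],
                               atol=1e-9)


def test_stimulus_density_helper():
    d = stimulus_feature_density([0.05, 0.15, 0.15, np.nan],
                                 np.linspace(0, 1, 11))
    assert d.sum() == pytest.approx(1.0)
    assert d[1] == pytest.approx(2 / 3)
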