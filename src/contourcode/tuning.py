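"""Tuning maps, constrained tuning-curve fits, and permutation significance.

A tuning map is a histogram of mean spike counts per feature bin,
normalised by its maximum.  Closure and symmetry maps are fitted with a
constrained Gaussian

    f(x) = a * exp(-(x - b)^2 / c^2),      0 <= a, b, c <= 1

whose tuning strength is a/c; curvature and orientation maps with a cosine

    f(t) = a * cos(b*t - c) + d,           b fixed to 1

(curvature: -1 <= c <= 1, a and d free; orientation: t in radians,
0 <= a <= 1, 0 <= c <= pi, 0 <= d <= 1) whose strength is a.

Significance of tuning is a permutation test on the fit error: the
stimulus–response assignment is shuffled, the map rebuilt and refitted,
and the original map is significant iff its error is below the bottom 1%
of 1,000 shuffled errors.  To keep the test fair *and* affordable, the
error used in the test comes from a deterministic dense-grid fitter with
closed-form amplitude, applied identically to the original and to every
shuffled map; the parameters reported for the original map are polished
by bounded least squares from the best grid starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

# family registry: per-feature fitting family, domain, default bin count
FEATURE_SPECS = {
    "closure": {"family": "gaussian", "range": (0.0, 1.0), "bins": 10},
    "symmetry": {"family": "gaussian", "range": (0.0, 1.0), "bins": 10},
    "curvature": {"family": "cosine_curvature", "range": (-1.0, 1.0),
                  "bins": 20},
    "orientation": {"family": "cosine_orientation", "range": (0.0, 180.0),
                    "bins": 18},
}


def feature_edges(feature: str, bins: int | None = None) -> np.ndarray:
    spec = FEATURE_SPECS[feature]
    return np.linspace(*spec["range"], (bins or spec["bins"]) + 1)


# --------------------------------------------------------------------------
# tuning maps
# --------------------------------------------------------------------------

@dataclass
class TuningMap:
    """Histogram of (response-weighted) mean spikes per feature bin."""

    feature: str
    edges: np.ndarray
    values: np.ndarray        # raw per-bin values (mean spikes / weighted)
    normalized: np.ndarray    # values / max (max = 1 unless all-zero)
    counts: np.ndarray        # data points per bin
    mask: np.ndarray          # True where the bin is occupied

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_occupied(self) -> int:
        return int(self.mask.sum())


def _normalize(values: np.ndarray) -> np.ndarray:
    m = values.max() if values.size else 0.0
    return values / m if m > 0 else np.zeros_like(values)


def scalar_map_weights(feature_values: np.ndarray,
                       edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear operator W (bins x stimuli) with  map = W @ responses  being
    the per-bin *mean* response, plus the per-bin counts."""
    fv = np.asarray(feature_values, dtype=float)
    nb = len(edges) - 1
    idx = np.clip(np.digitize(fv, edges) - 1, 0, nb - 1)
    W = np.zeros((nb, len(fv)))
    W[idx, np.arange(len(fv))] = 1.0
    counts = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(counts[:, None] > 0, W / counts[:, None], 0.0)
    return W, counts


def curvature_map_weights(curvature_lists: dict, stimulus_order: list,
                          edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear operator for the response-weighted local-curvature histogram.

    ``W[b, s]`` is the number of local curvatures of stimulus ``s`` in bin
    ``b``; ``W @ responses`` sums the response-weighted histograms across
    stimuli (each stimulus's curvature histogram multiplied by its
    response, then added).  The tuning map divides this response
    histogram by the per-bin counts — the mean number of spikes per
    curvature bin — via :func:`mean_map_weights`."""
    nb = len(edges) - 1
    W = np.zeros((nb, len(stimulus_order)))
    for j, sid in enumerate(stimulus_order):
        vals = np.asarray(curvature_lists.get(sid, ()), dtype=float)
        if vals.size:
            idx = np.clip(np.digitize(vals, edges) - 1, 0, nb - 1)
            np.add.at(W[:, j], idx, 1.0)
    counts = W.sum(axis=1)
    return W, counts


def mean_map_weights(W: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Turn a count-weighted operator into a per-bin-mean operator."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts[:, None] > 0, W / counts[:, None], 0.0)


def build_tuning_map(feature: str, feature_values, responses,
                     edges: np.ndarray | None = None,
                     stimulus_order: list | None = None) -> TuningMap:
    """Build the tuning map of one neuron for one feature.

    For scalar features ``feature_values`` is one value per stimulus
    (aligned with ``responses``, the trial-averaged spike counts); for
    curvature it is a dict stimulus_id -> array of local curvatures, with
    ``stimulus_order`` giving the alignment of ``responses``.  The
    curvature map accumulates each stimulus's response-weighted
    local-curvature histogram across stimuli and divides by the pooled
    counts, yielding the mean spikes per curvature bin.
    """
    if edges is None:
        edges = feature_edges(feature)
    responses = np.asarray(responses, dtype=float)
    if feature == "curvature":
        if stimulus_order is None:
            raise ValueError("curvature maps need stimulus_order")
        Wc, counts = curvature_map_weights(feature_values, stimulus_order,
                                           edges)
        W = mean_map_weights(Wc, counts)
    else:
        fv = np.asarray(feature_values, dtype=float)
        ok = ~np.isnan(fv)
        if not ok.any():
            raise ValueError(f"all {feature} values missing for this neuron")
        W, counts = scalar_map_weights(fv[ok], edges)
        responses = responses[ok]
    values = W @ responses
    return TuningMap(feature=feature, edges=np.asarray(edges, float),
                     values=values, normalized=_normalize(values),
                     counts=counts, mask=counts > 0)


# --------------------------------------------------------------------------
# grid fitters (deterministic, closed-form amplitude) — vectorised over maps
# --------------------------------------------------------------------------

def _gaussian_grid(x: np.ndarray, nb: int = 25, nc: int = 24):
    b = np.linspace(0.0, 1.0, nb)
    c = np.linspace(0.04, 1.0, nc)
    B, C = np.meshgrid(b, c, indexing="ij")
    M = np.exp(-((x[None, None, :] - B[..., None]) ** 2) / C[..., None] ** 2)
    return M.reshape(-1, len(x)), B.ravel(), C.ravel()


def _grid_fit_gaussian(Y: np.ndarray, x: np.ndarray):
    """Best grid (a, b, c) and rmse per map.  Y is (k, nx), rows = maps."""
    M, Bs, Cs = _gaussian_grid(x)
    mm = np.einsum("mi,mi->m", M, M)
    G = Y @ M.T                                   # (k, m)
    a = np.clip(G / mm[None, :], 0.0, 1.0)
    yy = np.einsum("ki,ki->k", Y, Y)
    sse = yy[:, None] - 2.0 * a * G + a**2 * mm[None, :]
    rmse = np.sqrt(np.maximum(sse, 0.0) / len(x))
    best = np.argmin(rmse, axis=1)
    k = np.arange(len(Y))
    params = np.stack([a[k, best], Bs[best], Cs[best]], axis=1)
    return params, rmse[k, best], rmse


def _cosine_grid(x: np.ndarray, c_lo: float, c_hi: float, nc: int = 49):
    c = np.linspace(c_lo, c_hi, nc)
    M = np.cos(x[None, :] - c[:, None])           # (nc, nx)
    return M, c


def _grid_fit_cosine(Y: np.ndarray, x: np.ndarray, c_lo: float, c_hi: float,
                     a_bounds=None, d_bounds=None, nc: int = 49):
    """Best grid (a, c, d) and rmse per map for f = a*cos(x - c) + d.

    For each phase on the grid the (a, d) pair is the exact least-squares
    solution; box constraints are enforced by a few rounds of clipped
    coordinate refinement (deterministic).
    """
    M, cs = _cosine_grid(x, c_lo, c_hi, nc)
    n = float(len(x))
    Sm = M.sum(axis=1)                            # (nc,)
    Smm = np.einsum("ci,ci->c", M, M)
    Sy = Y.sum(axis=1)                            # (k,)
    Syy = np.einsum("ki,ki->k", Y, Y)
    Smy = Y @ M.T                                 # (k, nc)
    denom = n * Smm - Sm**2
    safe = np.where(np.abs(denom) > 1e-12, denom, 1.0)
    a = (n * Smy - Sy[:, None] * Sm[None, :]) / safe[None, :]
    a = np.where(np.abs(denom)[None, :] > 1e-12, a, 0.0)
    d = (Sy[:, None] - a * Sm[None, :]) / n
    if a_bounds is not None or d_bounds is not None:
        for _ in range(4):
            if a_bounds is not None:
                a = np.clip(a, *a_bounds)
            d = (Sy[:, None] - a * Sm[None, :]) / n
            if d_bounds is not None:
                d = np.clip(d, *d_bounds)
            with np.errstate(invalid="ignore", divide="ignore"):
                a_new = (Smy - d * Sm[None, :]) / Smm[None, :]
            a = np.where(Smm[None, :] > 1e-12, a_new, a)
        if a_bounds is not None:
            a = np.clip(a, *a_bounds)
        d = np.clip((Sy[:, None] - a * Sm[None, :]) / n,
                    *(d_bounds or (-np.inf, np.inf)))
    sse = (Syy[:, None] + a**2 * Smm[None, :] + n * d**2
           + 2 * a * d * Sm[None, :] - 2 * a * Smy - 2 * d * Sy[:, None])
    rmse = np.sqrt(np.maximum(sse, 0.0) / n)
    best = np.argmin(rmse, axis=1)
    k = np.arange(len(Y))
    params = np.stack([a[k, best], cs[best], d[k, best]], axis=1)
    return params, rmse[k, best], rmse


def grid_fit(Y: np.ndarray, x: np.ndarray, family: str):
    """Deterministic grid fit of one or many maps; returns (params, rmse)."""
    Y = np.atleast_2d(Y)
    if family == "gaussian":
        p, r, _ = _grid_fit_gaussian(Y, x)
    elif family == "cosine_curvature":
        p, r, _ = _grid_fit_cosine(Y, x, -1.0, 1.0)
    elif family == "cosine_orientation":
        p, r, _ = _grid_fit_cosine(Y, x, 0.0, np.pi,
                                   a_bounds=(0.0, 1.0), d_bounds=(0.0, 1.0))
    else:
        raise ValueError(f"unknown family {family!r}")
    return p, r


# --------------------------------------------------------------------------
# reported fit (grid starts + bounded least-squares polish)
# --------------------------------------------------------------------------

@dataclass
class TuningFit:
    """A fitted tuning curve with strength, optimum and significance."""

    feature: str
    family: str
    params: dict
    strength: float
    rmse: float
    optimal: float
    n_occupied: int
    significant: bool | None = None
    p_perm: float | None = None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family == "gaussian":
            return p["a"] * np.exp(-((x - p["b"]) ** 2) / p["c"] ** 2)
        return p["a"] * np.cos(x - p["c"]) + p["d"]


def _polish(x, y, family, starts, n_starts=10):
    """Bounded least-squares refinement from the best grid starts.

    Ties are broken by lowest rmse, then lowest amplitude a.
    """
    if family == "gaussian":
        lo, hi = [0.0, 0.0, 1e-6], [1.0, 1.0, 1.0]

        def resid(p):
            return p[0] * np.exp(-((x - p[1]) ** 2) / p[2] ** 2) - y
    elif family == "cosine_curvature":
        lo, hi = [-np.inf, -1.0, -np.inf], [np.inf, 1.0, np.inf]

        def resid(p):
            return p[0] * np.cos(x - p[1]) + p[2] - y
    else:  # cosine_orientation
        lo, hi = [0.0, 0.0, 0.0], [1.0, np.pi, 1.0]

        def resid(p):
            return p[0] * np.cos(x - p[1]) + p[2] - y

    best = None
    for p0 in starts[:n_starts]:
        p0 = np.clip(p0, lo, hi)
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-12,
                                ftol=1e-12, gtol=1e-12)
        except ValueError:
            continue
        rmse = float(np.sqrt(np.mean(sol.fun**2)))
        key = (round(rmse, 12), round(abs(sol.x[0]), 12))
        if best is None or key < best[0]:
            best = (key, sol.x, rmse)
    if best is None:  # pragma: no cover - grid start always valid
        raise RuntimeError("tuning fit failed from every start")
    return best[1], best[2]


def _grid_starts(Y_row, x, family, n=10):
    """Top-n grid points (by rmse) to seed the polish."""
    Y = Y_row[None, :]
    if family == "gaussian":
        M, Bs, Cs = _gaussian_grid(x)
        mm = np.einsum("mi,mi->m", M, M)
        G = (Y @ M.T)[0]
        a = np.clip(G / mm, 0.0, 1.0)
        sse = np.einsum("i,i->", Y_row, Y_row) - 2 * a * G + a**2 * mm
        order = np.argsort(sse, kind="stable")[:n]
        return [np.array([a[i], Bs[i], Cs[i]]) for i in order]
    c_lo, c_hi = ((-1.0, 1.0) if family == "cosine_curvature"
                  else (0.0, np.pi))
    bounds = (((0.0, 1.0), (0.0, 1.0)) if family == "cosine_orientation"
              else (None, None))
    _, _, rmse_all = _grid_fit_cosine(Y, x, c_lo, c_hi,
                                      a_bounds=bounds[0], d_bounds=bounds[1])
    order = np.argsort(rmse_all[0], kind="stable")[:n]
    # rebuild (a, c, d) for the chosen phases
    M, cs = _cosine_grid(x, c_lo, c_hi)
    starts = []
    for i in order:
        m = M[i]
        A = np.stack([m, np.ones_like(m)], axis=1)
        coef, *_ = np.linalg.lstsq(A, Y_row, rcond=None)
        starts.append(np.array([coef[0], cs[i], coef[1]]))
    return starts


def _optimal_from_params(family, params, x_range):
    a, c = params["a"], params["c"]
    if family == "gaussian":
        return float(params["b"])
    if family == "cosine_orientation":
        # peak of a*cos(t-c)+d with a >= 0 is at t = c (radians)
        return float(np.degrees(c)) % 180.0
    # curvature: in-range argmax of the fitted function on [-1, 1]
    xx = np.linspace(x_range[0], x_range[1], 2001)
    f = a * np.cos(xx - c) + params["d"]
    return float(xx[np.argmax(f)])


class TuningCurve(BaseEstimator):
    """Sklearn-style estimator for one constrained tuning-curve fit.

    ``fit(x, y)`` takes occupied-bin centres (already in fitting units:
    radians for orientation) and the normalised map values.
    """

    def __init__(self, family: str = "gaussian", n_starts: int = 10):
        self.family = family
        self.n_starts = n_starts

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 4:
            raise ValueError("need at least 4 occupied bins to fit tuning")
        starts = _grid_starts(y, x, self.family, n=self.n_starts)
        params, rmse = _polish(x, y, self.family, starts,
                               n_starts=self.n_starts)
        if self.family == "gaussian":
            self.params_ = {"a": float(params[0]), "b": float(params[1]),
                            "c": float(params[2])}
            self.strength_ = self.params_["a"] / self.params_["c"]
        else:
            self.params_ = {"a": float(params[0]), "b": 1.0,
                            "c": float(params[1]), "d": float(params[2])}
            self.strength_ = self.params_["a"]
        self.rmse_ = float(rmse)
        return self

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params_
        if self.family == "gaussian":
            return p["a"] * np.exp(-((x - p["b"]) ** 2) / p["c"] ** 2)
        return p["a"] * np.cos(x - p["c"]) + p["d"]


def _fitting_x(map_: TuningMap) -> np.ndarray:
    x = map_.centers[map_.mask]
    if map_.feature == "orientation":
        x = np.radians(x)
    return x


def fit_tuning(map_: TuningMap, family: str | None = None) -> TuningFit:
    """Constrained least-squares fit of a tuning map (missing bins excluded)."""
    family = family or FEATURE_SPECS[map_.feature]["family"]
    x = _fitting_x(map_)
    y = map_.normalized[map_.mask]
    est = TuningCurve(family=family).fit(x, y)
    spec = FEATURE_SPECS.get(map_.feature, {"range": (x.min(), x.max())})
    optimal = _optimal_from_params(family, est.params_, spec["range"])
    return TuningFit(feature=map_.feature, family=family, params=est.params_,
                     strength=float(est.strength_), rmse=est.rmse_,
                     optimal=optimal, n_occupied=len(x))


# --------------------------------------------------------------------------
# permutation significance
# --------------------------------------------------------------------------

@dataclass
class PermutationResult:
    significant: bool
    p: float
    rmse_obs: float
    null_rmses: np.ndarray
    criterion: float  # the bottom-alpha percentile of the null


def permutation_maps(W: np.ndarray, responses: np.ndarray, n_perm: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Original map plus ``n_perm`` maps from shuffled stimulus-response
    assignment, each max-normalised.  Row 0 is the original."""
    resp = np.asarray(responses, dtype=float)
    R = np.empty((n_perm + 1, len(resp)))
    R[0] = resp
    for i in range(1, n_perm + 1):
        R[i] = rng.permutation(resp)
    Y = R @ W.T
    maxima = Y.max(axis=1, keepdims=True)
    np.divide(Y, maxima, out=Y, where=maxima > 0)
    Y[maxima[:, 0] <= 0] = 0.0
    return Y


def permutation_test_tuning(
    feature: str,
    feature_values,
    responses,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    edges: np.ndarray | None = None,
    stimulus_order: list | None = None,
    family: str | None = None,
    shuffle_unit: str = "bins",
) -> PermutationResult:
    """Permutation test of tuning for one neuron and one feature.

    The map is shuffled ``n_perm`` times and refitted; tuning is
    significant iff the original fit error is smaller than the bottom
    ``alpha`` fraction of the shuffled fit errors.  ``p`` is the
    permutation p-value (1 + #{null <= observed}) / (n_perm + 1).
    Identical seeds give identical results.

    ``shuffle_unit="bins"`` (default) permutes the occupied-bin values of
    the map, asking whether the map's *arrangement* is closer to the
    tuning family than chance arrangements of the same values.
    ``shuffle_unit="stimuli"`` instead shuffles the stimulus–response
    assignment and rebuilds the map; because bin means of shuffled
    responses concentrate toward a flat map, that null systematically
    fits *better* than any real map with per-bin noise and the test loses
    essentially all power — it is kept only as a comparison variant.
    """
    if shuffle_unit not in ("bins", "stimuli"):
        raise ValueError(f"unknown shuffle unit {shuffle_unit!r}")
    if edges is None:
        edges = feature_edges(feature)
    family = family or FEATURE_SPECS[feature]["family"]
    responses = np.asarray(responses, dtype=float)
    if feature == "curvature":
        if stimulus_order is None:
            raise ValueError("curvature test needs stimulus_order")
        Wc, counts = curvature_map_weights(feature_values, stimulus_order,
                                           edges)
        W = mean_map_weights(Wc, counts)
    else:
        fv = np.asarray(feature_values, dtype=float)
        ok = ~np.isnan(fv)
        responses = responses[ok]
        W, counts = scalar_map_weights(fv[ok], edges)
    mask = counts > 0
    if mask.sum() < 4:
        raise ValueError("need at least 4 occupied bins for the "
                         "permutation test")
    centers = 0.5 * (np.asarray(edges)[:-1] + np.asarray(edges)[1:])
    x = centers[mask]
    if feature == "orientation":
        x = np.radians(x)

    rng = np.random.default_rng(seed)
    if shuffle_unit == "bins":
        y = _normalize(W[mask] @ responses)
        Y = np.empty((n_perm + 1, len(y)))
        Y[0] = y
        for i in range(1, n_perm + 1):
            Y[i] = rng.permutation(y)
    else:
        Y = permutation_maps(W[mask], responses, n_perm, rng)
    _, rmse = grid_fit(Y, x, family)
    rmse_obs, null = float(rmse[0]), rmse[1:]
    criterion = float(np.percentile(null, 100.0 * alpha))
    p = float((1 + np.count_nonzero(null <= rmse_obs)) / (n_perm + 1))
    return PermutationResult(significant=bool(rmse_obs < criterion), p=p,
                             rmse_obs=rmse_obs, null_rmses=null,
                             criterion=criterion)


# --------------------------------------------------------------------------
# population distributions of optima
# --------------------------------------------------------------------------

@dataclass
class NormalizedHistogram:
    edges: np.ndarray
    raw: np.ndarray
    density: np.ndarray
    normalized: np.ndarray  # raw / density on valid bins, NaN elsewhere
    valid: np.ndarray       # density > 0
    flagged: bool           # a zero-density bin held a nonzero count


def optimal_distribution(optima, edges,
                         stimulus_density) -> NormalizedHistogram:
    """Histogram of tuning optima divided bin-wise by the stimulus feature
    density, compensating the uneven feature content of the stimulus set."""
    edges = np.asarray(edges, dtype=float)
    optima = np.asarray(list(optima), dtype=float)
    density = np.asarray(stimulus_density, dtype=float)
    if optima.size:
        raw, _ = np.histogram(optima, bins=edges)
    else:
        raw = np.zeros(len(edges) - 1, dtype=int)
    raw = raw.astype(float)
    valid = density > 0
    normalized = np.full_like(raw, np.nan)
    normalized[valid] = raw[valid] / density[valid]
    flagged = bool(np.any(~valid & (raw > 0)))
    return NormalizedHistogram(edges=edges, raw=raw, density=density,
                               normalized=normalized, valid=valid,
                               flagged=flagged)


@dataclass
class CrossTuning:
    closure_edges: np.ndarray
    curvature_edges: np.ndarray
    neuron_counts: np.ndarray     # 2-D histogram of (opt closure, opt curv)
    stimulus_density: np.ndarray  # joint feature density over stimuli
    normalized: np.ndarray        # counts / density (NaN where density = 0)
    valid: np.ndarray
    flagged: bool


def stimulus_feature_density(values, edges, normalize: bool = True):
    """Per-bin density of a feature across the stimulus set.  For curvature
    pass the pooled local-curvature values of all stimuli."""
    vals = np.asarray(list(values), dtype=float)
    vals = vals[~np.isnan(vals)]
    h, _ = np.histogram(vals, bins=np.asarray(edges, float))
    h = h.astype(float)
    if normalize and h.sum() > 0:
        h = h / h.sum()
    return h


def cross_tuning(closure_optima, curvature_optima,
                 stim_closure, stim_curvature,
                 closure_edges=None, curvature_edges=None) -> CrossTuning:
    """Joint distribution of (optimal closure, optimal curvature) across
    neurons, normalised by the stimulus set's joint feature density.

    ``stim_closure``/``stim_curvature`` are paired per-stimulus values
    (each local curvature paired with its stimulus's closure).
    """
    ce = np.asarray(closure_edges if closure_edges is not None
                    else feature_edges("closure"), float)
    ke = np.asarray(curvature_edges if curvature_edges is not None
                    else feature_edges("curvature"), float)
    counts, _, _ = np.histogram2d(np.asarray(list(closure_optima), float),
                                  np.asarray(list(curvature_optima), float),
                                  bins=[ce, ke])
    dens, _, _ = np.histogram2d(np.asarray(list(stim_closure), float),
                                np.asarray(list(stim_curvature), float),
                                bins=[ce, ke])
    if dens.sum() > 0:
        dens = dens / dens.sum()
    valid = dens > 0
    normalized = np.full_like(counts, np.nan)
    normalized[valid] = counts[valid] / dens[valid]
    flagged = bool(np.any(~valid & (counts > 0)))
    return CrossTuning(closure_edges=ce, curvature_edges=ke,
                       neuron_counts=counts, stimulus_density=dens,
                       normalized=normalized, valid=valid, flagged=flagged)
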