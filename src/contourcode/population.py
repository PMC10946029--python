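"""Population-level representation: normalised response matrix, nonmetric
MDS, natural-vs-silhouette preference, and axis profiles/regressions.

Each neuron's trial-averaged responses are normalised by its maximum
across stimuli; neuron-to-neuron dissimilarity is the Euclidean distance
between the normalised rows (correlation distance available).  The 2-D
embedding is nonmetric MDS minimising Kruskal's Stress-1 over random
restarts.  Axis structure is read out by equal-count grouping, 30-neuron
moving windows with moving-average smoothing, and per-neuron OLS
regressions on the axis coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.manifold import MDS


# --------------------------------------------------------------------------
# response matrix
# --------------------------------------------------------------------------

@dataclass
class ResponseMatrix:
    """Neurons x stimuli matrix of row-max-normalised responses."""

    values: pd.DataFrame          # rows = neurons, columns = stimuli
    kinds: pd.Series              # stimulus -> "natural" | "silhouette"
    dropped: list                 # all-zero neurons removed

    @property
    def neurons(self) -> list:
        return list(self.values.index)

    def silhouette_only(self) -> "ResponseMatrix":
        sil = self.kinds.index[self.kinds == "silhouette"]
        sub = self.values.loc[:, [c for c in self.values.columns
                                  if c in set(sil)]]
        return _normalize_matrix(sub, self.kinds.loc[list(sub.columns)])


def _normalize_matrix(matrix: pd.DataFrame, kinds: pd.Series):
    maxima = matrix.max(axis=1)
    dropped = list(matrix.index[maxima <= 0])
    kept = matrix.loc[maxima > 0]
    normalized = kept.div(maxima[maxima > 0], axis=0)
    return ResponseMatrix(values=normalized, kinds=kinds, dropped=dropped)


def build_response_matrix(responses, kinds: dict | pd.Series) -> ResponseMatrix:
    """Trial-average, then row-max-normalise the spike counts.

    ``responses`` is a :class:`~contourcode.io.ResponseTable` (or a tidy
    DataFrame with neuron/stimulus/trial/count columns); ``kinds`` maps
    stimulus id -> kind.  All-zero neurons are dropped (logged in
    ``dropped``).
    """
    df = responses.df if hasattr(responses, "df") else responses
    matrix = df.pivot_table(index="neuron", columns="stimulus",
                            values="count", aggfunc="mean")
    kinds = pd.Series(kinds)
    return _normalize_matrix(matrix, kinds.loc[list(matrix.columns)])


def dissimilarities(matrix: ResponseMatrix,
                    metric: str = "euclidean") -> np.ndarray:
    """Pairwise neuron dissimilarities from the normalised rows."""
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unknown dissimilarity metric {metric!r}")
    return squareform(pdist(matrix.values.to_numpy(float), metric=metric))


# --------------------------------------------------------------------------
# nonmetric MDS
# --------------------------------------------------------------------------

@dataclass
class PopulationMap:
    coords: np.ndarray           # (n, dim), centred at the origin
    stress: float                # Kruskal Stress-1
    seed: int
    n_restarts: int
    neurons: list | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.stress <= 1.0 + 1e-9):
            raise ValueError("Stress-1 must lie in [0, 1]")


class NonmetricEmbedding(BaseEstimator):
    """Sklearn-style wrapper for nonmetric MDS with Stress-1.

    ``fit(D)`` takes a square dissimilarity matrix.  The best embedding
    over ``n_restarts`` random initial configurations is kept, centred at
    the origin, and rotated into its canonical frame: Stress-1 is
    invariant under rotation, so the raw SMACOF coordinates are an
    arbitrary direction pair; the embedding is therefore aligned to its
    principal axes (axis 0 = direction of maximal variance) with a
    deterministic sign convention, which makes repeated runs directly
    comparable.  Any remaining per-axis reflection ambiguity is resolved
    downstream by :func:`orient_axes`.
    """

    def __init__(self, n_components: int = 2, n_restarts: int = 20,
                 seed: int = 0, max_iter: int = 300, eps: float = 1e-7,
                 canonical_frame: bool = True):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.seed = seed
        self.max_iter = max_iter
        self.eps = eps
        self.canonical_frame = canonical_frame

    def _run(self, D: np.ndarray, random_state: int):
        mds = MDS(n_components=self.n_components, metric="precomputed",
                  metric_mds=False, n_init=self.n_restarts,
                  max_iter=self.max_iter, eps=self.eps,
                  random_state=random_state, init="random",
                  normalized_stress=True)
        coords = mds.fit_transform(D)
        return coords - coords.mean(axis=0), float(mds.stress_)

    @staticmethod
    def _canonicalise(coords: np.ndarray) -> np.ndarray:
        # principal-axis rotation (variance-ordered) + deterministic signs
        _, _, vt = np.linalg.svd(coords, full_matrices=False)
        rotated = coords @ vt.T
        for k in range(rotated.shape[1]):
            i = int(np.argmax(np.abs(rotated[:, k])))
            if rotated[i, k] < 0:
                rotated[:, k] = -rotated[:, k]
        return rotated

    def fit(self, D, y=None):
        D = np.asarray(D, dtype=float)
        if D.shape[0] < 3:
            raise ValueError("need at least 3 neurons to embed")
        coords, stress = self._run(D, self.seed)
        if self.canonical_frame:
            coords = self._canonicalise(coords)
        self.embedding_ = coords
        self.stress_ = stress
        return self

    def fit_transform(self, D, y=None):
        return self.fit(D).embedding_


def run_mds(matrix, dim: int = 2, seed: int = 0, n_restarts: int = 20,
            metric: str = "euclidean") -> PopulationMap:
    """Nonmetric MDS of a :class:`ResponseMatrix` (or a precomputed square
    dissimilarity matrix) into ``dim`` dimensions."""
    if isinstance(matrix, ResponseMatrix):
        D = dissimilarities(matrix, metric=metric)
        neurons = matrix.neurons
    else:
        D = np.asarray(matrix, dtype=float)
        neurons = None
    est = NonmetricEmbedding(n_components=dim, n_restarts=n_restarts,
                             seed=seed)
    coords = est.fit_transform(D)
    return PopulationMap(coords=coords, stress=est.stress_, seed=seed,
                         n_restarts=n_restarts, neurons=neurons)


def stress_by_dimension(matrix, dims=(1, 2, 3, 4, 5), seed: int = 0,
                        n_restarts: int = 8) -> pd.Series:
    """Stress-1 of the best embedding per dimension (for a stress plot)."""
    out = {}
    for d in dims:
        out[d] = run_mds(matrix, dim=d, seed=seed,
                         n_restarts=n_restarts).stress
    return pd.Series(out, name="stress")


# --------------------------------------------------------------------------
# natural-vs-silhouette preference
# --------------------------------------------------------------------------

def ns_preference(r_nat: float, r_sil: float) -> float:
    """NSpref = (R_nat - R_sil) / (R_nat + R_sil); NaN when both are 0."""
    if r_nat < 0 or r_sil < 0:
        raise ValueError("mean responses must be non-negative")
    total = r_nat + r_sil
    if total == 0:
        return float("nan")
    return (r_nat - r_sil) / total


def ns_preferences(responses, kinds: dict | pd.Series) -> pd.Series:
    """Per-neuron NS preference from a response table."""
    df = responses.df if hasattr(responses, "df") else responses
    kinds = pd.Series(kinds)
    means = df.pivot_table(index="neuron", columns="stimulus",
                           values="count", aggfunc="mean")
    nat = [s for s in means.columns if kinds.get(s) == "natural"]
    sil = [s for s in means.columns if kinds.get(s) == "silhouette"]
    out = {}
    for nid, row in means.iterrows():
        out[nid] = ns_preference(float(row[nat].mean()),
                                 float(row[sil].mean()))
    return pd.Series(out, name="ns_preference")


# --------------------------------------------------------------------------
# axis structure
# --------------------------------------------------------------------------

def group_equal_count(coords: np.ndarray, axis: int = 0,
                      k: int = 5) -> np.ndarray:
    """Split neurons into ``k`` groups of (near-)equal size along one axis.

    Ties at a boundary are broken by stable input order.  Group sizes
    differ by at most 1.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < k:
        raise ValueError("need at least k neurons")
    order = np.argsort(coords[:, axis], kind="stable")
    labels = np.empty(len(coords), dtype=int)
    for g, chunk in enumerate(np.array_split(order, k)):
        labels[chunk] = g
    return labels


@dataclass
class AxisProfile:
    """Windowed profile of a quantity along one embedding axis."""

    axis: int
    centers: np.ndarray        # mean axis coordinate per window
    raw: np.ndarray            # per-window ratio (binary) or mean (values)
    smoothed: np.ndarray       # moving-average of ``raw``
    dispersion: np.ndarray     # per-window standard deviation
    window: int
    smooth: int


def axis_profile(coords: np.ndarray, axis: int, values,
                 window: int = 30, smooth: int = 15) -> AxisProfile:
    """Moving-window profile of ``values`` along an embedding axis.

    Neurons are sorted by the axis coordinate (stable); every contiguous
    window of ``window`` neurons contributes its mean value (= the ratio
    for binary labels) at the window's mean coordinate.  The profile is
    smoothed by a centred moving average of length ``smooth``
    (``smooth=1`` is the identity).  The dispersion band is the windowed
    standard deviation.
    """
    coords = np.asarray(coords, dtype=float)
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < window:
        raise ValueError(f"need at least {window} neurons for the profile")
    order = np.argsort(coords[:, axis], kind="stable")
    xs = coords[order, axis]
    vs = v[order]
    win = pd.Series(vs).rolling(window)
    raw = win.mean().to_numpy()[window - 1:]
    disp = win.std(ddof=0).to_numpy()[window - 1:]
    centers = pd.Series(xs).rolling(window).mean().to_numpy()[window - 1:]
    smoothed = (pd.Series(raw).rolling(smooth, center=True, min_periods=1)
                .mean().to_numpy())
    return AxisProfile(axis=axis, centers=centers, raw=raw,
                       smoothed=smoothed, dispersion=disp,
                       window=window, smooth=smooth)


@dataclass
class RegressionResult:
    r2: float
    r: float
    p: float
    slope: float
    intercept: float
    ok: bool


def regress_axis(values, coords: np.ndarray, axis: int) -> RegressionResult:
    """OLS of per-neuron values on the axis coordinate: R^2, R, p."""
    coords = np.asarray(coords, dtype=float)
    v = np.asarray(values, dtype=float)
    x = coords[:, axis]
    if len(v) < 3:
        raise ValueError("need at least 3 neurons to regress")
    if np.ptp(v) == 0 or np.ptp(x) == 0:
        return RegressionResult(r2=float("nan"), r=float("nan"),
                                p=float("nan"), slope=0.0,
                                intercept=float(np.mean(v)), ok=False)
    res = stats.linregress(x, v)
    return RegressionResult(r2=float(res.rvalue**2), r=float(res.rvalue),
                            p=float(res.pvalue), slope=float(res.slope),
                            intercept=float(res.intercept), ok=True)


def orient_axes(coords: np.ndarray, primary_values=None,
                secondary_values=None) -> np.ndarray:
    """Flip axis signs so the regression slopes of interest are positive.

    Nonmetric MDS axes have no canonical sign; orienting them to the
    quantity each axis is read against removes the reflection ambiguity.
    """
    coords = np.asarray(coords, dtype=float).copy()
    for axis, vals in ((0, primary_values), (1, secondary_values)):
        if vals is None or coords.shape[1] <= axis:
            continue
        res = regress_axis(vals, coords, axis)
        if res.ok and res.slope < 0:
            coords[:, axis] = -coords[:, axis]
    return coords
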