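"""Mutual information between spike counts and contour features.

The plug-in MI estimator on a binned joint histogram,

    I(X;Y) = sum_{x,y} p(x,y) * log2( p(x,y) / (p(x) p(y)) ),

with X the neural responses and Y the feature values.  The bin count per
(neuron, feature) combination follows Sturges' rule, nbin = ceil(1 +
log2(n)); the literal base-10 reading of the printed rule is available as
``rule="log10"``.  Neurons with weak responses (< 15 analysed spikes) are
excluded; MI significance uses a permutation test (p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# --------------------------------------------------------------------------
# binning
# --------------------------------------------------------------------------

def sturges_bins(n: int, rule: str = "sturges") -> int:
    """Number of histogram bins for ``n`` data points.

    ``rule="sturges"`` (default): ceil(1 + log2 n).  ``rule="log10"``:
    round(1 + log10(2n)), the literal reading of the printed formula.
    Always at least 2.
    """
    if n < 2:
        raise ValueError("need at least 2 data points to bin")
    if rule == "sturges":
        nbin = int(np.ceil(1.0 + np.log2(n)))
    elif rule == "log10":
        nbin = int(round(1.0 + np.log10(2.0 * n)))
    else:
        raise ValueError(f"unknown binning rule {rule!r}")
    return max(nbin, 2)


@dataclass(frozen=True)
class BinningSpec:
    """Equal-width bin edges for the response and feature axes."""

    n: int
    nbin: int
    response_edges: np.ndarray
    feature_edges: np.ndarray

    def __post_init__(self) -> None:
        if self.nbin < 2:
            raise ValueError("nbin must be >= 2")
        for e in (self.response_edges, self.feature_edges):
            if np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be strictly increasing")


def make_binning(responses, features, rule: str = "sturges") -> BinningSpec:
    """Equal-width binning over the observed range of both axes, with the
    bin count from the Sturges-type rule applied to each axis."""
    x = np.asarray(responses, dtype=float)
    y = np.asarray(features, dtype=float)
    n = len(x)
    nbin = sturges_bins(n, rule=rule)

    def _edges(v):
        lo, hi = float(np.min(v)), float(np.max(v))
        if hi == lo:  # degenerate axis; one occupied bin
            lo, hi = lo - 0.5, hi + 0.5
        return np.linspace(lo, hi, nbin + 1)

    return BinningSpec(n=n, nbin=nbin, response_edges=_edges(x),
                       feature_edges=_edges(y))


# --------------------------------------------------------------------------
# plug-in MI
# --------------------------------------------------------------------------

def _joint_counts(x, y, spec: BinningSpec) -> np.ndarray:
    hx = np.clip(np.digitize(x, spec.response_edges) - 1, 0, spec.nbin - 1)
    hy = np.clip(np.digitize(y, spec.feature_edges) - 1, 0, spec.nbin - 1)
    return np.bincount(hx * spec.nbin + hy,
                       minlength=spec.nbin**2).reshape(spec.nbin, spec.nbin)


def mi_from_joint(joint: np.ndarray) -> float:
    """Plug-in MI in bits from a joint count (or probability) table;
    0*log(0) terms are 0."""
    joint = np.asarray(joint, dtype=float)
    total = joint.sum()
    if total <= 0:
        return 0.0
    p = joint / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def compute_mi(responses, features, spec: BinningSpec | None = None,
               rule: str = "sturges") -> float:
    """Plug-in MI (bits) between paired responses and feature values.

    A constant response or constant feature axis yields 0 bits (degenerate
    but well defined).  Pairs with a missing (NaN) feature must be removed
    by the caller; at least 4 pairs are required.
    """
    x = np.asarray(responses, dtype=float)
    y = np.asarray(features, dtype=float)
    if len(x) != len(y):
        raise ValueError("responses and features must be paired")
    if len(x) < 4:
        raise ValueError("need at least 4 paired data points")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values must be removed before MI")
    if spec is None:
        spec = make_binning(x, y, rule=rule)
    return mi_from_joint(_joint_counts(x, y, spec))


def entropy_bits(values, edges) -> float:
    """Plug-in entropy (bits) of one binned axis; used for the MI bound
    MI <= min(H(X), H(Y))."""
    h, _ = np.histogram(np.asarray(values, float), bins=edges)
    p = h / h.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# --------------------------------------------------------------------------
# exclusions
# --------------------------------------------------------------------------

def exclude_weak(totals: pd.Series, threshold: int = 15):
    """Drop neurons whose total analysed spike count is below ``threshold``.

    Returns (retained_index, exclusion_log).  ``threshold=0`` disables the
    exclusion (every neuron retained).
    """
    totals = pd.Series(totals)
    keep = totals[totals >= threshold]
    dropped = totals[totals < threshold]
    log = pd.DataFrame({"neuron_id": dropped.index,
                        "total_spikes": dropped.to_numpy(),
                        "threshold": threshold})
    return list(keep.index), log


# --------------------------------------------------------------------------
# permutation significance
# --------------------------------------------------------------------------

@dataclass
class MIPermutationResult:
    significant: bool
    p: float
    mi_obs: float
    null_mis: np.ndarray


def permutation_test_mi(responses, features, n_perm: int = 1000,
                        alpha: float = 0.05, seed: int = 0,
                        rule: str = "sturges") -> MIPermutationResult:
    """Permutation test of MI: the null shuffles feature values across
    stimuli; p = (1 + #{null >= observed}) / (n_perm + 1)."""
    x = np.asarray(responses, dtype=float)
    y = np.asarray(features, dtype=float)
    spec = make_binning(x, y, rule=rule)
    hx = np.clip(np.digitize(x, spec.response_edges) - 1, 0, spec.nbin - 1)
    hy = np.clip(np.digitize(y, spec.feature_edges) - 1, 0, spec.nbin - 1)
    nb = spec.nbin
    obs = mi_from_joint(np.bincount(hx * nb + hy,
                                    minlength=nb * nb).reshape(nb, nb))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(hy)
        null[i] = mi_from_joint(np.bincount(hx * nb + perm,
                                            minlength=nb * nb).reshape(nb,
                                                                       nb))
    p = float((1 + np.count_nonzero(null >= obs)) / (n_perm + 1))
    return MIPermutationResult(significant=bool(p < alpha), p=p, mi_obs=obs,
                               null_mis=null)


# --------------------------------------------------------------------------
# MI profiles across the four features
# --------------------------------------------------------------------------

@dataclass
class MIProfile:
    """Per-neuron greatest/least MI ratios and their population tests."""

    table: pd.DataFrame          # neuron_id, mi_*, sum, greatest, least
    mean_greatest: float
    mean_least: float
    greatest_test: "GroupComparison"
    least_test: "GroupComparison"
    mean_within_neuron_variance: float


@dataclass
class GroupComparison:
    test: str           # "rank-sum" | "one-sample permutation"
    statistic: float
    p: float
    effect_size: float  # r for rank-sum, Cliff's delta for permutation

    def __post_init__(self) -> None:
        if np.isfinite(self.effect_size) and abs(self.effect_size) > 1:
            raise ValueError("effect size out of [-1, 1]")


def one_sample_permutation(values, null_value: float = 0.25,
                           n_resamples: int = 10_000,
                           seed: int = 0) -> GroupComparison:
    """Sign-flip permutation test of mean deviation from ``null_value``,
    with Cliff's delta against the null value as effect size."""
    v = np.asarray(values, dtype=float) - null_value
    obs = float(np.mean(v))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_resamples, len(v)))
    null = (signs * v).mean(axis=1)
    p = float((1 + np.count_nonzero(np.abs(null) >= abs(obs)))
              / (n_resamples + 1))
    delta = float((np.count_nonzero(v > 0) - np.count_nonzero(v < 0))
                  / len(v))
    return GroupComparison(test="one-sample permutation", statistic=obs,
                           p=p, effect_size=delta)


def mi_profile(mi_table: pd.DataFrame, n_resamples: int = 10_000,
               seed: int = 0) -> MIProfile:
    """Greatest/least MI ratios per neuron and their deviation from the
    even split (0.25).

    ``mi_table`` must have one row per neuron with columns ``neuron_id``
    and the four MI values ``mi_closure``, ``mi_curvature``,
    ``mi_symmetry``, ``mi_orientation`` (all present and finite).
    Neurons with a zero MI sum are dropped.
    """
    cols = ["mi_closure", "mi_curvature", "mi_symmetry", "mi_orientation"]
    M = mi_table[cols].to_numpy(float)
    if np.isnan(M).any():
        raise ValueError("all four MI values must be present and finite")
    s = M.sum(axis=1)
    keep = s > 0
    M, s = M[keep], s[keep]
    greatest = M.max(axis=1) / s
    least = M.min(axis=1) / s
    table = pd.DataFrame({
        "neuron_id": np.asarray(mi_table["neuron_id"])[keep],
        **{c: M[:, i] for i, c in enumerate(cols)},
        "mi_sum": s, "greatest": greatest, "least": least,
    })
    g_test = one_sample_permutation(greatest, 0.25, n_resamples, seed)
    l_test = one_sample_permutation(least, 0.25, n_resamples, seed + 1)
    return MIProfile(table=table,
                     mean_greatest=float(greatest.mean()),
                     mean_least=float(least.mean()),
                     greatest_test=g_test, least_test=l_test,
                     mean_within_neuron_variance=float(
                         M.var(axis=1, ddof=0).mean()))


def compare_tuned_vs_untuned(mi_values, tuned_flags) -> GroupComparison:
    """Wilcoxon rank-sum comparison of MI between neurons with and without
    significant tuning; effect size r = |z| / sqrt(N)."""
    mi = np.asarray(mi_values, dtype=float)
    flags = np.asarray(tuned_flags, dtype=bool)
    a, b = mi[flags], mi[~flags]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if min(len(a), len(b)) <= 8
                             and len(a) + len(b) <= 25 else "asymptotic")
    # z from the normal approximation (tie-corrected), for the effect size
    n1, n2 = len(a), len(b)
    u = res.statistic
    mu = n1 * n2 / 2.0
    allv = np.concatenate([a, b])
    _, counts = np.unique(allv, return_counts=True)
    n = n1 + n2
    tie = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    sd = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie))
    z = 0.0 if sd == 0 else (u - mu) / sd
    r = abs(z) / np.sqrt(n)
    return GroupComparison(test="rank-sum", statistic=float(u),
                           p=float(res.pvalue), effect_size=float(min(r, 1.0)))
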