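"""The four contour features: closure, signed squashed curvature, symmetry,
and orientation.

Closure, curvature and orientation are local: only contour points inside a
neuron's CRF extent (the strict 2-SD ellipse) enter the computation, so the
same stimulus yields different values for different neurons.  Symmetry is
global: one value per stimulus, independent of the CRF.

When the gated contour is insufficient (too few points in the extent, no
surviving circle fits, no qualifying point pairs) the feature is *missing*
— never silently defaulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .crf import CRFModel
from .io import Contour


# --------------------------------------------------------------------------
# closure
# --------------------------------------------------------------------------

def compute_closure(contour: Contour, crf: CRFModel, n_rays: int = 100) -> float:
    """Fraction of radial lines from the CRF centre that hit the contour
    inside the CRF extent.

    ``n_rays`` rays are cast at angles 2*pi*k/n_rays.  A ray counts as a
    collision iff its *first* intersection with the contour polyline lies
    strictly inside the 2-SD ellipse.  Tangential grazing counts.  A ray
    origin exactly on the contour does not count as a self-collision
    (intersections at parameter < 1e-6 px are ignored).
    """
    o = np.asarray(crf.center, dtype=float)
    ang = 2 * np.pi * np.arange(n_rays) / n_rays
    d = np.stack([np.cos(ang), np.sin(ang)], axis=1)        # (R, 2)

    p, q = contour.segments()
    e = q - p                                               # (S, 2)
    w = p - o                                               # (S, 2)
    # o + t d = p + s e  ;  solve with 2x2 cross products
    denom = d[:, None, 0] * e[None, :, 1] - d[:, None, 1] * e[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[None, :, 0] * e[None, :, 1]
             - w[None, :, 1] * e[None, :, 0]) / denom       # (R, S)
        s = (w[None, :, 0] * d[:, None, 1]
             - w[None, :, 1] * d[:, None, 0]) / denom
    valid = (np.abs(denom) > 1e-12) & (s >= 0.0) & (s <= 1.0) & (t > 1e-6)
    t = np.where(valid, t, np.inf)
    first = np.min(t, axis=1)                               # (R,)
    hit = np.isfinite(first)
    if not hit.any():
        return 0.0
    pts = o[None, :] + first[hit, None] * d[hit]
    inside = crf.in_extent(pts)
    return float(np.count_nonzero(inside)) / n_rays


# --------------------------------------------------------------------------
# curvature
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CurvatureParams:
    """Window scheme and squashing constant for local curvature estimation.

    ``a`` is dimensionless with raw curvature in 1/pixels; the default 20
    implies a characteristic radius of 20 px at the 69-px patch scale.
    ``scale_factor`` rescales ``a`` for other patch sizes.
    """

    a: float = 20.0
    window_scales: tuple = (1.0, 0.75, 0.5, 0.25, 0.1)
    slide_step: int = 10
    min_points: int = 10
    error_percentile: float = 80.0
    max_circles: int = 20
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if not all(0 < s <= 1 for s in self.window_scales):
            raise ValueError("window scales must lie in (0, 1]")
        if self.slide_step < 1:
            raise ValueError("slide step must be >= 1 px")


@dataclass(frozen=True)
class LocalCurvature:
    """One surviving windowed circle fit."""

    c_raw: float          # 1 / fitted radius, 1/px (0 for straight fits)
    c_prime: float        # squashed magnitude, in [0, 1)
    sign: int             # +1 convex / -1 concave w.r.t. the figure
    fit_error: float      # RMS radial residual, px
    window: tuple         # (scale, x0, y0)

    @property
    def value(self) -> float:
        """Signed squashed curvature in (-1, 1)."""
        return self.sign * self.c_prime


def squash(c_raw, a: float = 20.0):
    """Monotone odd sigmoid flattening the raw curvature distribution:
    c' = 2 / (1 + exp(-a*c)) - 1."""
    c = np.asarray(c_raw, dtype=float)
    out = 2.0 / (1.0 + np.exp(-a * c)) - 1.0
    return float(out) if np.isscalar(c_raw) else out


def _window_offsets(patch: int, side: float, step: int) -> np.ndarray:
    if side >= patch:
        return np.array([0.0])
    offs = list(np.arange(0.0, patch - side + 1e-9, step))
    last = patch - side
    if not offs or offs[-1] < last - 1e-9:
        offs.append(last)
    return np.asarray(offs)


def _kasa_fit(x: np.ndarray, y: np.ndarray):
    """Algebraic (Kasa) circle fit.  Returns (cx, cy, r, rms_error); a
    degenerate (collinear) point set falls back to a straight-line fit with
    infinite radius and perpendicular RMS error."""
    z = x**2 + y**2
    A = np.stack([x, y, np.ones_like(x)], axis=1)
    AtA = A.T @ A
    Atb = A.T @ z
    if abs(np.linalg.det(AtA)) < 1e-8 * max(1.0, np.abs(AtA).max() ** 3):
        return _line_fallback(x, y)
    try:
        sol = np.linalg.solve(AtA, Atb)
    except np.linalg.LinAlgError:
        return _line_fallback(x, y)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0:
        return _line_fallback(x, y)
    r = float(np.sqrt(r2))
    d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    err = float(np.sqrt(np.mean((d - r) ** 2)))
    return float(cx), float(cy), r, err


def _line_fallback(x: np.ndarray, y: np.ndarray):
    pts = np.stack([x, y], axis=1)
    c = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - c, full_matrices=False)
    resid = (pts - c) @ vt[1]
    err = float(np.sqrt(np.mean(resid**2)))
    return float("nan"), float("nan"), float("inf"), err


def compute_local_curvatures(
    contour: Contour,
    crf: CRFModel,
    params: CurvatureParams = CurvatureParams(),
    error_cutoff: float | None = None,
) -> list[LocalCurvature]:
    """Windowed local curvatures of the contour inside the CRF extent.

    Square windows at every scale in ``params.window_scales`` (fractions of
    the patch side) are slid over the patch in both directions in steps of
    ``params.slide_step`` px.  For each window holding at least
    ``params.min_points`` contour points that are also inside the CRF
    extent, a circle is fitted (algebraic least squares); fits with an RMS
    radial residual above the ``error_percentile`` of this (stimulus,
    neuron) pair's error distribution are discarded, and at most
    ``max_circles`` lowest-error fits are kept.

    Each surviving fit contributes ``sign * c'`` where ``c' = squash(1/r)``
    and the sign is +1 when the fitted circle's centre lies on the figure
    side of the local chord (convex w.r.t. the figure), -1 otherwise.

    ``error_cutoff`` overrides the per-pair percentile with an externally
    pooled cutoff.  An empty return list means the curvature of this
    (neuron, stimulus) pair is missing.
    """
    pts = contour.points
    in_crf = crf.in_extent(pts)
    if np.count_nonzero(in_crf) < params.min_points:
        return []
    patch = contour.patch_size
    a_eff = params.a * params.scale_factor

    fits = []  # (error, c_raw, sign, window)
    for scale in params.window_scales:
        side = scale * patch
        offs = _window_offsets(patch, side, params.slide_step)
        for x0 in offs:
            inx = (pts[:, 0] >= x0 - 1e-9) & (pts[:, 0] <= x0 + side + 1e-9)
            if np.count_nonzero(inx & in_crf) < params.min_points:
                continue
            for y0 in offs:
                mask = (inx & in_crf
                        & (pts[:, 1] >= y0 - 1e-9)
                        & (pts[:, 1] <= y0 + side + 1e-9))
                idx = np.flatnonzero(mask)
                if len(idx) < params.min_points:
                    continue
                x, y = pts[idx, 0], pts[idx, 1]
                cx, cy, r, err = _kasa_fit(x, y)
                if np.isinf(r):
                    sign = 1
                    c_raw = 0.0
                else:
                    c_raw = 1.0 / r
                    # convex iff the circle centre lies on the figure side:
                    # vote over locally adjacent segments, figure normal =
                    # figure_side * (dy, -dx)
                    adj = idx[:-1][np.diff(idx) == 1]
                    centre = np.array([cx, cy])
                    if adj.size:
                        d = pts[adj + 1] - pts[adj]
                        mid = 0.5 * (pts[adj + 1] + pts[adj])
                        nrm = (np.stack([d[:, 1], -d[:, 0]], axis=1)
                               * contour.figure_side)
                        vote = float(np.einsum("ij,ij->i",
                                               centre - mid, nrm).sum())
                    else:  # sparse mask: fall back to the overall chord
                        chord = pts[idx[-1]] - pts[idx[0]]
                        nrm = contour.figure_side * np.array([chord[1],
                                                              -chord[0]])
                        mid = 0.5 * (pts[idx[0]] + pts[idx[-1]])
                        vote = float((centre - mid) @ nrm)
                    sign = 1 if vote >= 0 else -1
                fits.append((err, c_raw, sign, (scale, float(x0), float(y0))))

    if not fits:
        return []
    errors = np.array([f[0] for f in fits])
    cutoff = (error_cutoff if error_cutoff is not None
              else np.percentile(errors, params.error_percentile))
    keep = [f for f in fits if f[0] <= cutoff]
    keep.sort(key=lambda f: f[0])
    keep = keep[: params.max_circles]
    return [
        LocalCurvature(
            c_raw=c_raw,
            c_prime=squash(c_raw, a_eff),
            sign=sign,
            fit_error=err,
            window=win,
        )
        for err, c_raw, sign, win in keep
    ]


# --------------------------------------------------------------------------
# symmetry
# --------------------------------------------------------------------------

def _rasterize(points: np.ndarray, n: int) -> np.ndarray:
    """Accumulate points onto an (n, n) grid at rounded pixel coordinates."""
    img = np.zeros((n, n))
    ij = np.rint(points).astype(int)
    ok = ((ij[:, 0] >= 0) & (ij[:, 0] < n)
          & (ij[:, 1] >= 0) & (ij[:, 1] < n))
    np.add.at(img, (ij[ok, 1], ij[ok, 0]), 1.0)
    return img


def compute_symmetry(
    contour: Contour,
    blur_sd: float = 2.0,
    n_axes: int = 24,
    mode: str = "min",
) -> float:
    """Raw mirror-symmetry score: the greatest fold overlap over ``n_axes``
    radial axes through the stimulus centre (7.5 deg apart for 24 axes).

    The contour points are blurred into a density map (Gaussian,
    SD = ``blur_sd`` px).  For each axis the point set is reflected about
    the axis, blurred the same way, and the overlap *ratio* between the
    two maps is computed — ``mode="min"``: sum of the pixel-wise minimum
    divided by the map's total mass (the fraction of contour mass that
    folds onto itself; default); ``mode="dot"``: normalised correlation of
    the two maps.  The maximum over axes is returned.  Scores are
    comparable only within a stimulus set; use :func:`normalize_symmetry`
    to map them onto [0, 1].
    """
    if mode not in ("min", "dot"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    n = contour.patch_size
    c = np.asarray(contour.center)
    base = gaussian_filter(_rasterize(contour.points, n), blur_sd)
    total = float(base.sum())
    if total <= 0:
        return 0.0
    best = -np.inf
    for k in range(n_axes):
        ang = np.pi * k / n_axes
        u = np.array([np.cos(ang), np.sin(ang)])
        R = 2.0 * np.outer(u, u) - np.eye(2)
        refl = (contour.points - c) @ R.T + c
        mirror = gaussian_filter(_rasterize(refl, n), blur_sd)
        if mode == "min":
            ov = float(np.minimum(base, mirror).sum()) / total
        else:
            denom = np.sqrt(float((base**2).sum())
                            * float((mirror**2).sum()))
            ov = float((base * mirror).sum()) / denom if denom > 0 else 0.0
        best = max(best, ov)
    return best


def normalize_symmetry(raw_scores) -> np.ndarray:
    """Min-max normalise raw symmetry scores across the stimulus set."""
    raw = np.asarray(raw_scores, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least 2 stimuli to normalise symmetry")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


# --------------------------------------------------------------------------
# orientation
# --------------------------------------------------------------------------

def compute_orientation(
    contour: Contour,
    crf: CRFModel,
    pair_sep: float = 5.0,
    naive: bool = False,
    return_resultant: bool = False,
):
    """Mean local orientation (degrees in [0, 180)) of the contour inside
    the CRF extent, or NaN when no qualifying point pair exists.

    Local orientations are the tilts (w.r.t. horizontal) of lines through
    point pairs separated by ``pair_sep`` px of arc length along the
    contour, both points inside the CRF extent.  They are averaged axially
    (angles doubled, unit vectors summed, resultant angle halved), which is
    well defined across the 0/180 wrap; ``naive=True`` switches to the
    arithmetic mean of the raw angles for strict replication.

    With ``return_resultant=True`` also returns the doubled-angle mean
    resultant length in [0, 1] — near 0 flags a degenerate (direction-
    balanced) orientation sample.
    """
    pts = contour.points
    s = contour.arc_lengths()
    in_crf = crf.in_extent(pts)
    # first index j with s[j] - s[i] >= pair_sep, per i
    j = np.searchsorted(s, s + pair_sep, side="left")
    i = np.arange(len(pts))
    ok = (j < len(pts))
    i, j = i[ok], j[ok]
    ok = in_crf[i] & in_crf[j]
    i, j = i[ok], j[ok]
    if len(i) == 0:
        return (np.nan, np.nan) if return_resultant else np.nan
    d = pts[j] - pts[i]
    theta = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 180.0
    if naive:
        mean = float(np.mean(theta))
        resultant = np.nan
    else:
        doubled = np.radians(2.0 * theta)
        C, S = np.mean(np.cos(doubled)), np.mean(np.sin(doubled))
        resultant = float(np.hypot(C, S))
        mean = float(np.degrees(np.arctan2(S, C)) / 2.0) % 180.0
    if return_resultant:
        return mean, resultant
    return mean


# --------------------------------------------------------------------------
# feature tables
# --------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Per-(neuron, stimulus) contour features.

    ``per_pair`` has one row per (neuron_id, stimulus_id) with columns
    ``closure``, ``symmetry`` (the stimulus's normalised value, repeated per
    neuron), ``orientation`` (NaN = missing), ``orientation_resultant``,
    and ``n_curvatures``.  ``curvatures`` is a long table with one row per
    surviving local curvature (columns ``neuron_id``, ``stimulus_id``,
    ``value``, ``fit_error``).  ``symmetry_raw`` maps stimulus_id to the raw
    (un-normalised) symmetry score.
    """

    per_pair: pd.DataFrame
    curvatures: pd.DataFrame
    symmetry_raw: pd.Series

    def curvature_lists(self, neuron_id) -> dict:
        sub = self.curvatures[self.curvatures["neuron_id"] == neuron_id]
        return {sid: g["value"].to_numpy()
                for sid, g in sub.groupby("stimulus_id", sort=False)}


def compute_features(
    contours: list[Contour],
    crfs: dict,
    curvature_params: CurvatureParams = CurvatureParams(),
    n_rays: int = 100,
    pair_sep: float = 5.0,
    blur_sd: float = 2.0,
    n_axes: int = 24,
) -> FeatureTable:
    """Compute all four features for every (neuron, stimulus) combination.

    ``crfs`` maps neuron_id -> CRFModel.  Neurons sharing an identical
    CRFModel share the gated computations (the features depend on the
    neuron only through its CRF), so populations recorded — or simulated —
    with a common probe geometry are cheap to process.
    """
    raw_sym = pd.Series(
        {c.stimulus_id: compute_symmetry(c, blur_sd=blur_sd, n_axes=n_axes)
         for c in contours},
        dtype=float,
    )
    norm_sym = pd.Series(
        normalize_symmetry(raw_sym.to_numpy()), index=raw_sym.index
    )

    # group neurons by identical CRF so gated features are computed once
    by_crf: dict[CRFModel, list] = {}
    for nid, crf in crfs.items():
        by_crf.setdefault(crf, []).append(nid)

    pair_rows = []
    curv_rows = []
    for crf, neuron_ids in by_crf.items():
        for contour in contours:
            clos = compute_closure(contour, crf, n_rays=n_rays)
            orient, res = compute_orientation(
                contour, crf, pair_sep=pair_sep, return_resultant=True
            )
            curls = compute_local_curvatures(contour, crf, curvature_params)
            for nid in neuron_ids:
                pair_rows.append((nid, contour.stimulus_id, clos,
                                  norm_sym[contour.stimulus_id],
                                  orient, res, len(curls)))
                for lc in curls:
                    curv_rows.append((nid, contour.stimulus_id, lc.value,
                                      lc.fit_error))
    per_pair = pd.DataFrame(
        pair_rows,
        columns=["neuron_id", "stimulus_id", "closure", "symmetry",
                 "orientation", "orientation_resultant", "n_curvatures"],
    )
    curvatures = pd.DataFrame(
        curv_rows, columns=["neuron_id", "stimulus_id", "value", "fit_error"]
    )
    return FeatureTable(per_pair=per_pair, curvatures=curvatures,
                        symmetry_raw=raw_sym)
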