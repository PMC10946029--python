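"""Data model and readers/writers for contour stimuli and spike-count tables.

Conventions
-----------
Coordinates are 0-based pixel indices, ``x`` rightward and ``y`` downward,
all geometry in pixel units.  A stimulus patch is ``patch_size`` pixels
square (default 69) and its centre is at ``((patch_size-1)/2,)*2``.

The figure side of a contour is stored as a signed normal convention:
with ``figure_side = +1`` the figure region lies to the left of the
direction of traversal (for a rightward-travelling contour in screen
coordinates, "left" is upward, i.e. decreasing ``y``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml


class ContourValidationError(ValueError):
    """A contour violates a structural invariant."""


class SchemaError(ValueError):
    """A tabular file does not have the expected columns/values."""


class RenderingError(ValueError):
    """A contour cannot be rendered into a two-tone silhouette."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Contour:
    """An ordered open polyline through the patch centre with a figure label.

    Parameters
    ----------
    stimulus_id : str
        Identifier of the stimulus this contour belongs to.
    points : (n, 2) ndarray
        Ordered ``(x, y)`` pixel coordinates of the sampled contour.
    figure_side : int
        ``+1`` if the figure lies to the left of the traversal direction,
        ``-1`` if to the right.
    is_mirror : bool
        Whether this contour is the mirror variant of another stimulus.
    patch_size : int
        Side of the square stimulus patch in pixels.
    """

    stimulus_id: str
    points: np.ndarray
    figure_side: int
    is_mirror: bool = False
    patch_size: int = 69

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourValidationError(
                f"{self.stimulus_id}: points must be an (n, 2) array"
            )
        object.__setattr__(self, "points", pts)

    # -- geometry helpers ---------------------------------------------------
    @property
    def center(self) -> tuple[float, float]:
        c = (self.patch_size - 1) / 2.0
        return (c, c)

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (start, end) arrays of the polyline segments."""
        return self.points[:-1], self.points[1:]

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at every point, starting at 0."""
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(d)])

    def validate(self, max_step: float = 10.0) -> "Contour":
        pts = self.points
        if len(pts) < 2:
            raise ContourValidationError(
                f"{self.stimulus_id}: a contour needs at least 2 points"
            )
        if self.figure_side not in (-1, 1):
            raise ContourValidationError(
                f"{self.stimulus_id}: figure_side must be +1 or -1"
            )
        lo, hi = -0.5, self.patch_size - 0.5
        if np.any(pts < lo) or np.any(pts > hi):
            raise ContourValidationError(
                f"{self.stimulus_id}: contour points fall outside the patch"
            )
        c = np.asarray(self.center)
        if np.min(np.linalg.norm(pts - c, axis=1)) > 1.0:
            raise ContourValidationError(
                f"{self.stimulus_id}: contour misses the patch centre by >1 px"
            )
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps <= 0) or np.any(steps > max_step):
            raise ContourValidationError(
                f"{self.stimulus_id}: consecutive points must form a "
                f"connected polyline (0 < step <= {max_step} px)"
            )
        return self

    def mirrored(self, new_id: str | None = None) -> "Contour":
        """Mirror about the tangent of the contour at the patch centre.

        The figure flag is flipped so that the physical figure side of the
        reflected geometry is preserved (the recorded stimuli inverted the
        colour contrast of mirror images for the same reason).
        """
        c = np.asarray(self.center)
        i = int(np.argmin(np.linalg.norm(self.points - c, axis=1)))
        j0, j1 = max(i - 1, 0), min(i + 1, len(self.points) - 1)
        t = self.points[j1] - self.points[j0]
        n = np.linalg.norm(t)
        if n == 0:
            t = np.array([1.0, 0.0])
        else:
            t = t / n
        # reflection matrix about a line through `anchor` with direction t
        R = 2.0 * np.outer(t, t) - np.eye(2)
        anchor = self.points[i]
        pts = (self.points - anchor) @ R.T + anchor
        return Contour(
            stimulus_id=new_id or f"{self.stimulus_id}m",
            points=pts,
            figure_side=-self.figure_side,
            is_mirror=not self.is_mirror,
            patch_size=self.patch_size,
        )


@dataclass(frozen=True)
class Stimulus:
    """A contour plus its presentation kind (natural vs silhouette)."""

    stimulus_id: str
    contour: Contour
    kind: str  # "natural" | "silhouette"
    fg_polarity: str = "black-figure"  # silhouettes: which tone fills the figure
    image: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("natural", "silhouette"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.fg_polarity not in ("black-figure", "white-figure"):
            raise ValueError(f"unknown fg_polarity {self.fg_polarity!r}")


class ResponseTable:
    """Spike counts per (neuron, stimulus, trial), backed by a DataFrame."""

    COLUMNS = ("neuron", "stimulus", "trial", "count")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"response table missing column(s): {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        if (df["count"] < 0).any():
            bad = df.index[df["count"] < 0][0]
            raise SchemaError(f"negative spike count at row {bad}")
        if df.duplicated(subset=["neuron", "stimulus", "trial"]).any():
            raise SchemaError("duplicate (neuron, stimulus, trial) entries")
        self.df = df.sort_values(["neuron", "stimulus", "trial"], kind="stable")
        self.df.reset_index(drop=True, inplace=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def neurons(self) -> list:
        return list(pd.unique(self.df["neuron"]))

    @property
    def stimuli(self) -> list:
        return list(pd.unique(self.df["stimulus"]))

    def neuron_totals(self) -> pd.Series:
        return self.df.groupby("neuron", sort=False)["count"].sum()

    def stimulus_totals(self) -> pd.Series:
        return self.df.groupby("stimulus", sort=False)["count"].sum()

    def trial_means(self) -> pd.DataFrame:
        """Neuron x stimulus matrix of trial-averaged spike counts."""
        return self.df.pivot_table(
            index="neuron", columns="stimulus", values="count", aggfunc="mean"
        )


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run, with explicit seeds.

    Every stochastic stage has its own seed so that stages are individually
    reproducible.  All numeric parameters must be positive.
    """

    seed_stimuli: int = 0
    seed_neurons: int = 1
    seed_responses: int = 2
    seed_permutation: int = 3
    seed_mds: int = 4

    # feature binning
    closure_bins: int = 10
    symmetry_bins: int = 10
    curvature_bins: int = 20
    orientation_bins: int = 18

    # curvature window scheme
    squash_a: float = 20.0
    window_scales: tuple = (1.0, 0.75, 0.5, 0.25, 0.1)
    slide_step: int = 10
    min_points: int = 10
    error_percentile: float = 80.0
    max_circles: int = 20

    # significance
    n_perm_tuning: int = 1000
    alpha_tuning: float = 0.01
    n_perm_mi: int = 1000
    alpha_mi: float = 0.05
    weak_spike_threshold: int = 15

    # population
    mds_restarts: int = 20
    axis_window: int = 30
    axis_smooth: int = 15
    n_groups: int = 5

    out_dir: str = "results"

    def validate(self) -> "RunConfig":
        for name in (
            "closure_bins", "symmetry_bins", "curvature_bins",
            "orientation_bins", "squash_a", "slide_step", "min_points",
            "error_percentile", "max_circles", "n_perm_tuning",
            "alpha_tuning", "n_perm_mi", "alpha_mi", "mds_restarts",
            "axis_window", "axis_smooth", "n_groups",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"RunConfig.{name} must be positive")
        if not all(0 < s <= 1 for s in self.window_scales):
            raise ValueError("window scales must lie in (0, 1]")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "window_scales" in data:
            data["window_scales"] = tuple(data["window_scales"])
        return cls(**data).validate()

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["window_scales"] = list(data["window_scales"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

_CONTOUR_COLUMNS = [
    "stimulus_id", "figure_side", "is_mirror", "patch_size",
    "point_index", "x", "y",
]


def write_contours(contours: Iterable[Contour], path: str | Path) -> None:
    """Write contours as a tidy CSV, one point per row."""
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.points):
            rows.append((c.stimulus_id, c.figure_side, int(c.is_mirror),
                         c.patch_size, i, x, y))
    pd.DataFrame(rows, columns=_CONTOUR_COLUMNS).to_csv(path, index=False)


def read_contours(path: str | Path, validate: bool = True) -> list[Contour]:
    """Read contours from the tidy CSV written by :func:`write_contours`."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _CONTOUR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col in ("x", "y", "point_index", "figure_side"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            line = int(df.index[coerced.isna()][0]) + 2  # header + 1-based
            raise SchemaError(f"{path}: malformed value in column "
                              f"{col!r} at line {line}")
        df[col] = coerced
    out: list[Contour] = []
    for sid, g in df.groupby("stimulus_id", sort=False):
        g = g.sort_values("point_index", kind="stable")
        contour = Contour(
            stimulus_id=str(sid),
            points=g[["x", "y"]].to_numpy(float),
            figure_side=int(g["figure_side"].iloc[0]),
            is_mirror=bool(g["is_mirror"].iloc[0]),
            patch_size=int(g["patch_size"].iloc[0]),
        )
        if validate:
            contour.validate()
        out.append(contour)
    return out


def write_responses(table: ResponseTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_responses(path: str | Path) -> ResponseTable:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    return ResponseTable(df)


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


# --------------------------------------------------------------------------
# silhouette rendering
# --------------------------------------------------------------------------

def render_silhouette(
    contour: Contour,
    fg_polarity: str = "black-figure",
    envelope: bool = True,
    envelope_sd: float | None = None,
) -> np.ndarray:
    """Render a two-tone silhouette of the figure/ground partition.

    Each pixel is labelled figure or ground by the side it falls on relative
    to its nearest contour segment (using the stored figure-side normal
    convention).  The figure is filled with one intensity extreme and the
    ground with the other; the contrast is then attenuated toward the patch
    border by a radial Gaussian envelope (SD = patch_size/3 by default) so
    the patch blends into a mid-grey surround.

    Returns a float image in [0, 1] of shape (patch_size, patch_size),
    indexed ``image[y, x]``.
    """
    if fg_polarity not in ("black-figure", "white-figure"):
        raise ValueError(f"unknown fg_polarity {fg_polarity!r}")
    n = contour.patch_size
    ys, xs = np.mgrid[0:n, 0:n]
    pix = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)

    p, q = contour.segments()
    e = q - p                                   # (m, 2) segment vectors
    seg_len2 = np.maximum(np.einsum("ij,ij->i", e, e), 1e-12)
    # closest point on each segment for each pixel
    w = pix[:, None, :] - p[None, :, :]          # (npix, m, 2)
    t = np.clip(np.einsum("pmk,mk->pm", w, e) / seg_len2, 0.0, 1.0)
    proj = p[None, :, :] + t[..., None] * e[None, :, :]
    d2 = np.sum((pix[:, None, :] - proj) ** 2, axis=2)
    nearest = np.argmin(d2, axis=1)              # (npix,)

    en = e[nearest]
    # figure normal: left of traversal is (dy, -dx) in screen coords
    normal = np.stack([en[:, 1], -en[:, 0]], axis=1) * contour.figure_side
    rel = pix - proj[np.arange(len(pix)), nearest]
    side = np.einsum("ij,ij->i", rel, normal)
    is_figure = side > 0

    if is_figure.all() or (~is_figure).all():
        raise RenderingError(
            f"{contour.stimulus_id}: contour does not partition the patch"
        )

    fig_val, gnd_val = (0.0, 1.0) if fg_polarity == "black-figure" else (1.0, 0.0)
    img = np.where(is_figure, fig_val, gnd_val).reshape(n, n)

    if envelope:
        sd = envelope_sd if envelope_sd is not None else n / 3.0
        c = (n - 1) / 2.0
        r2 = (xs - c) ** 2 + (ys - c) ** 2
        atten = np.exp(-r2 / (2.0 * sd**2))
        img = 0.5 + (img - 0.5) * atten
    return img
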