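"""Shared fixtures: a small synthetic stimulus set and reference CRF.

The small set (60 geometries from a 600-candidate pool, relaxed flatness
target) keeps unit tests fast; the full-size default set is built once per
session for the acceptance checks that exercise the stated configuration.
"""

import numpy as np
import pytest

from contourcode.crf import CRFModel
from contourcode.synthetic import (StimulusSetConfig, generate_contours,
                                   reference_crf)


@pytest.fixture(scope="session")
def small_set():
    cfg = StimulusSetConfig(n_patches=60, pool_size=600, seed=0,
                            min_flatness=0.25)
    return generate_contours(cfg)


@pytest.fixture(scope="session")
def default_set():
    return generate_contours(StimulusSetConfig(seed=0))


@pytest.fixture(scope="session")
def ref_crf():
    return reference_crf()


@pytest.fixture
def central_crf():
    return CRFModel(center=(34.0, 34.0), sd=(12.0, 12.0))


def circle_contour(radius=20.0, center=(34.0, 34.0), n=400, figure_side=-1,
                   stimulus_id="circle"):
    """A closed circle; with increasing parameter the interior lies on the
    figure side when figure_side = -1 (screen coordinates, y down)."""
    from contourcode.io import Contour

    th = np.linspace(0, 2 * np.pi, n)
    pts = np.stack([center[0] + radius * np.cos(th),
                    center[1] + radius * np.sin(th)], axis=1)
    return Contour(stimulus_id, pts, figure_side=figure_side)


def segment_contour(p0, p1, n=60, figure_side=1, stimulus_id="seg"):
    from contourcode.io import Contour

    t = np.linspace(0, 1, n)[:, None]
    pts = np.asarray(p0, float) + t * (np.asarray(p1, float)
                                       - np.asarray(p0, float))
    return Contour(stimulus_id, pts, figure_side=figure_side)
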