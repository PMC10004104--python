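"""Shared fixtures: small synthetic frames and a reduced closed-loop session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lmposl import imaging, phantom, synthdata, transport
from lmposl.efficiency import EfficiencyCurve


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_uniform_image(value: float, n: int = 1024, **kwargs) -> imaging.DetectorImage:
    return imaging.DetectorImage(pixels=np.full((n, n), float(value)), **kwargs)


def make_disc_image(
    n: int = 1024,
    cx: float = 512.0,
    cy: float = 512.0,
    radius: float = 280.0,
    value: float = 1000.0,
    background: float = 10.0,
    marker_angle: float | None = None,
    marker_dim: float = 0.55,
    **kwargs,
) -> imaging.DetectorImage:
    """Noise-free disc on a dark background, optional rim notch marker."""
    yy, xx = np.ogrid[:n, :n]
    dx, dy = xx - cx, yy - cy
    rho = np.hypot(dx, dy)
    px = np.where(rho <= radius, value, background).astype(float)
    if marker_angle is not None:
        theta = np.degrees(np.arctan2(np.broadcast_to(dx, (n, n)),
                                      -np.broadcast_to(dy, (n, n))))
        delta = (theta - marker_angle + 180.0) % 360.0 - 180.0
        band = (rho >= 0.88 * radius) & (rho <= 0.98 * radius) & (np.abs(delta) <= 6.0)
        px = np.where(band, marker_dim * px, px)
    return imaging.DetectorImage(pixels=px, **kwargs)


def small_layout(n_foils: int = 8, plate_mm: float = 3.0) -> phantom.StackLayout:
    """A short stack: foils separated by PMMA plates, spanning the Bragg curve."""
    elements: list[phantom.StackElement] = []
    for k in range(1, n_foils + 1):
        elements.append(phantom.foil(f"s{k:02d}"))
        if k < n_foils:
            elements.append(phantom.pmma_plate(thickness_mm=plate_mm))
    return phantom.StackLayout(elements)


UNIT_ETA = EfficiencyCurve(amplitude=1.0, center=-1000.0, width=1.0, slope=0.0)


@pytest.fixture(scope="session")
def noiseless_session():
    """Reduced noise-free eta==1 session: transport truth plus processed signals."""
    from lmposl import pipeline

    layout = small_layout()
    scen = synthdata.ScenarioSpec(layout=layout, efficiency=UNIT_ETA, seed=11)
    cam = synthdata.CameraModel(vignette_strength=0.1).noiseless()
    res = pipeline.run_closed_loop(mode="pristine", scenario=scen, cam=cam,
                                   n_protons=20000, seed=11, fit=False)
    return res
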