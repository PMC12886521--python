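"""Shared fixtures: rasterized shapes and small rendered trials."""

from __future__ import annotations

import numpy as np
import pytest

from lumenpulse import (
    DEFAULT_PROTOCOL,
    VesselGroundTruth,
    generate_diameter_timecourse,
    render_trial,
)
from lumenpulse.synthetic import NOISELESS


def rasterize_disk(shape, center_rc, radius):
    """Pixel-centre-inside rasterization of a filled disk."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center_rc[0]) ** 2 + (xx - center_rc[1]) ** 2 <= radius**2


def rasterize_ellipse(shape, center_rc, semi_minor, semi_major, theta_rad):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = yy - center_rc[0]
    dc = xx - center_rc[1]
    u = dr * np.cos(theta_rad) + dc * np.sin(theta_rad)
    v = -dr * np.sin(theta_rad) + dc * np.cos(theta_rad)
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def rasterize_square(shape, side):
    m = np.zeros(shape, dtype=bool)
    o_r = (shape[0] - side) // 2
    o_c = (shape[1] - side) // 2
    m[o_r : o_r + side, o_c : o_c + side] = True
    return m


@pytest.fixture(scope="session")
def protocol():
    return DEFAULT_PROTOCOL


@pytest.fixture(scope="session")
def noiseless_trial(protocol):
    """One clean rendered trial with a 15% dilation, reused across tests."""
    truth = VesselGroundTruth(
        basal_diameter_um=20.0,
        dilation_amplitude_pct=15.0,
        t_max_s=2.5,
        center_rc=(55.5, 55.5),
        pixel_size_um=0.5,
        ellipticity=1.2,
    )
    trace = generate_diameter_timecourse(truth, protocol)
    trial = render_trial(trace, truth, NOISELESS, protocol, shape=(112, 112))
    return trial
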