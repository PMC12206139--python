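"""Shared fixtures: phantoms and pipeline runs reused across test modules.

The two pipeline runs (noisy and clean) each take ~30 s, so they are
session-scoped and shared by the unit, integration and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from hepatovasc.phantom import PhantomSpec, generate_phantom
from hepatovasc.pipeline import PipelineConfig, run_pipeline

#: test-scale grid: the analysis is resolution-agnostic, and this size keeps
#: one pipeline run around half a minute.
TEST_SHAPE = (96, 160, 160)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-degradation normal-stage phantom (noise 10 %, 2 mm^-1)."""
    return generate_phantom(PhantomSpec(shape=TEST_SHAPE, seed=1))


@pytest.fixture(scope="session")
def noisy_result(noisy_phantom):
    return run_pipeline(noisy_phantom.intensity, PipelineConfig())


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and attenuation-free phantom for parameter recovery."""
    return generate_phantom(PhantomSpec.clean(seed=1, shape=TEST_SHAPE))


@pytest.fixture(scope="session")
def clean_result(clean_phantom):
    return run_pipeline(clean_phantom.intensity, PipelineConfig.noiseless())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


def digital_semicircle(radius):
    """A thin 8-connected half-circle arc in one Z slice.

    Plain rounding leaves L-corners whose flanking voxels touch diagonally,
    reading as spurious junctions under 26-connectivity; dropping any voxel
    whose neighbours are mutually adjacent yields a simple degree-2 chain.
    """
    theta = np.linspace(0, np.pi, 40 * radius)
    pts = []
    for t in theta:
        v = (int(round(radius * np.sin(t))), int(round(radius * np.cos(t))))
        if not pts or v != pts[-1]:
            pts.append(v)
    changed = True
    while changed:
        changed = False
        i = 1
        while i < len(pts) - 1:
            dy = abs(pts[i - 1][0] - pts[i + 1][0])
            dx = abs(pts[i - 1][1] - pts[i + 1][1])
            if max(dy, dx) <= 1:  # corner voxel is redundant
                pts.pop(i)
                changed = True
            else:
                i += 1
    data = np.zeros((3, radius + 5, 2 * radius + 5), dtype=bool)
    for y, x in pts:
        data[1, y + 2, x + radius + 2] = True
    return data


def make_cylinder(shape, axis_len, radius, spacing=(1.0, 1.0, 1.0), axis=0,
                  value=255.0):
    """Digital cylinder along one axis, centered in the cross-section."""
    grid = np.zeros(shape, dtype=np.float64)
    centers = [(s - 1) / 2 for s in shape]
    idx = np.indices(shape).astype(np.float64)
    cross = [i for i in range(3) if i != axis]
    r2 = sum(((idx[i] - centers[i]) * spacing[i]) ** 2 for i in cross)
    along = idx[axis] * spacing[axis]
    start = (shape[axis] * spacing[axis] - axis_len) / 2
    inside = (r2 <= radius ** 2) & (along >= start) & (along < start + axis_len)
    grid[inside] = value
    return grid
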