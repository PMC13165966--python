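"""Shared fixtures: the desk-scale synthetic scene and its derived stages.

Everything is generated programmatically (no stored binary fixtures) and
session-scoped so the simulate -> stitch -> retrieve chain runs once.
"""

from __future__ import annotations

import numpy as np
import pytest

from mdefov import analysis, io, pipeline, retrieval, simulate, stitching
from mdefov.optics import ComplexField, OpticalConfig, propagate


@pytest.fixture(scope="session")
def demo_cfg() -> dict:
    return pipeline.demo_config()


@pytest.fixture(scope="session")
def optics_cfg(demo_cfg) -> OpticalConfig:
    return io.resolve_optics(demo_cfg)


@pytest.fixture(scope="session")
def scan_grid(demo_cfg, optics_cfg) -> simulate.ScanGrid:
    sim = demo_cfg["simulate"]
    return simulate.ScanGrid(
        rows=sim["grid_rows"],
        cols=sim["grid_cols"],
        step=sim["step_mm"] * 1e-3,
        tile_side_px=sim["tile_px"],
        pitch=optics_cfg.pitch,
    )


@pytest.fixture(scope="session")
def scene(demo_cfg, optics_cfg):
    """(object wavefront, chart elements) for the demo scan extent."""
    return pipeline.build_object(demo_cfg, optics_cfg)


@pytest.fixture(scope="session")
def scan(scene, scan_grid, optics_cfg):
    """Noiseless 3x3 x 5-plane simulated scan: (holograms, records)."""
    obj, _ = scene
    return simulate.simulate_scan(obj, scan_grid, optics_cfg, noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def stitched_stack(scan, optics_cfg):
    """(stitched planes, per-plane StitchInfo), co-registered on the
    reference plane's layout and crop."""
    holograms, _ = scan
    return stitching.stitch_stack(holograms, optics_cfg.reference_index)


@pytest.fixture(scope="session")
def retrieved(stitched_stack, optics_cfg):
    """(field at reference plane, ConvergenceTrace) after 10 iterations."""
    stitched, _ = stitched_stack
    stack = retrieval.MultiDepthStack(
        holograms=[s.amplitude for s in stitched],
        z_planes=optics_cfg.z_planes,
        pitch=optics_cfg.pitch,
        wavelength=optics_cfg.wavelength,
        reference_index=optics_cfg.reference_index,
    )
    return retrieval.multi_depth_retrieve(stack, iterations=10, tol=0.0)


@pytest.fixture(scope="session")
def direct_stack(optics_cfg):
    """Co-registered 256 px stack simulated directly from a known field:
    (stack, true object values, true reference-plane field values).

    The phase is a windowed cosine grating whose spectrum sits inside the
    band the defocus distances transfer well, so retrieval can recover it.
    The z planes stay within the 256 px alias-free propagation bound.
    """
    n = 256
    z_planes = (0.6e-3, 0.8e-3, 1.0e-3, 1.2e-3, 1.4e-3)
    reference_index = 2
    rr = np.arange(n)[:, None]
    cc = np.arange(n)[None, :]
    envelope = np.exp(-(((rr - 128) / 40.0) ** 2 + ((cc - 128) / 40.0) ** 2) / 2.0)
    phase = 0.3 * np.cos(2.0 * np.pi * cc / 24.0) * envelope
    amplitude = 1.0 - 0.3 * np.exp(
        -(((rr - 90.0) / 25.0) ** 2 + ((cc - 170.0) / 25.0) ** 2) / 2.0
    )
    obj = amplitude * np.exp(1j * phase)
    fld = ComplexField(obj, optics_cfg.pitch, optics_cfg.wavelength, 0.0)
    holograms = [np.abs(propagate(fld, z).values) for z in z_planes]
    true_ref = propagate(fld, z_planes[reference_index]).values
    stack = retrieval.MultiDepthStack(
        holograms=holograms,
        z_planes=z_planes,
        pitch=optics_cfg.pitch,
        wavelength=optics_cfg.wavelength,
        reference_index=reference_index,
    )
    return stack, obj, true_ref
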