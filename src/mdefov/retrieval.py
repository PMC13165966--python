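"""Multi-depth amplitude-constrained iterative phase retrieval.

Recovers the complex wavefront at a chosen reference plane from K >= 2
co-registered amplitude holograms recorded at distinct axial distances.
Starting from zero phase at the reference plane, each iteration performs
one full down-up propagation sweep over all planes
(``ref -> ... -> K-1 -> ... -> 0 -> ... -> ref``), replacing the field
modulus with the measured amplitude at every visited plane while keeping
the propagated phase.  Convergence is tracked by the normalized RMSE
between the measured reference amplitude and the field amplitude arriving
back at the reference plane, and its per-iteration difference.

The loop contains no randomness and is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import ComplexField, normalize_amplitude, propagate

__all__ = [
    "MultiDepthStack",
    "ConvergenceTrace",
    "amplitude_constraint",
    "rmse",
    "multi_depth_retrieve",
]


@dataclass
class MultiDepthStack:
    """K co-registered amplitude holograms at ascending axial distances."""

    holograms: list[np.ndarray]
    z_planes: tuple[float, ...]
    pitch: float
    wavelength: float
    reference_index: int

    def __post_init__(self) -> None:
        self.holograms = [np.asarray(h, dtype=np.float64) for h in self.holograms]
        self.z_planes = tuple(float(z) for z in self.z_planes)
        if len(self.holograms) != len(self.z_planes):
            raise ValueError("number of holograms must equal number of z planes")
        if len(self.holograms) < 2:
            raise ValueError("multi-depth retrieval needs at least 2 planes")
        shapes = {h.shape for h in self.holograms}
        if len(shapes) != 1:
            raise ValueError(f"holograms are not co-registered: shapes {shapes}")
        if any(h.ndim != 2 for h in self.holograms):
            raise ValueError("holograms must be 2-D")
        if any(np.any(h < 0) for h in self.holograms):
            raise ValueError("hologram amplitudes must be nonnegative")
        if any(b <= a for a, b in zip(self.z_planes, self.z_planes[1:])):
            raise ValueError("z_planes must be strictly increasing")
        if not (0 <= self.reference_index < len(self.z_planes)):
            raise ValueError("reference_index out of range")
        if not (self.pitch > 0 and self.wavelength > 0):
            raise ValueError("pitch and wavelength must be positive")

    @property
    def num_planes(self) -> int:
        return len(self.z_planes)

    @property
    def reference(self) -> np.ndarray:
        return self.holograms[self.reference_index]

    @property
    def z_ref(self) -> float:
        return self.z_planes[self.reference_index]


@dataclass
class ConvergenceTrace:
    """Per-iteration reference-plane RMSE and its consecutive differences.

    ``delta_rmse[m] = rmse_per_iteration[m + 1] - rmse_per_iteration[m]``;
    it has one entry fewer than ``rmse_per_iteration``.
    """

    rmse_per_iteration: list[float] = field(default_factory=list)
    iterations_run: int = 0

    @property
    def delta_rmse(self) -> list[float]:
        r = self.rmse_per_iteration
        return [b - a for a, b in zip(r, r[1:])]

    def to_dict(self) -> dict:
        return {
            "rmse_per_iteration": self.rmse_per_iteration,
            "delta_rmse": self.delta_rmse,
            "iterations_run": self.iterations_run,
        }


def amplitude_constraint(fld: ComplexField, measured: np.ndarray) -> ComplexField:
    """Replace the field modulus with a measured amplitude, keeping phase.

    Pixels whose input value is exactly 0 have undefined phase; they get
    phase 0 by convention.
    """
    measured = np.asarray(measured, dtype=np.float64)
    if measured.shape != fld.shape:
        raise ValueError(
            f"measured amplitude shape {measured.shape} != field shape {fld.shape}"
        )
    if np.any(measured < 0):
        raise ValueError("measured amplitude must be nonnegative")
    phase = np.angle(fld.values)  # angle(0) == 0: zero-phase convention
    values = measured * np.exp(1j * phase)
    return ComplexField(values, fld.pitch, fld.wavelength, fld.z)


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized root-mean-square error between two amplitude images.

    Both images are max-normalized (:func:`normalize_amplitude`) before
    ``sqrt(mean((a' - b')**2))`` is taken; symmetric and >= 0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    a_n = normalize_amplitude(a)
    b_n = normalize_amplitude(b)
    return float(np.sqrt(np.mean((a_n - b_n) ** 2)))


def _sweep_order(num_planes: int, reference: int) -> list[int]:
    """Plane visiting order for one iteration: ref -> top -> bottom -> ref."""
    down = list(range(reference + 1, num_planes))
    up = list(range(num_planes - 2, -1, -1))
    back = list(range(1, reference + 1))
    return down + up + back


def _sweep(values: np.ndarray, stack: MultiDepthStack, band_limited: bool) -> np.ndarray:
    """One full propagation sweep starting and ending at the reference plane.

    The amplitude constraint is applied at every visited plane except the
    final arrival back at the reference (left to the caller, which needs
    the unconstrained amplitude for the convergence RMSE).
    """
    r = stack.reference_index
    order = _sweep_order(stack.num_planes, r)
    fld = ComplexField(values, stack.pitch, stack.wavelength, stack.z_ref)
    current = r
    for j, plane in enumerate(order):
        fld = propagate(
            fld, stack.z_planes[plane] - stack.z_planes[current],
            band_limited=band_limited,
        )
        current = plane
        if j < len(order) - 1:
            fld = amplitude_constraint(fld, stack.holograms[plane])
    return fld.values


def multi_depth_retrieve(
    stack: MultiDepthStack,
    iterations: int = 10,
    tol: float = 1e-6,
    band_limited: bool = False,
) -> tuple[ComplexField, ConvergenceTrace]:
    """Iterative multi-plane phase retrieval at the reference plane.

    Initializes with the measured reference amplitude and zero phase, then
    runs up to ``iterations`` propagation sweeps, each ending with the RMSE
    between the measured reference hologram and the returning field
    amplitude.  Stops early once ``|delta RMSE| < tol`` (the per-iteration
    RMSE change), mirroring the usual fixed-cap behaviour otherwise.

    Returns the field ``H_ref * exp(i * phi_f)`` (measured reference
    amplitude carrying the retrieved phase) and the convergence trace.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if stack.num_planes < 2:
        raise ValueError("need at least 2 planes")
    values = stack.reference.astype(np.complex128)  # phi = 0 initialization
    trace = ConvergenceTrace()
    for _ in range(iterations):
        values = _sweep(values, stack, band_limited)
        trace.rmse_per_iteration.append(rmse(stack.reference, np.abs(values)))
        trace.iterations_run += 1
        # re-impose the measured amplitude at the reference plane
        fld = ComplexField(values, stack.pitch, stack.wavelength, stack.z_ref)
        values = amplitude_constraint(fld, stack.reference).values
        if len(trace.rmse_per_iteration) >= 2 and abs(trace.delta_rmse[-1]) < tol:
            break
    out = ComplexField(values, stack.pitch, stack.wavelength, stack.z_ref)
    return out, trace
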