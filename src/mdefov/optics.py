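"""Sampled scalar wavefields and angular-spectrum free-space propagation.

This module is the numerical engine of the package: a :class:`ComplexField`
carries a 2-D complex wavefront together with its sampling pitch, wavelength
and axial position, and :func:`propagate` moves it along the optical axis
with the exact (non-paraxial scalar) angular-spectrum transfer function.

Conventions
-----------
* Arrays are indexed ``(row, col)`` with ``row`` increasing downward (+y)
  and ``col`` increasing rightward (+x).
* All lengths are SI metres.  Unit conversion happens at the I/O boundary.
* Frequency grids follow the standard discrete-Fourier layout with the zero
  frequency at the array origin (``numpy.fft.fftfreq``).
* Evanescent frequencies (``fx**2 + fy**2 > 1/wavelength**2``) are
  hard-zeroed by the transfer function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ComplexField",
    "OpticalConfig",
    "SamplingValidityWarning",
    "alias_free_distance",
    "angular_spectrum_kernel",
    "propagate",
    "normalize_amplitude",
]


class SamplingValidityWarning(UserWarning):
    """Propagation distance exceeds the alias-free bound of the plain kernel."""


@dataclass
class ComplexField:
    """A sampled 2-D complex wavefront.

    Parameters
    ----------
    values : ndarray
        2-D complex field amplitude (unitless).
    pitch : float
        Sample spacing in metres per pixel (square pixels).
    wavelength : float
        Illumination wavelength in metres.
    z : float
        Axial position in metres, relative to the object plane.
    """

    values: np.ndarray
    pitch: float
    wavelength: float
    z: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError(f"field values must be 2-D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values contain NaN or Inf")
        if not (self.pitch > 0):
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        if not (self.wavelength > 0):
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    @property
    def energy(self) -> float:
        """Total energy ``sum(|values|**2)``."""
        return float(np.sum(np.abs(self.values) ** 2))

    @property
    def fov_side(self) -> float:
        """Physical side length of the (smaller) field extent, metres."""
        return min(self.shape) * self.pitch

    def copy(self) -> "ComplexField":
        return replace(self, values=self.values.copy())


@dataclass(frozen=True)
class OpticalConfig:
    """Acquisition geometry: wavelength, pixel pitch and sensor planes.

    ``z_planes`` are object-to-sensor distances in metres, strictly
    increasing.  ``reference_index`` selects the reconstruction plane and is
    0-based (the middle plane of five has index 2).
    """

    wavelength: float
    pitch: float
    z_planes: tuple[float, ...]
    reference_index: int = 0
    fov_side: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "z_planes", tuple(float(z) for z in self.z_planes))
        if not (self.wavelength > 0):
            raise ValueError("wavelength must be positive")
        if not (self.pitch > 0):
            raise ValueError("pitch must be positive")
        if len(self.z_planes) < 1:
            raise ValueError("need at least one z plane")
        if any(b <= a for a, b in zip(self.z_planes, self.z_planes[1:])):
            raise ValueError(f"z_planes must be strictly increasing: {self.z_planes}")
        if not (0 <= self.reference_index < len(self.z_planes)):
            raise ValueError(
                f"reference_index {self.reference_index} out of range for "
                f"{len(self.z_planes)} planes"
            )

    @property
    def num_planes(self) -> int:
        return len(self.z_planes)

    @property
    def z_ref(self) -> float:
        return self.z_planes[self.reference_index]


def alias_free_distance(shape: Sequence[int], pitch: float, wavelength: float) -> float:
    """Largest |dz| for which the plain transfer function is alias-free.

    The sampled kernel phase stays below the Nyquist rate of the frequency
    grid for ``|dz| <= N * pitch**2 / wavelength`` with ``N`` the smaller
    array side.  Beyond that, use the band-limited kernel.
    """
    return min(shape) * pitch**2 / wavelength


def angular_spectrum_kernel(
    shape: Sequence[int],
    pitch: float,
    wavelength: float,
    dz: float,
    band_limited: bool = False,
) -> np.ndarray:
    """Angular-spectrum transfer function for a propagation step ``dz``.

    Returns the 2-D complex kernel ``exp(i*2*pi*dz*sqrt(1/wavelength**2 -
    fx**2 - fy**2))`` on the propagating support and exactly 0 at evanescent
    frequencies.  With ``band_limited=True`` the local-frequency cutoff of
    the band-limited angular spectrum method is additionally applied, which
    suppresses kernel aliasing for distances beyond
    :func:`alias_free_distance`.
    """
    if not (pitch > 0):
        raise ValueError(f"pitch must be positive, got {pitch}")
    if not (wavelength > 0):
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    rows, cols = int(shape[0]), int(shape[1])
    fy = np.fft.fftfreq(rows, d=pitch)[:, None]
    fx = np.fft.fftfreq(cols, d=pitch)[None, :]
    arg = 1.0 / wavelength**2 - fx**2 - fy**2
    propagating = arg >= 0.0
    kernel = np.zeros((rows, cols), dtype=np.complex128)
    kernel[propagating] = np.exp(
        1j * 2.0 * np.pi * dz * np.sqrt(arg[propagating])
    )
    if band_limited and dz != 0.0:
        # Local-frequency cutoff (Matsushima-style band limit): zero the
        # kernel where its sampled phase gradient exceeds the grid Nyquist.
        dfy = 1.0 / (rows * pitch)
        dfx = 1.0 / (cols * pitch)
        fy_lim = 1.0 / (wavelength * np.hypot(2.0 * dz * dfy, 1.0))
        fx_lim = 1.0 / (wavelength * np.hypot(2.0 * dz * dfx, 1.0))
        kernel[(np.abs(fy) > fy_lim) | (np.abs(fx) > fx_lim)] = 0.0
    return kernel


def propagate(
    fld: ComplexField,
    dz: float,
    band_limited: bool = False,
    validity: str = "warn",
) -> ComplexField:
    """Propagate a field a distance ``dz`` (metres) along the optical axis.

    Parameters
    ----------
    fld : ComplexField
        Input wavefront.
    dz : float
        Signed propagation distance; negative values back-propagate.
    band_limited : bool
        Apply the band-limited kernel (required for distances beyond the
        alias-free bound; see :func:`alias_free_distance`).
    validity : {"warn", "error", "ignore"}
        What to do when ``|dz|`` exceeds the alias-free bound and
        ``band_limited`` is off.

    Returns
    -------
    ComplexField
        The propagated field, with ``z`` advanced by ``dz``.
    """
    if validity not in ("warn", "error", "ignore"):
        raise ValueError(f"unknown validity policy {validity!r}")
    if not band_limited:
        bound = alias_free_distance(fld.shape, fld.pitch, fld.wavelength)
        if abs(dz) > bound:
            msg = (
                f"|dz| = {abs(dz):.4g} m exceeds the alias-free bound "
                f"{bound:.4g} m for shape {fld.shape}; enable band_limited "
                "propagation or reduce the distance"
            )
            if validity == "error":
                raise ValueError(msg)
            if validity == "warn":
                warnings.warn(msg, SamplingValidityWarning, stacklevel=2)
    if dz == 0.0:
        return replace(fld, values=fld.values.copy())
    kernel = angular_spectrum_kernel(
        fld.shape, fld.pitch, fld.wavelength, dz, band_limited=band_limited
    )
    spectrum = np.fft.fft2(fld.values)
    out = np.fft.ifft2(spectrum * kernel)
    return replace(fld, values=out, z=fld.z + dz)


def normalize_amplitude(image: np.ndarray) -> np.ndarray:
    """Scale a nonnegative image by its maximum so that max(output) == 1.

    Division by the maximum preserves the zero background of amplitude
    holograms (the minimum is *not* forced to 0).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains NaN or Inf")
    if np.any(image < 0):
        raise ValueError("image must be nonnegative")
    peak = image.max()
    if peak == 0:
        raise ValueError("cannot normalize an all-zero image")
    return image / peak
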