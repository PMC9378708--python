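"""Scalar free-space propagation by the angular spectrum method.

This module is the physics kernel shared by the hologram simulator and the
iterative multi-height phase-retrieval solver.  A monochromatic scalar field
sampled on a regular grid is propagated a distance ``z`` by multiplying its
2D spatial-frequency spectrum with the transfer function

    H(fx, fy) = exp(i 2*pi*z * sqrt((n/lambda)^2 - fx^2 - fy^2))

on propagating frequencies (``fx^2 + fy^2 <= (n/lambda)^2``); evanescent
frequencies are hard-zeroed.  Distances in this package are hundreds of
micrometres, so evanescent content is negligible anyway and zeroing avoids
exponential overflow for negative ``z``.

Conventions (used consistently package-wide):

* forward DFT with negative exponent and no scaling, inverse DFT carries the
  1/N^2 factor (numpy's default "backward" normalization);
* the frequency grid follows the standard DFT sample spacing 1/(N*pitch)
  with DC at index 0;
* all lengths are in micrometres; fields are dimensionless transmittances.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field, replace

import numpy as np

__all__ = [
    "ComplexField",
    "TransferFunction",
    "angular_spectrum_transfer",
    "propagate",
]


@dataclass
class ComplexField:
    """A 2D complex optical field with its sampling metadata.

    Parameters
    ----------
    grid
        2D complex array of field values (dimensionless).
    pitch
        Pixel spacing in micrometres.
    wavelength
        Illumination wavelength in micrometres.
    medium_index
        Refractive index of the propagation medium (1.0 = air).
    """

    grid: np.ndarray
    pitch: float
    wavelength: float
    medium_index: float = 1.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.complex128)
        if self.grid.ndim != 2 or min(self.grid.shape) < 2:
            raise ValueError("field grid must be 2D with at least 2 rows and 2 columns")
        if not np.all(np.isfinite(self.grid.view(np.float64))):
            raise ValueError("field grid contains non-finite values")
        if self.pitch <= 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.grid)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.grid) ** 2

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.grid)

    def copy(self) -> "ComplexField":
        return replace(self, grid=self.grid.copy())


@dataclass
class TransferFunction:
    """Angular-spectrum transfer function sampled on the DFT frequency grid.

    ``grid`` has unit modulus on propagating frequencies and is zero on
    evanescent ones; DC sits at index (0, 0).
    """

    grid: np.ndarray
    z: float
    pitch: float = dataclass_field(default=1.0)
    wavelength: float = dataclass_field(default=1.0)


def _frequency_grids(shape: tuple[int, int], pitch: float) -> tuple[np.ndarray, np.ndarray]:
    fy = np.fft.fftfreq(shape[0], d=pitch)
    fx = np.fft.fftfreq(shape[1], d=pitch)
    return fy[:, None], fx[None, :]


def angular_spectrum_transfer(
    shape: tuple[int, int],
    pitch: float,
    wavelength: float,
    z: float,
    medium_index: float = 1.0,
) -> TransferFunction:
    """Build the angular-spectrum transfer function for a propagation of ``z``.

    Parameters
    ----------
    shape
        Grid dimensions (rows, cols); each must be >= 2.
    pitch
        Sample spacing in micrometres.
    wavelength
        Wavelength in micrometres.
    z
        Propagation distance in micrometres (may be negative for
        back-propagation).
    medium_index
        Refractive index of the medium between the planes.

    Returns
    -------
    TransferFunction
        ``exp(i 2 pi z sqrt((n/lambda)^2 - fx^2 - fy^2))`` on propagating
        frequencies, zero on evanescent ones, DC at index 0.
    """
    if pitch <= 0 or wavelength <= 0:
        raise ValueError("pitch and wavelength must be positive")
    if len(shape) != 2 or min(shape) < 2:
        raise ValueError("shape must be 2D with each dimension >= 2")
    fy, fx = _frequency_grids(shape, pitch)
    f_cut_sq = (medium_index / wavelength) ** 2
    arg = f_cut_sq - fx**2 - fy**2
    propagating = arg >= 0
    kz = np.sqrt(np.where(propagating, arg, 0.0))
    if z == 0:
        H = np.ones(np.broadcast_shapes(fy.shape, fx.shape), dtype=complex)
    else:
        H = np.where(propagating, np.exp(2j * np.pi * z * kz), 0.0 + 0.0j)
    return TransferFunction(grid=H, z=z, pitch=pitch, wavelength=wavelength)


def propagate(field: ComplexField, z: float, pad: bool = False) -> ComplexField:
    """Propagate a field a distance ``z`` via the angular spectrum method.

    ``propagate(f, 0)`` is the identity up to floating-point error, and the
    operation forms a semigroup in ``z``.  Metadata (pitch, wavelength,
    medium index) is carried through unchanged.

    Parameters
    ----------
    field
        The input field.
    z
        Propagation distance in micrometres; negative back-propagates.
    pad
        If True, zero-pad each dimension to the next power of two before the
        transform to suppress periodic wrap-around, then crop back.  Off by
        default; unnecessary for the distances and field sizes used here.
    """
    grid = field.grid
    orig_shape = grid.shape
    if pad:
        padded_shape = tuple(1 << int(np.ceil(np.log2(2 * s))) for s in orig_shape)
        buf = np.zeros(padded_shape, dtype=np.complex128)
        buf[: orig_shape[0], : orig_shape[1]] = grid
        grid = buf
    H = angular_spectrum_transfer(
        grid.shape, field.pitch, field.wavelength, z, field.medium_index
    )
    out = np.fft.ifft2(H.grid * np.fft.fft2(grid))
    if pad:
        out = out[: orig_shape[0], : orig_shape[1]]
    return ComplexField(
        grid=out,
        pitch=field.pitch,
        wavelength=field.wavelength,
        medium_index=field.medium_index,
    )
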