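"""Synthetic specimens and lensfree multi-height hologram simulation.

Two phantom families emulate the sample classes seen by lensfree in-line
holographic microscopes of thin transmissive specimens:

``connected_tissue``
    spatially connected, texture-like transmittance fields (histopathology
    sections): Gaussian-filtered white noise with a controllable correlation
    length is mapped through smooth monotone functions to amplitude and
    phase.
``sparse_cells``
    isolated smooth objects on a unit background (smear-type slides): a
    Poisson-distributed number of randomly placed super-Gaussian blobs.

The thin-object approximation is assumed throughout: the specimen acts as a
multiplicative complex transmittance ``A * exp(i phi)`` on a unit plane wave.
Intensity holograms are formed by angular-spectrum propagation to each
sample-to-sensor distance; optional Poisson shot noise (parameterised by a
photon budget), Gaussian read noise and quantization model the sensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .wave_optics import ComplexField, propagate

__all__ = [
    "PhantomParams",
    "SensorParams",
    "HologramStack",
    "generate_phantom",
    "simulate_hologram_stack",
    "simulate_shifted_lowres_set",
]

PHANTOM_KINDS = ("connected_tissue", "sparse_cells")


@dataclass
class PhantomParams:
    """Parameters of a synthetic complex-transmittance phantom.

    Defaults are the package's standard study conditions: a weakly absorbing
    (amplitude 0.75–1.0), weakly phase-shifting (0–0.8 rad) thin object with
    5 um texture correlation length, matching the scale of cellular detail
    resolved at a 0.37 um effective pixel.
    """

    kind: str = "connected_tissue"
    size: tuple[int, int] = (256, 256)
    pitch: float = 0.37
    wavelength: float = 0.530
    amplitude_range: tuple[float, float] = (0.75, 1.0)
    phase_range: tuple[float, float] = (0.0, 0.8)
    correlation_length: float = 5.0   # um, connected_tissue
    cell_density: float = 500.0       # objects per mm^2, sparse_cells
    cell_radius: float = 8.0          # um, sparse_cells
    seed: int = 0

    def validate(self) -> None:
        a0, a1 = self.amplitude_range
        if not (0.0 <= a0 <= a1 <= 1.0):
            raise ValueError("amplitude_range must satisfy 0 <= a_min <= a_max <= 1")
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {PHANTOM_KINDS}")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")


@dataclass
class SensorParams:
    """Image-sensor model: pixel pitch, binning factor, noise, quantization."""

    pixel_pitch: float = 2.24          # um, CMOS pixel
    downsample_factor: int = 1
    shot_noise: bool = False
    photons_per_pixel: float = 10_000  # photon budget at unit intensity
    read_noise_sigma: float = 0.0      # in intensity units
    bit_depth: int | None = None       # None = no quantization

    def validate(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.bit_depth is not None and not (8 <= self.bit_depth <= 16):
            raise ValueError("bit_depth must be in 8..16")


@dataclass
class HologramStack:
    """M co-registered intensity holograms with their acquisition distances."""

    images: list[np.ndarray]
    distances: list[float]    # z2,i in um
    pitch: float              # um
    wavelength: float         # um
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.images) < 1:
            raise ValueError("a hologram stack needs at least one image")
        if len(self.images) != len(self.distances):
            raise ValueError("one distance per image required")
        if len(set(float(z) for z in self.distances)) != len(self.distances):
            raise ValueError("sample-to-sensor distances must be pairwise distinct")
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1:
            raise ValueError("all hologram planes must share one shape")
        for im in self.images:
            if np.any(im < 0):
                raise ValueError("intensities must be non-negative")

    @property
    def m(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape


def _correlated_noise(rng: np.random.Generator, size: tuple[int, int], sigma_px: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian field with correlation length ~sigma_px."""
    white = rng.standard_normal(size)
    smooth = ndimage.gaussian_filter(white, sigma_px, mode="wrap")
    smooth -= smooth.mean()
    std = smooth.std()
    if std > 0:
        smooth /= std
    return smooth


def generate_phantom(params: PhantomParams) -> ComplexField:
    """Generate a complex transmittance phantom, deterministic in the seed.

    Returns a :class:`ComplexField` with amplitude inside
    ``params.amplitude_range`` and phase inside ``params.phase_range``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    a0, a1 = params.amplitude_range
    p0, p1 = params.phase_range
    size = tuple(params.size)

    if params.kind == "connected_tissue":
        # The autocorrelation of white noise filtered by a Gaussian of std
        # sigma is a Gaussian of std sigma*sqrt(2), whose 1/e half-width is
        # 2*sigma; invert that to hit the requested correlation length.
        sigma_px = params.correlation_length / params.pitch / 2.0
        t_amp = _correlated_noise(rng, size, sigma_px)
        t_phi = _correlated_noise(rng, size, sigma_px)
        # logistic squashing keeps values strictly inside the stated ranges
        amp = a0 + (a1 - a0) / (1.0 + np.exp(-1.2 * t_amp))
        phi = p0 + (p1 - p0) / (1.0 + np.exp(-1.2 * t_phi))
    else:  # sparse_cells
        fov_mm2 = (size[0] * params.pitch * 1e-3) * (size[1] * params.pitch * 1e-3)
        # at least one object: an empty field is not a specimen
        n_cells = max(1, int(rng.poisson(params.cell_density * fov_mm2)))
        depth = np.zeros(size)
        yy = np.arange(size[0])[:, None]
        xx = np.arange(size[1])[None, :]
        r_px = params.cell_radius / params.pitch
        for _ in range(n_cells):
            cy = rng.uniform(0, size[0])
            cx = rng.uniform(0, size[1])
            r = r_px * rng.uniform(0.6, 1.4)
            rho2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / r**2
            depth += rng.uniform(0.5, 1.0) * np.exp(-(rho2**2))  # super-Gaussian
        depth = np.clip(depth, 0.0, 1.0)
        amp = a1 - (a1 - a0) * depth
        phi = p0 + (p1 - p0) * depth

    grid = amp * np.exp(1j * phi)
    return ComplexField(grid=grid, pitch=params.pitch, wavelength=params.wavelength)


def _apply_sensor_noise(
    intensity: np.ndarray, sensor: SensorParams, rng: np.random.Generator
) -> np.ndarray:
    out = intensity
    if sensor.shot_noise:
        out = rng.poisson(np.clip(out, 0, None) * sensor.photons_per_pixel) / sensor.photons_per_pixel
    if sensor.read_noise_sigma > 0:
        out = out + rng.normal(0.0, sensor.read_noise_sigma, out.shape)
    out = np.clip(out, 0.0, None)
    if sensor.bit_depth is not None:
        levels = 2**sensor.bit_depth - 1
        # full scale = 2x the mean intensity, a typical exposure choice
        full_scale = 2.0 * max(out.mean(), np.finfo(float).tiny)
        out = np.round(np.clip(out / full_scale, 0, 1) * levels) / levels * full_scale
    return out


def _box_downsample(image: np.ndarray, q: int) -> np.ndarray:
    h, w = image.shape
    h2, w2 = (h // q) * q, (w // q) * q
    return image[:h2, :w2].reshape(h2 // q, q, w2 // q, q).mean(axis=(1, 3))


def simulate_hologram_stack(
    field: ComplexField,
    distances: list[float],
    sensor: SensorParams | None = None,
    seed: int = 0,
) -> HologramStack:
    """Simulate the M-height in-line hologram acquisition of ``field``.

    Each plane is ``|propagate(field, z_i)|^2`` passed through the sensor
    model (shot noise, read noise, binning, quantization).  With noise and
    binning off the planes equal the direct intensity computation exactly.
    """
    if len(distances) == 0:
        raise ValueError("at least one distance required")
    if len(set(float(z) for z in distances)) != len(distances):
        raise ValueError("distances must be pairwise distinct")
    sensor = sensor or SensorParams()
    sensor.validate()
    rng = np.random.default_rng(seed)
    images = []
    for z in distances:
        intensity = propagate(field, z).intensity
        if sensor.downsample_factor > 1:
            intensity = _box_downsample(intensity, sensor.downsample_factor)
        images.append(_apply_sensor_noise(intensity, sensor, rng))
    pitch = field.pitch * sensor.downsample_factor
    return HologramStack(
        images=images,
        distances=[float(z) for z in distances],
        pitch=pitch,
        wavelength=field.wavelength,
        meta={"seed": seed},
    )


def _fourier_shift(image: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Circularly shift a real image by a (possibly fractional) pixel amount."""
    ky = np.fft.fftfreq(image.shape[0])[:, None]
    kx = np.fft.fftfreq(image.shape[1])[None, :]
    phase = np.exp(-2j * np.pi * (ky * dy + kx * dx))
    return np.real(np.fft.ifft2(np.fft.fft2(image) * phase))


def simulate_shifted_lowres_set(
    field: ComplexField,
    z: float,
    shift_grid: list[tuple[float, float]],
    sensor: SensorParams,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[tuple[float, float]]]:
    """Simulate sub-pixel-shifted low-resolution captures of one hologram.

    Shifts are given in low-resolution pixel units as (dx, dy); each capture
    is the high-resolution intensity laterally shifted by that amount
    (Fourier shift, exact for band-limited fields) and then box-integrated by
    the sensor's downsample factor.  Returns the images together with the
    ground-truth shifts for downstream testing.
    """
    if len(shift_grid) == 0:
        raise ValueError("shift grid must be non-empty")
    sensor.validate()
    if sensor.downsample_factor <= 1:
        raise ValueError("shifted low-res capture requires downsample_factor > 1")
    q = sensor.downsample_factor
    rng = np.random.default_rng(seed)
    intensity_hr = propagate(field, z).intensity
    images = []
    for dx, dy in shift_grid:
        # shift convention: (dx, dy) is the content displacement in the
        # captured image, in low-res pixels: image(x) = scene(x - d)
        shifted = _fourier_shift(intensity_hr, dy * q, dx * q)
        low = _box_downsample(shifted, q)
        images.append(_apply_sensor_noise(low, sensor, rng))
    return images, [(float(dx), float(dy)) for dx, dy in shift_grid]


def regular_shift_grid(n: int = 6) -> list[tuple[float, float]]:
    """The n x n sub-pixel shift raster (spacing 1/n low-res pixel)."""
    return [(ix / n, iy / n) for iy in range(n) for ix in range(n)]
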