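"""Partially coherent image formation for the LED-array microscope.

Two forward models are provided:

* :func:`abbe_image` — the exact partially coherent model.  Each lit LED is
  a mutually incoherent point source launching a tilted plane wave through
  the thin specimen; its coherent image is the specimen spectrum filtered
  by the pupil shifted to the LED's spatial frequency, and the camera sums
  the intensities::

      I(x) = Σ_j | IFT[ P(u + u_j) · FT[t(x)] ] |²,
      t = exp(-absorption) · exp(i·2π·opl/λ)

* :func:`wotf` / :func:`linear_image` — the first-order (weak-object)
  linearization.  For a point-source sum the absorption and phase transfer
  functions are discrete source–pupil correlations::

      h_abs(u) = -Σ_j [P(u + u_j) + P(u - u_j)],
      h_ph(u)  = i·Σ_j [P(u + u_j) - P(u - u_j)],
      dc_level = number of lit LEDs inside the pupil,

  so that I ≈ dc_level + IFT[h_abs·FT(μ) + h_ph·FT(φ)] for small phase φ
  and absorption μ.  Both models use the same continuous LED tilt
  frequencies and the same analytically evaluated shifted-pupil masks, so
  the linearization agrees with the Abbe sum to first order by
  construction.

All FFTs are unitary ("ortho") and frequency grids are in cycles/µm in FFT
layout.  The Abbe model pads the field by ~10% with an apodized
(cosine-tapered) extension of the object before imaging and crops after,
which suppresses periodic wrap-around at the field edges.

A small camera model (:class:`NoiseModel`, :func:`apply_noise`,
:func:`dark_frame`) converts normalized intensities into quantized counts
with shot noise, Gaussian read noise and a fixed offset, reproducibly from
a seed.  It underpins the noise-floor, centering and darkfield-SNR
procedures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .exceptions import ConfigError, GridMismatchError
from .optics import IlluminationPattern, OpticalSystem, led_spatial_frequency
from .phantoms import SpecimenField


def frequency_grid(shape: tuple[int, int],
                   pixel_size_um: float) -> tuple[np.ndarray, np.ndarray]:
    """FFT-layout frequency grids ``(uy, ux)`` in cycles/µm."""
    uy = np.fft.fftfreq(shape[0], d=pixel_size_um)
    ux = np.fft.fftfreq(shape[1], d=pixel_size_um)
    return np.meshgrid(uy, ux, indexing="ij")


def pupil_mask(shape: tuple[int, int], pixel_size_um: float,
               optics: OpticalSystem,
               shift_cycles_per_um: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Binary pupil indicator |u + shift| <= NA/λ on the FFT frequency grid."""
    uy, ux = frequency_grid(shape, pixel_size_um)
    sx, sy = shift_cycles_per_um
    cutoff = optics.pupil_cutoff_cycles_per_um
    return (ux + sx) ** 2 + (uy + sy) ** 2 <= cutoff ** 2


@dataclass
class TransferFunctions:
    """First-order absorption/phase transfer functions for one pattern.

    ``h_abs`` and ``h_ph`` live on the FFT frequency grid (cycles/µm);
    ``dc_level`` is the mean unscattered background intensity in per-LED
    radiance units (= number of lit LEDs inside the pupil).
    """

    h_abs: np.ndarray
    h_ph: np.ndarray
    dc_level: float
    pixel_size_um: float
    label: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.h_ph.shape


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise at ``photons_at_unity`` expected
    photons per unit normalized intensity, Gaussian read noise, a fixed
    offset, and quantization to ``bit_depth`` bits.  Fully reproducible
    from ``seed``."""

    photons_at_unity: float = 10000.0
    read_noise_sd: float = 0.0
    offset: float = 0.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.photons_at_unity < 0 or self.read_noise_sd < 0 or self.offset < 0:
            raise ConfigError("noise-model parameters must be non-negative")
        if not (1 <= self.bit_depth <= 32):
            raise ConfigError("bit_depth must be between 1 and 32")


def _lit_frequencies(pattern: IlluminationPattern,
                     wavelength_um: float) -> np.ndarray:
    """(n_lit, 2) array of LED tilt frequencies (ux, uy) in cycles/µm."""
    xs, ys = pattern.lit_positions_mm()
    d = pattern.geom.distance_mm
    freqs = [led_spatial_frequency((x, y), d, wavelength_um) for x, y in zip(xs, ys)]
    return np.array(freqs).reshape(-1, 2)


def _pad_apodize(t: np.ndarray, pad_fraction: float) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Pad the complex transmittance by ``pad_fraction`` of the field on
    each side with an edge-replicated, cosine-tapered extension that decays
    to vacuum (t = 1) at the outer border.  Returns the padded array and
    the slices that crop back to the original field."""
    if pad_fraction <= 0:
        return t, (slice(None), slice(None))
    ny, nx = t.shape
    py = sfft.next_fast_len(ny + 2 * max(int(round(pad_fraction * ny / 2)), 4)) - ny
    px = sfft.next_fast_len(nx + 2 * max(int(round(pad_fraction * nx / 2)), 4)) - nx
    py0, px0 = py // 2, px // 2
    padded = np.pad(t - 1.0, ((py0, py - py0), (px0, px - px0)), mode="edge")

    def taper(n_pad0, n_pad1, n):
        w = np.ones(n_pad0 + n + n_pad1)
        if n_pad0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_pad0) / n_pad0))
            w[:n_pad0] = ramp
        if n_pad1:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_pad1) / n_pad1))
            w[-n_pad1:] = ramp[::-1]
        return w

    wy = taper(py0, py - py0, ny)
    wx = taper(px0, px - px0, nx)
    padded *= wy[:, None] * wx[None, :]
    padded += 1.0
    return padded, (slice(py0, py0 + ny), slice(px0, px0 + nx))


def abbe_image(specimen: SpecimenField, pattern: IlluminationPattern,
               optics: OpticalSystem, pad_fraction: float = 0.1) -> np.ndarray:
    """Exact partially coherent intensity image (per-LED radiance units).

    LEDs are mutually incoherent with equal radiance; a dark pattern yields
    an all-zero image; an empty specimen under brightfield yields a
    spatially uniform image equal to the number of lit LEDs inside the
    pupil.  Out-of-pupil LEDs contribute only specimen-scattered light
    (the physical darkfield signal).
    """
    if specimen.pixel_size_um <= 0:
        raise ConfigError("specimen pixel size must be positive")
    if pattern.n_lit == 0:
        return np.zeros(specimen.shape)
    t = specimen.transmittance(optics.wavelength_um)
    tpad, crop = _pad_apodize(t, pad_fraction)
    T = sfft.fft2(tpad, norm="ortho")
    uy, ux = frequency_grid(tpad.shape, specimen.pixel_size_um)
    cutoff2 = optics.pupil_cutoff_cycles_per_um ** 2
    u_grid_max = float(np.abs(uy).max() + np.abs(ux).max())
    intensity = np.zeros(tpad.shape)
    for ujx, ujy in _lit_frequencies(pattern, optics.wavelength_um):
        if np.hypot(ujx, ujy) > np.sqrt(cutoff2) + u_grid_max:
            continue  # shifted pupil has no overlap with the sampled band
        mask = (ux + ujx) ** 2 + (uy + ujy) ** 2 <= cutoff2
        if not mask.any():
            continue
        field = sfft.ifft2(np.where(mask, T, 0.0), norm="ortho")
        intensity += np.abs(field) ** 2
    return intensity[crop]


def wotf(pattern: IlluminationPattern, optics: OpticalSystem,
         grid_shape: tuple[int, int], pixel_size_um: float) -> TransferFunctions:
    """Weak-object transfer functions of one illumination pattern.

    Evaluates the source–pupil correlation integral as a discrete sum over
    lit LEDs (each LED a delta in source space), on the FFT frequency grid
    of an image of ``grid_shape`` at ``pixel_size_um``.  Only LEDs inside
    the pupil contribute at first order; a pattern with none (pure
    darkfield) has ``dc_level == 0`` and cannot be used for linear phase
    retrieval.
    """
    uy, ux = frequency_grid(grid_shape, pixel_size_um)
    cutoff = optics.pupil_cutoff_cycles_per_um
    cutoff2 = cutoff ** 2
    s_plus = np.zeros(grid_shape)
    s_minus = np.zeros(grid_shape)
    n_inside = 0
    for ujx, ujy in _lit_frequencies(pattern, optics.wavelength_um):
        if ujx * ujx + ujy * ujy > cutoff2:
            continue  # out-of-pupil LED: no first-order contribution
        n_inside += 1
        s_plus += (ux + ujx) ** 2 + (uy + ujy) ** 2 <= cutoff2
        s_minus += (ux - ujx) ** 2 + (uy - ujy) ** 2 <= cutoff2
    h_abs = -(s_plus + s_minus).astype(complex)
    h_ph = 1j * (s_plus - s_minus)
    return TransferFunctions(h_abs, h_ph, float(n_inside), pixel_size_um,
                             label=pattern.label)


def linear_image(specimen: SpecimenField, tfs: TransferFunctions,
                 optics: OpticalSystem) -> np.ndarray:
    """First-order image I = dc_level + IFT[h_abs·FT(μ) + h_ph·FT(φ)].

    Exactly linear in the specimen's phase and absorption; matches
    :func:`abbe_image` to first order in the weak-object limit.
    """
    if specimen.shape != tfs.shape:
        raise GridMismatchError(
            f"specimen grid {specimen.shape} != transfer-function grid {tfs.shape}")
    if abs(specimen.pixel_size_um - tfs.pixel_size_um) > 1e-9:
        raise GridMismatchError("specimen and transfer functions disagree on pixel size")
    phi = 2.0 * np.pi * specimen.opl / optics.wavelength_um
    spectrum = (tfs.h_abs * sfft.fft2(specimen.absorption, norm="ortho")
                + tfs.h_ph * sfft.fft2(phi, norm="ortho"))
    ac = sfft.ifft2(spectrum, norm="ortho")
    residue = np.abs(ac.imag).max()
    dynamic = max(np.abs(ac.real).max(), 1.0)
    if residue > 1e-10 * dynamic:  # h symmetry guarantees a real image
        raise RuntimeError(f"linear image has imaginary residue {residue:.3g}")
    return tfs.dc_level + ac.real


def apply_noise(image: np.ndarray, model: NoiseModel,
                seed: int | None = None) -> np.ndarray:
    """Convert normalized intensity to quantized camera counts.

    Per pixel: Poisson(photons_at_unity · I) + N(0, read_noise_sd) +
    offset, clipped to [0, 2^bit_depth − 1] and rounded.  ``seed``
    overrides the model's seed (used for per-frame child seeds).
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("input intensity must be non-negative")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    counts = rng.poisson(model.photons_at_unity * image).astype(float)
    if model.read_noise_sd > 0:
        counts += rng.normal(0.0, model.read_noise_sd, size=image.shape)
    counts += model.offset
    full_scale = 2 ** model.bit_depth - 1
    counts = np.clip(np.rint(counts), 0, full_scale)
    dtype = np.uint16 if model.bit_depth <= 16 else np.uint32
    return counts.astype(dtype)


def dark_frame(model: NoiseModel, shape: tuple[int, int],
               seed: int | None = None) -> np.ndarray:
    """Camera frame with no illumination: noise on an all-zero image."""
    return apply_noise(np.zeros(shape), model, seed=seed)
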