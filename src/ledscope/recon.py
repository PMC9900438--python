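"""DPC signal formation and Tikhonov-regularized quantitative phase retrieval.

Differential phase contrast (DPC) pairs two complementary half-circle
illuminations per axis.  The normalized difference image::

    DPC = (I_a − I_b) / (I_a + I_b)

is, to first order in the specimen phase φ, a linear filtering of φ by the
dc-normalized difference of the two patterns' phase transfer functions::

    FT(DPC_k) ≈ H_k · FT(φ),   H_k = (h_ph,a − h_ph,b) / (dc_a + dc_b)

Stacking the two orthogonal axes, the phase is recovered by a Tikhonov
(least-squares, quadratically penalized) inversion.  The regularization
parameter enters the normal equations squared, as in the textbook form
``min ||HΦ − D||² + reg2²·||Φ||²``::

    φ = Re IFT[ Σ_k conj(H_k)·FT(DPC_k) / (Σ_k |H_k|² + reg2²) ]

``reg2`` is dimensionless because both the DPC maps and the transfer
functions are dc-normalized; the operating default is 1e-3, with 0.004
used by the fixed-regularization coherence sweep.  With this convention
the operating values suppress only the frequencies where the stacked
transfer magnitude falls below ~reg2 — the behavior under which those
published values keep bead optical volumes quantitative.  H_k(0) = 0, so the
retrieval has a DC null space: absolute phase offsets are not recoverable
and downstream measurement subtracts the empty-region median instead.  No
phase unwrapping is applied — the bead standards are designed so the OPL
never exceeds λ/2 — but inputs that would wrap trigger a warning upstream.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import fft as sfft

from .exceptions import ConfigError, GridMismatchError
from .forward import TransferFunctions

#: axis-angle convention: the angle (degrees, counterclockwise from +x) of
#: the normal to the dividing axis selects the half-image pair for that axis
AXIS_PAIRS = {90: ("top", "bottom"), 180: ("left", "right")}


@dataclass(frozen=True)
class ReconstructionConfig:
    """Parameters of the DPC retrieval.

    ``axis_angles_deg`` pairs the four half-images into two orthogonal DPC
    axes (90 → top/bottom, 180 → left/right); ``sigma`` records the
    coherence parameter of the half patterns used (provenance only).
    """

    reg2: float = 1e-3
    axis_angles_deg: tuple[int, ...] = (90, 180)
    sigma: float = 2.1
    wavelength_um: float = 0.63

    def __post_init__(self):
        if self.reg2 <= 0:
            raise ConfigError(f"reg2 must be positive, got {self.reg2}")
        for a in self.axis_angles_deg:
            if a not in AXIS_PAIRS:
                raise ConfigError(
                    f"unsupported axis angle {a}; known angles: {sorted(AXIS_PAIRS)}")
        if self.wavelength_um <= 0:
            raise ConfigError("wavelength_um must be positive")

    def pairs(self) -> list[tuple[str, str]]:
        return [AXIS_PAIRS[a] for a in self.axis_angles_deg]


@dataclass
class PhaseMap:
    """Reconstructed phase (radians) with its pixel grid and provenance."""

    phase: np.ndarray
    pixel_size_um: float
    wavelength_um: float
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        if self.pixel_size_um <= 0 or self.wavelength_um <= 0:
            raise ConfigError("pixel_size_um and wavelength_um must be positive")


def dpc_signal(i_a: np.ndarray, i_b: np.ndarray) -> np.ndarray:
    """Normalized asymmetric-illumination difference (i_a − i_b)/(i_a + i_b).

    Antisymmetric under swapping the inputs.  Pixels where the sum is zero
    (no light on either half) are masked to zero and reported with a
    warning rather than silently propagating NaNs.
    """
    i_a = np.asarray(i_a, dtype=float)
    i_b = np.asarray(i_b, dtype=float)
    if i_a.shape != i_b.shape:
        raise GridMismatchError(f"image shapes differ: {i_a.shape} vs {i_b.shape}")
    total = i_a + i_b
    bad = total == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-sum pixels masked in DPC signal",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, 0.0, (i_a - i_b) / np.where(bad, 1.0, total))
    return out


def dpc_transfer(tf_a: TransferFunctions, tf_b: TransferFunctions) -> np.ndarray:
    """dc-normalized DPC phase transfer H = (h_ph,a − h_ph,b)/(dc_a + dc_b)."""
    if tf_a.shape != tf_b.shape:
        raise GridMismatchError("transfer-function grids differ")
    dc = tf_a.dc_level + tf_b.dc_level
    if dc <= 0:
        raise ConfigError(
            "pattern pair has no LEDs inside the pupil (dc_level == 0); "
            "linear phase retrieval from pure darkfield is refused")
    return (tf_a.h_ph - tf_b.h_ph) / dc


def retrieve_phase(dpc_maps: list[np.ndarray], transfer: list[np.ndarray],
                   config: ReconstructionConfig,
                   pixel_size_um: float) -> PhaseMap:
    """Tikhonov inversion of one or more DPC axes into a phase map (radians).

    ``transfer`` holds the dc-normalized per-axis transfer functions (from
    :func:`dpc_transfer`), index-aligned with ``dpc_maps``.  Deterministic:
    identical inputs and config give bit-identical output.
    """
    if len(dpc_maps) == 0 or len(dpc_maps) != len(transfer):
        raise ConfigError("need >= 1 DPC axis with one transfer function each")
    shape = dpc_maps[0].shape
    numerator = np.zeros(shape, dtype=complex)
    denominator = np.zeros(shape, dtype=float)
    for dpc, h in zip(dpc_maps, transfer):
        if dpc.shape != shape or h.shape != shape:
            raise GridMismatchError("DPC maps and transfer functions must share a grid")
        numerator += np.conj(h) * sfft.fft2(dpc, norm="ortho")
        denominator += np.abs(h) ** 2
    spectrum = numerator / (denominator + config.reg2 ** 2)
    phase = sfft.ifft2(spectrum, norm="ortho").real
    prov = {
        "reg2": config.reg2,
        "axis_angles_deg": list(config.axis_angles_deg),
        "sigma": config.sigma,
        "wavelength_um": config.wavelength_um,
        "input_sha1": _hash_arrays(dpc_maps),
    }
    return PhaseMap(phase, pixel_size_um, config.wavelength_um, prov)


def phase_to_opl(pm: PhaseMap) -> np.ndarray:
    """Optical path length OPL = φ·λ/(2π) in µm."""
    return pm.phase * pm.wavelength_um / (2.0 * np.pi)


def _hash_arrays(arrays: list[np.ndarray]) -> str:
    h = hashlib.sha1()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:12]
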