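"""Synthetic specimens: bead-in-polymer fields, stage-micrometer rulers,
and smooth cell-like blobs.

All phantoms are emitted as :class:`SpecimenField` objects — co-registered
optical-path-length (OPL, µm) and absorption maps on a physical pixel grid.
The workhorse is the polystyrene-bead-in-NOA73 phantom: a sphere of uniform
refractive index ``n_bead`` (default 1.583) embedded in a medium of
``n_medium`` (default 1.56) is a pure-phase object whose OPL at lateral
distance ρ from the bead center is the chord length times the index
difference::

    OPL(ρ) = Δn · 2·sqrt(R² − ρ²),   Δn = n_bead − n_medium

Its integrated OPL (the *optical volume*) equals Δn · (4/3)πR³, which is
the analytic ground truth every calibration sweep in this package scores
against.

Conventions: pixels are sampled at their centers; coordinates are physical
µm with the origin at the top-left pixel center.  Bead edges are
anti-aliased by 4x4 subpixel averaging, since edge pixels dominate the
optical-volume discretization error at coarse sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .exceptions import ConfigError

#: subpixel oversampling factor for bead-edge anti-aliasing
_AA = 4


@dataclass
class SpecimenField:
    """Co-registered OPL (µm) and absorption maps on a physical grid.

    ``absorption`` is the dimensionless amplitude-attenuation exponent:
    complex transmittance = exp(-absorption) * exp(i*2π*opl/λ).
    """

    opl: np.ndarray
    absorption: np.ndarray
    pixel_size_um: float
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.opl = np.asarray(self.opl, dtype=float)
        self.absorption = np.asarray(self.absorption, dtype=float)
        if self.opl.shape != self.absorption.shape:
            raise ConfigError("opl and absorption maps must share a shape")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.opl)):
            raise ConfigError("OPL map contains non-finite values")
        if np.any(self.absorption < 0):
            raise ConfigError("absorption must be >= 0 (attenuation exponent)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.opl.shape

    def transmittance(self, wavelength_um: float) -> np.ndarray:
        """Complex transmittance exp(-absorption + i*2π*opl/λ); |t| <= 1."""
        return np.exp(-self.absorption + 2j * np.pi * self.opl / wavelength_um)


@dataclass(frozen=True)
class BeadPhantom:
    """Non-overlapping spheres of ``n_bead`` in a medium of ``n_medium``.

    ``beads`` is a list of ``(center_x_um, center_y_um, radius_um)``;
    ``field_size`` is ``(n_rows, n_cols)`` pixels.
    """

    beads: tuple[tuple[float, float, float], ...]
    n_bead: float = 1.583
    n_medium: float = 1.56
    field_size: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.586

    def __post_init__(self):
        object.__setattr__(self, "beads", tuple(tuple(b) for b in self.beads))
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")
        ny, nx = self.field_size
        w, h = nx * self.pixel_size_um, ny * self.pixel_size_um
        for cx, cy, r in self.beads:
            if r <= 0:
                raise ConfigError(f"bead radius must be positive, got {r}")
            if not (r <= cx <= w - r and r <= cy <= h - r):
                raise ConfigError(
                    f"bead at ({cx:.1f}, {cy:.1f}) µm with R={r:.1f} µm is not "
                    f"fully inside the {w:.0f}x{h:.0f} µm field")
        for i in range(len(self.beads)):
            for j in range(i + 1, len(self.beads)):
                xi, yi, ri = self.beads[i]
                xj, yj, rj = self.beads[j]
                if np.hypot(xi - xj, yi - yj) < ri + rj:
                    raise ConfigError(f"beads {i} and {j} overlap")

    @property
    def delta_n(self) -> float:
        return self.n_bead - self.n_medium

    def analytic_optical_volumes(self) -> np.ndarray:
        """Ground-truth optical volume Δn·(4/3)πR³ per bead (µm³)."""
        radii = np.array([b[2] for b in self.beads])
        return self.delta_n * (4.0 / 3.0) * np.pi * radii ** 3


@dataclass(frozen=True)
class RulerPhantom:
    """Stage-micrometer ruler: absorbing graduation lines every
    ``fine_spacing_um``, heavier lines every ``coarse_spacing_um``."""

    fine_spacing_um: float = 10.0
    coarse_spacing_um: float = 100.0
    line_width_um: float = 2.0
    orientation: str = "x"
    contrast: float = 0.5

    def __post_init__(self):
        if self.fine_spacing_um <= 0 or self.line_width_um <= 0:
            raise ConfigError("spacings and line width must be positive")
        ratio = self.coarse_spacing_um / self.fine_spacing_um
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError("coarse_spacing must be an integer multiple of fine_spacing")
        if self.orientation not in ("x", "y"):
            raise ConfigError("orientation must be 'x' or 'y'")
        if self.contrast < 0:
            raise ConfigError("contrast must be >= 0")


def bead_opl_map(phantom: BeadPhantom, wavelength_um: float | None = None) -> SpecimenField:
    """Render a bead phantom as a pure-phase :class:`SpecimenField`.

    OPL(x, y) = Δn · 2·sqrt(R² − ρ²) inside each bead, 0 outside;
    absorption is identically zero.  Edges are anti-aliased by 4x4 subpixel
    averaging.  If ``wavelength_um`` is given and the peak OPL exceeds λ/2,
    a phase-wrap warning is emitted (retrieval does not unwrap).
    """
    ny, nx = phantom.field_size
    px = phantom.pixel_size_um
    opl = np.zeros((ny, nx), dtype=float)
    # subpixel sample offsets within one pixel (pixel-center convention)
    sub = (np.arange(_AA) + 0.5) / _AA - 0.5
    for cx, cy, r in phantom.beads:
        # bounding box of the bead, padded one pixel for the AA border
        i0 = max(int(np.floor((cy - r) / px)) - 1, 0)
        i1 = min(int(np.ceil((cy + r) / px)) + 2, ny)
        j0 = max(int(np.floor((cx - r) / px)) - 1, 0)
        j1 = min(int(np.ceil((cx + r) / px)) + 2, nx)
        ys = (np.arange(i0, i1)[:, None] + 0.5 + sub[None, :]).ravel() * px - cy
        xs = (np.arange(j0, j1)[:, None] + 0.5 + sub[None, :]).ravel() * px - cx
        rho2 = ys[:, None] ** 2 + xs[None, :] ** 2
        chord = 2.0 * np.sqrt(np.clip(r * r - rho2, 0.0, None))
        chord = chord.reshape(i1 - i0, _AA, j1 - j0, _AA).mean(axis=(1, 3))
        opl[i0:i1, j0:j1] += phantom.delta_n * chord
    if wavelength_um is not None and opl.max() > wavelength_um / 2.0:
        warnings.warn(
            f"peak OPL {opl.max():.3f} µm exceeds λ/2 = {wavelength_um / 2:.3f} µm; "
            "retrieved phase would wrap", stacklevel=2)
    meta = {"phantom": "bead", "n_bead": phantom.n_bead, "n_medium": phantom.n_medium,
            "beads": [list(b) for b in phantom.beads]}
    return SpecimenField(opl, np.zeros_like(opl), px, meta)


def opl_to_phase(field: SpecimenField, wavelength_um: float) -> np.ndarray:
    """Unwrapped ground-truth phase φ = 2π · OPL / λ (radians)."""
    if wavelength_um <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_um}")
    if field.opl.max() > wavelength_um / 2.0:
        warnings.warn("peak OPL exceeds λ/2; a real acquisition would phase-wrap",
                      stacklevel=2)
    return 2.0 * np.pi * field.opl / wavelength_um


def ruler_field(phantom: RulerPhantom, field_size: tuple[int, int],
                pixel_size_um: float) -> SpecimenField:
    """Render a ruler phantom as an absorption-only specimen.

    Graduation lines are Gaussian absorption profiles centered at integer
    multiples of the fine spacing, doubled in strength at coarse multiples.
    The dominant spatial frequency of a perpendicular line profile is
    1/fine_spacing cycles/µm.
    """
    if phantom.fine_spacing_um <= 2.0 * pixel_size_um:
        raise ConfigError(
            f"fine spacing {phantom.fine_spacing_um} µm must exceed twice the "
            f"pixel size ({pixel_size_um} µm) to be resolvable")
    ny, nx = field_size
    n_along = nx if phantom.orientation == "x" else ny
    coords = (np.arange(n_along) + 0.5) * pixel_size_um
    sigma = phantom.line_width_um / 2.355  # FWHM -> Gaussian sigma
    fine, coarse = phantom.fine_spacing_um, phantom.coarse_spacing_um
    profile = np.zeros(n_along)
    for k in range(int(coords[-1] // fine) + 2):
        center = k * fine
        weight = 2.0 if (k * fine) % coarse < 1e-9 else 1.0
        profile += weight * np.exp(-0.5 * ((coords - center) / sigma) ** 2)
    profile *= phantom.contrast
    if phantom.orientation == "x":
        absorption = np.broadcast_to(profile[None, :], (ny, nx)).copy()
    else:
        absorption = np.broadcast_to(profile[:, None], (ny, nx)).copy()
    meta = {"phantom": "ruler", "fine_spacing_um": fine, "coarse_spacing_um": coarse,
            "orientation": phantom.orientation}
    return SpecimenField(np.zeros((ny, nx)), absorption, pixel_size_um, meta)


def bead_timeseries(phantom: BeadPhantom, n_frames: int,
                    seed: int = 0) -> list[SpecimenField]:
    """Static bead specimen repeated over ``n_frames``.

    Beads are fixed in cured polymer, so every frame is pixel-identical
    before imaging; temporal variation enters downstream through the
    camera-noise model.  Each frame's metadata records a child seed for the
    noise draw so a full time series is reproducible from one parent seed.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    base = bead_opl_map(phantom)
    frame_seeds = np.random.SeedSequence(seed).generate_state(n_frames) % (2 ** 31)
    frames = []
    for i in range(n_frames):
        meta = dict(base.meta, frame=i, noise_seed=int(frame_seeds[i]), parent_seed=seed)
        frames.append(SpecimenField(base.opl.copy(), base.absorption.copy(),
                                    base.pixel_size_um, meta))
    return frames


def cell_like_field(seed: int, field_size: tuple[int, int] = (512, 512),
                    pixel_size_um: float = 0.586, mean_opl_um: float = 0.02,
                    n_blobs: int = 8, wavelength_um: float = 0.63) -> SpecimenField:
    """Smooth, compact random blobs emulating adherent cells (demo input).

    Deterministic for a fixed seed.  Peak OPL is capped just below λ/2 so
    the phase never wraps; ``mean_opl_um = 0`` yields an empty field.
    """
    if mean_opl_um < 0:
        raise ValueError("mean_opl_um must be >= 0")
    ny, nx = field_size
    opl = np.zeros((ny, nx))
    if mean_opl_um > 0:
        rng = np.random.default_rng(seed)
        y = (np.arange(ny) + 0.5) * pixel_size_um
        x = (np.arange(nx) + 0.5) * pixel_size_um
        for _ in range(n_blobs):
            cx = rng.uniform(0.1, 0.9) * x[-1]
            cy = rng.uniform(0.1, 0.9) * y[-1]
            rx = rng.uniform(8.0, 20.0)
            ry = rng.uniform(8.0, 20.0)
            q = ((x[None, :] - cx) / rx) ** 2 + ((y[:, None] - cy) / ry) ** 2
            bump = np.clip(1.0 - q, 0.0, None) ** 2  # compact C1 bump
            opl += rng.uniform(0.5, 1.0) * bump
        opl *= mean_opl_um / opl.mean()
        cap = 0.95 * wavelength_um / 2.0
        if opl.max() > cap:
            opl *= cap / opl.max()
    meta = {"phantom": "cell_like", "seed": seed, "mean_opl_um": mean_opl_um}
    return SpecimenField(opl, np.zeros_like(opl), pixel_size_um, meta)


def random_bead_phantom(n_beads: int = 3, radius_um: float = 5.0,
                        field_size: tuple[int, int] = (512, 512),
                        pixel_size_um: float = 0.586,
                        n_bead: float = 1.583, n_medium: float = 1.56,
                        seed: int = 0, margin_um: float | None = None,
                        min_separation_um: float | None = None) -> BeadPhantom:
    """Place ``n_beads`` equal-radius beads uniformly at random (no overlap).

    Rejection sampling with a minimum center separation (default 3R) and an
    edge margin (default 2R); deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    ny, nx = field_size
    w, h = nx * pixel_size_um, ny * pixel_size_um
    margin = 2.0 * radius_um if margin_um is None else margin_um
    min_sep = 3.0 * radius_um if min_separation_um is None else min_separation_um
    beads: list[tuple[float, float, float]] = []
    for _ in range(10000):
        if len(beads) == n_beads:
            break
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        if all(np.hypot(cx - bx, cy - by) >= min_sep for bx, by, _ in beads):
            beads.append((cx, cy, radius_um))
    if len(beads) < n_beads:
        raise ConfigError(
            f"could not place {n_beads} beads of R={radius_um} µm in a "
            f"{w:.0f}x{h:.0f} µm field without overlap")
    return BeadPhantom(tuple(beads), n_bead=n_bead, n_medium=n_medium,
                       field_size=field_size, pixel_size_um=pixel_size_um)
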