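"""Geometry of the imaging and illumination system.

The LED-array microscope is characterized by two pieces of geometry: the
detection optics (objective NA, magnification, camera pixel pitch) and the
LED illumination array (a planar grid of point sources at a fixed distance
from the specimen).  Everything downstream — coherence parameters,
illumination NAs, pupil cutoffs, and the boolean lit-masks that define
brightfield, half-circle and annular (darkfield) illumination — derives
from these two dataclasses.

Conventions
-----------
* Physical LED position (mm): ``(col - (n_cols-1)/2, row - (n_rows-1)/2) *
  pitch + center_offset``.  On an even-sized grid the coordinates are
  half-integers in LED units, so no LED ever sits exactly on a dividing
  axis or on the grid center.
* ``illumination_na`` defaults to the geometrically exact sine,
  ``r / sqrt(r**2 + d**2)``.  A ``paper_literal`` mode evaluates the
  small-angle form ``r / d`` for cross-checking published numbers; it can
  exceed 1 for ``r > d`` and then logs a warning.
* Half-patterns light LEDs strictly on one side of the dividing axis.
  LEDs exactly on the axis (impossible on even grids, possible on odd
  grids) are unlit in both halves, so opposite halves are disjoint and
  their union is the full circle minus the axis.
* Radial index = Euclidean distance from the pattern center in LED units;
  annuli are half-open, ``inner <= index < outer``.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .exceptions import ConfigError, SigmaOutOfRangeError

logger = logging.getLogger(__name__)

HALF_DIRECTIONS = ("left", "right", "top", "bottom")
OPPOSITE_HALF = {"left": "right", "right": "left", "top": "bottom", "bottom": "top"}


@dataclass(frozen=True)
class OpticalSystem:
    """Detection-side optics.

    Parameters
    ----------
    na_objective : float
        Objective numerical aperture, ``0 < NA < 1``.
    magnification : float
        Total magnification onto the camera.
    tube_focal_length_mm : float
        Tube lens focal length (mm); informational.
    wavelength_um : float
        Illumination wavelength (µm).  The red LED array has no published
        wavelength; 0.63 µm is the configurable default.
    camera_pixel_pitch_um : float
        Physical camera pixel pitch (µm).
    """

    na_objective: float = 0.25
    magnification: float = 10.0
    tube_focal_length_mm: float = 200.0
    wavelength_um: float = 0.63
    camera_pixel_pitch_um: float = 5.86

    def __post_init__(self):
        if not (0.0 < self.na_objective < 1.0):
            raise ConfigError(f"na_objective must be in (0, 1), got {self.na_objective}")
        for name in ("magnification", "tube_focal_length_mm", "wavelength_um",
                     "camera_pixel_pitch_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def magnified_pixel_size_um(self) -> float:
        """Specimen-plane pixel size, camera pitch / magnification (µm)."""
        return self.camera_pixel_pitch_um / self.magnification

    @property
    def pupil_cutoff_cycles_per_um(self) -> float:
        """Coherent pupil cutoff frequency NA / λ (cycles/µm)."""
        return self.na_objective / self.wavelength_um


@dataclass(frozen=True)
class LEDArrayGeometry:
    """Physical LED grid: ``n_rows x n_cols`` at ``pitch_mm``, a plane at
    ``distance_mm`` from the specimen, laterally displaced by
    ``center_offset_mm`` from the optical axis."""

    n_rows: int = 16
    n_cols: int = 24
    pitch_mm: float = 4.7
    distance_mm: float = 110.0
    center_offset_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigError("LED grid must have at least one row and column")
        if self.pitch_mm <= 0 or self.distance_mm <= 0:
            raise ConfigError("pitch_mm and distance_mm must be positive")

    def index_offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """LED offsets from the grid center, in LED units.

        Returns ``(col_off, row_off)`` broadcastable grids of shape
        ``(n_rows, n_cols)``; half-integers on even-sized grids.
        """
        row = np.arange(self.n_rows) - (self.n_rows - 1) / 2.0
        col = np.arange(self.n_cols) - (self.n_cols - 1) / 2.0
        col_off, row_off = np.meshgrid(col, row)
        return col_off, row_off

    def led_positions_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) of every LED in mm, including the center offset."""
        col_off, row_off = self.index_offsets()
        ox, oy = self.center_offset_mm
        return col_off * self.pitch_mm + ox, row_off * self.pitch_mm + oy

    def radial_index(self) -> np.ndarray:
        """Euclidean distance of each LED from the pattern center (LED units)."""
        col_off, row_off = self.index_offsets()
        return np.hypot(col_off, row_off)

    @property
    def max_radial_index(self) -> float:
        """Radial index of the farthest (corner) LED."""
        return float(np.max(self.radial_index()))


@dataclass(frozen=True)
class IlluminationPattern:
    """A boolean lit-mask over the LED grid with a semantic label.

    ``label`` is one of ``left/right/top/bottom/full/annulus/dark``.
    ``radius_leds`` applies to half/full patterns, the ``*_radius_leds``
    pair to annuli.
    """

    lit: np.ndarray
    label: str
    geom: LEDArrayGeometry
    radius_leds: float | None = None
    inner_radius_leds: float | None = None
    outer_radius_leds: float | None = None

    def __post_init__(self):
        lit = np.asarray(self.lit, dtype=bool)
        if lit.shape != (self.geom.n_rows, self.geom.n_cols):
            raise ConfigError(
                f"lit mask shape {lit.shape} does not match LED grid "
                f"({self.geom.n_rows}, {self.geom.n_cols})"
            )
        object.__setattr__(self, "lit", lit)

    @property
    def n_lit(self) -> int:
        return int(self.lit.sum())

    def lit_positions_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) in mm of the lit LEDs."""
        x, y = self.geom.led_positions_mm()
        return x[self.lit], y[self.lit]

    def union(self, other: "IlluminationPattern", label: str = "full") -> "IlluminationPattern":
        if self.geom != other.geom:
            raise ConfigError("patterns live on different LED arrays")
        return IlluminationPattern(self.lit | other.lit, label, self.geom,
                                   radius_leds=self.radius_leds)

    def to_text(self) -> str:
        """Serialize as rows of 0/1 characters (one line per LED row)."""
        return "\n".join("".join("1" if v else "0" for v in row) for row in self.lit)

    @classmethod
    def from_text(cls, text: str, geom: LEDArrayGeometry,
                  label: str = "custom") -> "IlluminationPattern":
        rows = [line.strip() for line in text.strip().splitlines()]
        lit = np.array([[c == "1" for c in row] for row in rows], dtype=bool)
        return cls(lit, label, geom)

    def lit_table(self):
        """DataFrame of lit LED indices and physical coordinates (mm)."""
        import pandas as pd

        rows, cols = np.nonzero(self.lit)
        x, y = self.geom.led_positions_mm()
        return pd.DataFrame({
            "row": rows, "col": cols,
            "x_mm": x[rows, cols], "y_mm": y[rows, cols],
        })


# ---------------------------------------------------------------------------
# scalar optics arithmetic


def coherence_parameter(na_illumination: float, na_objective: float) -> float:
    """Coherence parameter σ = NA_illumination / NA_objective."""
    if na_objective <= 0:
        raise ValueError(f"na_objective must be positive, got {na_objective}")
    if na_illumination < 0:
        raise ValueError(f"na_illumination must be >= 0, got {na_illumination}")
    return na_illumination / na_objective


def illumination_na(r_mm: float, d_mm: float, mode: str = "exact") -> float:
    """Illumination NA of a source at lateral radius ``r`` and distance ``d``.

    ``exact`` returns sin θ = r / sqrt(r² + d²) with tan θ = r / d.
    ``paper_literal`` returns the small-angle ratio r / d, which is how the
    published formula is printed; it exceeds 1 (nonphysical) for r > d and
    then logs a warning.
    """
    if d_mm <= 0:
        raise ValueError(f"distance must be positive, got {d_mm}")
    if r_mm < 0:
        raise ValueError(f"radius must be >= 0, got {r_mm}")
    if mode == "exact":
        return r_mm / math.hypot(r_mm, d_mm)
    if mode == "paper_literal":
        na = r_mm / d_mm
        if na > 1:
            warnings.warn(
                f"paper_literal illumination NA {na:.3f} exceeds 1 (nonphysical); "
                "use mode='exact' for the sine form", stacklevel=2)
        return na
    raise ValueError(f"mode must be 'exact' or 'paper_literal', got {mode!r}")


def led_spatial_frequency(led_xy_mm: tuple[float, float], d_mm: float,
                          wavelength_um: float) -> tuple[float, float]:
    """Transverse spatial frequency (cycles/µm) of the tilted plane wave an
    LED at ``led_xy_mm`` launches through the specimen.

    Magnitude equals ``illumination_na(hypot(x, y), d, 'exact') / λ``.
    """
    if d_mm <= 0:
        raise ValueError(f"distance must be positive, got {d_mm}")
    x, y = led_xy_mm
    rho = math.sqrt(x * x + y * y + d_mm * d_mm)
    return x / rho / wavelength_um, y / rho / wavelength_um


def magnified_pixel_size(optics: OpticalSystem) -> float:
    """Specimen-plane pixel size in µm."""
    return optics.magnified_pixel_size_um


def z_step_size(translation_per_rev_um: float, steps_per_rev: int) -> float:
    """Axial translation per motor step (µm/step)."""
    if translation_per_rev_um <= 0 or steps_per_rev <= 0:
        raise ValueError("translation_per_rev_um and steps_per_rev must be positive")
    return translation_per_rev_um / steps_per_rev


# ---------------------------------------------------------------------------
# pattern construction


def _clip_warning(radius: float, geom: LEDArrayGeometry, what: str):
    if radius > geom.max_radial_index:
        warnings.warn(
            f"{what} radius {radius:g} LEDs exceeds the grid extent "
            f"({geom.max_radial_index:.2f}); pattern clipped to the grid",
            stacklevel=3)


def make_full_pattern(geom: LEDArrayGeometry, radius_leds: float) -> IlluminationPattern:
    """Full-circle (brightfield) pattern: all LEDs within ``radius_leds``."""
    if radius_leds < 1:
        raise ValueError(f"radius_leds must be >= 1, got {radius_leds}")
    _clip_warning(radius_leds, geom, "full-pattern")
    lit = geom.radial_index() <= radius_leds
    return IlluminationPattern(lit, "full", geom, radius_leds=radius_leds)


def make_half_pattern(geom: LEDArrayGeometry, direction: str,
                      radius_leds: float) -> IlluminationPattern:
    """Half-circle pattern for asymmetric (DPC) illumination.

    LEDs within ``radius_leds`` of the pattern center and strictly on the
    named side of the dividing axis are lit.  ``left``/``right`` split by
    the vertical axis (x < 0 / x > 0); ``top``/``bottom`` by the horizontal
    axis (y < 0 is top, matching image-row order).
    """
    if direction not in HALF_DIRECTIONS:
        raise ValueError(f"direction must be one of {HALF_DIRECTIONS}, got {direction!r}")
    if radius_leds < 1:
        raise ValueError(f"radius_leds must be >= 1, got {radius_leds}")
    _clip_warning(radius_leds, geom, "half-pattern")
    col_off, row_off = geom.index_offsets()
    within = geom.radial_index() <= radius_leds
    side = {
        "left": col_off < 0, "right": col_off > 0,
        "top": row_off < 0, "bottom": row_off > 0,
    }[direction]
    return IlluminationPattern(within & side, direction, geom, radius_leds=radius_leds)


def make_annulus_pattern(geom: LEDArrayGeometry, inner_radius_leds: float,
                         outer_radius_leds: float) -> IlluminationPattern:
    """Annular (darkfield) pattern: lit iff ``inner <= radial index < outer``."""
    if not (0 < inner_radius_leds < outer_radius_leds):
        raise ValueError(
            f"need 0 < inner < outer, got inner={inner_radius_leds}, "
            f"outer={outer_radius_leds}")
    _clip_warning(outer_radius_leds, geom, "annulus outer")
    r = geom.radial_index()
    lit = (r >= inner_radius_leds) & (r < outer_radius_leds)
    return IlluminationPattern(lit, "annulus", geom,
                               inner_radius_leds=inner_radius_leds,
                               outer_radius_leds=outer_radius_leds)


def make_dark_pattern(geom: LEDArrayGeometry) -> IlluminationPattern:
    """All-off pattern (dark frame)."""
    return IlluminationPattern(np.zeros((geom.n_rows, geom.n_cols), bool), "dark", geom)


def sigma_to_led_radius(sigma: float, optics: OpticalSystem,
                        geom: LEDArrayGeometry) -> int:
    """Smallest integer LED radius realizing coherence parameter >= ``sigma``.

    Uses the exact sine NA of an LED at ``k * pitch``.  Raises
    :class:`SigmaOutOfRangeError` (naming the maximum attainable sigma) when
    even the farthest (corner) LED of the grid falls short of the requested
    illumination NA; a radius that overshoots the grid but is covered by
    the corner LEDs is allowed (the pattern clips to the grid).
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return 0
    target_na = sigma * optics.na_objective
    max_na = illumination_na(geom.max_radial_index * geom.pitch_mm, geom.distance_mm)
    if target_na > max_na:
        raise SigmaOutOfRangeError(sigma, coherence_parameter(max_na, optics.na_objective))
    k_max = int(math.ceil(geom.max_radial_index))
    for k in range(1, k_max + 1):
        if illumination_na(k * geom.pitch_mm, geom.distance_mm) >= target_na:
            return k
    return k_max  # corner LEDs cover the target; pattern clips to the grid


def pattern_sigma(radius_leds: float, optics: OpticalSystem,
                  geom: LEDArrayGeometry) -> float:
    """Coherence parameter realized by a pattern of ``radius_leds``."""
    na = illumination_na(radius_leds * geom.pitch_mm, geom.distance_mm)
    return coherence_parameter(na, optics.na_objective)


# ---------------------------------------------------------------------------
# configuration I/O


_DEF = object()


def load_config(path: str | Path) -> tuple[OpticalSystem, LEDArrayGeometry]:
    """Read optics + LED geometry from a single YAML or JSON file.

    Recognized keys: ``na_objective, magnification, wavelength_um,
    camera_pixel_pitch_um, tube_focal_length_mm`` and a ``led`` mapping with
    ``rows, cols, pitch_mm, distance_mm, offset_mm``.  Missing keys fall
    back to the dataclass defaults.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        import yaml

        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    led = raw.get("led", {})
    try:
        optics = OpticalSystem(
            na_objective=raw.get("na_objective", 0.25),
            magnification=raw.get("magnification", 10.0),
            tube_focal_length_mm=raw.get("tube_focal_length_mm", 200.0),
            wavelength_um=raw.get("wavelength_um", 0.63),
            camera_pixel_pitch_um=raw.get("camera_pixel_pitch_um", 5.86),
        )
        geom = LEDArrayGeometry(
            n_rows=led.get("rows", 16),
            n_cols=led.get("cols", 24),
            pitch_mm=led.get("pitch_mm", 4.7),
            distance_mm=led.get("distance_mm", 110.0),
            center_offset_mm=tuple(led.get("offset_mm", (0.0, 0.0))),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration in {path}: {exc}") from exc
    logger.info("loaded config from %s (wavelength %.3g um)", path, optics.wavelength_um)
    return optics, geom


def config_dict(optics: OpticalSystem, geom: LEDArrayGeometry) -> dict:
    """Round-trippable dict form of a configuration (for provenance sidecars)."""
    return {
        "na_objective": optics.na_objective,
        "magnification": optics.magnification,
        "tube_focal_length_mm": optics.tube_focal_length_mm,
        "wavelength_um": optics.wavelength_um,
        "camera_pixel_pitch_um": optics.camera_pixel_pitch_um,
        "led": {
            "rows": geom.n_rows, "cols": geom.n_cols,
            "pitch_mm": geom.pitch_mm, "distance_mm": geom.distance_mm,
            "offset_mm": list(geom.center_offset_mm),
        },
    }
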