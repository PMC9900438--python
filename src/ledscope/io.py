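"""File formats and fixture generation.

Canonical on-disk formats are open and language-agnostic: TIFF for images
(pixel size recorded both in the resolution tags and in a JSON
ImageDescription), CSV for position lists and per-bead tables, JSON/YAML
for configuration and reports, plain text for LED lit-masks.  Acquisitions
follow the instrument's own layout: one folder per stage position
(``pos1``, ``pos2``, ...) holding the four labelled half-images, a
darkfield image and a dark frame per time point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import ConfigError, FormatError

POSITION_COLUMNS = ("position", "x_um", "y_um", "z_um")
FRAME_LABELS = ("left", "right", "top", "bottom", "darkfield", "dark")


def write_image(path: str | Path, image: np.ndarray,
                pixel_size_um: float | None = None) -> None:
    """Write a TIFF with the pixel size in resolution tags + description."""
    path = Path(path)
    kwargs = {}
    if pixel_size_um is not None:
        ppcm = 1e4 / pixel_size_um  # pixels per centimeter
        kwargs.update(resolution=(ppcm, ppcm), resolutionunit="CENTIMETER",
                      description=json.dumps({"pixel_size_um": pixel_size_um}))
    tifffile.imwrite(path, image, **kwargs)


def read_image(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read a TIFF; returns ``(image, pixel_size_um or None)``.

    Supports 8/16-bit integer and 32/64-bit float grayscale images; other
    dtypes and corrupt files raise :class:`FormatError`.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            image = page.asarray()
            desc = page.tags.get("ImageDescription")
            px = None
            if desc is not None:
                try:
                    px = json.loads(desc.value).get("pixel_size_um")
                except (ValueError, AttributeError, TypeError):
                    px = None
            if px is None:
                res = page.tags.get("XResolution")
                unit = page.tags.get("ResolutionUnit")
                if res is not None and getattr(unit, "value", None) is not None:
                    num, den = res.value
                    if num:
                        per_px = den / num
                        unit_um = {2: 2.54e4, 3: 1e4}.get(int(unit.value))
                        if unit_um:
                            px = per_px * unit_um
    except (tifffile.TiffFileError, OSError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if image.dtype not in (np.uint8, np.uint16, np.int16, np.float32, np.float64):
        raise FormatError(f"unsupported TIFF dtype {image.dtype} in {path}")
    return image, px


def write_position_list(path: str | Path, positions: pd.DataFrame) -> None:
    """Write an x-y-z position list as CSV (columns position, x_um, y_um, z_um)."""
    df = validate_position_list(positions)
    df.to_csv(path, index=False)


def read_position_list(path: str | Path) -> pd.DataFrame:
    """Read and validate a CSV position list; lossless round trip."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, OSError, ValueError) as exc:
        raise FormatError(f"cannot read position list {path}: {exc}") from exc
    return validate_position_list(df)


def validate_position_list(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"position list is missing column(s): {', '.join(missing)}")
    if df["position"].duplicated().any():
        dups = df.loc[df["position"].duplicated(), "position"].tolist()
        raise ConfigError(f"duplicate position id(s): {dups}")
    return df.loc[:, list(POSITION_COLUMNS)]


@dataclass(frozen=True)
class AcquisitionLayout:
    """Folder naming of a multi-position acquisition: ``root/pos{p}/`` with
    files ``{fstart}pos{p}_frame{f}_{label}.tif``."""

    root: Path
    fstart: str = ""

    def position_dir(self, position: int) -> Path:
        return Path(self.root) / f"pos{position}"

    def image_path(self, position: int, frame: int, label: str) -> Path:
        if label not in FRAME_LABELS:
            raise ConfigError(f"unknown image label {label!r}; expected {FRAME_LABELS}")
        return self.position_dir(position) / (
            f"{self.fstart}pos{position}_frame{frame}_{label}.tif")


def generate_fixtures(out_dir: str | Path, seed: int = 0, n_positions: int = 1,
                      n_frames: int = 1, sigma: float = 2.1,
                      n_beads: int = 3, bead_radius_um: float = 5.0,
                      field_size: tuple[int, int] = (256, 256),
                      optics=None, geom=None, noise_model=None,
                      force: bool = False) -> AcquisitionLayout:
    """Write a complete synthetic acquisition tree with ground-truth sidecars.

    Per position and frame: the four half-images, a darkfield (annular)
    image and a dark frame as 16-bit TIFFs, plus ``truth.json`` recording
    the phantom, seeds, config and analytic optical volumes.  Byte-
    reproducible for a fixed seed.
    """
    from .forward import NoiseModel, abbe_image, apply_noise, dark_frame
    from .optics import (OpticalSystem, config_dict, make_annulus_pattern,
                         sigma_to_led_radius)
    from .phantoms import bead_opl_map, random_bead_phantom
    from .pipeline import dpc_geometry, simulate_dpc_acquisition

    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"{out_dir} exists and is not empty; pass force=True to overwrite")
    optics = optics or OpticalSystem()
    geom = geom or dpc_geometry()
    noise_model = noise_model or NoiseModel(photons_at_unity=10000, read_noise_sd=5.0,
                                            offset=100.0, seed=seed)
    layout = AcquisitionLayout(out_dir)
    pos_seeds = np.random.SeedSequence(seed).generate_state(n_positions) % (2 ** 31)
    px = optics.magnified_pixel_size_um
    for p in range(1, n_positions + 1):
        pdir = layout.position_dir(p)
        pdir.mkdir(parents=True, exist_ok=True)
        phantom = random_bead_phantom(n_beads=n_beads, radius_um=bead_radius_um,
                                      field_size=field_size, pixel_size_um=px,
                                      seed=int(pos_seeds[p - 1]))
        specimen = bead_opl_map(phantom, wavelength_um=optics.wavelength_um)
        annulus = make_annulus_pattern(
            geom, sigma_to_led_radius(1.3, optics, geom) + 1, geom.max_radial_index)
        df_img = abbe_image(specimen, annulus, optics)
        bf_level = max(float(df_img.max()), 1e-12)
        frame_seeds = np.random.SeedSequence(int(pos_seeds[p - 1]) + 1).generate_state(
            n_frames) % (2 ** 31)
        for f in range(n_frames):
            acq = simulate_dpc_acquisition(specimen, optics, geom, sigma,
                                           noise_model=noise_model,
                                           seed=int(frame_seeds[f]))
            for label in ("left", "right", "top", "bottom"):
                write_image(layout.image_path(p, f, label), acq.images[label], px)
            df_counts = apply_noise(df_img / bf_level, noise_model,
                                    seed=int(frame_seeds[f]) ^ 0x5F5F)
            write_image(layout.image_path(p, f, "darkfield"), df_counts, px)
            write_image(layout.image_path(p, f, "dark"), acq.dark, px)
        truth = {
            "seed": seed, "position_seed": int(pos_seeds[p - 1]),
            "sigma": sigma, "pixel_size_um": px,
            "config": config_dict(optics, geom),
            "beads": [list(b) for b in phantom.beads],
            "n_bead": phantom.n_bead, "n_medium": phantom.n_medium,
            "analytic_optical_volumes_um3":
                phantom.analytic_optical_volumes().tolist(),
            "discrete_opl_integral_um3":
                float(specimen.opl.sum() * px * px),
        }
        (pdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return layout
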