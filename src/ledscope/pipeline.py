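"""End-to-end DPC workflows: simulate a four-half-image acquisition of a
specimen, reconstruct its phase, and measure it.

This module wires the pieces together the way the instrument is operated:
build the four half-circle patterns at a requested coherence parameter,
image the specimen with the exact Abbe model, optionally push the images
through the camera-noise model, then normalize, form the two DPC axes and
invert them with matched weak-object transfer functions.

The default simulated-study geometry is the 16x24 / 4.7 mm LED array at
100 mm from the specimen.  At that distance integer LED radii realize
coherence parameters of 1.09, 1.56 and 2.10 for requested values of 1.0,
1.5 and 2.1 — in particular the operating point σ = 2.1 is attainable,
which it is not at the array's darkfield distance of 110 mm (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .forward import NoiseModel, TransferFunctions, abbe_image, apply_noise, dark_frame, wotf
from .optics import (HALF_DIRECTIONS, IlluminationPattern, LEDArrayGeometry,
                     OpticalSystem, make_half_pattern, sigma_to_led_radius)
from .phantoms import SpecimenField
from .recon import PhaseMap, ReconstructionConfig, dpc_signal, dpc_transfer, retrieve_phase

#: LED-array distance (mm) used for the simulated DPC studies
DPC_DISTANCE_MM = 100.0


def dpc_geometry(distance_mm: float = DPC_DISTANCE_MM,
                 center_offset_mm: tuple[float, float] = (0.0, 0.0)) -> LEDArrayGeometry:
    """Standard 16x24 / 4.7 mm array at the simulated-study DPC distance."""
    return LEDArrayGeometry(distance_mm=distance_mm, center_offset_mm=center_offset_mm)


@dataclass
class Acquisition:
    """One simulated DPC acquisition: the four half-illumination images
    (label → array), the patterns that produced them, and bookkeeping."""

    images: dict[str, np.ndarray]
    patterns: dict[str, IlluminationPattern]
    optics: OpticalSystem
    pixel_size_um: float
    radius_leds: int
    noise_model: NoiseModel | None = None
    dark: np.ndarray | None = None
    meta: dict = dc_field(default_factory=dict)


def half_patterns(geom: LEDArrayGeometry, radius_leds: int) -> dict[str, IlluminationPattern]:
    return {d: make_half_pattern(geom, d, radius_leds) for d in HALF_DIRECTIONS}


def simulate_dpc_acquisition(specimen: SpecimenField, optics: OpticalSystem,
                             geom: LEDArrayGeometry, sigma: float,
                             noise_model: NoiseModel | None = None,
                             seed: int | None = None) -> Acquisition:
    """Image ``specimen`` under the four half patterns at coherence
    parameter >= ``sigma`` with the exact Abbe model.

    With a noise model, each image is normalized to a unit mean-pair
    background before the photon draw (so ``photons_at_unity`` is the
    expected background photon count), and a matching dark frame is
    attached.  Per-image noise seeds are spawned deterministically from
    ``seed`` (or the model's seed).
    """
    radius = sigma_to_led_radius(sigma, optics, geom)
    patterns = half_patterns(geom, radius)
    images = {d: abbe_image(specimen, p, optics) for d, p in patterns.items()}
    meta = {"sigma_requested": sigma, "radius_leds": radius}
    dark = None
    if noise_model is not None:
        base_seed = noise_model.seed if seed is None else seed
        child = np.random.SeedSequence(base_seed).generate_state(5) % (2 ** 31)
        # one exposure scale for all four images: unit background = the
        # mean dc of an opposing pair (halves of a centered array match)
        tfs = {d: wotf(p, optics, specimen.shape, specimen.pixel_size_um)
               for d, p in patterns.items()}
        scale = np.mean([tfs[d].dc_level for d in HALF_DIRECTIONS])
        if scale <= 0:
            raise ValueError("patterns have no LEDs inside the pupil; cannot expose")
        images = {d: apply_noise(images[d] / scale, noise_model, seed=int(child[i]))
                  for i, d in enumerate(HALF_DIRECTIONS)}
        dark = dark_frame(noise_model, specimen.shape, seed=int(child[4]))
        meta["noise_seed"] = int(base_seed)
    return Acquisition(images, patterns, optics, specimen.pixel_size_um,
                       radius, noise_model, dark, meta)


def reconstruct_acquisition(acq: Acquisition,
                            config: ReconstructionConfig | None = None) -> PhaseMap:
    """DPC phase retrieval from a four-half-image acquisition.

    Camera offset (taken from the dark frame when present) is subtracted
    before the DPC normalization; the transfer functions are computed from
    the acquisition's own patterns so signs and axis pairing are
    self-consistent.
    """
    if config is None:
        config = ReconstructionConfig(wavelength_um=acq.optics.wavelength_um)
    shape = next(iter(acq.images.values())).shape
    offset = 0.0
    if acq.noise_model is not None and acq.noise_model.offset > 0:
        offset = (float(acq.dark.mean()) if acq.dark is not None
                  else acq.noise_model.offset)
    tfs = {d: wotf(p, acq.optics, shape, acq.pixel_size_um)
           for d, p in acq.patterns.items()}
    dpc_maps, transfer = [], []
    for a, b in config.pairs():
        for label in (a, b):
            if label not in acq.images:
                raise ValueError(f"acquisition is missing the {label!r} half-image")
        dpc_maps.append(dpc_signal(acq.images[a].astype(float) - offset,
                                   acq.images[b].astype(float) - offset))
        transfer.append(dpc_transfer(tfs[a], tfs[b]))
    pm = retrieve_phase(dpc_maps, transfer, config, acq.pixel_size_um)
    pm.provenance.update(acq.meta)
    return pm


def simulate_and_reconstruct(specimen: SpecimenField, optics: OpticalSystem,
                             geom: LEDArrayGeometry, sigma: float,
                             reg2: float = 1e-3,
                             noise_model: NoiseModel | None = None,
                             seed: int | None = None) -> PhaseMap:
    """Convenience: Abbe acquisition at ``sigma`` + retrieval at ``reg2``."""
    acq = simulate_dpc_acquisition(specimen, optics, geom, sigma,
                                   noise_model=noise_model, seed=seed)
    config = ReconstructionConfig(reg2=reg2, sigma=sigma,
                                  wavelength_um=optics.wavelength_um)
    return reconstruct_acquisition(acq, config)
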