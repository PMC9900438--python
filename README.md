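# ledscope

A hardware-free toolkit for the computational core of an LED-array
multimodal microscope: illumination-pattern design, partially coherent
image simulation, differential phase contrast (DPC) quantitative phase
retrieval, and the calibration/validation procedures such an instrument
needs before its numbers can be trusted.

LED-array microscopes replace the condenser of a conventional microscope
with a programmable LED matrix. Lighting LEDs inside the objective's
numerical aperture gives brightfield; an annulus entirely outside the NA
gives darkfield; and pairs of complementary half-circle patterns give DPC
quantitative phase imaging (QPI), from which optical path length, optical
volume, refractive index and cell dry mass follow. `ledscope` implements
the physics and the data processing of such an instrument so that every
procedure — LED centering, pixel-size calibration, coherence and
regularization tuning, bead-standard QPI validation, darkfield design and
SNR — can be exercised, tested and reasoned about entirely in software,
on synthetic specimens with known ground truth. It is aimed at builders
of LED-array microscopes who need to validate a processing chain, and at
anyone studying DPC reconstruction quantitatively.

## The model

Illumination geometry is summarized by the coherence parameter

    σ = NA_illumination / NA_objective,

with the NA of an LED at lateral radius r and distance d given by
sin θ = r/√(r²+d²). Darkfield annuli are characterized by inner/outer σ;
DPC needs σ > 1 and works best for σ ≥ 1.5.

Image formation is the exact partially coherent (Abbe) model — each LED
an incoherent tilted plane wave, its coherent image filtered by the
pupil — alongside its first-order weak-object transfer-function (WOTF)
linearization computed as discrete source–pupil correlations over the
same LEDs. Phase is retrieved from the four half-circle images by pairing
them into two normalized DPC signals, DPC = (I_a−I_b)/(I_a+I_b), and
inverting both axes jointly with Tikhonov regularization:

    φ = Re IFT[ Σ_k conj(H_k)·FT(DPC_k) / (Σ_k |H_k|² + reg2²) ]

Bead standards (polystyrene, n = 1.583, in NOA73, n = 1.56) provide
ground truth: a sphere's optical path length is OPL = Δn·t with chord
thickness t, so its integrated OPL — the optical volume — is
Δn·(4/3)πR³, and the recovered refractive index is
n = n_medium + OV/((4/3)π(d_eq/2)³).

## Worked example

Simulate three 5 µm polystyrene beads in NOA73, image them through the
four half-circle patterns with the exact Abbe model, reconstruct the
phase, and measure each bead:

```python
import ledscope as ls

optics = ls.OpticalSystem()            # 10x / NA 0.25, 5.86 um camera pixels
geom = ls.dpc_geometry()               # 16x24 LED array, 4.7 mm pitch, 100 mm away
phantom = ls.random_bead_phantom(n_beads=3, radius_um=5.0, seed=1,
                                 field_size=(512, 512),
                                 pixel_size_um=optics.magnified_pixel_size_um)
specimen = ls.bead_opl_map(phantom, wavelength_um=optics.wavelength_um)
pm = ls.simulate_and_reconstruct(specimen, optics, geom, sigma=2.1, reg2=1e-3)
beads = ls.measure_beads(pm, n_medium=phantom.n_medium)
```

Output:

```
 label  equivalent_diameter_um  optical_volume_um3  delta_n  n_bead
     1                 10.0062             11.8583   0.0226  1.5826
     2                 10.0281             11.6928   0.0221  1.5821
     3                 10.0062             11.6920   0.0223  1.5823
mean recovered index: 1.5823 (expected 1.583)
```

Each bead's diameter is recovered to ~0.3%, its optical volume sits a few
percent below the analytic 12.04 µm³ (the DC component of phase lies in
the retrieval's null space), and the recovered refractive index lands
within 0.05% of the true 1.583 — the level of agreement a physical bead
standard is used to certify.

The same workflows are available from the command line:

```sh
ledscope simulate --seed 1 --sigma 2.1 --out acq/
ledscope reconstruct --pos-dir acq/pos1 --sigma 2.1 --out phase.tif
ledscope center-check --seed 1 --out centering.csv
ledscope pixel-cal --image ruler.tif --line 8 0 8 1023 --out profile.csv
ledscope sweep-sigma --seed 1 --out sigma_sweep.csv
ledscope darkfield-design --seed 1 --out design.csv
```

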