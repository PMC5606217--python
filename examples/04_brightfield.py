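"""Annotate a voxelized neuron with a Golgi-stain absorber and render an
orthographic Beer–Lambert brightfield projection.

Transmission T = exp(-mu_a * path length); stained structures appear dark
against the full illumination (T = 1) of empty pixels.
"""

import numpy as np

from morphovox.optics import GOLGI_STAIN, XENON_LAMP, annotate, brightfield_project
from morphovox.repair import repair
from morphovox.synthetic import MorphogenParams, generate_morphology
from morphovox.voxelize import voxelize_circuit_per_neuron

m, _ = repair(generate_morphology(MorphogenParams(seed=11)))
solid = voxelize_circuit_per_neuron([(m, None)], resolution=128)[0]
labels = annotate([(solid, 1)], {1: ("neuron_1", GOLGI_STAIN)})

img = brightfield_project(labels, XENON_LAMP, axis="z")
t = img.transmission
print(f"image {t.shape[1]}x{t.shape[2]} pixels at {len(img.wavelengths)} wavelengths")
print(f"transmission range [{t.min():.4f}, {t.max():.4f}] (1.0 = unobstructed light)")
dark = (t[0] < 0.99).sum()
print(f"{dark} pixels are shadowed by the stained neuron at {img.wavelengths[0]:.0f} nm")
print(f"deepest shadow corresponds to {-np.log(t.min()) / 0.05:.1f} um of stained path "
      f"(mu_a = 0.05 /um)")
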