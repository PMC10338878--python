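"""Thin-lens defocus geometry: blur radius vs. stage offset.

Builds the 20X-objective stand-in, sweeps stage offsets across +/-10 um
and prints the blur-circle radius at the sensor for each, plus the
rasterised kernel size at the default camera pitch.  The radius is zero
exactly at the focal plane and grows nearly linearly with |z|; at a
4.4 um/px pitch one micrometre of defocus costs about 1.2 px of blur.
"""

from ldsefocus import BlurSpec, blur_radius_from_defocus, psf_kernel
from ldsefocus.simulate import default_lens

lens = default_lens("20X")
print(f"lens: f={lens.focal_length_f:.0f} um, u={lens.object_distance_u:.0f} um, "
      f"s={lens.sensor_distance_s:.0f} um, D={lens.aperture_diameter_D:.0f} um")
print(f"{'z (um)':>8} {'R (um)':>10} {'R (px @4.4)':>12} {'kernel':>8}")
for z in [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, -10.0]:
    r = blur_radius_from_defocus(lens, z)
    kernel = psf_kernel(BlurSpec(blur_radius_R=r, pixel_size=4.4))
    print(f"{z:8.1f} {r:10.2f} {r / 4.4:12.2f} {kernel.shape[0]:>4}x{kernel.shape[1]}")
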