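"""Thin-lens defocus geometry and blur-circle point-spread functions.

The geometric picture: a point on the sample at object distance ``u`` is
imaged by a lens of focal length ``f`` onto the Gauss-conjugate plane at
image distance ``v`` with ``1/u + 1/v = 1/f``.  If the sensor sits at
distance ``s != v``, the converging cone of half-aperture ``D/2`` intersects
the sensor in a disk — the blur circle — of radius

    R = (s * D / 2) * |1/f - 1/u - 1/s|

which vanishes exactly when the sensor plane is the conjugate plane and
grows with axial defocus ``z``.  All lengths are micrometres; conversion to
pixels happens only when a kernel is rasterised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "LensParameters",
    "BlurSpec",
    "NoRealImageError",
    "ExcessiveDefocusError",
    "image_distance",
    "blur_radius",
    "blur_radius_from_defocus",
    "psf_kernel",
    "load_lens_yaml",
]

#: relative tolerance for the in-focus Gauss check
_FOCUS_RTOL = 1e-6


class NoRealImageError(ValueError):
    """Object at or inside the focal length: no real image forms."""


class ExcessiveDefocusError(ValueError):
    """Requested blur kernel exceeds the configured maximum support."""


def image_distance(f: float, u: float) -> float:
    """Gauss-conjugate image distance ``v`` with ``1/u + 1/v = 1/f``.

    Parameters
    ----------
    f : focal length (um), > 0
    u : object distance (um), must exceed ``f`` for a real image

    Returns
    -------
    v : image distance (um)
    """
    if f <= 0 or u <= 0:
        raise ValueError(f"focal length and object distance must be positive, got f={f}, u={u}")
    if u <= f:
        raise NoRealImageError(f"object distance u={u} must exceed focal length f={f} for a real image")
    return f * u / (u - f)


@dataclass(frozen=True)
class LensParameters:
    """Thin-lens acquisition geometry, all lengths in micrometres.

    Attributes
    ----------
    focal_length_f : lens focal length
    object_distance_u : sample-to-lens distance
    sensor_distance_s : lens-to-sensor distance
    aperture_diameter_D : clear aperture diameter
    """

    focal_length_f: float
    object_distance_u: float
    sensor_distance_s: float
    aperture_diameter_D: float

    def __post_init__(self) -> None:
        for name in ("focal_length_f", "object_distance_u", "sensor_distance_s", "aperture_diameter_D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")

    @classmethod
    def in_focus(cls, focal_length_f: float, object_distance_u: float, aperture_diameter_D: float) -> "LensParameters":
        """Construct a lens with the sensor on the Gauss-conjugate plane."""
        s = image_distance(focal_length_f, object_distance_u)
        return cls(focal_length_f, object_distance_u, s, aperture_diameter_D)

    @property
    def is_in_focus(self) -> bool:
        """True when ``1/u + 1/s = 1/f`` holds within tolerance."""
        lhs = 1.0 / self.object_distance_u + 1.0 / self.sensor_distance_s
        rhs = 1.0 / self.focal_length_f
        return math.isclose(lhs, rhs, rel_tol=_FOCUS_RTOL)

    @property
    def magnification(self) -> float:
        return self.sensor_distance_s / self.object_distance_u


def blur_radius(lens: LensParameters) -> float:
    """Blur-circle radius ``R = (sD/2) |1/f - 1/u - 1/s|`` in um.

    Returns the magnitude; R is zero exactly when the sensor plane
    coincides with the Gauss-conjugate plane.
    """
    f, u, s, D = (
        lens.focal_length_f,
        lens.object_distance_u,
        lens.sensor_distance_s,
        lens.aperture_diameter_D,
    )
    return abs(s * D / 2.0 * (1.0 / f - 1.0 / u - 1.0 / s))


def blur_radius_from_defocus(lens: LensParameters, z: float) -> float:
    """Blur-circle radius for a signed axial stage offset ``z`` (um).

    ``lens`` must describe the in-focus configuration (z = 0).  Positive z
    moves the sample toward the lens (stage raised), shrinking the object
    distance to ``u - z``; the sign of the defocus is carried by ``z``
    while the returned radius is a magnitude, ``R(0) = 0`` and R grows
    monotonically with ``|z|`` on either side.
    """
    if not lens.is_in_focus:
        raise ValueError("blur_radius_from_defocus requires an in-focus lens (use LensParameters.in_focus)")
    if z == 0:
        return 0.0
    u = lens.object_distance_u - z
    if u <= lens.focal_length_f:
        raise NoRealImageError(f"defocus z={z} pushes the object inside the focal length")
    displaced = replace(lens, object_distance_u=u)
    return blur_radius(displaced)


@dataclass(frozen=True)
class BlurSpec:
    """Rasterisation recipe turning a blur radius into a normalised PSF.

    Attributes
    ----------
    blur_radius_R : blur-circle radius in um (magnitude, >= 0)
    kernel_kind : "disk" (uniform geometric blur circle, default) or
        "gaussian" (std = R/2)
    pixel_size : sensor sampling pitch, um per pixel
    asymmetry : signed coefficient in (-1, 1) that tilts the disk's radial
        intensity profile — positive values weight the rim (ring-like PSF,
        typical above focus under spherical aberration), negative values
        weight the centre (below focus).  0 gives the plain uniform disk.
        Ignored by the gaussian kernel.
    astigmatism : signed eccentricity in (-1, 1).  Mild astigmatism of a
        real optical train stretches the blur patch horizontally on one
        side of focus and vertically on the other (the cue exploited by
        cylindrical-lens axial localisation); positive values stretch the
        kernel in x by ``1 + |e|`` and compress y by the same factor,
        negative values do the opposite.  The area (and hence the mean
        blur radius) is preserved.
    max_radius_px : largest admissible kernel radius in pixels
    """

    blur_radius_R: float
    kernel_kind: Literal["disk", "gaussian"] = "disk"
    pixel_size: float = 1.0
    asymmetry: float = 0.0
    astigmatism: float = 0.0
    max_radius_px: float = 64.0

    def __post_init__(self) -> None:
        if self.blur_radius_R < 0:
            raise ValueError(f"blur_radius_R must be >= 0, got {self.blur_radius_R}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.kernel_kind not in ("disk", "gaussian"):
            raise ValueError(f"kernel_kind must be 'disk' or 'gaussian', got {self.kernel_kind!r}")
        if not -1.0 < self.asymmetry < 1.0:
            raise ValueError(f"asymmetry must lie in (-1, 1), got {self.asymmetry}")
        if not -1.0 < self.astigmatism < 1.0:
            raise ValueError(f"astigmatism must lie in (-1, 1), got {self.astigmatism}")


def psf_kernel(spec: BlurSpec) -> np.ndarray:
    """Rasterise a blur circle into a square, unit-sum convolution kernel.

    Sub-pixel radii (R < 0.5 px) return the 1x1 identity kernel so that
    near-focus frames are passed through untouched instead of being smeared
    by an aliased one-pixel stencil.  The disk kernel is anti-aliased by
    4x4 subpixel area sampling; its radial profile is optionally tilted by
    ``spec.asymmetry`` (see :class:`BlurSpec`).
    """
    r_px = spec.blur_radius_R / spec.pixel_size
    stretch = 1.0 + abs(spec.astigmatism)
    rx = r_px * (stretch if spec.astigmatism > 0 else 1.0 / stretch)
    ry = r_px * (stretch if spec.astigmatism < 0 else 1.0 / stretch)
    if max(rx, ry) > spec.max_radius_px:
        raise ExcessiveDefocusError(
            f"blur radius {max(rx, ry):.1f} px exceeds maximum kernel radius {spec.max_radius_px} px"
        )
    if r_px < 0.5:
        return np.ones((1, 1), dtype=np.float64)

    if spec.kernel_kind == "gaussian":
        sx, sy = rx / 2.0, ry / 2.0
        half = max(1, int(math.ceil(3.0 * max(sx, sy))))
        ax = np.arange(-half, half + 1, dtype=np.float64)
        gy = np.exp(-0.5 * (ax / sy) ** 2)
        gx = np.exp(-0.5 * (ax / sx) ** 2)
        kernel = np.outer(gy, gx)
        return kernel / kernel.sum()

    half = int(math.ceil(max(rx, ry)))
    n_sub = 4  # subpixel samples per axis for anti-aliasing
    coords = np.arange(-half, half + 1, dtype=np.float64)
    offs = (np.arange(n_sub) + 0.5) / n_sub - 0.5
    yy = coords[:, None] + offs[None, :]  # (2half+1, n_sub)
    sub = yy.reshape(-1)
    # normalised elliptical radius squared: 1 on the support boundary
    rho2 = (sub[:, None] / ry) ** 2 + (sub[None, :] / rx) ** 2
    inside = rho2 <= 1.0
    if spec.asymmetry != 0.0:
        # radial profile 1 + a*(2 rho^2 - 1): rim-weighted for a > 0,
        # centre-weighted for a < 0; stays non-negative for |a| < 1
        weight = 1.0 + spec.asymmetry * (2.0 * rho2 - 1.0)
        vals = np.where(inside, np.maximum(weight, 0.0), 0.0)
    else:
        vals = inside.astype(np.float64)
    n = 2 * half + 1
    kernel = vals.reshape(n, n_sub, n, n_sub).sum(axis=(1, 3))
    total = kernel.sum()
    if total <= 0:  # pragma: no cover - unreachable for valid specs
        raise RuntimeError("degenerate PSF kernel")
    return kernel / total


def load_lens_yaml(path) -> tuple[LensParameters, BlurSpec]:
    """Read a lens/acquisition configuration from YAML.

    Expected keys: ``focal_length_um``, ``object_distance_um``,
    ``sensor_distance_um`` (optional; defaults to the in-focus conjugate),
    ``aperture_um``, ``pixel_size_um``, ``kernel`` (disk|gaussian) and
    optional ``asymmetry``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return lens_from_dict(cfg)


def lens_from_dict(cfg: dict) -> tuple[LensParameters, BlurSpec]:
    """Build (LensParameters, BlurSpec-template) from a config mapping."""
    f = float(cfg["focal_length_um"])
    u = float(cfg["object_distance_um"])
    D = float(cfg["aperture_um"])
    if "sensor_distance_um" in cfg and cfg["sensor_distance_um"] is not None:
        lens = LensParameters(f, u, float(cfg["sensor_distance_um"]), D)
    else:
        lens = LensParameters.in_focus(f, u, D)
    blur = BlurSpec(
        blur_radius_R=0.0,
        kernel_kind=cfg.get("kernel", "disk"),
        pixel_size=float(cfg.get("pixel_size_um", 1.0)),
        asymmetry=float(cfg.get("asymmetry", 0.0)),
        astigmatism=float(cfg.get("astigmatism", 0.0)),
        max_radius_px=float(cfg.get("max_kernel_radius_px", 64.0)),
    )
    return lens, blur
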