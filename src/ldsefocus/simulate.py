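"""Cell-phantom fields and labelled defocus z-stacks.

Real training data for single-shot focus regression comes from motorised
z-stacks of stained tissue: the stage sweeps an axial range around the
focal plane and every frame is labelled with its signed offset z.  This
module emulates that acquisition on synthetic phantoms so that the whole
pipeline is reproducible from a seed:

* :func:`generate_phantom` draws a bright-field-like field of soft-edged
  elliptical cells over a textured background, with a contiguous blank
  band that later exercises the blank-tile discriminant;
* :func:`render_defocus_stack` sweeps the configured z grid (default
  -10 um .. +10 um in 0.5 um steps, 41 frames), convolving the sharp
  phantom with the thin-lens blur kernel for each offset and adding
  sensor noise;
* :func:`tile_stack` cuts every frame into non-overlapping labelled
  patches; :func:`split_dataset` partitions *by field* into disjoint
  train/test sets.

Through-focus asymmetry.  The geometric blur radius is nearly symmetric
in the sign of z, so a purely symmetric blur model would make the *sign*
of the defocus unrecoverable from a single frame — unlike real
micrographs, where three well-known asymmetries break the tie and are
exactly what single-shot methods exploit.  The renderer reproduces all
three:

* **phase-contrast reversal** (transport of intensity): semi-transparent
  specimens gain edge contrast linear in z, with bright rims on one side
  of focus and dark rims on the other (``tie_strength``);
* **spherical aberration**: the blur disk is rim-weighted (ring-like)
  above focus and centre-weighted below (``psf_asymmetry``);
* **residual astigmatism**: the blur patch stretches along orthogonal
  axes on opposite sides of focus (``psf_astigmatism``).

See the methods note for the model and parameter choices.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter, gaussian_laplace
from scipy.signal import fftconvolve
from scipy.special import expit

from ldsefocus.optics import BlurSpec, LensParameters, blur_radius_from_defocus, psf_kernel

__all__ = [
    "PhantomSpec",
    "FocalStackSpec",
    "FocalStack",
    "LabeledTile",
    "generate_phantom",
    "render_defocus_stack",
    "tile_stack",
    "split_dataset",
    "default_lens",
    "build_dataset",
    "tiles_to_arrays",
    "save_tiles",
    "load_tiles",
]

#: default tilt of the disk PSF's radial profile per sign of defocus
DEFAULT_PSF_ASYMMETRY = 0.6
#: default astigmatic eccentricity of the PSF per sign of defocus
DEFAULT_PSF_ASTIGMATISM = 0.25
#: default phase-contrast gain per um of defocus (transport-of-intensity)
DEFAULT_TIE_STRENGTH = 0.03


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one sharp cell-phantom field.

    ``blank_fraction`` reserves a contiguous vertical band on the right of
    the field that contains background only (no cells, no texture) — the
    stand-in for the empty glass regions of a real slide.  ``seed`` fully
    determines the rendered field.
    """

    width: int = 256
    height: int = 256
    n_cells: int = 25
    cell_radius_range: tuple[float, float] = (6.0, 14.0)
    texture_amplitude: float = 0.08
    blank_fraction: float = 0.25
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("phantom dimensions must be positive")
        if not 0 <= self.blank_fraction < 1:
            raise ValueError(f"blank_fraction must lie in [0, 1), got {self.blank_fraction}")
        if self.cell_radius_range[0] > self.cell_radius_range[1] or self.cell_radius_range[0] <= 0:
            raise ValueError(f"invalid cell_radius_range {self.cell_radius_range}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass(frozen=True)
class FocalStackSpec:
    """Axial sampling of the z-stack acquisition.

    Defaults follow the usual motorised-stage protocol: -10 um to +10 um
    in 0.5 um steps, i.e. 41 frames with the in-focus frame included.
    """

    z_min: float = -10.0
    z_max: float = 10.0
    z_step: float = 0.5
    magnification_tag: str = "20X"

    def __post_init__(self):
        if not (self.z_min < 0 < self.z_max):
            raise ValueError("z grid must straddle the focal plane (z_min < 0 < z_max)")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        offs = self.z_offsets()
        if not np.any(np.isclose(offs, 0.0, atol=1e-9)):
            raise ValueError("z grid must include the in-focus plane z = 0")

    def z_offsets(self) -> np.ndarray:
        n = int(round((self.z_max - self.z_min) / self.z_step))
        return self.z_min + self.z_step * np.arange(n + 1)


@dataclass
class FocalStack:
    """Images of one field at known axial offsets, plus acquisition metadata."""

    frames: np.ndarray  # (n_z, H, W) float in [0, 1]
    z_offsets_um: np.ndarray  # (n_z,)
    field_id: str
    magnification_tag: str = "20X"
    pixel_size_um: float = 1.0
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def save(self, directory) -> None:
        """Multi-page TIFF + CSV sidecar + JSON manifest."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(d / f"{self.field_id}.tif", self.frames.astype(np.float32))
        pd.DataFrame(
            {"frame_index": np.arange(len(self.frames)), "z_um": self.z_offsets_um}
        ).to_csv(d / f"{self.field_id}.csv", index=False)
        manifest = {
            "field_id": self.field_id,
            "magnification_tag": self.magnification_tag,
            "pixel_size_um": self.pixel_size_um,
            "n_frames": int(len(self.frames)),
            "shape": list(self.frames.shape[1:]),
            "params": self.params,
        }
        (d / f"{self.field_id}.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory, field_id: str) -> "FocalStack":
        d = Path(directory)
        frames = tifffile.imread(d / f"{field_id}.tif")
        sidecar = pd.read_csv(d / f"{field_id}.csv")
        manifest = json.loads((d / f"{field_id}.json").read_text())
        return cls(
            frames=np.asarray(frames, dtype=np.float64),
            z_offsets_um=sidecar["z_um"].to_numpy(),
            field_id=field_id,
            magnification_tag=manifest.get("magnification_tag", "20X"),
            pixel_size_um=manifest.get("pixel_size_um", 1.0),
            params=manifest.get("params", {}),
        )


@dataclass(frozen=True)
class LabeledTile:
    """A square patch cut from one stack frame with its true defocus."""

    pixels: np.ndarray  # (tile, tile) float in [0, 1]
    z_true: float  # um
    field_id: str
    row: int
    col: int


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the sharp (in-focus) field for a phantom recipe.

    Bright background (~0.85) with ``n_cells`` darker soft-edged ellipses
    carrying internal texture, plus low-amplitude background texture; the
    rightmost ``blank_fraction`` of columns stays background-only.
    Deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    background = 0.85
    img = np.full((h, w), background, dtype=np.float64)

    blank_cols = int(round(w * spec.blank_fraction))
    usable_w = w - blank_cols
    r_lo, r_hi = spec.cell_radius_range
    if spec.n_cells > 0 and (usable_w < 2 * r_hi or h < 2 * r_hi):
        raise ValueError(
            f"cells of radius up to {r_hi} px do not fit the {h}x{usable_w} non-blank region"
        )

    if spec.texture_amplitude > 0:
        texture = gaussian_filter(rng.standard_normal((h, w)), sigma=3.0)
        texture *= spec.texture_amplitude / max(texture.std(), 1e-12)
        if blank_cols:
            texture[:, usable_w:] = 0.0
        img += texture

    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(spec.n_cells):
        a = rng.uniform(r_lo, r_hi)
        b = rng.uniform(r_lo, r_hi)
        theta = rng.uniform(0, np.pi)
        cx = rng.uniform(r_hi, usable_w - r_hi)
        cy = rng.uniform(r_hi, h - r_hi)
        ct, st = np.cos(theta), np.sin(theta)
        xr = (xx - cx) * ct + (yy - cy) * st
        yr = -(xx - cx) * st + (yy - cy) * ct
        d = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
        edge = expit(-(d - 1.0) / 0.08)  # soft rim
        depth = rng.uniform(0.3, 0.5)
        interior = gaussian_filter(rng.standard_normal((h, w)), sigma=2.0)
        interior *= 0.08 / max(interior.std(), 1e-12)
        img -= edge * (depth + interior)

    return np.clip(img, 0.0, 1.0)


def default_lens(magnification_tag: str = "20X") -> LensParameters:
    """Thin-lens stand-ins for common dry objectives.

    20X/0.25 NA: f = 9 mm, in-focus object distance 9450 um, aperture from
    the NA half-angle.  40X/0.65 NA: f = 4.5 mm, object distance 4612.5 um.
    The higher NA of the 40X doubles-plus the blur growth per um of
    defocus, which is what makes 40X fields harder to predict.
    """
    if magnification_tag == "20X":
        f, mag, na = 9000.0, 20.0, 0.25
    elif magnification_tag == "40X":
        f, mag, na = 4500.0, 40.0, 0.65
    else:
        raise ValueError(f"unknown magnification_tag {magnification_tag!r}")
    u = f * (mag + 1.0) / mag
    d = 2.0 * u * np.tan(np.arcsin(na))
    return LensParameters.in_focus(f, u, d)


def _convolve_reflect(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """FFT convolution with reflective boundary handling."""
    if kernel.shape == (1, 1):
        return img * kernel[0, 0]
    py, px = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(img, ((py, py), (px, px)), mode="reflect")
    out = fftconvolve(padded, kernel, mode="same")
    return out[py : py + img.shape[0], px : px + img.shape[1]]


def render_defocus_stack(
    phantom: np.ndarray,
    stack_spec: FocalStackSpec,
    lens: LensParameters,
    *,
    pixel_size_um: float = 4.4,
    noise_sigma: float = 0.01,
    psf_asymmetry: float = DEFAULT_PSF_ASYMMETRY,
    psf_astigmatism: float = DEFAULT_PSF_ASTIGMATISM,
    tie_strength: float = DEFAULT_TIE_STRENGTH,
    kernel_kind: str = "disk",
    max_kernel_radius_px: float = 128.0,  # the 40X lens reaches ~78 px at z=10
    field_id: str = "field0",
    seed: int = 0,
) -> FocalStack:
    """Sweep the z grid and render one blurred, noisy frame per offset.

    Each frame is the sharp phantom convolved with the PSF for the
    thin-lens blur radius at that offset (identity at z = 0), with the
    disk profile tilted by ``psf_asymmetry * sign(z)``, plus i.i.d.
    Gaussian sensor noise of standard deviation ``noise_sigma``.
    ``pixel_size_um`` is the effective sensor sampling pitch used to
    rasterise the blur radius.
    """
    rng = np.random.default_rng(seed)
    z_offsets = stack_spec.z_offsets()
    frames = np.empty((len(z_offsets), *phantom.shape), dtype=np.float64)
    # transport-of-intensity edge contrast: optical thickness is proxied by
    # the specimen's absorption relief; its (band-limited) Laplacian flips
    # the rim brightness with the sign of z
    thickness = np.max(phantom) - phantom
    lap = gaussian_laplace(thickness, sigma=1.5)
    lap_std = lap.std()
    lap = lap / lap_std if lap_std > 0 else lap
    for i, z in enumerate(z_offsets):
        r_um = blur_radius_from_defocus(lens, float(z))
        spec = BlurSpec(
            blur_radius_R=r_um,
            kernel_kind=kernel_kind,
            pixel_size=pixel_size_um,
            asymmetry=float(psf_asymmetry * np.sign(z)),
            astigmatism=float(psf_astigmatism * np.sign(z)),
            max_radius_px=max_kernel_radius_px,
        )
        sharp = phantom + tie_strength * z * lap
        frame = _convolve_reflect(sharp, psf_kernel(spec))
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma, size=frame.shape)
        frames[i] = np.clip(frame, 0.0, 1.0)
    params = {
        "lens": dataclasses.asdict(lens),
        "stack_spec": dataclasses.asdict(stack_spec),
        "pixel_size_um": pixel_size_um,
        "noise_sigma": noise_sigma,
        "psf_asymmetry": psf_asymmetry,
        "psf_astigmatism": psf_astigmatism,
        "tie_strength": tie_strength,
        "kernel_kind": kernel_kind,
        "seed": seed,
    }
    return FocalStack(
        frames=frames,
        z_offsets_um=z_offsets,
        field_id=field_id,
        magnification_tag=stack_spec.magnification_tag,
        pixel_size_um=pixel_size_um,
        params=params,
    )


def tile_stack(stack: FocalStack, tile_size: int = 224) -> list[LabeledTile]:
    """Cut every frame into a non-overlapping grid of labelled patches.

    Partial tiles at the right/bottom edges are discarded; every tile of a
    frame inherits that frame's z offset.
    """
    n_z, h, w = stack.frames.shape
    if h < tile_size or w < tile_size:
        raise ValueError(f"frames of {h}x{w} are smaller than the {tile_size} px tile")
    n_rows, n_cols = h // tile_size, w // tile_size
    tiles = []
    for iz, z in enumerate(stack.z_offsets_um):
        frame = stack.frames[iz]
        for r in range(n_rows):
            for c in range(n_cols):
                patch = frame[r * tile_size : (r + 1) * tile_size, c * tile_size : (c + 1) * tile_size]
                tiles.append(
                    LabeledTile(pixels=patch.copy(), z_true=float(z), field_id=stack.field_id, row=r, col=c)
                )
    return tiles


def split_dataset(
    tiles: list[LabeledTile], ratio: float = 0.9, seed: int = 0
) -> tuple[list[LabeledTile], list[LabeledTile]]:
    """Disjoint train/test split *by field* (all tiles of a field together).

    Splitting at the tile level would leak near-duplicate content between
    the sets, so the unit of assignment is the field.  The split is
    exhaustive, disjoint and reproducible from ``seed``.
    """
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    fields = sorted({t.field_id for t in tiles})
    if len(fields) < 2:
        raise ValueError("need at least 2 fields for a field-level split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(fields))
    n_train = int(round(ratio * len(fields)))
    n_train = min(max(n_train, 1), len(fields) - 1)
    train_fields = set(order[:n_train])
    train = [t for t in tiles if t.field_id in train_fields]
    test = [t for t in tiles if t.field_id not in train_fields]
    return train, test


def build_dataset(
    n_fields: int,
    phantom_spec: PhantomSpec,
    stack_spec: FocalStackSpec,
    lens: LensParameters | None = None,
    *,
    tile_size: int = 224,
    pixel_size_um: float = 4.4,
    psf_asymmetry: float = DEFAULT_PSF_ASYMMETRY,
    psf_astigmatism: float = DEFAULT_PSF_ASTIGMATISM,
    tie_strength: float = DEFAULT_TIE_STRENGTH,
    seed: int = 0,
) -> tuple[list[LabeledTile], list[FocalStack]]:
    """Render ``n_fields`` stacks and tile them all.

    Field i uses an independent phantom seeded from ``seed`` and a noise
    stream of its own, mirroring the repeated lateral-step acquisition of
    a real slide survey.  For the 40X tag the cell density is halved
    (narrower field of view sees fewer cells) and the 40X lens supplies
    the steeper blur growth.
    """
    lens = lens or default_lens(stack_spec.magnification_tag)
    if stack_spec.magnification_tag == "40X":
        phantom_spec = dataclasses.replace(phantom_spec, n_cells=max(1, phantom_spec.n_cells // 2))
    tiles: list[LabeledTile] = []
    stacks: list[FocalStack] = []
    for i in range(n_fields):
        pspec = dataclasses.replace(phantom_spec, seed=seed * 100003 + i)
        phantom = generate_phantom(pspec)
        stack = render_defocus_stack(
            phantom,
            stack_spec,
            lens,
            pixel_size_um=pixel_size_um,
            noise_sigma=phantom_spec.noise_sigma,
            psf_asymmetry=psf_asymmetry,
            psf_astigmatism=psf_astigmatism,
            tie_strength=tie_strength,
            field_id=f"field{i:03d}",
            seed=seed * 900001 + i,
        )
        stacks.append(stack)
        tiles.extend(tile_stack(stack, tile_size=tile_size))
    return tiles, stacks


def tiles_to_arrays(tiles: list[LabeledTile], channels: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Stack tiles into ``(N, C, S, S)`` float32 inputs and z labels (um)."""
    x = np.stack([t.pixels for t in tiles]).astype(np.float32)[:, None]
    if channels > 1:
        x = np.repeat(x, channels, axis=1)
    y = np.array([t.z_true for t in tiles], dtype=np.float32)
    return x, y


def save_tiles(tiles: list[LabeledTile], directory) -> None:
    """PNG directory + labels.csv + JSON manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, t in enumerate(tiles):
        name = f"tile{i:06d}.png"
        iio.imwrite(d / name, (np.clip(t.pixels, 0, 1) * 65535).astype(np.uint16))
        rows.append(
            {"file": name, "z_um": t.z_true, "field_id": t.field_id, "row": t.row, "col": t.col}
        )
    pd.DataFrame(rows).to_csv(d / "labels.csv", index=False)
    manifest = {"n_tiles": len(tiles), "tile_size": int(tiles[0].pixels.shape[0]) if tiles else 0}
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_tiles(directory) -> list[LabeledTile]:
    d = Path(directory)
    table = pd.read_csv(d / "labels.csv")
    tiles = []
    for rec in table.itertuples():
        pixels = iio.imread(d / rec.file).astype(np.float64) / 65535.0
        tiles.append(
            LabeledTile(pixels=pixels, z_true=float(rec.z_um), field_id=str(rec.field_id),
                        row=int(rec.row), col=int(rec.col))
        )
    return tiles
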