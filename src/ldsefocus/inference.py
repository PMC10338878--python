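"""Wide-field focal-distance prediction with blank-tile rejection.

A wide-field micrograph is cut into non-overlapping tiles of the
network's input size; tiles that are mostly blank glass carry no defocus
information and would corrupt the estimate, so a discriminant discards
them before the per-tile predictions are averaged into the field-level
focal distance ``D_p``.  A 3x3 regional analysis repeats the prediction
on nine non-overlapping sub-regions to probe spatial uniformity of the
focus error across the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ldsefocus.nn.network import LDSENet

__all__ = [
    "DiscriminantConfig",
    "TileVerdict",
    "FocusPrediction",
    "blank_discriminant",
    "predict_focus",
    "regional_errors",
]


@dataclass(frozen=True)
class DiscriminantConfig:
    """Thresholds of the blank-tile discriminant.

    A tile is kept when its foreground fraction is at least ``f_min``
    (inclusive) *and* its intensity standard deviation is at least
    ``s_min`` (inclusive).  Foreground pixels are those deviating from
    the tile's modal background intensity by more than ``k_noise`` times
    the background noise scale (a robust MAD estimate).
    """

    f_min: float = 0.1
    s_min: float = 0.01
    k_noise: float = 3.0


@dataclass(frozen=True)
class TileVerdict:
    """Keep/discard decision and prediction for one tile."""

    row: int
    col: int
    kept: bool
    reason: str  # "ok" | "blank" | "low_variance"
    prediction_um: float | None = None

    def __post_init__(self):
        if self.kept != (self.prediction_um is not None):
            raise ValueError("prediction must be present exactly when the tile is kept")


@dataclass(frozen=True)
class FocusPrediction:
    """Aggregated focal distance of a wide-field image."""

    D_p_um: float | None
    n_tiles_total: int
    n_tiles_kept: int
    verdicts: tuple[TileVerdict, ...]

    @property
    def ok(self) -> bool:
        return self.D_p_um is not None


def _foreground_fraction(tile: np.ndarray, cfg: DiscriminantConfig) -> float:
    """Fraction of pixels deviating from the modal background level."""
    # modal background from a coarse histogram; noise scale via MAD around it
    hist, edges = np.histogram(tile, bins=64, range=(0.0, 1.0))
    mode = 0.5 * (edges[hist.argmax()] + edges[hist.argmax() + 1])
    dev = np.abs(tile - mode)
    near = dev[dev < 0.1]
    noise = 1.4826 * np.median(near) if near.size else 0.0
    noise = max(noise, 1e-3)
    return float(np.mean(dev > cfg.k_noise * noise))


def blank_discriminant(tile: np.ndarray, config: DiscriminantConfig | None = None) -> TileVerdict:
    """Decide whether a tile carries enough content to predict from.

    Returns a verdict with ``row = col = 0`` and no prediction; callers
    embed the decision into their own verdicts.
    """
    cfg = config or DiscriminantConfig()
    tile = np.asarray(tile, dtype=np.float64)
    std = float(tile.std())
    if std < cfg.s_min:
        return TileVerdict(0, 0, kept=False, reason="low_variance")
    if _foreground_fraction(tile, cfg) < cfg.f_min:
        return TileVerdict(0, 0, kept=False, reason="blank")
    return TileVerdict(0, 0, kept=True, reason="ok", prediction_um=np.nan)


def _iter_tiles(image: np.ndarray, tile_size: int):
    h, w = image.shape[:2]
    for r in range(h // tile_size):
        for c in range(w // tile_size):
            yield r, c, image[r * tile_size : (r + 1) * tile_size, c * tile_size : (c + 1) * tile_size]


def predict_focus(
    image: np.ndarray,
    model: LDSENet,
    tile_size: int | None = None,
    discriminant: DiscriminantConfig | None = None,
) -> FocusPrediction:
    """Tile-averaged focal distance of one wide-field image.

    The image is cut into the non-overlapping tile grid (remainder pixels
    at the right/bottom truncated), blank and low-variance tiles are
    discarded, the model predicts each kept tile, and ``D_p`` is the
    unweighted mean of the kept predictions.  When every tile is
    discarded the prediction is absent (``D_p_um is None``).
    """
    cfg = discriminant or DiscriminantConfig()
    tile_size = tile_size or model.config.input_size
    image = np.asarray(image, dtype=np.float64)
    if image.shape[0] < tile_size or image.shape[1] < tile_size:
        raise ValueError(f"image {image.shape} smaller than tile size {tile_size}")

    kept_tiles, kept_pos, verdicts = [], [], []
    for r, c, tile in _iter_tiles(image, tile_size):
        v = blank_discriminant(tile, cfg)
        if v.kept:
            kept_tiles.append(tile)
            kept_pos.append((r, c))
            verdicts.append(None)  # placeholder until predictions exist
        else:
            verdicts.append(TileVerdict(r, c, kept=False, reason=v.reason))

    if kept_tiles:
        batch = np.stack(kept_tiles)[:, None]
        if model.config.input_channels > 1:
            batch = np.repeat(batch, model.config.input_channels, axis=1)
        preds = model.predict_um(batch)
    else:
        preds = np.empty(0)

    it = iter(zip(kept_pos, preds))
    final = []
    for v in verdicts:
        if v is None:
            (r, c), p = next(it)
            final.append(TileVerdict(r, c, kept=True, reason="ok", prediction_um=float(p)))
        else:
            final.append(v)

    d_p = float(np.mean(preds)) if len(preds) else None
    return FocusPrediction(
        D_p_um=d_p,
        n_tiles_total=len(final),
        n_tiles_kept=len(preds),
        verdicts=tuple(final),
    )


def regional_errors(
    image: np.ndarray,
    model: LDSENet,
    z_true: float,
    grid: tuple[int, int] = (3, 3),
    tile_size: int | None = None,
    discriminant: DiscriminantConfig | None = None,
) -> np.ndarray:
    """Absolute focus error (um) per region of a ``grid`` partition.

    The image is split into ``grid`` non-overlapping regions (remainder
    truncated) and :func:`predict_focus` runs independently in each;
    entries are ``|prediction - z_true|``, NaN where every tile of a
    region was discarded.
    """
    tile_size = tile_size or model.config.input_size
    image = np.asarray(image, dtype=np.float64)
    gr, gc = grid
    rh, cw = image.shape[0] // gr, image.shape[1] // gc
    if rh < tile_size or cw < tile_size:
        raise ValueError(
            f"regions of {rh}x{cw} px cannot hold a {tile_size} px tile; supply a larger image"
        )
    errors = np.full(grid, np.nan)
    for i in range(gr):
        for j in range(gc):
            region = image[i * rh : (i + 1) * rh, j * cw : (j + 1) * cw]
            pred = predict_focus(region, model, tile_size=tile_size, discriminant=discriminant)
            if pred.ok:
                errors[i, j] = abs(pred.D_p_um - z_true)
    return errors
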