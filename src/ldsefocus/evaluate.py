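"""Evaluation reports: RMSE, error histogram, per-z error profile.

The headline statistic is the fraction of tiles whose signed prediction
error falls within +/-250 nm, reported alongside the RMSE in both um and
nm; the error histogram uses 50 nm bins across +/-1 um plus two overflow
bins so the +/-250 nm band is resolved by whole bins.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ldsefocus.nn.network import LDSENet, model_size_bytes
from ldsefocus.simulate import LabeledTile, tiles_to_arrays
from ldsefocus.training import mse_loss

__all__ = ["EvalReport", "evaluate", "render_report"]

#: histogram geometry: 50 nm bins across +/-1 um, plus two overflow bins
_BIN_HALF_RANGE_UM = 1.0
_BIN_WIDTH_UM = 0.05


@dataclass
class EvalReport:
    """Deterministic summary of a model on a labelled tile set."""

    rmse_um: float
    rmse_nm: float
    mean_abs_error_um: float
    fraction_within_250nm: float
    n_tiles: int
    bin_edges_um: list[float]
    bin_counts: list[int]
    per_z_um: list[float]
    per_z_mean_abs_error_um: list[float]
    model_size_bytes: int
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "EvalReport":
        return cls(**json.loads(Path(path).read_text()))


def evaluate(model: LDSENet, test_tiles: list[LabeledTile]) -> EvalReport:
    """Score a trained model on labelled tiles.

    Errors are signed ``prediction - z_true`` in um; the histogram counts
    sum to the number of tiles (overflow bins catch |error| > 1 um), and
    the per-z curve has one entry per distinct true offset.
    """
    if not test_tiles:
        raise ValueError("evaluate requires a non-empty test set")
    x, y = tiles_to_arrays(test_tiles, channels=model.config.input_channels)
    preds = model.predict_um(x)
    errors = preds - y

    inner = np.arange(-_BIN_HALF_RANGE_UM, _BIN_HALF_RANGE_UM + _BIN_WIDTH_UM / 2, _BIN_WIDTH_UM)
    edges = np.concatenate([[-np.inf], inner, [np.inf]])
    counts, _ = np.histogram(errors, bins=edges)

    z_values = np.unique(y)
    per_z = [float(np.mean(np.abs(errors[y == z]))) for z in z_values]

    rmse = float(np.sqrt(mse_loss(y, preds)))
    return EvalReport(
        rmse_um=rmse,
        rmse_nm=rmse * 1000.0,
        mean_abs_error_um=float(np.mean(np.abs(errors))),
        fraction_within_250nm=float(np.mean(np.abs(errors) <= 0.25)),
        n_tiles=len(test_tiles),
        bin_edges_um=[float(e) for e in edges],
        bin_counts=[int(c) for c in counts],
        per_z_um=[float(z) for z in z_values],
        per_z_mean_abs_error_um=per_z,
        model_size_bytes=model_size_bytes(model.config),
        config=asdict(model.config) | {"layers_per_block": list(model.config.layers_per_block)},
    )


def render_report(report: EvalReport, out_dir) -> list[Path]:
    """Write the error histogram and error-vs-z plots as PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(6, 4))
    edges = np.array(report.bin_edges_um)
    centers = np.concatenate(
        [[-_BIN_HALF_RANGE_UM - _BIN_WIDTH_UM], 0.5 * (edges[1:-2] + edges[2:-1]),
         [_BIN_HALF_RANGE_UM + _BIN_WIDTH_UM]]
    )
    ax.bar(centers, report.bin_counts, width=_BIN_WIDTH_UM * 0.9, color="steelblue")
    ax.axvspan(-0.25, 0.25, color="orange", alpha=0.2, label="+/-250 nm")
    ax.set_xlabel("prediction error (um)")
    ax.set_ylabel("tiles")
    ax.legend()
    path = out / "error_histogram.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(report.per_z_um, report.per_z_mean_abs_error_um, "o-", color="firebrick")
    ax.set_xlabel("true defocus z (um)")
    ax.set_ylabel("mean |error| (um)")
    path = out / "error_vs_z.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)
    return written
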