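"""Scaled-down parameter-recovery study: the package's reference benchmark.

The full-scale protocol (224 px tiles, ~130k patches, GPU-hours of
training) is impractical for a self-check, so the benchmark runs the same
pipeline end to end at reduced scale: 64 px tiles cut from 256 px phantom
fields, the full +/-10 um z grid at 0.5 um steps, about two thousand
content tiles after blank rejection, and a reduced LDSE-NET (two dense
blocks, ~15k parameters).  The quantities it reports — held-out tile
RMSE, the +/-250 nm error fraction, and the wide-field recovery error at
a known stage offset — are the scaled analogues of the full protocol's
headline metrics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from ldsefocus.evaluate import EvalReport, evaluate
from ldsefocus.inference import predict_focus, regional_errors, blank_discriminant
from ldsefocus.nn.network import LDSENet, LDSENetConfig
from ldsefocus.simulate import (
    FocalStackSpec,
    PhantomSpec,
    build_dataset,
    default_lens,
    generate_phantom,
    render_defocus_stack,
    split_dataset,
    tiles_to_arrays,
)
from ldsefocus.training import TrainConfig, train

__all__ = ["ScaledStudy", "StudyResult", "run_scaled_study"]

#: study conditions of the scaled benchmark (fixed; see the methods note)
SCALED_TILE_SIZE = 64
SCALED_N_FIELDS = 5
SCALED_PHANTOM = PhantomSpec()  # 256 px field, 25 cells, 25% blank band
SCALED_STACK = FocalStackSpec()  # -10..+10 um by 0.5 um
SCALED_NET = LDSENetConfig(
    input_channels=1,
    input_size=SCALED_TILE_SIZE,
    stem_channels=16,
    layers_per_block=(3, 3),
    growth_rate_k=10,
    se_reduction_r=4,
)
SCALED_TRAIN = TrainConfig(max_epochs=70, plateau_patience=18, lr_decay_every=15)
#: held-out wide-field recovery is probed at this true stage offset
RECOVERY_Z_TRUE_UM = 3.0


@dataclass
class StudyResult:
    """Outcome of one scaled parameter-recovery run."""

    test_rmse_um: float
    fraction_within_250nm: float
    recovery_error_um: float
    recovery_n_tiles: int
    regional_errors_um: np.ndarray  # 3x3
    n_train_tiles: int
    n_test_tiles: int
    n_epochs: int
    model_size_bytes: int
    report: EvalReport
    net: LDSENet


def _filter_content_tiles(tiles):
    """Drop blank/low-variance tiles: they carry no defocus information."""
    return [t for t in tiles if blank_discriminant(t.pixels).kept]


def run_scaled_study(seed: int = 1, log=None, max_epochs: int | None = None) -> StudyResult:
    """Generate data, train the reduced network and measure recovery.

    Fully deterministic in ``seed``.  ``max_epochs`` can shorten the run
    for quick smoke checks; the reported metrics always come from the
    best-test-loss weights.
    """
    tiles, _ = build_dataset(
        SCALED_N_FIELDS, SCALED_PHANTOM, SCALED_STACK, tile_size=SCALED_TILE_SIZE, seed=seed
    )
    train_tiles, test_tiles = split_dataset(tiles, ratio=0.9, seed=seed)
    train_tiles = _filter_content_tiles(train_tiles)
    test_tiles = _filter_content_tiles(test_tiles)

    net = LDSENet(SCALED_NET, seed=seed)
    tcfg = dataclasses.replace(SCALED_TRAIN, seed=seed)
    if max_epochs is not None:
        tcfg = dataclasses.replace(tcfg, max_epochs=max_epochs)
    net, trace = train(
        net,
        tiles_to_arrays(train_tiles),
        tiles_to_arrays(test_tiles),
        tcfg,
        log=log,
    )
    report = evaluate(net, test_tiles)

    # wide-field recovery on a fresh, fully populated field at known z
    lens = default_lens(SCALED_STACK.magnification_tag)
    # fully populated 384 px field at training-like cell statistics; each
    # 3x3 region spans a 2x2 tile grid, so every region carries content
    recovery_phantom = generate_phantom(
        dataclasses.replace(SCALED_PHANTOM, width=384, height=384, n_cells=100,
                            blank_fraction=0.0, seed=seed + 77)
    )
    frame_spec = FocalStackSpec(z_min=-RECOVERY_Z_TRUE_UM, z_max=RECOVERY_Z_TRUE_UM,
                                z_step=RECOVERY_Z_TRUE_UM)
    stack = render_defocus_stack(recovery_phantom, frame_spec, lens,
                                 noise_sigma=SCALED_PHANTOM.noise_sigma,
                                 field_id="recovery", seed=seed + 99)
    frame = stack.frames[-1]  # the +z frame
    wide = predict_focus(frame, net, tile_size=SCALED_TILE_SIZE)
    recovery_error = abs(wide.D_p_um - RECOVERY_Z_TRUE_UM) if wide.ok else np.inf
    regional = regional_errors(frame, net, z_true=RECOVERY_Z_TRUE_UM,
                               tile_size=SCALED_TILE_SIZE)

    return StudyResult(
        test_rmse_um=report.rmse_um,
        fraction_within_250nm=report.fraction_within_250nm,
        recovery_error_um=float(recovery_error),
        recovery_n_tiles=wide.n_tiles_kept,
        regional_errors_um=regional,
        n_train_tiles=len(train_tiles),
        n_test_tiles=len(test_tiles),
        n_epochs=len(trace.train_loss),
        model_size_bytes=4 * net.n_parameters(),
        report=report,
        net=net,
    )
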