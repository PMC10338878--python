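"""Wide-field prediction with blank-tile rejection (untrained weights).

Demonstrates the aggregation machinery in isolation: a field that is
half cells, half blank glass is tiled, the blank discriminant discards
the empty tiles, and the per-tile predictions of a freshly initialised
network are averaged into D_p.  The point here is the bookkeeping — which
tiles were kept and why — not the (meaningless) value an untrained net
predicts; see 03_train_and_evaluate.py for trained recovery.
"""

import numpy as np

from ldsefocus import LDSENet, LDSENetConfig, PhantomSpec, generate_phantom, predict_focus

field = np.full((128, 256), 0.85)
field[:, :128] = generate_phantom(
    PhantomSpec(width=128, height=128, n_cells=10, blank_fraction=0.0, seed=3)
)

net = LDSENet(
    LDSENetConfig(input_channels=1, input_size=64, stem_channels=8,
                  layers_per_block=(2,), growth_rate_k=4, se_reduction_r=2),
    seed=0,
)
result = predict_focus(field, net, tile_size=64)
print(f"tiles: {result.n_tiles_total} total, {result.n_tiles_kept} kept")
for v in result.verdicts:
    pred = f"{v.prediction_um:+.2f} um" if v.kept else "--"
    print(f"  tile ({v.row},{v.col}): {'kept   ' if v.kept else 'dropped'} [{v.reason:12s}] {pred}")
print(f"D_p = {result.D_p_um:+.2f} um (mean of kept tiles)")
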