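"""Wire a small spiking cube, propagate spikes, train it with STDP.

Neurons sit on a 3-D grid; connections only join neurons within the
small-world radius; EEG channels inject signed current at the grid sites
nearest their scalp positions.  STDP strengthens connections that fire in
causal order and weakens the reverse.
"""

import numpy as np

from spikecube import (
    build_geometry,
    build_samples,
    experiment_preset,
    generate_dataset,
    init_connections,
    run_sample,
    tbr_encode,
    train_stdp,
)
from spikecube.io import ExperimentSpec

geom = build_geometry(n_neurons=125, grid_shape=(5, 5, 5), channels=("FP1", "F3", "C4", "C3"))
print("input sites:", {ch: tuple(int(x) for x in geom.coords[i]) for ch, i in geom.input_map.items()})

net = init_connections(geom, radius=2.5, conn_prob=0.15, seed=0)
print(f"{net.n_connections} connections among {net.n_neurons} neurons "
      f"({np.mean(net.signs[net.signs != 0] < 0):.0%} inhibitory)")

ds = generate_dataset(1, 4, seed=2)
spec = ExperimentSpec(name="demo", participant_indices=(0,), trial_indices=(0, 1, 2, 3),
                      window_start_s=2.0, window_len_points=512)
samples = build_samples(ds, spec)
encoded = [tbr_encode(s, channel_names=samples.channel_names) for s in samples.samples]

record = run_sample(net, encoded[0])
active = int((record.spike_count > 0).sum())
print(f"untrained cube: {int(record.spike_count.sum())} spikes from {active} neurons")

trained = train_stdp(net, encoded, rate=0.01)
delta = trained.magnitudes - net.magnitudes
print(f"STDP changed {int((delta != 0).sum())} connection magnitudes "
      f"(largest increase {delta.max():.3f}, largest decrease {delta.min():.3f})")
# Potentiated connections trace the causal pathways the stimulus repeatedly
# drove; the sparsity pattern and signs never change.
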