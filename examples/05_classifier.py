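"""The deSNN output layer: rank-order state vectors and nearest-neighbour recall.

Each cube neuron's weight in a sample's state vector is mod^rank by
first-spike order (earliest spiker 1.0, next 0.8, then 0.64, ...) plus
drift = 0.005 for every spike after its first.
"""

import numpy as np

from spikecube import CubeStateRecord, state_vector, train_classifier, classify

rec = CubeStateRecord(
    first_spike_time=np.array([12, 3, 7, -1]),
    spike_count=np.array([1, 1, 41, 0]),
    duration=100,
)
v = state_vector(rec, mod=0.8, drift=0.005)
print("first-spike times:", rec.first_spike_time.tolist())
print("state vector     :", np.round(v, 3).tolist())
# neuron 1 spiked first -> 1.0; neuron 2 second -> 0.8 plus 40 * 0.005 drift;
# neuron 0 third -> 0.64; neuron 3 never spiked -> 0.

rng = np.random.default_rng(0)
records, labels = [], []
for i in range(10):
    first = rng.permutation(50)[:8].astype(np.int64)
    counts = rng.integers(1, 6, 8).astype(np.int64)
    records.append(CubeStateRecord(first, counts, 50))
    labels.append("high" if i % 2 else "low")

model = train_classifier(records[:8], labels[:8])
print(f"model: one output neuron per training sample -> {model.n_output_neurons} neurons")
for r, truth in zip(records[8:], labels[8:]):
    print(f"held-out sample: predicted {classify(model, r)!r}, true {truth!r}")
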