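"""Carve the named experiment subsets out of a dataset and split them.

Each preset selects participants, trials, the four channels FP1/F3/C4/C3 and
a 1152-point window from 34 s; ratings are binarised at 5 into low/high.
"""

from spikecube import build_samples, experiment_preset, generate_dataset, split_train_test

ds = generate_dataset(n_participants=12, n_trials=40, seed=3)

for name in ("Exp1", "Exp2", "Exp3", "Exp4"):
    spec = experiment_preset(name, dimension="valence")
    samples = build_samples(ds, spec)
    counts = samples.class_counts()
    print(f"{name}: {len(samples)} samples of shape "
          f"{samples.samples[0].values.shape}, low/high = "
          f"{counts['low']}/{counts['high']}")

spec = experiment_preset("Exp1")
samples = build_samples(ds, spec)
split = split_train_test(samples, train_fraction=0.8, seed=1)
print(f"Exp1 80/20 split: {len(split.train_ids)} train / {len(split.test_ids)} test")
# 60 samples -> floor(0.8 * 60) = 48 train, 12 held-out test, stratified by label.
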