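"""Simulate a synthetic PRM experiment and write it to disk.

Builds the built-in demo study (2 genotypes x 2 conditions x 3 replicates,
one phosphoprotein with a 2.5-fold abundance change and a 12% -> 40% occupancy
shift, one loading-control protein), simulates scheduled-acquisition
chromatograms with 10% multiplicative noise, and writes the dataset.
"""

from prmkit import dataio, pipeline

config = pipeline.demo_config(cv=0.10)
run = pipeline.run_demo_pipeline(config, seed=1)

out = dataio.write_dataset(
    run["design"], run["truth"], run["chromatograms"], "scratch/demo_dataset",
    transitions=run["transitions"],
)
n_transitions = len(run["transitions"])
n_samples = len(run["design"].samples())
print(f"transitions targeted : {n_transitions}")
print(f"samples simulated    : {n_samples}")
print(f"chromatograms written: {len(run['chromatograms'])} -> {out}")
# Each chromatogram holds one scheduled RT window on a 0.01-min grid; the
# counts above are transitions x samples, i.e. what the instrument would
# acquire across the whole sample queue.
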