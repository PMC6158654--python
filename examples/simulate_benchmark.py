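"""Generate a synthetic antioxidant-vs-background benchmark.

Draws 20 positive sequences from a Markov chain with planted dipeptide
enrichment and 120 i.i.d. negatives (the ~6:1 imbalance of the curated
data), then verifies the enrichment by recomputing composition features.
"""

import numpy as np

from idaod import SimulationConfig, count_ggap_dipeptides, dipeptide_index, simulate_dataset

sim = simulate_dataset(SimulationConfig(
    n_positive=20, n_negative=120, length_range=(50, 300),
    bias_strength=6.0, seed=42,
))

n_pos = int(sim.labels.sum())
print(f"{len(sim.records)} sequences: {n_pos} positive, "
      f"{len(sim.records) - n_pos} negative")
print("planted dipeptides:", ["".join(p) for p in sim.biased_dipeptides])

pair = sim.biased_dipeptides[0]
idx = dipeptide_index(*pair)


def mean_freq(records):
    return np.mean([
        count_ggap_dipeptides(r, 0)[idx] / (r.length - 1) for r in records
    ])


pos = [r for r, l in zip(sim.records, sim.labels) if l == 1]
neg = [r for r, l in zip(sim.records, sim.labels) if l == 0]
print(f"mean f^0({''.join(pair)}) in positives: {mean_freq(pos):.4f}")
print(f"mean f^0({''.join(pair)}) in negatives: {mean_freq(neg):.4f}")
print("The planted pair is several-fold enriched in the positive class;")
print("this composition difference is the signal the classifier must find.")
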