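"""Discover over-represented motifs in a seeded synthetic dataset.

Plants the motif DEG into 6 of 12 otherwise-random proteins, then runs
support-pruned discovery with the exact Sig' scheme and prints the ranking.
"""

import numpy as np

from slimsig import (
    DiscoveryConfig,
    SequenceDataset,
    SWISSPROT_FREQUENCIES,
    run_discovery,
)

rng = np.random.default_rng(7)
symbols = np.array(sorted(SWISSPROT_FREQUENCIES))
probs = np.array([SWISSPROT_FREQUENCIES[s] for s in symbols])
probs /= probs.sum()

seqs = []
for i in range(12):
    residues = list(rng.choice(symbols, size=80, p=probs))
    if i < 6:  # plant DEG at a random position in half the proteins
        pos = int(rng.integers(0, 78))
        residues[pos : pos + 3] = list("DEG")
    seqs.append("".join(residues))

dataset = SequenceDataset.from_strings(seqs)
config = DiscoveryConfig(length=3, scheme="sig_prime", min_support=3)
ranked = run_discovery(dataset, config)

print(f"{'motif':>6} {'k/N':>6} {'p':>10} {'Sig_prime':>10}")
for r in ranked[:8]:
    print(f"{r.pattern:>6} {r.k:>3}/{r.N:<2} {r.p:>10.3g} {r.significance:>10.3g}")

top = ranked[0]
print(
    f"\ntop motif {top.pattern}: the probability that ANY length-3 motif in "
    f"the search\nspace reaches p <= {top.p:.2g} by chance is {top.significance:.2g}; "
    f"values well below\nthe conventional 0.01 cutoff indicate genuine enrichment."
)
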