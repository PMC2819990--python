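"""How residue-multiset grouping shrinks the exact-significance computation.

An ordered motif's occurrence probability depends only on WHICH residues it
uses, not their order, so the a^l ordered motifs collapse into C(a+l-1, l)
unordered groupings that each need scoring once.
"""

from slimsig import (
    Alphabet,
    enumerate_groupings,
    integer_partitions,
    motif_space_size,
    nonredundant_count,
)

aa = Alphabet()  # the 20 standard amino acids
print(f"{'l':>2} {'partitions':>10} {'motifs':>12} {'non-redundant':>14} {'%':>7} {'speed-up':>9}")
for l in (3, 4, 5, 6):
    total = motif_space_size(l, aa.size)
    nr = nonredundant_count(l, aa.size)
    print(
        f"{l:>2} {len(integer_partitions(l)):>10} {total:>12} {nr:>14} "
        f"{100 * nr / total:>6.2f}% {total / nr:>8.1f}x"
    )

# Small concrete case: length-3 groupings over {L, W} and how many ordered
# motifs each one stands for (multiplicities sum to 2^3 = 8).
groups = list(enumerate_groupings(Alphabet(("L", "W")), 3))
print("\nlength-3 groupings over {L, W}:")
for g in groups:
    print(f"  {str(g):6s} stands for {g.multiplicity} ordered motif(s)")
print("sum of multiplicities:", sum(g.multiplicity for g in groups))
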