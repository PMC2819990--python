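"""Score a motif in a tiny hand-checkable dataset under all four schemes.

Four proteins over the two-letter alphabet {L, W}; the rare dimer WW occurs
in one protein. Every intermediate quantity is small enough to verify with
a pocket calculator.
"""

from slimsig import (
    SequenceDataset,
    compute_frequencies,
    evaluate_all_schemes,
    parse_motif,
    prob_one_or_more,
)

dataset = SequenceDataset.from_strings(["LLLLL", "LLLLL", "LWWLL", "LLLLL"])
freqs = compute_frequencies(dataset)
print(f"global frequencies: f_L={freqs.get('L'):.2f}, f_W={freqs.get('W'):.2f}")

motif = parse_motif("WW", dataset.alphabet)
p1 = prob_one_or_more(motif, dataset.proteins[0], freqs)
print(f"P(a length-5 protein contains WW) = {p1:.4f}")

reports = evaluate_all_schemes(dataset, motif)
print(f"\nWW occurs in 1 of {dataset.N} proteins; p = {reports['sig'].p:.4f}")
for scheme, report in reports.items():
    print(f"  {report.label:7s} = {report.value:.4f}")

# Sig treats all 4 dimers over {L,W} as equally able to reach p = 0.1485,
# giving 1-(1-p)^4 = 0.474. Sig' asks each dimer individually: LL can never
# score that low (p' = 0), WL/LW only at support >= 3 (p' = 0.0949), so the
# exact chance that ANY dimer scores <= p is the smaller 0.302.
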