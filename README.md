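# slimsig

Over-representation statistics for **short linear motifs (SLiMs)** — short,
degenerate protein subsequences (3–10 residues) that recur in unrelated
proteins and mediate signalling, modification and localisation. Given a set
of unrelated proteins (for example, partners of a common binding domain),
`slimsig` answers two questions for a candidate motif:

1. **How unlikely is this motif's recurrence?** The probability that a
   motif with per-position background frequencies *f* occurs at one
   placement of a protein is
   `p_motif = ∏_i Σ_k f(m_ik)` over the motif's non-wildcard positions, and
   the probability of ≥ 1 occurrence in a protein with `n = L − span + 1`
   placements is `p₁₊ = 1 − (1 − p_motif)ⁿ`. The probability of reaching the
   observed support `k` (number of proteins containing the motif, out of
   `N`) is either the binomial tail on the **mean** success probability
   (`p_μ`, fast, assumes all proteins alike) or the **Poisson-binomial**
   tail on the per-protein probabilities (`p_v`, exact, computed by an
   O(N²) dynamic programme rather than combination enumeration).

2. **How unlikely is *any* motif scoring this well?** Discovery scans a
   motif space of size `R = a^l (x+1)^(l−1)`, so a raw p-value overstates
   significance. The heuristic correction is `Sig = 1 − (1 − p)^R`; the
   exact correction is `Sig′ = 1 − ∏_m (1 − p′_m)`, where `p′_m` is each
   motif's own probability of attaining a p-value ≤ p. Because occurrence
   probability is invariant under residue permutation, the product over all
   `a^l` ordered motifs collapses to one over `C(a+l−1, l)` residue
   multisets — a ≥ 75-fold saving for 5-mers over the 20-letter alphabet.

Combining the two choices gives four schemes: `Sig`, `Sig_v`, `Sig′`,
`Sig′_v`. The exact `Sig′_v` is calibrated (uniform top-rank significance on
null data); `Sig` is conservative and cheap, useful for first-pass screens.

## Worked example

Four proteins over the alphabet {L, W}; the dimer WW occurs in one of them
(`python examples/worked_example.py`):

```
global frequencies: f_L=0.90, f_W=0.10
P(a length-5 protein contains WW) = 0.0394

WW occurs in 1 of 4 proteins; p = 0.1485
  Sig     = 0.4744
  Sig_v   = 0.4744
  Sig'    = 0.3024
  Sig'_v  = 0.3024
```

`Sig` treats all four dimers as equally able to reach p = 0.1485, giving
`1 − (1 − 0.1485)⁴ = 0.474`. `Sig′` asks each dimer individually: LL can
never score that low (p′ = 0), WL and LW only at support ≥ 3
(p′ = 0.0949), so the exact probability that *any* dimer scores ≤ p is
`1 − (1 − 0)(1 − 0.0949)²(1 − 0.1485) = 0.302`. The `_v` variants coincide
here because all proteins share one length and composition.

Other narrative examples in `examples/`: `discover_motifs.py` (end-to-end
discovery of a planted motif), `motif_space_redundancy.py` (grouping
combinatorics), `null_uniformity.py` (calibration on null datasets).

## Command line

```sh
slimsig score    --fasta proteins.fasta --motif "WW"
slimsig discover --fasta proteins.fasta --length 3 --scheme sig_prime \
                 --cutoff 0.01 --out results.tsv
slimsig bench    --kind shuffled --n 10 --datasets 100 --length 3 \
                 --scheme sig_prime_v --seed 7 --out bench.tsv
```

`discover` writes a TSV ranking (motif, support, p-values, significance,
supporting protein ids); `bench` generates seeded null datasets and reports
how uniform each scheme's top-rank significances are.

## Scope

Exact significance is defined for fixed (non-ambiguous, unanchored) motifs;
ambiguous motifs and variable-length spacers are scored by the heuristic
`Sig` only, and scanning supports them fully. Homology clustering and
disorder/conservation masking are out of scope: pass one representative per
evolutionary cluster, or pre-masked sequences, as the input dataset. See
`docs/methods.md` for the model, its assumptions and numerical choices.
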