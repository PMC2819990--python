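# Methods

## The occurrence model

All statistics build on a three-level probability model for a fixed-span
motif `m` with `l` non-wildcard positions:

* **Per placement.** `p_motif = ∏_{i∈non-wildcard} Σ_k f(m_ik)`, the product
  over motif positions of the summed background frequencies of the residues
  admissible there. Wildcards contribute a factor 1. Frequencies come either
  from the whole dataset (`global` scope) or from each protein's own
  composition (`per-protein` scope); a residue absent from the relevant
  composition has frequency exactly 0, so motifs using it are impossible in
  that protein — the behaviour that masking workflows rely on, and the
  reason no pseudocount is added by default (an optional pseudocount
  parameter exists for callers who want smoothed frequencies).

* **Per protein.** A protein of length `L` offers `n = L − span + 1`
  placements (0 when shorter than the motif). The probability of at least
  one occurrence is `p₁₊ = 1 − (1 − p_motif)ⁿ`, treating placements as
  independent Bernoulli trials. This independence is a deliberate modelling
  choice: overlapping placements are correlated in reality, and for dense
  motifs (per-placement probability approaching 1/n) the model understates
  the true ≥1-occurrence probability by a few percent. Monte-Carlo
  validation in the test suite therefore checks the model in the sparse
  regime where the approximation error is far below sampling noise; for the
  short rare motifs the statistics are designed for, the effect is
  second-order.

* **Per dataset.** The support `k` is the number of proteins containing the
  motif at least once (occurrence multiplicity within a protein is
  irrelevant). Its null distribution is Poisson-binomial with the
  per-protein `p₁₊` values as success probabilities.

Terminal anchors pin a motif to one placement: `^` or `$` give `n = 1` when
the motif fits (`L ≥ span`), both together require `L = span`. Coordinates
in scan output are 0-based half-open.

## Support p-values: p_μ and p_v

`p_μ` approximates the support tail by a binomial at the **mean** of the
per-protein probabilities, evaluated through the regularized incomplete
beta function. `p_v` keeps the per-protein probabilities and evaluates the
Poisson-binomial upper tail exactly.

`p_v` is computed by dynamic programming over the success-count
distribution: convolving one trial at a time costs O(N²) multiplications
and handles zero-probability proteins exactly (they are skipped — they can
never contribute a success). The alternative definition as a sum over all
C(N, k) success combinations is retained only as a brute-force oracle
(guarded at N ≤ 20) that the test suite checks the DP against to 1e-12 on
hundreds of random vectors. The tail is summed from its smallest terms
downward to limit cancellation.

When all proteins share length and composition the two tails coincide
exactly; the shuffled-clone null design (below) exploits this.

## Significance: Sig and Sig′

For a motif space of size `R = a^l (x+1)^(l−1)` (`a` alphabet size, `x` the
longest allowed wildcard run between non-wildcard positions), the heuristic
`Sig = 1 − (1 − p)^R` assumes every motif is equally able to reach the
observed p-value. It is evaluated as `-expm1(R·log1p(−p))` so that p-values
near 1e-18 survive multiplication by spaces of size 10⁷. The printed-base
form of the space size uses the 20-letter alphabet; here `R` generalizes to
the dataset's own alphabet, which the two-letter worked example requires.

`Sig′` replaces the assumption with each motif's own probability `p′` of
attaining a p-value ≤ p: since the support tail is non-increasing in `k`,
the qualifying supports form `{k*, …, N}` for a minimal `k*`, and
`p′ = tail(k*)` (0 if no support qualifies). The membership test carries a
`p·(1+1e-12)+1e-300` slack so a motif's own `(k, p)` always qualifies
despite floating-point round trips. Then
`Sig′ = 1 − ∏_m (1 − p′_m)`, accumulated as `Σ log1p(−p′)` in log space.

### Grouping

`p_motif` is a commutative product, so every permutation of a motif's
residue multiset shares one `p′`. The product over `a^l` ordered motifs
therefore collapses to `C(a+l−1, l)` multisets ("groupings"), each weighted
by its multinomial multiplicity `l!/∏ count_r!`. Groupings are streamed as
lexicographic combinations-with-replacement; all combinatorics use exact
integer arithmetic. The per-grouping support tails are computed as a single
(G × N+1) matrix — vectorised binomial survival functions for the `p_μ`
route, a vectorised Poisson-binomial DP for the `p_v` route — which
discovery reuses across all candidates of a dataset, since a candidate only
changes the threshold p.

Wildcard spacing for `x > 0` is handled exactly by default: orderings with
total span `s` share tails computed at `n = L − s + 1`, and the number of
layouts per span is the composition count of the total gap into `l−1` parts
each ≤ x. A cheaper approximation (`exact_spans=False`) treats all layouts
as having the contiguous span `l`; the difference is second-order for
proteins much longer than the motif. The grouped computation is verified
against the flat product over every ordered motif (including wildcard
layouts) to 1e-10.

`Sig′` is undefined for ambiguous motifs and variable spacers: the
combinatorial space of degenerate motifs admits no comparable exact
correction, and applying the fixed-motif `Sig′` to them overstates
significance. Such motifs are scored by the conservative heuristic `Sig`
only, and rankings of ambiguous and fixed motifs should be kept separate.
Anchored motifs are likewise excluded from the exact motif space.

## Discovery

Candidates are the fixed motifs actually present in the data (all
length-`l` residue selections with wildcard gaps ≤ x drawn from sequence
windows), filtered to `min_support` (default 1). Windows containing
out-of-alphabet residues at non-wildcard offsets are skipped: characters
outside the alphabet (X, masked residues) match nothing, including
wildcards. Ranking is by ascending significance with ties broken by
ascending p then pattern, and is deterministic. A `two_pass` mode screens
with `Sig` at a loose cutoff (default 0.1) before exact rescoring, the
recommended pattern for scanning many datasets.

## Null simulation and calibration

Two synthetic null designs:

* **shuffled-clone** — each protein is an independent permutation of one
  random template (default 300 residues), so all proteins in a dataset
  share length and composition and every motif has equal per-protein
  probabilities. This isolates the motif-space correction and collapses
  `Sig_v → Sig`, `Sig′_v → Sig′`.
* **heterogeneous** — i.i.d. residues from a Swiss-Prot-like composition
  (shipped as a static table), lengths log-normal with median 350 and
  log-σ 0.5, emulating the varying lengths and compositions that bias the
  mean-probability approximation.

Neither design reproduces real proteins' residue autocorrelation,
low-complexity regions, homology or disorder structure; calibration results
on them validate the statistics under their own independence model, not
performance on biological data.

The uniformity experiment runs discovery on `n` replicate datasets (one
seeded RNG stream; a fresh template per dataset), collects each dataset's
top-ranking fixed-motif significance, and reports the RMSE of the sorted
values against uniform quantiles, a one-sample Kolmogorov–Smirnov test
against Uniform(0,1) (primary), and a Mann–Whitney test against a seeded
uniform reference sample of 1000 points (reported because the uniformity
question is sometimes posed as a two-sample comparison; the one-sample KS
is the statistically unambiguous form). At the default desk scale — 100
shuffled-clone datasets of 10 proteins, motif length 3 — `Sig′_v` passes KS
at α = 0.01 while `Sig` is strongly right-shifted (median ≈ 0.9) and
rejected; these sizes keep the full experiment under two minutes on one
core.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `frequency_scope` | `global` | background from dataset vs per protein |
| `pseudocount` | 0 | additive smoothing of frequency counts |
| `x_max` | 0 | longest wildcard run in the motif space |
| `min_support` | 1 | candidate filter; raise to 3+ for large datasets |
| `significance_cutoff` | 0.01 | reporting threshold in discovery |
| `pass1_cutoff` | 0.1 | heuristic screen threshold in two-pass mode |
| `template_length` | 300 | shuffled-clone template size (residues) |

## Degenerate inputs and tie-breaks

Empty datasets, empty sequences, duplicate ids, malformed patterns and
out-of-range probabilities raise typed errors naming the offender. A motif
absent from every protein has `k = 0` and support p-value 1 by convention.
Probabilities are clipped into [0, 1] only to absorb final floating-point
drift; all accumulation is in log space or compensated sums. Grouping
enumeration refuses spaces above 10⁷ multisets; brute-force oracles refuse
N > 20 trials or motif spaces above 2·10⁵.

## Known limitations

* Placement independence overstates `1 − p₁₊` for dense or self-overlapping
  motifs (see above).
* Exact significance for ambiguous motifs and variable spacers is not
  provided — only the conservative heuristic applies to them.
* Proteins are treated as independent trials; homology among dataset
  members must be handled upstream by passing cluster representatives.
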