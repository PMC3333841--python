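# Methods

## Model

Two parent proteins are given pre-aligned (`a1`, `a2`, length *n* over the 20
amino acids and `-`; columns gapped in both parents are rejected). A *plan*
assigns one codon to every non-gap position of each parent; gap columns emit
the gap codon `---`, so the designed DNA strings have length `3n` in the
alignment frame. Residue *i* (0-based) occupies nucleotides `[3i, 3i+3)`;
all reports are 1-based inclusive.

The design space at position *i* is the possible codon set: all non-rare
codons of the wild-type amino acid (substitution flag 0) plus all non-rare
codons of each allowed replacement (flag 1). Stop codons are never options,
since plans must encode full-length proteins. A plan using exactly *s*
flagged codons spends *s* of the substitution budget *m*.

Cross-over potential is scored four ways (all evaluated both directly on
finished plans and inside the optimizers):

1. **Common nucleotides** `o_nt`: identical non-gap nucleotides at aligned
   positions.
2. **Annealing energy** `o_nn`: sum over adjacent positions of the
   nearest-neighbor free energy `ΔG°37 = ΔH − T·ΔS/1000` of the aligned
   dinucleotide pair (T = 310.15 K). Constant initiation/symmetry terms are
   omitted — they shift every plan equally. Lookups are symmetrized under
   simultaneous reverse complement of both dinucleotides (strand symmetry of
   annealing).
3. **Run score** `o_run = Σ_R f(|R|)` over maximal runs of identical non-gap
   nucleotides. `f` must be non-decreasing with `f(0) = 0` (asserted on
   construction; required for dominance pruning). Built-ins: `f1(r) = r` for
   `r ≥ θ` else 0; `f2` ramps `9/4·(r−5)` for `6 ≤ r < 9` and equals `r`
   beyond.
4. **Library diversity variance**: a run of ≥ θ nt ending at nucleotide `e`
   fixes a breakpoint at residue `⌊e/3⌋` (kept only within `[1, n−1]`; a run
   flush against the end of the gene yields an empty fragment and no
   breakpoint). λ fragments imply 2^λ chimeras; with `m(H_i, H_j)` the number
   of positions at which two chimeras differ *by amino-acid class*, the
   objective is `Σ_{i<j} (m(H_i,H_j) − m̄)² / (2^λ(2^λ−1))`, minimized among
   plans attaining the maximum breakpoint count.

## Dynamic programs

All four optimizers scan positions left to right with an exact-substitution
dimension `s ∈ [0, m]`; each transition selects a codon pair from
`C1[i] × C2[i]`, spending `t1 + t2 ∈ {0,1,2}`. Infeasible states are ±∞, so
they can never extend into an answer. Per-`s` optima are exposed alongside
the best over `s ≤ m`; the command line reports the budget semantics by
default (`--exact-m` recovers the quota semantics, which can be worse than
spending fewer substitutions and is exempt from monotonicity).

* **cn** needs no extra state: `N[i, s]`.
* **dg** tracks the third nucleotides `(b1, b2)` of the previous codons
  (25 combinations including the gap symbol), because they stack against the
  first nucleotides of the next codons. Position 1 contributes only its two
  internal stacks.
* **run** tracks the current run length `r`, stored sparsely. A common codon
  extends the run (`r → r+3`, increment `f(r+3) − f(r)`); an unequal pair
  with common prefix `a` and suffix `z` closes the old run
  (`f(r'+a) − f(r')`), credits an interior single match when the pattern is
  mismatch–match–mismatch (`f(1)`; only observable at θ = 1 but required for
  the exact θ = 1 ≡ common-nucleotide identity), and opens a run of `z`.
  Within each cell, run length `r1` is pruned when some `r2 > r1` satisfies
  `value(r1) + f(r2) − f(r1) < value(r2)` — strictly, so every tied-optimal
  assignment survives; pruning is asserted to change nothing.
* **div** adds the breakpoint count `k` and last breakpoint position `l`.
  Closing a run with total length `r'+a ≥ θ` at position *i* registers
  breakpoint `k+1` at residue `i−1`. The carried value is the integer
  `Q = Σ δ_f²` over prefix fragments (δ = class-differences per fragment):
  for fixed `k` the library variance is affine and increasing in `Q`
  (see below), so integer comparison is exact and cheap. Gap columns admit
  only the gap codon on the gapped side, contribute 0 matches, gap-valued
  energy terms, and force `r ← 0`.

Tracebacks regenerate *all* tied-optimal assignments (deterministic
lexicographic order by position then codon pair; capped at 1000 by default).
Tie resolution is uniform across objectives: (1) objective value, (2) most
nucleotides in θ-runs, then most common nucleotides, (3) seeded sampling
weighted by codon-usage frequency, so reruns are reproducible.

## Incremental diversity algebra

Let `d(l, κ)` be the diversity variance of the library restricted to the
prefix `[1, l]` split into κ fragments. Chaining breakpoints `b_1 < … < b_k`:

    d(b_1, 1) = 0
    d(b_j, j) = (2^j − 2)/(2^j − 1) · d(b_{j−1}, j−1) + E(b_j, b_{j−1}, j)

and the full-library variance is one further step, `d(n, k+1)`. `E` depends
only on prefix mutation levels `M(x)` (cumulative class-difference counts,
O(1) after O(n) precomputation). The prefix-library reading is essential:
the recursion's own value is *not* the full-library variance until the final
step at *n* closes the last fragment. Correctness is established empirically
in exact rational arithmetic against direct enumeration of the chimera
library (hundreds of random profiles in the test suite), not re-derived.

Equivalently, writing `S = Σ δ_f` (fixed by the parents) and `Q = Σ δ_f²`,

    d = 2^(k−2)(Q + S²)/T − 2^(2k−1) S²/T²,  T = 2^(k+1) − 1,

which is the collapsed form the diversity DP uses; the chain and the closed
form are asserted equal in the tests. Minimizing variance at fixed `k` is
exactly minimizing `Q`, which is why evenly spread breakpoints win.

Mutation levels use a fixed physicochemical partition
`{AVLIMC} {FWYH} {STNQ} {KR} {DE} {GP}` (gap its own class; scheme
configurable). The difference profile is computed on the *wild-type*
parents: the incremental algebra requires prefix counts that do not depend
on the codon choices being optimized, and conservative substitutions rarely
change classes. The brute-force oracle uses the same convention.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `m` (`--mutations`) | 0 | substitution budget (at-most semantics) |
| `θ` (`--theta`) | 9 nt | run length deemed sufficient for a cross-over |
| run score | `f1` | θ-thresholded run value |
| BLOSUM62 penalty | 4 | conservative-substitution allowance |
| rare-codon cutoff | 10% | usage fraction below which codons are excluded |
| usage table | E. coli K-12 | relative synonymous codon usage |
| NN table | unified 37 °C, 1 M Na⁺ | Watson–Crick ΔH/ΔS stack parameters |
| mismatch ΔG | 0 kcal/mol | pairs absent from the NN table |
| gap ΔG | 0 kcal/mol | dinucleotides containing a gap |
| tie limit | 1000 | traceback cap |

The bundled NN table carries the 16 Watson–Crick dinucleotide entries;
mismatch stacks default to 0 kcal/mol (neither favorable nor penalized),
which keeps the energy objective driven by complementary stretches. Any TSV
with `dinuc1, dinuc2, ΔH, ΔS` (or precomputed ΔG) columns can replace it,
e.g. to supply published single-mismatch parameters.

## Synthetic data

`make_synthetic_parents(seed, n, target_identity)` draws a uniform random
protein of length *n* and mutates an exact count of positions to random
different residues, hitting the target identity up to rounding. This
emulates the *identity level* of real parent pairs (the desk-scale sweeps
use n = 200 at 40% and 15% identity, matching the diversity range of
published shuffling targets) but none of real proteins' spatial structure:
no conserved motifs, no composition bias, no indel clustering (the generator
emits gap-free alignments; gap handling is tested separately on toy
instances). Passing trend tests therefore shows the optimizers exploit
whatever freedom the identity level allows — not that any particular real
pair will yield a given run count.

`make_toy` builds exhaustively enumerable instances (n ≤ 6, option sets
downsampled to ≤ 3 codons per parent per position, optional one-sided gap
columns). The brute-force oracle enumerates codon assignments — never DP
states — and scores them with the same direct scorers used to validate
traceback output, so the reference path shares no recurrence logic with the
optimizers.

## Numerical choices

* Run scores are floats, but `f1` is integer-valued and `f2` quarter-integer
  valued, so forward/traceback equality comparisons are exact.
* Energy tracebacks recompute each candidate in the same operation order as
  the forward pass and compare within 1e-9; bundled parameters are two-decimal
  kcal/mol, so distinct sums differ by far more.
* Diversity values are exact rationals end to end (integer `Q` in the DP,
  `Fraction` conversion at the final step); the claimed 1e-9 agreement
  between chain and enumeration is in fact exact.
* Degenerate inputs: an amino acid whose codons are all rare keeps its single
  most frequent codon (logged); zero usage mass among tied codons falls back
  to a uniform draw (logged); if no θ-run is attainable the diversity
  optimizer returns the no-breakpoint plan (two-parent library, variance 0)
  with a warning; an infeasible exactly-`m` request is reported as absent
  rather than silently relaxed.

## Problem sizes

The test suite validates the DPs on 100 enumerable instances
(n ∈ [2,5], m ∈ [0,2]) and runs the budget sweeps at n = 200, m ≤ 10; the
acceptance script uses the same sizes. The diversity DP is the heaviest
engine (state includes run length, breakpoint count and position); at
n = 200, θ = 9 it is run with m ≤ 4, which already yields 13+ breakpoints at
40% identity.

## Limitations

* Two parents only; multi-parent shuffling and non-uniform cross-over
  patterns are out of scope.
* One objective at a time; no Pareto combination of objectives.
* The annealing model is the fixed-temperature NN sum — no salt correction,
  dangling ends, loops, or kinetics; it ranks plans, it does not predict
  melting curves.
* Breakpoint placement from θ-runs is a deterministic convention; real
  cross-over positions within a shared run are stochastic.
* The wild-type-profile convention for diversity means substitutions that
  change an amino acid's class are not reflected in the library variance.
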