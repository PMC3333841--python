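# shuffleplan

Codon-level design of DNA shuffling experiments between two parent proteins.

DNA shuffling recombines parent genes by random fragmentation, annealing and
reassembly; cross-overs form only where the parents share a sufficiently long
stretch of identical DNA. Because the genetic code is redundant, the engineer
is free to *choose* the codons that encode each parent — and, if a few
conservative amino-acid substitutions are acceptable, to spend those too — so
that the two genes share as much productively-placed sequence as possible.
`shuffleplan` makes those choices by polynomial-time dynamic programming,
guaranteeing a globally optimal codon assignment under each of four
objectives.

## The optimization problem

Input: a pairwise protein alignment `a1, a2` of length *n* (residues and
gaps), a substitution budget *m*, an organism codon-usage table, and a
nearest-neighbor (NN) thermodynamic parameter table. For every position *i*
a *possible codon set* `C1[i]` (`C2[i]`) holds each allowed codon paired with
a flag `t` saying whether choosing it spends a substitution — wild-type
synonymous codons carry `t = 0`, codons of conservative replacements carry
`t = 1`. By default an amino acid `b` may replace `a` when
`BLOSUM62[a][b] >= BLOSUM62[a][a] - 4`; per-position overrides (e.g. from
structural analysis) replace the matrix rule. Codons rarer than 10% of their
amino acid's usage are excluded.

The output is a pair of aligned DNA sequences `d1, d2` of length `3n`
(gap columns as `---`) optimizing one of:

* **cn** — common nucleotides: `o_nt = Σ_i 1{d1[i] = d2[i]}`, maximized;
* **dg** — annealing free energy: `o_nn = Σ_i ΔG°nn(d1[i..i+1], d2[i..i+1])`,
  the nearest-neighbor stacking approximation, minimized;
* **run** — run score: `o_run = Σ_R f(|R|)` over maximal common-nucleotide
  runs `R`, for a non-decreasing value function `f` (built-in `f1`: a run
  counts its full length once it reaches a threshold θ; `f2`: partial credit
  ramps between 6 and 9 nt), maximized;
* **div** — library diversity: a run of ≥ θ nt fixes a recombination
  breakpoint; λ fragments imply 2^λ chimeras, and the variance of pairwise
  mutation levels over that library is minimized among plans attaining the
  maximum number of θ-runs, so the library samples sequence space uniformly.

All four are solved exactly by dynamic programs over positions × spent
substitutions, with extra state where the objective is non-local (previous
third nucleotides for **dg**; current run length for **run**; breakpoint
count and position, plus an incremental variance value, for **div**).
Tied-optimal plans are enumerated by traceback; ties are resolved by most
nucleotides in θ-runs, then most common nucleotides, then seeded sampling
weighted by codon usage.

## Worked example

Generate a synthetic parent pair (60 aligned residues, ~45% identity) and
optimize runs at θ = 9 with a budget of 4 substitutions:

```sh
shuffleplan fixtures --seed 11 --n 60 --identity 0.45 --out demo.fasta
shuffleplan optimize demo.fasta --objective run --mutations 4 --theta 9 \
    --seed 0 --out demo_run
```

which prints

```
run	m=4	value=81.0	subs=4
```

i.e. the optimal plan places 81 nucleotides inside runs of ≥ 9 nt using
exactly 4 substitutions. `demo_run.json` records where they went and what the
plan scores under every objective:

```
objective_value: 81.0
substitutions: [{from: R, parent: 1, position: 37, to: K},
                {from: I, parent: 1, position: 41, to: F},
                {from: Y, parent: 2, position: 41, to: F},
                {from: A, parent: 1, position: 44, to: S}]
breakpoints: [12, 17, 30, 38, 44, 49]
scores: {common_nt: 105, dG_nn: -122.48, run_score: 81.0,
         n_runs_theta: 7, nt_in_runs_theta: 81}
```

Seven runs reach the θ = 9 threshold (see `demo_run.runs.tsv` for their
nucleotide coordinates, e.g. one of 17 nt at positions 116–132); six of them
fix usable breakpoints, so the implied chimeric library has 2^7 = 128
members. `demo_run.dna.fasta` holds the aligned designed genes and
`demo_run.dna.ungapped.fasta` the bench-ready sequences. The same
configuration and seed reproduce these files byte for byte.

`shuffleplan sweep` tabulates objective values over a substitution range,
and `shuffleplan score` re-scores any designed pair against all four
objectives.

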