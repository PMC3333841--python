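"""Direct (non-DP) evaluation of the four shuffling objectives.

Everything here scores *finished* sequence pairs; the DP engines are
validated against these scorers. The objectives are:

* common nucleotides: number of aligned positions with identical non-gap
  nucleotides;
* annealing free energy: nearest-neighbor sum (delegated to
  :mod:`shuffleplan.energetics`);
* run score: sum of f(|R|) over maximal common-nucleotide runs R, for a
  non-decreasing run value function f;
* library diversity variance: variance of pairwise mutation levels over the
  2**lambda chimeras implied by the breakpoints, where a run of at least
  theta common nucleotides fixes a breakpoint.

A run ending at nucleotide e (1-based, alignment frame) fixes a breakpoint
at residue e // 3, kept only when it falls in [1, n-1]; a threshold run
flush against the end of the sequence therefore yields none (its "fragment"
would be empty).

Mutation levels collapse amino acids into physicochemical classes so that
neutral differences do not count as diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Callable, Optional, Sequence

import numpy as np

from .alignment_io import AlignedParents
from .energetics import NNParameterTable, sequence_energy


class ObjectiveError(ValueError):
    """Invalid objective evaluation input."""


# ---------------------------------------------------------------------------
# runs

@dataclass(frozen=True)
class Run:
    """A maximal stretch of identical non-gap nucleotides at aligned
    positions; coordinates 1-based inclusive in the alignment frame."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def score_common_nt(d1: str, d2: str) -> int:
    """Number of aligned positions with identical non-gap nucleotides."""
    if len(d1) != len(d2):
        raise ObjectiveError("length mismatch")
    return sum(1 for x, y in zip(d1, d2) if x == y and x != "-")


def find_runs(d1: str, d2: str) -> list[Run]:
    """Maximal common-nucleotide runs; gap columns terminate runs."""
    if len(d1) != len(d2):
        raise ObjectiveError("length mismatch")
    runs: list[Run] = []
    start = None
    for i, (x, y) in enumerate(zip(d1, d2)):
        if x == y and x != "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append(Run(start + 1, i))
            start = None
    if start is not None:
        runs.append(Run(start + 1, len(d1)))
    return runs


@dataclass(frozen=True)
class RunScoreFunction:
    """Run value function f; must be non-decreasing with f(0) = 0.

    ``f1``: 0 below the threshold theta, the run length at or above it.
    ``f2``: 0 below 6 nt, ramps 9/4*(r-5) for 6 <= r < 9, the run length for
    r >= 9. ``custom`` takes tabulated values (clamped at the last entry).
    """

    kind: str = "f1"
    theta: int = 9
    table: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in {"f1", "f2", "custom"}:
            raise ObjectiveError(f"unknown run score kind {self.kind!r}")
        if self.kind == "f1" and self.theta < 1:
            raise ObjectiveError("theta must be >= 1")
        if self.kind == "custom":
            if not self.table or self.table[0] != 0:
                raise ObjectiveError("custom table must start with f(0) = 0")
            if any(b < a for a, b in zip(self.table, self.table[1:])):
                raise ObjectiveError("run score function must be non-decreasing")

    def __call__(self, r: int) -> float:
        if r < 0:
            raise ObjectiveError("run length must be >= 0")
        if self.kind == "f1":
            return float(r) if r >= self.theta else 0.0
        if self.kind == "f2":
            if r < 6:
                return 0.0
            if r < 9:
                return 2.25 * (r - 5)
            return float(r)
        return float(self.table[min(r, len(self.table) - 1)])


def score_runs(runs: Sequence[Run], f: RunScoreFunction) -> float:
    """o_run = sum of f over run lengths."""
    return sum(f(run.length) for run in runs)


def nt_in_runs(runs: Sequence[Run], theta: int) -> int:
    """Total nucleotides inside runs of length >= theta."""
    return sum(run.length for run in runs if run.length >= theta)


def breakpoints_from_runs(runs: Sequence[Run], theta: int, n: int) -> tuple[int, ...]:
    """Residue breakpoints fixed by runs of length >= theta (see module
    docstring for the placement convention)."""
    bps = sorted(
        {run.end // 3 for run in runs if run.length >= theta}
    )
    return tuple(b for b in bps if 1 <= b <= n - 1)


# ---------------------------------------------------------------------------
# amino-acid classes and mutation levels

#: default physicochemical grouping; the gap is its own class
DEFAULT_CLASSES = ("AVLIMC", "FWYH", "STNQ", "KR", "DE", "GP")

_SCHEMES: dict[str, tuple[str, ...]] = {
    "chemical6": DEFAULT_CLASSES,
    "identity": tuple("ACDEFGHIKLMNPQRSTVWY"),
}


@dataclass(frozen=True)
class ClassScheme:
    """Partition of the amino acids into classes; residues in the same class
    are treated as equivalent when counting mutation levels."""

    name: str
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if seen & set(g):
                raise ObjectiveError("amino acid in more than one class")
            seen |= set(g)

    def class_of(self, aa: str) -> int:
        if aa == "-":
            return -1
        for idx, g in enumerate(self.groups):
            if aa in g:
                return idx
        return 100 + ord(aa)  # unlisted residues: each its own class


def get_scheme(name: str = "chemical6") -> ClassScheme:
    try:
        return ClassScheme(name=name, groups=_SCHEMES[name])
    except KeyError:
        raise ObjectiveError(f"unknown class scheme {name!r}") from None


def mutation_level(seq_a: str, seq_b: str, classes: ClassScheme) -> int:
    """Number of positions whose residues fall in different classes."""
    if len(seq_a) != len(seq_b):
        raise ObjectiveError("length mismatch")
    return sum(
        1 for x, y in zip(seq_a, seq_b) if classes.class_of(x) != classes.class_of(y)
    )


# ---------------------------------------------------------------------------
# diversity

MAX_ENUMERABLE_FRAGMENTS = 12


@dataclass(frozen=True)
class DiversityContext:
    """Class-collapsed parent difference profile plus breakpoints.

    ``diff[i]`` is 1 when the wild-type parents differ by class at residue
    i (0-based); breakpoints are 1-based residue indices, strictly
    increasing, within [1, n-1]. lambda = len(breakpoints) + 1 fragments.
    """

    diff: tuple[int, ...]
    breakpoints: tuple[int, ...] = ()
    scheme: str = "chemical6"

    def __post_init__(self) -> None:
        n = len(self.diff)
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ObjectiveError("breakpoints must be strictly increasing")
        if self.breakpoints and not (
            1 <= self.breakpoints[0] and self.breakpoints[-1] <= n - 1
        ):
            raise ObjectiveError("breakpoints must lie in [1, n-1]")

    @classmethod
    def from_parents(
        cls,
        parents: AlignedParents,
        breakpoints: Sequence[int] = (),
        classes: Optional[ClassScheme] = None,
    ) -> "DiversityContext":
        classes = classes or get_scheme()
        diff = tuple(
            int(classes.class_of(x) != classes.class_of(y))
            for x, y in zip(parents.a1, parents.a2)
        )
        return cls(diff=diff, breakpoints=tuple(breakpoints), scheme=classes.name)

    @property
    def n(self) -> int:
        return len(self.diff)

    @property
    def n_fragments(self) -> int:
        return len(self.breakpoints) + 1

    def prefix_mutations(self) -> tuple[int, ...]:
        """Cumulative class-difference counts; entry x is m(Pa[1,x], Pb[1,x])."""
        out = [0]
        for d in self.diff:
            out.append(out[-1] + d)
        return tuple(out)

    def fragment_mutations(self) -> tuple[int, ...]:
        """Class-difference count per fragment delimited by the breakpoints."""
        pref = self.prefix_mutations()
        bounds = (0,) + self.breakpoints + (self.n,)
        return tuple(pref[b] - pref[a] for a, b in zip(bounds, bounds[1:]))


def enumerate_chimeras(ctx: DiversityContext) -> list[tuple[int, ...]]:
    """All 2**lambda fragment-choice vectors, in stable lexicographic order."""
    lam = ctx.n_fragments
    if lam > MAX_ENUMERABLE_FRAGMENTS:
        raise ObjectiveError(
            f"{lam} fragments exceed the enumerable limit; "
            "use the incremental formula (diversity_math.chain_variance)"
        )
    return list(product((0, 1), repeat=lam))


def diversity_variance_direct(ctx: DiversityContext):
    """o_div by enumeration: all 2**lambda chimeras, all pairwise mutation
    levels, variance normalized by 2**lambda * (2**lambda - 1).

    Exact (returns a Fraction; callers may cast to float)."""
    deltas = np.array(ctx.fragment_mutations(), dtype=np.int64)
    chimeras = np.array(enumerate_chimeras(ctx), dtype=np.int64)
    # mutation level between chimeras i, j: sum of deltas where choices differ
    diffs = (chimeras[:, None, :] != chimeras[None, :, :])
    m = (diffs * deltas).sum(axis=2)
    iu = np.triu_indices(len(chimeras), k=1)
    ms = m[iu]
    npairs = int(ms.size)
    s1 = int(ms.sum())
    s2 = int((ms.astype(np.int64) ** 2).sum())
    lam = ctx.n_fragments
    # sum (m - mbar)^2 = s2 - s1^2 / npairs, exactly
    dev = Fraction(s2) - Fraction(s1 * s1, npairs)
    return dev / (2**lam * (2**lam - 1))


def build_chimera(parents: AlignedParents, ctx: DiversityContext,
                  choice: tuple[int, ...]) -> str:
    """Assemble a chimera amino-acid string from parent fragments (used as an
    independent cross-check of the profile-based mutation levels)."""
    bounds = (0,) + ctx.breakpoints + (parents.n,)
    parts = []
    for frag, (a, b) in zip(choice, zip(bounds, bounds[1:])):
        src = parents.a1 if frag == 0 else parents.a2
        parts.append(src[a:b])
    return "".join(parts)


# ---------------------------------------------------------------------------
# one-stop scoring of a finished sequence pair

def score_all(
    d1: str,
    d2: str,
    parents: AlignedParents,
    nn_table: NNParameterTable,
    f: RunScoreFunction,
    theta: int,
    classes: Optional[ClassScheme] = None,
) -> dict:
    """All four objective values for a designed pair, plus run statistics."""
    runs = find_runs(d1, d2)
    bps = breakpoints_from_runs(runs, theta, parents.n)
    ctx = DiversityContext.from_parents(parents, bps, classes)
    if ctx.n_fragments <= MAX_ENUMERABLE_FRAGMENTS:
        div = float(diversity_variance_direct(ctx))
    else:
        from .diversity_math import chain_variance

        div = chain_variance(bps, ctx)
    return {
        "common_nt": score_common_nt(d1, d2),
        "dG_nn": sequence_energy(d1, d2, nn_table),
        "run_score": score_runs(runs, f),
        "diversity_variance": div,
        "n_runs_theta": sum(1 for r in runs if r.length >= theta),
        "nt_in_runs_theta": nt_in_runs(runs, theta),
        "breakpoints": list(bps),
    }
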