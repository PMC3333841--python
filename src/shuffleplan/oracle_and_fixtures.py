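"""Brute-force reference optimizer and synthetic instance generation.

The brute-force enumerator exhaustively walks every codon assignment of a
toy instance and scores each one with the direct scorers in
:mod:`shuffleplan.objectives` — it deliberately never touches the DP code,
so the two routes cannot share a bug class. Synthetic parent pairs at a
controlled amino-acid identity provide desk-scale analogs of real shuffling
targets for trend studies.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Optional

from .alignment_io import AlignedParents
from .codon_space import (
    CODON_TO_AA,
    GAP_CODON,
    STANDARD_AAS,
    CodonOption,
    CodonUsageTable,
    PossibleCodonSets,
    SubstitutionPolicy,
    build_codon_sets,
    default_usage_table,
)
from .energetics import NNParameterTable, load_nn_table
from .objectives import (
    ClassScheme,
    DiversityContext,
    RunScoreFunction,
    breakpoints_from_runs,
    diversity_variance_direct,
    find_runs,
    score_common_nt,
    score_runs,
)

MAX_ENUMERABLE = 10**7


class OracleError(ValueError):
    """Instance too large or ill-formed for exhaustive enumeration."""


@dataclass(frozen=True)
class ToyInstance:
    """A small, exhaustively enumerable optimization instance."""

    parents: AlignedParents
    sets: PossibleCodonSets
    m: int
    seed: int

    def __post_init__(self) -> None:
        total = 1
        for c1, c2 in zip(self.sets.C1, self.sets.C2):
            total *= len(c1) * len(c2)
            if total > MAX_ENUMERABLE:
                raise OracleError("instance too large to enumerate")

    @property
    def n_assignments(self) -> int:
        total = 1
        for c1, c2 in zip(self.sets.C1, self.sets.C2):
            total *= len(c1) * len(c2)
        return total


def _score(
    objective: str,
    d1: str,
    d2: str,
    parents: AlignedParents,
    params: dict,
):
    if objective == "cn":
        return score_common_nt(d1, d2)
    if objective == "dg":
        from .energetics import sequence_energy

        return sequence_energy(d1, d2, params["table"])
    if objective == "run":
        return score_runs(find_runs(d1, d2), params["f"])
    if objective == "div":
        theta = params["theta"]
        base_ctx: DiversityContext = params["ctx"]
        bps = breakpoints_from_runs(find_runs(d1, d2), theta, parents.n)
        ctx = DiversityContext(diff=base_ctx.diff, breakpoints=bps,
                               scheme=base_ctx.scheme)
        # maximize breakpoint count, then minimize variance
        return (len(bps), diversity_variance_direct(ctx))
    raise OracleError(f"unknown objective {objective!r}")


def _better(objective: str, a, b) -> bool:
    """True when score a strictly beats score b."""
    if objective == "cn" or objective == "run":
        return a > b
    if objective == "dg":
        return a < b
    if objective == "div":
        return (a[0], -a[1]) > (b[0], -b[1])
    raise OracleError(objective)


def brute_force(
    instance: ToyInstance,
    objective: str,
    params: Optional[dict] = None,
) -> dict:
    """Exhaustive optimum per exact substitution count plus best-at-most-m.

    Returns ``{"exact": {s: (optimum, [assignments])}, "at_most":
    (optimum, [assignments])}``; infeasible s values are absent. Assignments
    are tuples of (CodonOption, CodonOption) per position.
    """
    params = params or {}
    if objective == "dg" and "table" not in params:
        params["table"] = load_nn_table()
    if objective == "run" and "f" not in params:
        params["f"] = RunScoreFunction("f1", theta=params.get("theta", 9))
    if objective == "div":
        params.setdefault("theta", 6)
        params.setdefault(
            "ctx", DiversityContext.from_parents(instance.parents)
        )
    parents = instance.parents
    per_exact: dict[int, tuple] = {}
    position_pairs = [
        sorted(
            product(c1, c2),
            key=lambda p: (p[0].codon, p[1].codon),
        )
        for c1, c2 in zip(instance.sets.C1, instance.sets.C2)
    ]
    for assignment in product(*position_pairs):
        s = sum(o1.is_substitution + o2.is_substitution for o1, o2 in assignment)
        if s > instance.m:
            continue
        d1 = "".join(o1.codon for o1, _ in assignment)
        d2 = "".join(o2.codon for _, o2 in assignment)
        score = _score(objective, d1, d2, parents, params)
        if s not in per_exact:
            per_exact[s] = (score, [assignment])
        else:
            best, tied = per_exact[s]
            if _better(objective, score, best):
                per_exact[s] = (score, [assignment])
            elif score == best:
                tied.append(assignment)
    if not per_exact:
        raise OracleError("no feasible assignment")
    at_most_best = None
    at_most_tied: list = []
    for s, (score, tied) in sorted(per_exact.items()):
        if at_most_best is None or _better(objective, score, at_most_best):
            at_most_best = score
            at_most_tied = list(tied)
        elif score == at_most_best:
            at_most_tied.extend(tied)
    return {"exact": per_exact, "at_most": (at_most_best, at_most_tied)}


def make_toy(
    seed: int,
    n: int = 3,
    subs_allowed: bool = True,
    gap_rate: float = 0.0,
    m: int = 1,
    max_options: int = 3,
    usage: Optional[CodonUsageTable] = None,
) -> ToyInstance:
    """Seeded random enumerable instance.

    Parents are random amino-acid strings (optionally with one-sided gap
    columns at ``gap_rate``); codon sets are built by
    :func:`shuffleplan.codon_space.build_codon_sets` and then downsampled to
    at most ``max_options`` options per parent per position, always keeping
    at least one wild-type (flag 0) option.
    """
    if n > 6:
        raise OracleError("toy instances are capped at n = 6 for enumerability")
    rng = random.Random(seed)
    aas = STANDARD_AAS
    cols1, cols2 = [], []
    for _ in range(n):
        if gap_rate > 0 and rng.random() < gap_rate:
            if rng.random() < 0.5:
                cols1.append("-")
                cols2.append(rng.choice(aas))
            else:
                cols1.append(rng.choice(aas))
                cols2.append("-")
        else:
            # bias toward identical residues so runs are attainable
            x = rng.choice(aas)
            cols1.append(x)
            cols2.append(x if rng.random() < 0.5 else rng.choice(aas))
    parents = AlignedParents(a1="".join(cols1), a2="".join(cols2))
    policy = SubstitutionPolicy(
        budget=m, max_penalty=4 if subs_allowed else -1
    )
    sets = build_codon_sets(parents, policy, usage or default_usage_table())

    def downsample(options: tuple[CodonOption, ...]) -> tuple[CodonOption, ...]:
        if len(options) <= max_options:
            return options
        wild = [o for o in options if not o.is_substitution]
        keep = {rng.choice(wild)}
        pool = [o for o in options if o not in keep]
        rng.shuffle(pool)
        keep.update(pool[: max_options - 1])
        return tuple(sorted(keep, key=lambda o: (o.is_substitution, o.codon)))

    sets = PossibleCodonSets(
        C1=tuple(downsample(c) for c in sets.C1),
        C2=tuple(downsample(c) for c in sets.C2),
    )
    return ToyInstance(parents=parents, sets=sets, m=m, seed=seed)


def make_synthetic_parents(
    seed: int, n: int = 200, target_identity: float = 0.4
) -> AlignedParents:
    """Seeded parent pair with amino-acid identity within +/-3% of target
    (exact up to rounding of the differing-position count)."""
    if not 0 <= target_identity <= 1:
        raise OracleError("target identity must be in [0, 1]")
    rng = random.Random(seed)
    aas = STANDARD_AAS
    a1 = [rng.choice(aas) for _ in range(n)]
    a2 = list(a1)
    k = round((1 - target_identity) * n)
    for i in rng.sample(range(n), k):
        choices = [x for x in aas if x != a1[i]]
        a2[i] = rng.choice(choices)
    return AlignedParents(
        a1="".join(a1), a2="".join(a2), names=("synthA", "synthB")
    )
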