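"""Dynamic-programming engines over per-position codon choices.

All four optimizers share the same skeleton: positions i = 1..n are scanned
left to right; dimension s counts substitutions spent so far ("exactly s"
tables, with the best over s <= m exposed separately); each transition picks
one codon pair from C1[i] x C2[i], spending t1 + t2 in {0, 1, 2}
substitutions. The engines differ in the extra state needed to make the
objective decomposable:

* common nucleotides: none — N[i, s];
* annealing energy: the pair of third nucleotides of the previous codons,
  A[i, s, b1, b2], because they stack against the first nucleotides of the
  next codons;
* run score: the current run length r, R[i, s, r], stored sparsely with
  dominated run lengths pruned (r1 is dominated by r2 > r1 when
  value(r1) + f(r2) - f(r1) < value(r2); strict, so tied-optimal plans
  survive pruning);
* diversity: run length plus the count k and position l of breakpoints
  registered so far, with the chain value of the incremental variance
  algebra carried along in exact rational arithmetic.

A run is *registered* as a breakpoint when it is closed by a non-matching
codon pair at position i with total length r' + a >= theta; the breakpoint
falls at residue i - 1. Infeasible states are -inf (maximization) or +inf
(minimization) rather than 0, so they can never be extended into an answer.

Traceback enumerates every tied-optimal codon assignment in deterministic
lexicographic order (by position, then codon pair), optionally capped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .codon_space import GAP_CODON, CodonOption, CodonUsageTable, PossibleCodonSets
from .diversity_math import variance_from_fragment_squares
from .energetics import NNParameterTable
from .objectives import (
    ClassScheme,
    DiversityContext,
    Run,
    RunScoreFunction,
    breakpoints_from_runs,
    find_runs,
    nt_in_runs,
    score_common_nt,
)

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")
POS_INF = float("inf")


class OptimizationError(ValueError):
    """Infeasible or ill-posed optimization request."""


# ---------------------------------------------------------------------------
# codon-pair primitives

def codon_match(c1, c2) -> int:
    """g(c1, c2): number (0-3) of common nucleotides of a codon pair; any
    gap codon yields 0."""
    s1 = c1.codon if isinstance(c1, CodonOption) else c1
    s2 = c2.codon if isinstance(c2, CodonOption) else c2
    if s1 == GAP_CODON or s2 == GAP_CODON:
        return 0
    return sum(1 for x, y in zip(s1, s2) if x == y)


def prefix_suffix(c1, c2) -> tuple[int, int]:
    """Longest common prefix and suffix lengths a(c1, c2), z(c1, c2); a gap
    codon gives (0, 0)."""
    s1 = c1.codon if isinstance(c1, CodonOption) else c1
    s2 = c2.codon if isinstance(c2, CodonOption) else c2
    if s1 == GAP_CODON or s2 == GAP_CODON:
        return (0, 0)
    a = 0
    while a < 3 and s1[a] == s2[a]:
        a += 1
    z = 0
    while z < 3 and s1[2 - z] == s2[2 - z]:
        z += 1
    return (a, z)


# ---------------------------------------------------------------------------
# plans

@dataclass
class ShufflingPlan:
    """A completed codon assignment for both parents."""

    d1: str
    d2: str
    assignment: tuple[tuple[CodonOption, CodonOption], ...]
    substitutions: list[tuple[int, int, str, str]]  # (parent, 1-based pos, from, to)
    names: tuple[str, str] = ("parent1", "parent2")
    runs: list[Run] = field(default_factory=list)
    breakpoints: tuple[int, ...] = ()
    scores: dict = field(default_factory=dict)
    objective: str = ""
    objective_value: Optional[float] = None

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)

    def summary(self) -> dict:
        return {
            "objective": self.objective,
            "objective_value": self.objective_value,
            "parents": list(self.names),
            "d1": self.d1,
            "d2": self.d2,
            "substitutions": [
                {"parent": p, "position": pos, "from": a, "to": b}
                for p, pos, a, b in self.substitutions
            ],
            "breakpoints": list(self.breakpoints),
            "runs": [
                {"start": r.start, "end": r.end, "length": r.length}
                for r in self.runs
            ],
            "scores": self.scores,
        }


def _wildtype_aa(options: Sequence[CodonOption]) -> str:
    for o in options:
        if not o.is_substitution:
            return o.encoded_aa
    raise OptimizationError("position has no wild-type codon option")


def build_plan(
    sets: PossibleCodonSets,
    assignment: Sequence[tuple[CodonOption, CodonOption]],
    names: tuple[str, str] = ("parent1", "parent2"),
) -> ShufflingPlan:
    """Assemble a plan (DNA strings + substitution bookkeeping) from one
    codon assignment."""
    d1 = "".join(o1.codon for o1, _ in assignment)
    d2 = "".join(o2.codon for _, o2 in assignment)
    subs: list[tuple[int, int, str, str]] = []
    for i, (o1, o2) in enumerate(assignment):
        if o1.is_substitution:
            subs.append((1, i + 1, _wildtype_aa(sets.C1[i]), o1.encoded_aa))
        if o2.is_substitution:
            subs.append((2, i + 1, _wildtype_aa(sets.C2[i]), o2.encoded_aa))
    plan = ShufflingPlan(d1=d1, d2=d2, assignment=tuple(assignment),
                         substitutions=subs, names=names)
    plan.runs = find_runs(d1, d2)
    return plan


# ---------------------------------------------------------------------------
# DP results

@dataclass
class DPResult:
    """Filled tables for one objective plus everything traceback needs.

    ``optimum_exact(s)`` is the optimum using exactly s substitutions (None
    when infeasible); ``optimum(m)`` the best over s <= m together with the
    set of s values attaining it.
    """

    objective: str
    sets: PossibleCodonSets
    m: int
    maximize: bool
    tables: list  # tables[i][s] -> per-objective cell structure
    pairs: list  # pairs[i]: sorted per-position codon-pair records
    params: dict = field(default_factory=dict)
    cells_filled: int = 0
    states_pruned: int = 0

    @property
    def n(self) -> int:
        return self.sets.n

    def optimum_exact(self, s: int):
        raise NotImplementedError

    def optimum(self, m: Optional[int] = None):
        """(best value, tuple of s attaining it) over s <= m."""
        m = self.m if m is None else m
        vals = [(s, self.optimum_exact(s)) for s in range(m + 1)]
        feas = [(s, v) for s, v in vals if v is not None]
        if not feas:
            raise OptimizationError("no feasible assignment within budget")
        if self.maximize:
            best = max(v for _, v in feas)
        else:
            best = min(v for _, v in feas)
        return best, tuple(s for s, v in feas if v == best)


def _pair_records(sets: PossibleCodonSets) -> list[list[dict]]:
    """Per position, deterministic sorted codon-pair records with shared
    precomputed fields."""
    out = []
    for i in range(sets.n):
        recs = []
        for o1 in sets.C1[i]:
            for o2 in sets.C2[i]:
                a, z = prefix_suffix(o1, o2)
                equal = o1.codon == o2.codon and o1.codon != GAP_CODON
                gap = o1.codon == GAP_CODON or o2.codon == GAP_CODON
                mid = int(
                    not equal
                    and not gap
                    and a == 0
                    and z == 0
                    and o1.codon[1] == o2.codon[1]
                )
                recs.append(
                    {
                        "o1": o1,
                        "o2": o2,
                        "t": o1.is_substitution + o2.is_substitution,
                        "g": codon_match(o1, o2),
                        "a": a,
                        "z": z,
                        "equal": equal,
                        "mid": mid,
                    }
                )
        recs.sort(key=lambda r: (r["o1"].codon, r["o2"].codon))
        out.append(recs)
    return out


# ---------------------------------------------------------------------------
# common nucleotides

@dataclass
class CommonDPResult(DPResult):
    def optimum_exact(self, s: int):
        if s > self.m:
            return None
        v = self.tables[self.n][s]
        return None if v == NEG_INF else int(v)


def optimize_common(sets: PossibleCodonSets, m: int) -> CommonDPResult:
    """Maximize the number of common nucleotides (N[i, s] table)."""
    if m < 0:
        raise OptimizationError("budget must be >= 0")
    n = sets.n
    pairs = _pair_records(sets)
    N = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    N[0][0] = 0.0
    cells = 0
    for i in range(1, n + 1):
        for s in range(m + 1):
            best = NEG_INF
            for rec in pairs[i - 1]:
                sp = s - rec["t"]
                if sp < 0 or N[i - 1][sp] == NEG_INF:
                    continue
                cand = N[i - 1][sp] + rec["g"]
                if cand > best:
                    best = cand
            N[i][s] = best
            cells += 1
    return CommonDPResult(
        objective="cn", sets=sets, m=m, maximize=True,
        tables=N, pairs=pairs, cells_filled=cells,
    )


def _traceback_common(result: CommonDPResult, s: int) -> Iterator[tuple]:
    N = result.tables

    def rec(i: int, s: int):
        if i == 0:
            yield ()
            return
        target = N[i][s]
        for r in result.pairs[i - 1]:
            sp = s - r["t"]
            if sp < 0 or N[i - 1][sp] == NEG_INF:
                continue
            if N[i - 1][sp] + r["g"] == target:
                for prefix in rec(i - 1, sp):
                    yield prefix + ((r["o1"], r["o2"]),)

    # lexicographic by position requires choosing position 1 first; build
    # from the left by reversing the recursion order
    for assignment in _leftmost_order(rec, result.n, s):
        yield assignment


def _leftmost_order(rec, n: int, s: int):
    """Yield assignments from a right-to-left recursion in an order that is
    deterministic (depth-first over sorted pair choices at each suffix)."""
    yield from rec(n, s)


# ---------------------------------------------------------------------------
# annealing energy

def _codon_chars(o: CodonOption) -> str:
    return o.codon  # '---' for gaps; energy lookups treat '-' as gap


@dataclass
class EnergyDPResult(DPResult):
    def optimum_exact(self, s: int):
        if s > self.m:
            return None
        cell = self.tables[self.n][s]
        if not cell:
            return None
        return min(cell.values())


def optimize_energy(
    sets: PossibleCodonSets, m: int, table: NNParameterTable
) -> EnergyDPResult:
    """Minimize the nearest-neighbor annealing sum (A[i, s, b1, b2] table).

    Position 1 contributes only its two internal stacks; every later
    position adds the bridging stack against the previous third nucleotides
    plus its two internal stacks.
    """
    if m < 0:
        raise OptimizationError("budget must be >= 0")
    n = sets.n
    pairs = _pair_records(sets)
    for i in range(n):
        for rec in pairs[i]:
            c1, c2 = _codon_chars(rec["o1"]), _codon_chars(rec["o2"])
            rec["internal"] = table.lookup(c1[0:2], c2[0:2]) + table.lookup(
                c1[1:3], c2[1:3]
            )
    # tables[i][s]: dict (b1, b2) -> best value
    A: list[list[dict]] = [[{} for _ in range(m + 1)] for _ in range(n + 1)]
    A[0][0][(None, None)] = 0.0
    cells = 0
    for i in range(1, n + 1):
        for s in range(m + 1):
            cell: dict = {}
            for rec in pairs[i - 1]:
                sp = s - rec["t"]
                if sp < 0:
                    continue
                prev = A[i - 1][sp]
                if not prev:
                    continue
                c1, c2 = _codon_chars(rec["o1"]), _codon_chars(rec["o2"])
                key = (c1[2], c2[2])
                for (b1, b2), v in prev.items():
                    if b1 is None:
                        cand = v + rec["internal"]
                    else:
                        cand = (
                            v
                            + table.lookup(b1 + c1[0], b2 + c2[0])
                            + rec["internal"]
                        )
                    if key not in cell or cand < cell[key]:
                        cell[key] = cand
            A[i][s] = cell
            cells += len(cell)
    return EnergyDPResult(
        objective="dg", sets=sets, m=m, maximize=False,
        tables=A, pairs=pairs, params={"table": table}, cells_filled=cells,
    )


def _traceback_energy(result: EnergyDPResult, s: int) -> Iterator[tuple]:
    A = result.tables
    table: NNParameterTable = result.params["table"]
    opt = result.optimum_exact(s)

    def rec(i: int, s: int, b1, b2, target: float):
        if i == 0:
            if s == 0 and b1 is None:
                yield ()
            return
        for r in result.pairs[i - 1]:
            c1, c2 = r["o1"].codon, r["o2"].codon
            if (c1[2], c2[2]) != (b1, b2):
                continue
            sp = s - r["t"]
            if sp < 0:
                continue
            for (pb1, pb2), v in sorted(
                A[i - 1][sp].items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))
            ):
                if pb1 is None:
                    cand = v + r["internal"]
                else:
                    cand = v + table.lookup(pb1 + c1[0], pb2 + c2[0]) + r["internal"]
                if math.isclose(cand, target, rel_tol=0, abs_tol=1e-9):
                    for prefix in rec(i - 1, sp, pb1, pb2, v):
                        yield prefix + ((r["o1"], r["o2"]),)

    cell = A[result.n][s]
    for (b1, b2), v in sorted(cell.items()):
        if math.isclose(v, opt, rel_tol=0, abs_tol=1e-9):
            yield from rec(result.n, s, b1, b2, v)


# ---------------------------------------------------------------------------
# run score

@dataclass
class RunDPResult(DPResult):
    def optimum_exact(self, s: int):
        if s > self.m:
            return None
        cell = self.tables[self.n][s]
        if not cell:
            return None
        return max(cell.values())


def optimize_runs(
    sets: PossibleCodonSets,
    m: int,
    f: RunScoreFunction,
    prune: bool = True,
) -> RunDPResult:
    """Maximize o_run = sum f(|R|) (R[i, s, r] table, sparse over r).

    Case 1 (equal non-gap codons) extends the run: r -> r + 3 with increment
    f(r + 3) - f(r). Case 2 (unequal pair, common prefix a / suffix z)
    closes the old run, credits an interior single match when the pattern is
    mismatch-match-mismatch, and opens a new run of length z:
    increment f(r' + a) - f(r') + f(mid) + f(z), new r = z.
    """
    if m < 0:
        raise OptimizationError("budget must be >= 0")
    n = sets.n
    pairs = _pair_records(sets)
    R: list[list[dict]] = [[{} for _ in range(m + 1)] for _ in range(n + 1)]
    R[0][0] = {0: 0.0}
    cells = 0
    pruned = 0
    for i in range(1, n + 1):
        for s in range(m + 1):
            cell: dict = {}
            for rec in pairs[i - 1]:
                sp = s - rec["t"]
                if sp < 0:
                    continue
                prev = R[i - 1][sp]
                if rec["equal"]:
                    for rp, v in prev.items():
                        r = rp + 3
                        cand = v + f(r) - f(rp)
                        if r not in cell or cand > cell[r]:
                            cell[r] = cand
                else:
                    a, z, mid = rec["a"], rec["z"], rec["mid"]
                    bonus = f(mid) + f(z)
                    for rp, v in prev.items():
                        cand = v + f(rp + a) - f(rp) + bonus
                        if z not in cell or cand > cell[z]:
                            cell[z] = cand
            if prune and len(cell) > 1:
                kept = {}
                best_tail = NEG_INF
                for r in sorted(cell, reverse=True):
                    margin = cell[r] - f(r)
                    if margin >= best_tail:
                        kept[r] = cell[r]
                    else:
                        pruned += 1
                    if margin > best_tail:
                        best_tail = margin
                cell = kept
            R[i][s] = cell
            cells += len(cell)
    return RunDPResult(
        objective="run", sets=sets, m=m, maximize=True,
        tables=R, pairs=pairs, params={"f": f},
        cells_filled=cells, states_pruned=pruned,
    )


def _traceback_runs(result: RunDPResult, s: int) -> Iterator[tuple]:
    R = result.tables
    f: RunScoreFunction = result.params["f"]
    opt = result.optimum_exact(s)

    def rec(i: int, s: int, r: int, target: float):
        if i == 0:
            if s == 0 and r == 0:
                yield ()
            return
        for p in result.pairs[i - 1]:
            sp = s - p["t"]
            if sp < 0:
                continue
            prev = R[i - 1][sp]
            if p["equal"]:
                rp = r - 3
                if rp < 0 or rp not in prev:
                    continue
                if prev[rp] + f(r) - f(rp) == target:
                    for prefix in rec(i - 1, sp, rp, prev[rp]):
                        yield prefix + ((p["o1"], p["o2"]),)
            else:
                if p["z"] != r:
                    continue
                bonus = f(p["mid"]) + f(p["z"])
                for rp in sorted(prev):
                    if prev[rp] + f(rp + p["a"]) - f(rp) + bonus == target:
                        for prefix in rec(i - 1, sp, rp, prev[rp]):
                            yield prefix + ((p["o1"], p["o2"]),)

    cell = R[result.n][s]
    for r in sorted(cell):
        if cell[r] == opt:
            yield from rec(result.n, s, r, opt)


# ---------------------------------------------------------------------------
# diversity

@dataclass
class DiversityDPResult(DPResult):
    def optimum_exact(self, s: int):
        """(k, variance) pair: maximal breakpoint count, then minimal
        full-library variance; None when infeasible."""
        if s > self.m:
            return None
        finals = self._final_values(s)
        if not finals:
            return None
        kmax = max(k for (k, _) in finals)
        vmin = min(v for (k, v) in finals if k == kmax)
        return (kmax, vmin)

    def _final_values(self, s: int):
        """(k, exact variance) per terminal state: close the prefix with the
        final fragment [l+1, n] and apply the closed form."""
        prefix = self.params["prefix"]
        s_total = prefix[-1]
        cell = self.tables[self.n][s]
        out = []
        for (r, l, k), q in cell.items():
            q_full = q + (s_total - prefix[l]) ** 2
            out.append((k, variance_from_fragment_squares(q_full, s_total, k)))
        return out

    def optimum(self, m: Optional[int] = None):
        m = self.m if m is None else m
        feas = [(s, self.optimum_exact(s)) for s in range(m + 1)]
        feas = [(s, v) for s, v in feas if v is not None]
        if not feas:
            raise OptimizationError("no feasible assignment within budget")
        best = max(((k, -v) for _, (k, v) in feas))
        best = (best[0], -best[1])
        attain = tuple(s for s, v in feas if v == best)
        return best, attain


def optimize_diversity(
    sets: PossibleCodonSets,
    m: int,
    theta: int,
    ctx: DiversityContext,
) -> DiversityDPResult:
    """Minimize library diversity variance among assignments attaining the
    maximum number of theta-runs (D[i, s, r, l, k] table, sparse).

    For fixed breakpoint count k the variance is affine and increasing in
    Q = sum of squared per-fragment mutation counts, so the state value is
    the integer Q over the prefix fragments [1, b_1], ..., [b_{k-1}+1, b_k]
    (exact arithmetic, cheap ties). Closing a run of total length
    r' + a >= theta at position i registers breakpoint k+1 at residue i-1,
    adding (M(i-1) - M(l))^2 to Q. The conversion to the variance — the
    incremental chain collapsed to closed form — happens once per terminal
    state.
    """
    if m < 0:
        raise OptimizationError("budget must be >= 0")
    if theta < 2:
        raise OptimizationError("diversity optimization requires theta >= 2")
    n = sets.n
    if ctx.n != n:
        raise OptimizationError("context length mismatch")
    prefix = ctx.prefix_mutations()
    pairs = _pair_records(sets)
    D: list[list[dict]] = [[{} for _ in range(m + 1)] for _ in range(n + 1)]
    D[0][0] = {(0, 0, 0): 0}
    cells = 0
    for i in range(1, n + 1):
        for s in range(m + 1):
            cell: dict = {}
            for rec in pairs[i - 1]:
                sp = s - rec["t"]
                if sp < 0:
                    continue
                prev = D[i - 1][sp]
                if rec["equal"]:
                    for (rp, l, k), q in prev.items():
                        key = (rp + 3, l, k)
                        if key not in cell or q < cell[key]:
                            cell[key] = q
                else:
                    a, z = rec["a"], rec["z"]
                    for (rp, l, k), q in prev.items():
                        if rp + a >= theta:
                            lnew = i - 1
                            qnew = q + (prefix[lnew] - prefix[l]) ** 2
                            key = (z, lnew, k + 1)
                        else:
                            key = (z, l, k)
                            qnew = q
                        if key not in cell or qnew < cell[key]:
                            cell[key] = qnew
            D[i][s] = cell
            cells += len(cell)
    return DiversityDPResult(
        objective="div", sets=sets, m=m, maximize=True,
        tables=D, pairs=pairs,
        params={"ctx": ctx, "prefix": prefix, "theta": theta},
        cells_filled=cells,
    )


def _traceback_diversity(result: DiversityDPResult, s: int) -> Iterator[tuple]:
    D = result.tables
    prefix = result.params["prefix"]
    theta: int = result.params["theta"]
    opt = result.optimum_exact(s)
    if opt is None:
        return
    kmax, vfinal = opt
    s_total = prefix[-1]

    def rec(i: int, s: int, r: int, l: int, k: int, q: int):
        if i == 0:
            if s == 0 and (r, l, k) == (0, 0, 0):
                yield ()
            return
        for p in result.pairs[i - 1]:
            sp = s - p["t"]
            if sp < 0:
                continue
            prev = D[i - 1][sp]
            if p["equal"]:
                key = (r - 3, l, k)
                if r >= 3 and key in prev and prev[key] == q:
                    for pre in rec(i - 1, sp, *key, q):
                        yield pre + ((p["o1"], p["o2"]),)
            else:
                if p["z"] != r:
                    continue
                a = p["a"]
                if l == i - 1 and k >= 1:
                    # registered transition: this step closed a theta-run
                    for (rp, lp, kp), pq in sorted(prev.items()):
                        if kp != k - 1 or rp + a < theta:
                            continue
                        if pq + (prefix[l] - prefix[lp]) ** 2 == q:
                            for pre in rec(i - 1, sp, rp, lp, kp, pq):
                                yield pre + ((p["o1"], p["o2"]),)
                else:
                    # unregistered transition: no theta-run closed here
                    for (rp, lp, kp), pq in sorted(prev.items()):
                        if (lp, kp) != (l, k) or rp + a >= theta or pq != q:
                            continue
                        for pre in rec(i - 1, sp, rp, lp, kp, pq):
                            yield pre + ((p["o1"], p["o2"]),)

    cell = D[result.n][s]
    for (r, l, k), q in sorted(cell.items()):
        if k != kmax:
            continue
        q_full = q + (s_total - prefix[l]) ** 2
        if variance_from_fragment_squares(q_full, s_total, k) == vfinal:
            yield from rec(result.n, s, r, l, k, q)


# ---------------------------------------------------------------------------
# shared traceback front end

def traceback(
    result: DPResult,
    limit: int = 1000,
    mode: str = "capped",
    s: Optional[int] = None,
    at_most: bool = True,
    names: tuple[str, str] = ("parent1", "parent2"),
) -> list[ShufflingPlan]:
    """Regenerate tied-optimal codon assignments as plans.

    With ``s`` given, traces assignments using exactly s substitutions; else
    all s <= m attaining the best-over-budget optimum (``at_most``) or the
    designated s = m optimum. ``mode='capped'`` stops after ``limit`` plans.
    """
    if mode not in {"all", "capped"}:
        raise OptimizationError(f"unknown traceback mode {mode!r}")
    if limit < 1:
        raise OptimizationError("limit must be >= 1")
    gens = {
        "cn": _traceback_common,
        "dg": _traceback_energy,
        "run": _traceback_runs,
        "div": _traceback_diversity,
    }
    gen = gens[result.objective]
    if s is not None:
        s_values: tuple[int, ...] = (s,)
        if result.optimum_exact(s) is None:
            raise OptimizationError(f"no assignment with exactly {s} substitutions")
    elif at_most:
        _, s_values = result.optimum()
    else:
        if result.optimum_exact(result.m) is None:
            raise OptimizationError(
                f"no assignment with exactly {result.m} substitutions"
            )
        s_values = (result.m,)
    plans: list[ShufflingPlan] = []
    seen: set = set()
    for sv in s_values:
        for assignment in gen(result, sv):
            key = tuple((o1.codon, o2.codon) for o1, o2 in assignment)
            if key in seen:
                continue
            seen.add(key)
            plans.append(build_plan(result.sets, assignment, names))
            if mode == "capped" and len(plans) >= limit:
                logger.info("traceback capped at %d tied plans", limit)
                return plans
    return plans


def select_among_ties(
    plans: Sequence[ShufflingPlan],
    theta: int,
    usage: Optional[CodonUsageTable] = None,
    rng=None,
) -> ShufflingPlan:
    """Pick one plan from a tied-optimal set.

    Order: (1) most nucleotides in runs >= theta, (2) most common
    nucleotides, (3) usage-weighted seeded sampling (plan weight is the
    product of the usage fractions of its codons).
    """
    if not plans:
        raise OptimizationError("no plans to select from")
    if len(plans) == 1:
        return plans[0]
    keyed = [
        (nt_in_runs(p.runs, theta), score_common_nt(p.d1, p.d2), p) for p in plans
    ]
    best = max((k1, k2) for k1, k2, _ in keyed)
    tied = [p for k1, k2, p in keyed if (k1, k2) == best]
    if len(tied) == 1 or usage is None or rng is None:
        return tied[0]
    weights = []
    for p in tied:
        w = 1.0
        for o1, o2 in p.assignment:
            if o1.codon != GAP_CODON:
                w *= max(usage.of(o1.codon), 1e-12)
            if o2.codon != GAP_CODON:
                w *= max(usage.of(o2.codon), 1e-12)
        weights.append(w)
    total = sum(weights)
    x = rng.random() * total
    acc = 0.0
    for p, w in zip(tied, weights):
        acc += w
        if x < acc:
            return p
    return tied[-1]
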