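import random

import pytest

from shuffleplan.alignment_io import AlignedParents
from shuffleplan.codon_space import SubstitutionPolicy, build_codon_sets
from shuffleplan.dp_optimizers import (
    OptimizationError,
    codon_match,
    optimize_common,
    optimize_diversity,
    optimize_energy,
    optimize_runs,
    prefix_suffix,
    select_among_ties,
    traceback,
)
from shuffleplan.energetics import NNParameterTable, sequence_energy
from shuffleplan.objectives import (
    DiversityContext,
    RunScoreFunction,
    find_runs,
    score_common_nt,
    score_runs,
)
from shuffleplan.oracle_and_fixtures import brute_force, make_toy


@pytest.mark.parametrize(
    "c1,c2,expected",
    [("ATG", "ATG", 3), ("TTT", "TTC", 2), ("GCA", "CGT", 0), ("---", "ATG", 0)],
)
def test_codon_match(c1, c2, expected):
    assert codon_match(c1, c2) == expected


@pytest.mark.parametrize(
    "c1,c2,expected",
    [
        ("ATG", "ATC", (2, 0)),
        ("TTG", "GGG", (0, 1)),
        ("AAA", "AAA", (3, 3)),
        ("ATA", "GTG", (0, 0)),
        ("---", "ATG", (0, 0)),
    ],
)
def test_prefix_suffix(c1, c2, expected):
    assert prefix_suffix(c1, c2) == expected


def _sets(a1, a2, m=0, penalty=4):
    parents = AlignedParents(a1, a2)
    return parents, build_codon_sets(
        parents, SubstitutionPolicy(budget=m, max_penalty=penalty)
    )


def test_common_identical_residue_scores_three():
    _, sets = _sets("F", "F")
    result = optimize_common(sets, 0)
    assert result.optimum_exact(0) == 3


def test_common_f_vs_l_scores_two():
    # best F/L codon pair shares 2 nucleotides (e.g. TTT/TTG)
    _, sets = _sets("F", "L")
    assert optimize_common(sets, 0).optimum_exact(0) == 2


def test_infeasible_exact_budget_reported_absent():
    _, sets = _sets("M", "M", m=2, penalty=-1)  # no substitutions possible
    result = optimize_common(sets, 2)
    assert result.optimum_exact(0) == 3
    assert result.optimum_exact(2) is None
    with pytest.raises(OptimizationError):
        traceback(result, at_most=False)


def test_energy_identical_single_codon(nn_table):
    # one position, identical parents: optimum is the best codon's two
    # internal stacks
    _, sets = _sets("K", "K")
    result = optimize_energy(sets, 0, nn_table)
    best = min(
        nn_table.lookup(c[0:2], c[0:2]) + nn_table.lookup(c[1:3], c[1:3])
        for c in ("AAA", "AAG")
    )
    assert result.optimum_exact(0) == pytest.approx(best)


def test_energy_all_zero_table_scores_zero():
    from shuffleplan.energetics import WATSON_CRICK_DINUCS, _canonical

    table = NNParameterTable(
        entries={_canonical(d, d): 0.0 for d in WATSON_CRICK_DINUCS}
    )
    _, sets = _sets("MKF", "MLF", m=1)
    result = optimize_energy(sets, 1, table)
    assert result.optimum_exact(0) == 0.0
    assert result.optimum_exact(1) == 0.0


def test_runs_ff_ll_reaches_theta_four():
    # e.g. d1 = TTTTTT vs d2 = CTTTTA: one run of 4 straddling the boundary
    _, sets = _sets("FF", "LL")
    f = RunScoreFunction("f1", theta=4)
    result = optimize_runs(sets, 0, f)
    oracle = brute_force(_toy_from_sets(sets, 0), "run", {"f": f})
    assert result.optimum_exact(0) == oracle["exact"][0][0] == 4.0


def _toy_from_sets(sets, m):
    from shuffleplan.oracle_and_fixtures import ToyInstance

    # reconstruct parent strings from the wild-type options
    a1 = "".join(
        next(o.encoded_aa for o in c if not o.is_substitution) for c in sets.C1
    )
    a2 = "".join(
        next(o.encoded_aa for o in c if not o.is_substitution) for c in sets.C2
    )
    return ToyInstance(
        parents=AlignedParents(a1, a2), sets=sets, m=m, seed=0
    )


def test_traceback_enumerates_exact_tie_set():
    _, sets = _sets("F", "F")
    plans = traceback(optimize_common(sets, 0), mode="all")
    assert {(p.d1, p.d2) for p in plans} == {("TTT", "TTT"), ("TTC", "TTC")}


def test_traceback_cap_respected():
    _, sets = _sets("FFF", "FFF")
    plans = traceback(optimize_common(sets, 0), mode="capped", limit=3)
    assert len(plans) == 3


def test_traceback_plans_satisfy_invariants(nn_table):
    inst = make_toy(3, n=4, m=2, gap_rate=0.3)
    ctx = DiversityContext.from_parents(inst.parents)
    f = RunScoreFunction("f1", theta=4)
    for result in [
        optimize_common(inst.sets, inst.m),
        optimize_energy(inst.sets, inst.m, nn_table),
        optimize_runs(inst.sets, inst.m, f),
        optimize_diversity(inst.sets, inst.m, 4, ctx),
    ]:
        opt, s_values = result.optimum()
        for plan in traceback(result, limit=50):
            assert plan.runs == find_runs(plan.d1, plan.d2)
            assert plan.n_substitutions in s_values
            if result.objective == "cn":
                assert score_common_nt(plan.d1, plan.d2) == opt
            elif result.objective == "dg":
                assert sequence_energy(plan.d1, plan.d2, nn_table) == pytest.approx(opt)
            elif result.objective == "run":
                assert score_runs(plan.runs, f) == opt


def test_budget_monotonicity_on_toys(nn_table):
    f = RunScoreFunction("f1", theta=4)
    for seed in range(6):
        inst = make_toy(seed + 200, n=3, m=2)
        ctx = DiversityContext.from_parents(inst.parents)
        rc = optimize_common(inst.sets, 2)
        re_ = optimize_energy(inst.sets, 2, nn_table)
        rr = optimize_runs(inst.sets, 2, f)
        rd = optimize_diversity(inst.sets, 2, 4, ctx)
        for m in (1, 2):
            assert rc.optimum(m)[0] >= rc.optimum(m - 1)[0]
            assert re_.optimum(m)[0] <= re_.optimum(m - 1)[0]
            assert rr.optimum(m)[0] >= rr.optimum(m - 1)[0]
            k1, v1 = rd.optimum(m)[0]
            k0, v0 = rd.optimum(m - 1)[0]
            assert (k1, -v1) >= (k0, -v0)


def test_gap_column_forces_run_break():
    parents = AlignedParents("M-M", "MKM")
    sets = build_codon_sets(parents, SubstitutionPolicy())
    f = RunScoreFunction("f1", theta=1)
    result = optimize_runs(sets, 0, f)
    plans = traceback(result, mode="all")
    for plan in plans:
        assert plan.d1[3:6] == "---"
        assert all(run.length <= 3 for run in plan.runs)
    assert result.optimum_exact(0) == 6.0  # two ATG codons match fully


def test_diversity_identical_parents_zero_variance():
    _, sets = _sets("MKM", "MKM")
    ctx = DiversityContext.from_parents(AlignedParents("MKM", "MKM"))
    result = optimize_diversity(sets, 0, theta=4, ctx=ctx)
    k, v = result.optimum_exact(0)
    assert v == 0


def test_diversity_no_theta_run_falls_back_to_no_breakpoints():
    # parents too different for any run of >= 6 nt within a single codon pair
    _, sets = _sets("KD", "FW", penalty=-1)
    ctx = DiversityContext.from_parents(AlignedParents("KD", "FW"))
    result = optimize_diversity(sets, 0, theta=6, ctx=ctx)
    k, v = result.optimum_exact(0)
    assert (k, v) == (0, 0)


def test_diversity_prefers_even_breakpoint_spread():
    """Among plans with the same number of threshold runs, evenly spread
    breakpoints give lower variance than clustered ones."""
    from shuffleplan.diversity_math import chain_variance_exact

    diff = tuple([1, 0] * 12)  # 24 residues, differences spread uniformly
    ctx = DiversityContext(diff=diff)
    even = chain_variance_exact((8, 16), ctx)
    clustered = chain_variance_exact((2, 4), ctx)
    assert even < clustered


def test_select_among_ties_prefers_run_nucleotides(usage):
    _, sets = _sets("FF", "FF")
    result = optimize_common(sets, 0)
    plans = traceback(result, mode="all")
    # all plans tie on common nt (6); the winner must have all 6 nt in one run
    chosen = select_among_ties(plans, theta=6, usage=usage, rng=random.Random(0))
    assert chosen.d1 == chosen.d2
    assert max(r.length for r in chosen.runs) == 6


def test_select_among_ties_is_seeded(usage):
    _, sets = _sets("LL", "KK")
    plans = traceback(optimize_common(sets, 0), mode="all")
    pick1 = select_among_ties(plans, 9, usage, random.Random(42))
    pick2 = select_among_ties(plans, 9, usage, random.Random(42))
    assert (pick1.d1, pick1.d2) == (pick2.d1, pick2.d2)
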