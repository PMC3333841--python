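import random

import pytest
from Bio.Seq import Seq

from shuffleplan.alignment_io import AlignedParents
from shuffleplan.codon_space import (
    AA_TO_CODONS,
    CODON_TO_AA,
    CodonSpaceError,
    CodonUsageTable,
    GAP_CODON,
    STANDARD_AAS,
    SubstitutionPolicy,
    allowed_substitutions,
    build_codon_sets,
    filter_rare,
    load_usage_table,
    sample_tied_codon,
)


def test_genetic_code_table_is_consistent():
    assert len(CODON_TO_AA) == 61
    for codon, aa in CODON_TO_AA.items():
        assert str(Seq(codon).translate()) == aa


@pytest.mark.parametrize(
    "aa,expected",
    [("F", {"Y"}), ("I", {"L", "V", "M", "F"})],
)
def test_blosum62_conservative_substitutions(aa, expected):
    assert allowed_substitutions(aa, SubstitutionPolicy(max_penalty=4)) == expected


def test_negative_penalty_allows_nothing():
    policy = SubstitutionPolicy(max_penalty=-1)
    for aa in STANDARD_AAS:
        assert allowed_substitutions(aa, policy) == frozenset()


def test_allowed_substitutions_monotone_in_penalty():
    for aa in STANDARD_AAS:
        prev = frozenset()
        for penalty in range(0, 9):
            cur = allowed_substitutions(aa, SubstitutionPolicy(max_penalty=penalty))
            assert prev <= cur
            prev = cur


def test_unknown_amino_acid_rejected():
    with pytest.raises(CodonSpaceError):
        allowed_substitutions("X", SubstitutionPolicy())


def test_codon_sets_wildtype_only(usage):
    parents = AlignedParents("F", "F")
    sets = build_codon_sets(parents, SubstitutionPolicy(max_penalty=-1), usage)
    assert {(o.codon, o.is_substitution) for o in sets.C1[0]} == {
        ("TTT", 0),
        ("TTC", 0),
    }


def test_codon_sets_gap_position(usage):
    parents = AlignedParents("M-", "MK")
    sets = build_codon_sets(parents, SubstitutionPolicy(), usage)
    assert [(o.codon, o.is_substitution, o.encoded_aa) for o in sets.C1[1]] == [
        (GAP_CODON, 0, "-")
    ]


def test_override_extends_codon_set_beyond_matrix_rule(usage):
    # F->W scores 5 below the BLOSUM62 self-score, so only an explicit
    # per-position allowance admits it
    parents = AlignedParents("F", "F")
    policy = SubstitutionPolicy(
        budget=1, per_position_override={(1, 1): frozenset("W")}
    )
    sets = build_codon_sets(parents, policy, usage)
    assert {(o.codon, o.is_substitution) for o in sets.C1[0]} == {
        ("TTT", 0),
        ("TTC", 0),
        ("TGG", 1),
    }
    # parent 2 has no override: matrix rule applies (F -> Y)
    assert {(o.codon, o.is_substitution) for o in sets.C2[0]} == {
        ("TTT", 0),
        ("TTC", 0),
        ("TAT", 1),
        ("TAC", 1),
    }


def test_empty_override_means_wildtype_only(usage):
    parents = AlignedParents("F", "F")
    policy = SubstitutionPolicy(
        budget=1, per_position_override={(1, 1): frozenset()}
    )
    sets = build_codon_sets(parents, policy, usage)
    assert all(not o.is_substitution for o in sets.C1[0])
    assert any(o.is_substitution for o in sets.C2[0])


def test_every_position_keeps_a_wildtype_option(usage):
    parents = AlignedParents("MKFILVWY", "MKFILVWY")
    sets = build_codon_sets(parents, SubstitutionPolicy(budget=3), usage)
    for options in list(sets.C1) + list(sets.C2):
        assert any(not o.is_substitution for o in options)


def _leu_usage():
    freq = {c: u for c, u in zip(AA_TO_CODONS["L"], [0, 0, 0, 0, 0, 0])}
    freq.update(
        {"CTG": 0.40, "CTC": 0.20, "CTT": 0.13, "CTA": 0.07, "TTG": 0.13, "TTA": 0.07}
    )
    # complete the table for all other amino acids (uniform)
    for aa, codons in AA_TO_CODONS.items():
        if aa == "L":
            continue
        for c in codons:
            freq[c] = 1.0 / len(codons)
    return CodonUsageTable(organism="toy", frequency=freq)


def test_filter_rare_drops_codons_below_threshold():
    filtered = filter_rare(_leu_usage(), 0.10)
    leu = {c for c in AA_TO_CODONS["L"] if c in filtered.frequency}
    assert leu == {"CTG", "CTC", "CTT", "TTG"}


def test_filter_rare_threshold_zero_is_identity(usage):
    filtered = filter_rare(usage, 0.0)
    assert dict(filtered.frequency) == dict(usage.frequency)


def test_filter_rare_keeps_single_codon_amino_acids(usage):
    filtered = filter_rare(usage, 0.5)
    assert "ATG" in filtered.frequency  # Met
    assert "TGG" in filtered.frequency  # Trp


def test_filter_rare_keeps_best_codon_when_all_rare():
    freq = {}
    for aa, codons in AA_TO_CODONS.items():
        for c in codons:
            freq[c] = 1.0 / len(codons)
    table = CodonUsageTable(organism="toy", frequency=freq)
    filtered = filter_rare(table, 0.30)  # every Leu/Ser/Arg codon is below 0.3
    assert sum(1 for c in AA_TO_CODONS["L"] if c in filtered.frequency) == 1


def test_usage_validation_rejects_bad_sums():
    freq = {c: 1.0 for c in CODON_TO_AA}
    with pytest.raises(CodonSpaceError):
        CodonUsageTable(organism="bad", frequency=freq).validate()


def test_load_usage_table_normalizes_rna(tmp_path, usage):
    path = tmp_path / "usage.tsv"
    with open(path, "w") as fh:
        fh.write("codon\tfraction\n")
        for codon, frac in usage.frequency.items():
            fh.write(f"{codon.replace('T', 'U')}\t{frac}\n")
    loaded = load_usage_table(path)
    assert dict(loaded.frequency) == dict(usage.frequency)


def test_sample_tied_codon_single_option(usage):
    parents = AlignedParents("M", "M")
    sets = build_codon_sets(parents, SubstitutionPolicy(max_penalty=-1), usage)
    assert len(sets.C1[0]) == 1
    opt = sample_tied_codon(sets.C1[0], usage, random.Random(0))
    assert opt.codon == "ATG"


def test_sample_tied_codon_follows_usage_weights(usage):
    # D codons GAT (0.63) / GAC (0.37): expected draw fraction 0.63
    parents = AlignedParents("D", "D")
    sets = build_codon_sets(parents, SubstitutionPolicy(max_penalty=-1), usage)
    rng = random.Random(12345)
    n = 100_000
    hits = sum(
        1 for _ in range(n) if sample_tied_codon(sets.C1[0], usage, rng).codon == "GAT"
    )
    p = 0.63
    sigma = (n * p * (1 - p)) ** 0.5
    assert abs(hits - n * p) < 3 * sigma


def test_sample_tied_codon_deterministic_given_seed(usage):
    parents = AlignedParents("L", "L")
    sets = build_codon_sets(parents, SubstitutionPolicy(max_penalty=-1), usage)
    picks = [
        sample_tied_codon(sets.C1[0], usage, random.Random(7)).codon
        for _ in range(5)
    ]
    assert len(set(picks)) == 1
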