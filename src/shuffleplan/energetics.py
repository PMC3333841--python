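"""Nearest-neighbor annealing thermodynamics.

The annealing objective approximates the free-energy change of hybridizing
the two designed strands as a sum over aligned dinucleotide pairs,

    o_nn = sum_i dG_nn(d1[i..i+1], d2[i..i+1])        (kcal/mol),

where identical dinucleotide pairs take the Watson-Crick stack free energy
dG37 = dH - T*dS/1000 from the unified parameter set (dH in kcal/mol, dS in
cal/mol*K, compiled at 37 C, 1 M Na+). Constant initiation and symmetry
terms are omitted; they do not affect the optimization. Pairs absent from
the table (mismatch stacks) contribute ``mismatch_default`` (0 by default:
neither favorable nor penalized), and any dinucleotide containing a gap
contributes ``gap_value`` (0 by default: a gap cannot stabilize annealing).

Lookups are symmetrized under simultaneous reverse-complement of both
dinucleotides, reflecting strand symmetry of the annealing score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_DNA = "ACGT"
WATSON_CRICK_DINUCS = tuple(a + b for a in _DNA for b in _DNA)

#: built-in table identifier
BUILTIN_TABLE = "unified-37C-1MNa"


class EnergeticsError(ValueError):
    """Malformed NN parameter input or lookup."""


def _revcomp2(dinuc: str) -> str:
    return _COMPLEMENT[dinuc[1]] + _COMPLEMENT[dinuc[0]]


def _canonical(d1: str, d2: str) -> tuple[str, str]:
    alt = (_revcomp2(d1), _revcomp2(d2))
    return min((d1, d2), alt)


@dataclass(frozen=True)
class NNParameterTable:
    """Map (parent-1 dinucleotide, parent-2 dinucleotide) -> dG37 kcal/mol."""

    entries: Mapping[tuple[str, str], float]
    temperature: float = 310.15
    mismatch_default: float = 0.0
    gap_value: float = 0.0

    def __post_init__(self) -> None:
        missing = [
            d for d in WATSON_CRICK_DINUCS
            if _canonical(d, d) not in self.entries
        ]
        if missing:
            raise EnergeticsError(
                f"missing Watson-Crick entries: {missing}"
            )

    def lookup(self, d1: str, d2: str) -> float:
        if "-" in d1 or "-" in d2:
            return self.gap_value
        return self.entries.get(_canonical(d1, d2), self.mismatch_default)


def load_nn_table(
    source=BUILTIN_TABLE,
    temperature: float = 310.15,
    mismatch_default: float = 0.0,
    gap_value: float = 0.0,
) -> NNParameterTable:
    """Load NN parameters from a TSV (columns dinuc1, dinuc2, then either
    dH and dS or a single precomputed dG) or the built-in table id."""
    if source == BUILTIN_TABLE:
        ref = resources.files("shuffleplan.data") / "nn_unified_37C.tsv"
        with resources.as_file(ref) as path:
            return load_nn_table(path, temperature, mismatch_default, gap_value)
    entries: dict[tuple[str, str], float] = {}
    with open(source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].strip().lower() in {"dinuc1", "d1"}:
                continue
            if len(parts) not in (3, 4):
                raise EnergeticsError(f"line {lineno}: expected 3 or 4 columns")
            d1, d2 = parts[0].strip().upper(), parts[1].strip().upper()
            if len(d1) != 2 or len(d2) != 2 or set(d1 + d2) - set(_DNA):
                raise EnergeticsError(f"line {lineno}: bad dinucleotides")
            if len(parts) == 4:
                dh, ds = float(parts[2]), float(parts[3])
                dg = dh - temperature * ds / 1000.0
            else:
                dg = float(parts[2])
            entries[_canonical(d1, d2)] = dg
    return NNParameterTable(
        entries=entries,
        temperature=temperature,
        mismatch_default=mismatch_default,
        gap_value=gap_value,
    )


def pair_energy(d1_window: str, d2_window: str, table: NNParameterTable) -> float:
    """Energy of a 2-mer pair (one stack) or a 4-mer pair (base bridging into
    a codon: the three stacks (b.c[1]), (c[1].c[2]), (c[2].c[3]))."""
    if len(d1_window) != len(d2_window):
        raise EnergeticsError("window length mismatch")
    if len(d1_window) == 2:
        return table.lookup(d1_window, d2_window)
    if len(d1_window) == 4:
        return sum(
            table.lookup(d1_window[i : i + 2], d2_window[i : i + 2])
            for i in range(3)
        )
    raise EnergeticsError("windows must be 2-mers or 4-mers")


def sequence_energy(d1: str, d2: str, table: NNParameterTable) -> float:
    """Direct evaluation of o_nn by sliding 2-mer lookups over the full
    aligned sequences (the non-DP oracle for the annealing objective)."""
    if len(d1) != len(d2):
        raise EnergeticsError("sequence length mismatch")
    return sum(
        table.lookup(d1[i : i + 2], d2[i : i + 2]) for i in range(len(d1) - 1)
    )
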