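"""Reading the parent alignment and writing finished shuffling plans.

The tool takes a pairwise protein alignment (aligned FASTA, two records of
equal length, '-' for gaps) and emits, per plan: the designed aligned DNA
sequences as FASTA (gap columns as ``---``), an ungapped DNA FASTA for bench
use, a TSV run report, and a JSON summary with all four objective scores.

Coordinates are 0-based half-open internally; every report is 1-based
inclusive. Residue i (0-based) occupies nucleotides [3i, 3i+3) of the
alignment frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .dp_optimizers import ShufflingPlan

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


class AlignmentError(ValueError):
    """Base class for alignment validation failures."""


class RecordCountError(AlignmentError):
    """The FASTA did not contain exactly two parent records."""


class UnequalLengthError(AlignmentError):
    """The two aligned records have different lengths."""


class AlphabetError(AlignmentError):
    """A record contains a character outside the 20 amino acids and '-'."""


class AllGapColumnError(AlignmentError):
    """Some alignment column is a gap in both parents."""


@dataclass(frozen=True)
class AlignedParents:
    """The aligned parent amino-acid sequences a1, a2 of common length n."""

    a1: str
    a2: str
    names: tuple[str, str] = ("parent1", "parent2")

    def __post_init__(self) -> None:
        if len(self.a1) != len(self.a2):
            raise UnequalLengthError(
                f"unequal alignment lengths: {len(self.a1)} vs {len(self.a2)}"
            )
        if self.n < 1:
            raise AlignmentError("empty alignment")
        for name, seq in zip(self.names, (self.a1, self.a2)):
            bad = set(seq) - VALID_AA - {"-"}
            if bad:
                raise AlphabetError(
                    f"illegal characters in {name}: {sorted(bad)!r}"
                )
        for i, (x, y) in enumerate(zip(self.a1, self.a2)):
            if x == "-" and y == "-":
                raise AllGapColumnError(f"column {i + 1} is gap in both parents")

    @property
    def n(self) -> int:
        return len(self.a1)


def read_alignment(path) -> AlignedParents:
    """Read a two-record aligned FASTA; lowercase is accepted and uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise RecordCountError(
            f"expected exactly two parents, found {len(records)} records"
        )
    a1, a2 = (str(r.seq).upper() for r in records)
    return AlignedParents(a1=a1, a2=a2, names=(records[0].id, records[1].id))


def write_alignment(parents: AlignedParents, path) -> None:
    records = [
        SeqRecord(Seq(parents.a1), id=parents.names[0], description=""),
        SeqRecord(Seq(parents.a2), id=parents.names[1], description=""),
    ]
    SeqIO.write(records, str(path), "fasta")


def write_plan(plan: "ShufflingPlan", prefix) -> dict:
    """Write a completed plan.

    Emits ``<prefix>.dna.fasta`` (aligned, gap columns as ``---``),
    ``<prefix>.dna.ungapped.fasta``, ``<prefix>.runs.tsv`` (1-based inclusive
    nucleotide coordinates in the alignment frame) and ``<prefix>.json``.
    Returns the JSON summary dict.
    """
    prefix = Path(prefix)
    if len(plan.d1) != len(plan.d2) or len(plan.d1) % 3:
        raise AlignmentError("incomplete plan: DNA lengths invalid")
    prefix.parent.mkdir(parents=True, exist_ok=True)

    names = plan.names
    SeqIO.write(
        [
            SeqRecord(Seq(plan.d1), id=names[0], description="designed"),
            SeqRecord(Seq(plan.d2), id=names[1], description="designed"),
        ],
        str(prefix) + ".dna.fasta",
        "fasta",
    )
    SeqIO.write(
        [
            SeqRecord(Seq(plan.d1.replace("-", "")), id=names[0], description="ungapped"),
            SeqRecord(Seq(plan.d2.replace("-", "")), id=names[1], description="ungapped"),
        ],
        str(prefix) + ".dna.ungapped.fasta",
        "fasta",
    )
    with open(str(prefix) + ".runs.tsv", "w") as fh:
        fh.write("parent_pair\trun_start\trun_end\trun_length\n")
        for run in plan.runs:
            fh.write(f"{names[0]}|{names[1]}\t{run.start}\t{run.end}\t{run.length}\n")

    summary = plan.summary()
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
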