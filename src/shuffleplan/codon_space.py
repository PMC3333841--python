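"""Per-position possible-codon sets.

For each aligned residue position the optimizers choose one codon per parent.
A position's *possible codon set* contains every non-rare codon of the
wild-type amino acid (substitution flag 0) plus every non-rare codon of each
allowed conservative substitution (flag 1). Gap columns admit only the gap
codon ``---``.

Conservative substitutions default to the BLOSUM62 rule: amino acid ``b`` may
replace ``a`` when ``BLOSUM62[a][b] >= BLOSUM62[a][a] - max_penalty`` (default
penalty 4). Per-position overrides replace the matrix rule entirely, e.g. for
allowances derived from structural analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Mapping, Optional, Sequence

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .alignment_io import AlignedParents

logger = logging.getLogger(__name__)

GAP_CODON = "---"
STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"

_standard_table = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid over the 61 sense codons of the standard genetic code
CODON_TO_AA: dict[str, str] = dict(_standard_table.forward_table)
#: amino acid -> sorted tuple of its sense codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in STANDARD_AAS
}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class CodonSpaceError(ValueError):
    """Invalid codon-space configuration or lookup."""


@dataclass(frozen=True)
class CodonOption:
    """One selectable codon at a position: the codon, whether choosing it
    spends a substitution (the flag t in the recurrences), and the amino acid
    it encodes ('-' for the gap codon)."""

    codon: str
    is_substitution: int
    encoded_aa: str

    def __post_init__(self) -> None:
        if self.codon == GAP_CODON:
            if self.is_substitution or self.encoded_aa != "-":
                raise CodonSpaceError("gap codon cannot be a substitution")
        elif CODON_TO_AA.get(self.codon) != self.encoded_aa:
            raise CodonSpaceError(
                f"{self.codon!r} does not encode {self.encoded_aa!r}"
            )


@dataclass(frozen=True)
class SubstitutionPolicy:
    """How many substitutions may be spent (budget m) and which replacements
    each amino acid admits.

    ``per_position_override`` maps (parent index 1|2, 1-based alignment
    column) to an explicit set of allowed replacement amino acids; an empty
    set means wild-type only at that position.
    """

    budget: int = 0
    max_penalty: int = 4
    matrix: object = field(default_factory=lambda: _BLOSUM62)
    per_position_override: Mapping[tuple[int, int], frozenset[str]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise CodonSpaceError("substitution budget must be >= 0")


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative synonymous codon usage: codon -> fraction among the codons of
    its amino acid. Fractions per amino acid sum to 1 before rare filtering."""

    organism: str
    frequency: Mapping[str, float]

    def validate(self) -> None:
        for aa, codons in AA_TO_CODONS.items():
            total = sum(self.frequency.get(c, 0.0) for c in codons)
            if abs(total - 1.0) > 1e-6:
                raise CodonSpaceError(
                    f"usage fractions for {aa} sum to {total}, expected 1"
                )

    def of(self, codon: str) -> float:
        return float(self.frequency.get(codon, 0.0))


@dataclass(frozen=True)
class PossibleCodonSets:
    """Per-position option sets C1[i], C2[i] (0-based position lists)."""

    C1: tuple[tuple[CodonOption, ...], ...]
    C2: tuple[tuple[CodonOption, ...], ...]

    @property
    def n(self) -> int:
        return len(self.C1)


def allowed_substitutions(aa: str, policy: SubstitutionPolicy) -> frozenset[str]:
    """Amino acids that may conservatively replace ``aa`` under the policy's
    matrix rule (wild type itself excluded)."""
    if aa not in STANDARD_AAS:
        raise CodonSpaceError(f"unknown amino acid {aa!r}")
    self_score = policy.matrix[aa][aa]
    return frozenset(
        b
        for b in STANDARD_AAS
        if b != aa and policy.matrix[aa][b] >= self_score - policy.max_penalty
    )


def load_usage_table(path, organism: str = "custom") -> CodonUsageTable:
    """Read a codon usage TSV.

    Accepts 2 columns (codon, fraction) or 3 columns (codon, count,
    fraction); RNA codons (with U) are normalized to DNA. A header line is
    detected and skipped.
    """
    freq: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            codon = parts[0].strip().upper().replace("U", "T")
            if lineno == 1 and codon not in CODON_TO_AA:
                continue  # header
            if codon not in CODON_TO_AA:
                raise CodonSpaceError(f"line {lineno}: not a sense codon: {parts[0]!r}")
            try:
                frac = float(parts[-1])
            except ValueError as exc:
                raise CodonSpaceError(f"line {lineno}: bad fraction") from exc
            freq[codon] = frac
    table = CodonUsageTable(organism=organism, frequency=freq)
    table.validate()
    return table


def default_usage_table() -> CodonUsageTable:
    """Bundled E. coli K-12 usage fractions."""
    ref = resources.files("shuffleplan.data") / "ecoli_k12_usage.tsv"
    with resources.as_file(ref) as path:
        return load_usage_table(path, organism="E. coli K-12")


def filter_rare(usage: CodonUsageTable, threshold: float = 0.10) -> CodonUsageTable:
    """Drop codons whose usage fraction is below ``threshold``.

    If every codon of an amino acid falls below the threshold, the single
    most frequent one is kept (logged). Surviving fractions are NOT
    renormalized here; sampling renormalizes among survivors.
    """
    if not 0 <= threshold < 1:
        raise CodonSpaceError("threshold must be in [0, 1)")
    kept: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        survivors = [c for c in codons if usage.of(c) >= threshold]
        if not survivors:
            best = max(codons, key=lambda c: (usage.of(c), c))
            logger.warning(
                "all codons of %s below usage threshold %.3g; keeping %s",
                aa, threshold, best,
            )
            survivors = [best]
        for c in survivors:
            kept[c] = usage.of(c)
    return CodonUsageTable(organism=usage.organism, frequency=kept)


def sample_tied_codon(options: Sequence[CodonOption], usage: CodonUsageTable, rng):
    """Draw one option with probability proportional to usage frequency.

    The caller guarantees the options are score-equivalent. Zero total usage
    mass falls back to a uniform draw (logged). Deterministic given the rng
    state.
    """
    options = list(options)
    if not options:
        raise CodonSpaceError("no options to sample from")
    if len(options) == 1:
        return options[0]
    weights = [usage.of(o.codon) for o in options]
    total = sum(weights)
    if total <= 0:
        logger.warning("zero usage mass among tied codons; sampling uniformly")
        weights = [1.0] * len(options)
        total = float(len(options))
    x = rng.random() * total
    acc = 0.0
    for opt, w in zip(options, weights):
        acc += w
        if x < acc:
            return opt
    return options[-1]


def build_codon_sets(
    parents: AlignedParents,
    policy: SubstitutionPolicy,
    usage: Optional[CodonUsageTable] = None,
    rare_threshold: float = 0.10,
) -> PossibleCodonSets:
    """Construct C1[i], C2[i] for every alignment column.

    Non-gap positions get all non-rare codons of the wild-type amino acid
    (flag 0) plus all non-rare codons of each allowed substitution (flag 1);
    gap positions get exactly the gap codon. Stop codons are never options.
    """
    if usage is None:
        usage = default_usage_table()
    filtered = filter_rare(usage, rare_threshold) if rare_threshold > 0 else usage
    allowed_codons = {
        aa: tuple(c for c in AA_TO_CODONS[aa] if c in filtered.frequency)
        for aa in STANDARD_AAS
    }
    subs_cache = {aa: allowed_substitutions(aa, policy) for aa in STANDARD_AAS}

    def options_for(aa: str, parent: int, pos0: int) -> tuple[CodonOption, ...]:
        if aa == "-":
            return (CodonOption(GAP_CODON, 0, "-"),)
        override = policy.per_position_override.get((parent, pos0 + 1))
        subs = sorted(override if override is not None else subs_cache[aa])
        opts = [CodonOption(c, 0, aa) for c in allowed_codons[aa]]
        for b in subs:
            if b == aa:
                continue
            if b not in STANDARD_AAS:
                raise CodonSpaceError(f"unknown substitution target {b!r}")
            opts.extend(CodonOption(c, 1, b) for c in allowed_codons[b])
        return tuple(opts)

    C1 = tuple(options_for(parents.a1[i], 1, i) for i in range(parents.n))
    C2 = tuple(options_for(parents.a2[i], 2, i) for i in range(parents.n))
    return PossibleCodonSets(C1=C1, C2=C2)


def load_overrides(path) -> dict[tuple[int, int], frozenset[str]]:
    """Read a per-position substitution override TSV with columns
    parent (1|2), position (1-based alignment column), allowed amino acids
    (string, possibly empty for wild-type-only)."""
    overrides: dict[tuple[int, int], frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].strip().lower() in {"parent", "p"}:
                continue
            if len(parts) < 2:
                raise CodonSpaceError(f"line {lineno}: expected >=2 columns")
            parent = int(parts[0])
            pos = int(parts[1])
            aas = parts[2].strip().upper() if len(parts) > 2 else ""
            if parent not in (1, 2):
                raise CodonSpaceError(f"line {lineno}: parent must be 1 or 2")
            overrides[(parent, pos)] = frozenset(aas)
    return overrides
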