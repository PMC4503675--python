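"""GC-content and fragile-codon statistics of coding sequences.

A *fragile* codon is a sense codon one point mutation away from a stop
codon; sequences rich in fragile codons are more susceptible to nonsense
mutations and therefore have shorter expected ORF lifespans. Because the
three stop codons (TAA, TAG, TGA) are AT-rich, fragile-codon content
falls with GC content — the mechanistic link between GC-rich sequence
and ORF stability exploited throughout this package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable as _BioCodonTable

from .errors import UndefinedValueError

BASES = "ACGT"


def _standard_code() -> dict[str, str]:
    table = _BioCodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


@dataclass(frozen=True)
class CodonTable:
    """A genetic code: codon -> amino acid, with '*' marking stops."""

    code: dict[str, str] = field(default_factory=_standard_code)

    def __post_init__(self):
        if len(self.code) != 64:
            raise ValueError(f"expected 64 codons, got {len(self.code)}")
        if len(self.stops) != 3:
            raise ValueError(f"expected 3 stop codons, got {sorted(self.stops)}")

    @property
    def stops(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.code.items() if aa == "*")

    def is_stop(self, codon: str) -> bool:
        return self.code.get(codon) == "*"

    def translate(self, codon: str) -> str:
        return self.code[codon]


STANDARD_TABLE = CodonTable()
STOP_CODONS = STANDARD_TABLE.stops


@dataclass(frozen=True)
class CodingSequence:
    """A DNA ORF; length must be a multiple of 3.

    When ``includes_terminal_stop`` is set the last codon must be a stop
    and no internal codon may be one (codons containing N are not checked).
    """

    gene_id: str
    species: str
    seq: str
    includes_terminal_stop: bool = False

    def __post_init__(self):
        if len(self.seq) % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: length {len(self.seq)} not divisible by 3"
            )
        if self.includes_terminal_stop:
            if not self.seq:
                raise ValueError(f"{self.gene_id}: empty sequence cannot end in stop")
            codons = self.codons()
            if codons[-1] not in STOP_CODONS:
                raise ValueError(f"{self.gene_id}: last codon {codons[-1]} not a stop")
            internal = [c for c in codons[:-1] if c in STOP_CODONS]
            if internal:
                raise ValueError(f"{self.gene_id}: internal stop codon(s) {internal}")

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    def sense_codons(self) -> list[str]:
        """Codons excluding the terminal stop (when present) and any codon
        containing N."""
        codons = self.codons()
        if self.includes_terminal_stop:
            codons = codons[:-1]
        return [c for c in codons if "N" not in c]


def gc_content(seq: str) -> float:
    """GC fraction of a DNA string; N bases are excluded entirely."""
    counted = [b for b in seq.upper() if b in BASES]
    if not counted:
        raise UndefinedValueError("GC content undefined for empty/all-N sequence")
    gc = sum(1 for b in counted if b in "GC")
    return gc / len(counted)


def gc3(cds: CodingSequence) -> float:
    """GC fraction over third positions of sense codons only."""
    thirds = [c[2] for c in cds.sense_codons()]
    if not thirds:
        raise UndefinedValueError(f"{cds.gene_id}: no sense codons for GC3")
    return gc_content("".join(thirds))


@lru_cache(maxsize=None)
def _fragile_set(stops: frozenset[str]) -> frozenset[str]:
    fragile = set()
    for codon_tuple in itertools.product(BASES, repeat=3):
        codon = "".join(codon_tuple)
        if codon in stops:
            continue
        for pos in range(3):
            for base in BASES:
                if base == codon[pos]:
                    continue
                if codon[:pos] + base + codon[pos + 1 :] in stops:
                    fragile.add(codon)
    return frozenset(fragile)


def enumerate_fragile_codons(table: CodonTable = STANDARD_TABLE) -> frozenset[str]:
    """All sense codons at Hamming distance 1 from a stop codon (18 in the
    standard code); stop codons themselves are excluded."""
    return _fragile_set(table.stops)


def fragile_codon_fraction(cds: CodingSequence,
                           table: CodonTable = STANDARD_TABLE) -> float:
    """Proportion of sense codons that are fragile. The terminal stop is
    excluded from numerator and denominator; codons containing N are
    skipped."""
    sense = cds.sense_codons()
    if not sense:
        raise UndefinedValueError(f"{cds.gene_id}: no sense codons")
    fragile = enumerate_fragile_codons(table)
    return sum(1 for c in sense if c in fragile) / len(sense)


def stop_mutation_opportunities(cds: CodingSequence,
                                table: CodonTable = STANDARD_TABLE) -> int:
    """Total number of single-base changes across sense codons that create
    a stop codon (a codon neighbouring two stops counts twice).

    This weighted count is the per-sequence nonsense-mutation target size
    used by the lifespan module's analytic hazard approximation.
    """
    stops = table.stops
    total = 0
    for codon in cds.sense_codons():
        for pos in range(3):
            for base in BASES:
                if base != codon[pos] and codon[:pos] + base + codon[pos + 1 :] in stops:
                    total += 1
    return total
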