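"""Genetic-code tables and codon bookkeeping.

The default is NCBI translation table 5 (invertebrate mitochondrial), the
code of every hymenopteran mitogenome: AGA/AGG encode Ser, TGA encodes Trp,
ATA encodes Met, and the stop set is {TAA, TAG}.  All codon-level machinery
(RSCU, ENC degeneracy classes, NG86 site counting, the MG94 simulator) is
driven by this table so that a different mitochondrial code is a one-line
config change.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
STOP = "*"

#: Codons of the four-fold degenerate families used for PR2 analysis are
#: derived from the table itself (families whose synonym count is exactly 4).

ALL_CODONS = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)]


@dataclass(frozen=True, eq=False)
class GeneticCode:
    """A codon -> amino-acid map plus the derived degeneracy structure.

    Attributes
    ----------
    code_id : NCBI translation table number.
    codon_to_aa : all 64 codons mapped to a one-letter amino acid or ``*``.
    family : amino acid -> tuple of synonymous codons (sense only).
    degeneracy_classes : family size -> number of amino acids in that class.
    """

    code_id: int
    codon_to_aa: dict[str, str]
    family: dict[str, tuple[str, ...]] = field(default_factory=dict)
    degeneracy_classes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must map exactly 64 codons")
        fam: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = self.codon_to_aa[codon]
            if aa != STOP:
                fam.setdefault(aa, []).append(codon)
        object.__setattr__(self, "family", {a: tuple(c) for a, c in fam.items()})
        classes: dict[int, int] = {}
        for codons in self.family.values():
            classes[len(codons)] = classes.get(len(codons), 0) + 1
        object.__setattr__(self, "degeneracy_classes", classes)

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, a in self.codon_to_aa.items() if a == STOP)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != STOP)

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == STOP

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_synonymous(self, c1: str, c2: str) -> bool:
        return self.codon_to_aa[c1] == self.codon_to_aa[c2]

    def fourfold_families(self) -> dict[str, tuple[str, ...]]:
        """Families with exactly four synonymous codons (PR2 convention)."""
        return {a: c for a, c in self.family.items() if len(c) == 4}

    def is_valid_start(self, codon: str) -> bool:
        """Mitochondrial ATN start-codon convention."""
        return len(codon) == 3 and codon[0] == "A" and codon[1] == "T"


@lru_cache(maxsize=None)
def get_code(code_id: int = 5) -> GeneticCode:
    """Build a :class:`GeneticCode` from Biopython's NCBI table registry."""
    try:
        table = CodonTable.unambiguous_dna_by_id[code_id]
    except KeyError as exc:
        raise ValueError(f"unknown NCBI translation table: {code_id}") from exc
    mapping = {}
    for codon in ALL_CODONS:
        if codon in table.stop_codons:
            mapping[codon] = STOP
        else:
            mapping[codon] = table.forward_table[codon]
    return GeneticCode(code_id=code_id, codon_to_aa=mapping)
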