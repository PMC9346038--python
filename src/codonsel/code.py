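"""Genetic code tables and codon indexing.

The universal (standard) genetic code is used throughout: vertebrate
coding sequences are translated nuclearly. Codons are indexed by their
position in the stable, alphabetically ordered list of sense codons
(61 for the universal code); stop codons are never assigned an index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

#: Sentinel state for gaps / ambiguous codons treated as missing data.
MISSING = -1


@dataclass(frozen=True, eq=False)
class GeneticCode:
    """A genetic code with a stable sense-codon ordering.

    Attributes
    ----------
    table_id:
        NCBI translation table identifier (1 = universal).
    codon_to_aa:
        Map from each of the 64 codons to its one-letter amino acid,
        with stop codons mapped to ``*``.
    sense_codons:
        Alphabetically ordered tuple of non-stop codons; the index of a
        codon in this tuple is its state index in every rate matrix,
        frequency vector and alignment column.
    stop_codons:
        Tuple of stop codons.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    sense_codons: tuple[str, ...]
    stop_codons: tuple[str, ...]
    codon_index: dict[str, int] = field(default_factory=dict)

    @classmethod
    def universal(cls) -> "GeneticCode":
        return cls.from_ncbi_id(1)

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa: dict[str, str] = {}
        for codon in ("".join(p) for p in product(NUCLEOTIDES, repeat=3)):
            if codon in tbl.stop_codons:
                codon_to_aa[codon] = "*"
            else:
                codon_to_aa[codon] = tbl.forward_table[codon]
        stops = tuple(sorted(tbl.stop_codons))
        sense = tuple(c for c in sorted(codon_to_aa) if c not in stops)
        obj = cls(table_id, codon_to_aa, sense, stops)
        object.__setattr__(obj, "codon_index", {c: i for i, c in enumerate(sense)})
        return obj

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_synonymous(self, i: int, j: int) -> bool:
        """Whether sense codons with indices ``i`` and ``j`` encode the same residue."""
        return self.codon_to_aa[self.sense_codons[i]] == self.codon_to_aa[self.sense_codons[j]]

    def encode(self, codon: str) -> int:
        """State index of a codon string; gaps/ambiguity yield :data:`MISSING`.

        Codons containing a gap character or any non-ACGT letter (e.g. N)
        are treated as missing data. Stop codons raise ``ValueError`` so
        frame errors surface loudly; callers may mask them beforehand.
        """
        codon = codon.upper().replace("U", "T")
        if any(ch not in NUCLEOTIDES for ch in codon) or len(codon) != 3:
            return MISSING
        if codon in self.stop_codons:
            raise ValueError(f"stop codon {codon!r} in coding sequence")
        return self.codon_index[codon]


UNIVERSAL = GeneticCode.universal()
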