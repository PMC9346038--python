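"""Codon alignment container and FASTA I/O.

A :class:`CodonAlignment` is a gapped, in-frame coding alignment keyed by
taxon, with one row designated the human-style reference whose (gapless)
codons define the coordinate system every downstream table reports in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .code import MISSING, UNIVERSAL, GeneticCode

GAP_CHARS = "-."


@dataclass
class ReferenceColumnMap:
    """Map from alignment codon columns to 1-based reference codon indices.

    Columns where the reference row is gapped have no homologous human
    site and are excluded from all site-level reporting.
    """

    column_to_ref: dict[int, int]
    reference_length: int

    def __post_init__(self) -> None:
        vals = [self.column_to_ref[c] for c in sorted(self.column_to_ref)]
        if vals != sorted(vals) or len(set(vals)) != len(vals):
            raise ValueError("reference map must be strictly increasing")
        if len(vals) != self.reference_length:
            raise ValueError("mapped column count != reference length")

    @property
    def ref_to_column(self) -> dict[int, int]:
        return {v: k for k, v in self.column_to_ref.items()}

    def mapped_columns(self) -> list[int]:
        return sorted(self.column_to_ref)


@dataclass
class CodonAlignment:
    """Gapped in-frame codon alignment.

    Parameters
    ----------
    taxa:
        Row labels, unique.
    sequences:
        Aligned nucleotide strings, equal length divisible by 3.
    reference:
        Taxon whose row defines reference codon coordinates (optional).
    """

    taxa: list[str]
    sequences: list[str]
    reference: str | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa/sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("unequal alignment row lengths")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        if self.reference is not None and self.reference not in self.taxa:
            raise ValueError(f"reference taxon {self.reference!r} not in alignment")
        self._index = {t: i for i, t in enumerate(self.taxa)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    def row(self, taxon: str) -> str:
        return self.sequences[self._index[taxon]]

    def codon(self, taxon: str, column: int) -> str:
        """Codon string at 0-based codon column."""
        return self.row(taxon)[3 * column : 3 * column + 3]

    # -- encoding --------------------------------------------------------
    def encode(self, code: GeneticCode = UNIVERSAL, mask_stops: bool = False) -> np.ndarray:
        """Integer state matrix (n_taxa x n_codons); gaps/ambiguity -> MISSING.

        Stop codons raise unless ``mask_stops`` is set, in which case they
        are treated as missing data.
        """
        out = np.full((self.n_taxa, self.n_codons), MISSING, dtype=np.int16)
        for i, seq in enumerate(self.sequences):
            for c in range(self.n_codons):
                codon = seq[3 * c : 3 * c + 3]
                if any(ch in GAP_CHARS for ch in codon):
                    continue
                try:
                    out[i, c] = code.encode(codon)
                except ValueError:
                    if not mask_stops:
                        raise ValueError(
                            f"stop codon {codon!r} at codon column {c + 1} in "
                            f"{self.taxa[i]!r}; pass mask_stops=True to treat as missing"
                        ) from None
        return out

    # -- FASTA -----------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path, reference: str | None = None) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq).upper() for r in records], reference)

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(s), id=t, description="") for t, s in zip(self.taxa, self.sequences)
        ]
        SeqIO.write(recs, str(path), "fasta")


def map_alignment_to_reference(
    alignment: CodonAlignment, reference_taxon: str | None = None
) -> ReferenceColumnMap:
    """Number the reference row's codons 1..L and map alignment columns onto them.

    Columns where the reference codon contains a gap character are unmapped
    (no homologous human site) and are dropped from downstream reports.
    """
    ref = reference_taxon or alignment.reference
    if ref is None:
        raise ValueError("no reference taxon given")
    if ref not in alignment.taxa:
        raise ValueError(f"reference taxon {ref!r} not in alignment")
    row = alignment.row(ref)
    mapping: dict[int, int] = {}
    idx = 0
    for c in range(alignment.n_codons):
        codon = row[3 * c : 3 * c + 3]
        if any(ch in GAP_CHARS for ch in codon):
            continue
        idx += 1
        mapping[c] = idx
    if idx == 0:
        raise ValueError(f"reference row {ref!r} is all gaps")
    return ReferenceColumnMap(mapping, idx)
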