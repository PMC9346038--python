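"""Ortholog curation: pairwise alignment scoring, inclusion filtering,
canonical-start trimming, and orthology assignment.

Candidate protein sequences are aligned globally to the human reference
(Needleman–Wunsch with affine gaps, BLOSUM62, end gaps penalized, the
convention of EMBOSS-style aligners) and scored for percent identity and
percent similarity over the full alignment length, gap columns included.
Sequences with >= 50% identity and >= 60% similarity (inclusive bounds)
pass the filter; spurious in-silico N-terminal extensions are trimmed
back to the canonical start implied by the reference alignment; and
orthology is assigned by neighbor-joining clustering against a labelled
reference paralog panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .trees import nj_tree

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

EXCL_NONE = "none"
EXCL_IDENTITY = "below_identity"
EXCL_SIMILARITY = "below_similarity"
EXCL_NON_ORTHOLOG = "non_ortholog"


@dataclass(frozen=True)
class ProteinRecord:
    """A candidate protein with optional in-frame source CDS."""

    taxon: str
    sequence: str
    source_cds: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.taxon!r}")
        bad = set(self.sequence.upper()) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"unknown residue {sorted(bad)[0]!r} in sequence of {self.taxon!r}"
            )
        if self.source_cds is not None:
            n = len(self.sequence)
            if len(self.source_cds) not in (3 * n, 3 * n + 3):
                raise ValueError(
                    f"CDS of {self.taxon!r} has length {len(self.source_cds)}, "
                    f"expected {3 * n} or {3 * n + 3} (with stop)"
                )


@dataclass(frozen=True)
class PairwiseAlignmentResult:
    """Global alignment with EMBOSS-style identity/similarity percentages."""

    percent_identity: float
    percent_similarity: float
    aligned_query: str
    aligned_reference: str
    score: float


@dataclass(frozen=True)
class CurationRecord:
    taxon: str
    identity: float
    similarity: float
    included: bool
    exclusion_reason: str = EXCL_NONE
    assigned_family: str | None = None
    trimmed_offset: int = 0


@dataclass(frozen=True)
class ScoringConfig:
    """Alignment scoring: BLOSUM62 with X scoring 0 against everything,
    affine gap penalties (first gap residue 10, each further 0.5), end
    gaps penalized (true global alignment)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


def _scoring_matrix(config: ScoringConfig):
    m = substitution_matrices.load(config.matrix_name)
    arr = np.array(m)
    alphabet = m.alphabet
    if "X" in alphabet:
        xi = alphabet.index("X")
        arr[xi, :] = 0.0
        arr[:, xi] = 0.0
    out = substitution_matrices.Array(alphabet=alphabet, dims=2, data=arr)
    return out


def _make_aligner(config: ScoringConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _scoring_matrix(config)
    aligner.open_gap_score = -config.gap_open
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def global_align(
    query: ProteinRecord,
    reference: ProteinRecord,
    scoring: ScoringConfig | None = None,
) -> PairwiseAlignmentResult:
    """Optimal global alignment; identity and similarity use the full
    alignment length (gap columns in the denominator).

    A column is identical when both residues match and neither is X;
    similar when the substitution score of the pair is strictly positive.
    """
    scoring = scoring or ScoringConfig()
    aligner = _make_aligner(scoring)
    matrix = aligner.substitution_matrix
    aln = aligner.align(query.sequence.upper(), reference.sequence.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    length = len(a)
    ident = sim = 0
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb and ca != "X":
            ident += 1
        if matrix[ca, cb] > 0:
            sim += 1
    return PairwiseAlignmentResult(
        100.0 * ident / length, 100.0 * sim / length, a, b, float(aln.score)
    )


def apply_inclusion_filter(
    records: list[CurationRecord],
    identity_min: float = 50.0,
    similarity_min: float = 60.0,
) -> list[CurationRecord]:
    """Inclusive thresholding; identity is checked before similarity, so
    a doubly failing record reports ``below_identity``."""
    if identity_min < 0 or similarity_min < 0:
        raise ValueError("thresholds must be non-negative")
    out = []
    for rec in records:
        if rec.identity < identity_min:
            out.append(replace(rec, included=False, exclusion_reason=EXCL_IDENTITY))
        elif rec.similarity < similarity_min:
            out.append(replace(rec, included=False, exclusion_reason=EXCL_SIMILARITY))
        else:
            out.append(replace(rec, included=True, exclusion_reason=EXCL_NONE))
    return out


def trim_to_canonical_start(
    query: ProteinRecord,
    reference: ProteinRecord,
    scoring: ScoringConfig | None = None,
) -> tuple[ProteinRecord, int]:
    """Drop query residues aligned upstream of the reference's first
    residue (putative in-silico N-terminal extensions); the CDS, if
    present, is trimmed in register."""
    res = global_align(query, reference, scoring)
    offset = 0
    for ca, cb in zip(res.aligned_query, res.aligned_reference):
        if cb != "-":
            break
        if ca != "-":
            offset += 1
    if offset == 0:
        return query, 0
    if offset >= len(query.sequence):
        raise ValueError(f"trimming would empty sequence of {query.taxon!r}")
    new_seq = query.sequence[offset:]
    if not new_seq.startswith("M"):
        warnings.warn(
            f"{query.taxon}: first retained residue after trimming is "
            f"{new_seq[0]!r}, not Met"
        )
    new_cds = query.source_cds[3 * offset :] if query.source_cds else None
    return ProteinRecord(query.taxon, new_seq, new_cds), offset


def assign_ortholog_group(
    query: ProteinRecord,
    panel: list[tuple[str, ProteinRecord]],
    scoring: ScoringConfig | None = None,
) -> str | None:
    """Family label from NJ clustering of the query with a labelled panel.

    Distances are 1 - identity/100 from pairwise global alignments. The
    query's sister directions in the NJ tree are inspected: if the
    single-family directions agree on one family, that family is
    returned; otherwise None (candidate treated as non-ortholog).
    """
    if len(panel) + 1 < 3:
        raise ValueError("orthology assignment needs at least 3 sequences in total")
    families = {fam for fam, _ in panel}
    if len(families) < 2:
        raise ValueError("panel must contain at least 2 distinct family labels")
    records = [query] + [rec for _, rec in panel]
    # newick-safe internal labels; index 0 is the query
    labels = ["Q0"] + [f"P{i}" for i in range(1, len(records))]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(records[i], records[j], scoring)
            d[i, j] = d[j, i] = 1.0 - res.percent_identity / 100.0
    tree = nj_tree(d, labels)

    fam_of = {f"P{i}": fam for i, (fam, _) in enumerate(panel, start=1)}
    dtree = tree.tree
    qleaf = None
    for lf in dtree.leaf_node_iter():
        if lf.taxon.label == labels[0]:
            qleaf = lf
            break
    assert qleaf is not None
    parent = qleaf.parent_node
    if parent is None:  # degenerate 2-leaf tree cannot occur (n >= 3)
        return None
    all_leaves = {lf.taxon.label for lf in dtree.leaf_node_iter()}
    directions: list[set[str]] = []
    for child in parent.child_nodes():
        if child is qleaf:
            continue
        directions.append({lf.taxon.label for lf in child.leaf_iter()})
    below_parent = {lf.taxon.label for lf in parent.leaf_iter()}
    up = all_leaves - below_parent
    if up:
        directions.append(up)

    single_fams = set()
    for leaves in directions:
        fams = {fam_of[lab] for lab in leaves if lab in fam_of}
        if len(fams) == 1:
            single_fams.add(next(iter(fams)))
    if len(single_fams) == 1:
        return next(iter(single_fams))
    if len(single_fams) > 1:
        # a query basal to one family sees pure directions on both sides;
        # break the tie by patristic distance to each family's nearest
        # member, staying undecided on exact ties
        pdm = dtree.phylogenetic_distance_matrix()
        qtax = dtree.taxon_namespace.get_taxon(labels[0])
        nearest = {}
        for lab, fam in fam_of.items():
            if fam not in single_fams:
                continue
            dist = pdm.distance(qtax, dtree.taxon_namespace.get_taxon(lab))
            nearest[fam] = min(nearest.get(fam, np.inf), dist)
        ranked = sorted(nearest.items(), key=lambda kv: kv[1])
        if len(ranked) > 1 and np.isclose(ranked[0][1], ranked[1][1]):
            return None
        return ranked[0][0]
    return None


def load_panel_fasta(path: str | Path) -> list[tuple[str, ProteinRecord]]:
    """Reference paralog panel FASTA with ``family|taxon`` headers."""
    panel = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"panel header {rec.id!r} is not 'family|taxon'")
        fam, taxon = rec.id.split("|", 1)
        panel.append((fam, ProteinRecord(taxon, str(rec.seq).upper())))
    return panel


def curate(
    candidates: list[ProteinRecord],
    reference: ProteinRecord,
    panel: list[tuple[str, ProteinRecord]] | None = None,
    *,
    identity_min: float = 50.0,
    similarity_min: float = 60.0,
    scoring: ScoringConfig | None = None,
) -> tuple[list[CurationRecord], list[ProteinRecord]]:
    """Full inclusion pipeline; returns records and the retained,
    start-trimmed sequences."""
    drafts: list[CurationRecord] = []
    trimmed: dict[str, ProteinRecord] = {}
    for cand in candidates:
        t, offset = trim_to_canonical_start(cand, reference, scoring)
        res = global_align(t, reference, scoring)
        trimmed[cand.taxon] = t
        drafts.append(
            CurationRecord(
                cand.taxon, res.percent_identity, res.percent_similarity,
                included=False, trimmed_offset=offset,
            )
        )
    records = apply_inclusion_filter(drafts, identity_min, similarity_min)
    final: list[CurationRecord] = []
    kept: list[ProteinRecord] = []
    for rec in records:
        if rec.included and panel is not None:
            fam = assign_ortholog_group(trimmed[rec.taxon], panel, scoring)
            if fam is None:
                rec = replace(rec, included=False, exclusion_reason=EXCL_NON_ORTHOLOG)
            else:
                rec = replace(rec, assigned_family=fam)
        final.append(rec)
        if rec.included:
            kept.append(trimmed[rec.taxon])
    return final, kept


def curation_report(records: list[CurationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon": [r.taxon for r in records],
            "identity": [r.identity for r in records],
            "similarity": [r.similarity for r in records],
            "included": [r.included for r in records],
            "exclusion_reason": [r.exclusion_reason for r in records],
            "assigned_family": [r.assigned_family or "" for r in records],
            "trimmed_offset": [r.trimmed_offset for r in records],
        }
    )
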