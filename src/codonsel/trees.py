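"""Phylogenetic tree container, Newick I/O, and a neighbor-joining fallback.

Trees carry branch lengths in expected substitutions per codon site once
they have been refit under the codon model; trees arriving in other units
are usable as topologies whose branch lengths serve as starting values.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj


class PhyloTree:
    """Thin wrapper around a :class:`dendropy.Tree` with label helpers."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    # -- construction ----------------------------------------------------
    @classmethod
    def from_newick(cls, source: str | Path) -> "PhyloTree":
        text = str(source)
        looks_like_newick = "(" in text or text.endswith(";")
        try:
            is_file = not looks_like_newick and Path(text).exists()
        except OSError:
            is_file = False
        data = Path(text).read_text() if is_file else text
        t = dendropy.Tree.get(data=data, schema="newick", preserve_underscores=True)
        return cls(t)

    def to_newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            ).strip()
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.tree.clone(depth=1))

    # -- accessors -------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def total_length(self) -> float:
        return sum(e.length or 0.0 for e in self.tree.edges() if e.head_node.parent_node)

    def branch_lengths(self) -> dict[str, float]:
        """Branch lengths keyed by the leaf-set signature below each edge."""
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            key = ",".join(sorted(lf.taxon.label for lf in node.leaf_iter()))
            out[key] = node.edge.length or 0.0
        return out

    def path_length(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        ta = self.tree.taxon_namespace.get_taxon(a)
        tb = self.tree.taxon_namespace.get_taxon(b)
        return pdm.distance(ta, tb)


def nj_tree(distances: np.ndarray, labels: list[str]) -> PhyloTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch-length estimates are clamped to zero. Raises on
    non-symmetric input or fewer than 3 labels.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if len(labels) != d.shape[0]:
        raise ValueError("label count does not match matrix size")
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")
    dm = DistanceMatrix(d, ids=list(labels))
    tr = _skbio_nj(dm, neg_as_zero=True)
    buf = _io.StringIO()
    tr.write(buf, format="newick")
    return PhyloTree.from_newick(buf.getvalue().strip())


def codon_p_distance(encoded: np.ndarray) -> np.ndarray:
    """Pairwise fraction of differing codon columns (both states observed).

    Used to seed the NJ fallback when no tree is supplied. Pairs sharing
    no observed column get distance 0.75 (saturation placeholder).
    """
    n = encoded.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (encoded[i] >= 0) & (encoded[j] >= 0)
            if not ok.any():
                d[i, j] = d[j, i] = 0.75
                continue
            frac = float(np.mean(encoded[i][ok] != encoded[j][ok]))
            d[i, j] = d[j, i] = frac
    return d
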