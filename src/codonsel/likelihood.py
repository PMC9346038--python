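"""Phylogenetic likelihood by Felsenstein pruning over codon states.

Gap or ambiguous codons are missing data and are marginalized by giving
their tips a partial-likelihood vector of ones; the root is weighted by
the model's equilibrium codon frequencies. Per-site scaling keeps the
computation in range for large trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .code import MISSING, UNIVERSAL, GeneticCode
from .mg94 import RateMatrix, Spectral, spectral_decompose
from .trees import PhyloTree

_SCALE_FLOOR = 1e-200


@dataclass
class TreeArrays:
    """Flattened rooted traversal of a tree for fast repeated pruning.

    Nodes are numbered in postorder; ``children[n]`` lists child node ids,
    ``brlen[n]`` is the length of the branch above node n (root entry
    unused), and ``leaf_row[n]`` maps leaves to alignment rows.
    """

    postorder: list[int]
    children: list[list[int]]
    parent: np.ndarray
    brlen: np.ndarray
    leaf_row: np.ndarray  # -1 for internal nodes
    root: int
    taxa: list[str]
    node_label: list[str | None]

    @classmethod
    def from_tree(cls, tree: PhyloTree, taxa: list[str]) -> "TreeArrays":
        row_of = {t: i for i, t in enumerate(taxa)}
        dnodes = list(tree.tree.postorder_node_iter())
        ids = {id(nd): k for k, nd in enumerate(dnodes)}
        n = len(dnodes)
        children: list[list[int]] = [[] for _ in range(n)]
        parent = np.full(n, -1, dtype=int)
        brlen = np.zeros(n)
        leaf_row = np.full(n, -1, dtype=int)
        labels: list[str | None] = [None] * n
        seen = set()
        for k, nd in enumerate(dnodes):
            if nd.parent_node is not None:
                parent[k] = ids[id(nd.parent_node)]
                children[parent[k]].append(k)
                brlen[k] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                label = nd.taxon.label
                labels[k] = label
                if label not in row_of:
                    raise ValueError(f"tree leaf {label!r} not found in alignment")
                leaf_row[k] = row_of[label]
                seen.add(label)
        if seen != set(taxa):
            missing = sorted(set(taxa) - seen)
            raise ValueError(f"alignment taxa absent from tree: {missing}")
        return cls(list(range(n)), children, parent, brlen, leaf_row, n - 1, list(taxa), labels)

    @property
    def n_nodes(self) -> int:
        return len(self.postorder)

    def branch_nodes(self) -> list[int]:
        """Nodes carrying an optimizable branch (everything but the root)."""
        return [k for k in self.postorder if self.parent[k] >= 0]

    def write_branch_lengths(self, tree: PhyloTree) -> None:
        """Copy ``brlen`` back onto a dendropy tree with identical traversal order."""
        for k, nd in enumerate(tree.tree.postorder_node_iter()):
            if nd.parent_node is not None:
                nd.edge.length = float(self.brlen[k])


def _leaf_partial(states: np.ndarray, n_states: int) -> np.ndarray:
    s = np.atleast_1d(states)
    part = np.zeros((n_states, s.shape[0]))
    obs = s >= 0
    part[s[obs], np.nonzero(obs)[0]] = 1.0
    part[:, ~obs] = 1.0
    return part


def alignment_loglik(
    tree: TreeArrays,
    states: np.ndarray,
    spec: Spectral,
    freqs: np.ndarray,
    brlen: np.ndarray | None = None,
    rate: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Total and per-site log-likelihood of a state matrix (taxa x sites).

    ``rate`` uniformly scales every branch length, which lets callers
    profile an overall rate without rebuilding the spectral factorization.
    """
    bl = tree.brlen if brlen is None else brlen
    n_states = spec.w.shape[0]
    n_sites = states.shape[1]
    log_scale = np.zeros(n_sites)
    partials: dict[int, np.ndarray] = {}
    for k in tree.postorder:
        if tree.leaf_row[k] >= 0:
            partials[k] = _leaf_partial(states[tree.leaf_row[k]], n_states)
            continue
        acc = np.ones((n_states, n_sites))
        for c in tree.children[k]:
            acc *= spec.propagate(rate * bl[c], partials.pop(c))
        mx = acc.max(axis=0)
        small = mx < _SCALE_FLOOR
        if small.any():
            safe = np.where(mx > 0, mx, 1.0)
            acc[:, small] /= safe[small]
            log_scale[small] += np.log(np.where(mx[small] > 0, mx[small], 1.0))
        partials[k] = acc
    site_lik = freqs @ partials[tree.root]
    with np.errstate(divide="ignore"):
        per_site = np.log(site_lik) + log_scale
    return float(per_site.sum()), per_site


def site_log_likelihood(
    tree: PhyloTree,
    column: dict[str, str | int],
    Q: RateMatrix,
    freqs: np.ndarray | None = None,
    code: GeneticCode = UNIVERSAL,
) -> float:
    """Log-likelihood of a single codon column under a fixed rate matrix.

    ``column`` maps taxon labels to codon strings (gap/ambiguous treated
    as missing) or precomputed state indices. Every tree leaf must appear.
    """
    taxa = tree.taxa
    unknown = set(column) - set(taxa)
    if unknown:
        raise ValueError(f"column names unknown taxa: {sorted(unknown)}")
    pi = Q.freqs if freqs is None else np.asarray(freqs, float)
    states = np.full((len(taxa), 1), MISSING, dtype=np.int16)
    for i, t in enumerate(taxa):
        if t not in column:
            raise ValueError(f"no state for taxon {t!r}")
        v = column[t]
        states[i, 0] = v if isinstance(v, (int, np.integer)) else code.encode(str(v))
    ta = TreeArrays.from_tree(tree, taxa)
    spec = spectral_decompose(Q.matrix, pi)
    total, _ = alignment_loglik(ta, states, spec, pi)
    return total
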