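"""Global MG94xREV fit: nuisance parameters shared by every site analysis.

The fit maximizes the alignment-wide likelihood over the five free REV
exchangeabilities (GT fixed at 1), a single gene-wide omega, and the
branch lengths, with codon frequencies set empirically by F3x4 (not
optimized). Site-level (FEL) and partition-level analyses then hold this
fit fixed, which is what makes their per-site/per-partition tests cheap
and mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .code import NUCLEOTIDES, UNIVERSAL, GeneticCode
from .io import CodonAlignment
from .likelihood import TreeArrays, alignment_loglik
from .mg94 import MG94Params, build_mg94_matrix, spectral_decompose
from .trees import PhyloTree

OMEGA_BOUNDS = (1e-6, 100.0)
RATE_BOUNDS = (1e-6, 100.0)
BRANCH_BOUNDS = (1e-9, 25.0)


@dataclass
class GlobalFit:
    """Converged (or best-found) alignment-wide MG94xREV fit."""

    params: MG94Params
    tree: PhyloTree
    log_likelihood: float
    converged: bool
    trace: list[float] = field(default_factory=list)
    alignment: CodonAlignment | None = None
    states: np.ndarray | None = None
    tree_arrays: TreeArrays | None = None


def empirical_position_freqs(
    alignment: CodonAlignment, floor: float = 1e-6
) -> np.ndarray:
    """F3x4 input: observed nucleotide frequencies per codon position.

    Counts ignore gaps and ambiguity codes; a small floor keeps unseen
    nucleotides from zeroing out whole codon classes.
    """
    counts = np.zeros((3, 4))
    nuc_idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for seq in alignment.sequences:
        for c in range(len(seq) // 3):
            for k in range(3):
                ch = seq[3 * c + k]
                if ch in nuc_idx:
                    counts[k, nuc_idx[ch]] += 1
    counts = np.maximum(counts, 0.0) + floor
    return counts / counts.sum(axis=1, keepdims=True)


def _loglik_for(params: MG94Params, ta: TreeArrays, states: np.ndarray) -> float:
    rm = build_mg94_matrix(params)
    spec = spectral_decompose(rm.matrix, rm.freqs)
    total, _ = alignment_loglik(ta, states, spec, rm.freqs)
    return total


def fit_global_model(
    alignment: CodonAlignment,
    tree: PhyloTree,
    *,
    code: GeneticCode = UNIVERSAL,
    optimize_branches: bool = True,
    init_omega: float = 0.5,
    init_params: MG94Params | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 25,
    mask_stops: bool = False,
) -> GlobalFit:
    """Maximum-likelihood fit of rates, omega and branch lengths.

    Alternates a bounded quasi-Newton step over (log-exchangeabilities,
    log-omega) with one-dimensional branch-length optimizations until the
    log-likelihood improves by less than ``tol`` per sweep. Input branch
    lengths are starting values; they are always refit (when
    ``optimize_branches``) so the output is in expected substitutions per
    codon site regardless of the units the tree arrived in.
    """
    if alignment.n_taxa < 3:
        raise ValueError("global fit needs at least 3 taxa")
    states = alignment.encode(code, mask_stops=mask_stops)
    observed = states[states >= 0]
    if observed.size == 0:
        raise ValueError("alignment has no observed codons")
    work = tree.copy()
    ta = TreeArrays.from_tree(work, alignment.taxa)
    ta.brlen = np.clip(np.where(ta.brlen > 0, ta.brlen, 0.1), *BRANCH_BOUNDS)
    pos_freqs = empirical_position_freqs(alignment)

    if init_params is not None:
        x = np.concatenate(
            [np.log(np.maximum(init_params.rev_rates[:5], RATE_BOUNDS[0])),
             [np.log(max(init_params.omega, OMEGA_BOUNDS[0]))]]
        )
    else:
        x = np.concatenate([np.zeros(5), [np.log(init_omega)]])  # log rates, GT=1 implicit

    def make_params(xv: np.ndarray) -> MG94Params:
        rates = np.ones(6)
        rates[:5] = np.exp(xv[:5])
        return MG94Params(rates, pos_freqs, float(np.exp(xv[5])), code)

    def neg_obj(xv: np.ndarray) -> float:
        return -_loglik_for(make_params(xv), ta, states)

    log_rb = (np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1]))
    log_ob = (np.log(OMEGA_BOUNDS[0]), np.log(OMEGA_BOUNDS[1]))
    bounds = [log_rb] * 5 + [log_ob]

    trace = [-neg_obj(x)]
    converged = False
    for _ in range(max_sweeps):
        res = minimize(neg_obj, x, method="L-BFGS-B", bounds=bounds)
        if -res.fun >= trace[-1]:
            x = res.x
        current = max(trace[-1], -res.fun)

        if optimize_branches:
            params = make_params(x)
            rm = build_mg94_matrix(params)
            spec = spectral_decompose(rm.matrix, rm.freqs)

            def bl_loglik() -> float:
                t, _ = alignment_loglik(ta, states, spec, rm.freqs)
                return t

            for node in ta.branch_nodes():
                t0 = ta.brlen[node]
                ll0 = bl_loglik()

                def neg_bl(t: float, node=node) -> float:
                    ta.brlen[node] = t
                    return -bl_loglik()

                r = minimize_scalar(
                    neg_bl, bounds=BRANCH_BOUNDS, method="bounded",
                    options={"xatol": 1e-7},
                )
                if -r.fun >= ll0:
                    ta.brlen[node] = float(r.x)
                else:
                    ta.brlen[node] = t0
            current = bl_loglik()

        trace.append(current)
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn("global MG94xREV fit did not converge; returning best-found values")

    ta.write_branch_lengths(work)
    params = make_params(x)
    return GlobalFit(params, work, trace[-1], converged, trace, alignment, states, ta)
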