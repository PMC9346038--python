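"""MG94xREV codon substitution model.

The model combines the Muse–Gaut (1994) separation of synonymous and
non-synonymous substitution rates with general-time-reversible (REV)
nucleotide exchangeabilities. A substitution between sense codons i and j
is allowed only if they differ at exactly one nucleotide position k, with
instantaneous rate

    q_ij = rho(x, y) * pi_k(y) * (omega if aa(i) != aa(j) else 1),

where rho are the six symmetric exchangeabilities (GT fixed to 1 for
identifiability), pi_k(y) is the equilibrium frequency of the target
nucleotide y at codon position k (the F3x4 parameterization), and omega
is the non-synonymous/synonymous rate ratio. The codon equilibrium
distribution is the normalized product of the position-specific
nucleotide frequencies over the 61 sense codons, and the generator is
reversible with respect to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import eigh, expm

from .code import NUCLEOTIDES, UNIVERSAL, GeneticCode

#: Order of the six reversible exchangeabilities.
REV_PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass
class MG94Params:
    """Parameters of the MG94xREV model.

    Attributes
    ----------
    rev_rates:
        Six exchangeabilities in :data:`REV_PAIRS` order; GT is
        conventionally fixed to 1.
    position_freqs:
        3x4 array of nucleotide frequencies per codon position (ACGT
        order, rows summing to 1); the F3x4 frequency parameterization.
    omega:
        Non-synonymous/synonymous rate ratio, >= 0.
    """

    rev_rates: np.ndarray
    position_freqs: np.ndarray
    omega: float
    code: GeneticCode = field(default_factory=lambda: UNIVERSAL)

    def __post_init__(self) -> None:
        self.rev_rates = np.asarray(self.rev_rates, dtype=float)
        self.position_freqs = np.asarray(self.position_freqs, dtype=float)
        if self.rev_rates.shape != (6,):
            raise ValueError("rev_rates must have 6 entries (AC, AG, AT, CG, CT, GT)")
        if np.any(self.rev_rates < 0):
            raise ValueError("exchangeabilities must be non-negative")
        if self.position_freqs.shape != (3, 4):
            raise ValueError("position_freqs must be 3x4 (positions x ACGT)")
        if np.any(self.position_freqs < 0):
            raise ValueError("nucleotide frequencies must be non-negative")
        rs = self.position_freqs.sum(axis=1)
        if np.any(rs <= 0):
            raise ValueError("each codon position needs positive total frequency")
        self.position_freqs = self.position_freqs / rs[:, None]
        if not np.isfinite(self.omega) or self.omega < 0:
            raise ValueError("omega must be finite and >= 0")

    @property
    def codon_freqs(self) -> np.ndarray:
        """F3x4 codon equilibrium frequencies over sense codons (sum to 1)."""
        return f3x4_codon_freqs(self.position_freqs, self.code)

    @classmethod
    def uniform(cls, omega: float = 1.0, code: GeneticCode = UNIVERSAL) -> "MG94Params":
        return cls(np.ones(6), np.full((3, 4), 0.25), omega, code)


@dataclass
class RateMatrix:
    """Instantaneous rates over sense codons plus the normalization used."""

    matrix: np.ndarray
    freqs: np.ndarray
    scale: float  # flux of the unnormalized generator (divisor applied)


def f3x4_codon_freqs(position_freqs: np.ndarray, code: GeneticCode = UNIVERSAL) -> np.ndarray:
    nuc_idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    p = np.array(
        [
            np.prod([position_freqs[k, nuc_idx[c[k]]] for k in range(3)])
            for c in code.sense_codons
        ]
    )
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate position frequencies: all sense codons have zero mass")
    return p / total


@lru_cache(maxsize=4)
def _single_step_table(code: GeneticCode):
    """Sparse table of one-nucleotide codon changes: (i, j, pos, x, y, synonymous)."""
    nuc_idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    pair_idx = {}
    for r, p in enumerate(REV_PAIRS):
        pair_idx[(nuc_idx[p[0]], nuc_idx[p[1]])] = r
        pair_idx[(nuc_idx[p[1]], nuc_idx[p[0]])] = r
    rows, cols, pos, pairs, syn = [], [], [], [], []
    sense = code.sense_codons
    for i, ci in enumerate(sense):
        for j, cj in enumerate(sense):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            (k,) = diffs
            rows.append(i)
            cols.append(j)
            pos.append(k)
            pairs.append(pair_idx[(nuc_idx[ci[k]], nuc_idx[cj[k]])])
            syn.append(code.is_synonymous(i, j))
    return (
        np.array(rows),
        np.array(cols),
        np.array(pos),
        np.array(pairs),
        np.array(syn, dtype=bool),
    )


def mg94_components(
    rev_rates: np.ndarray, position_freqs: np.ndarray, code: GeneticCode = UNIVERSAL
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized synonymous and non-synonymous parts of the generator.

    Off-diagonal only; the full generator at ratio omega is
    ``A_syn + omega * A_nonsyn`` with diagonals set to minus the row sums.
    """
    rows, cols, pos, pairs, syn = _single_step_table(code)
    nuc_idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    target = np.array(
        [position_freqs[k, nuc_idx[code.sense_codons[j][k]]] for k, j in zip(pos, cols)]
    )
    vals = np.asarray(rev_rates, float)[pairs] * target
    n = code.n_states
    a_syn = np.zeros((n, n))
    a_non = np.zeros((n, n))
    a_syn[rows[syn], cols[syn]] = vals[syn]
    a_non[rows[~syn], cols[~syn]] = vals[~syn]
    return a_syn, a_non


def _flux(a: np.ndarray, freqs: np.ndarray) -> float:
    return float(freqs @ a.sum(axis=1))


def build_mg94_matrix(params: MG94Params, normalize: bool = True) -> RateMatrix:
    """Assemble the MG94xREV generator; multi-nucleotide entries are zero.

    When ``normalize`` is set the generator is scaled so that the expected
    number of substitutions per codon site per unit branch length is 1.
    """
    a_syn, a_non = mg94_components(params.rev_rates, params.position_freqs, params.code)
    q = a_syn + params.omega * a_non
    pi = params.codon_freqs
    z = _flux(q, pi) if normalize else 1.0
    if normalize and z <= 0:
        raise ValueError("degenerate model: zero total substitution flux")
    q = q / z if normalize else q.copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return RateMatrix(q, pi, z)


def transition_matrix(Q: RateMatrix | np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) by scaling-and-squaring; rows sum to 1.

    Tiny negative entries from roundoff (above -1e-12) are clipped to 0.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    m = Q.matrix if isinstance(Q, RateMatrix) else np.asarray(Q, float)
    p = expm(m * t)
    neg = p < 0
    if neg.any():
        if p[neg].min() < -1e-12:
            raise FloatingPointError("transition matrix entry below -1e-12")
        p[neg] = 0.0
    return p


@dataclass
class Spectral:
    """Spectral factorization of a reversible generator: Q = A diag(w) B.

    Built by symmetrizing with the stationary distribution
    (D^{1/2} Q D^{-1/2} is symmetric for a reversible Q), so
    P(t) = A diag(exp(w t)) B exactly; this is the likelihood hot path.
    """

    w: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def propagate(self, t: float, partial: np.ndarray) -> np.ndarray:
        """P(t) @ partial without forming P; partial is (n_states, n_sites)."""
        tmp = self.B @ partial
        tmp *= np.exp(self.w * t)[:, None]
        out = self.A @ tmp
        np.maximum(out, 0.0, out=out)
        return out

    def back_propagate(self, t: float, partial: np.ndarray) -> np.ndarray:
        """P(t)^T @ partial (needed for root-side partials)."""
        tmp = self.A.T @ partial
        tmp *= np.exp(self.w * t)[:, None]
        out = self.B.T @ tmp
        np.maximum(out, 0.0, out=out)
        return out

    def matrix(self, t: float) -> np.ndarray:
        p = (self.A * np.exp(self.w * t)[None, :]) @ self.B
        np.maximum(p, 0.0, out=p)
        return p


def spectral_decompose(q: np.ndarray, freqs: np.ndarray) -> Spectral:
    d = np.sqrt(np.maximum(freqs, 1e-300))
    s = (d[:, None] * q) / d[None, :]
    s = 0.5 * (s + s.T)
    w, v = eigh(s)
    return Spectral(w, v / d[:, None], v.T * d[None, :])
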