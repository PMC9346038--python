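"""Forward simulation of codon alignments with known site-wise selection.

Emulates a vertebrate-style ortholog set: tens to ~150 taxa, a
reference-coordinate gapless codon alignment with piecewise-constant
site-specific omega structure — strongly purified core blocks, relaxed
flanking blocks, occasional sites above 1, and an invariant initiator
methionine. The generator evolves root codons drawn from the model's
equilibrium along a tree by sampling each branch's end state directly
from P(t) per site (endpoint sampling: exactly the distribution the
likelihood integrates over, no event-level simulation needed), so
estimator tests recover planted truth without any external data.

Defaults reflect a typical comparative study at desk scale: 64 taxa, 160 codons,
four region-like blocks plus exon-like blocks, transition/transversion
exchangeability 4, uniform position frequencies.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .code import UNIVERSAL, GeneticCode
from .curation import ProteinRecord, ScoringConfig, _scoring_matrix
from .io import CodonAlignment
from .mg94 import MG94Params, mg94_components, spectral_decompose
from .trees import PhyloTree

#: Transition-rich exchangeabilities (AC, AG, AT, CG, CT, GT), kappa ~ 4.
DEFAULT_REV_RATES = np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0])

DEFAULT_BLOCKS = [
    (1, 40, 0.6, "NTR"),
    (41, 70, 0.9, "CeR"),
    (71, 130, 0.08, "aCD"),
    (131, 160, 0.7, "CTE"),
]


@dataclass
class SiteProfile:
    """Ground-truth per-site synonymous/non-synonymous rates."""

    alpha: np.ndarray
    beta: np.ndarray
    partition_labels: list[str]
    invariant_start_met: bool = False

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, float)
        self.beta = np.asarray(self.beta, float)
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha/beta length mismatch")
        if np.any(self.alpha < 0) or np.any(self.beta < 0):
            raise ValueError("rates must be non-negative")
        if len(self.partition_labels) != self.alpha.shape[0]:
            raise ValueError("partition labels length mismatch")

    @property
    def n_sites(self) -> int:
        return self.alpha.shape[0]

    @property
    def omega(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.alpha

    @property
    def planted_positive(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return (self.beta > self.alpha) & (self.alpha > 0)

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": np.arange(1, self.n_sites + 1),
                "alpha": self.alpha,
                "beta": self.beta,
                "omega": self.omega,
                "partition": self.partition_labels,
            }
        )


def make_site_profile(
    blocks: list[tuple[int, int, float]] | list[tuple[int, int, float, str]] | dict[str, float],
    n_sites: int,
    *,
    invariant_start_met: bool = False,
) -> SiteProfile:
    """Piecewise-constant omega profile with alpha = 1 in every block.

    ``blocks`` is either a list of (start, end, omega[, label]) 1-based
    inclusive tuples tiling 1..n_sites, or a dict {"1-40": 0.8, ...}.
    With ``invariant_start_met`` site 1 gets both rates 0 and its state
    pinned to ATG by the simulator.
    """
    if isinstance(blocks, dict):
        parsed = []
        for rng, w in blocks.items():
            a, b = (int(x) for x in str(rng).split("-"))
            parsed.append((a, b, float(w)))
        blocks = parsed
    alpha = np.full(n_sites, np.nan)
    beta = np.full(n_sites, np.nan)
    labels = [""] * n_sites
    for blk in blocks:
        start, end, w = blk[0], blk[1], float(blk[2])
        label = blk[3] if len(blk) > 3 else f"{start}-{end}"
        if start < 1 or end > n_sites or end < start:
            raise ValueError(f"block {start}-{end} outside 1..{n_sites}")
        if np.any(~np.isnan(alpha[start - 1 : end])):
            raise ValueError(f"block {start}-{end} overlaps an earlier block")
        alpha[start - 1 : end] = 1.0
        beta[start - 1 : end] = w
        for s in range(start - 1, end):
            labels[s] = label
    if np.any(np.isnan(alpha)):
        missing = int(np.nonzero(np.isnan(alpha))[0][0]) + 1
        raise ValueError(f"blocks do not tile 1..{n_sites} (site {missing} uncovered)")
    if invariant_start_met:
        alpha[0] = beta[0] = 0.0
    return SiteProfile(alpha, beta, labels, invariant_start_met)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated ortholog set."""

    n_taxa: int = 64
    tree_shape: str = "yule"  # balanced | yule | a newick string
    tree_length: float = 6.0
    seed: int | None = None
    rev_rates: np.ndarray = field(default_factory=lambda: DEFAULT_REV_RATES.copy())
    position_freqs: np.ndarray = field(default_factory=lambda: np.full((3, 4), 0.25))
    code: GeneticCode = field(default_factory=lambda: UNIVERSAL)

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible simulation")


def _balanced_tree(n: int, rng: random.Random) -> dendropy.Tree:
    taxa = [f"t{i + 1:03d}" for i in range(n)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)

    def build(lo: int, hi: int, parent):
        if hi - lo == 1:
            node = parent.new_child()
            node.taxon = ns.get_taxon(taxa[lo])
            return
        mid = (lo + hi) // 2
        child = parent.new_child()
        build(lo, mid, child)
        build(mid, hi, child)

    build(0, n, tree.seed_node)
    tree.suppress_unifurcations()
    return tree


def _yule_tree(n: int, rng: random.Random) -> dendropy.Tree:
    from dendropy.simulate import treesim

    return treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, rng=rng
    )


def generate_tree(config: SimulationConfig) -> PhyloTree:
    """Random tree of the requested shape, scaled to the total length."""
    rng = random.Random(config.seed)
    if config.tree_shape == "balanced":
        tree = _balanced_tree(config.n_taxa, rng)
        for edge in tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                edge.length = 1.0
    elif config.tree_shape == "yule":
        tree = _yule_tree(config.n_taxa, rng)
        for i, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon.label = f"t{i + 1:03d}"
    else:
        return PhyloTree.from_newick(config.tree_shape)
    total = sum(
        e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node.parent_node
    )
    scale = config.tree_length / total
    for e in tree.preorder_edge_iter():
        if e.head_node.parent_node is not None:
            e.length = (e.length or 0.0) * scale
    return PhyloTree(tree)


def simulate_codon_alignment(
    config: SimulationConfig,
    profile: SiteProfile,
    tree: PhyloTree | None = None,
) -> tuple[CodonAlignment, PhyloTree, pd.DataFrame]:
    """Evolve codons along a tree under site-specific (alpha, beta).

    Rate matrices per site are ``alpha * Q_syn + beta * Q_nonsyn`` with
    the components normalized so a neutral site accumulates one expected
    substitution per unit branch length; branch lengths are therefore in
    neutral expected substitutions per codon site. Identical
    (config, profile) with the same seed give byte-identical output.
    """
    tree = tree if tree is not None else generate_tree(config)
    code = config.code
    params = MG94Params(config.rev_rates, config.position_freqs, 1.0, code)
    pi = params.codon_freqs
    a_syn, a_non = mg94_components(params.rev_rates, params.position_freqs, code)
    z1 = float(pi @ (a_syn + a_non).sum(axis=1))
    q_syn, q_non = a_syn / z1, a_non / z1

    rng = np.random.default_rng(config.seed)
    n_sites = profile.n_sites
    n_states = code.n_states

    # group sites by (alpha, beta) so each group shares spectral work
    pairs = np.stack([profile.alpha, profile.beta], axis=1)
    uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
    specs = []
    for a, b in uniq:
        if a == 0.0 and b == 0.0:
            specs.append(None)  # frozen sites: P(t) = I
            continue
        q = a * q_syn + b * q_non
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        specs.append(spectral_decompose(q, pi))

    ta_nodes = list(tree.tree.postorder_node_iter())
    root = ta_nodes[-1]

    states: dict[int, np.ndarray] = {}
    root_states = rng.choice(n_states, size=n_sites, p=pi)
    if profile.invariant_start_met:
        root_states[0] = code.codon_index["ATG"]
    states[id(root)] = root_states

    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_states = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        child = parent_states.copy()
        for g, spec in enumerate(specs):
            if spec is None:
                continue
            sel = np.nonzero(inv == g)[0]
            if sel.size == 0:
                continue
            p = spec.matrix(t)
            p /= p.sum(axis=1, keepdims=True)
            cum = np.cumsum(p, axis=1)
            u = rng.random(sel.size)
            child[sel] = np.argmax(cum[parent_states[sel]] > u[:, None], axis=1)
        states[id(node)] = child

    taxa, seqs = [], []
    for node in tree.tree.leaf_node_iter():
        taxa.append(node.taxon.label)
        seqs.append("".join(code.sense_codons[s] for s in states[id(node)]))
    order = np.argsort(taxa)
    alignment = CodonAlignment(
        [taxa[i] for i in order], [seqs[i] for i in order], reference=taxa[order[0]]
    )
    return alignment, tree, profile.truth_table()


def default_fixture(seed: int, n_taxa: int = 64, tree_length: float = 6.0):
    """The packaged desk-scale benchmark: region blocks with an invariant
    initiator Met and one planted positively selected site."""
    blocks = [(1, 1, 0.0, "M1")] + [
        (max(2, a), b, w, lab) for a, b, w, lab in DEFAULT_BLOCKS
    ]
    profile = make_site_profile(blocks, 160, invariant_start_met=True)
    profile.beta[47] = 2.0  # one planted positive site inside the CeR
    config = SimulationConfig(n_taxa=n_taxa, tree_shape="yule", tree_length=tree_length, seed=seed)
    return config, profile


def write_fixture(
    outdir: str | Path,
    config: SimulationConfig,
    profile: SiteProfile,
    alignment: CodonAlignment,
    tree: PhyloTree,
    truth: pd.DataFrame,
) -> None:
    """Emit FASTA + Newick + truth TSV + generating-config YAML."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    alignment.to_fasta(out / "alignment.fasta")
    tree.write(out / "tree.nwk")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    (out / "config.yaml").write_text(
        yaml.safe_dump(
            {
                "n_taxa": config.n_taxa,
                "tree_shape": config.tree_shape,
                "tree_length": config.tree_length,
                "seed": config.seed,
                "rev_rates": [float(x) for x in config.rev_rates],
                "position_freqs": [[float(x) for x in row] for row in config.position_freqs],
                "n_sites": profile.n_sites,
            }
        )
    )


# ---------------------------------------------------------------------------
# curation fixtures


_AA_CODON = {}
for _c in UNIVERSAL.sense_codons:
    _AA_CODON.setdefault(UNIVERSAL.translate(_c), _c)

_SIMILAR = {}
_DISSIMILAR = {}


def _substitution_pools():
    if _SIMILAR:
        return
    mat = _scoring_matrix(ScoringConfig())
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for a in aas:
        _SIMILAR[a] = [b for b in aas if b != a and mat[a, b] > 0]
        _DISSIMILAR[a] = [b for b in aas if b != a and mat[a, b] <= 0]


def make_curation_fixture(
    targets: list[tuple[float, float]],
    *,
    seed: int,
    length: int = 100,
    reference: str | None = None,
) -> tuple[ProteinRecord, list[tuple[ProteinRecord, dict]]]:
    """Mutants of a reference protein with planted identity/similarity.

    Each target is (percent_identity, percent_similarity) with
    similarity >= identity; substitution-only mutants at a length where
    the percentages are whole residue counts land exactly on target
    (verified post hoc by the aligner itself in the tests). The returned
    truth dict records the expected include/exclude call at the 50/60
    thresholds. Matched CDS strings are emitted for every record.
    """
    _substitution_pools()
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    if reference is None:
        body = "".join(rng.choice(list(aas), size=length - 1))
        reference = "M" + body
    ref_rec = ProteinRecord("reference", reference, _reverse_translate(reference, rng))

    out = []
    for ident, sim in targets:
        if not (0 <= ident <= 100 and 0 <= sim <= 100):
            raise ValueError(f"unreachable identity/similarity target ({ident}, {sim})")
        if sim < ident:
            raise ValueError(
                f"similarity target {sim} below identity target {ident}: impossible "
                "for substitution-only mutants"
            )
        n = len(reference)
        n_mut = round(n * (1 - ident / 100))
        n_similar = round(n * (sim - ident) / 100)
        if n_similar > n_mut:
            raise ValueError(f"targets ({ident}, {sim}) are inconsistent")
        # some residues (e.g. G under BLOSUM62) have no positive-scoring
        # partner, so draw positions from the residues that can host each
        # substitution flavor
        can_sim = [i for i in range(1, n) if _SIMILAR[reference[i]]]
        can_dis = [i for i in range(1, n) if _DISSIMILAR[reference[i]]]
        if n_similar > len(can_sim):
            raise ValueError(
                f"targets ({ident}, {sim}) need {n_similar} similar substitutions "
                f"but only {len(can_sim)} positions admit one"
            )
        sim_pos = rng.choice(can_sim, size=n_similar, replace=False) if n_similar else []
        remaining = [i for i in can_dis if i not in set(sim_pos)]
        n_dis = n_mut - n_similar
        if n_dis > len(remaining):
            raise ValueError(
                f"targets ({ident}, {sim}) need {n_dis} dissimilar substitutions "
                f"but only {len(remaining)} positions admit one"
            )
        dis_pos = rng.choice(remaining, size=n_dis, replace=False) if n_dis else []
        seq = list(reference)
        for pos in sim_pos:
            seq[pos] = str(rng.choice(_SIMILAR[seq[pos]]))
        for pos in dis_pos:
            seq[pos] = str(rng.choice(_DISSIMILAR[seq[pos]]))
        mutant = "".join(seq)
        taxon = f"id{ident:g}_sim{sim:g}"
        rec = ProteinRecord(taxon, mutant, _reverse_translate(mutant, rng))
        truth = {
            "target_identity": ident,
            "target_similarity": sim,
            "expected_included": ident >= 50.0 and sim >= 60.0,
        }
        out.append((rec, truth))
    return ref_rec, out


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [_AA_CODON[aa] for aa in protein]
    return "".join(codons) + "TAA"
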