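"""Aggregate dN/dS for sequence partitions and their pairwise comparison.

A partition (full-length gene, a region such as NTR/CeR/alphaCD/CTE, or
an exon) gets a single aggregate omega-bar maximizing the joint
likelihood of its usable sites under the shared MG94xREV machinery, with
the global nuisance fit held fixed and an overall synonymous-rate scale
profiled out — exactly the per-site FEL parameterization applied to a
set of columns, so a one-site partition reproduces that site's FEL
estimate. Sites whose FEL omega is undefined (0/0, i.e. invariant
columns) are excluded from every aggregate fit; infinite-omega sites
(beta/0) stay in, since their non-synonymous changes are informative
about omega-bar and dropping them would bias aggregates downward.

Two fits are compared by a one-degree-of-freedom likelihood ratio test:
the null shares one omega-bar across both site sets (each keeping its
own rate scale and, for cross-gene comparisons, its own tree and
frequencies), the alternative estimates them separately. Significant
inequalities are summarized as a Hasse diagram with arrows pointing
toward the partition with the greater omega-bar, i.e. the one under less
stringent purifying selection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import yaml
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .fel import FELContext, FELScan, OMEGA_CAP, profile_confidence_interval
from .fitting import GlobalFit
from .io import ReferenceColumnMap

CATEGORIES = ("region", "exon", "full_length")


@dataclass(frozen=True)
class Partition:
    """Named set of 1-based reference codon indices."""

    name: str
    sites: frozenset[int]
    category: str = "region"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("partition needs a name")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown partition category {self.category!r}")
        if not self.sites:
            raise ValueError(f"partition {self.name!r} is empty")
        if any(s < 1 for s in self.sites):
            raise ValueError(f"partition {self.name!r} has non-positive site indices")

    @classmethod
    def from_ranges(cls, name: str, ranges: str, category: str = "region") -> "Partition":
        """Parse 1-based inclusive ranges like ``"1-85"`` or ``"1-10,20-30"``."""
        sites: set[int] = set()
        for chunk in str(ranges).split(","):
            chunk = chunk.strip()
            m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", chunk)
            if m:
                a, b = int(m.group(1)), int(m.group(2))
                if b < a:
                    raise ValueError(f"inverted range {chunk!r} in partition {name!r}")
                sites.update(range(a, b + 1))
            elif chunk.isdigit():
                sites.add(int(chunk))
            else:
                raise ValueError(f"cannot parse range {chunk!r} in partition {name!r}")
        return cls(name, frozenset(sites), category)


def parse_partition_config(source: str | Path | dict) -> list[Partition]:
    """Read partitions from YAML (name -> {category, ranges}) or TSV rows.

    TSV rows are ``name<TAB>category<TAB>ranges``. Duplicate names are
    rejected.
    """
    if isinstance(source, dict):
        entries = source
    else:
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        if "\t" in text.splitlines()[0] if text.splitlines() else False:
            entries = {}
            for line in text.splitlines():
                if not line.strip() or line.startswith("#"):
                    continue
                name, category, ranges = line.split("\t")[:3]
                if name in entries:
                    raise ValueError(f"duplicate partition name {name!r}")
                entries[name] = {"category": category, "ranges": ranges}
        else:
            entries = yaml.safe_load(text)
    parts: list[Partition] = []
    seen: set[str] = set()
    for name, spec in entries.items():
        if name in seen:
            raise ValueError(f"duplicate partition name {name!r}")
        seen.add(name)
        if isinstance(spec, dict):
            parts.append(
                Partition.from_ranges(name, spec["ranges"], spec.get("category", "region"))
            )
        else:
            parts.append(Partition.from_ranges(name, spec))
    return parts


@dataclass
class PartitionResult:
    """Aggregate omega-bar for one partition, with profile interval."""

    name: str
    category: str
    omega_bar: float
    ci_lower: float
    ci_upper: float
    log_likelihood: float
    n_sites_used: int
    # carried for comparisons; columns are alignment codon columns
    _ctx: FELContext | None = None
    _cols: np.ndarray | None = None


class _PartitionFitter:
    """Shared machinery mapping partitions onto usable alignment columns."""

    def __init__(
        self,
        fit: GlobalFit,
        ref_map: ReferenceColumnMap | None = None,
        scan: FELScan | None = None,
    ):
        self.ctx = FELContext.from_global_fit(fit)
        self.ref_map = ref_map
        self.scan = scan
        if scan is not None:
            self.excluded = set(scan.undefined_sites())
        else:
            self.excluded = self._invariant_sites()

    def _invariant_sites(self) -> set[int]:
        """Reference sites whose observed states are all identical.

        Exactly the alpha-hat = beta-hat = 0 (undefined 0/0) case; used
        when no FEL scan is supplied. Infinite-omega sites can only be
        recognized from a scan, which the pipeline always provides.
        """
        out: set[int] = set()
        for col, ref in self._all_pairs():
            colstates = self.ctx.states[:, col]
            obs = colstates[colstates >= 0]
            if obs.size == 0 or np.all(obs == obs[0]):
                out.add(ref)
        return out

    def _all_pairs(self) -> list[tuple[int, int]]:
        if self.ref_map is None:
            return [(c, c + 1) for c in range(self.ctx.states.shape[1])]
        return [(c, self.ref_map.column_to_ref[c]) for c in self.ref_map.mapped_columns()]

    def columns_for(self, partition: Partition) -> np.ndarray:
        ref_to_col = (
            {r: c for c, r in self._all_pairs()}
        )
        unknown = sorted(s for s in partition.sites if s not in ref_to_col)
        if unknown:
            raise ValueError(
                f"partition {partition.name!r} references unmapped codons: {unknown[:10]}"
            )
        usable = sorted(s for s in partition.sites if s not in self.excluded)
        if not usable:
            raise ValueError(
                f"partition {partition.name!r} has no usable sites after excluding "
                "undefined-omega (invariant) codons"
            )
        return np.array([ref_to_col[s] for s in usable])


def _maximize_omega(ctx: FELContext, cols: np.ndarray) -> tuple[float, float]:
    """(omega_bar, logL) maximizing the profiled likelihood over a column set."""

    def neg(logw: float) -> float:
        return -ctx.profile(cols, float(np.exp(logw)))[0]

    r = minimize_scalar(
        neg, bounds=(np.log(1e-6), np.log(OMEGA_CAP)), method="bounded",
        options={"xatol": 1e-5},
    )
    w = float(np.exp(r.x))
    ll, _ = ctx.profile(cols, w)
    ll0, _ = ctx.profile(cols, 0.0)
    if ll0 >= ll:
        return 0.0, ll0
    return w, ll


def fit_aggregate_omega(
    fit: GlobalFit,
    partition: Partition,
    *,
    ref_map: ReferenceColumnMap | None = None,
    scan: FELScan | None = None,
    ci_level: float = 0.95,
    _fitter: "_PartitionFitter | None" = None,
) -> PartitionResult:
    """Single omega-bar over the partition's usable sites, nuisance fixed."""
    fitter = _fitter or _PartitionFitter(fit, ref_map, scan)
    cols = fitter.columns_for(partition)
    w, ll = _maximize_omega(fitter.ctx, cols)
    lo, hi = profile_confidence_interval(fitter.ctx, cols, ll, w, level=ci_level)
    return PartitionResult(
        partition.name, partition.category, w, lo, hi, ll, len(cols), fitter.ctx, cols
    )


def fit_all_partitions(
    fit: GlobalFit,
    partitions: list[Partition],
    *,
    ref_map: ReferenceColumnMap | None = None,
    scan: FELScan | None = None,
    ci_level: float = 0.95,
) -> list[PartitionResult]:
    names = [p.name for p in partitions]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate partition names: {dupes}")
    fitter = _PartitionFitter(fit, ref_map, scan)
    return [
        fit_aggregate_omega(fit, p, ci_level=ci_level, _fitter=fitter) for p in partitions
    ]


@dataclass
class ComparisonResult:
    """One-df LRT between two aggregate fits; arrow points at ``higher``."""

    name_a: str
    name_b: str
    lrt: float
    p_value: float
    higher: str


def compare_aggregate(fit_a: PartitionResult, fit_b: PartitionResult) -> ComparisonResult:
    """Joint (shared omega-bar) versus separate fits, chi-square 1 df.

    Works within one alignment (disjoint partitions) or across genes
    (each side keeps its own tree, frequencies and rate scale; only
    omega-bar is shared under the null).
    """
    if fit_a._ctx is None or fit_b._ctx is None or fit_a._cols is None or fit_b._cols is None:
        raise ValueError("comparison needs PartitionResults produced by fit_aggregate_omega")
    if fit_a._ctx is fit_b._ctx or fit_a._ctx.states is fit_b._ctx.states:
        shared = set(fit_a._cols) & set(fit_b._cols)
        if shared:
            raise ValueError(
                f"partitions {fit_a.name!r} and {fit_b.name!r} overlap at alignment "
                f"columns {sorted(shared)[:10]}"
            )

    def neg_null(logw: float) -> float:
        w = float(np.exp(logw))
        la, _ = fit_a._ctx.profile(fit_a._cols, w)
        lb, _ = fit_b._ctx.profile(fit_b._cols, w)
        return -(la + lb)

    r = minimize_scalar(
        neg_null, bounds=(np.log(1e-6), np.log(OMEGA_CAP)), method="bounded",
        options={"xatol": 1e-5},
    )
    ll_null = -float(r.fun)
    # guard the 1-D search with the two separate optima as candidates
    for w_cand in (fit_a.omega_bar, fit_b.omega_bar):
        ll_null = max(ll_null, -neg_null(np.log(np.clip(w_cand, 1e-6, OMEGA_CAP))))
    ll_alt = fit_a.log_likelihood + fit_b.log_likelihood
    lrt = max(0.0, 2.0 * (ll_alt - ll_null))
    p = float(chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    if fit_a.omega_bar == fit_b.omega_bar:
        higher = min(fit_a.name, fit_b.name)
    else:
        higher = fit_a.name if fit_a.omega_bar > fit_b.omega_bar else fit_b.name
    return ComparisonResult(fit_a.name, fit_b.name, lrt, p, higher)


def compare_all(results: list[PartitionResult]) -> list[ComparisonResult]:
    out = []
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            out.append(compare_aggregate(results[i], results[j]))
    return out


@dataclass
class HasseDiagram:
    """Transitively reduced digraph of significant omega-bar inequalities."""

    nodes: list[tuple[str, float]]  # (name, omega_bar) sorted ascending
    edges: list[tuple[str, str]]  # lower -> higher
    alpha: float

    def to_dot(self) -> str:
        lines = ["digraph hasse {"]
        for name, w in self.nodes:
            lines.append(f'  "{name}" [label="{name}\\nw={w:.4g}"];')
        for a, b in self.edges:
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines)

    def to_edge_rows(self) -> list[dict]:
        return [{"lower": a, "higher": b} for a, b in self.edges]


def build_hasse(
    results: list[PartitionResult],
    comparisons: list[ComparisonResult],
    alpha: float = 0.05,
) -> HasseDiagram:
    """Edges for every significant pair (lower omega-bar -> higher), then
    transitive reduction; node order is deterministic by (omega_bar, name)."""
    names = {r.name for r in results}
    by_pair = {}
    for c in comparisons:
        by_pair[frozenset((c.name_a, c.name_b))] = c
    missing = [
        (a, b)
        for a in sorted(names)
        for b in sorted(names)
        if a < b and frozenset((a, b)) not in by_pair
    ]
    if missing:
        raise ValueError(f"comparisons missing for pairs: {missing[:10]}")

    omega = {r.name: r.omega_bar for r in results}
    g = nx.DiGraph()
    for r in sorted(results, key=lambda r: (r.omega_bar, r.name)):
        g.add_node(r.name)
    for key, c in sorted(by_pair.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(key)
        if {a, b} <= names and c.p_value <= alpha:
            lower = a if c.higher == b else b
            g.add_edge(lower, c.higher)
    if not nx.is_directed_acyclic_graph(g):  # unreachable for strict numeric order
        raise RuntimeError("significant inequalities form a cycle")
    red = nx.transitive_reduction(g)
    nodes = sorted(((n, omega[n]) for n in g.nodes), key=lambda t: (t[1], t[0]))
    edges = sorted(red.edges, key=lambda e: (omega[e[0]], e[0], omega[e[1]], e[1]))
    return HasseDiagram(nodes, list(edges), alpha)
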