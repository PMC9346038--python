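"""End-to-end analysis runs with bit-stable report files.

Stages: optional curation -> tree (user Newick or NJ fallback) -> global
MG94xREV fit -> per-site FEL scan -> partition aggregate fits -> pairwise
comparisons -> Hasse diagram. Numbers are serialized with fixed formats
(rates to 6 significant digits, p-values in 3-digit scientific notation,
infinite bounds as "inf", undefined omega as "NA") so identical inputs
give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .curation import ProteinRecord, curate, curation_report, load_panel_fasta
from .fel import FELScan, fel_scan
from .fitting import fit_global_model
from .io import CodonAlignment, map_alignment_to_reference
from .partition import (
    Partition,
    build_hasse,
    compare_all,
    fit_all_partitions,
    parse_partition_config,
)
from .trees import PhyloTree, codon_p_distance, nj_tree


@dataclass
class RunConfig:
    """Inputs and thresholds of a full analysis run."""

    alignment: str
    tree: str = "nj"  # path to Newick, or "nj" for the built-in fallback
    reference: str | None = None
    partitions: str | None = None
    sites_of_interest: str | None = None
    curation_panel: str | None = None
    curation_candidates: str | None = None
    p_site: float = 0.1
    alpha_hasse: float = 0.05
    identity_min: float = 50.0
    similarity_min: float = 60.0
    ci_level: float = 0.95
    seed: int = 0
    outdir: str = "codonsel_run"
    mask_stops: bool = False
    compute_ci: bool = True

    def validate(self) -> None:
        if not Path(self.alignment).exists():
            raise FileNotFoundError(f"alignment file not found: {self.alignment}")
        if self.tree != "nj" and not Path(self.tree).exists():
            raise FileNotFoundError(f"tree file not found: {self.tree}")
        for name, p in (
            ("partitions", self.partitions),
            ("sites_of_interest", self.sites_of_interest),
            ("curation_panel", self.curation_panel),
            ("curation_candidates", self.curation_candidates),
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if not (0 < self.p_site <= 1 and 0 < self.alpha_hasse <= 1):
            raise ValueError("p_site and alpha_hasse must be in (0, 1]")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")
        if self.identity_min < 0 or self.similarity_min < 0:
            raise ValueError("identity/similarity thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# -- serialization helpers --------------------------------------------------


def _fmt_rate(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    if math.isinf(x):
        return "inf"
    return f"{x:.6g}"


def _fmt_p(x: float) -> str:
    return f"{x:.3e}"


def site_results_table(scan: FELScan) -> pd.DataFrame:
    df = scan.to_dataframe()
    out = pd.DataFrame(
        {
            "site": df["site"],
            "alpha": df["alpha"].map(_fmt_rate),
            "beta": df["beta"].map(_fmt_rate),
            "omega": df["omega"].map(_fmt_rate),
            "omega_status": df["omega_status"],
            "ci_lower": df["ci_lower"].map(_fmt_rate),
            "ci_upper": df["ci_upper"].map(_fmt_rate),
            "lrt": df["lrt"].map(_fmt_rate),
            "p_value": df["p_value"].map(_fmt_p),
            "class": df["class"],
        }
    )
    return out


def summarize_classes(scan: FELScan) -> dict[str, str]:
    """Per-class "n/N; x.x%" fractions over all mapped reference codons."""
    total = len(scan.results)
    out = {}
    for cls in ("purifying", "neutral", "diversifying", "undefined"):
        n = scan.counts.get(cls, 0)
        if total == 0:
            out[cls] = "0/0; —"
        else:
            out[cls] = f"{n}/{total}; {100.0 * n / total:.1f}%"
    return out


def report_sites_of_interest(
    scan: FELScan, sites: pd.DataFrame, omega_flag: float = 0.05
) -> pd.DataFrame:
    """Join labelled sites (columns: site, label, phenotype) with FEL
    results; omega below ``omega_flag`` is flagged as strongly purified."""
    by_site = {r.site: r for r in scan.results}
    bad = [int(s) for s in sites["site"] if int(s) not in by_site]
    if bad:
        raise ValueError(f"sites of interest out of range: {bad}")
    rows = []
    for _, row in sites.iterrows():
        r = by_site[int(row["site"])]
        rows.append(
            {
                "site": r.site,
                "label": row.get("label", ""),
                "phenotype": row.get("phenotype", ""),
                "omega": _fmt_rate(r.omega),
                "ci_lower": _fmt_rate(r.ci_lower),
                "ci_upper": _fmt_rate(r.ci_upper),
                "class": r.cls,
                "flag": f"<{omega_flag:g}" if r.omega < omega_flag else "",
            }
        )
    cols = ["site", "label", "phenotype", "omega", "ci_lower", "ci_upper", "class", "flag"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class RunResult:
    outdir: Path
    scan: FELScan
    partition_results: list = field(default_factory=list)
    comparisons: list = field(default_factory=list)
    hasse: object | None = None
    log_lines: list[str] = field(default_factory=list)


def run_full_analysis(config: RunConfig) -> RunResult:
    """Execute every configured stage and write the report directory."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"codonsel {__version__}",
        f"seed={config.seed}",
        f"thresholds: p_site={config.p_site} alpha_hasse={config.alpha_hasse} "
        f"identity_min={config.identity_min} similarity_min={config.similarity_min} "
        f"ci_level={config.ci_level}",
        f"config: {config}",
    ]

    try:
        if config.curation_candidates and config.curation_panel:
            panel = load_panel_fasta(config.curation_panel)
            from Bio import SeqIO

            cands = [
                ProteinRecord(r.id, str(r.seq).upper())
                for r in SeqIO.parse(config.curation_candidates, "fasta")
            ]
            reference = panel[0][1]
            records, _ = curate(
                cands, reference, panel,
                identity_min=config.identity_min, similarity_min=config.similarity_min,
            )
            rep = curation_report(records)
            rep["identity"] = rep["identity"].map(_fmt_rate)
            rep["similarity"] = rep["similarity"].map(_fmt_rate)
            rep.to_csv(out / "curation_report.tsv", sep="\t", index=False)
            log.append(f"curation: {int(sum(r.included for r in records))}/{len(records)} included")
    except Exception as err:
        raise RuntimeError(f"stage curation failed: {err}") from err

    try:
        alignment = CodonAlignment.from_fasta(config.alignment, reference=config.reference)
        if alignment.reference is None:
            alignment.reference = alignment.taxa[0]
        ref_map = map_alignment_to_reference(alignment)
        if config.tree == "nj":
            enc = alignment.encode(mask_stops=config.mask_stops)
            tree = nj_tree(codon_p_distance(enc), alignment.taxa)
            log.append("tree: NJ fallback from codon p-distances")
        else:
            tree = PhyloTree.from_newick(config.tree)
            log.append(f"tree: {config.tree}")
    except Exception as err:
        raise RuntimeError(f"stage input failed: {err}") from err

    try:
        fit = fit_global_model(alignment, tree, mask_stops=config.mask_stops)
        log.append(
            f"global fit: logL={fit.log_likelihood:.6f} omega={fit.params.omega:.6g} "
            f"converged={fit.converged}"
        )
    except Exception as err:
        raise RuntimeError(f"stage global_fit failed: {err}") from err

    try:
        scan = fel_scan(
            fit, ref_map, p_threshold=config.p_site, ci_level=config.ci_level,
            compute_ci=config.compute_ci,
        )
        site_results_table(scan).to_csv(out / "site_results.tsv", sep="\t", index=False)
        for cls, frac in summarize_classes(scan).items():
            log.append(f"class {cls}: {frac}")
    except Exception as err:
        raise RuntimeError(f"stage fel_scan failed: {err}") from err

    presults, comps, hasse = [], [], None
    if config.partitions:
        try:
            parts = parse_partition_config(config.partitions)
            parts = list(parts) + [
                Partition("FL", frozenset(range(1, ref_map.reference_length + 1)), "full_length")
            ]
            presults = fit_all_partitions(
                fit, parts, ref_map=ref_map, scan=scan, ci_level=config.ci_level
            )
            pd.DataFrame(
                {
                    "name": [r.name for r in presults],
                    "category": [r.category for r in presults],
                    "omega_bar": [_fmt_rate(r.omega_bar) for r in presults],
                    "ci_lower": [_fmt_rate(r.ci_lower) for r in presults],
                    "ci_upper": [_fmt_rate(r.ci_upper) for r in presults],
                    "n_sites_used": [r.n_sites_used for r in presults],
                }
            ).to_csv(out / "partition_report.tsv", sep="\t", index=False)
            comparable = [r for r in presults if r.category != "full_length"]
            comps = compare_all(comparable)
            pd.DataFrame(
                {
                    "a": [c.name_a for c in comps],
                    "b": [c.name_b for c in comps],
                    "lrt": [_fmt_rate(c.lrt) for c in comps],
                    "p_value": [_fmt_p(c.p_value) for c in comps],
                    "higher": [c.higher for c in comps],
                }
            ).to_csv(out / "comparisons.tsv", sep="\t", index=False)
            hasse = build_hasse(comparable, comps, alpha=config.alpha_hasse)
            (out / "hasse.dot").write_text(hasse.to_dot() + "\n")
            pd.DataFrame(hasse.to_edge_rows(), columns=["lower", "higher"]).to_csv(
                out / "hasse_edges.tsv", sep="\t", index=False
            )
            log.append(f"hasse: {len(hasse.edges)} edges at alpha={config.alpha_hasse}")
        except Exception as err:
            raise RuntimeError(f"stage partitions failed: {err}") from err

    if config.sites_of_interest:
        try:
            sites = pd.read_csv(config.sites_of_interest, sep="\t")
            report_sites_of_interest(scan, sites).to_csv(
                out / "sites_of_interest.tsv", sep="\t", index=False
            )
        except Exception as err:
            raise RuntimeError(f"stage sites_of_interest failed: {err}") from err

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return RunResult(out, scan, presults, comps, hasse, log)
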