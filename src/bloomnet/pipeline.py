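"""End-to-end pipeline: preprocess -> EI -> network -> topology -> roles ->
comparison, driven by one config and one master seed, with every artifact
written as tab-separated text and hash-recorded in a run manifest.

Identical config + seed reruns produce byte-identical outputs: all floats are
written with fixed formats, orderings are lexicographic, and every random
stage derives its own sub-seed from the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import OtuTable, read_metadata_table, read_otu_table, write_network_files, write_otu_table
from .preprocess import alpha_diversity_table, prevalence_filter, rarefy, relative_abundance
from .rmt import RmtScanConfig, build_network, correlation_input, pearson_matrix, scan_rmt_threshold
from .stats import distance_matrix, mrpp, permanova, single_factor_screen, taxon_wise_comparison
from .synthetic import CommunityParams, generate_env_table, generate_planted_community, write_ground_truth
from .topology import classify_roles, ego_subnetwork, fast_greedy_partition, null_distribution, topology_summary, zi_pi
from .water import ei_table

__all__ = ["PipelineConfig", "run_pipeline", "compare_fractions", "run_network_stage"]

_ENV_SCREEN_VARIABLES = [
    "T", "DO", "pH", "turbidity", "suspended_particles",
    "NO3_N", "NO2_N", "NH4_N", "TN", "EI",
    "bacterial_density", "algal_density",
]


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from a YAML key-value file."""

    # inputs: either file paths or simulation
    otu_table: str | None = None
    metadata: str | None = None
    simulate: bool = False
    community: CommunityParams = field(default_factory=CommunityParams)
    # preprocessing
    rarefaction_depth: int | None = None      # None = shallowest sample
    min_prevalence: int = 8
    # network
    transform: str = "clr"
    pseudocount: float = 0.5
    scan: RmtScanConfig = field(default_factory=RmtScanConfig)
    threshold: float | None = None            # override: skip RMT selection
    # nulls, roles, tests
    n_null: int = 100
    zi_cut: float = 2.5
    pi_cut: float = 0.62
    n_permutations: int = 999
    focal_otu: str | None = None
    # bookkeeping
    outdir: str = "bloomnet_out"
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        community = CommunityParams(**raw.pop("community", {}))
        scan = RmtScanConfig(**raw.pop("scan", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(community=community, scan=scan, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(
                f"{v:.6g}" if isinstance(v, float) else str(v) for v in row
            ) + "\n")


def run_network_stage(table: OtuTable, config: PipelineConfig):
    """Correlation, threshold scan and network construction for one table.

    The transform (CLR by default) is computed on the full table so the
    centering reference is the whole community; the prevalence filter then
    selects which OTU rows enter the correlation matrix.
    """
    x_full = correlation_input(table, config.transform, config.pseudocount)
    filtered = prevalence_filter(table, config.min_prevalence)
    pos = {o: i for i, o in enumerate(table.otu_ids)}
    x = x_full[[pos[o] for o in filtered.otu_ids]]
    corr = pearson_matrix(x, filtered.otu_ids)
    scan = scan_rmt_threshold(corr, config.scan)
    threshold = config.threshold if config.threshold is not None else scan.selected_threshold
    net = None
    if threshold is not None:
        net = build_network(corr, threshold, taxonomy=table.taxonomy)
    return filtered, corr, scan, threshold, net


def _topology_block(net, config: PipelineConfig, seed: int):
    net.partition, _ = fast_greedy_partition(net)
    summary = topology_summary(net)
    null = null_distribution(net, config.n_null, seed)
    roles = classify_roles(zi_pi(net), config.zi_cut, config.pi_cut)
    return summary, null, roles


def _topology_rows(label: str, s, null) -> list[list]:
    return [
        [label, "No. of node", str(s.n_nodes)],
        [label, "No. of link", str(s.n_links)],
        [label, "Positive links (%)", f"{100 * s.positive_link_fraction:.1f}"],
        [label, "Modularity (no. of modules)", f"{s.modularity:.3f} ({s.n_modules})"],
        [label, "Avg connectivity (avgK)", f"{s.avg_k:.3f}"],
        [label, "Avg geodesic distance (GD)", f"{s.gd:.3f}"],
        [label, "Avg clustering coefficient (avgCC)", f"{s.avg_cc:.3f}"],
        [label, "Random Avg Modularity (M)", f"{null.modularity_mean:.3f} ± {null.modularity_sd:.3f}"],
        [label, "Random Avg geodesic distance (GD)", f"{null.gd_mean:.3f} ± {null.gd_sd:.3f}"],
        [label, "Random Avg clustering coefficient (avgCC)", f"{null.avg_cc_mean:.3f} ± {null.avg_cc_sd:.3f}"],
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sub_seed = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    artifacts: list[Path] = []

    # --- inputs
    if config.simulate:
        community = generate_planted_community(
            dataclasses.replace(config.community, seed=sub_seed())
        )
        table = community.counts
        records = generate_env_table(community, seed=sub_seed())
        write_otu_table(table, out / "otu_table.tsv")
        write_ground_truth(community, out / "planted_modules.tsv")
        _write_metadata(records, out / "metadata.tsv")
        artifacts += [out / "otu_table.tsv", out / "planted_modules.tsv", out / "metadata.tsv"]
    else:
        if not config.otu_table:
            raise ValueError("either simulate: true or an otu_table path is required")
        table = read_otu_table(config.otu_table)
        records = read_metadata_table(config.metadata) if config.metadata else []

    # --- preprocessing
    depth = config.rarefaction_depth or int(table.sample_sums().min())
    rarefied = rarefy(table, depth, sub_seed())
    write_otu_table(rarefied, out / "rarefied.tsv")
    artifacts.append(out / "rarefied.tsv")

    alpha = alpha_diversity_table(rarefied)
    _write_tsv(out / "alpha_diversity.tsv",
               ["sample_id", "shannon", "chao1", "goods_coverage", "observed_otus"],
               [[s, f"{a.shannon:.4f}", f"{a.chao1:.2f}", f"{a.goods_coverage:.4f}",
                 str(a.observed_otus)] for s, a in alpha.items()])
    artifacts.append(out / "alpha_diversity.tsv")

    # --- eutrophication index
    if records:
        eis = ei_table(records)
        _write_tsv(out / "eutrophication_index.tsv",
                   ["sample_id", "DIN", "DIP", "COD", "EI", "substitutions"],
                   [[e.sample_id, f"{e.din:.4f}", f"{e.dip:.4f}", f"{e.cod:.4f}",
                     f"{e.ei:.2f}",
                     ";".join(f"{v}<{lim}" for v, lim in e.substitutions_applied) or "-"]
                    for e in eis])
        artifacts.append(out / "eutrophication_index.tsv")

    # --- network
    filtered, corr, scan, threshold, net = run_network_stage(rarefied, config)
    write_otu_table(filtered, out / "filtered.tsv")
    _write_tsv(out / "threshold_scan.tsv",
               ["threshold", "n_nodes", "n_eigenvalues", "chi_square", "p_value", "poisson"],
               [[f"{c.threshold:.2f}", str(c.n_nodes), str(c.n_eigenvalues),
                 f"{c.chi_square:.3f}", f"{c.p_value:.4f}", str(c.is_poisson)]
                for c in scan.candidates])
    artifacts += [out / "filtered.tsv", out / "threshold_scan.tsv"]

    manifest: dict = {
        "bloomnet_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "rarefaction_depth": depth,
        "selected_threshold": threshold,
        "selection_note": scan.selection_rule_note,
    }

    if net is not None and net.n_nodes > 0:
        summary, null, roles = _topology_block(net, config, sub_seed())
        _write_tsv(out / "topology.tsv", ["network", "property", "value"],
                   _topology_rows("empirical", summary, null))
        write_network_files(net, roles, out / "edges.tsv", out / "nodes.tsv")
        artifacts += [out / "topology.tsv", out / "edges.tsv", out / "nodes.tsv"]

        focal = config.focal_otu
        if focal and focal in net.graph:
            ego = ego_subnetwork(net, focal)
            _write_tsv(out / "ego_network.tsv",
                       ["focal", "neighbor", "correlation", "sign"],
                       [[ego.focal, nb, f"{r:.4f}", sign] for nb, r, sign in ego.neighbors])
            artifacts.append(out / "ego_network.tsv")
            manifest["ego"] = {"focal": focal, "positive": ego.n_positive,
                               "negative": ego.n_negative}

    # --- environmental screening (one variable at a time, both metrics)
    if records:
        rel = relative_abundance(filtered)
        rows = []
        from .water import compute_ei

        values_by_var: dict[str, list[float]] = {}
        order = {r.sample_id: r for r in records}
        samples = [s for s in filtered.sample_ids if s in order]
        if len(samples) == len(filtered.sample_ids) and samples:
            for var in _ENV_SCREEN_VARIABLES:
                vals = []
                for s in samples:
                    rec = order[s]
                    if var == "EI":
                        vals.append(compute_ei(rec).ei)
                    else:
                        v = getattr(rec, var)
                        if v is None:
                            vals = []
                            break
                        vals.append(v.limit if hasattr(v, "limit") else float(v))
                if vals:
                    values_by_var[var] = vals
            for metric in ("bray_curtis", "euclidean"):
                mat = rel if metric == "bray_curtis" else filtered.counts.astype(float)
                dist = distance_matrix(mat, filtered.sample_ids, metric)
                for var, vals in values_by_var.items():
                    if np.ptp(vals) == 0:
                        continue
                    res = single_factor_screen(dist, vals, config.n_permutations, sub_seed())
                    stars = "**" if res.p_value < 0.01 else ("*" if res.p_value < 0.05 else "")
                    rows.append([var, metric, f"{res.statistic:.2f}", f"{res.p_value:.4f}", stars])
            _write_tsv(out / "screening.tsv",
                       ["factor", "metric", "pseudo_F", "p_value", "significance"], rows)
            artifacts.append(out / "screening.tsv")

    manifest["artifacts"] = {p.name: _sha256(p) for p in sorted(artifacts)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _write_metadata(records, path: Path) -> None:
    header = ["sample_id", "T", "DO", "pH", "turbidity", "suspended_particles",
              "NO3_N", "NO2_N", "NH4_N", "TN", "PO4_P", "COD",
              "bacterial_density", "algal_density"]
    rows = []
    for r in records:
        row = [r.sample_id]
        for name in header[1:]:
            v = getattr(r, name)
            row.append(f"<{v.limit}" if hasattr(v, "limit") else f"{float(v):.4f}")
        rows.append(row)
    _write_tsv(path, header, rows)


def compare_fractions(table_a: OtuTable, table_b: OtuTable, config: PipelineConfig,
                      labels: tuple[str, str] = ("A", "B"), outdir: str | Path | None = None) -> dict:
    """Side-by-side network comparison of two community fractions.

    Runs the network stage independently on each table, reports the topology
    panel side by side, and compares whole-community structure between the
    fractions with PERMANOVA and MRPP on the pooled Bray-Curtis matrix (the
    two tables must share their sample grid, e.g. two filter fractions of the
    same field samples).
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sub_seed = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    rows = []
    result: dict = {"labels": labels}
    for label, table in zip(labels, (table_a, table_b)):
        filtered, corr, scan, threshold, net = run_network_stage(table, config)
        if net is None or net.n_nodes == 0:
            rows.append([label, "selected threshold", "none found"])
            continue
        summary, null, _ = _topology_block(net, config, sub_seed())
        rows.append([label, "selected threshold", f"{threshold:.2f}"])
        rows += _topology_rows(label, summary, null)
        result[label] = {"threshold": threshold, "n_nodes": summary.n_nodes,
                         "n_links": summary.n_links, "modularity": summary.modularity}
    _write_tsv(out / "fraction_topology.tsv", ["fraction", "property", "value"], rows)

    # whole-community contrast on the pooled sample set
    shared = sorted(set(table_a.otu_ids) & set(table_b.otu_ids))
    if shared and table_a.n_samples >= 2 and table_b.n_samples >= 2:
        a = table_a.select_otus(shared)
        b = table_b.select_otus(shared)
        rel = np.hstack([relative_abundance(a), relative_abundance(b)])
        ids = [f"{labels[0]}:{s}" for s in a.sample_ids] + [f"{labels[1]}:{s}" for s in b.sample_ids]
        groups = [labels[0]] * a.n_samples + [labels[1]] * b.n_samples
        dist = distance_matrix(rel, ids, "bray_curtis")
        ad = permanova(dist, groups, config.n_permutations, sub_seed())
        mr = mrpp(dist, groups, config.n_permutations, sub_seed())
        result["adonis"] = {"pseudo_F": ad.statistic, "R2": ad.effect, "p": ad.p_value}
        result["mrpp"] = {"delta": mr.statistic, "A": mr.effect, "p": mr.p_value}
        taxa = taxon_wise_comparison(a, b)
        result["taxa_higher_in_A"] = sum(t.significant_raw and t.direction == "higher in A" for t in taxa)
        result["taxa_lower_in_A"] = sum(t.significant_raw and t.direction == "lower in A" for t in taxa)
        _write_tsv(out / "fraction_tests.tsv", ["test", "statistic", "value", "p_value"],
                   [["adonis", "pseudo-F", f"{ad.statistic:.3f}", f"{ad.p_value:.4f}"],
                    ["adonis", "R2", f"{ad.effect:.3f}", f"{ad.p_value:.4f}"],
                    ["mrpp", "delta", f"{mr.statistic:.3f}", f"{mr.p_value:.4f}"],
                    ["mrpp", "A", f"{mr.effect:.3f}", f"{mr.p_value:.4f}"]])
    return result
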