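"""End-to-end pipeline: expression -> DEGs -> diseasome -> enrichment ->
network analysis -> gene-disease association, driven by a YAML config.

Every stage writes its artifacts under the output directory and the run ends
with a ``manifest.json`` recording parameters, summary counts and the sha256
of every written file; identical config and inputs yield byte-identical
outputs (no timestamps, sorted iteration everywhere).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from diseasomics import __version__
from diseasomics.dataio import (
    DataError,
    read_edge_list,
    read_expression,
    read_gene_list,
    read_gmt,
    read_probe_map,
    write_network,
)
from diseasomics.deg import DEGSet, call_degs
from diseasomics.diseasome import build_diseasome, multiway_shared, pairwise_summary
from diseasomics.enrichment import associate_batch, enrich, results_to_frame
from diseasomics.netanalysis import (
    drug_interactions,
    induce_subnetwork,
    rank_hubs,
    rank_regulators,
)
from diseasomics.preprocess import collapse_probes, log2_transform

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when the pipeline configuration is invalid."""


@dataclass
class PipelineConfig:
    target: str
    conditions: dict[str, dict[str, Path]]  # id -> {"expression": ..., "groups": ...}
    out_dir: Path
    alpha: float = 0.05
    lfc: float = 1.0
    log2_offset: float = 1.0
    collapse_method: str = "max_abs_t"
    direction_consistent: bool = True
    neighbor_expansion: bool = False
    ppi: Path | None = None
    ppi_threshold: float = 0.4
    libraries: list[Path] = field(default_factory=list)
    tf_targets: Path | None = None
    mirna_targets: Path | None = None
    drug_targets: Path | None = None
    disease_genes: Path | None = None
    probe_maps: dict[str, Path] = field(default_factory=dict)
    hub_k: int = 10
    regulator_top_n: int = 5
    min_conditions: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.target not in self.conditions:
            raise ConfigError(f"target {self.target!r} missing from conditions")
        if len(self.conditions) < 2:
            raise ConfigError("need the target plus at least one risk-factor condition")
        if self.alpha <= 0 or self.lfc < 0:
            raise ConfigError("thresholds must be positive")
        for cond, paths in self.conditions.items():
            for key in ("expression", "groups"):
                if key not in paths:
                    raise ConfigError(f"condition {cond!r} lacks a {key!r} path")
                if not Path(paths[key]).exists():
                    raise ConfigError(f"condition {cond!r}: {key} file {paths[key]} not found")
        for label, p in [
            ("ppi", self.ppi),
            ("tf_targets", self.tf_targets),
            ("mirna_targets", self.mirna_targets),
            ("drug_targets", self.drug_targets),
            ("disease_genes", self.disease_genes),
        ]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{label} file {p} not found")
        for lib in self.libraries:
            if not Path(lib).exists():
                raise ConfigError(f"library file {lib} not found")
        for cond, p in self.probe_maps.items():
            if not Path(p).exists():
                raise ConfigError(f"probe map for {cond!r} ({p}) not found")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; relative paths resolve against the file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    base = path.parent

    def resolve(p):
        return None if p is None else (base / p)

    try:
        conditions = {
            str(cond): {k: base / v for k, v in spec.items()}
            for cond, spec in raw["conditions"].items()
        }
        cfg = PipelineConfig(
            target=str(raw["target"]),
            conditions=conditions,
            out_dir=base / raw.get("out_dir", "results"),
            alpha=float(raw.get("alpha", 0.05)),
            lfc=float(raw.get("lfc", 1.0)),
            log2_offset=float(raw.get("log2_offset", 1.0)),
            collapse_method=str(raw.get("collapse_method", "max_abs_t")),
            direction_consistent=bool(raw.get("direction_consistent", True)),
            neighbor_expansion=bool(raw.get("neighbor_expansion", False)),
            ppi=resolve(raw.get("ppi")),
            ppi_threshold=float(raw.get("ppi_threshold", 0.4)),
            libraries=[base / p for p in raw.get("libraries", [])],
            tf_targets=resolve(raw.get("tf_targets")),
            mirna_targets=resolve(raw.get("mirna_targets")),
            drug_targets=resolve(raw.get("drug_targets")),
            disease_genes=resolve(raw.get("disease_genes")),
            probe_maps={c: base / p for c, p in raw.get("probe_maps", {}).items()},
            hub_k=int(raw.get("hub_k", 10)),
            regulator_top_n=int(raw.get("regulator_top_n", 5)),
            min_conditions=int(raw.get("min_conditions", 2)),
            seed=int(raw.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing required key {exc}") from exc
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_ranking_tsv(path: Path, rows: list[tuple], header: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def prepare_condition(cfg: PipelineConfig, cond: str) -> DEGSet:
    """Read, collapse (if needed), log2-transform and DEG-call one condition."""
    paths = cfg.conditions[cond]
    M = read_expression(paths["expression"], paths["groups"], condition_id=cond)
    if cond in cfg.probe_maps:
        M = collapse_probes(M, read_probe_map(cfg.probe_maps[cond]), method=cfg.collapse_method)
    elif M.needs_collapse:
        M = collapse_probes(M, method=cfg.collapse_method)
    M = log2_transform(M, offset=cfg.log2_offset)
    return call_degs(M, alpha=cfg.alpha, lfc=cfg.lfc)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    counts: dict = {}

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    # --- stage 1: DEG calling per condition --------------------------------
    deg_dir = out / "degs"
    deg_dir.mkdir(exist_ok=True)
    degsets: dict[str, DEGSet] = {}
    for cond in sorted(cfg.conditions):
        try:
            ds = prepare_condition(cfg, cond)
        except (DataError, ValueError) as exc:
            raise RuntimeError(f"stage deg failed for condition {cond!r}: {exc}") from exc
        degsets[cond] = ds
        ds.write(emit(deg_dir / f"{cond}.tsv"))
    counts["degs"] = {
        c: {"up": len(d.up), "down": len(d.down), "degenerate": len(d.degenerate)}
        for c, d in degsets.items()
    }

    target = degsets[cfg.target]
    factors = [degsets[c] for c in sorted(cfg.conditions) if c != cfg.target]

    # --- stage 2: diseasome -------------------------------------------------
    dis_dir = out / "diseasome"
    dis_dir.mkdir(exist_ok=True)
    pairs = pairwise_summary(target, factors, cfg.direction_consistent)
    pairs.to_csv(emit(dis_dir / "pairs.tsv"), sep="\t", index=False, lineterminator="\n")
    shared_genes: set[str] = set()
    for col in ("shared_up", "shared_down"):
        for cell in pairs[col]:
            if cell:
                shared_genes.update(cell.split(","))
    for direction in ("up", "down"):
        net = build_diseasome(target, factors, direction, cfg.direction_consistent)
        for fmt in ("tsv", "sif", "graphml"):
            write_network(net, emit(dis_dir / f"diseasome_{direction}.{fmt}"), format=fmt)
    report = multiway_shared([target, *factors], min_conditions=cfg.min_conditions)
    report.to_frame().to_csv(
        emit(dis_dir / "multiway_shared.tsv"), sep="\t", index=False, lineterminator="\n"
    )
    counts["shared"] = {
        "pairwise": {r["factor"]: int(r["n_shared"]) for _, r in pairs.iterrows()},
        "distinct_shared_genes": len(shared_genes),
        "multiway_entries": len(report.entries),
    }

    measured = sorted(set().union(*(d.tested_genes for d in degsets.values())))

    # --- stage 3: enrichment -------------------------------------------------
    if cfg.libraries and shared_genes:
        enr_dir = out / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        counts["enrichment"] = {}
        for lib_path in sorted(cfg.libraries):
            lib = read_gmt(lib_path)
            universe = set(lib.universe) & set(measured) or set(lib.universe)
            results = enrich(shared_genes, lib, universe=universe)
            results_to_frame(results).to_csv(
                emit(enr_dir / f"{lib.name}.tsv"), sep="\t", index=False, lineterminator="\n"
            )
            counts["enrichment"][lib.name] = {
                "tested_terms": len(lib.sets),
                "significant": sum(r.p_adj < 0.05 for r in results),
                "top_term": results[0].term_id if results else None,
            }

    # --- stage 4: PPI hubs ---------------------------------------------------
    net_dir = out / "network"
    net_dir.mkdir(exist_ok=True)
    if cfg.ppi is not None and shared_genes:
        ppi = read_edge_list(cfg.ppi, kind="ppi_undirected", weight_threshold=cfg.ppi_threshold)
        sub = induce_subnetwork(ppi, shared_genes, neighbor_expansion=cfg.neighbor_expansion)
        if sub.n_edges:
            write_network(sub, emit(net_dir / "ppi_subnetwork.tsv"), format="tsv")
        hubs = rank_hubs(sub, k=cfg.hub_k) if sub.n_nodes else None
        if hubs is not None:
            _write_ranking_tsv(
                emit(net_dir / "hubs.tsv"),
                list(hubs.entries),
                ["protein", "degree", "rank"],
            )
            counts["hubs"] = {"top": hubs.nodes, "unmapped_query_genes": len(sub.meta["unmapped"])}

    # --- stage 5: regulators -------------------------------------------------
    for label, path in (("TF", cfg.tf_targets), ("miRNA", cfg.mirna_targets)):
        if path is None or not shared_genes:
            continue
        net = read_edge_list(path, kind="regulator_bipartite")
        ranking = rank_regulators(
            net, shared_genes, top_n=cfg.regulator_top_n, regulator_class=label
        )
        _write_ranking_tsv(
            emit(net_dir / f"regulators_{label.lower()}.tsv"),
            [(r, n, ",".join(sorted(t)), rank) for r, n, t, rank in ranking.entries],
            ["regulator", "n_deg_targets", "deg_targets", "rank"],
        )
        counts.setdefault("regulators", {})[label] = ranking.regulators

    # --- stage 6: drugs ------------------------------------------------------
    if cfg.drug_targets is not None and shared_genes:
        drug_net = read_edge_list(cfg.drug_targets, kind="drug_bipartite")
        hits = drug_interactions(drug_net, shared_genes)
        if hits.n_edges:
            write_network(hits, emit(net_dir / "drug_interactions.tsv"), format="tsv")
        counts["drugs"] = {
            "n_drugs": len(hits.nodes_of_class("drug")),
            "n_edges": hits.n_edges,
        }

    # --- stage 7: gene-disease association ----------------------------------
    if cfg.disease_genes is not None:
        disease = read_gene_list(cfg.disease_genes)
        queries = {d.condition_id: d.degs for d in factors if d.degs}
        if queries:
            results = associate_batch(queries, disease, measured)
            results_to_frame(results).rename(columns={"term_id": "factor"}).to_csv(
                emit(out / "association.tsv"), sep="\t", index=False, lineterminator="\n"
            )
            counts["association"] = {
                r.term_id: {"k": r.k, "p_adj": r.p_adj} for r in results
            }

    # --- manifest ------------------------------------------------------------
    manifest = {
        "version": __version__,
        "parameters": {
            "target": cfg.target,
            "conditions": sorted(cfg.conditions),
            "alpha": cfg.alpha,
            "lfc": cfg.lfc,
            "log2_offset": cfg.log2_offset,
            "collapse_method": cfg.collapse_method,
            "direction_consistent": cfg.direction_consistent,
            "neighbor_expansion": cfg.neighbor_expansion,
            "ppi_threshold": cfg.ppi_threshold,
            "hub_k": cfg.hub_k,
            "regulator_top_n": cfg.regulator_top_n,
            "min_conditions": cfg.min_conditions,
            "seed": cfg.seed,
        },
        "counts": counts,
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
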