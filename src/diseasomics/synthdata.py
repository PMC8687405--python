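"""Synthetic inputs with planted ground truth.

Generates everything the pipeline consumes — case/control expression
matrices with planted up/down DEGs and a designed cross-condition overlap
structure, a scale-free-ish PPI graph with planted hubs, a GMT library with
one planted enriched term, regulator/drug tables with planted top entries
and a disease gene list — plus a serialisable truth manifest so every
downstream recovery property can be asserted without regeneration.

Noise model: gene baselines are drawn lognormal (normal on the log2 scale)
and i.i.d. Gaussian noise is added on the log2 scale; planted DEGs shift the
case mean by +/- ``effect_size`` log2 units.  All generators are pure
functions of their parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from diseasomics.dataio import (
    ExpressionMatrix,
    GeneSetLibrary,
    InteractionNetwork,
    write_expression,
    write_gmt,
    write_network,
)


class DesignError(ValueError):
    """Raised when a planted overlap design is malformed or infeasible."""


@dataclass
class SimulationTruth:
    """Everything that was planted, sufficient to score downstream recovery."""

    seed: int
    params: dict
    conditions: list[str]
    up: dict[str, list[str]]  # condition -> planted up-regulated genes
    down: dict[str, list[str]]
    blocks: list[dict] = field(default_factory=list)  # shared-DEG blocks
    enriched_term: str | None = None
    hubs: list[str] = field(default_factory=list)
    regulators: dict[str, str] = field(default_factory=dict)  # class -> planted name

    def degs(self, condition: str) -> frozenset[str]:
        return frozenset(self.up[condition]) | frozenset(self.down[condition])

    def planted_shared(self, a: str, b: str) -> frozenset[str]:
        """Genes planted as shared DEGs of both conditions (same direction)."""
        out: set[str] = set()
        for blk in self.blocks:
            if a in blk["conditions"] and b in blk["conditions"]:
                out.update(blk["genes"])
        return frozenset(out)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SimulationTruth":
        return cls.from_json(Path(path).read_text())


def _gene_pool(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i + 1:0{width}d}" for i in range(n_genes)]


def _normalise_design(
    overlap_design, n_conditions: int
) -> dict[tuple[int, ...], int]:
    """Normalise an overlap design to {sorted condition-index tuple: count}.

    Accepts a symmetric n x n integer matrix (pairwise-exclusive blocks; the
    diagonal is ignored) or a mapping of condition-index tuples (length >=2)
    to counts; ``None`` means no planted overlap.
    """
    if overlap_design is None:
        return {}
    if isinstance(overlap_design, dict):
        blocks: dict[tuple[int, ...], int] = {}
        for key, count in overlap_design.items():
            idx = tuple(sorted(int(i) for i in key))
            if len(idx) < 2 or len(set(idx)) != len(idx):
                raise DesignError(f"block {key!r} must name >=2 distinct conditions")
            if not all(0 <= i < n_conditions for i in idx):
                raise DesignError(f"block {key!r} indexes outside 0..{n_conditions - 1}")
            if int(count) < 0:
                raise DesignError(f"block {key!r} has negative count {count}")
            if int(count):
                blocks[idx] = blocks.get(idx, 0) + int(count)
        return blocks
    mat = np.asarray(overlap_design, dtype=int)
    if mat.shape != (n_conditions, n_conditions):
        raise DesignError(
            f"overlap_design must be {n_conditions}x{n_conditions}, got {mat.shape}"
        )
    if (mat != mat.T).any():
        i, j = map(int, np.argwhere(mat != mat.T)[0])
        raise DesignError(f"overlap_design not symmetric at cell ({i}, {j})")
    if (mat < 0).any():
        raise DesignError("overlap_design has negative counts")
    return {
        (i, j): int(mat[i, j])
        for i in range(n_conditions)
        for j in range(i + 1, n_conditions)
        if mat[i, j]
    }


def simulate_condition_family(
    n_conditions: int = 5,
    n_genes: int = 2000,
    n_case: int = 10,
    n_ctrl: int = 10,
    n_deg_per_condition: int = 50,
    overlap_design=None,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    baseline_log2_mean: float = 8.0,
    baseline_log2_sd: float = 1.5,
    seed: int = 0,
    condition_ids: list[str] | None = None,
) -> tuple[list[ExpressionMatrix], SimulationTruth]:
    """Simulate a family of case/control cohorts with a planted DEG overlap.

    Shared blocks of the design are planted with one common direction across
    their conditions; remaining per-condition DEGs are unique, with random
    direction.  Matrices are returned on the raw intensity scale
    (``2 ** log2``-values) so the standard log2 -> t-test pipeline applies.
    """
    if n_conditions < 1 or n_genes < 1:
        raise DesignError("need >=1 condition and >=1 gene")
    if n_case < 2 or n_ctrl < 2:
        raise DesignError("need >=2 case and >=2 control samples")
    ids = condition_ids or [f"cond{i + 1}" for i in range(n_conditions)]
    if len(ids) != n_conditions or len(set(ids)) != n_conditions:
        raise DesignError("condition_ids must be unique and match n_conditions")

    blocks = _normalise_design(overlap_design, n_conditions)
    shared_per_cond = [0] * n_conditions
    for idx, count in blocks.items():
        for i in idx:
            shared_per_cond[i] += count
    for i, s in enumerate(shared_per_cond):
        if s > n_deg_per_condition:
            raise DesignError(
                f"condition {ids[i]!r}: design plants {s} shared DEGs but only "
                f"{n_deg_per_condition} DEGs per condition are allowed"
            )
    n_planted = sum(blocks.values()) + sum(
        n_deg_per_condition - s for s in shared_per_cond
    )
    if n_planted > n_genes:
        raise DesignError(f"design needs {n_planted} planted genes but only {n_genes} exist")

    rng = np.random.default_rng(seed)
    genes = _gene_pool(n_genes)
    cursor = 0

    up: dict[str, set[str]] = {c: set() for c in ids}
    down: dict[str, set[str]] = {c: set() for c in ids}
    block_records = []
    for idx in sorted(blocks):
        count = blocks[idx]
        blk_genes = genes[cursor : cursor + count]
        cursor += count
        direction = str(rng.choice(["up", "down"]))
        for i in idx:
            (up if direction == "up" else down)[ids[i]].update(blk_genes)
        block_records.append(
            {
                "conditions": [ids[i] for i in idx],
                "genes": list(blk_genes),
                "direction": direction,
            }
        )
    for i, cond in enumerate(ids):
        n_unique = n_deg_per_condition - shared_per_cond[i]
        uniq = genes[cursor : cursor + n_unique]
        cursor += n_unique
        dirs = rng.choice(["up", "down"], size=n_unique)
        for g, d in zip(uniq, dirs):
            (up if d == "up" else down)[cond].add(g)

    matrices = []
    samples_per = n_case + n_ctrl
    for cond in ids:
        baseline = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)
        log2_vals = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, samples_per))
        gene_index = {g: i for i, g in enumerate(genes)}
        for g in up[cond]:
            log2_vals[gene_index[g], :n_case] += effect_size
        for g in down[cond]:
            log2_vals[gene_index[g], :n_case] -= effect_size
        sample_ids = [f"{cond}_s{j + 1}" for j in range(samples_per)]
        groups = {
            s: ("case" if j < n_case else "control") for j, s in enumerate(sample_ids)
        }
        data = pd.DataFrame(np.exp2(log2_vals), index=genes, columns=sample_ids)
        matrices.append(
            ExpressionMatrix(condition_id=cond, data=data, groups=groups, scale="raw")
        )

    truth = SimulationTruth(
        seed=int(seed),
        params={
            "n_conditions": n_conditions,
            "n_genes": n_genes,
            "n_case": n_case,
            "n_ctrl": n_ctrl,
            "n_deg_per_condition": n_deg_per_condition,
            "effect_size": effect_size,
            "noise_sd": noise_sd,
            "baseline_log2_mean": baseline_log2_mean,
            "baseline_log2_sd": baseline_log2_sd,
        },
        conditions=list(ids),
        up={c: sorted(up[c]) for c in ids},
        down={c: sorted(down[c]) for c in ids},
        blocks=block_records,
    )
    return matrices, truth


def simulate_ppi(
    n_nodes: int = 200,
    attachment_m: int = 2,
    planted_hub_degree: int = 40,
    seed: int = 0,
    genes: list[str] | None = None,
    n_hubs: int = 1,
    planted_hubs: list[str] | None = None,
    boost_within: list[str] | None = None,
    weight_range: tuple[float, float] = (0.4, 1.0),
) -> InteractionNetwork:
    """Scale-free-ish undirected PPI (preferential attachment) with planted hubs.

    Planted hubs receive extra random edges until their degree reaches
    ``planted_hub_degree`` and strictly exceeds every non-hub degree, so that
    degree-based hub ranking must recover them.  ``boost_within`` biases the
    hubs' extra edges toward the given nodes (used to make a hub dominate an
    induced subgraph as well).  Weights are uniform in ``weight_range``.
    """
    if genes is not None and len(genes) < n_nodes:
        raise DesignError(f"need >= {n_nodes} gene names, got {len(genes)}")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_nodes, attachment_m, seed=int(rng.integers(2**31)))
    names = genes[:n_nodes] if genes is not None else _gene_pool(n_nodes)
    g = nx.relabel_nodes(g, dict(enumerate(names)))

    if planted_hubs is None:
        planted_hubs = [str(x) for x in rng.choice(names, size=n_hubs, replace=False)]
    for h in planted_hubs:
        if h not in g:
            raise DesignError(f"planted hub {h!r} is not a node of the graph")
    hub_set = set(planted_hubs)

    def candidates(h: str) -> list[str]:
        pool = [n for n in names if n != h and not g.has_edge(h, n)]
        if boost_within:
            preferred = [n for n in pool if n in set(boost_within)]
            rest = [n for n in pool if n not in set(boost_within)]
            return preferred + rest
        rng.shuffle(pool)
        return pool

    for h in planted_hubs:
        pool = candidates(h)
        while g.degree(h) < planted_hub_degree and pool:
            g.add_edge(h, pool.pop(0))
        # strictness: hub degrees must exceed every non-hub degree
        while True:
            max_other = max((d for n, d in g.degree() if n not in hub_set), default=0)
            if g.degree(h) > max_other:
                break
            pool = [n for n in names if n != h and not g.has_edge(h, n)]
            if not pool:
                raise DesignError(f"cannot make hub {h!r} dominate: graph saturated")
            # avoid boosting the current maximum-degree competitor
            pool.sort(key=lambda n: g.degree(n))
            g.add_edge(h, pool[0])

    lo, hi = weight_range
    for a, b in g.edges():
        g[a][b]["weight"] = float(rng.uniform(lo, hi))
    net = InteractionNetwork(kind="ppi_undirected", graph=g)
    net.meta["planted_hubs"] = sorted(planted_hubs)
    return net


def simulate_gmt(
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 40),
    planted_genes: list[str] | None = None,
    universe: list[str] | None = None,
    seed: int = 0,
    name: str = "synthetic_library",
) -> tuple[GeneSetLibrary, str | None]:
    """Random GMT library over ``universe`` with one term planted on given genes.

    Returns the library and the planted term id (``None`` when nothing was
    planted).  The library universe is the full provided universe.
    """
    if universe is None or len(universe) == 0:
        raise DesignError("a non-empty universe is required")
    if n_terms < 1:
        raise DesignError("need >=1 term")
    lo, hi = term_size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise DesignError(f"bad term_size_range {term_size_range} for universe of {len(universe)}")
    rng = np.random.default_rng(seed)
    uni = [str(g).upper() for g in universe]
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    planted_term = None
    start = 0
    if planted_genes:
        pg = frozenset(str(g).upper() for g in planted_genes)
        if not pg <= frozenset(uni):
            raise DesignError("planted genes must lie inside the universe")
        planted_term = "T000"
        sets[planted_term] = ("planted enriched set", pg)
        start = 1
    for i in range(start, n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(str(x) for x in rng.choice(uni, size=size, replace=False))
        sets[f"T{i:03d}"] = ("random set", members)
    lib = GeneSetLibrary(name=name, sets=sets, universe=frozenset(uni))
    return lib, planted_term


def simulate_regulator_tables(
    n_regulators: int = 30,
    targets_per_regulator: int = 20,
    degs: list[str] | None = None,
    universe: list[str] | None = None,
    seed: int = 0,
    regulator_class: str = "TF",
) -> tuple[InteractionNetwork, str | None]:
    """Random regulator->target table with one regulator boosted toward DEGs.

    The planted regulator targets as many distinct DEGs as needed to strictly
    out-rank every other regulator; background regulators draw targets
    uniformly from the universe.  Returns the network and the planted name.
    """
    if universe is None or len(universe) == 0:
        raise DesignError("a non-empty universe is required")
    if n_regulators < 1 or targets_per_regulator < 1:
        raise DesignError("need >=1 regulator with >=1 target")
    rng = np.random.default_rng(seed)
    uni = [str(g).upper() for g in universe]
    deg_list = sorted({str(g).upper() for g in (degs or [])})

    def reg_name(i: int) -> str:
        return f"TF{i:02d}" if regulator_class == "TF" else f"mir-{i:02d}-5p"

    edges: list[tuple[str, str, float]] = []
    deg_hits: dict[str, set[str]] = {}
    for i in range(1, n_regulators):
        reg = reg_name(i)
        targets = rng.choice(uni, size=min(targets_per_regulator, len(uni)), replace=False)
        deg_hits[reg] = set(targets) & set(deg_list)
        edges.extend((reg, t, 1.0) for t in targets)

    planted = None
    if deg_list:
        planted = reg_name(0)
        want = min(len(deg_list), targets_per_regulator)
        max_other = max((len(h) for h in deg_hits.values()), default=0)
        if want <= max_other:
            want = max_other + 1
        if want > len(deg_list):
            raise DesignError(
                f"cannot plant a dominant regulator: background already hits "
                f"{max_other} DEGs but only {len(deg_list)} DEGs exist"
            )
        chosen = [str(x) for x in rng.choice(deg_list, size=want, replace=False)]
        extra = [g for g in uni if g not in set(chosen)]
        n_extra = max(0, targets_per_regulator - want)
        padding = [str(x) for x in rng.choice(extra, size=min(n_extra, len(extra)), replace=False)]
        edges.extend((planted, t, 1.0) for t in chosen + padding)
    else:
        edges.extend(
            (reg_name(0), str(t), 1.0)
            for t in rng.choice(uni, size=min(targets_per_regulator, len(uni)), replace=False)
        )

    from diseasomics.dataio import build_network

    net = build_network("regulator_bipartite", edges)
    net.meta["planted_regulator"] = planted
    net.meta["regulator_class"] = regulator_class
    return net, planted


def simulate_drug_targets(
    n_drugs: int = 20,
    targets_per_drug: int = 5,
    universe: list[str] | None = None,
    planted_genes: list[str] | None = None,
    seed: int = 0,
) -> InteractionNetwork:
    """Random drug->target table; the first drug is guaranteed to hit planted genes."""
    if universe is None or len(universe) == 0:
        raise DesignError("a non-empty universe is required")
    rng = np.random.default_rng(seed)
    uni = [str(g).upper() for g in universe]
    edges: list[tuple[str, str, float]] = []
    for i in range(n_drugs):
        drug = f"DRUG{i:02d}"
        targets = {str(t) for t in rng.choice(uni, size=min(targets_per_drug, len(uni)), replace=False)}
        if i == 0 and planted_genes:
            pg = [str(g).upper() for g in planted_genes]
            targets.update(str(x) for x in rng.choice(pg, size=min(2, len(pg)), replace=False))
        edges.extend((drug, t, 1.0) for t in sorted(targets))
    from diseasomics.dataio import build_network

    return build_network("drug_bipartite", edges)


def simulate_disease_genes(
    universe: list[str],
    associated: list[str] | None = None,
    n_total: int = 30,
    n_from_associated: int = 10,
    seed: int = 0,
) -> frozenset[str]:
    """A disease gene list drawing part of its genes from a known-associated set."""
    rng = np.random.default_rng(seed)
    uni = [str(g).upper() for g in universe]
    assoc = sorted({str(g).upper() for g in (associated or [])})
    take = min(n_from_associated, len(assoc), n_total)
    chosen = set(str(x) for x in rng.choice(assoc, size=take, replace=False)) if take else set()
    rest_pool = [g for g in uni if g not in chosen]
    n_rest = min(n_total - len(chosen), len(rest_pool))
    chosen.update(str(x) for x in rng.choice(rest_pool, size=n_rest, replace=False))
    return frozenset(chosen)


def default_workspace_design(n_conditions: int, n_deg_per_condition: int) -> dict:
    """Pairwise target-factor blocks (decreasing sizes) plus one three-way
    block, scaled to the per-condition DEG budget and guaranteed feasible."""
    base = [12, 8, 6, 4, 3, 2, 2, 2, 2]
    scale = n_deg_per_condition / 60.0
    design: dict[tuple[int, ...], int] = {}
    for i in range(1, n_conditions):
        design[(0, i)] = max(1, round(base[(i - 1) % len(base)] * scale))
    if n_conditions >= 3:
        design[(0, 1, 2)] = max(1, round(3 * scale))
    while sum(design.values()) > n_deg_per_condition:
        biggest = max(design, key=lambda k: design[k])
        if design[biggest] <= 1:
            raise DesignError(
                f"{n_deg_per_condition} DEGs per condition cannot host a shared "
                f"block per factor for {n_conditions - 1} factors"
            )
        design[biggest] -= 1
    return design


def write_workspace(
    out_dir: str | Path,
    seed: int = 0,
    n_conditions: int = 5,
    n_genes: int = 1200,
    n_case: int = 10,
    n_ctrl: int = 10,
    n_deg_per_condition: int = 60,
    overlap_design=None,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    ppi_nodes: int = 300,
) -> SimulationTruth:
    """Write a self-contained analysis workspace: matrices, group maps, GMT,
    PPI/regulator/drug/disease tables, a truth manifest and a pipeline config.

    The first condition is the target; the default overlap design plants
    pairwise target-factor blocks plus one three-way block.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if overlap_design is None:
        overlap_design = default_workspace_design(n_conditions, n_deg_per_condition)
    ids = ["TARGET"] + [f"RF{i}" for i in range(1, n_conditions)]
    matrices, truth = simulate_condition_family(
        n_conditions=n_conditions,
        n_genes=n_genes,
        n_case=n_case,
        n_ctrl=n_ctrl,
        n_deg_per_condition=n_deg_per_condition,
        overlap_design=overlap_design,
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
        condition_ids=ids,
    )
    genes = matrices[0].gene_ids
    shared = sorted(
        set().union(
            *(truth.planted_shared("TARGET", f) for f in ids[1:]),
        )
    )

    for M in matrices:
        write_expression(M, out / f"expr_{M.condition_id}.tsv", out / f"groups_{M.condition_id}.tsv")

    hub = shared[0] if shared else genes[0]
    ppi = simulate_ppi(
        n_nodes=min(ppi_nodes, n_genes),
        planted_hub_degree=40,
        seed=int(rng.integers(2**31)),
        genes=shared + [g for g in genes if g not in set(shared)],
        planted_hubs=[hub],
        boost_within=shared,
    )
    write_network(ppi, out / "ppi.tsv", format="tsv")
    truth.hubs = [hub]

    lib, planted_term = simulate_gmt(
        n_terms=50,
        term_size_range=(10, 40),
        planted_genes=shared or None,
        universe=genes,
        seed=int(rng.integers(2**31)),
    )
    write_gmt(lib, out / "library.gmt")
    truth.enriched_term = planted_term

    tf_net, tf_planted = simulate_regulator_tables(
        degs=shared, universe=genes, seed=int(rng.integers(2**31)), regulator_class="TF"
    )
    write_network(tf_net, out / "tf_targets.tsv", format="tsv")
    mirna_net, mirna_planted = simulate_regulator_tables(
        degs=shared, universe=genes, seed=int(rng.integers(2**31)), regulator_class="miRNA"
    )
    write_network(mirna_net, out / "mirna_targets.tsv", format="tsv")
    truth.regulators = {"TF": tf_planted, "miRNA": mirna_planted}

    drug_net = simulate_drug_targets(
        universe=genes, planted_genes=shared or None, seed=int(rng.integers(2**31))
    )
    write_network(drug_net, out / "drug_targets.tsv", format="tsv")

    disease = simulate_disease_genes(
        universe=genes,
        associated=sorted(truth.degs("TARGET")),
        seed=int(rng.integers(2**31)),
    )
    (out / "disease_genes.txt").write_text("\n".join(sorted(disease)) + "\n")

    config = {
        "target": "TARGET",
        "conditions": {
            c: {"expression": f"expr_{c}.tsv", "groups": f"groups_{c}.tsv"} for c in ids
        },
        "alpha": 0.05,
        "lfc": 1.0,
        "log2_offset": 1.0,
        "collapse_method": "max_abs_t",
        "direction_consistent": True,
        "neighbor_expansion": False,
        "ppi": "ppi.tsv",
        "ppi_threshold": 0.4,
        "libraries": ["library.gmt"],
        "tf_targets": "tf_targets.tsv",
        "mirna_targets": "mirna_targets.tsv",
        "drug_targets": "drug_targets.tsv",
        "disease_genes": "disease_genes.txt",
        "out_dir": "results",
        "seed": int(seed),
        "min_conditions": 2,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    truth.params["workspace_seed"] = int(seed)
    truth.save(out / "truth.json")
    return truth
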