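"""Cross-comparative DEG intersection: diseasome networks.

A diseasome network is a bipartite graph linking the target condition and
each risk-factor condition to the genes they dysregulate in common.  Up- and
down-regulated genes are kept in separate networks; direction-consistent
intersection (up-with-up, down-with-down) is the default, with a symbol-only
mode available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from diseasomics.dataio import InteractionNetwork
from diseasomics.deg import DEGSet


@dataclass(frozen=True)
class DiseasomePair:
    """Genes shared between the target condition and one risk factor."""

    target_id: str
    factor_id: str
    shared_up: frozenset[str]
    shared_down: frozenset[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared_up) + len(self.shared_down)


@dataclass(frozen=True)
class SharedGeneReport:
    """Genes that are DEGs in at least ``min_conditions`` conditions."""

    min_conditions: int
    entries: tuple[tuple[str, frozenset[str]], ...]  # (gene, conditions), sorted

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [g for g, _ in self.entries],
                "n_conditions": [len(c) for _, c in self.entries],
                "conditions": [",".join(sorted(c)) for _, c in self.entries],
            }
        )


def intersect_pair(
    target: DEGSet, factor: DEGSet, direction_consistent: bool = True
) -> DiseasomePair:
    """Shared DEGs between target and one factor.

    With ``direction_consistent`` (default) shared_up = target.up ∩ factor.up
    and shared_down = target.down ∩ factor.down.  Otherwise the intersection
    is at the symbol level (either direction in the factor), split by the
    target's direction.
    """
    if (target.alpha, target.lfc) != (factor.alpha, factor.lfc):
        warnings.warn(
            f"DEG thresholds differ between {target.condition_id} "
            f"({target.alpha}, {target.lfc}) and {factor.condition_id} "
            f"({factor.alpha}, {factor.lfc}); shared counts may not be comparable",
            stacklevel=2,
        )
    if direction_consistent:
        up = target.up & factor.up
        down = target.down & factor.down
    else:
        up = target.up & factor.degs
        down = target.down & factor.degs
    return DiseasomePair(
        target_id=target.condition_id,
        factor_id=factor.condition_id,
        shared_up=frozenset(up),
        shared_down=frozenset(down),
    )


def build_diseasome(
    target: DEGSet,
    factors: list[DEGSet],
    direction: str,
    direction_consistent: bool = True,
) -> InteractionNetwork:
    """Bipartite condition-gene network for one direction (``up`` or ``down``).

    Condition nodes are the target plus every factor; gene nodes are the
    genes of that direction shared between the target and at least one
    factor; an edge links a condition to a gene when the gene is a
    direction-matched DEG of that condition and is shared with the target.
    An empty network (no shared genes) is returned with a warning.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if not factors:
        raise ValueError("need at least one factor DEGSet")

    pairs = [intersect_pair(target, f, direction_consistent) for f in factors]
    shared = {
        p.factor_id: (p.shared_up if direction == "up" else p.shared_down) for p in pairs
    }
    genes = sorted(set().union(*shared.values()))

    g = nx.Graph()
    g.add_node(target.condition_id, node_class="condition")
    for f in factors:
        g.add_node(f.condition_id, node_class="condition")
    for gene in genes:
        g.add_node(gene, node_class="gene")
        g.add_edge(target.condition_id, gene, weight=1.0)
    for f in factors:
        for gene in sorted(shared[f.condition_id]):
            g.add_edge(f.condition_id, gene, weight=1.0)

    if not genes:
        warnings.warn(
            f"no {direction}-regulated genes shared between {target.condition_id} "
            "and any factor; returning an empty diseasome",
            stacklevel=2,
        )
    net = InteractionNetwork(kind="diseasome_bipartite", graph=g)
    net.meta["direction"] = direction
    net.meta["pair_counts"] = {p.factor_id: p.n_shared for p in pairs}
    return net


def multiway_shared(degsets: list[DEGSet], min_conditions: int = 2) -> SharedGeneReport:
    """Genes that are DEGs in at least ``min_conditions`` of the given conditions.

    Sorted by multiplicity descending, then symbol ascending.
    """
    if min_conditions < 2:
        raise ValueError(f"min_conditions must be >=2, got {min_conditions}")
    if len(degsets) < 2:
        raise ValueError("need at least two DEGSets")
    membership: dict[str, set[str]] = {}
    for ds in degsets:
        for gene in ds.degs:
            membership.setdefault(gene, set()).add(ds.condition_id)
    entries = sorted(
        ((g, frozenset(c)) for g, c in membership.items() if len(c) >= min_conditions),
        key=lambda e: (-len(e[1]), e[0]),
    )
    return SharedGeneReport(min_conditions=min_conditions, entries=tuple(entries))


def pairwise_summary(target: DEGSet, factors: list[DEGSet], direction_consistent: bool = True) -> pd.DataFrame:
    """One row per (target, factor) pair: n_up, n_down, n_shared and the genes."""
    rows = []
    for f in factors:
        p = intersect_pair(target, f, direction_consistent)
        rows.append(
            {
                "target": p.target_id,
                "factor": p.factor_id,
                "n_up": len(p.shared_up),
                "n_down": len(p.shared_down),
                "n_shared": p.n_shared,
                "shared_up": ",".join(sorted(p.shared_up)),
                "shared_down": ",".join(sorted(p.shared_down)),
            }
        )
    return pd.DataFrame(rows)
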