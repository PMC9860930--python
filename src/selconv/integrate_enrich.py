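"""Cross-stage gene-set bookkeeping and hypergeometric pathway enrichment.

Collects the gene sets the earlier stages produce (PSGs, REGs, convergent
genes, sweep candidates, module genes, DEGs), computes exact intersections
with pairwise Venn counts, runs upper-tail hypergeometric enrichment with
BH-corrected q-values, and exports a bipartite gene--pathway edge list.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ConfigError

log = logging.getLogger("selconv.enrich")


@dataclass
class GeneSetLedger:
    """Named, deduplicated gene sets with provenance."""

    universe: list[str]
    sets: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, genes: Iterable[str], source: str = "") -> None:
        uni = set(self.universe)
        dedup = []
        for g in genes:
            if g not in dedup:
                dedup.append(g)
        outside = [g for g in dedup if g not in uni]
        if outside:
            log.warning("set %r: %d genes outside the declared universe",
                        name, len(outside))
        self.sets[name] = dedup
        self.provenance[name] = source

    def get(self, name: str) -> list[str]:
        if name not in self.sets:
            raise ConfigError(f"unknown gene set {name!r}")
        return self.sets[name]


def intersect_sets(ledger: GeneSetLedger, *names: str
                   ) -> tuple[list[str], pd.DataFrame]:
    """Exact intersection of the named sets plus all pairwise overlap counts
    for Venn-style reporting."""
    sets = {n: set(ledger.get(n)) for n in names}
    inter = set.intersection(*sets.values()) if sets else set()
    rows = [(a, b, len(sets[a]), len(sets[b]), len(sets[a] & sets[b]))
            for a, b in itertools.combinations(names, 2)]
    pairwise = pd.DataFrame(rows, columns=["set_a", "set_b", "n_a", "n_b",
                                           "n_overlap"])
    return sorted(inter), pairwise


def hypergeom_enrich(gene_set: Sequence[str],
                     pathways: Mapping[str, Sequence[str]],
                     universe: Sequence[str],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``gene_set`` in each pathway.

    p = P[X >= k] with X ~ Hypergeometric(N, K, m): N universe size, K
    pathway size (restricted to the universe), m set size, k the overlap.
    Significance is flagged at raw p < alpha; BH q-values are reported
    alongside. Rows sorted by p.
    """
    uni = set(universe)
    if not uni:
        raise ConfigError("empty gene universe")
    s = set(gene_set) & uni
    m = len(s)
    rows = []
    for pw, genes in pathways.items():
        pk = set(genes) & uni
        k = len(s & pk)
        K = len(pk)
        p = float(stats.hypergeom.sf(k - 1, len(uni), K, m))
        rows.append((pw, k, m, K, len(uni), p, ";".join(sorted(s & pk))))
    df = pd.DataFrame(rows, columns=["pathway", "k", "set_size",
                                     "pathway_size", "universe", "p_value",
                                     "member_genes"])
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["significant"] = df["p_value"] < alpha
        df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return df


def gene_pathway_network(enrichment: pd.DataFrame,
                         provenance: Mapping[str, str] | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bipartite (gene, pathway) edges for significant pathways plus a node
    table carrying set provenance for plotting tools."""
    edges = []
    for _, row in enrichment.iterrows():
        if not row.get("significant", False):
            continue
        for g in str(row["member_genes"]).split(";"):
            if g:
                edges.append((g, row["pathway"]))
    edge_df = pd.DataFrame(edges, columns=["gene", "pathway"])
    nodes = []
    for g in sorted({e[0] for e in edges}):
        nodes.append((g, "gene", (provenance or {}).get(g, "")))
    for p in sorted({e[1] for e in edges}):
        nodes.append((p, "pathway", ""))
    node_df = pd.DataFrame(nodes, columns=["node", "kind", "provenance"])
    return edge_df, node_df
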