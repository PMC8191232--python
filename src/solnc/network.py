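"""lncRNA–mRNA–miRNA network assembly.

Two products: the tripartite network built around mRNAs that are targets of
both a DE lncRNA and a phosphate-related miRNA, and the interest-gene network
of lncRNAs whose targets include a transcription factor, phosphate-related or
hormone-related mRNA (with ALL targets of those lncRNAs retained, labelled
or not).  Networks are data products exported as GraphML/TSV.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx

from .mirna import MirnaHit
from .targets import TargetPair

logger = logging.getLogger(__name__)

NODE_TYPES = ("lncRNA", "mRNA", "miRNA")
INTEREST_LABELS = ("TF", "P_related", "hormone", "none")


def validate_network(g: nx.DiGraph) -> None:
    for u, v, data in g.edges(data=True):
        if u not in g.nodes or v not in g.nodes:
            raise ValueError(f"edge endpoint not declared: {u} -> {v}")
        if u == v:
            raise ValueError(f"self-edge at {u}")
        if data.get("edge_type") == "mirna_target" and g.nodes[u].get("node_type") != "miRNA":
            raise ValueError(f"mirna_target edge must originate at a miRNA node: {u}")
    for n, data in g.nodes(data=True):
        if data.get("node_type") not in NODE_TYPES:
            raise ValueError(f"node {n} has invalid node_type {data.get('node_type')}")


def build_tripartite(
    target_pairs: Sequence[TargetPair],
    mirna_hits: Sequence[MirnaHit],
    shared: Mapping[str, tuple[set[str], set[str]]],
) -> nx.DiGraph:
    """Network around each shared mRNA: its targeting lncRNAs (edges typed by
    target mode) and its targeting miRNAs (mirna_target edges)."""
    g = nx.DiGraph()
    if not shared:
        logger.info("build_tripartite: empty shared target set -> empty network")
        return g
    pair_modes: dict[tuple[str, str], set[str]] = {}
    for p in target_pairs:
        pair_modes.setdefault((p.lncrna_id, p.gene_id), set()).add(p.mode)
    for mrna, (lncs, mirs) in sorted(shared.items()):
        g.add_node(mrna, node_type="mRNA", interest_label="none")
        for lnc in sorted(lncs):
            g.add_node(lnc, node_type="lncRNA", interest_label="none")
            for mode in sorted(pair_modes.get((lnc, mrna), {"trans"})):
                g.add_edge(lnc, mrna, edge_type=mode)
        for mir in sorted(mirs):
            g.add_node(mir, node_type="miRNA", interest_label="none")
            g.add_edge(mir, mrna, edge_type="mirna_target")
    validate_network(g)
    return g


def build_interest_network(
    target_pairs: Sequence[TargetPair],
    interest_labels: Mapping[str, str],
) -> nx.DiGraph:
    """lncRNAs with ≥1 labelled target plus ALL targets of those lncRNAs.

    ``interest_labels`` maps gene id → TF / P_related / hormone (anything
    else, or absence, means "none").  Labels for genes that never appear as
    targets are warned about and ignored.  If a gene somehow carries several
    labels upstream, the mapping's single value wins.
    """
    g = nx.DiGraph()
    known_genes = {p.gene_id for p in target_pairs}
    for gene, label in sorted(interest_labels.items()):
        if gene not in known_genes:
            logger.warning("interest label for unknown gene %s ignored", gene)
        if label not in INTEREST_LABELS[:-1]:
            logger.warning("unrecognized interest label %r for %s treated as none", label, gene)
    by_lnc: dict[str, list[TargetPair]] = {}
    for p in target_pairs:
        by_lnc.setdefault(p.lncrna_id, []).append(p)
    for lnc, pairs in sorted(by_lnc.items()):
        labelled = [
            p for p in pairs
            if interest_labels.get(p.gene_id, "none") in INTEREST_LABELS[:-1]
        ]
        if not labelled:
            continue
        g.add_node(lnc, node_type="lncRNA", interest_label="none")
        for p in sorted(pairs, key=lambda p: (p.gene_id, p.mode)):
            label = interest_labels.get(p.gene_id, "none")
            if label not in INTEREST_LABELS:
                label = "none"
            g.add_node(p.gene_id, node_type="mRNA", interest_label=label)
            g.add_edge(lnc, p.gene_id, edge_type=p.mode)
    validate_network(g)
    return g
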