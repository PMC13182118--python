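"""Networks relating protein variants by single amino-acid changes.

Two variants are adjacent when their substitution sets differ at exactly one
mature-protein position — a substitution added, removed, or changed to a
different residue all count as one step. Detected variants and catalogued but
undetected variants both appear as nodes, distinguished by status, with
observed chromosome-copy counts attached.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .errors import ConfigError, MilkvarError
from .protein_variants import Catalog, ProteinVariant, Substitution, format_substitutions

STATUS_KNOWN_DETECTED = "known_detected"
STATUS_KNOWN_UNDETECTED = "known_undetected"
STATUS_NOVEL = "novel"


def substitution_distance(
    a: frozenset[Substitution], b: frozenset[Substitution]
) -> int:
    """Number of mature-protein positions at which two variants differ."""
    pos_a = {s.mature_pos: s.alt_aa for s in a}
    pos_b = {s.mature_pos: s.alt_aa for s in b}
    return sum(
        1
        for p in set(pos_a) | set(pos_b)
        if pos_a.get(p) != pos_b.get(p)
    )


def _edge_label(a: frozenset[Substitution], b: frozenset[Substitution]) -> str:
    pos_a = {s.mature_pos: s for s in a}
    pos_b = {s.mature_pos: s for s in b}
    for p in sorted(set(pos_a) | set(pos_b)):
        sa, sb = pos_a.get(p), pos_b.get(p)
        if (sa.alt_aa if sa else None) != (sb.alt_aa if sb else None):
            aa1 = sa.alt_aa if sa else (sa or sb).ref_aa
            aa2 = sb.alt_aa if sb else (sa or sb).ref_aa
            return f"{p}: {aa1}↔{aa2}"
    raise MilkvarError("variants are identical; no edge label")


def build_network(
    variants: Sequence[ProteinVariant],
    catalog: Catalog,
    gene: Optional[str] = None,
) -> nx.Graph:
    """Build the single-step substitution network for one gene.

    Nodes: every detected variant plus every catalogued-but-undetected
    variant. Edge between two nodes iff their substitution sets differ at
    exactly one position; edges are labeled "pos: aa1<->aa2".
    """
    genes = {v.gene for v in variants}
    if gene is None:
        if len(genes) > 1:
            raise ConfigError(f"variants span several genes: {sorted(genes)}")
        gene = next(iter(genes)) if genes else None
    elif genes - {gene}:
        raise ConfigError(f"variants from {sorted(genes)} mixed with gene={gene}")
    g = nx.Graph(gene=gene)
    subs_of: dict[str, frozenset[Substitution]] = {}
    for v in variants:
        status = STATUS_NOVEL if v.status == "novel" else STATUS_KNOWN_DETECTED
        g.add_node(
            v.name,
            status=status,
            occurrences=int(v.occurrences),
            substitutions=format_substitutions(v.substitutions),
        )
        subs_of[v.name] = v.substitutions
    if gene is not None:
        for name, subs in catalog.entries.get(gene, {}).items():
            if name not in g:
                g.add_node(
                    name,
                    status=STATUS_KNOWN_UNDETECTED,
                    occurrences=0,
                    substitutions=format_substitutions(subs),
                )
                subs_of[name] = subs
    names = list(g.nodes)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if substitution_distance(subs_of[a], subs_of[b]) == 1:
                g.add_edge(a, b, label=_edge_label(subs_of[a], subs_of[b]))
    return g


def export_network(net: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write the network as round-trippable GraphML, styled DOT, or a TSV edge list."""
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "dot":
        _write_dot(net, path)
    elif fmt == "tsv":
        rows = [
            {"source": a, "target": b, "label": d.get("label", "")}
            for a, b, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "label"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ConfigError(f"unknown network format {fmt!r} (graphml/dot/tsv)")


_DOT_STYLE = {
    STATUS_KNOWN_DETECTED: 'style=filled, fillcolor="palegreen"',
    STATUS_KNOWN_UNDETECTED: 'style=filled, fillcolor="white"',
    STATUS_NOVEL: 'style=filled, fillcolor="grey80"',
}


def _write_dot(net: nx.Graph, path) -> None:
    lines = ["graph variants {", "  node [shape=circle];"]
    for n, d in net.nodes(data=True):
        style = _DOT_STYLE.get(d.get("status", STATUS_NOVEL), "")
        occ = d.get("occurrences", 0)
        lines.append(f'  "{n}" [label="{n}\\n{occ}", {style}];')
    for a, b, d in net.edges(data=True):
        lines.append(f'  "{a}" -- "{b}" [label="{d.get("label", "")}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_graphml(path) -> nx.Graph:
    """Re-import a GraphML network written by :func:`export_network`."""
    return nx.read_graphml(path)
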