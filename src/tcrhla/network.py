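"""Sequence features of HLA-associated TCRs and CDR3 similarity networks.

Associated clonotypes are organised into similarity networks: nodes are
clonotypes, and an edge joins two clonotypes of the same chain, same V
family and same CDR3 length whose CDR3s differ by at most one amino acid
(Hamming distance <= 1).  Connected components typically collect receptors
with a shared specificity; nodes can be annotated with epitopes by exact
(CDR3, V family) lookup in a user-supplied reference table such as a VDJdb
export.

Also provided: CDR3 length profiles and V-family usage of an associated
subset against a background, and per-V-family Mann-Whitney U comparisons of
whole-repertoire V-gene frequencies between donor groups.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .association import AssociationRecord, bh_adjust
from .types import Clonotype

logger = logging.getLogger(__name__)

__all__ = [
    "hamming1",
    "build_network",
    "annotate_epitopes",
    "cdr3_length_profile",
    "v_usage_enrichment",
    "compare_repertoire_v_usage",
    "write_network",
]


def hamming1(a: str, b: str) -> bool:
    """True iff equal-length strings differ in at most one position."""
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > 1:
                return False
    return True


def build_network(records: Sequence[AssociationRecord]) -> nx.Graph:
    """Similarity network over the distinct clonotypes of an association list.

    Node attributes: ``alleles`` (sorted codes the clonotype is associated
    with), ``component`` (integer label), ``purity`` (fraction of component
    nodes whose allele set contains the component's majority allele).
    Output is independent of input order.
    """
    if not records:
        raise ValueError("empty association record list")
    alleles_by_node: Dict[Clonotype, set] = {}
    for r in records:
        alleles_by_node.setdefault(r.clonotype, set()).add(r.allele.code)
    nodes = sorted(alleles_by_node, key=lambda c: (c.chain, c.v_family, c.cdr3_aa))

    g = nx.Graph()
    for c in nodes:
        g.add_node(c, alleles=tuple(sorted(alleles_by_node[c])))
    buckets: Dict[Tuple[str, str, int], List[Clonotype]] = {}
    for c in nodes:
        buckets.setdefault((c.chain, c.v_family, len(c.cdr3_aa)), []).append(c)
    for bucket in buckets.values():
        for i in range(len(bucket)):
            for j in range(i + 1, len(bucket)):
                if hamming1(bucket[i].cdr3_aa, bucket[j].cdr3_aa):
                    g.add_edge(bucket[i], bucket[j])

    for label, comp in enumerate(
        sorted(nx.connected_components(g), key=lambda s: min(s))
    ):
        votes = Counter()
        for c in comp:
            votes.update(g.nodes[c]["alleles"])
        majority, _ = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
        purity = sum(1 for c in comp if majority in g.nodes[c]["alleles"]) / len(comp)
        for c in comp:
            g.nodes[c]["component"] = label
            g.nodes[c]["purity"] = purity
            g.nodes[c]["majority_allele"] = majority
    return g


def annotate_epitopes(g: nx.Graph, reference: pd.DataFrame) -> nx.Graph:
    """Attach epitopes to nodes by exact (cdr3_aa, v_family) match.

    ``reference`` needs columns ``cdr3_aa, v_family, epitope`` (an ``hla``
    column, if present, is carried along).  Malformed rows are skipped and
    counted.  The graph is annotated in place and returned.
    """
    required = {"cdr3_aa", "v_family", "epitope"}
    missing = required - set(reference.columns)
    if missing:
        raise ValueError(f"reference table missing columns {sorted(missing)}")
    lookup: Dict[Tuple[str, str], set] = {}
    n_skipped = 0
    for row in reference.itertuples(index=False):
        cdr3, vf, epi = row.cdr3_aa, row.v_family, row.epitope
        if not (isinstance(cdr3, str) and isinstance(vf, str) and isinstance(epi, str)) or not (
            cdr3 and vf and epi
        ):
            n_skipped += 1
            continue
        lookup.setdefault((cdr3, vf), set()).add(epi)
    if n_skipped:
        logger.info("annotate_epitopes: skipped %d malformed reference rows", n_skipped)
    for c in g.nodes:
        epis = lookup.get((c.cdr3_aa, c.v_family))
        if epis:
            g.nodes[c]["epitopes"] = tuple(sorted(epis))
    return g


def cdr3_length_profile(
    subset: Sequence[Clonotype], background: Sequence[Clonotype]
) -> Dict[str, object]:
    """Per-chain normalized CDR3-length histograms of a subset vs background,
    with a two-sample Mann-Whitney location test on the lengths."""
    if not subset or not background:
        raise ValueError("both clonotype lists must be non-empty")
    out: Dict[str, object] = {}
    for chain in ("alpha", "beta"):
        sub = [len(c.cdr3_aa) for c in subset if c.chain == chain]
        bg = [len(c.cdr3_aa) for c in background if c.chain == chain]
        if not sub or not bg:
            continue
        lengths = range(min(sub + bg), max(sub + bg) + 1)
        sub_hist = pd.Series(Counter(sub)).reindex(lengths, fill_value=0) / len(sub)
        bg_hist = pd.Series(Counter(bg)).reindex(lengths, fill_value=0) / len(bg)
        stat, p = mannwhitneyu(sub, bg, alternative="two-sided")
        out[chain] = {
            "subset_hist": sub_hist,
            "background_hist": bg_hist,
            "subset_mean": float(np.mean(sub)),
            "background_mean": float(np.mean(bg)),
            "mwu_p": float(p),
        }
    return out


def v_usage_enrichment(
    subset: Sequence[Clonotype], background: Sequence[Clonotype]
) -> pd.DataFrame:
    """Per-V-family frequency in subset vs background (unique clonotypes).

    Frequencies are normalized per chain; every family seen in either list
    is reported (0.0 rather than dropped when absent from one side).
    """
    if not subset or not background:
        raise ValueError("both clonotype lists must be non-empty")
    rows = []
    for chain in ("alpha", "beta"):
        sub = [c.v_family for c in subset if c.chain == chain]
        bg = [c.v_family for c in background if c.chain == chain]
        if not sub and not bg:
            continue
        sub_n, bg_n = Counter(sub), Counter(bg)
        for fam in sorted(set(sub_n) | set(bg_n)):
            f_sub = sub_n[fam] / len(sub) if sub else 0.0
            f_bg = bg_n[fam] / len(bg) if bg else 0.0
            rows.append(
                {
                    "chain": chain,
                    "v_family": fam,
                    "freq_subset": f_sub,
                    "freq_background": f_bg,
                    "ratio": f_sub / f_bg if f_bg > 0 else float("inf"),
                }
            )
    return pd.DataFrame(rows, columns=["chain", "v_family", "freq_subset", "freq_background", "ratio"])


def compare_repertoire_v_usage(
    group_a: Sequence[Dict[str, float]], group_b: Sequence[Dict[str, float]]
) -> pd.DataFrame:
    """Per-V-family two-sided Mann-Whitney U tests between donor groups.

    Each group is a list of per-donor V-family frequency mappings.  Returns
    one row per family with the U statistic, raw p, and BH-adjusted p across
    families; a family with identical constant values in both groups gets
    p = 1 and a tie flag.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 donors per group")
    families = sorted({f for d in list(group_a) + list(group_b) for f in d})
    rows = []
    for fam in families:
        a = np.array([d.get(fam, 0.0) for d in group_a], dtype=float)
        b = np.array([d.get(fam, 0.0) for d in group_b], dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0.0:
            rows.append({"v_family": fam, "u_stat": len(a) * len(b) / 2.0, "p_raw": 1.0, "all_tied": True})
            continue
        stat, p = mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"v_family": fam, "u_stat": float(stat), "p_raw": float(p), "all_tied": False})
    df = pd.DataFrame(rows, columns=["v_family", "u_stat", "p_raw", "all_tied"])
    df["p_BH"] = bh_adjust(df["p_raw"].to_numpy())
    return df


def write_network(g: nx.Graph, edges_path, nodes_path) -> None:
    """Export as an edge-list TSV and a node-attribute TSV."""
    edge_rows = [
        {
            "chain": a.chain,
            "v_family": a.v_family,
            "cdr3_a": a.cdr3_aa,
            "cdr3_b": b.cdr3_aa,
        }
        for a, b in sorted(g.edges, key=lambda e: tuple(sorted((str(e[0]), str(e[1])))))
    ]
    pd.DataFrame(edge_rows, columns=["chain", "v_family", "cdr3_a", "cdr3_b"]).to_csv(
        edges_path, sep="\t", index=False
    )
    node_rows = [
        {
            "chain": c.chain,
            "v_family": c.v_family,
            "cdr3_aa": c.cdr3_aa,
            "alleles": ",".join(g.nodes[c]["alleles"]),
            "component": g.nodes[c]["component"],
            "purity": g.nodes[c]["purity"],
            "epitopes": ",".join(g.nodes[c].get("epitopes", ())),
        }
        for c in sorted(g.nodes, key=lambda c: (c.chain, c.v_family, c.cdr3_aa))
    ]
    pd.DataFrame(
        node_rows,
        columns=["chain", "v_family", "cdr3_aa", "alleles", "component", "purity", "epitopes"],
    ).to_csv(nodes_path, sep="\t", index=False)
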