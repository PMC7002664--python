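"""Structure-function characterization of selected motifs.

Significant motifs are compared by Hamming distance, grouped by
average-linkage hierarchical clustering (tree cut so that members of a
cluster share more than 75% identity), summarized per cluster as a
position weight matrix with per-position information content, and laid
out as a single-mutation network: nodes are motifs, edges connect motifs
differing at exactly one position, and Girvan-Newman edge-betweenness
communities expose families of related switches whose fold changes can be
compared within and between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "hamming",
    "distance_matrix",
    "DistanceMatrix",
    "MotifCluster",
    "cluster_motifs",
    "pwm",
    "build_network",
    "communities",
    "community_summary",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
IDENTITY_THRESHOLD = 0.75
_CUT_EPS = 1e-9


def hamming(m1: str, m2: str) -> int:
    """Number of mismatching positions between equal-length motifs."""
    if len(m1) != len(m2):
        raise ValueError(f"length mismatch: {len(m1)} vs {len(m2)}")
    return sum(a != b for a, b in zip(m1, m2))


def _encode(motifs: list[str]) -> np.ndarray:
    length = len(motifs[0])
    if any(len(m) != length for m in motifs):
        raise ValueError("motifs have mixed lengths")
    out = np.empty((len(motifs), length), dtype=np.uint8)
    for i, m in enumerate(motifs):
        try:
            out[i] = [_BASE_INDEX[b] for b in m]
        except KeyError as exc:
            raise ValueError(f"invalid base in motif {m!r}") from exc
    return out


@dataclass
class DistanceMatrix:
    """Pairwise normalized Hamming distances (mismatches / length)."""

    motifs: list[str]
    values: np.ndarray  # square, symmetric, zero diagonal

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.motifs, columns=self.motifs).to_csv(
            path, sep="\t", index_label="motif"
        )


def distance_matrix(motifs) -> DistanceMatrix:
    motifs = list(motifs)
    if not motifs:
        raise ValueError("no motifs")
    if len(motifs) == 1:
        return DistanceMatrix(motifs, np.zeros((1, 1)))
    enc = _encode(motifs)
    d = squareform(pdist(enc, metric="hamming"))
    return DistanceMatrix(motifs, d)


@dataclass
class MotifCluster:
    """A group of >75%-identical motifs with its PWM and IC profile."""

    members: list[str]
    pwm: np.ndarray  # positions x 4, columns sum to 1
    information_content: np.ndarray  # bits per position, in [0, 2]


def pwm(members, pseudocount: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Position weight matrix and information content of a motif set.

    Per position j: p_jb = (count_jb + pseudocount) / sum_b(...), and
    IC_j = 2 + sum_b p_jb log2 p_jb bits (0 log 0 := 0).
    """
    members = list(members)
    if not members:
        raise ValueError("empty cluster")
    enc = _encode(members)
    length = enc.shape[1]
    counts = np.zeros((length, 4))
    for j in range(length):
        counts[j] = np.bincount(enc[:, j], minlength=4)
    counts += pseudocount
    probs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    return probs, np.clip(ic, 0.0, 2.0)


def cluster_motifs(
    motifs, identity_threshold: float = IDENTITY_THRESHOLD, pseudocount: float = 0.0
) -> list[MotifCluster]:
    """Average-linkage clustering on normalized Hamming distance.

    The tree is cut so that merged clusters share strictly more than
    ``identity_threshold`` identity (identity = 1 - normalized distance).
    Deterministic: motifs are ordered lexicographically before linkage,
    and clusters are returned largest-first, then by first member.
    """
    motifs = sorted(set(motifs))
    if not motifs:
        raise ValueError("no motifs")
    if len(motifs) == 1:
        p, ic = pwm(motifs, pseudocount)
        return [MotifCluster(motifs, p, ic)]
    enc = _encode(motifs)
    d = pdist(enc, metric="hamming")
    z = linkage(d, method="average")
    cut = (1.0 - identity_threshold) - _CUT_EPS
    labels = fcluster(z, t=cut, criterion="distance")
    out: list[MotifCluster] = []
    for lab in np.unique(labels):
        members = [m for m, l in zip(motifs, labels) if l == lab]
        p, ic = pwm(members, pseudocount)
        out.append(MotifCluster(members, p, ic))
    out.sort(key=lambda c: (-len(c.members), c.members[0]))
    return out


def write_pwm_jaspar(clusters: list[MotifCluster], path: str | Path) -> None:
    """Plain-text JASPAR-style probability matrices, one block per cluster."""
    with open(path, "w") as fh:
        for i, cl in enumerate(clusters, start=1):
            fh.write(f">cluster{i} n={len(cl.members)}\n")
            for bi, base in enumerate(BASES):
                row = " ".join(f"{cl.pwm[j, bi]:.4f}" for j in range(cl.pwm.shape[0]))
                fh.write(f"{base}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# single-mutation network
# ---------------------------------------------------------------------------

def build_network(motifs_with_lfc: dict | pd.Series) -> nx.Graph:
    """Graph of motifs with edges at Hamming distance exactly 1.

    ``motifs_with_lfc`` maps motif -> log2FC (stored as node attribute).
    Isolated nodes are retained; duplicate motifs collapse with a warning.
    Motifs are indexed by (length-1)-mer wildcards so construction is
    O(n * L) rather than all-pairs.
    """
    if isinstance(motifs_with_lfc, pd.Series):
        items = list(motifs_with_lfc.items())
    else:
        items = list(motifs_with_lfc.items())
    seen: dict[str, float] = {}
    for motif, lfc in items:
        if motif in seen:
            warnings.warn(f"duplicate motif {motif!r} collapsed")
        seen[motif] = float(lfc)
    g = nx.Graph()
    for motif, lfc in seen.items():
        g.add_node(motif, log2fc=lfc)
    buckets: dict[tuple[int, str], list[str]] = {}
    for motif in seen:
        for j in range(len(motif)):
            buckets.setdefault((j, motif[:j] + motif[j + 1 :]), []).append(motif)
    for group in buckets.values():
        group.sort()
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if a != b:
                    g.add_edge(a, b)
    return g


def _most_central_edge(g: nx.Graph):
    centrality = nx.edge_betweenness_centrality(g)
    # deterministic tie-break: lexicographically smallest among the maxima
    best = max(centrality.values())
    cands = sorted(e for e, c in centrality.items() if c >= best - 1e-12)
    return cands[0]


def communities(g: nx.Graph) -> list[set[str]]:
    """Girvan-Newman partition maximizing modularity over the removal path.

    Edges with maximal betweenness are removed iteratively (ties broken
    lexicographically); among all partitions visited -- starting from the
    connected components of the input graph -- the one with the highest
    modularity is returned.  Graphs without edges decompose into singleton
    communities; the empty graph gives an empty partition.
    """
    if g.number_of_nodes() == 0:
        return []
    if g.number_of_edges() == 0:
        return [{n} for n in sorted(g.nodes)]
    base = [set(c) for c in nx.connected_components(g)]
    best, best_q = base, nx.community.modularity(g, base)
    for part in nx.community.girvan_newman(g, most_valuable_edge=_most_central_edge):
        q = nx.community.modularity(g, part)
        if q > best_q + 1e-12:
            best, best_q = [set(c) for c in part], q
    return sorted(best, key=min)


def community_summary(g: nx.Graph, partition: list[set[str]]) -> pd.DataFrame:
    """Per-community size and mean log2FC of member motifs."""
    rows = []
    for i, comm in enumerate(partition, start=1):
        lfcs = [g.nodes[m].get("log2fc", np.nan) for m in comm]
        rows.append(
            {
                "community": i,
                "size": len(comm),
                "mean_log2fc": float(np.nanmean(lfcs)) if lfcs else np.nan,
                "members": ",".join(sorted(comm)),
            }
        )
    return pd.DataFrame(rows)


def write_network(g: nx.Graph, graphml_path: str | Path, edges_path: str | Path) -> None:
    """GraphML plus an edge-list TSV with per-node log2FC attributes."""
    nx.write_graphml(g, graphml_path)
    with open(edges_path, "w") as fh:
        fh.write("motif_a\tmotif_b\tlog2fc_a\tlog2fc_b\n")
        for a, b in sorted(g.edges):
            fh.write(
                f"{a}\t{b}\t{g.nodes[a].get('log2fc', '')}\t{g.nodes[b].get('log2fc', '')}\n"
            )
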