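"""CDR3 similarity clustering: Hamming-1 candidate hashing + Markov clustering.

Unique (locus, V gene, CDR3) items are compared within a chain class only; an
edge joins two items whose CDR3s have equal length and Hamming distance at
most one.  Candidate pairs are found with a wildcard-hashing scheme that never
materializes the quadratic all-pairs comparison, and communities are read out
of the similarity graph with the Markov clustering (MCL) algorithm.  Clusters
are summarized by their modal V/J name and a per-position residue-frequency
motif.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .repertoire_io import Repertoire

#: Chain-class code per locus; clustering never mixes classes.
LOCUS_TO_CHAIN = {"TRA": "A", "TRB": "B", "TRG": "G", "TRD": "D"}


@dataclass(frozen=True)
class SequenceItem:
    """One unique (locus, v_gene, cdr3) combination with its cell multiplicity."""

    item_id: int
    v_gene: str
    j_gene: str
    cdr3_aa: str
    locus: str
    multiplicity: int = 1

    @property
    def chain(self) -> str:
        return LOCUS_TO_CHAIN[self.locus]


@dataclass
class SimilarityGraph:
    """Undirected graph over item ids; edges are Hamming-distance-<=1 pairs."""

    nodes: List[int]
    edges: List[Tuple[int, int]]

    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class CDR3Cluster:
    cluster_id: int
    member_ids: List[int]
    name: str
    junction_length: int
    chain: str
    #: per-position residue relative frequencies; columns sum to 1
    motif: List[Dict[str, float]] = field(default_factory=list)
    consensus: str = ""


# ---------------------------------------------------------------------------
# Hamming-1 candidate detection by hashing
# ---------------------------------------------------------------------------


def hamming_pairs(items: Sequence[SequenceItem], require_same_v: bool = False) -> SimilarityGraph:
    """All pairs of items whose CDR3s are equal length and Hamming distance <= 1.

    For a sequence of length L we emit L wildcard keys (one position masked)
    plus the exact sequence key; items sharing a key are candidates, verified
    by a direct Hamming check.  Expected cost is linear in total sequence
    length.  Identical CDR3s carried by different V genes are distinct items
    joined at distance 0.  With ``require_same_v`` edges are additionally
    restricted to items sharing a V gene.
    """
    if not items:
        return SimilarityGraph(nodes=[], edges=[])
    chains = {it.chain for it in items}
    if len(chains) > 1:
        raise ValueError(f"hamming_pairs expects a single chain class, got {sorted(chains)}")

    buckets: Dict[Tuple[int, int, str], List[int]] = defaultdict(list)
    for idx, it in enumerate(items):
        s = it.cdr3_aa
        L = len(s)
        buckets[(L, -1, s)].append(idx)  # exact key: catches distance-0 pairs
        for pos in range(L):
            buckets[(L, pos, s[:pos] + s[pos + 1:])].append(idx)

    edges = set()
    for bucket in buckets.values():
        if len(bucket) < 2:
            continue
        for i_pos, i in enumerate(bucket):
            si = items[i].cdr3_aa
            for j in bucket[i_pos + 1:]:
                if require_same_v and items[i].v_gene != items[j].v_gene:
                    continue
                sj = items[j].cdr3_aa
                mism = sum(a != b for a, b in zip(si, sj))
                if mism <= 1:
                    a, b = items[i].item_id, items[j].item_id
                    if a != b:
                        edges.add((min(a, b), max(a, b)))
    return SimilarityGraph(nodes=[it.item_id for it in items], edges=sorted(edges))


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


def mcl_partition(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    prune_tol: float = 1e-5,
    conv_tol: float = 1e-8,
):
    """Markov clustering on the similarity graph.

    The adjacency matrix with self-loops is column-normalized into a stochastic
    matrix, then alternately expanded (matrix power) and inflated (element-wise
    power followed by column renormalization), pruning entries below
    ``prune_tol``, until the matrix stops changing.  Each node is assigned to
    the attractor holding the largest mass in its column (ties to the smallest
    attractor id).  Returns ``(clusters, singletons)`` where clusters are the
    attractor groups of size >= 2.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        return [], []
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, data = [], [], []
    for a, b in graph.edges:
        if a == b:
            raise ValueError("self-edges are not allowed in the similarity graph")
        ia, ib = index[a], index[b]
        rows += [ia, ib]
        cols += [ib, ia]
        data += [1.0, 1.0]
    rows += list(range(n))
    cols += list(range(n))
    data += [1.0] * n
    m = sp.csc_matrix((data, (rows, cols)), shape=(n, n))

    def normalize(mat):
        colsum = np.asarray(mat.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        return mat @ sp.diags(1.0 / colsum)

    m = normalize(m)
    for _ in range(max_iter):
        expanded = m
        for _ in range(expansion - 1):
            expanded = expanded @ m
        inflated = expanded.copy()
        inflated.data = np.power(inflated.data, inflation)
        inflated.data[inflated.data < prune_tol] = 0.0
        inflated.eliminate_zeros()
        inflated = normalize(inflated)
        diff = abs(inflated - m)
        change = diff.max() if diff.nnz else 0.0
        m = inflated
        if change < conv_tol:
            break

    dense = m.toarray()
    assignment = {}
    for j in range(n):
        col = dense[:, j]
        best = col.max()
        attractor = int(np.flatnonzero(col == best)[0])  # smallest id on ties
        assignment[nodes[j]] = nodes[attractor]

    groups: Dict[int, List[int]] = defaultdict(list)
    for node, attractor in assignment.items():
        groups[attractor].append(node)
    clusters = [sorted(g) for g in groups.values() if len(g) >= 2]
    clusters.sort(key=lambda g: g[0])
    singletons = sorted(node for a, g in groups.items() if len(g) == 1 for node in g)
    return clusters, singletons


# ---------------------------------------------------------------------------
# cluster summarization
# ---------------------------------------------------------------------------


def build_clusters(
    partition: Iterable[List[int]],
    items: Sequence[SequenceItem],
    conserved_freq: float = 0.95,
) -> List[CDR3Cluster]:
    """Summarize each member set: modal V-J name, motif, consensus string.

    The name is the modal V gene plus modal J gene among members, weighted by
    cell multiplicity (ties broken lexicographically).  The motif records
    per-position residue relative frequencies; in the consensus, positions
    whose top residue reaches ``conserved_freq`` are uppercase, others are the
    lowercase majority residue.
    """
    by_id = {it.item_id: it for it in items}
    clusters = []
    for cid, member_ids in enumerate(partition):
        members = [by_id[i] for i in member_ids]
        if len(members) < 2:
            raise ValueError("clusters must have at least 2 members")
        lengths = {len(m.cdr3_aa) for m in members}
        chains = {m.chain for m in members}
        if len(lengths) != 1 or len(chains) != 1:
            raise AssertionError(
                "cluster invariant violated: members must share junction length and chain"
            )
        L = lengths.pop()

        def modal(attr: str) -> str:
            weights: Counter = Counter()
            for m in members:
                weights[getattr(m, attr)] += m.multiplicity
            top = max(weights.values())
            return min(g for g, w in weights.items() if w == top)

        total = sum(m.multiplicity for m in members)
        motif = []
        consensus = []
        for pos in range(L):
            freqs: Counter = Counter()
            for m in members:
                freqs[m.cdr3_aa[pos]] += m.multiplicity
            col = {aa: w / total for aa, w in sorted(freqs.items())}
            motif.append(col)
            top_aa = min(a for a, f in col.items() if f == max(col.values()))
            consensus.append(top_aa if col[top_aa] >= conserved_freq else top_aa.lower())
        clusters.append(
            CDR3Cluster(
                cluster_id=cid,
                member_ids=sorted(member_ids),
                name=f"{modal('v_gene')} {modal('j_gene')}",
                junction_length=L,
                chain=members[0].chain,
                motif=motif,
                consensus="".join(consensus),
            )
        )
    return clusters


def cluster_chain_split(repertoire: Repertoire) -> Dict[str, List[SequenceItem]]:
    """Deduplicated per-chain item lists (A, B, G, D) with cell multiplicities.

    Each resolved clonotype contributes its AG chain to the A or G list and its
    BD chain to the B or D list; cells sharing (locus, v_gene, cdr3) collapse
    into a single item whose multiplicity counts them.
    """
    counters: Dict[str, Counter] = {c: Counter() for c in "ABGD"}
    j_genes: Dict[Tuple[str, str, str], str] = {}
    for clone in repertoire.clonotypes:
        for ch in (clone.chain_ag, clone.chain_bd):
            if ch is None or not ch.cdr3_aa:
                continue
            key = (ch.locus, ch.v_gene, ch.cdr3_aa)
            counters[LOCUS_TO_CHAIN[ch.locus]][key] += 1
            j_genes.setdefault(key, ch.j_gene)
    out: Dict[str, List[SequenceItem]] = {}
    next_id = 0
    for chain in "ABGD":
        items = []
        for key in sorted(counters[chain]):
            locus, v_gene, cdr3 = key
            items.append(
                SequenceItem(
                    item_id=next_id,
                    v_gene=v_gene,
                    j_gene=j_genes[key],
                    cdr3_aa=cdr3,
                    locus=locus,
                    multiplicity=counters[chain][key],
                )
            )
            next_id += 1
        out[chain] = items
    return out


def cluster_chain(
    items: Sequence[SequenceItem],
    inflation: float = 2.0,
    require_same_v: bool = False,
) -> Tuple[List[CDR3Cluster], List[int]]:
    """Convenience: hash candidate pairs, run MCL, summarize clusters."""
    graph = hamming_pairs(items, require_same_v=require_same_v)
    partition, singletons = mcl_partition(graph, inflation=inflation)
    return build_clusters(partition, items), singletons
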