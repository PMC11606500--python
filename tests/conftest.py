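"""Shared fixtures: miniature models, synthetic inputs, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

import tcrfirst as tf
from tcrfirst.neighbor_enrichment import AMINO_ACIDS


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture()
def mini_model():
    """2V x 2J model with inserts <= 1 and trims <= 1: exactly enumerable."""
    return tf.RecombinationModel(
        v_segments=[("TRBV1", 0.6, "CASS"), ("TRBV2", 0.4, "CASR")],
        j_segments=[("TRBJ1", 0.7, "EQYF"), ("TRBJ2", 0.3, "NTLYF")],
        insert_length_dist=np.array([0.5, 0.5]),
        insert_residue_dist=np.full(20, 0.05),
        trim_dist=np.array([0.8, 0.2]),
        min_length=5,
    )


@pytest.fixture()
def degenerate_model():
    """Single V and J, no trims, no inserts: emits exactly one junction."""
    return tf.RecombinationModel(
        v_segments=[("TRBV20-1", 1.0, "CASS")],
        j_segments=[("TRBJ1-1", 1.0, "EQYF")],
        insert_length_dist=np.array([1.0]),
        insert_residue_dist=np.full(20, 0.05),
        trim_dist=np.array([1.0]),
        min_length=5,
    )


def random_cdr3(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def brute_force_hamming_edges(items):
    """O(n^2) oracle for the Hamming<=1 candidate graph."""
    edges = set()
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i], items[j]
            if len(a.cdr3_aa) != len(b.cdr3_aa):
                continue
            if sum(x != y for x, y in zip(a.cdr3_aa, b.cdr3_aa)) <= 1:
                edges.add((min(a.item_id, b.item_id), max(a.item_id, b.item_id)))
    return edges


def reference_mcl(edges, nodes, inflation=2.0, expansion=2, max_iter=100,
                  prune_tol=1e-5):
    """Independent dense-matrix MCL used as an oracle against the sparse one."""
    nodes = sorted(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.eye(n)
    for a, b in edges:
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = 1.0
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = expanded ** inflation
        inflated[inflated < prune_tol] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - m).max() < 1e-8:
            m = inflated
            break
        m = inflated
    groups = {}
    for j in range(n):
        attractor = int(np.flatnonzero(m[:, j] == m[:, j].max())[0])
        groups.setdefault(nodes[attractor], []).append(nodes[j])
    clusters = sorted(sorted(g) for g in groups.values() if len(g) >= 2)
    return clusters


def make_items(seqs, locus="TRB", v_gene="TRBV1", j_gene="TRBJ1"):
    """SequenceItems over one chain; seqs may be strings or (v, seq) pairs."""
    items = []
    for i, s in enumerate(seqs):
        v, seq = s if isinstance(s, tuple) else (v_gene, s)
        items.append(
            tf.SequenceItem(item_id=i, v_gene=v, j_gene=j_gene, cdr3_aa=seq,
                            locus=locus, multiplicity=1)
        )
    return items
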